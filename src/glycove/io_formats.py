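"""Readers and writers for the external table formats.

This module holds the domain containers (PSM records, per-dataset spectral
count tables, cluster-median expression matrices) and the parsing/serialising
code around them.  It contains no scientific logic: filtering, scoring and
enrichment live in their own modules.

PSM tables follow the MSFragger ``psm.tsv`` dialect: tab-separated with a
header row, one peptide-spectrum match per line, compact modification tokens
such as ``5N(0.9840)`` (1-based position within the peptide, residue letter,
mass delta in Da), and decoy proteins flagged by an accession prefix
(default ``rev_``).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence
import warnings

import numpy as np
import pandas as pd

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

SPECIES = ("rat", "mouse")
CONDITIONS = ("oxy", "ctl", "lysate", "cell_surface")
PROTEASES = ("trypsin", "chymotrypsin")

#: Default header names for the MSFragger psm.tsv dialect; every name can be
#: overridden through the ``columns`` argument of :func:`read_psm_table`
#: (the probability column in particular varies between exports).
DEFAULT_PSM_COLUMNS: Mapping[str, str] = {
    "spectrum": "Spectrum",
    "peptide": "Peptide",
    "modifications": "Assigned Modifications",
    "protein": "Protein",
    "mapped_proteins": "Mapped Proteins",
    "probability": "Protein Probability",
}

_MOD_TOKEN = re.compile(r"^(\d+)([A-Z])\(([-+]?\d*\.?\d+)\)$")


class FormatError(ValueError):
    """A file does not conform to the expected table dialect."""


@dataclass(frozen=True)
class Modification:
    """One variable modification on a peptide (position is 1-based)."""

    position: int
    residue: str
    mass_delta: float


@dataclass
class PSMRecord:
    """One peptide-spectrum match from a search-engine output table."""

    spectrum_id: str
    peptide: str
    modifications: list[Modification]
    proteins: list[str]
    protein_probability: float
    is_decoy: bool
    experiment_id: str = ""
    protease: str = "trypsin"

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValueError("peptide must be non-empty")
        bad = set(self.peptide) - AMINO_ACIDS
        if bad:
            raise ValueError(f"non-standard residues in peptide: {sorted(bad)}")
        if self.protease not in PROTEASES:
            raise ValueError(f"unknown protease {self.protease!r}")
        for mod in self.modifications:
            if not 1 <= mod.position <= len(self.peptide):
                raise ValueError(
                    f"modification position {mod.position} outside peptide "
                    f"of length {len(self.peptide)}"
                )
            if self.peptide[mod.position - 1] != mod.residue:
                raise ValueError(
                    f"modification residue {mod.residue!r} does not match "
                    f"peptide letter {self.peptide[mod.position - 1]!r} at "
                    f"position {mod.position}"
                )


@dataclass
class ProteinCountTable:
    """Per-dataset map of gene symbol -> spectral count with metadata."""

    dataset_id: str
    species: str
    condition: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        for gene, count in self.counts.items():
            if count < 0:
                raise ValueError(f"negative spectral count for {gene!r}")
        if self.counts and self.total() == 0:
            raise ValueError("non-empty count table with zero total count")

    def total(self) -> int:
        return int(sum(self.counts.values()))

    def genes(self) -> set[str]:
        return set(self.counts)


@dataclass
class ClusterExpression:
    """Gene x labeled-cluster matrix of median expression values."""

    genes: list[str]
    clusters: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.clusters)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.clusters)} clusters"
            )
        if len(set(self.clusters)) != len(self.clusters):
            raise FormatError("duplicated cluster label")
        if np.isnan(self.values).any():
            raise FormatError("missing expression value (no imputation)")
        if (self.values < 0).any():
            raise ValueError("negative expression value")


def parse_modification_field(text: str) -> list[Modification]:
    """Parse a compact modification field like ``"5N(0.9840), 3M(15.9949)"``.

    An empty or all-whitespace field means no modifications.
    """
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return []
    text = str(text).strip()
    if not text:
        return []
    mods = []
    for token in text.split(","):
        token = token.strip()
        if not token:
            continue
        m = _MOD_TOKEN.match(token)
        if m is None:
            raise FormatError(f"unparsable modification token {token!r}")
        mods.append(Modification(int(m.group(1)), m.group(2), float(m.group(3))))
    return mods


def format_modification_field(mods: Sequence[Modification]) -> str:
    return ", ".join(f"{m.position}{m.residue}({m.mass_delta:.4f})" for m in mods)


def _split_proteins(primary: str, mapped: str | float | None) -> list[str]:
    proteins = [str(primary).strip()]
    if mapped is not None and not (isinstance(mapped, float) and np.isnan(mapped)):
        for acc in str(mapped).split(","):
            acc = acc.strip()
            if acc and acc not in proteins:
                proteins.append(acc)
    return proteins


def read_psm_table(
    path: str | Path,
    decoy_prefix: str = "rev_",
    protease: str = "trypsin",
    columns: Mapping[str, str] | None = None,
    experiment_id: str | None = None,
) -> list[PSMRecord]:
    """Read one MSFragger-dialect PSM table into a list of records.

    A PSM is a decoy iff any of its mapped protein accessions starts with
    ``decoy_prefix``.  Column names are resolved through ``columns`` (see
    :data:`DEFAULT_PSM_COLUMNS`); the reader is insensitive to column order.
    """
    names = dict(DEFAULT_PSM_COLUMNS)
    if columns:
        names.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for key in ("peptide", "modifications", "protein", "probability"):
        if names[key] not in df.columns:
            raise FormatError(f"missing required column {names[key]!r}")
    exp = experiment_id if experiment_id is not None else Path(path).stem
    has_spectrum = names["spectrum"] in df.columns
    has_mapped = names["mapped_proteins"] in df.columns
    records: list[PSMRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        try:
            mods = parse_modification_field(row[names["modifications"]])
        except FormatError as err:
            raise FormatError(f"row {i}: {err}") from err
        proteins = _split_proteins(
            row[names["protein"]], row[names["mapped_proteins"]] if has_mapped else None
        )
        records.append(
            PSMRecord(
                spectrum_id=str(row[names["spectrum"]]) if has_spectrum else f"{exp}.{i}",
                peptide=str(row[names["peptide"]]).strip().upper(),
                modifications=mods,
                proteins=proteins,
                protein_probability=float(row[names["probability"]]),
                is_decoy=any(p.startswith(decoy_prefix) for p in proteins),
                experiment_id=exp,
                protease=protease,
            )
        )
    return records


def write_psm_table(
    records: Iterable[PSMRecord],
    path: str | Path,
    columns: Mapping[str, str] | None = None,
) -> None:
    """Write records back to the tab-separated PSM dialect."""
    names = dict(DEFAULT_PSM_COLUMNS)
    if columns:
        names.update(columns)
    rows = []
    for r in records:
        rows.append(
            {
                names["spectrum"]: r.spectrum_id,
                names["peptide"]: r.peptide,
                names["modifications"]: format_modification_field(r.modifications),
                names["protein"]: r.proteins[0],
                names["mapped_proteins"]: ", ".join(r.proteins[1:]),
                names["probability"]: repr(r.protein_probability),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            names["spectrum"],
            names["peptide"],
            names["modifications"],
            names["protein"],
            names["mapped_proteins"],
            names["probability"],
        ],
    ).to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> set[str]:
    """Read a plain-text gene list (one symbol per line) into an uppercase set."""
    symbols = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            symbols.add(line.upper())
    if not symbols:
        warnings.warn(f"gene list {path} is empty", stacklevel=2)
    return symbols


def read_gene_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping (accession or symbol -> gene symbol)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise FormatError("gene map must have two tab-separated columns")
    return dict(zip(df.iloc[:, 0].str.strip(), df.iloc[:, 1].str.strip().str.upper()))


def read_cluster_csv(path: str | Path) -> ClusterExpression:
    """Read a gene x cluster median-expression CSV.

    The first column carries gene identifiers; every remaining column is one
    labeled cluster.  Cells must be numeric and present; cluster labels must
    be unique.  Labels are preserved verbatim.
    """
    with open(path) as fh:
        header = next(csv.reader(fh))[1:]
    seen = set()
    for label in header:  # pandas would silently mangle duplicates
        if label in seen:
            raise FormatError(f"duplicated cluster label {label!r}")
        seen.add(label)
    df = pd.read_csv(path, index_col=0)
    df.columns = header
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.argmax()]
            raise FormatError(f"non-numeric expression cell at ({gene!r}, {col!r})")
        if converted.isna().any():
            gene = df.index[converted.isna().argmax()]
            raise FormatError(f"missing expression cell at ({gene!r}, {col!r})")
        values[:, j] = converted.to_numpy()
    return ClusterExpression(
        genes=[str(g) for g in df.index],
        clusters=[str(c) for c in df.columns],
        values=values,
    )


def write_cluster_csv(expr: ClusterExpression, path: str | Path) -> None:
    pd.DataFrame(expr.values, index=expr.genes, columns=expr.clusters).to_csv(path)


def read_count_table(
    path: str | Path, dataset_id: str, species: str, condition: str
) -> ProteinCountTable:
    """Read a two-column TSV (gene, spectral_count) into a count table."""
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns or "spectral_count" not in df.columns:
        raise FormatError("count table needs 'gene' and 'spectral_count' columns")
    if df["gene"].duplicated().any():
        raise FormatError("duplicate gene symbol in count table")
    counts = {
        str(g).upper(): int(c) for g, c in zip(df["gene"], df["spectral_count"])
    }
    return ProteinCountTable(dataset_id, species, condition, counts)


def write_count_table(table: ProteinCountTable, path: str | Path) -> None:
    df = pd.DataFrame(
        sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["gene", "spectral_count"],
    )
    df.to_csv(path, sep="\t", index=False)
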