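"""Glycopeptide-specific PSM filtering and decoy-based protein FDR control.

PNGase F releases an N-linked glycan by converting the glycosylated
asparagine to aspartate, which the search engine reports as a deamidation
(+0.984 Da) on N.  A genuine formerly-glycosylated peptide must therefore
carry at least one consensus N-glycosylation sequon, N-X-S/T/C with X != P,
and between 1 and x deamidated asparagines where x is the number of sequons
on the peptide.  PSMs failing either condition are discarded.  The surviving
proteins are then thresholded on their ProteinProphet-style probability so
that the decoy-estimated FDR stays below a configured bound.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence
import warnings

from .io_formats import AMINO_ACIDS, PSMRecord, ProteinCountTable

DEAMIDATION_MASS = 0.9840
#: Search engines print rounded masses; match the deamidation delta loosely.
DEAMIDATION_TOLERANCE = 0.01
#: Probability thresholds tried for protein-level FDR control.
DEFAULT_CANDIDATE_THRESHOLDS = (0.75, 0.80)

# Lookahead so overlapping sequons (e.g. N-N-C-S) are all reported.
_SEQUON = re.compile(r"(?=N[^P][STC])")


@dataclass(frozen=True)
class SequonSet:
    """All consensus N-glycosylation motif start positions on one peptide."""

    peptide: str
    positions: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class ProteinRow:
    """One protein entering or leaving the FDR filter."""

    accession: str
    gene: str
    score: float
    is_decoy: bool
    spectral_count: int


@dataclass
class FilteredProteinList:
    """Target proteins retained at the selected probability threshold."""

    proteins: list[ProteinRow]
    threshold: float
    achieved_fdr: float
    fdr_bound: float = 0.01
    n_decoys_retained: int = 0


def find_sequons(peptide: str) -> SequonSet:
    """Locate every N-X(!P)-S/T/C motif start (0-based) on a peptide.

    Overlapping motifs are all counted; a motif truncated by the peptide end
    (N or N-X at the C-terminus) is not.
    """
    bad = set(peptide) - AMINO_ACIDS
    if bad or not peptide:
        raise ValueError(f"invalid peptide {peptide!r}")
    positions = tuple(m.start() for m in _SEQUON.finditer(peptide))
    return SequonSet(peptide=peptide, positions=positions)


def count_deamidated_N(psm: PSMRecord, tolerance: float = DEAMIDATION_TOLERANCE) -> int:
    """Number of deamidated asparagines on a PSM, anywhere in the peptide."""
    return sum(
        1
        for m in psm.modifications
        if m.residue == "N" and abs(m.mass_delta - DEAMIDATION_MASS) <= tolerance
    )


def passes_glyco_filter(psm: PSMRecord) -> bool:
    x = len(find_sequons(psm.peptide))
    if x < 1:
        return False
    return 1 <= count_deamidated_N(psm) <= x


def filter_psms(psms: Iterable[PSMRecord]) -> list[PSMRecord]:
    """Keep PSMs with >=1 sequon and a deamidated-N count in 1..x (x = #sequons)."""
    return [p for p in psms if passes_glyco_filter(p)]


def razor_assign(psms: Sequence[PSMRecord]) -> list[str]:
    """Assign each PSM to a single protein (razor rule).

    Proteins are ranked by the total number of PSMs that list them
    (ties broken by accession); each shared PSM counts only for its
    top-ranked candidate, preventing double counting in CPM totals.
    """
    support: dict[str, int] = {}
    for p in psms:
        for acc in p.proteins:
            support[acc] = support.get(acc, 0) + 1
    return [min(p.proteins, key=lambda a: (-support[a], a)) for p in psms]


def summarize_proteins(
    psms: Sequence[PSMRecord], gene_map: Mapping[str, str] | None = None
) -> list[ProteinRow]:
    """Collapse PSMs to per-protein rows (razor counts, max probability)."""
    assignment = razor_assign(psms)
    rows: dict[str, ProteinRow] = {}
    for psm, acc in zip(psms, assignment):
        row = rows.get(acc)
        if row is None:
            rows[acc] = ProteinRow(
                accession=acc,
                gene=_gene_for(acc, gene_map),
                score=psm.protein_probability,
                is_decoy=psm.is_decoy,
                spectral_count=1,
            )
        else:
            row.spectral_count += 1
            row.score = max(row.score, psm.protein_probability)
    return sorted(rows.values(), key=lambda r: r.accession)


def _gene_for(accession: str, gene_map: Mapping[str, str] | None) -> str:
    if gene_map is not None:
        if accession in gene_map:
            return gene_map[accession]
        warnings.warn(f"accession {accession!r} missing from gene map", stacklevel=3)
    return accession


def protein_fdr_filter(
    proteins: Sequence[ProteinRow],
    fdr_bound: float = 0.01,
    candidate_thresholds: Sequence[float] = DEFAULT_CANDIDATE_THRESHOLDS,
) -> FilteredProteinList:
    """Select the smallest probability threshold keeping the decoy FDR below bound.

    The FDR estimate is decoys-retained / targets-retained at each candidate
    threshold (score >= threshold); the conservative count after decoys are
    removed from the report.  If no candidate qualifies, the result is empty
    and carries the FDR achieved at the strictest threshold.  Zero retained
    targets is an explicit "no identifications" result (FDR reported as inf
    when decoys remain, 0 otherwise), not an exception.
    """
    if not 0 < fdr_bound < 1:
        raise ValueError("fdr_bound must be in (0, 1)")
    if not candidate_thresholds:
        raise ValueError("need at least one candidate threshold")
    thresholds = sorted(candidate_thresholds)
    last_fdr = None
    for thr in thresholds:
        retained = [p for p in proteins if p.score >= thr]
        targets = [p for p in retained if not p.is_decoy]
        n_decoys = len(retained) - len(targets)
        if targets:
            fdr = n_decoys / len(targets)
        else:
            fdr = float("inf") if n_decoys else 0.0
        last_fdr = (thr, fdr, targets, n_decoys)
        if fdr < fdr_bound:
            return FilteredProteinList(
                proteins=sorted(targets, key=lambda r: (-r.spectral_count, r.accession)),
                threshold=thr,
                achieved_fdr=fdr,
                fdr_bound=fdr_bound,
                n_decoys_retained=n_decoys,
            )
    thr, fdr, _, n_decoys = last_fdr
    return FilteredProteinList(
        proteins=[], threshold=thr, achieved_fdr=fdr, fdr_bound=fdr_bound,
        n_decoys_retained=n_decoys,
    )


def aggregate_proteins(
    psms: Sequence[PSMRecord],
    dataset_id: str,
    species: str,
    condition: str,
    gene_map: Mapping[str, str] | None = None,
    retained_accessions: Iterable[str] | None = None,
) -> ProteinCountTable:
    """Spectral-count table from filtered PSMs (razor assignment).

    When ``retained_accessions`` is given (the FDR-filtered protein list),
    PSMs razor-assigned to other proteins are dropped.
    """
    assignment = razor_assign(psms)
    keep = set(retained_accessions) if retained_accessions is not None else None
    counts: dict[str, int] = {}
    for acc in assignment:
        if keep is not None and acc not in keep:
            continue
        gene = _gene_for(acc, gene_map)
        counts[gene] = counts.get(gene, 0) + 1
    return ProteinCountTable(dataset_id, species, condition, counts)
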