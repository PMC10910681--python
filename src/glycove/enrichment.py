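"""CPM normalisation and the Vessel Enrichment (VE) score.

Spectral counts are converted to counts-per-million (CPM) within each
dataset so that datasets of different depth are comparable.  The VE score of
a protein is CPM(in vivo glycocapture) - CPM(brain-lysate glycocapture): a
positive score means the protein is relatively more abundant in the perfused
vessel dataset than in whole brain.  Cross-species scores are combined by
normalising each species' VE values to that species' median VE and summing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ProteinCountTable


@dataclass
class VERow:
    gene: str
    cpm_vessel: float
    cpm_lysate: float
    ve: float
    rank: int = 0
    percentile: float = float("nan")


@dataclass
class VETable:
    """Per-gene VE scores for one species (or the combined-species table)."""

    species: str  # rat, mouse, or combined
    rows: dict[str, VERow] = field(default_factory=dict)

    def ve(self, gene: str) -> float:
        return self.rows[gene].ve

    def median_ve(self) -> float:
        return float(np.median([r.ve for r in self.rows.values()]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene": r.gene,
                    "cpm_vessel": r.cpm_vessel,
                    "cpm_lysate": r.cpm_lysate,
                    "ve": r.ve,
                    "rank": r.rank,
                    "percentile": r.percentile,
                }
                for r in sorted(self.rows.values(), key=lambda r: r.rank)
            ]
        )


def to_cpm(counts: ProteinCountTable) -> dict[str, float]:
    """Spectral counts scaled to a per-dataset total of 1e6."""
    total = counts.total()
    if total == 0:
        raise ValueError(f"empty count table {counts.dataset_id!r}: cannot compute CPM")
    return {g: c / total * 1e6 for g, c in counts.counts.items()}


def vessel_enrichment(
    cpm_vessel: dict[str, float], cpm_lysate: dict[str, float], species: str = "rat"
) -> VETable:
    """VE = CPM(vessel) - CPM(lysate) for every gene identified in the vessel set.

    Genes absent from the lysate dataset take CPM(lysate) = 0; genes found
    only in the lysate get no VE row (the table is indexed by the in vivo
    identification list).
    """
    table = VETable(species=species)
    for gene, cv in cpm_vessel.items():
        cl = cpm_lysate.get(gene, 0.0)
        table.rows[gene] = VERow(gene=gene, cpm_vessel=cv, cpm_lysate=cl, ve=cv - cl)
    return table


def combine_species(ve_rat: VETable, ve_mouse: VETable) -> VETable:
    """Median-normalised sum of per-species VE scores.

    combined(g) = ve_rat(g)/median_rat + ve_mouse(g)/median_mouse over genes
    identified in either species; a missing species contributes 0.  Gene
    symbols must already be harmonized between species.
    """
    if not ve_rat.rows or not ve_mouse.rows:
        raise ValueError("both species tables must be non-empty")
    med_rat, med_mouse = ve_rat.median_ve(), ve_mouse.median_ve()
    if med_rat == 0 or med_mouse == 0:
        raise ValueError(
            f"zero median VE (rat={med_rat}, mouse={med_mouse}): "
            "median normalisation undefined"
        )
    combined = VETable(species="combined")
    for gene in set(ve_rat.rows) | set(ve_mouse.rows):
        vr = ve_rat.rows.get(gene)
        vm = ve_mouse.rows.get(gene)
        score = (vr.ve / med_rat if vr else 0.0) + (vm.ve / med_mouse if vm else 0.0)
        combined.rows[gene] = VERow(
            gene=gene,
            cpm_vessel=(vr.cpm_vessel if vr else 0.0) + (vm.cpm_vessel if vm else 0.0),
            cpm_lysate=(vr.cpm_lysate if vr else 0.0) + (vm.cpm_lysate if vm else 0.0),
            ve=score,
        )
    return combined


def rank_percentile(table: VETable) -> VETable:
    """Fill ranks (1 = highest VE, ties by gene symbol) and percentiles.

    percentile = 100 * (N - rank) / N, so the top-ranked gene of N sits at
    100*(N-1)/N and the bottom-ranked at 0.
    """
    ordered = sorted(table.rows.values(), key=lambda r: (-r.ve, r.gene))
    n = len(ordered)
    for i, row in enumerate(ordered, start=1):
        row.rank = i
        row.percentile = 100.0 * (n - i) / n
    return table


def ve_subset(table: VETable, cutoff: float) -> set[str]:
    """Genes with VE strictly greater than the cutoff."""
    if not math.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    return {g for g, r in table.rows.items() if r.ve > cutoff}


def positive_fraction(table: VETable) -> float:
    """Fraction of genes with VE > 0 (headline summary of a VE table)."""
    if not table.rows:
        raise ValueError("empty VE table")
    return sum(1 for r in table.rows.values() if r.ve > 0) / len(table.rows)
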