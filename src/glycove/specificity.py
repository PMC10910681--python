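"""OXY/CTL specificity classification and per-species list compilation.

Glycocapture should only pull down proteins whose glycans were oxidised
during perfusion, so proteins identified in buffer-perfused control animals
(CTL) at spectral-count levels similar to the oxidised animals (OXY) are
treated as background binders and removed from the final identification
list.  Proteins found in both fractions but clearly higher in OXY (fold
>= 1.5 by default) are kept as oxidation-enriched.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .io_formats import ProteinCountTable


class SpecificityClass(str, Enum):
    OXY_ONLY = "oxy_only"
    OXY_ENRICHED = "oxy_enriched"
    BACKGROUND = "background"
    CTL_ONLY = "ctl_only"


@dataclass
class GeneSpecificity:
    gene: str
    classification: SpecificityClass
    oxy_count: int
    ctl_count: int
    fold_change: float  # inf when ctl_count == 0


@dataclass
class SpecificityReport:
    fold_cutoff: float
    genes: dict[str, GeneSpecificity]

    def of_class(self, cls: SpecificityClass) -> set[str]:
        return {g for g, s in self.genes.items() if s.classification is cls}


def classify_ctl_oxy(
    oxy: ProteinCountTable, ctl: ProteinCountTable, fold_cutoff: float = 1.5
) -> SpecificityReport:
    """Classify every gene in the OXY/CTL union by its spectral-count fold.

    Fold change is computed on raw spectral counts.  A gene absent from CTL
    is ``oxy_only``; present in both with fold >= cutoff is ``oxy_enriched``;
    present in both with fold < cutoff is ``background``; absent from OXY is
    ``ctl_only``.
    """
    if not oxy.counts:
        raise ValueError("empty OXY table: nothing to classify")
    if oxy.species != ctl.species:
        raise ValueError("OXY and CTL tables must come from the same species")
    if fold_cutoff <= 1:
        raise ValueError("fold_cutoff must be > 1")
    genes: dict[str, GeneSpecificity] = {}
    for gene in oxy.genes() | ctl.genes():
        o = oxy.counts.get(gene, 0)
        c = ctl.counts.get(gene, 0)
        if o == 0:
            cls, fold = SpecificityClass.CTL_ONLY, 0.0
        elif c == 0:
            cls, fold = SpecificityClass.OXY_ONLY, float("inf")
        else:
            fold = o / c
            cls = (
                SpecificityClass.OXY_ENRICHED
                if fold >= fold_cutoff
                else SpecificityClass.BACKGROUND
            )
        genes[gene] = GeneSpecificity(gene, cls, o, c, fold)
    return SpecificityReport(fold_cutoff=fold_cutoff, genes=genes)


def remove_background(
    oxy: ProteinCountTable, report: SpecificityReport
) -> ProteinCountTable:
    """Drop background-classified genes from the OXY table; keep all counts."""
    background = report.of_class(SpecificityClass.BACKGROUND)
    counts = {g: c for g, c in oxy.counts.items() if g not in background}
    return ProteinCountTable(oxy.dataset_id, oxy.species, oxy.condition, counts)


def compile_species(tables: Sequence[ProteinCountTable]) -> ProteinCountTable:
    """Union per-experiment tables of one species/condition, summing counts."""
    if not tables:
        raise ValueError("no tables to compile")
    species = tables[0].species
    condition = tables[0].condition
    counts: dict[str, int] = {}
    for t in tables:
        if t.species != species:
            raise ValueError(
                f"species mismatch: {t.species!r} vs {species!r} in compilation"
            )
        if t.condition != condition:
            raise ValueError(
                f"condition mismatch: {t.condition!r} vs {condition!r} in compilation"
            )
        for gene, c in t.counts.items():
            counts[gene] = counts.get(gene, 0) + c
    dataset_id = "+".join(t.dataset_id for t in tables)
    return ProteinCountTable(dataset_id, species, condition, counts)


def cross_list_overlap(
    list1: Iterable[str], list2: Iterable[str]
) -> tuple[int, int, int, int]:
    """(intersection, union, |list1|, |list2|) for two harmonized gene sets."""
    s1, s2 = set(list1), set(list2)
    return len(s1 & s2), len(s1 | s2), len(s1), len(s2)
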