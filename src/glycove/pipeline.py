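"""End-to-end orchestration: filter -> specificity -> VE -> cell types.

Thin glue over the stage modules so that analysis scripts, the CLI and the
acceptance checks all run the identical computation.  Also provides the
seeded synthetic-study runner used for parameter-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import celltype as ct
from . import enrichment, specificity
from .glycofilter import (
    DEFAULT_CANDIDATE_THRESHOLDS,
    FilteredProteinList,
    aggregate_proteins,
    filter_psms,
    protein_fdr_filter,
    summarize_proteins,
)
from .io_formats import PSMRecord, ProteinCountTable
from .synthetic_data import (
    SimulatedDatasets,
    SimulationConfig,
    SyntheticProteome,
    simulate_cluster_matrix,
    simulate_proteome,
    simulate_psm_tables,
)


def identify_proteins(
    psms: Sequence[PSMRecord],
    dataset_id: str,
    species: str,
    condition: str,
    gene_map: Mapping[str, str] | None = None,
    fdr_bound: float = 0.01,
    candidate_thresholds: Sequence[float] = DEFAULT_CANDIDATE_THRESHOLDS,
) -> tuple[FilteredProteinList, ProteinCountTable]:
    """Glyco-filter PSMs, apply protein FDR control, and count spectra."""
    kept = filter_psms(psms)
    rows = summarize_proteins(kept, gene_map)
    fdr_result = protein_fdr_filter(rows, fdr_bound, candidate_thresholds)
    table = aggregate_proteins(
        kept,
        dataset_id,
        species,
        condition,
        gene_map,
        retained_accessions=[p.accession for p in fdr_result.proteins],
    )
    return fdr_result, table


def auc_from_scores(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC of scores separating labels==True."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos, n_neg = labels.sum(), (~labels).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both classes for an AUC")
    ranks = pd.Series(scores).rank().to_numpy()
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


@dataclass
class SpeciesResult:
    fdr_result: FilteredProteinList
    oxy_table: ProteinCountTable
    ctl_table: ProteinCountTable
    lysate_table: ProteinCountTable
    report: specificity.SpecificityReport
    final_table: ProteinCountTable
    ve_table: enrichment.VETable
    filter_sensitivity: float
    realized_fdr: float


@dataclass
class StudyResult:
    config: SimulationConfig
    proteome: SyntheticProteome
    datasets: SimulatedDatasets
    species: dict[str, SpeciesResult] = field(default_factory=dict)
    ve_combined: enrichment.VETable | None = None
    cluster_summary: pd.DataFrame | None = None
    merged: ct.MergedClusters | None = None
    signatures: dict[str, str] = field(default_factory=dict)

    def identified_genes(self, sp: str) -> set[str]:
        return self.species[sp].final_table.genes()

    def endo_flagged_high(self) -> bool:
        df = self.cluster_summary
        row = df[df["cluster"] == "Endo"]
        return bool(row["outlier_flag"].iloc[0]) and row["direction"].iloc[0] == "high"


def run_species(
    config: SimulationConfig,
    proteome: SyntheticProteome,
    datasets: SimulatedDatasets,
    sp: str,
) -> SpeciesResult:
    gene_map = proteome.gene_map
    fdr_result, oxy_table = identify_proteins(
        datasets.tables[(sp, "oxy")], f"{sp}_oxy", sp, "oxy", gene_map
    )
    _, ctl_table = identify_proteins(
        datasets.tables[(sp, "ctl")], f"{sp}_ctl", sp, "ctl", gene_map
    )
    _, lysate_table = identify_proteins(
        datasets.tables[(sp, "lysate")], f"{sp}_lysate", sp, "lysate", gene_map
    )
    report = specificity.classify_ctl_oxy(oxy_table, ctl_table)
    final_table = specificity.remove_background(oxy_table, report)
    ve_table = enrichment.rank_percentile(
        enrichment.vessel_enrichment(
            enrichment.to_cpm(final_table), enrichment.to_cpm(lysate_table), species=sp
        )
    )

    # truth-based recovery metrics
    spurious_accs = {
        proteome.accessions[i] for i in np.flatnonzero(datasets.spurious_targets[sp])
    }
    true_accs = {
        r.proteins[0]
        for r in datasets.tables[(sp, "oxy")]
        if not r.is_decoy and r.proteins[0] not in spurious_accs
    }
    retained_accs = {p.accession for p in fdr_result.proteins}
    sensitivity = len(retained_accs & true_accs) / len(true_accs) if true_accs else 0.0
    realized_fdr = (
        len(retained_accs & spurious_accs) / len(retained_accs) if retained_accs else 0.0
    )
    return SpeciesResult(
        fdr_result=fdr_result,
        oxy_table=oxy_table,
        ctl_table=ctl_table,
        lysate_table=lysate_table,
        report=report,
        final_table=final_table,
        ve_table=ve_table,
        filter_sensitivity=sensitivity,
        realized_fdr=realized_fdr,
    )


def run_synthetic_study(
    config: SimulationConfig,
    species: Sequence[str] = ("rat", "mouse"),
    with_celltype: bool = True,
) -> StudyResult:
    """Simulate a full study and run every pipeline stage on it."""
    proteome = simulate_proteome(config)
    datasets = simulate_psm_tables(config, proteome, species=species)
    result = StudyResult(config=config, proteome=proteome, datasets=datasets)
    for sp in species:
        result.species[sp] = run_species(config, proteome, datasets, sp)
    if len(species) == 2:
        result.ve_combined = enrichment.rank_percentile(
            enrichment.combine_species(
                result.species["rat"].ve_table, result.species["mouse"].ve_table
            )
        )
    if with_celltype:
        expr = simulate_cluster_matrix(config, proteome)
        merged = ct.merge_clusters(expr)
        surface = {
            g for g, s in zip(proteome.genes, proteome.is_surface) if s
        }
        identified = set().union(*(result.identified_genes(sp) for sp in species))
        result.merged = merged
        result.signatures = ct.signature_genes(merged)
        result.cluster_summary = ct.cell_type_summary(merged, surface, identified)
    return result
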