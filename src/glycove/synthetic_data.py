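"""Ground-truth-tagged synthetic inputs for every pipeline stage.

The generator emulates the statistical structure of an in vivo glycocapture
study: a target/decoy protein database with sequon-bearing tryptic
peptides, PSM tables for oxidised (OXY), buffer-control (CTL), brain-lysate
and cell-surface glycocapture datasets in two species under an
overdispersed spectral-count model, and an Allen-style cluster-median
expression matrix with consecutive same-name clusters, cell-type-restricted
signature genes, and an endothelial-like cell type whose surface genes are
preferentially pulled into the in vivo identified set.

Every random draw flows from ``SimulationConfig.seed`` through
``numpy.random.default_rng``; runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .glycofilter import DEAMIDATION_MASS, find_sequons
from .io_formats import (
    ClusterExpression,
    Modification,
    PSMRecord,
    ProteinCountTable,
)

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: Brain cell-type names used for merged-cluster labels; the first is the
#: endothelial-like type carrying the planted identification enrichment.
CELLTYPE_NAMES = [
    "Endo", "Astro", "Oligo", "Micro-PVM", "VLMC", "SMC-Peri", "OPC", "CR",
    "Sst", "Pvalb", "Vip", "Lamp5", "L2-3 IT", "L5 IT", "L6 CT", "L6b",
    "Sncg", "Meis2", "L5 ET", "L6 IT",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults for the synthetic glycocapture experiment.

    Sizes mirror the real study: a ~2000-entry searched proteome yielding a
    few hundred in vivo identifications per species, a broader brain-lysate
    identification list, tens of CTL background proteins, and a cluster
    matrix merging to a few dozen cell types.
    """

    seed: int = 0
    n_proteins: int = 2000
    n_decoys: int = 2000
    protein_length: int = 120
    frac_glyco: float = 0.8
    frac_contaminant: float = 0.02
    contaminant_enriched_frac: float = 0.5
    contaminant_abundance_scale: float = 5.0
    frac_vessel_enriched: float = 0.2
    vessel_fold: float = 5.0
    mean_spectral_count: float = 8.0
    count_model: str = "negative_binomial"  # or "poisson"
    dispersion: float = 0.3
    abundance_sigma: float = 0.7
    capture_rate: float = 0.12
    lysate_rate: float = 0.55
    cell_surface_rate: float = 0.4
    mouse_capture_scale: float = 0.65
    spurious_psm_rate: float = 0.01
    target_score_alpha: float = 30.0
    deamidation_completeness: float = 0.95
    n_clusters: int = 150
    n_celltypes: int = 75
    frac_signature: float = 0.2
    frac_surface: float = 0.6
    cross_detection_rate: float = 0.3
    endo_identification_odds: float = 5.0

    def __post_init__(self) -> None:
        for name in (
            "frac_glyco", "frac_contaminant", "contaminant_enriched_frac",
            "frac_vessel_enriched", "capture_rate", "lysate_rate",
            "cell_surface_rate", "spurious_psm_rate", "deamidation_completeness",
            "frac_signature", "frac_surface", "cross_detection_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_proteins < 10:
            raise ValueError("n_proteins must be at least 10")
        if self.vessel_fold < 1:
            raise ValueError("vessel_fold must be >= 1")
        if self.count_model not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown count model {self.count_model!r}")
        if not 1 <= self.n_celltypes <= self.n_clusters:
            raise ValueError("need 1 <= n_celltypes <= n_clusters")

    def scaled(self, **overrides) -> "SimulationConfig":
        return replace(self, **overrides)


@dataclass
class SyntheticProteome:
    """Target/decoy database plus the per-protein ground-truth table."""

    config: SimulationConfig
    accessions: list[str]
    genes: list[str]
    sequences: list[str]
    decoy_accessions: list[str]
    decoy_sequences: list[str]
    is_glyco: np.ndarray
    is_contaminant: np.ndarray
    contaminant_enriched: np.ndarray
    is_surface: np.ndarray
    is_signature: np.ndarray
    celltype: np.ndarray  # index into celltype_names
    celltype_names: list[str]
    detection: np.ndarray  # genes x celltypes boolean
    vessel_factor: np.ndarray
    rel_abundance: np.ndarray
    sequon_peptides: list[list[str]]
    decoy_sequon_peptides: list[list[str]]

    @property
    def gene_map(self) -> dict[str, str]:
        m = {a: g for a, g in zip(self.accessions, self.genes)}
        m.update({a: a for a in self.decoy_accessions})
        return m

    def truth_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "accession": self.accessions,
                "gene": self.genes,
                "is_glyco": self.is_glyco,
                "is_contaminant": self.is_contaminant,
                "contaminant_enriched": self.contaminant_enriched,
                "is_surface": self.is_surface,
                "is_signature": self.is_signature,
                "celltype": [self.celltype_names[i] for i in self.celltype],
                "detected_in_endo": self.detection[:, 0],
                "vessel_factor": self.vessel_factor,
                "rel_abundance": self.rel_abundance,
            }
        )


def cleave_tryptic(sequence: str) -> list[str]:
    """Cleave after every K/R (no proline rule) -- a stated simplification."""
    peptides, start = [], 0
    for i, aa in enumerate(sequence):
        if aa in "KR":
            peptides.append(sequence[start : i + 1])
            start = i + 1
    if start < len(sequence):
        peptides.append(sequence[start:])
    return [p for p in peptides if p]


def _sequon_peptides(sequence: str) -> list[str]:
    return [p for p in cleave_tryptic(sequence) if len(find_sequons(p)) > 0]


def simulate_proteome(config: SimulationConfig) -> SyntheticProteome:
    """Random-sequence protein database with shuffled decoys and truth tags.

    Every designated glycoprotein gets at least one sequon-bearing tryptic
    peptide (an ``NAS`` motif spliced into its sequence).  The truth table
    records glyco status, contaminant status, vessel enrichment factor, cell
    type of origin and the scRNAseq detection pattern that the cluster
    matrix will later render.
    """
    rng = np.random.default_rng([config.seed, 1])
    n = config.n_proteins
    seqs = ["".join(s) for s in rng.choice(_AA, size=(n, config.protein_length))]
    is_glyco = rng.random(n) < config.frac_glyco
    is_contaminant = rng.random(n) < config.frac_contaminant
    # contaminants are identified in CTL animals too, so they carry sequons
    is_glyco = is_glyco | is_contaminant
    contaminant_enriched = is_contaminant & (
        rng.random(n) < config.contaminant_enriched_frac
    )
    for i in np.flatnonzero(is_glyco):
        pos = int(rng.integers(5, config.protein_length - 8))
        seqs[i] = seqs[i][:pos] + "NAS" + seqs[i][pos + 3 :]
    decoys = ["".join(rng.permutation(list(s))) for s in seqs[: config.n_decoys]]

    celltype_names = list(CELLTYPE_NAMES)
    while len(celltype_names) < config.n_celltypes:
        celltype_names.append(f"Type-{len(celltype_names) + 1}")
    celltype_names = celltype_names[: config.n_celltypes]
    celltype = rng.integers(0, config.n_celltypes, size=n)
    is_signature = rng.random(n) < config.frac_signature
    is_surface = rng.random(n) < config.frac_surface
    detection = np.zeros((n, config.n_celltypes), dtype=bool)
    detection[np.arange(n), celltype] = True
    cross = rng.random((n, config.n_celltypes)) < config.cross_detection_rate
    cross[is_signature] = False
    detection |= cross
    detection[np.arange(n), celltype] = True
    detection[is_signature] = False
    detection[np.flatnonzero(is_signature), celltype[is_signature]] = True

    vessel_factor = np.ones(n)
    enriched = is_glyco & ~is_contaminant & (
        rng.random(n) < config.frac_vessel_enriched
    )
    vessel_factor[enriched] = config.vessel_fold
    rel_abundance = np.exp(rng.normal(0.0, config.abundance_sigma, size=n))

    genes = [f"GENE{i:04d}" for i in range(n)]
    accessions = [f"sp|P{i:05d}|{g}" for i, g in enumerate(genes)]
    return SyntheticProteome(
        config=config,
        accessions=accessions,
        genes=genes,
        sequences=seqs,
        decoy_accessions=[f"rev_{a}" for a in accessions[: config.n_decoys]],
        decoy_sequences=decoys,
        is_glyco=is_glyco,
        is_contaminant=is_contaminant,
        contaminant_enriched=contaminant_enriched,
        is_surface=is_surface,
        is_signature=is_signature,
        celltype=celltype,
        celltype_names=celltype_names,
        detection=detection,
        vessel_factor=vessel_factor,
        rel_abundance=rel_abundance,
        sequon_peptides=[_sequon_peptides(s) for s in seqs],
        decoy_sequon_peptides=[_sequon_peptides(s) for s in decoys],
    )


def capture_probability(proteome: SyntheticProteome, scale: float = 1.0) -> np.ndarray:
    """Per-protein probability of being captured by in vivo glycocapture.

    Baseline ``capture_rate`` on the odds scale, multiplied by
    ``endo_identification_odds`` for surface genes detected in the
    endothelial-like cell type; zero for non-glycoproteins; one for
    contaminants (they bind the beads regardless of oxidation).
    """
    cfg = proteome.config
    base_odds = cfg.capture_rate / (1 - cfg.capture_rate)
    odds = np.full(cfg.n_proteins, base_odds)
    upweight = proteome.is_surface & proteome.detection[:, 0]
    odds[upweight] *= cfg.endo_identification_odds
    p = odds / (1 + odds)
    p = np.clip(p * scale, 0, 1)
    p[~proteome.is_glyco] = 0.0
    p[proteome.is_contaminant] = 1.0
    return p


def _draw_counts(rng, mean: np.ndarray, config: SimulationConfig) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if config.count_model == "poisson":
        return rng.poisson(mean)
    size = 1.0 / config.dispersion
    return rng.negative_binomial(size, size / (size + mean))


def _psms_for_protein(
    rng,
    accession: str,
    peptides: Sequence[str],
    count: int,
    score: float,
    is_decoy: bool,
    experiment_id: str,
    completeness: float,
) -> list[PSMRecord]:
    records = []
    for k in range(count):
        peptide = peptides[k % len(peptides)]
        sequons = find_sequons(peptide).positions
        mods = [
            Modification(pos + 1, "N", DEAMIDATION_MASS)
            for pos in sequons
            if rng.random() < completeness
        ]
        records.append(
            PSMRecord(
                spectrum_id=f"{experiment_id}.{accession}.{k}",
                peptide=peptide,
                modifications=mods,
                proteins=[accession],
                protein_probability=score,
                is_decoy=is_decoy,
                experiment_id=experiment_id,
            )
        )
    return records


@dataclass
class SimulatedDatasets:
    """PSM tables per (species, condition) plus capture ground truth."""

    tables: dict[tuple[str, str], list[PSMRecord]]
    captured: dict[str, np.ndarray]  # species -> boolean over target proteins
    lysate_present: dict[str, np.ndarray]
    spurious_targets: dict[str, np.ndarray]


def simulate_psm_tables(
    config: SimulationConfig,
    proteome: SyntheticProteome,
    species: Sequence[str] = ("rat", "mouse"),
    conditions: Sequence[str] = ("oxy", "ctl", "lysate", "cell_surface"),
) -> SimulatedDatasets:
    """Draw PSM tables for the requested species x condition grid.

    OXY contains captured glycoproteins (vessel-enriched proteins at
    ``vessel_fold`` times their lysate-relative abundance) plus all
    contaminants; CTL contains only contaminant proteins; the lysate dataset
    samples the glycoproteome broadly without vessel enrichment.  Decoy PSMs
    and spurious-target PSMs are injected at the same rate with protein
    scores drawn from the same low-score Beta(1, 3) distribution, so the decoy-based FDR estimate is
    calibrated against the planted false identifications.
    """
    rng = np.random.default_rng([config.seed, 2])
    cfg = config
    n = cfg.n_proteins
    scores = rng.beta(cfg.target_score_alpha, 1.0, size=n)
    tables: dict[tuple[str, str], list[PSMRecord]] = {}
    captured_truth: dict[str, np.ndarray] = {}
    lysate_truth: dict[str, np.ndarray] = {}
    spurious_truth: dict[str, np.ndarray] = {}
    base_mean = cfg.mean_spectral_count * proteome.rel_abundance
    contaminant_mean = base_mean * np.where(
        proteome.is_contaminant, cfg.contaminant_abundance_scale, 1.0
    )

    for sp in species:
        scale = 1.0 if sp == "rat" else cfg.mouse_capture_scale
        p_capture = capture_probability(proteome, scale)
        captured = rng.random(n) < p_capture
        lysate_present = proteome.is_glyco & (rng.random(n) < cfg.lysate_rate)
        lysate_present |= proteome.is_contaminant
        surface_present = proteome.is_glyco & (rng.random(n) < cfg.cell_surface_rate)
        captured_truth[sp] = captured
        lysate_truth[sp] = lysate_present

        presence = {
            "oxy": (captured, contaminant_mean * np.where(
                proteome.is_contaminant & ~proteome.contaminant_enriched,
                1.0,
                proteome.vessel_factor * np.where(proteome.contaminant_enriched, 3.0, 1.0),
            )),
            "ctl": (proteome.is_contaminant, contaminant_mean),
            "lysate": (lysate_present, base_mean),
            "cell_surface": (surface_present, base_mean),
        }
        spurious = np.zeros(n, dtype=bool)
        for cond in conditions:
            present, mean = presence[cond]
            counts = np.where(present, _draw_counts(rng, mean, cfg), 0)
            exp_id = f"{sp}_{cond}"
            records: list[PSMRecord] = []
            for i in np.flatnonzero(counts):
                peptides = proteome.sequon_peptides[i]
                if not peptides:
                    continue
                records.extend(
                    _psms_for_protein(
                        rng, proteome.accessions[i], peptides, int(counts[i]),
                        float(scores[i]), False, exp_id,
                        cfg.deamidation_completeness,
                    )
                )
            if cond == "oxy":
                # spurious target and decoy PSMs at matched rates/scores
                spurious = (~present) & (rng.random(n) < cfg.spurious_psm_rate)
                for i in np.flatnonzero(spurious):
                    peptides = proteome.sequon_peptides[i]
                    if not peptides:
                        spurious[i] = False
                        continue
                    records.extend(
                        _psms_for_protein(
                            rng, proteome.accessions[i], peptides, 1,
                            float(rng.beta(1.0, 3.0)), False, exp_id, 1.0,
                        )
                    )
                n_dec = cfg.n_decoys
                decoy_hits = rng.random(n_dec) < cfg.spurious_psm_rate
                for i in np.flatnonzero(decoy_hits):
                    peptides = proteome.decoy_sequon_peptides[i]
                    if not peptides:
                        continue
                    records.extend(
                        _psms_for_protein(
                            rng, proteome.decoy_accessions[i], peptides, 1,
                            float(rng.beta(1.0, 3.0)), True, exp_id, 1.0,
                        )
                    )
            tables[(sp, cond)] = records
        spurious_truth[sp] = spurious
    return SimulatedDatasets(
        tables=tables,
        captured=captured_truth,
        lysate_present=lysate_truth,
        spurious_targets=spurious_truth,
    )


def simulate_ve_benchmark(
    seed: int,
    n_proteins: int = 500,
    mean_count: float = 20.0,
    frac_enriched: float = 0.2,
    fold: float = 5.0,
    dispersion: float = 0.3,
    count_model: str = "negative_binomial",
) -> tuple[ProteinCountTable, ProteinCountTable, np.ndarray]:
    """Paired vessel/lysate count tables with known vessel-enriched proteins.

    Every protein is present in both datasets; the designated fraction has
    its vessel-side mean multiplied by ``fold``.  Returns the two count
    tables and the boolean enrichment truth, for VE parameter-recovery
    checks (AUC of the VE ranking, expected VE under fold = 1).
    """
    rng = np.random.default_rng([seed, 4])
    cfg = SimulationConfig(
        seed=seed, count_model=count_model, dispersion=dispersion,
        n_proteins=max(n_proteins, 10),
    )
    enriched = rng.random(n_proteins) < frac_enriched
    mean = np.full(n_proteins, mean_count)
    vessel_counts = _draw_counts(rng, mean * np.where(enriched, fold, 1.0), cfg)
    lysate_counts = _draw_counts(rng, mean, cfg)
    genes = [f"GENE{i:04d}" for i in range(n_proteins)]
    vessel = ProteinCountTable(
        "bench_vessel", "rat", "oxy",
        {g: int(c) for g, c in zip(genes, vessel_counts)},
    )
    lysate = ProteinCountTable(
        "bench_lysate", "rat", "lysate",
        {g: int(c) for g, c in zip(genes, lysate_counts)},
    )
    return vessel, lysate, enriched


def simulate_cluster_matrix(
    config: SimulationConfig, proteome: SyntheticProteome
) -> ClusterExpression:
    """Allen-style cluster-median matrix rendering the proteome's truth.

    ``n_clusters`` labeled columns (``"<i> <celltype>"``) are split into
    consecutive runs over ``n_celltypes`` cell types, so merging consecutive
    same-description clusters recovers exactly one column per cell type.
    Signature genes are expressed in their home cell type only; every other
    gene follows the detection pattern fixed by :func:`simulate_proteome`.
    """
    rng = np.random.default_rng([config.seed, 3])
    n_types = config.n_celltypes
    # run lengths >= 1 summing to n_clusters
    cuts = np.sort(
        rng.choice(np.arange(1, config.n_clusters), size=n_types - 1, replace=False)
    ) if n_types > 1 else np.array([], dtype=int)
    run_lengths = np.diff(np.concatenate([[0], cuts, [config.n_clusters]]))
    base_expr = rng.exponential(2.0, size=(config.n_proteins, n_types)) + 0.1
    base_expr *= proteome.detection
    labels, cols = [], []
    cluster_no = 1
    for t in range(n_types):
        for _ in range(int(run_lengths[t])):
            labels.append(f"{cluster_no} {proteome.celltype_names[t]}")
            cluster_no += 1
            # member clusters scatter around the cell-type median; at least
            # one member per run carries the full value so the merged max
            # reproduces the detection pattern exactly
            scatter = rng.uniform(0.3, 1.0, size=config.n_proteins)
            cols.append(base_expr[:, t] * scatter)
        cols[-1] = base_expr[:, t]
    values = np.column_stack(cols)
    return ClusterExpression(genes=list(proteome.genes), clusters=labels, values=values)
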