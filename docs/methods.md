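# Methods

## The measurement being modelled

In vivo glycocapture labels glycoproteins on the luminal surface of brain
vessels by perfusing a mild periodate oxidation solution, captures the
oxidised glycoproteins on hydrazide beads, and analyses the PNGase
F-released, formerly N-glycosylated peptides by LC-MS/MS. The package
consumes search-engine output (MSFragger-style `psm.tsv` tables including
decoy hits) and implements all downstream analysis. Raw spectra, the
database search itself, and GO/pathway over-representation are out of
scope.

## Glycopeptide filter

PNGase F converts a glycosylated asparagine to aspartate, reported as a
deamidation of +0.984 Da on N. A PSM is retained iff its peptide contains
at least one sequon N-X-S/T/C (X ≠ P; C accepted as third residue) and its
deamidated-N count *d* satisfies 1 ≤ *d* ≤ *x*, with *x* the number of
sequons on the peptide. Choices:

- Sequon scanning uses a regex with lookahead so **overlapping** motifs all
  count; motifs truncated by the peptide C-terminus (N or N-X at the end)
  never count, because the rule operates on the peptide string alone.
- Deamidated asparagines are counted **anywhere** in the peptide, not only
  at sequon positions — the literal filter rule. Masses are matched to the
  deamidation delta within ±0.01 Da because search engines print rounded
  values.
- Reported sequon positions are 0-based; modification positions in PSM
  tables are 1-based, as in the input dialect.

## Protein FDR control

Proteins surviving the peptide filter carry a ProteinProphet-style
probability (consumed, never recomputed). The filter tries candidate
thresholds (default 0.75 then 0.80) and keeps the smallest whose
decoy-estimated FDR — decoys retained / targets retained, the conservative
estimate after decoys are removed from the report — is strictly below the
bound (default 1%). If no candidate qualifies the result is an explicit
empty identification list carrying the FDR at the strictest threshold.
Multi-protein PSMs are razor-assigned to the single candidate protein with
the most supporting PSMs (ties: lexicographic accession) so spectral counts
are never double-counted.

## Specificity classification

Per gene, OXY vs CTL raw spectral counts give one of four classes:
`oxy_only` (absent from CTL), `oxy_enriched` (fold ≥ 1.5), `background`
(present in both, fold < 1.5), `ctl_only`. Background genes are removed
from the final list. The 1.5 cutoff operationalises "similar spectral
counts" as the complement of the observed 1.5–64-fold enrichment band; it
is a config parameter and is recorded in output metadata. Fold changes use
raw counts (both fractions come from the same workflow), and multiple
CTL experiments are summed before comparison.

## Vessel Enrichment score

Counts are scaled to counts-per-million within each dataset (sum exactly
10⁶). VE(g) = CPM_vessel(g) − CPM_lysate(g) for every gene on the in vivo
identification list; genes missing from the lysate take CPM 0, genes found
only in the lysate get no row. Cross-species combination divides each
species' VE by that species' median VE (over all its values, positive and
negative) and sums; a gene absent from one species contributes 0 for that
term, recorded in output metadata. Ranks order by descending VE with
lexicographic tie-break; percentile = 100·(N − rank)/N. Note the combined
score is in median units, so absolute cutoffs such as VE > 1000 are
meaningful on per-species CPM-scale tables and must be re-interpreted on
the combined scale.

## Cell-type concordance

Cluster labels `"<number> <description>"` are split on the first
whitespace; runs of **consecutive** clusters with equal descriptions merge
into one column keeping the per-gene maximum (non-consecutive repeats stay
separate, disambiguated with `#n`). Detection is strictly `> 0` on the
cluster-median expression (configurable). For each merged cell type the
statistic is 100 · |detected ∩ surface ∩ identified| / |detected ∩ surface|;
cell types with no detected surface genes are excluded from outlier
testing rather than imputed.

### ROUT outlier test

Only the method name and Q level are fixed by convention, so the internals
follow the published recipe (Motulsky & Brown 2006) with every constant
exposed: a constant location model fit by minimising the Lorentzian merit
Σ log(1 + (r/RSDR)²), iterating location and scale to a fixed point; RSDR =
68.27th percentile of |residuals| × N/(N−K) (K = 1); residuals scaled by
RSDR treated as t statistics with N−K df; the largest residuals (at most
30% of points) flagged by the FDR step: with p-values ordered by descending
|residual|, flag the largest k with p₍ᵢ₌ₖ₎ < Q·k/N. Degenerate inputs: all
values equal → RSDR 0, no flags; RSDR 0 with unequal values → nonzero
residuals get p = 0. Fewer than 4 values is an error.

### Signature genes

Genes detected in exactly one merged cell type map to that type; fractions
are percentages of all identified signature genes, and dataset differences
(e.g. in vivo minus lysate) are computed from the same signature table with
only the identified set changing.

## Synthetic data generator

The generator emulates the study's statistical structure at study scale:
2000 target proteins (~80% glycosylated, each guaranteed a sequon-bearing
tryptic peptide) plus an equal shuffled decoy database; negative-binomial
spectral counts (dispersion 0.3, log-normal protein abundance, σ = 0.7)
with a 5-fold vessel enrichment planted in 20% of glycoproteins; a baseline
in vivo capture probability of 0.12 upweighted (odds × 5) for surface genes
detected in the endothelial-like cell type; a broad lysate dataset
(capture 0.55); ~2% contaminant proteins present in both OXY and CTL at
5× abundance, half of them oxidation-enriched 3-fold; deamidation
completeness 0.95 per sequon; true protein probabilities Beta(30, 1) and
false-hit (decoy and spurious-target) probabilities Beta(1, 3) injected at
matched rates so the decoy FDR estimate is calibrated against planted false
identifications; 150 labeled clusters merging to 75 cell types with 20%
signature genes and 30% cross-type detection. Mouse capture is scaled by
0.65, reproducing the smaller mouse identification list.

These defaults yield a pipeline output that mirrors the real study's
shape: a few hundred in vivo identifications per species against a
~900-protein lysate list, tens of CTL proteins mostly removed as
background, a mostly-positive VE distribution, and an endothelial cell
type far above the other 74 in identified-surface-gene percentage.

What the generator does **not** emulate: correlated capture between
species (each species draws independently, so cross-species overlap is
smaller than in real data), chemical (non-PNGase F) deamidation, peptide
length/detectability effects, shared peptides between homologous proteins,
and scRNAseq depth-of-coverage differences between cell types. Passing
recovery tests therefore demonstrates the pipeline's correctness under the
assumed count and detection models, not robustness to these real-data
effects.

## Problem sizes and tolerances in the checks

Replicated checks scale sizes to keep runs short while retaining power:
the end-to-end recovery check runs 100 single-species replicates at mean
spectral count 6; the VE-ranking check uses the benchmark generator
(n = 500 proteins, mean count 20, 20% enriched 5-fold) and reports the
mean AUC over 30 seeded replicates (per-replicate sd ≈ 0.025); ROUT
calibration uses 1,000 null normal samples of n = 75. Monte-Carlo
comparisons (contaminant background rates, zero-fold VE means) are
asserted within 3–4 standard errors of independent simulation estimates.

## Known limitations

- The FDR estimator assumes one search per dataset with a concatenated
  target-decoy database and a configurable decoy accession prefix.
- Gene-symbol harmonisation between species is uppercase string matching
  unless a mapping file is supplied.
- The percentile convention 100·(N − rank)/N is one of several in use and
  can differ by ~1 point from other conventions at mid-list ranks.
- ROUT's t-tail calibration is approximate for very small samples (< ~10
  values); the FDR guarantee is empirical, verified in the test suite.
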