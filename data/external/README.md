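# External inputs for the reproduction tests

Two acceptance tests recompute published summary numbers from inputs that
cannot be redistributed here and must be downloaded once by hand.  All other
tests and `scripts/acceptance.py` run entirely on generated data.

Place the following plain-text files in this directory:

From the study's supplementary material (Additional File 1 Data S1 and
Additional File 4 Tables S2–S6), exported as one uppercase gene symbol per
line (`*_genes.txt`) or as two-column TSV with header `gene<TAB>spectral_count`
(`*_counts.tsv`):

- `rat_oxy_genes.txt` — compiled rat OXY identifications (356 genes)
- `rat_ctl_genes.txt` — compiled rat CTL identifications (31 genes)
- `rat_invivo_genes.txt` — final rat in vivo list, Table S2 (347 genes)
- `mouse_invivo_genes.txt` — final mouse in vivo list, Table S3 (224 genes)
- `sv_arbec_genes.txt` — SV-ARBEC cell-surface list, Table S5 (557 genes)
- `rat_lysate_genes.txt` — rat brain-lysate list, Table S6 (961 genes)
- `rat_invivo_counts.tsv`, `rat_lysate_counts.tsv`,
  `mouse_invivo_counts.tsv`, `mouse_lysate_counts.tsv` — spectral counts
  for the VE-score reproduction (Tfrc VE, rank, positive-VE fractions,
  combined VE > 1000 count)

From the Allen Brain Map "Mouse Whole Cortex and Hippocampus 10x" dataset:

- `allen_cluster_median.csv` — the "Gene Expression by Cluster, median
  (.csv)" file (388 labeled cluster columns)

When a file is missing the corresponding test fails with a pointer to this
README rather than silently skipping.
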