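"""Compare identified proteins to scRNAseq cell-type clusters.

Merges consecutive same-description clusters of the cluster-median matrix,
computes the percentage of each cell type's detected surface genes that
were identified by glycocapture, flags outlier cell types with ROUT
(Q = 0.1%), and summarises signature-gene fractions for the in vivo vs the
brain-lysate identification sets.  Writes tables under ``results/celltype/``.
"""

from pathlib import Path

import pandas as pd

from glycove import celltype as ct
from glycove import io_formats

ROOT = Path(__file__).resolve().parent.parent
RAW = ROOT / "scratch" / "synthetic"
IDS = ROOT / "results"
OUT = ROOT / "results" / "celltype"

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    merged = ct.merge_clusters(io_formats.read_cluster_csv(RAW / "cluster_median.csv"))
    surface = io_formats.read_gene_list(RAW / "surface_genes.txt")
    invivo = set().union(
        *(
            io_formats.read_count_table(
                IDS / "specificity" / f"{sp}_final_counts.tsv", sp, sp, "oxy"
            ).genes()
            for sp in ("rat", "mouse")
        )
    )
    lysate = set().union(
        *(
            io_formats.read_count_table(
                IDS / "identifications" / f"{sp}_lysate_counts.tsv", sp, sp, "lysate"
            ).genes()
            for sp in ("rat", "mouse")
        )
    )
    print(f"{merged.values.shape[1]} merged cell types from "
          f"{sum(len(v) for v in merged.provenance.values())} clusters")

    for name, identified in [("invivo", invivo), ("lysate", lysate)]:
        summary = ct.cell_type_summary(merged, surface, identified)
        summary.to_csv(OUT / f"summary_{name}.tsv", sep="\t", index=False)
        flagged = summary[summary["outlier_flag"]]
        med = summary["percent"].median()
        label = ", ".join(
            f"{r.cluster} ({r.percent:.0f}%, {r.direction})" for r in flagged.itertuples()
        )
        print(f"{name}: median {med:.1f}% identified; outliers: {label or 'none'}")

    signatures = ct.signature_genes(merged)
    frac_invivo = ct.signature_fraction(signatures, invivo)
    diff = ct.signature_fraction_difference(signatures, invivo, lysate)
    frame = pd.DataFrame(
        {
            "cluster": sorted(frac_invivo),
            "invivo_percent": [frac_invivo[c] for c in sorted(frac_invivo)],
            "invivo_minus_lysate": [diff[c] for c in sorted(frac_invivo)],
        }
    )
    frame.to_csv(OUT / "signature_fractions.tsv", sep="\t", index=False)
    top = frame.sort_values("invivo_percent", ascending=False).head(3)
    print(
        "top signature fractions (in vivo): "
        + ", ".join(f"{r.cluster} {r.invivo_percent:.0f}%" for r in top.itertuples())
    )
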