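"""Generate the synthetic glycocapture study used by the downstream steps.

Writes the raw simulated inputs (PSM tables for OXY/CTL/lysate/cell-surface
in rat and mouse, the cluster-median expression matrix, the surface gene
list, the accession->gene map and the ground-truth table) under
``scratch/synthetic/``.  These files are large and regenerable, so they live
outside ``results/``; re-run this script to rebuild them.
"""

import json
import dataclasses
from pathlib import Path

from glycove import io_formats
from glycove.synthetic_data import (
    SimulationConfig,
    simulate_cluster_matrix,
    simulate_proteome,
    simulate_psm_tables,
)

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "scratch" / "synthetic"

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=1)
    proteome = simulate_proteome(cfg)
    datasets = simulate_psm_tables(cfg, proteome)
    for (sp, cond), records in datasets.tables.items():
        io_formats.write_psm_table(records, OUT / f"{sp}_{cond}_psm.tsv")
        print(f"{sp:6s} {cond:13s} {len(records):6d} PSMs")
    io_formats.write_cluster_csv(
        simulate_cluster_matrix(cfg, proteome), OUT / "cluster_median.csv"
    )
    surface = [g for g, s in zip(proteome.genes, proteome.is_surface) if s]
    (OUT / "surface_genes.txt").write_text("\n".join(surface) + "\n")
    with open(OUT / "gene_map.tsv", "w") as fh:
        for acc, gene in proteome.gene_map.items():
            fh.write(f"{acc}\t{gene}\n")
    proteome.truth_frame().to_csv(OUT / "truth.tsv", sep="\t", index=False)
    (OUT / "sim_config.json").write_text(
        json.dumps(dataclasses.asdict(cfg), indent=2) + "\n"
    )
    print(f"\nsimulated study (seed {cfg.seed}) written to {OUT}")
    print(f"{cfg.n_proteins} target proteins, {int(proteome.is_glyco.sum())} "
          f"glycoproteins, {int(proteome.is_contaminant.sum())} background binders")
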