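"""Score vessel enrichment: CPM(in vivo) - CPM(brain lysate) per protein.

Converts spectral counts to counts-per-million within each dataset,
subtracts the lysate CPM from the in vivo CPM (VE score), ranks proteins,
combines the two species by median-normalised summation, and writes the VE
tables under ``results/ve/``.
"""

from pathlib import Path

from glycove import enrichment, io_formats

ROOT = Path(__file__).resolve().parent.parent
IDS = ROOT / "results"
OUT = ROOT / "results" / "ve"

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    tables = {}
    for sp in ("rat", "mouse"):
        vessel = io_formats.read_count_table(
            IDS / "specificity" / f"{sp}_final_counts.tsv", f"{sp}_final", sp, "oxy"
        )
        lysate = io_formats.read_count_table(
            IDS / "identifications" / f"{sp}_lysate_counts.tsv", f"{sp}_lysate", sp, "lysate"
        )
        ve = enrichment.rank_percentile(
            enrichment.vessel_enrichment(
                enrichment.to_cpm(vessel), enrichment.to_cpm(lysate), sp
            )
        )
        tables[sp] = ve
        frame = ve.to_frame()
        frame.to_csv(OUT / f"{sp}_ve.tsv", sep="\t", index=False)
        top = ", ".join(frame.head(5)["gene"])
        print(
            f"{sp}: {len(ve.rows)} proteins, {100 * enrichment.positive_fraction(ve):.0f}% "
            f"with positive VE, {len(enrichment.ve_subset(ve, 1000.0))} with VE > 1000; "
            f"top: {top}"
        )
    combined = enrichment.rank_percentile(
        enrichment.combine_species(tables["rat"], tables["mouse"])
    )
    combined.to_frame().to_csv(OUT / "combined_ve.tsv", sep="\t", index=False)
    high = enrichment.ve_subset(combined, 1000.0)
    print(
        f"combined: {len(combined.rows)} proteins, "
        f"{100 * enrichment.positive_fraction(combined):.0f}% positive, "
        f"{len(high)} with combined VE > 1000"
    )
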