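"""Classify OXY vs CTL identifications and compile the final species lists.

Proteins identified at similar spectral counts in oxidised (OXY) and
buffer-control (CTL) animals are background binders and are removed; the
remaining OXY identifications form the final per-species lists, which are
then compared across species.  Writes the per-gene specificity table and
final lists under ``results/specificity/``.
"""

from pathlib import Path

import pandas as pd

from glycove import io_formats, specificity

ROOT = Path(__file__).resolve().parent.parent
IDS = ROOT / "results" / "identifications"
OUT = ROOT / "results" / "specificity"

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    finals = {}
    for sp in ("rat", "mouse"):
        oxy = io_formats.read_count_table(IDS / f"{sp}_oxy_counts.tsv", f"{sp}_oxy", sp, "oxy")
        ctl = io_formats.read_count_table(IDS / f"{sp}_ctl_counts.tsv", f"{sp}_ctl", sp, "ctl")
        report = specificity.classify_ctl_oxy(oxy, ctl)
        final = specificity.remove_background(oxy, report)
        finals[sp] = final
        pd.DataFrame(
            [
                {
                    "gene": s.gene,
                    "oxy_count": s.oxy_count,
                    "ctl_count": s.ctl_count,
                    "fold": s.fold_change,
                    "class": s.classification.value,
                }
                for s in sorted(report.genes.values(), key=lambda s: s.gene)
            ]
        ).to_csv(OUT / f"{sp}_specificity.tsv", sep="\t", index=False)
        io_formats.write_count_table(final, OUT / f"{sp}_final_counts.tsv")
        n_bg = len(report.of_class(specificity.SpecificityClass.BACKGROUND))
        n_enr = len(report.of_class(specificity.SpecificityClass.OXY_ENRICHED))
        print(
            f"{sp}: {len(oxy.counts)} OXY / {len(ctl.counts)} CTL identifications; "
            f"{n_enr} OXY-enriched, {n_bg} background removed -> "
            f"{len(final.counts)} final proteins"
        )
    inter, union, n_rat, n_mouse = specificity.cross_list_overlap(
        finals["rat"].genes(), finals["mouse"].genes()
    )
    print(
        f"cross-species: {n_rat} rat + {n_mouse} mouse -> union {union}, "
        f"shared {inter}"
    )
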