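#!/usr/bin/env python
"""Screen every cell's variant calls against the driver panel.

Uses each cell's breadth from results/coverage_summary.tsv (run 03
first) to apply the C >= 70% gate, screens the per-cell VCFs against
the bundled CTNNB1/KRAS/PIK3CA panel, and writes the samples x
variants status grid (results/panel_report.tsv) and per-variant
tallies (results/panel_tallies.tsv).
"""

from pathlib import Path

import pandas as pd

from cellpath import bundled_driver_panel
from cellpath import variant_panel as vp

ROOT = Path(__file__).resolve().parent.parent
COHORT = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    panel = vp.load_panel(bundled_driver_panel())
    breadths = (
        pd.read_csv(RESULTS / "coverage_summary.tsv", sep="\t")
        .set_index("sample")["breadth"]
        .to_dict()
    )
    reports = []
    for vcf_path in sorted(COHORT.glob("*.vcf")):
        cell = vcf_path.stem
        reports.append(
            vp.screen_sample(
                vcf_path,
                panel,
                COHORT / f"{cell}.callable.bed",
                breadth=breadths[cell],
                sample=cell,
            )
        )
    grid, tallies = vp.aggregate_reports(reports)
    grid.to_csv(RESULTS / "panel_report.tsv", sep="\t")
    tallies.to_csv(RESULTS / "panel_tallies.tsv", sep="\t", index=False)
    print(f"screened {len(reports)} cells against {len(panel)} driver variants:")
    for _, row in tallies.iterrows():
        print(f"  {row['variant']}: {row['summary']}")


if __name__ == "__main__":
    main()
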