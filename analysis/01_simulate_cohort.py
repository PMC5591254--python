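#!/usr/bin/env python
"""Simulate the study cohort: expression, WGA depth, and variant calls.

Generates, under scratch/cohort/:
  * bulk calibration samples (2 pathway-active + 2 inactive) and a
    log2 expression matrix for 7 active-like and 6 inactive-like single
    cells (with dropout);
  * a per-cell WGA depth histogram (zero-inflated negative binomial);
  * per-cell VCFs + callable BEDs: active-like cells carry all three
    panel drivers, inactive-like cells carry the PIK3CA hotspot only,
    and one inactive-like cell has no callable evidence at CTNNB1.

Everything downstream (02-04) reads only these files.
"""

from pathlib import Path

import pandas as pd

from cellpath import bundled_driver_panel, bundled_wnt_panel
from cellpath import synthetic_data as sd
from cellpath import variant_panel as vp
from cellpath.pathway_model import read_panel_tsv

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "scratch" / "cohort"
SEED = 20170908 % 2**31


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    model = read_panel_tsv(bundled_wnt_panel())
    genes = model.gene_names

    cal_cfg = sd.SyntheticConfig(genes=genes, n_active=2, n_inactive=2, seed=SEED)
    cal_m, cal_labels, _ = sd.simulate_expression(cal_cfg)
    cal_m.values.to_csv(OUT / "calibration_expression.tsv", sep="\t", index_label="gene")
    pd.DataFrame(cal_labels.items(), columns=["sample", "label"]).to_csv(
        OUT / "calibration_labels.tsv", sep="\t", index=False
    )

    cell_cfg = sd.SyntheticConfig(
        genes=genes, n_active=7, n_inactive=6, mode="single_cell", seed=SEED + 1
    )
    cell_m, cell_labels, manifest = sd.simulate_expression(cell_cfg)
    # active_* -> ls174t_like_*, inactive_* -> rko_like_*
    rename = {
        s: (
            f"ls174t_like_{s.split('_')[1]}"
            if s.startswith("active")
            else f"rko_like_{s.split('_')[1]}"
        )
        for s in cell_m.samples
    }
    cell_m.values.columns = [rename[s] for s in cell_m.samples]
    cell_labels = {rename[s]: l for s, l in cell_labels.items()}
    cell_m.values.to_csv(OUT / "cell_expression.tsv", sep="\t", index_label="gene")
    pd.DataFrame(cell_labels.items(), columns=["sample", "label"]).to_csv(
        OUT / "cell_labels.tsv", sep="\t", index=False
    )
    manifest["sample"] = manifest["sample"].map(rename)
    manifest.to_csv(OUT / "cell_expression_manifest.tsv", sep="\t", index=False)

    cells = list(cell_labels)
    for i, cell in enumerate(cells):
        depth_cfg = sd.SyntheticConfig(genes=genes, genome_bins=100_000, seed=SEED + 2)
        h = sd.simulate_depth(depth_cfg, seed=SEED + 100 + i)
        total = h.total_bases
        with open(OUT / f"{cell}.depth.tsv", "w") as fh:
            for depth in sorted(h.entries):
                fh.write(
                    f"genome\t{depth}\t{h.entries[depth]}\t{total}\t{h.entries[depth] / total:.6f}\n"
                )

    panel = vp.load_panel(bundled_driver_panel())
    by_gene = {v.gene: v for v in panel}
    plant = {
        cell: (list(panel) if cell.startswith("ls174t") else [by_gene["PIK3CA"]])
        for cell in cells
    }
    uncallable = {"rko_like_006": [by_gene["CTNNB1"]]}
    screen_manifest = sd.write_variant_calls(plant, panel, OUT, uncallable=uncallable)
    screen_manifest.to_csv(OUT / "variant_manifest.tsv", sep="\t", index=False)

    print(f"cohort written to {OUT}")
    print(f"  calibration: {len(cal_labels)} bulk samples x {len(genes)} genes")
    print(f"  single cells: {len(cells)} ({sum(l == 'active' for l in cell_labels.values())} active-like)")
    print(f"  depth histograms + VCFs per cell; one cell uncallable at CTNNB1")


if __name__ == "__main__":
    main()
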