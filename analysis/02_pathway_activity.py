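#!/usr/bin/env python
"""Calibrate the pathway model and score every sample.

Reads the cohort from scratch/cohort/ (run 01 first), fits per-gene
thresholds on the labelled bulk samples, converts each sample's
expression to soft evidence, infers the posterior log-odds of pathway
activity, classifies by the sign of the log-odds, and evaluates the
labelled cells with a two-sided Fisher exact test.

Writes to results/: thresholds.tsv, pathway_odds.tsv,
cluster_matrix.tsv, classification_summary.tsv.
"""

from pathlib import Path

import pandas as pd

from cellpath import bundled_wnt_panel
from cellpath import calibration as cal
from cellpath import pipeline as pl
from cellpath.pathway_model import infer_log_odds, read_panel_tsv

ROOT = Path(__file__).resolve().parent.parent
COHORT = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    model = read_panel_tsv(bundled_wnt_panel())

    cal_m = cal.read_expression_matrix(COHORT / "calibration_expression.tsv")
    cal_labels = pl._read_labels_tsv(COHORT / "calibration_labels.tsv")
    thresholds = cal.fit_thresholds(cal_m, cal_labels)
    pd.DataFrame(
        {
            "gene": thresholds.genes,
            "threshold": thresholds.thresholds.to_numpy(),
            "direction_ok": thresholds.direction_ok.to_numpy(),
        }
    ).to_csv(RESULTS / "thresholds.tsv", sep="\t", index=False)

    cell_m = cal.read_expression_matrix(COHORT / "cell_expression.tsv")
    cell_labels = pl._read_labels_tsv(COHORT / "cell_labels.tsv")

    rows = []
    predictions = {}
    for group, m in (("calibration", cal_m), ("single_cell", cell_m)):
        for sample in m.samples:
            ev = cal.evidence_from_sample(m, sample, thresholds, softness=0.25)
            res = infer_log_odds(model, ev)
            predictions[sample] = pl.classify(res)
            rows.append(
                {
                    "sample": sample,
                    "group": group,
                    "log_odds": res.log_odds,
                    "log10_odds": res.log10_odds,
                    "predicted": predictions[sample],
                }
            )
    odds = pd.DataFrame(rows)
    odds.to_csv(RESULTS / "pathway_odds.tsv", sep="\t", index=False)

    q = pd.concat(
        [
            cal.evidence_matrix(cal_m, thresholds, 0.25),
            cal.evidence_matrix(cell_m, thresholds, 0.25),
        ],
        axis=1,
    )
    cal.export_cluster_matrix(q, RESULTS / "cluster_matrix.tsv")

    truth = {**cal_labels, **cell_labels}
    evaluation = pl.evaluate_classification(
        {s: t for s, t in truth.items() if s in cell_labels}, predictions
    )
    pd.DataFrame(
        {
            "n_cells": [len(cell_labels)],
            "accuracy": [evaluation.accuracy],
            "fisher_p": [evaluation.fisher_p],
        }
    ).to_csv(RESULTS / "classification_summary.tsv", sep="\t", index=False)

    cells = odds[odds["group"] == "single_cell"]
    print(f"scored {len(odds)} samples ({len(cells)} single cells)")
    print(
        "single-cell log10 odds range: "
        f"{cells['log10_odds'].min():.1f} to {cells['log10_odds'].max():.1f}"
    )
    print(
        f"cell classification accuracy {evaluation.accuracy:.1%}, "
        f"Fisher exact p = {evaluation.fisher_p:.4f}"
    )


if __name__ == "__main__":
    main()
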