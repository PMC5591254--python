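"""Orchestration: calibrate -> score -> classify -> evaluate, plus QC/screen.

The end-to-end flow mirrors the study design this package supports:
calibrate per-gene thresholds on a few bulk samples of known pathway
status, score new samples (bulk or single cells) with the Bayesian
pathway model, classify each by the sign of its posterior log-odds
(active iff log-odds > 0; ties conservatively inactive), and evaluate
labelled samples with a two-sided Fisher exact test on the resulting
2x2 confusion table.  Coverage QC and driver-panel screening run on
the per-sample depth and VCF inputs when configured.

:func:`run_pipeline` consumes a YAML config naming all inputs and
writes the report bundle (thresholds, per-sample odds in natural log
and log10, the cluster matrix, the classification and Fisher summary,
coverage summaries, and the panel report).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.special import gammaln

from . import calibration, coverage_qc, variant_panel
from .calibration import ACTIVE, INACTIVE
from .pathway_model import InferenceResult, infer_log_odds, read_panel_tsv

__all__ = [
    "ClassificationResult",
    "PipelineError",
    "fisher_exact_two_sided",
    "classify",
    "evaluate_classification",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Configuration or input error that aborts a run before any output."""


_FISHER_TIE_RTOL = 1e-7


def _log_choose(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table of non-negative counts.

    Minimum-likelihood convention: the sum, over all tables with the
    observed margins, of hypergeometric probabilities not exceeding the
    observed table's (relative tie tolerance 1e-7).  For the
    all-correct 7-active/6-inactive validation confusion [[7,0],[0,6]]
    this gives 1/C(13,7) = 1/1716 ~= 5.83e-4.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("table entries must be non-negative")
    n = int(t.sum())
    if n == 0:
        raise ValueError("at least one margin must be positive")
    a = int(t[0, 0])
    row1 = int(t[0].sum())
    col1 = int(t[:, 0].sum())
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    ks = np.arange(lo, hi + 1)
    pmf = np.exp(_log_choose(col1, ks) + _log_choose(n - col1, row1 - ks) - _log_choose(n, row1))
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + _FISHER_TIE_RTOL)].sum())
    return min(1.0, p)


def classify(result) -> str:
    """"active" iff posterior log-odds > 0; ties resolve to "inactive"."""
    log_odds = result.log_odds if isinstance(result, InferenceResult) else float(result)
    if not math.isfinite(log_odds):
        raise ValueError("log_odds must be finite")
    return ACTIVE if log_odds > 0 else INACTIVE


@dataclass
class ClassificationResult:
    """Per-sample calls plus the labelled-sample evaluation.

    ``confusion`` is indexed [truth][prediction] over (active,
    inactive); ``fisher_p`` is the two-sided Fisher exact p of that
    table.
    """

    per_sample: pd.DataFrame
    confusion: np.ndarray
    fisher_p: float
    accuracy: float


def evaluate_classification(
    truth: Mapping[str, str], predicted: Mapping[str, str]
) -> ClassificationResult:
    """Confusion table, accuracy, and Fisher exact p over labelled samples."""
    samples = [s for s in truth if s in predicted]
    if not samples:
        raise ValueError("no labelled samples to evaluate")
    order = (ACTIVE, INACTIVE)
    confusion = np.zeros((2, 2), dtype=int)
    for s in samples:
        confusion[order.index(truth[s]), order.index(predicted[s])] += 1
    accuracy = float(np.trace(confusion)) / confusion.sum()
    per_sample = pd.DataFrame(
        {
            "sample": samples,
            "truth": [truth[s] for s in samples],
            "predicted": [predicted[s] for s in samples],
        }
    )
    return ClassificationResult(
        per_sample=per_sample,
        confusion=confusion,
        fisher_p=fisher_exact_two_sided(confusion),
        accuracy=accuracy,
    )


def _read_labels_tsv(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise PipelineError(f"{path}: labels TSV needs (sample, label) columns")
    sample_col, label_col = df.columns[0], df.columns[1]
    return {str(r[sample_col]).strip(): str(r[label_col]).strip() for _, r in df.iterrows()}


def _require(path, what: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise PipelineError(f"{what} not found: {p}")
    return p


def run_pipeline(config, out_dir=None) -> dict:
    """Run the configured analysis end to end and write the report bundle.

    ``config`` is a YAML path or an equivalent dict.  Keys:

    - ``calibration_matrix`` (TSV, required), ``calibration_labels``
      (TSV, required), ``matrix_scale`` ("log2" default, or "rpkm"),
      ``pseudocount``, ``softness``
    - ``pathway_panel`` (panel TSV; default: bundled Wnt panel),
      ``tc_prior_odds``
    - ``test_matrix`` / ``test_labels`` (optional)
    - ``depth`` — list of {sample, path, dialect} (optional)
    - ``variants`` — list of {sample, vcf, callable_bed, breadth}
      (breadth may be omitted when a depth entry provides it);
      ``driver_panel`` (TSV; default bundled), ``breadth_gate``
    - ``out_dir`` (overridden by the ``out_dir`` argument)

    All referenced inputs are validated before any output is written.
    Returns a dict of the in-memory results.
    """
    if isinstance(config, (str, Path)):
        with open(_require(config, "config file")) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise PipelineError("config must be a mapping")

    out = Path(out_dir or config.get("out_dir", "."))

    from importlib import resources

    data_dir = resources.files("cellpath") / "data"
    panel_path = config.get("pathway_panel") or str(data_dir / "wnt_target_panel_synthetic.tsv")
    driver_panel_path = config.get("driver_panel") or str(data_dir / "ls174t_driver_panel.tsv")

    # --- validate every input up front: no partial outputs on failure
    cal_matrix_path = _require(config.get("calibration_matrix", ""), "calibration matrix")
    cal_labels_path = _require(config.get("calibration_labels", ""), "calibration labels")
    _require(panel_path, "pathway panel")
    test_matrix_path = config.get("test_matrix")
    if test_matrix_path:
        test_matrix_path = _require(test_matrix_path, "test matrix")
    test_labels_path = config.get("test_labels")
    if test_labels_path:
        test_labels_path = _require(test_labels_path, "test labels")
    depth_cfg = config.get("depth") or []
    for entry in depth_cfg:
        _require(entry["path"], f"depth input for {entry.get('sample')}")
    variants_cfg = config.get("variants") or []
    for entry in variants_cfg:
        _require(entry["vcf"], f"VCF for {entry.get('sample')}")
        _require(entry["callable_bed"], f"callable BED for {entry.get('sample')}")
    if variants_cfg:
        _require(driver_panel_path, "driver panel")

    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("cellpath")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    results: dict = {}
    try:
        scale = config.get("matrix_scale", calibration.SCALE_LOG2)
        pseudocount = float(config.get("pseudocount", 1.0))
        softness = float(config.get("softness", 0.25))
        model = read_panel_tsv(panel_path, tc_prior_odds=float(config.get("tc_prior_odds", 1.0)))
        logger.info("pathway model: %d target genes", len(model.genes))

        cal = calibration.read_expression_matrix(cal_matrix_path, scale=scale)
        if cal.scale == calibration.SCALE_RPKM:
            cal = calibration.log_transform(cal, pseudocount)
        cal_labels = _read_labels_tsv(cal_labels_path)
        thresholds = calibration.fit_thresholds(cal, cal_labels)
        n_discordant = int((~thresholds.direction_ok).sum())
        if n_discordant:
            logger.info("%d gene(s) with discordant calibration direction", n_discordant)
        thr_df = pd.DataFrame(
            {
                "gene": thresholds.genes,
                "threshold": thresholds.thresholds.to_numpy(),
                "direction_ok": thresholds.direction_ok.to_numpy(),
            }
        )
        thr_df.to_csv(out / "thresholds.tsv", sep="\t", index=False)
        results["thresholds"] = thresholds

        matrices = {"calibration": cal}
        if test_matrix_path:
            test = calibration.read_expression_matrix(test_matrix_path, scale=scale)
            if test.scale == calibration.SCALE_RPKM:
                test = calibration.log_transform(test, pseudocount)
            matrices["test"] = test

        # score every sample (calibration samples serve as a sanity check)
        odds_rows = []
        q_blocks = []
        predictions: dict[str, str] = {}
        for group, m in matrices.items():
            q = calibration.evidence_matrix(m, thresholds, softness)
            q_blocks.append(q)
            for sample in m.samples:
                ev = calibration.evidence_from_sample(m, sample, thresholds, softness)
                res = infer_log_odds(model, ev)
                label = classify(res)
                predictions[sample] = label
                odds_rows.append(
                    {
                        "sample": sample,
                        "group": group,
                        "log_odds": res.log_odds,
                        "log10_odds": res.log10_odds,
                        "n_genes_used": res.n_genes_used,
                        "predicted": label,
                    }
                )
        odds_df = pd.DataFrame(odds_rows)
        odds_df.to_csv(out / "odds.tsv", sep="\t", index=False)
        results["odds"] = odds_df

        q_all = pd.concat(q_blocks, axis=1)
        calibration.export_cluster_matrix(q_all, out / "cluster_matrix.tsv")

        truth = dict(cal_labels)
        if test_labels_path:
            truth.update(_read_labels_tsv(test_labels_path))
        labelled = {s: t for s, t in truth.items() if s in predictions}
        if labelled:
            evaluation = evaluate_classification(labelled, predictions)
            results["classification"] = evaluation
            order = (ACTIVE, INACTIVE)
            summary = pd.DataFrame(
                {
                    "n_labelled": [len(labelled)],
                    "accuracy": [evaluation.accuracy],
                    "fisher_p": [evaluation.fisher_p],
                    "true_active_pred_active": [evaluation.confusion[0, 0]],
                    "true_active_pred_inactive": [evaluation.confusion[0, 1]],
                    "true_inactive_pred_active": [evaluation.confusion[1, 0]],
                    "true_inactive_pred_inactive": [evaluation.confusion[1, 1]],
                }
            )
            summary.to_csv(out / "classification_summary.tsv", sep="\t", index=False)
            logger.info(
                "classification: accuracy %.4f, Fisher p %.3g over %d labelled samples",
                evaluation.accuracy,
                evaluation.fisher_p,
                len(labelled),
            )

        breadths: dict[str, float] = {}
        if depth_cfg:
            cov_rows = []
            for entry in depth_cfg:
                sample = entry["sample"]
                h = coverage_qc.read_depth_histogram(entry["path"], entry.get("dialect", "histogram"))
                summary = coverage_qc.coverage_summary(h)
                breadths[sample] = summary.breadth
                row = {"sample": sample}
                row.update(summary.__dict__)
                cov_rows.append(row)
                lor = coverage_qc.lorenz_curve(h)
                coverage_qc.write_xy_tsv(
                    lor.points,
                    out / f"lorenz_{sample}.tsv",
                    header=("genome_fraction", "read_fraction"),
                )
            cov_df = pd.DataFrame(cov_rows)
            cov_df.to_csv(out / "coverage_summary.tsv", sep="\t", index=False)
            results["coverage"] = cov_df

        if variants_cfg:
            gate = float(config.get("breadth_gate", variant_panel.DEFAULT_BREADTH_GATE))
            panel = variant_panel.load_panel(driver_panel_path)
            reports = []
            for entry in variants_cfg:
                sample = entry["sample"]
                breadth = entry.get("breadth", breadths.get(sample))
                if breadth is None:
                    raise PipelineError(
                        f"no breadth for sample {sample!r}: provide 'breadth' or a depth input"
                    )
                report = variant_panel.screen_sample(
                    entry["vcf"],
                    panel,
                    entry["callable_bed"],
                    float(breadth),
                    sample=sample,
                    breadth_gate=gate,
                )
                if all(s == variant_panel.SAMPLE_EXCLUDED for s in report.statuses.values()):
                    logger.info("sample %s excluded: breadth %.3f < gate %.2f", sample, breadth, gate)
                reports.append(report)
            grid, tallies = variant_panel.aggregate_reports(reports)
            grid.to_csv(out / "panel_report.tsv", sep="\t")
            tallies.to_csv(out / "panel_tallies.tsv", sep="\t", index=False)
            results["panel_report"] = grid
            results["panel_tallies"] = tallies
    finally:
        root.removeHandler(handler)
        handler.close()
    return results
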