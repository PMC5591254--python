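"""Expression calibration: thresholds on labelled samples, soft evidence.

The pathway model consumes, per target gene, the probability ``q`` that
the gene's measured expression lies above a threshold.  Thresholds are
calibrated on a handful of labelled bulk samples of known pathway
status: for each gene the threshold is the midpoint between the mean
log2 RPKM of the "active" group and that of the "inactive" group.
Expression values are then converted to soft calls with a logistic
whose width (``softness``, in log2 units) sets how graded the call is;
``softness = 0`` recovers hard above/below calls.

Gene-name matching is case-insensitive after whitespace trimming
throughout, since expression matrices and panels often come from mixed
sources.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .pathway_model import MISSING, _norm_gene

__all__ = [
    "ExpressionMatrix",
    "ThresholdSet",
    "read_expression_matrix",
    "log_transform",
    "fit_thresholds",
    "soft_call",
    "evidence_from_sample",
    "evidence_matrix",
    "export_cluster_matrix",
    "ACTIVE",
    "INACTIVE",
]

logger = logging.getLogger(__name__)

ACTIVE = "active"
INACTIVE = "inactive"

SCALE_RPKM = "rpkm"
SCALE_LOG2 = "log2"


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with an explicit scale.

    ``values`` is a pandas DataFrame with gene rows and sample columns;
    ``scale`` is ``"rpkm"`` (raw, non-negative) or ``"log2"``
    (log2(RPKM + pseudocount)).
    """

    values: pd.DataFrame
    scale: str = SCALE_LOG2

    def __post_init__(self) -> None:
        if self.scale not in (SCALE_RPKM, SCALE_LOG2):
            raise ValueError(f"scale must be 'rpkm' or 'log2', got {self.scale!r}")
        genes = [_norm_gene(g) for g in self.values.index]
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate gene names in expression matrix")
        samples = [str(s).strip() for s in self.values.columns]
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample names in expression matrix")
        if self.scale == SCALE_RPKM and (self.values.to_numpy() < 0).any():
            raise ValueError("negative values are not valid on the RPKM scale")

    @property
    def genes(self) -> list[str]:
        return [str(g) for g in self.values.index]

    @property
    def samples(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    def locate_gene(self, name: str) -> Optional[str]:
        """Row label matching ``name`` case-insensitively, or None."""
        key = _norm_gene(name)
        for g in self.values.index:
            if _norm_gene(g) == key:
                return g
        return None


def read_expression_matrix(path, scale: str = SCALE_LOG2) -> ExpressionMatrix:
    """Read a genes-x-samples TSV (first column gene names, header row samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty expression matrix")
    try:
        df = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric cell in expression matrix") from exc
    df.index = df.index.map(str)
    return ExpressionMatrix(values=df, scale=scale)


def log_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(RPKM + pseudocount); rejects an already-transformed matrix."""
    if m.scale != SCALE_RPKM:
        raise ValueError("matrix is already on the log2 scale")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return ExpressionMatrix(values=np.log2(m.values + pseudocount), scale=SCALE_LOG2)


@dataclass
class ThresholdSet:
    """Per-gene expression thresholds from labelled calibration samples.

    ``thresholds`` holds the midpoint of the active-group and
    inactive-group means (log2 RPKM); ``direction_ok`` is False for
    genes whose active mean did not exceed the inactive mean (kept, but
    flagged, since the Bayesian combination tolerates noisy genes).
    """

    thresholds: pd.Series
    direction_ok: pd.Series

    def __post_init__(self) -> None:
        if not np.isfinite(self.thresholds.to_numpy(dtype=float)).all():
            raise ValueError("thresholds must be finite")

    @property
    def genes(self) -> list[str]:
        return [str(g) for g in self.thresholds.index]


def fit_thresholds(
    m: ExpressionMatrix, labels: Mapping[str, str]
) -> ThresholdSet:
    """Midpoint-of-class-means threshold per gene.

    ``labels`` maps sample name to "active"/"inactive"; both classes
    must be represented.  Genes whose inactive mean is >= the active
    mean are retained with ``direction_ok = False`` and a warning.
    """
    if m.scale != SCALE_LOG2:
        raise ValueError("thresholds are calibrated on the log2 scale")
    by_class: dict[str, list[str]] = {ACTIVE: [], INACTIVE: []}
    for sample, label in labels.items():
        if label not in by_class:
            raise ValueError(f"label for {sample!r} must be 'active' or 'inactive'")
        if sample not in m.values.columns:
            raise KeyError(f"labelled sample {sample!r} not in expression matrix")
        by_class[label].append(sample)
    for label, cols in by_class.items():
        if not cols:
            raise ValueError(f"no calibration sample labelled {label!r}")

    active_mean = m.values[by_class[ACTIVE]].mean(axis=1)
    inactive_mean = m.values[by_class[INACTIVE]].mean(axis=1)
    if active_mean.isna().any() or inactive_mean.isna().any():
        bad = sorted(m.values.index[active_mean.isna() | inactive_mean.isna()])
        raise ValueError(f"gene(s) with no calibration values: {bad}")

    thresholds = (active_mean + inactive_mean) / 2.0
    direction_ok = active_mean > inactive_mean
    for gene in m.values.index[~direction_ok]:
        logger.warning(
            "gene %s: active calibration mean does not exceed inactive mean "
            "(kept with direction_ok=False)",
            gene,
        )
    return ThresholdSet(thresholds=thresholds, direction_ok=direction_ok)


def soft_call(x, threshold, softness: float):
    """Probability that expression ``x`` is above ``threshold``.

    Logistic in ``(x - threshold) / softness``; ``softness = 0`` gives a
    hard call (1 above, 0 below, 0.5 at equality).  Accepts scalars or
    arrays.
    """
    if softness < 0:
        raise ValueError("softness must be >= 0")
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(threshold, dtype=float)
    if softness == 0:
        q = np.where(d > 0, 1.0, np.where(d < 0, 0.0, 0.5))
    else:
        from scipy.special import expit

        q = expit(d / softness)
    return float(q) if q.ndim == 0 else q


def evidence_from_sample(
    m: ExpressionMatrix,
    sample: str,
    thresholds: ThresholdSet,
    softness: float = 0.25,
) -> dict[str, Optional[float]]:
    """Soft-evidence vector for one sample.

    One entry per threshold gene: ``q`` from :func:`soft_call`, or
    MISSING when the gene is absent from the matrix.
    """
    if sample not in m.values.columns:
        raise KeyError(f"unknown sample {sample!r}")
    evidence: dict[str, Optional[float]] = {}
    for gene in thresholds.genes:
        row = m.locate_gene(gene)
        if row is None:
            evidence[gene] = MISSING
            continue
        x = m.values.at[row, sample]
        if pd.isna(x):
            evidence[gene] = MISSING
            continue
        evidence[gene] = soft_call(float(x), float(thresholds.thresholds[gene]), softness)
    return evidence


def evidence_matrix(
    m: ExpressionMatrix, thresholds: ThresholdSet, softness: float = 0.25
) -> pd.DataFrame:
    """Gene x sample matrix of soft calls (NaN where MISSING)."""
    cols = {}
    for sample in m.samples:
        ev = evidence_from_sample(m, sample, thresholds, softness)
        cols[sample] = {g: (np.nan if q is MISSING else q) for g, q in ev.items()}
    return pd.DataFrame(cols, index=thresholds.genes, columns=m.samples, dtype=float)


def export_cluster_matrix(q_matrix: pd.DataFrame, path) -> None:
    """Write the soft-call matrix (genes x samples) for cluster display.

    Values to 4 decimals, MISSING as "NA"; rejects q outside [0, 1].
    """
    vals = q_matrix.to_numpy(dtype=float)
    finite = np.isfinite(vals)
    if ((vals[finite] < 0) | (vals[finite] > 1)).any():
        raise ValueError("soft calls must lie in [0, 1]")
    q_matrix.to_csv(path, sep="\t", float_format="%.4f", na_rep="NA")
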