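"""Bayesian network model of transcription-complex (TC) activity.

The network has three layers: a latent binary root node for the
transcription complex (e.g. TCF4/beta-catenin for the canonical Wnt
pathway), one binary node per target gene (transcriptionally up or down),
and one binary measurement node per gene (measured expression above or
below its calibrated threshold).  Evidence enters as *soft* calls: for
each gene a probability ``q`` that the measurement is in the "high"
state, handled as virtual evidence (likelihood weights ``q : 1 - q`` on
the measurement node), never by clamping.

Because the graph is a tree rooted at the TC node, exact inference
reduces to a product of per-gene likelihood ratios; a full-joint
enumeration oracle (:func:`infer_log_odds_bruteforce`) is provided for
cross-checking.

The default conditional probability tables encode the model's one
quantitative asymmetry: an up-regulated call moves the log-odds five
times as far towards "active" as a non-up-regulated call moves it
towards "inactive" (composite likelihood ratios ``lr_high = 5`` and
``lr_low = 5**(-1/5)``).
"""

from __future__ import annotations

import csv
import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "TargetGeneSpec",
    "PathwayModel",
    "InferenceResult",
    "build_model",
    "composite_lr",
    "infer_log_odds",
    "infer_log_odds_bruteforce",
    "read_panel_tsv",
    "write_panel_tsv",
    "DEFAULT_LR_HIGH",
    "DEFAULT_LR_LOW",
]

#: Sentinel for absent evidence on a gene's measurement node.
MISSING = None

# Composite likelihood-ratio targets for the default tables: a "high"
# measurement multiplies the active:inactive odds by 5, a "low"
# measurement divides them by 5**(1/5), so on the log scale an
# up-regulated gene weighs 5x a non-up-regulated one.
DEFAULT_LR_HIGH = 5.0
DEFAULT_LR_LOW = 5.0 ** (-1.0 / 5.0)

DEFAULT_P_UP_GIVEN_ACTIVE = 0.95
DEFAULT_P_UP_GIVEN_INACTIVE = 0.05


def _solve_measurement_cpt(
    lr_high: float,
    lr_low: float,
    p_up_given_active: float,
    p_up_given_inactive: float,
) -> tuple[float, float]:
    """Solve measurement-layer CPT entries hitting the composite LRs.

    With A = P(high | TC active) and B = P(high | TC inactive), the two
    constraints A/B = lr_high and (1-A)/(1-B) = lr_low give B in closed
    form; inverting the gene-layer mixing then yields
    (p_high_given_up, p_high_given_down).
    """
    b = (1.0 - lr_low) / (lr_high - lr_low)
    a = lr_high * b
    det = p_up_given_active - p_up_given_inactive
    p_high_up = ((1.0 - p_up_given_inactive) * a - (1.0 - p_up_given_active) * b) / det
    p_high_down = (p_up_given_active * b - p_up_given_inactive * a) / det
    return p_high_up, p_high_down


DEFAULT_P_HIGH_GIVEN_UP, DEFAULT_P_HIGH_GIVEN_DOWN = _solve_measurement_cpt(
    DEFAULT_LR_HIGH,
    DEFAULT_LR_LOW,
    DEFAULT_P_UP_GIVEN_ACTIVE,
    DEFAULT_P_UP_GIVEN_INACTIVE,
)


def _check_prob_open(name: str, value: float) -> None:
    if not (0.0 < value < 1.0):
        raise ValueError(f"{name} must lie strictly in (0, 1), got {value!r}")


@dataclass(frozen=True)
class TargetGeneSpec:
    """CPTs for one positively regulated target gene.

    ``p_up_given_active``/``p_up_given_inactive`` parameterize the
    TC -> gene edge; ``p_high_given_up``/``p_high_given_down`` the
    gene -> measurement edge.  All probabilities strictly in (0, 1);
    the gene must be induced by the TC (``p_up_given_active >
    p_up_given_inactive``) and the measurement informative
    (``p_high_given_up > p_high_given_down``).
    """

    name: str
    p_up_given_active: float = DEFAULT_P_UP_GIVEN_ACTIVE
    p_up_given_inactive: float = DEFAULT_P_UP_GIVEN_INACTIVE
    p_high_given_up: float = DEFAULT_P_HIGH_GIVEN_UP
    p_high_given_down: float = DEFAULT_P_HIGH_GIVEN_DOWN

    def __post_init__(self) -> None:
        if not self.name or not str(self.name).strip():
            raise ValueError("gene name must be non-empty")
        for attr in (
            "p_up_given_active",
            "p_up_given_inactive",
            "p_high_given_up",
            "p_high_given_down",
        ):
            _check_prob_open(attr, getattr(self, attr))
        if not self.p_up_given_active > self.p_up_given_inactive:
            raise ValueError(
                f"{self.name}: p_up_given_active must exceed p_up_given_inactive "
                "(only positively regulated targets are supported)"
            )
        if not self.p_high_given_up > self.p_high_given_down:
            raise ValueError(
                f"{self.name}: p_high_given_up must exceed p_high_given_down"
            )


def _norm_gene(name: str) -> str:
    """Case-insensitive, whitespace-trimmed gene-name key."""
    return str(name).strip().upper()


@dataclass(frozen=True)
class PathwayModel:
    """A pathway model: prior odds on the TC plus its target genes."""

    genes: tuple[TargetGeneSpec, ...]
    tc_prior_odds: float = 1.0

    def __post_init__(self) -> None:
        if self.tc_prior_odds <= 0 or not math.isfinite(self.tc_prior_odds):
            raise ValueError("tc_prior_odds must be a positive finite number")
        keys = [_norm_gene(g.name) for g in self.genes]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate gene name(s): {', '.join(dupes)}")

    @property
    def gene_names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.genes)

    def gene_index(self) -> dict[str, TargetGeneSpec]:
        return {_norm_gene(g.name): g for g in self.genes}


@dataclass(frozen=True)
class InferenceResult:
    """Posterior log-odds of TC activity and its per-gene decomposition.

    ``log_odds`` is the natural log of the posterior active:inactive
    odds; it always equals ``ln(tc_prior_odds)`` plus the sum of
    ``per_gene_log_lr`` (genes with MISSING evidence contribute 0).
    """

    log_odds: float
    per_gene_log_lr: dict[str, float]
    n_genes_used: int

    @property
    def log10_odds(self) -> float:
        return self.log_odds / math.log(10.0)


def composite_lr(gene) -> tuple[float, float]:
    """Likelihood ratios of a high/low measurement, gene layer summed out.

    Returns ``(lr_high, lr_low)`` with
    ``lr_high = P(measurement high | TC active) / P(high | TC inactive)``
    where ``P(high | TC) = sum_state P(high | state) P(state | TC)``,
    and ``lr_low`` analogously for a low measurement.
    """
    a = _p_high_given_tc(gene, active=True)
    b = _p_high_given_tc(gene, active=False)
    return a / b, (1.0 - a) / (1.0 - b)


def _p_high_given_tc(gene, active: bool) -> float:
    p_up = gene.p_up_given_active if active else gene.p_up_given_inactive
    return p_up * gene.p_high_given_up + (1.0 - p_up) * gene.p_high_given_down


def build_model(
    panel: Sequence[str],
    cpt_config: Optional[Mapping[str, Mapping[str, float]]] = None,
    tc_prior_odds: float = 1.0,
) -> PathwayModel:
    """Build a :class:`PathwayModel` from a gene panel.

    Parameters
    ----------
    panel:
        Non-empty list of unique gene symbols.
    cpt_config:
        Optional per-gene CPT overrides, keyed by gene name
        (case-insensitive); each value maps TargetGeneSpec field names
        to probabilities.  Omitted entries fall back to the defaults,
        which satisfy the factor-of-five weighting.
    tc_prior_odds:
        Prior active:inactive odds on the TC node (default 1, i.e.
        uninformative; the reported log-odds then reflect the evidence
        alone).
    """
    if len(panel) == 0:
        raise ValueError("panel must be non-empty")
    overrides = { _norm_gene(k): dict(v) for k, v in (cpt_config or {}).items() }
    unknown = set(overrides) - {_norm_gene(g) for g in panel}
    if unknown:
        raise ValueError(f"cpt_config references genes not in panel: {sorted(unknown)}")
    genes = tuple(
        TargetGeneSpec(name=name, **overrides.get(_norm_gene(name), {}))
        for name in panel
    )
    return PathwayModel(genes=genes, tc_prior_odds=tc_prior_odds)


def _validate_evidence(
    model: PathwayModel, evidence: Mapping[str, Optional[float]]
) -> dict[str, Optional[float]]:
    """Normalize evidence keys and reject genes absent from the model."""
    index = model.gene_index()
    out: dict[str, Optional[float]] = {}
    for key, q in evidence.items():
        nkey = _norm_gene(key)
        if nkey not in index:
            raise KeyError(f"evidence references unknown gene {key!r}")
        if q is not MISSING:
            q = float(q)
            if not (0.0 <= q <= 1.0) or not math.isfinite(q):
                raise ValueError(f"evidence q for {key!r} must be in [0, 1], got {q}")
        out[nkey] = q
    return out


def infer_log_odds(
    model: PathwayModel, evidence: Mapping[str, Optional[float]]
) -> InferenceResult:
    """Exact posterior log-odds of TC activity under soft evidence.

    Each gene with evidence ``q`` contributes
    ``ln[(q A + (1-q)(1-A)) / (q B + (1-q)(1-B))]`` with
    ``A = P(high | active)`` and ``B = P(high | inactive)`` (gene layer
    marginalized); MISSING genes contribute exactly 0.
    """
    ev = _validate_evidence(model, evidence)
    per_gene: dict[str, float] = {}
    n_used = 0
    total = math.log(model.tc_prior_odds)
    for gene in model.genes:
        q = ev.get(_norm_gene(gene.name), MISSING)
        if q is MISSING:
            per_gene[gene.name] = 0.0
            continue
        a = _p_high_given_tc(gene, active=True)
        b = _p_high_given_tc(gene, active=False)
        llr = math.log(q * a + (1.0 - q) * (1.0 - a)) - math.log(
            q * b + (1.0 - q) * (1.0 - b)
        )
        per_gene[gene.name] = llr
        total += llr
        n_used += 1
    return InferenceResult(log_odds=total, per_gene_log_lr=per_gene, n_genes_used=n_used)


_BRUTEFORCE_MAX_GENES = 15
_CHUNK_ROWS = 2048


def infer_log_odds_bruteforce(
    model: PathwayModel, evidence: Mapping[str, Optional[float]]
) -> float:
    """Oracle: posterior log-odds by full-joint enumeration.

    Enumerates every configuration of TC state x all gene states x all
    measurement states, applies virtual-evidence weights ``q`` ("high")
    and ``1 - q`` ("low") per measurement node (MISSING -> weight 1 on
    both states), and conditions.  Intentionally independent of the
    factorized path in :func:`infer_log_odds`; guarded to <= 15 genes.
    """
    ev = _validate_evidence(model, evidence)
    n = len(model.genes)
    if n > _BRUTEFORCE_MAX_GENES:
        raise ValueError(f"bruteforce enumeration limited to {_BRUTEFORCE_MAX_GENES} genes")
    if n == 0:
        return math.log(model.tc_prior_odds)

    # states[i, g] = 0/1 state of node g in configuration i (down/up for
    # the gene layer, low/high for the measurement layer).
    states = np.array(list(itertools.product((0, 1), repeat=n)), dtype=np.intp)
    n_states = states.shape[0]

    # Per-gene 2x2 factor M[u, m] = P(meas=m | gene=u) * weight(m).
    meas_factor = []
    for gene in model.genes:
        q = ev.get(_norm_gene(gene.name), MISSING)
        w_high, w_low = (1.0, 1.0) if q is MISSING else (q, 1.0 - q)
        m = np.array(
            [
                [(1.0 - gene.p_high_given_down) * w_low, gene.p_high_given_down * w_high],
                [(1.0 - gene.p_high_given_up) * w_low, gene.p_high_given_up * w_high],
            ]
        )
        meas_factor.append(m)

    def total_mass(active: bool) -> float:
        p_up = np.array(
            [
                g.p_up_given_active if active else g.p_up_given_inactive
                for g in model.genes
            ]
        )
        # P(gene configuration | TC) for every row of `states`.
        gene_mass = np.prod(np.where(states == 1, p_up, 1.0 - p_up), axis=1)
        total = 0.0
        for lo in range(0, n_states, _CHUNK_ROWS):
            rows = slice(lo, min(lo + _CHUNK_ROWS, n_states))
            w = np.ones((states[rows].shape[0], n_states))
            for g in range(n):
                w *= meas_factor[g][states[rows, g]][:, states[:, g]]
            total += float(gene_mass[rows] @ w.sum(axis=1))
        return total

    prior_on = model.tc_prior_odds
    return math.log(prior_on * total_mass(True)) - math.log(total_mass(False))


_PANEL_COLUMNS = (
    "gene",
    "p_up_given_active",
    "p_up_given_inactive",
    "p_high_given_up",
    "p_high_given_down",
)


def read_panel_tsv(path, tc_prior_odds: float = 1.0) -> PathwayModel:
    """Read a gene-panel TSV into a model.

    Columns: gene, p_up_given_active, p_up_given_inactive,
    p_high_given_up, p_high_given_down.  Empty cells fall back to the
    default CPTs.
    """
    genes: list[str] = []
    overrides: dict[str, dict[str, float]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "gene" not in reader.fieldnames:
            raise ValueError(f"{path}: panel TSV must have a 'gene' column")
        for row in reader:
            name = row["gene"].strip()
            if not name:
                continue
            genes.append(name)
            cfg = {
                col: float(row[col])
                for col in _PANEL_COLUMNS[1:]
                if row.get(col) not in (None, "")
            }
            if cfg:
                overrides[name] = cfg
    return build_model(genes, overrides or None, tc_prior_odds=tc_prior_odds)


def write_panel_tsv(model: PathwayModel, path) -> None:
    """Write a model's panel to TSV; round-trips through repr strings."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_PANEL_COLUMNS)
        for g in model.genes:
            writer.writerow(
                [
                    g.name,
                    repr(g.p_up_given_active),
                    repr(g.p_up_given_inactive),
                    repr(g.p_high_given_up),
                    repr(g.p_high_given_down),
                ]
            )
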