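"""Synthetic data with the statistical structure the analysis assumes.

Three generators, all deterministic given a seed:

* expression — log2 RPKM values, Gaussian around a per-gene baseline
  ``mu_g``, shifted up by ``delta_g`` in pathway-active samples; in
  single-cell mode a value drops out (to ``log2(pseudocount)``) with a
  probability that grows linearly as the baseline falls below a
  reference level, emulating the vulnerability of lowly expressed
  genes to amplification dropout;
* depth — per-bin sequencing depth from a zero-inflated negative
  binomial, the two knobs (overdispersion and zero-inflation)
  emulating whole-genome-amplification bias and locus dropout;
* variant calls — minimal VCF 4.2 files with planted driver variants,
  plus callable-region BEDs, for exercising the panel screen.

``depth_dispersion`` is the overdispersion coefficient ``alpha`` with
``variance = mu + alpha * mu**2`` (negative-binomial size ``1/alpha``);
``alpha = 0`` selects the exact Poisson branch.  Each generator returns
a manifest recording ground truth for end-to-end checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import ACTIVE, INACTIVE, SCALE_LOG2, ExpressionMatrix
from .coverage_qc import DepthHistogram
from .variant_panel import DriverVariant

__all__ = ["SyntheticConfig", "simulate_expression", "simulate_depth", "write_variant_calls"]

MODE_BULK = "bulk"
MODE_SINGLE_CELL = "single_cell"


@dataclass(frozen=True)
class SyntheticConfig:
    """All generator parameters.

    Expression: per-gene baseline ``mu`` (log2 RPKM; default spread
    evenly over 2–8 across the panel), activation effect ``delta``
    (log2 units, default 2.0), Gaussian ``noise_sd`` (default 0.5).
    Single-cell dropout: probability
    ``min(1, dropout_base + dropout_slope * max(0, dropout_ref - mu_g))``,
    dropping the value to ``log2(pseudocount)``.

    Depth: ``depth_mean`` (x), overdispersion ``depth_dispersion``
    (alpha; variance = mu + alpha mu^2, 0 = Poisson), ``zero_inflation``
    (extra point mass at depth 0), over ``genome_bins`` bins.  The
    defaults (16.2x, alpha 1.0, zero-inflation 0.05) emulate a
    single-cell WGA library with roughly 10% of the genome uncovered at
    a mean depth of ~16x.
    """

    genes: tuple[str, ...]
    mu: Optional[Mapping[str, float]] = None
    delta: float = 2.0
    noise_sd: float = 0.5
    n_active: int = 0
    n_inactive: int = 0
    mode: str = MODE_BULK
    dropout_base: float = 0.1
    dropout_slope: float = 0.15
    dropout_ref: float = 4.0
    pseudocount: float = 1.0
    depth_mean: float = 16.2
    depth_dispersion: float = 1.0
    zero_inflation: float = 0.05
    genome_bins: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("at least one gene required")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_active < 0 or self.n_inactive < 0:
            raise ValueError("sample counts must be >= 0")
        if self.mode not in (MODE_BULK, MODE_SINGLE_CELL):
            raise ValueError(f"unknown mode {self.mode!r}")
        for name in ("dropout_base", "zero_inflation"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.dropout_slope < 0:
            raise ValueError("dropout_slope must be >= 0")
        if self.depth_mean <= 0 or self.depth_dispersion < 0:
            raise ValueError("depth_mean must be > 0 and depth_dispersion >= 0")
        if self.genome_bins < 1:
            raise ValueError("genome_bins must be >= 1")

    def gene_mu(self) -> dict[str, float]:
        if self.mu is not None:
            return {g: float(self.mu[g]) for g in self.genes}
        n = len(self.genes)
        spread = np.linspace(2.0, 8.0, n) if n > 1 else np.array([5.0])
        return dict(zip(self.genes, spread.tolist()))


def simulate_expression(
    cfg: SyntheticConfig,
) -> tuple[ExpressionMatrix, dict[str, str], pd.DataFrame]:
    """Simulate a log2-scale expression matrix with known labels.

    Returns (matrix, labels, manifest); the manifest records, per
    (sample, gene), the baseline, effect, pre-dropout draw and whether
    the value was dropped.  Bit-identical for identical seeds.
    """
    rng = np.random.default_rng(cfg.seed)
    mu = cfg.gene_mu()
    samples = [f"active_{i + 1:03d}" for i in range(cfg.n_active)] + [
        f"inactive_{i + 1:03d}" for i in range(cfg.n_inactive)
    ]
    labels = {
        s: (ACTIVE if s.startswith("active") else INACTIVE) for s in samples
    }
    floor = math.log2(cfg.pseudocount)

    records = []
    data = np.empty((len(cfg.genes), len(samples)))
    for j, sample in enumerate(samples):
        is_active = labels[sample] == ACTIVE
        for i, gene in enumerate(cfg.genes):
            mean = mu[gene] + (cfg.delta if is_active else 0.0)
            value = rng.normal(mean, cfg.noise_sd)
            dropped = False
            if cfg.mode == MODE_SINGLE_CELL:
                p_drop = min(
                    1.0,
                    cfg.dropout_base
                    + cfg.dropout_slope * max(0.0, cfg.dropout_ref - mu[gene]),
                )
                dropped = bool(rng.random() < p_drop)
            final = floor if dropped else value
            data[i, j] = final
            records.append(
                {
                    "sample": sample,
                    "gene": gene,
                    "label": labels[sample],
                    "mu": mu[gene],
                    "delta": cfg.delta if is_active else 0.0,
                    "value_pre_dropout": value,
                    "dropped": dropped,
                    "value": final,
                }
            )
    matrix = ExpressionMatrix(
        values=pd.DataFrame(data, index=list(cfg.genes), columns=samples),
        scale=SCALE_LOG2,
    )
    return matrix, labels, pd.DataFrame(records)


def simulate_depth(cfg: SyntheticConfig, seed: Optional[int] = None) -> DepthHistogram:
    """Per-bin depth from a zero-inflated negative binomial.

    ``seed`` overrides ``cfg.seed`` so one config can generate several
    independent samples.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.genome_bins
    alpha = cfg.depth_dispersion
    if alpha == 0:
        depths = rng.poisson(cfg.depth_mean, size=n)
    else:
        size = 1.0 / alpha
        p = size / (size + cfg.depth_mean)
        depths = rng.negative_binomial(size, p, size=n)
    if cfg.zero_inflation > 0:
        depths = np.where(rng.random(n) < cfg.zero_inflation, 0, depths)
    counts = np.bincount(depths)
    entries = {int(d): int(c) for d, c in enumerate(counts) if c > 0}
    return DepthHistogram(entries=entries)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=cellpath synthetic variant generator
{contigs}##FILTER=<ID=PASS,Description="All filters passed">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_variant_calls(
    plant: Mapping[str, Sequence[DriverVariant]],
    panel: Sequence[DriverVariant],
    out_dir,
    uncallable: Optional[Mapping[str, Sequence[DriverVariant]]] = None,
) -> pd.DataFrame:
    """Write per-sample VCFs and callable BEDs with planted variants.

    ``plant`` maps sample name to the panel variants present in that
    sample (heterozygous 0/1, FILTER PASS); ``uncallable`` marks panel
    sites to exclude from a sample's callable BED.  Returns the
    manifest: per (sample, variant), the paths and the status the panel
    screen is expected to report (before breadth gating).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panel_set = set(panel)
    uncallable = uncallable or {}
    for mapping, what in ((plant, "plant"), (uncallable, "uncallable")):
        for sample, variants in mapping.items():
            unknown = [v for v in variants if v not in panel_set]
            if unknown:
                raise ValueError(
                    f"{what} for {sample!r} references variants outside the panel: "
                    f"{[v.label for v in unknown]}"
                )

    contigs = "".join(
        f"##contig=<ID={chrom}>\n" for chrom in dict.fromkeys(v.chrom for v in panel)
    )
    records = []
    for sample, variants in plant.items():
        planted = set(variants)
        masked = set(uncallable.get(sample, ()))
        vcf_path = out_dir / f"{sample}.vcf"
        bed_path = out_dir / f"{sample}.callable.bed"
        with open(vcf_path, "w", newline="") as fh:
            fh.write(_VCF_HEADER.format(contigs=contigs, sample=sample))
            for v in sorted(planted, key=lambda v: (v.chrom, v.pos)):
                fh.write(
                    f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t0/1\n"
                )
        with open(bed_path, "w", newline="") as fh:
            for v in sorted(panel_set, key=lambda v: (v.chrom, v.pos)):
                if v not in masked:
                    fh.write(f"{v.chrom}\t{v.pos - 1}\t{v.pos}\n")
        for v in panel:
            if v in planted:
                expected = "mutant"
            elif v in masked:
                expected = "insufficient_coverage"
            else:
                expected = "wild_type"
            records.append(
                {
                    "sample": sample,
                    "variant": v.label,
                    "vcf": str(vcf_path),
                    "callable_bed": str(bed_path),
                    "expected_status": expected,
                }
            )
    return pd.DataFrame(records)
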