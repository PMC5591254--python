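"""Coverage-uniformity QC for (single-cell) whole-genome amplification.

Whole-genome amplification of single-cell DNA introduces locus-to-locus
amplification bias; the standard summary is the Lorenz curve of
sequencing coverage — the cumulative fraction of total reads as a
function of the cumulative fraction of genome bases, bases sorted by
increasing depth — together with the coverage profile (fraction of the
genome at depth >= d) and scalar summaries: breadth (fraction of bases
covered at least once), mean depth, fractions at the 20x/30x depths
typically required for SNP calling, and the Gini coefficient (1 minus
twice the area under the Lorenz curve; 0 for perfectly uniform
coverage).

Inputs are per-sample depth histograms, read either from a
genomecov-style histogram TSV or from BED4 depth intervals (0-based,
half-open).  Uncovered bases (depth 0) count toward the genome axis but
contribute no reads, so amplification dropout appears as the flat
initial segment of the Lorenz curve.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "DepthHistogram",
    "LorenzCurve",
    "CoverageSummary",
    "read_depth_histogram",
    "lorenz_curve",
    "coverage_profile",
    "coverage_summary",
    "write_xy_tsv",
]


@dataclass(frozen=True)
class DepthHistogram:
    """Map depth -> number of genome bases at that depth, one sample."""

    entries: dict[int, int]

    def __post_init__(self) -> None:
        for depth, bases in self.entries.items():
            if depth < 0:
                raise ValueError(f"negative depth {depth}")
            if bases <= 0:
                raise ValueError(f"non-positive base count {bases} at depth {depth}")

    @property
    def total_bases(self) -> int:
        return sum(self.entries.values())

    @property
    def total_reads(self) -> int:
        """Total depth mass (sum of depth x bases), proportional to reads."""
        return sum(d * b for d, b in self.entries.items())


@dataclass(frozen=True)
class LorenzCurve:
    """Ordered (genome fraction, read fraction) points from (0,0) to (1,1)."""

    points: tuple[tuple[float, float], ...]

    @property
    def x(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def y(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


@dataclass(frozen=True)
class CoverageSummary:
    mean_depth: float
    breadth: float
    frac_uncovered: float
    frac_ge_20x: float
    frac_ge_30x: float
    gini: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def read_depth_histogram(path, dialect: str) -> DepthHistogram:
    """Read per-sample depth data into a histogram.

    ``dialect="histogram"``: genomecov-style rows
    (label, depth, bases_at_depth, total_bases, fraction); if a summary
    label "genome" is present only those rows are used, otherwise
    per-label rows are aggregated, and per-label totals are checked for
    consistency.

    ``dialect="bed_intervals"``: BED4 rows (chrom, start, end, depth),
    0-based half-open; interval lengths accumulate into base counts and
    overlapping intervals on one chromosome are rejected.
    """
    if dialect == "histogram":
        return _read_histogram_dialect(path)
    if dialect == "bed_intervals":
        return _read_bed_dialect(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_histogram_dialect(path) -> DepthHistogram:
    rows: list[tuple[str, int, int, int]] = []
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 columns")
            label = fields[0]
            depth, bases, total = int(fields[1]), int(fields[2]), int(fields[3])
            if depth < 0:
                raise ValueError(f"{path}:{lineno}: negative depth")
            rows.append((label, depth, bases, total))
    if not rows:
        raise ValueError(f"{path}: empty depth histogram")
    labels = {r[0] for r in rows}
    use = {"genome"} if "genome" in labels else labels
    entries: dict[int, int] = {}
    for label in use:
        label_rows = [r for r in rows if r[0] == label]
        declared_total = {r[3] for r in label_rows}
        if len(declared_total) != 1 or sum(r[2] for r in label_rows) != declared_total.pop():
            raise ValueError(f"{path}: inconsistent total_bases for label {label!r}")
        for _, depth, bases, _ in label_rows:
            if bases:
                entries[depth] = entries.get(depth, 0) + bases
    return DepthHistogram(entries=entries)


def _read_bed_dialect(path) -> DepthHistogram:
    intervals: dict[str, list[tuple[int, int, int]]] = {}
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns (chrom,start,end,depth)")
            chrom, start, end, depth = fields[0], int(fields[1]), int(fields[2]), int(fields[3])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            if depth < 0:
                raise ValueError(f"{path}:{lineno}: negative depth")
            intervals.setdefault(chrom, []).append((start, end, depth))
    if not intervals:
        raise ValueError(f"{path}: empty depth BED")
    entries: dict[int, int] = {}
    for chrom, ivs in intervals.items():
        ivs.sort()
        prev_end = -1
        for start, end, depth in ivs:
            if start < prev_end:
                raise ValueError(f"{path}: overlapping intervals on {chrom}")
            prev_end = end
            entries[depth] = entries.get(depth, 0) + (end - start)
    return DepthHistogram(entries=entries)


def lorenz_curve(h: DepthHistogram) -> LorenzCurve:
    """Lorenz curve of coverage: bases sorted by increasing depth.

    Point k is (cumulative bases / total bases, cumulative depth mass /
    total depth mass) after the k-th depth class; (0, 0) is prepended.
    """
    total_reads = h.total_reads
    if total_reads == 0:
        raise ValueError("no reads: Lorenz curve undefined")
    total_bases = h.total_bases
    points = [(0.0, 0.0)]
    cum_bases = 0
    cum_reads = 0
    for depth in sorted(h.entries):
        bases = h.entries[depth]
        cum_bases += bases
        cum_reads += depth * bases
        points.append((cum_bases / total_bases, cum_reads / total_reads))
    return LorenzCurve(points=tuple(points))


def coverage_profile(h: DepthHistogram, max_depth: int) -> list[tuple[int, float]]:
    """(d, fraction of bases with depth >= d) for d = 1 .. max_depth."""
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    total = h.total_bases
    depths = sorted(h.entries)
    out = []
    for d in range(1, max_depth + 1):
        frac = sum(h.entries[k] for k in depths if k >= d) / total
        out.append((d, frac))
    return out


def _frac_ge(h: DepthHistogram, d: int) -> float:
    return sum(b for depth, b in h.entries.items() if depth >= d) / h.total_bases


def coverage_summary(h: DepthHistogram) -> CoverageSummary:
    """Scalar uniformity summaries; Gini from the trapezoidal Lorenz area."""
    total = h.total_bases
    if total == 0:
        raise ValueError("empty histogram")
    mean_depth = h.total_reads / total
    breadth = _frac_ge(h, 1)
    if h.total_reads > 0:
        lor = lorenz_curve(h)
        gini = 1.0 - 2.0 * float(np.trapezoid(lor.y, lor.x))
    else:
        gini = float("nan")  # Lorenz undefined with zero reads
    return CoverageSummary(
        mean_depth=mean_depth,
        breadth=breadth,
        frac_uncovered=1.0 - breadth,
        frac_ge_20x=_frac_ge(h, 20),
        frac_ge_30x=_frac_ge(h, 30),
        gini=gini,
    )


def write_xy_tsv(points: Iterable[tuple[float, float]], path, header=("x", "y")) -> None:
    """Write an (x, y) curve (Lorenz or coverage profile) as TSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for x, y in points:
            writer.writerow([x, y])
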