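"""Driver-mutation panel screening of per-sample variant calls.

A panel lists known driver mutations (gene, genomic coordinates,
alleles, HGVS labels).  For each single-cell sample the screen assigns
one status per panel entry:

* ``mutant`` — a matching, passing VCF record carrying the alternate
  allele;
* ``wild_type`` — no call at the site, but the site lies inside the
  sample's callable regions (positive evidence of reference);
* ``insufficient_coverage`` — no call and no callable evidence (in
  amplified single-cell DNA, absence of a call is not evidence of the
  reference allele);
* ``sample_excluded`` — the whole sample fails the breadth gate
  (genome fraction covered >= 1x below the gate, default 0.70), so no
  per-site call is attempted.

Multi-allelic records are decomposed; matching is exact on
(chrom, pos, ref, alt) and assumes upstream left-alignment.  Genome
build consistency is the panel file's responsibility.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "DriverVariant",
    "PanelReport",
    "load_panel",
    "read_callable_bed",
    "screen_sample",
    "aggregate_reports",
    "MUTANT",
    "WILD_TYPE",
    "INSUFFICIENT_COVERAGE",
    "SAMPLE_EXCLUDED",
    "DEFAULT_BREADTH_GATE",
]

logger = logging.getLogger(__name__)

MUTANT = "mutant"
WILD_TYPE = "wild_type"
INSUFFICIENT_COVERAGE = "insufficient_coverage"
SAMPLE_EXCLUDED = "sample_excluded"

DEFAULT_BREADTH_GATE = 0.70

_ALLELE_RE = re.compile(r"^[ACGT]+$")


@dataclass(frozen=True)
class DriverVariant:
    """One panel entry; ``cdna``/``protein`` are display labels only."""

    gene: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    cdna: str = ""
    protein: str = ""

    def __post_init__(self) -> None:
        if int(self.pos) < 1:
            raise ValueError(f"{self.gene}: pos must be >= 1")
        for allele in (self.ref, self.alt):
            if not _ALLELE_RE.match(allele):
                raise ValueError(f"{self.gene}: malformed allele {allele!r}")
        if self.ref == self.alt:
            raise ValueError(f"{self.gene}: ref and alt alleles are identical")

    @property
    def label(self) -> str:
        return f"{self.gene}:{self.cdna}" if self.cdna else f"{self.gene}:{self.chrom}:{self.pos}{self.ref}>{self.alt}"


_PANEL_COLUMNS = ("gene", "chrom", "pos", "ref", "alt", "cdna", "protein")


def load_panel(path) -> list[DriverVariant]:
    """Load a driver panel TSV (columns gene, chrom, pos, ref, alt, cdna, protein)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: panel missing column(s) {sorted(missing)}")
    if df.shape[0] == 0:
        logger.warning("%s: empty driver panel", path)
        return []
    variants = []
    for _, row in df.iterrows():
        try:
            pos = int(row["pos"])
        except ValueError as exc:
            raise ValueError(f"{path}: non-integer pos {row['pos']!r}") from exc
        variants.append(
            DriverVariant(
                gene=row["gene"].strip(),
                chrom=row["chrom"].strip(),
                pos=pos,
                ref=row["ref"].strip().upper(),
                alt=row["alt"].strip().upper(),
                cdna=row["cdna"].strip(),
                protein=row["protein"].strip(),
            )
        )
    return variants


def read_callable_bed(path) -> list[tuple[str, int, int]]:
    """Read callable regions from a BED file (0-based, half-open)."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(f"{path}: end <= start in callable BED")
            regions.append((chrom, start, end))
    return regions


def _site_callable(regions: Iterable[tuple[str, int, int]], chrom: str, pos: int) -> bool:
    """1-based position inside any 0-based half-open region?"""
    return any(c == chrom and start < pos <= end for c, start, end in regions)


def _passing_alt_calls(vcf_path) -> set[tuple[str, int, str, str]]:
    """Decomposed (chrom, pos, ref, alt) keys of passing alt-carrying records."""
    calls: set[tuple[str, int, str, str]] = set()
    vcf = VCF(str(vcf_path))
    try:
        for record in vcf:
            if record.FILTER is not None and record.FILTER != "PASS":
                continue
            genotype = record.genotypes[0] if record.genotypes else None
            for i, alt in enumerate(record.ALT):
                if genotype is not None:
                    # allele code i+1 is this alt after decomposition
                    if (i + 1) not in genotype[:-1]:
                        continue
                calls.add((record.CHROM, record.POS, record.REF, alt))
    finally:
        vcf.close()
    return calls


@dataclass
class PanelReport:
    """Per-sample screen result: breadth and one status per panel entry."""

    sample: str
    breadth: float
    statuses: dict[DriverVariant, str]

    def rows(self) -> list[dict]:
        return [
            {
                "sample": self.sample,
                "gene": v.gene,
                "variant": v.label,
                "protein": v.protein,
                "breadth": self.breadth,
                "status": s,
            }
            for v, s in self.statuses.items()
        ]


def screen_sample(
    vcf_path,
    panel: Sequence[DriverVariant],
    callable_regions,
    breadth: float,
    sample: str = "",
    breadth_gate: float = DEFAULT_BREADTH_GATE,
) -> PanelReport:
    """Screen one sample's calls against the panel with breadth gating.

    ``callable_regions`` is a BED path or a list of (chrom, start, end)
    0-based half-open tuples; ``breadth`` is the sample's fraction of
    the genome covered at >= 1x.
    """
    if not (0.0 <= breadth <= 1.0):
        raise ValueError("breadth must lie in [0, 1]")
    if not panel:
        raise ValueError("empty panel")
    if breadth < breadth_gate:
        statuses = {v: SAMPLE_EXCLUDED for v in panel}
        return PanelReport(sample=sample, breadth=breadth, statuses=statuses)

    if isinstance(callable_regions, (str,)) or hasattr(callable_regions, "__fspath__"):
        regions = read_callable_bed(callable_regions)
    else:
        regions = list(callable_regions)
    calls = _passing_alt_calls(vcf_path)

    statuses = {}
    for v in panel:
        if (v.chrom, v.pos, v.ref, v.alt) in calls:
            statuses[v] = MUTANT
        elif _site_callable(regions, v.chrom, v.pos):
            statuses[v] = WILD_TYPE
        else:
            statuses[v] = INSUFFICIENT_COVERAGE
    return PanelReport(sample=sample, breadth=breadth, statuses=statuses)


def aggregate_reports(reports: Sequence[PanelReport]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Samples x variants status grid plus per-variant tallies.

    The tally line mirrors the usual reporting style, e.g.
    "5 of 5 callable cells wild_type, 1 insufficient_coverage".
    """
    if not reports:
        return pd.DataFrame(), pd.DataFrame()
    panels = [tuple(r.statuses.keys()) for r in reports]
    if len({p for p in panels}) != 1:
        raise ValueError("reports use different panels")
    panel = panels[0]

    grid = pd.DataFrame(
        {v.label: [r.statuses[v] for r in reports] for v in panel},
        index=[r.sample for r in reports],
    )
    grid.index.name = "sample"

    tallies = []
    for v in panel:
        col = grid[v.label]
        counts = col.value_counts()
        n_mut = int(counts.get(MUTANT, 0))
        n_wt = int(counts.get(WILD_TYPE, 0))
        n_insuf = int(counts.get(INSUFFICIENT_COVERAGE, 0))
        n_excl = int(counts.get(SAMPLE_EXCLUDED, 0))
        n_callable = n_mut + n_wt
        majority = MUTANT if n_mut >= n_wt else WILD_TYPE
        n_major = max(n_mut, n_wt)
        summary = f"{n_major} of {n_callable} callable cells {majority}"
        if n_insuf:
            summary += f", {n_insuf} insufficient_coverage"
        if n_excl:
            summary += f", {n_excl} sample_excluded"
        tallies.append(
            {
                "variant": v.label,
                "gene": v.gene,
                "mutant": n_mut,
                "wild_type": n_wt,
                "insufficient_coverage": n_insuf,
                "sample_excluded": n_excl,
                "summary": summary,
            }
        )
    return grid, pd.DataFrame(tallies)
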