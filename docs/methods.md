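# Methods

## The pathway-activity model

`cellpath` scores the transcriptional activity of a signalling pathway —
the reference implementation targets the canonical Wnt program driven by
the TCF4/β-catenin transcription complex (TC) — with a three-layer
Bayesian network:

* a latent binary root node, TC ∈ {active, inactive};
* one binary node per target gene, G ∈ {up, down}, with CPT
  P(G = up | TC);
* one binary measurement node per gene, M ∈ {high, low}, with CPT
  P(M = high | G), where "high" means the measured log2 RPKM lies above
  the gene's calibrated threshold.

Because the graph is a tree rooted at the TC, exact inference is a
product of independent per-gene likelihood ratios. With
A = P(M = high | TC = active) and B = P(M = high | TC = inactive)
(gene layer marginalized), soft evidence q on a measurement node
contributes the log likelihood ratio

    LLR(q) = ln[(qA + (1−q)(1−A)) / (qB + (1−q)(1−B))],

and the posterior log-odds is ln(prior odds) + Σ LLR(q_g). Soft calls
are handled as virtual evidence (likelihood weights q : 1−q on the
measurement node), never by clamping: a gene near its threshold
contributes almost nothing, as the cluster-matrix display suggests it
should. Missing genes contribute exactly zero. A full-joint enumeration
oracle (`infer_log_odds_bruteforce`, guarded to ≤ 15 genes) checks the
factorized path to < 1e−9 on the log scale in the test suite.

### Default CPTs and the factor-of-five weighting

The only quantitative constraint the model's description fixes is an
asymmetry: an up-regulated call should move the evidence five times as
far towards "active" as a non-up-regulated call moves it towards
"inactive". We encode this as composite likelihood ratios
lr_high = 5 and lr_low = 5^(−1/5), so that
ln(lr_high)/|ln(lr_low)| = 5 exactly. The gene layer defaults to
P(up | active) = 0.95 and P(up | inactive) = 0.05; the measurement-layer
entries are then solved exactly (the two constraints are linear given
the gene layer): P(high | up) ≈ 0.3362, P(high | down) ≈ 0.0501. All
four probabilities are overridable per gene through the panel TSV. The
prior odds default to 1 (log-odds 0), so reported odds reflect the
expression evidence alone and the natural decision boundary sits at
odds 1:1. Only positively regulated targets are supported; a repressed
target would need a mirrored CPT and is out of scope.

The bundled 34-gene panel (`wnt_target_panel_synthetic.tsv`) is a
synthetic stand-in: a representative set of 34 canonical TCF4/β-catenin
target genes assembled from the field's literature, since the original
panel's gene list is not available in machine-readable form. Swapping in
any other panel TSV changes nothing downstream.

## Calibration and soft calls

Per-gene thresholds are fitted on labelled bulk samples as the midpoint
between the active-group mean and the inactive-group mean of log2
RPKM — deterministic and sensible for the very small calibration groups
this design uses (2 + 2); an optimal-split search would overfit at that
n. Genes whose inactive mean is not below their active mean are kept
(flagged `direction_ok = False`, logged): the Bayesian combination over
34 genes tolerates individually noisy genes, and dropping them would
silently change the panel.

Raw RPKM is transformed as log2(RPKM + pseudocount) with pseudocount
1.0 (single-cell dropout produces exact zeros; log2(0) is unusable, and
pseudocount 1 maps 0 → 0). Soft calls use a logistic,
q = σ((x − threshold)/softness), with softness 0.25 log2 units —
roughly the calibration noise scale, giving graded calls near the
threshold; softness 0 recovers hard above/below calls.

## Coverage-uniformity QC

Whole-genome amplification of single-cell DNA is biased; the Lorenz
curve summarizes that bias robustly even at low coverage. Bases are
sorted by increasing depth; point k is (cumulative genome fraction,
cumulative read fraction) after the k-th depth class, prepended with
(0,0). Uncovered (depth 0) bases count toward the genome axis and
contribute no reads, so amplification dropout appears as the initial
flat segment. The Gini coefficient is 1 − 2·(trapezoidal area under the
curve): 0 for perfectly uniform coverage, → 1 for extreme bias. Scalar
summaries: mean depth, breadth (fraction ≥ 1x), uncovered fraction, and
the fractions at ≥ 20x and ≥ 30x (the depths typically required for SNP
calling). Curves are returned at exact depth-class boundaries; any
downsampling for plotting is presentation-layer.

Inputs are genomecov-style histogram TSVs (if a `genome` summary label
is present it is used, else per-label rows are aggregated, with totals
checked) or BED4 depth intervals (0-based half-open; overlaps rejected).

## Driver-panel screening

The screen assigns exactly one status per (cell, panel variant). A
sample whose breadth is below the gate (default C ≥ 0.70, the printed
filter) is `sample_excluded` wholesale. Otherwise a decomposed,
passing VCF record matching (chrom, pos, ref, alt) whose genotype
carries the alternate allele is `mutant`; absence of a call is only
`wild_type` when the site lies inside the sample's callable regions —
in WGA'd single-cell DNA, a missing call without callable evidence is
`insufficient_coverage`, not reference. Matching assumes upstream
left-alignment and a consistent genome build; HGVS labels in the panel
are metadata, never mapped to coordinates. The bundled panel carries
the three colorectal hotspots CTNNB1 c.134C>T (S45F), KRAS c.35G>A
(G12D) and PIK3CA c.3140A>G (H1047R) at their standard GRCh37
coordinates.

## The synthetic-data generator

The generator produces data with the statistical structure the analysis
assumes, so every stage is testable without external downloads.

*Expression.* Gene g in an inactive sample draws
N(mu_g, noise_sd²) log2 RPKM; in an active sample N(mu_g + delta_g,
noise_sd²). Defaults: baselines spread evenly over 2–8 log2 RPKM,
delta = 2.0, noise_sd = 0.5 — a clearly separated transcriptional
program with realistic measurement noise. In `single_cell` mode a value
drops to log2(pseudocount) with probability
min(1, dropout_base + dropout_slope·max(0, c − mu_g)), c = 4 log2 RPKM,
base 0.1, slope 0.15/log2 unit: dropout is frequent for lowly expressed
genes and rare for highly expressed ones, which is the qualitative
vulnerability the model's heavier weighting of up-calls exists to
absorb. The linear form is a modelling convenience, not a claim about
the mechanism.

*Depth.* Per-bin depth is a zero-inflated negative binomial.
`depth_dispersion` is the overdispersion coefficient α with variance
μ + αμ² (NB size 1/α); α = 0 selects an exact Poisson branch. This
parameterization makes the Gini monotone increasing in the knob, which
the QC property tests rely on. Defaults depth_mean = 16.2x, α = 1.0,
zero_inflation = 0.05 over 10⁵ bins emulate the reported single-cell
WGA regime (~10.5% of bases uncovered at a nominal 16x); note
zero-inflation lowers the realized mean depth to ≈ 0.95 · 16.2 ≈ 15.4x.
Bin-level simulation ignores within-bin autocorrelation of real WGA
bias; Lorenz/Gini computations are insensitive to base ordering, so
this does not limit what the QC tests show.

*Variants.* Minimal VCF 4.2 files (FILTER PASS, GT 0/1) containing
exactly the planted panel records, plus callable BEDs covering panel
sites except those marked uncallable, plus a manifest of expected
statuses. Screening generator output must reproduce the manifest
exactly; that identity is an acceptance test.

What passing the synthetic suite does *not* show: performance on real
single-cell RNA-seq (no transcript-level quantification noise, no
heavy-tailed expression, no doublets), or on real WGA depth (no
chimeric reads, no GC bias structure). The generator is a correctness
harness, not a biological simulator.

## Classification and evaluation

A sample is called active iff its posterior log-odds > 0; exact ties go
to inactive (conservative). Labelled samples are summarized in a 2×2
truth × prediction confusion table and tested with a two-sided Fisher
exact test under the minimum-likelihood convention: the p-value sums
hypergeometric probabilities of all margin-consistent tables whose
probability does not exceed the observed table's, with a 1e−7 relative
tie tolerance. The implementation is a vectorized enumeration over the
support; the tests check it against scipy's implementation and against
an exact rational-arithmetic enumeration, exhaustively for every 2×2
table with total ≤ 40. For the fully correct 7-active/6-inactive
validation design this yields p = 1/C(13,7) = 1/1716 ≈ 0.0006.

## Problem sizes and determinism

The analysis drivers and acceptance script use 2+2 calibration samples,
7+6 or 100+100 test cells, 10⁵–2·10⁵ depth bins, and ≤ 10-gene models
for the enumeration oracle — sizes at which every quantity they report
is stable to well within the tolerances asserted. All randomness flows
from explicit integer seeds (numpy `default_rng`); identical seeds give
bit-identical matrices, histograms and files, and the pipeline's
reports are byte-identical across reruns.

## Known limitations

* CPTs are homogeneous across genes by default; the original model may
  use gene-specific tables, which the panel TSV can express but the
  defaults do not.
* No uncertainty interval accompanies the per-sample odds; none is
  defined for this design.
* Single pathway per run; multi-pathway panels are future scope.
* The screen performs no variant calling or annotation; it consumes
  upstream VCFs as-is.
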