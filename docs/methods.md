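# Methods

This note documents the statistical model behind `mastat`, the
defaults it ships with, the numerical and design choices that were
genuinely open, and what the synthetic-data tests do and do not show
about real data.

## The MA-experiment model

An MA experiment propagates n independent lines through repeated
single-colony transfers. Each transfer bottlenecks the line to one
cell, so the drift-effective population size is tiny (see Ne below)
and selection is nearly powerless: mutations accumulate at close to
the spontaneous rate. The observable per line is a set of curated
mutation calls; the exposure — the number of opportunities for
mutation — is callable sites × total cell divisions.

Pooled class counts m (base substitutions, small indels, structural
variants) are modelled as Poisson with mean μ·g, where
g = Σ_lines sites_l × divisions_l. This is exact if per-line counts
are independent Poisson, which holds when mutations arise
independently at rate μ per site per division; it ignores
mutation-rate heterogeneity between lines (overdispersion), which MA
studies at these counts cannot resolve anyway.

* **Point estimate**: μ̂ = m/g.
* **Interval**: the Garwood construction
  [½χ²(α/2; 2m), ½χ²(1−α/2; 2m+2)]/g, lower bound 0 at m = 0. It is
  exact-coverage-conservative: ≥ 1−α for every true μ (empirically
  ≈ 0.97 at means near 20). Rates are displayed at 3 significant
  digits; internal values are never rounded.
* **Comparison**: RR = (m₂/g₂)/(m₁/g₁). Headline inference is the
  Wald log-scale interval and z-test (this matches how such studies
  usually print "Poisson rate test"); the exact conditional binomial
  test — m₂ out of m₂+m₁ against p₀ = g₂/(g₁+g₂) — is always computed
  alongside, since at counts of ~20 the normal approximation is
  borderline. With one zero count the ratio is reported as 0 or +inf
  with a one-sided flag; with both zero it is an error.

When per-line callable sites are unavailable the exposure falls back
to n × mean sites × mean divisions and carries an `approximate` flag;
the exact per-line sum is preferred whenever the metadata allows it.

## Spectra

Substitutions are strand-collapsed into six classes keyed by the
reference base pair (A:T→G:C, …, G:C→C:G). Class rates are
*conditional*: each class's count is divided by the number of sites
it can originate from (A/T or G/C sites), scaled per line by the
callable fraction callable_sites/genome_length (per-line base
composition is essentially never reported, so a uniform scaling is
the only defensible choice). The group rate is the unweighted mean
over lines and the error bar is the SEM across lines (0 for a single
line, by convention).

The A/T-direction bias is the ratio of conditional rates
[(G:C→A:T + G:C→T:A)/gc_sites] / [(A:T→G:C + A:T→C:G)/at_sites]. The
direction-neutral classes (G:C→C:G, A:T→T:A) change neither
composition and are excluded — "bias in the A/T direction" names a
direction, not a class list.

Ratios with an empty denominator (ts/tv with no transversions, In/Del
with no deletions, A/T bias with no A:T→G/C events) return IEEE
`inf` — the infinity itself is the flag — and `nan` when the
numerator is empty too. Degenerate spectra therefore never raise
mid-pipeline; report formatting renders them as "inf"/"NA".

## Selection tests

The nonsyn/syn goodness-of-fit test compares observed counts with
expectations proportional to the genome's nonsynonymous and
synonymous site totals; the between-group test is the 2×2 χ². Both
use Yates' continuity correction with the corrected deviation
*floored*: max(|O−E|−0.5, 0). The floor matters: for near-perfect
fits the naive subtraction would inflate the statistic. The 2×2 test
uses the margin-product shortcut N(|ad−bc|−N/2)²/(row·col products),
proven equal to the cell-wise formula in the tests. Larger r×2 tables
use the plain Pearson statistic (df = r−1) via scipy;
Yates applies only at df = 1.

Site counting follows the codon-degeneracy convention: each codon
position contributes (synonymous single-base changes)/3 synonymous
sites, so every sense codon contributes exactly 3 sites. Changes
creating a stop codon count as nonsynonymous by default
(`stops_as_nonsyn=False` excludes them and renormalises); the
alternative mutational-opportunity weighting (weighting changes by a
mutation spectrum) is deliberately not implemented — at MA-study
counts it moves the expected ratio far less than the Poisson noise.

## Effective population size

A colony grown from one cell for T doublings passes through census
sizes 1, 2, …, 2^T; the drift-effective size is their harmonic mean,
Ne = (T+1)/Σ_{i=0..T} 2^(−i) = (T+1)/(2−2^(−T)). The closed form
extends the integer definition continuously and monotonically to real
T, which is what a grand mean over colonies produces. T itself comes
from colony-forming units as log₂(CFU). Averaging is done on the log
scale (geometric mean of CFU) by default: colony-size noise is
multiplicative, and the log-scale mean is unbiased for T under
lognormal noise; log₂ of the arithmetic mean is available as
`method="arithmetic"`. At study scale (T ≈ 19.3–19.8) Ne ≈ 10.2–10.4;
published values computed from differently rounded T can differ by a
few hundredths, so cross-checks use a 0.05 tolerance.

## Power analysis

Power for the two-group comparison is estimated by simulation: for
each multiplicative effect f on a grid (default 0–300% in 10% steps),
draw x₁ ~ Poisson(μg₁) and x₂ ~ Poisson(μ(1+f)g₂), apply the
one-sided (toward increase — the alternative of interest is
mutagenicity) exact conditional binomial test at α = 0.05, and report
the rejection fraction with its binomial Monte-Carlo standard error.
Each effect size uses an independent child stream of the seed, so
curves are bitwise reproducible and grid-order-invariant. An empty
experiment (x₁+x₂ = 0) never rejects.

Two designs are provided, and they answer different questions:

* **both counts redrawn** (default): the average power of the design
  itself. At the study conditions (μ = 3.58×10⁻¹¹, g₁ = 5.02822×10¹¹,
  g₂ = 5.37022×10¹¹) this gives ≈ 0.77 at a 100% increase.
* **`fixed_control`**: hold the control count at its observed value
  (18) and redraw only the treatment count — the power of *this
  experiment as realised*. This gives ≈ 0.83 at a 100% increase and a
  minimum detectable effect of exactly +100% at the 80% target, and
  is the design the acceptance suite uses for the "80% power at
  doubling" claim; the unconditional design brackets the same claim
  from below.

The normal-approximation test exists only as an oracle inside the
test suite; the package's test is always the exact conditional one.

## Synthetic-data generator

`SimulationConfig` defaults are the study conditions the analysis was
built around: 46 control + 48 treatment lines, 46 transfers of 19.35
divisions (890 per line), a 12,521,788 bp genome at 36.06% GC with
98% of sites callable, μ_BPS = 3.58×10⁻¹¹, μ_indel = 4.77×10⁻¹¹,
μ_SV = 1.19×10⁻¹¹ per site per division, and `treatment_fold = 1.0`
(the no-effect truth; set 1.25 for the observed-ratio scenario). The
spectrum default (0.22, 0.06, 0.06, 0.45, 0.14, 0.07) was chosen once
to give ts/tv = 2.0 and a ≈ 3.7-fold conditional A/T-direction bias
at that GC content — the per-class split behind published aggregate
ratios is generally not printed, so the vector is a realistic
stand-in, not a reproduction. 87.5% of indels are insertions (21:3);
indel sizes are geometric (mostly 1 bp) capped at 49 bp, SV sizes
50 bp plus a geometric tail. Coding effects are assigned
probabilistically (coding fraction 0.616, nonsyn:syn site ratio 3.70)
rather than from an annotation; a synthetic GFF path exists for
exercising the annotation-based site counter.

Per-line draws use deterministic child streams of the global seed, so
enlarging a group never perturbs existing lines, and outputs are
byte-identical across runs. Position collisions are removed (and
counted); at desk-scale rates they essentially never occur. A guard
refuses configurations implying > 10⁶ expected mutations per group.

What the generator does *not* emulate: sequencing error, coverage
heterogeneity and callability masks, mutation hotspots or
context-dependence, between-line rate heterogeneity, and selection
during colony growth. Passing parameter-recovery tests therefore
shows the estimators are correct *under the model the analysis
assumes*, not that real curated call sets satisfy that model.

## Problem sizes and numerical choices

The seeded test suite runs the coverage study with 2,000 Poisson
draws per mean, the power checks with 2,000 replicates per effect,
and parameter recovery over 200 study-scale synthetic experiments —
sizes at which Monte-Carlo error is a small fraction of the tested
tolerances and the whole suite runs in seconds. Chi-square quantiles
and tails, binomial tests and Poisson draws come from scipy/numpy;
the Garwood interval, the floored-Yates statistics, the conditional
spectrum arithmetic, Ne and the power procedure are implemented here
and cross-checked against independent brute-force oracles in the
tests. Coordinates are 1-based closed (VCF convention); indels are
anchored on the preceding base; the small-indel/SV boundary is 50 bp;
imported SV calls keep their caller's tag as an annotation and skip
allele-length classification.

## Known limitations

* Rates assume equal mutability across callable sites within each
  origin-base class; context effects are out of scope.
* The Wald interval for RR is anti-conservative at very small counts;
  the exact conditional p-value is reported alongside for exactly
  that reason.
* Genome-wide syn/nonsyn site totals depend on the annotation used;
  the package takes them as inputs (or computes them from a provided
  CDS set) and does not attempt to reproduce any particular
  annotation's totals.
* No multiple-testing correction is applied across the handful of
  reported tests; the report says so in a note field.
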