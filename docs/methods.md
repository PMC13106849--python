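# Methods

This note records the statistical models implemented in `honeygeo`, the
assumptions behind them, the defaults of the synthetic-survey generator,
and the numerical and design choices made where more than one reasonable
option existed.

## Observation model

The unit of observation is a honey sample's **lineage pattern**: the
non-empty subset of the three major *A. mellifera* mtDNA lineages
`{A, C, M}` amplified from the sample. The assay behind such data is
qualitative (presence/absence per lineage), so patterns carry no
abundance information. Zero-amplification samples are rejected at parse
time: a survey table contains only samples with at least one detected
lineage.

Because a honey sample pools the DNA of many colonies, the pattern is
the union of the lineages of the contributing colonies. Colonies are
treated as mono-mitotype (one queen, maternal inheritance), which
identifies the colony-level lineage frequency with the individual-bee
frequency. This equivalence is what licenses comparing honey-sample
detection frequencies to individual-bee surveys via the inflation
factor.

## Pooled detection (poolmodel)

For a lineage at colony frequency `p`, a pool of `k` i.i.d. colonies,
and per-colony detection probability `d ∈ (0, 1]`:

    P(pattern contains the lineage) = 1 − (1 − p·d)^k

and, for a pool-size law `P(k)`, the mixture `Σ_k P(k)·(1 − (1−p·d)^k)`.
The default pool-size law is discrete uniform on `{10, …, 30}` colonies,
the plausible range for commercial honey; uniformity is an assumption
(no empirical pool-size distribution is available) and is exposed in the
configuration. `d = 1` by default: whether PCR competition suppresses
minority lineages in real pools (which would make `d < 1` and
`k`-dependent) is unknown, so the default is the optimistic qualitative
assay.

The inflation factor `honey_freq / bee_freq` is reported rounded to two
decimals, the convention used in honey-vs-bee comparisons.

## Frequency tabulation (samples)

Frequencies are reported per group (region, macro-region, year,
time-window, …) for the seven exact patterns and for derived binary
codings (`contains-X`, `only-X`, and `contains-A-or-M`, the complement
of `only-C`). Percentages are rounded **half-up to one decimal**; values
below 1% are additionally reported at two decimals so rare patterns do
not round to zero. Half-up was chosen over half-even because a single
documented rule is preferable and all reference values are consistent
with it; intermediate counts are never rounded. Groups with zero samples
are omitted, not zero-filled.

"Unique" samples are obtained by retaining exactly one sample per
(beekeeper, year) pair, drawn uniformly with a caller-supplied seed —
the random choice has no stated tie-break policy in the field, so a
seeded uniform draw keeps it reproducible. The operation is idempotent.

Historical samples are grouped into the windows 1986–1999, 2000–2009
and 2010–2017; years from 2018 on are labelled literally.

Region → macro-region mapping: the Northern set is the eight regions
between the Alpine contact zones of *A. m. mellifera* (west) and
*A. m. carnica* (east); Sicily and Sardinia are their own macro-regions;
the Central/South split of the remaining ten regions follows the
standard Italian statistical convention (Central = Tuscany, Umbria,
Marche, Lazio). The split ships as an editable YAML file because the
Central/South boundary is a convention, not a biological fact.

## Logistic clines (cline)

Single-predictor logistic regression, written from scratch as IRLS with
the conventional GLM defaults: convergence when the relative deviance
change is below 1e-8, at most 25 iterations. Inference reported per fit:
slope, its Wald SE/z/p, and the 1-df likelihood-ratio chi-square against
the intercept-only model ("model chi-square") with its p-value. The
model chi-square is the primary significance measure; Wald p is also
reported. Complete separation is detected (fitted probabilities
numerically 0/1 with vanishing deviance) and flagged instead of
reporting a divergent slope; no penalisation is applied, matching plain
GLM behaviour. Correctness anchors: the slope on a binary predictor
equals the closed-form log odds ratio to 1e-6, estimates match an
independent GLM implementation to 1e-6 relative on random datasets, and
the LR test holds its nominal size in simulation.

Orientation: latitude enters in raw decimal degrees (north-positive), so
"frequency rises southward" is a **negative** slope on latitude;
longitude is east-positive. Battery structure:

* latitude: peninsula-wide, with and without Sicily and Sardinia,
  pooled over years and separately per year;
* longitude: Northern macro-region only (the single wide, continuous
  longitudinal span bounded by natural barriers);
* year as predictor: within macro-region groupings (North,
  Central+South), using only macro-region-by-year cells with more than
  100 samples to limit small-cell sampling bias.

Per-year and pooled analyses use all samples (not the deduplicated
unique set) by default: headline frequencies are quoted on the full
denominator, and deduplication is available upstream for sensitivity
analyses. Degenerate combinations (constant outcome or predictor after
subsetting) are recorded as skipped, never fatal.

Because pooled detection is not exactly logistic in the coordinate even
when the colony-level frequency is, the generator's implied marginal
slope is computed as the KL projection of the true detection curve onto
the logistic family (`synthdata.marginal_cline_slope`), and calibration
experiments measure coverage against that pseudo-true value.

## Diversity trends (mktrend)

Each beekeeper's yearly **diversity** is the cardinality (1–3) of the
union of lineages over all their samples that year. Beekeepers observed
in at least four years are trend-eligible; others are retained in a
census output only. Kendall statistics depend only on order, so gap
years reduce to calendar ordering.

The trend test is the Modified Mann–Kendall in the Hamed–Rao (1998)
form — the canonical variant when none is specified: `S = Σ_{i<j}
sign(x_j − x_i)`; tau-b with tie adjustment; tie-corrected
`var(S) = [n(n−1)(2n+5) − Σ_t t(t−1)(2t+5)]/18`; lag-i autocorrelations
of the rank-transformed series, retaining lags significant at 5%
(two-sided, SE = 1/√n; only lags ≤ n−3 carry weight), with

    correction = 1 + 2/(n(n−1)(n−2)) · Σ_i (n−i)(n−i−1)(n−i−2)·ρ_rank(i)

floored at 0.01 so the corrected variance stays positive;
`z = (S − sign(S))/√var*(S)` with the continuity correction.

The variance of τ forwarded to the meta-analysis is `var*(S)/D²` with
the **untied** denominator `D = n(n−1)/2` (configurable to tau-b
scaling). Rationale: series of length 4–6 on {1,2,3} are dominated by
ties, and the tau-b denominator then fluctuates wildly between
beekeepers, destabilising the meta-analytic weights; the untied
denominator is conservative and uniform.

Constant (all-tied) series are a real and frequent case (a beekeeper
always sending only-C honey). Policy: τ = 0, degenerate flag set, and
the untied-formula variance `n(n−1)(2n+5)/18` forwarded so the
meta-analysis can still consume the estimate. These estimates are
included by default (no principled exclusion rule exists) and can be
dropped with a flag.

Simulation anchors: the test's size at n = 8 stays below 0.07 at nominal
0.05 (the statistic is discrete, hence conservative); the correction is
centred on 1 for white noise and exceeds 1 for AR(1) dependence.

## Random-effects pooling (metareml)

Per-beekeeper τ estimates `y_i` with variances `v_i` are pooled per
geographic area with `y_i = x_i'β + u_i + e_i`, `u_i ~ N(0, τ²_between)`,
`e_i ~ N(0, v_i)`. Areas are coded as dummies **without intercept**, so
each coefficient is directly its area's pooled mean τ. Two schemes:
five areas (North, Central, South, Sicily, Sardinia) and four
macro-areas (Central and South combined). Weights use the raw
(MMK-corrected) per-beekeeper variances as delivered by the trend stage.

`τ²_between` maximises the restricted log-likelihood
`−½[Σ log(v_i+τ²) + log|X'WX| + y'Py]` by safeguarded bounded search on
`[0, upper]` with an adaptively expanded bracket and an explicit check
of the τ² = 0 boundary (zero heterogeneity is a valid and common
solution). The estimate matches an independent grid-search maximiser to
1e-6 and recovers a known τ² = 0.04 within 15% on average in
simulation.

CIs are normal (Wald) `β̂ ± 1.96·SE` by default, matching standard
random-effects software defaults; a Knapp–Hartung t-based adjustment is
available behind a flag. Residual heterogeneity is summarised by the
usual `Q_E` with fixed-effect weights. Levels contributing one estimate
are reported but flagged. Forest-plot output lists level, contributing
beekeeper count, pooled τ and CI bounds; dot size in the rendered plot
scales with the count.

## Consistency summary (consistency)

Beekeeper-years with ≥ 2 samples are classified as "different patterns"
iff at least two distinct **exact** patterns occur (overlapping but
unequal patterns, e.g. {C} and {A,C}, count as different), otherwise
"all only-C" or "all ⟨pattern⟩". Single-sample beekeeper-years never
enter the denominator. Category granularity (whether uniform non-C
labels are merged) is left to the consumer; the output keeps them
separate.

## Synthetic surveys (synthdata)

The generator emulates the sampling structure of a national six-year
honey survey:

* **Geography.** A stylised peninsula of three latitude bands (North
  44–47°, Central 41.5–44°, South 38–41.5°) plus two island boxes
  (a Sicily and a Sardinia analogue), split into 20 regions in 5
  macro-regions. Beekeepers are placed uniformly within their
  macro-region's box (weights 0.50/0.18/0.22/0.05/0.05, approximating
  the real sampling imbalance toward the North) and keep a fixed
  location across years, mirroring geocoding by municipality.
* **Cline surface.** Colony-level frequencies follow a multinomial
  logit with C as reference: `η_L = α_L + β_L^lat·lat + β_L^lon·lon +
  γ_L·(year − year₀)`, `(p_A, p_C, p_M) = softmax(η_A, 0, η_M)`,
  `year₀` = first simulated year. Defaults (α_A = 7.31,
  β_A^lat = −0.25, α_M = 8.82, β_M^lat = −0.28, β^lon = −0.10, γ = 0)
  were set once so that pooled contains-A/contains-M frequencies run
  from roughly 11%/14% in the North to roughly 26%/34% in the South
  with only-C near 84% in the North — the magnitude of the real
  gradients. Island deviations are additive η boosts (Sicily +4.5 on
  A, the high-A island; Sardinia −1.5 on A and M, resembling the
  North). Drift (γ > 0) can be restricted to named macro-regions to
  emulate a Central–South diversification with a stable North.
* **Sampling.** Pool size uniform on {10, …, 30}; per-colony detection
  `d = 1`; samples per beekeeper-year on support 1–9 with
  P(1) = 0.75 and a decreasing tail (mean ≈ 1.4 samples); active years
  per beekeeper on support 1–6 with about a third of beekeepers active
  ≥ 4 years (the trend-eligible pool). An empty pattern under `d < 1`
  redraws the contribution step, since observed data contain no empty
  patterns.
* **Clustering.** Colonies are i.i.d. within a beekeeper-year (minimal
  model). An optional beekeeper-level normal random intercept on the
  logit scale (`beekeeper_sigma`) mimics apiary-level clustering
  (near-monomorphic apiaries); it is off by default.

What the generator does **not** emulate: transhumance (locations are
fixed), within-year botanical/temporal heterogeneity of a beekeeper's
production, spatial autocorrelation beyond the smooth cline surface,
PCR competition between lineages in one pool, and mitotype structure
within lineages (C1 vs C2 is not modelled). Passing tests therefore
validate the statistical machinery and its calibration under the stated
sampling model, not robustness to those real-data features.

## Problem sizes and determinism

Simulation-based checks use: 10⁵ pools for the pooled-detection
comparison (agreement within 3 Monte-Carlo SE); 100 replicates of
n = 2000 samples for cline sign recovery and CI coverage (coverage
measured against the KL-projected pseudo-true slope, tolerance ±4
points around 95%); 10⁴ length-8 null series for the Mann–Kendall size
check; 500 replicates at n = 10⁴ for the logistic LR size check; 200
replicates of k = 200 estimates for REML recovery of τ² = 0.04; and a
400-beekeeper, six-year survey (~1,700–2,000 samples, ~130
trend-eligible beekeepers) for the end-to-end qualitative structure.
These sizes keep the full validation suite under a minute of compute
while leaving Monte-Carlo error well inside every asserted tolerance.

All randomness flows from explicit seeds (numpy `default_rng` /
`SeedSequence`); reruns with the same seed reproduce all numeric
outputs byte-for-byte, which the pipeline manifest records.

## Known limitations

* Presence/absence coding overestimates rare-lineage prevalence by
  construction (any single carrier colony flips a pool positive); the
  inflation factor quantifies exactly this and should be kept in mind
  when comparing honey-derived frequencies to bee-level ones.
* The logistic cline model is a working approximation: the pooled
  detection curve is not exactly logistic in the coordinate, and no
  spatial autocorrelation or multi-predictor structure is modelled.
* Wald CIs in the meta-analysis are anti-conservative for very few
  contributing beekeepers per area; the Knapp–Hartung flag mitigates
  this at the cost of wider intervals.
* The untied-denominator choice for var(τ) is a policy, not an
  estimate; the tau-b alternative is available and shifts weights, not
  signs.
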