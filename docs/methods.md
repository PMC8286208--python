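# Methods

## The linking rule

A respondent answers items x₁…x₅ on a 7-point agreement scale. The direct
score is b = Σᵢ₌₁⁵ xᵢ ∈ [5, 35]. When only items 1–4 are collected, the
prorated score is

c = Σ₄ + Σ₄/4 = 1.25 Σ₄,  Σ₄ = x₁+x₂+x₃+x₄ ∈ [4, 28],

i.e. the missing fifth item is imputed by the mean of the observed four.
The rule is linear, so it commutes with averaging: the prorated group mean
is 1.25 × the group mean of Σ₄, identical to the mean of individual
prorated scores. Two consequences the tests exploit:

- c is always a multiple of 1.25 inside [5, 35] (2401 possible 4-item
  patterns, checked exhaustively);
- for any sample, mean(b − c) = mean(x₅) − mean(Σ₄)/4 exactly. With the
  default profile's item means this is 3.72 − 16.41/4 = −0.3825: the
  prorated score runs slightly above the direct score because the dropped
  item has the lowest mean.

Prorated scores are carried exactly: 1.25 × integer is exactly
representable in binary floating point, so no rational type is needed.
Rounding (1 decimal for scores, 2 for correlations/ICCs) happens only at
display time and never feeds back into computation.

Proration requires all four retained items. A 3-of-4 fallback would be a
different, unvalidated estimator and is deliberately not offered; rows
with any missing item are rejected (loudly skippable). A 5-item record's
prorated score uses items 1–4 only and never consults x₅.

## Category cutoffs

Published interpretive bands are stated for integer scores: 31–35
extremely satisfied, 26–30 satisfied, 20–25 neutral or slightly
satisfied, 15–19 slightly dissatisfied, 10–14 dissatisfied, 5–9 extremely
dissatisfied. Prorated scores fall on a quarter-point grid, so the gaps
between integer bands (e.g. 25–26) must be assigned somewhere. We extend
each band to a half-open interval — [5,10), [10,15), [15,20), [20,26),
[26,31), [31,35] — which preserves every integer assignment, makes
classification total and monotone on [5, 35], and resolves the open
choice between "round first" and "extend the interval" in favour of the
latter (rounding first would move 25.5 up a band; the extension keeps a
fractional score with the integers just below it). This choice affects
only scores in the five one-point gaps.

## Agreement battery

Differences are direct − prorated throughout (negative when proration
overshoots). All SDs use the n−1 denominator — the convention for
Bland–Altman limits; at the sample sizes involved the distinction is
immaterial either way.

- **Limits of agreement**: mean difference ± 1.96 × SD of differences.
  For approximately normal differences the interval covers ~95% of
  individual differences (verified by simulation at n = 10,000).
- **Pearson r** with the qualitative flag "very high" for r > 0.9. A
  constant vector leaves r undefined; it is reported as undefined, never
  coerced to 0.
- **ICC**: the two-way crossed ANOVA without replication (n subjects × 2
  measures) gives mean squares MSR (subjects), MSC (measures), MSE
  (residual). Single-measure coefficients:
  - consistency ICC(C,1) = (MSR − MSE)/(MSR + (k−1)MSE) — blind to a
    systematic offset between the two scores;
  - absolute agreement ICC(A,1) = (MSR − MSE)/(MSR + (k−1)MSE +
    (k/n)(MSC − MSE)) — penalizes the offset.

  The conventional "(3,1)" label and the words "absolute agreement"
  denote different coefficients, so **both are always computed and
  labelled**; the report's headline field is the absolute-agreement form,
  matching the verbal description of what a score link should deliver.
  95% CIs: exact F bounds for ICC(C,1); the McGraw–Wong
  Satterthwaite-df approximation for ICC(A,1); α = 0.05. Estimates and
  CIs are cross-checked in the tests against an independent OLS
  variance-components oracle (statsmodels) and against pingouin.
  Interpretation bands: poor < 0.5 ≤ moderate ≤ 0.75 < good ≤ 0.9 <
  excellent. Degenerate inputs (all entries equal) yield an undefined
  coefficient, reported as such.
- **Threshold proportions**: fraction of |difference| strictly below 2, 3
  and 4 points (strict because the benchmarks are stated as "< t");
  monotone in t and sign-invariant by construction.
- **Category concordance**: proportions classified the same / lower /
  higher by the prorated score, the largest category shift, and the full
  6×6 crosstab.
- **Normality screening** is a plotting utility (histogram + normal QQ),
  not a gate: the battery itself makes no formal normality test.

## Synthetic respondents

No individual-level data are bundled, so the pipeline is exercised on
synthetic samples. Each respondent is a draw from a 5-dimensional latent
normal with exchangeable correlation ρ (default 0.65) discretized per
item by rounding to the nearest integer and clipping to [1, 7] — the
simplest mechanism that yields correlated ordinal items with controllable
marginal moments.

Round-and-clip shifts the mean whenever latent mass falls outside
[0.5, 7.5], so latent means are **calibrated**: the expectation of the
discretized variable has a closed form (normal CDF mass on each of the 7
bins), and a scalar root-finder solves for the latent mean whose
discretized expectation equals the target. This is deterministic and
exact; a 200,000-draw Monte-Carlo check in the tests confirms the
calibration to within 0.02. Latent SDs are set to the target SDs and the
achieved (compressed) SDs are reported rather than forced — e.g. targets
of 2.0–2.2 come out near 1.8 — because every downstream analytic check
depends on the item means, not the SDs. Infeasible targets fail fast: a
distribution on [1, 7] with mean m has variance at most (7−m)(m−1), so
target pairs violating that bound (or boundary means, which force zero
variance) raise a calibration error.

Default profile: n = 17,897, item means 3.76/3.80/4.32/4.53/3.72, SDs
2.07/2.04/2.07/2.00/2.18 — the published overall marginals of a combined
spinal-cord/brain/burn-injury sample — with ρ = 0.65, an assumption (the
sample's inter-item covariance is not published) chosen to give the high
internal consistency reported for the scale, and overridable everywhere.

**What passing tests do and do not show.** The generator reproduces the
real sample's item means (hence the mean-difference structure, which is a
function of means only) but not its covariance, skew, or mixture of
injury groups. Simulated r, ICC, limits of agreement, threshold and
concordance percentages are therefore qualitative: with ρ = 0.65 the
synthetic sample gives r ≈ 0.99 and |difference| SDs around 1.3 where the
real sample shows r = 0.97 and SD 1.95. Tests assert the qualitative
pattern (very high r, excellent ICC, monotone threshold proportions, the
exact mean-difference identity), not the registry sample's printed
agreement values, which require the individual-level data.

## Numerical and design notes

- Problem sizes: the heaviest routine test draws 100,000 × 5 responses
  (<0.5 s); ICC oracle comparisons use 100 random matrices of n ≤ 20.
- Seeds: every stochastic routine takes an explicit seed
  (`numpy.random.default_rng`); identical configs are bitwise
  reproducible, and the JSON report is byte-identical across reruns.
- The multivariate draw uses the SVD square root, so singular correlation
  matrices (ρ → 1) remain valid.
- CSV contract: header `item1..item4[,item5]`, one respondent per row,
  integer 1–7 codes; any malformed row is logged with its index and
  reason, and aborts the run unless skipping is requested, because silent
  drops would bias the agreement statistics.
- ANOVA/ICC functions accept either validated score pairs (range-checked
  to [5, 35]) or a raw n×k matrix, so the machinery is usable on
  arbitrary method-comparison data.

## Limitations

- Proration is validated for complete 4-item responses only; no partial
  (3-of-4) proration.
- Only the two single-measure ICC forms are provided — no average-measure
  ICC, Lin's concordance, or regression-based (proportional-bias)
  Bland–Altman extensions.
- The Gaussian-copula generator cannot reproduce injury-group-specific
  distributions or item-level response styles (end-piling beyond what
  round-and-clip produces); no IRT generative model.
- No regression- or IRT-based linking (equipercentile, fixed-parameter
  calibration): the rule is deliberately the one clinicians can apply
  with a hand calculator.
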