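# Methods

## Data model and pairing

The canonical input is a long table with one row per administered trial,
keyed by (subject, test, day, trial), day and trial 1-based.  Analyses
never consume the long table directly; they consume *paired comparisons*:

- **intraday**: trial 1 vs trial 2 within one day (one comparison per
  day);
- **interday**: the mean of a day's trials vs the mean of the next day's
  trials (comparisons 1_2, 2_3, …), plus the first-vs-last day
  comparison 1_D.

The earlier measurement is always the reference vector x.  Missing data
are handled complete-case *per comparison*: a subject missing day 2
drops out of the 1_2 and 2_3 comparisons but stays in all others.  This
is a design choice, not an attempt to mirror how any particular study
handled invalid trials — most reports do not say.  Rows are canonically
sorted at construction, so every downstream statistic is invariant to
the row order of the input file.  Scores beyond physical bounds are not
auto-rejected; the generator supports bounds/censoring, and a loader
report counts dropped missing values.

## Relative reliability

For an n × 2 paired matrix, a two-way ANOVA splits the total sum of
squares into subjects (rows), occasions (columns) and residual.  The
default coefficient is the two-way absolute-agreement single-measure ICC

    ICC(A,1) = (MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE)),

which charges systematic occasion shifts (the MSC term) against
agreement — the correct penalty when the question is whether a retest
*agrees* with a test under possible learning.  A simplified variant that
omits the (k−1)MSE term, seen in some applied papers, is provided as
`paper_formula` so both conventions can be reported; the two coincide
when MSE = MSC = 0.  Confidence intervals for ICC(A,1) use the
McGraw–Wong F-based construction; the applied-literature sources this
mirrors typically do not state their CI method, so interval agreement
with any given published table is approximate by nature.
Negative estimates are reported as-is with a warning; the SEM is only
defined for ICC ∈ [0, 1], so callers must clamp negative estimates to
zero explicitly (the report layer does).

SEM = SD·√(1−ICC).  The SD basis defaults to the SD of the paired
differences; published SEM values of the order of a few percent of the
score SD (e.g. a 0.49-s SEM for a test with 8–9-s score SDs at
ICC = 0.97) are only consistent with the difference-SD reading, which is
why it is the default over the pooled-scores basis (also available).
MDC = SEM·1.96·√2, so MDC/SD = 2.7719·√(1−ICC) exactly; display rounds
to two decimals, internal math never rounds.

## Error decomposition

Bias is mean(x − y) with a two-sided paired t-test; with the
earlier-minus-later convention, time-scored tests show positive bias
under learning and count-scored tests negative bias.  Zero-variance
differences with zero bias yield p = 1 by convention (flagged); with
nonzero bias they are an error, not a silent NaN.  Familywise control is
Holm step-down by default (plain Bonferroni available; the per-test
threshold α/m, e.g. 0.05/25 = 0.002, is exposed for threshold-style
reporting).  The family is all comparisons of one mode in a report, and
the learning-curve detector adjusts within its own consecutive-day
family; which comparisons a published analysis pooled into one family is
usually not recoverable, so the report states what it used.

MAE and MAPE quantify random error on the score and percent scales;
MAPE's reference is always the chronologically earlier measurement and a
zero reference raises an error naming the subject.  Bland–Altman limits
of agreement are bias ± 1.96·SD(d); the bias CI is the exact t-interval
and each LoA CI uses the standard approximation with variance
SD²(1/n + 1.96²/(2(n−1))).  No proportional-bias (regression) extension
is provided.  Normality checks delegate to scipy's Shapiro–Wilk.

## Habituation decision

"Random error stabilizes" is not a standard quantity; it is
operationalized here as the absolute change in consecutive-day MAPE
being ≤ a tolerance, default 5 percentage points (configurable) — chosen
to separate the observed plateau pattern of well-behaved tests (MAPE
> 11% → < 5% over four comparisons) from the jumpy sequences of
high-variance tests.  The stabilization day is the earliest day d such
that *every* comparison from (d, d+1) onward passes both the adjusted
bias criterion (p ≥ α) and the MAPE criterion; requiring all remaining
comparisons guards against non-monotone error sequences, which
ruler-drop-style tasks genuinely produce.  If the final comparison
fails, the decision is "undetermined" rather than a day.  Decisions
always carry the bias point estimate next to the MDC, because a
nonsignificant bias can still be practically large.  Intraday bias does
not gate the decision by default (some tests stay intraday-significant
throughout while their day means stabilize); a strict mode could add it,
and the per-comparison trace contains everything needed to apply any
other rule post hoc.  The detector is monotone: a stricter α or a looser
MAPE tolerance can only move the day earlier.

## Group × time analysis

The ANOVA response is the day mean, not trial-level scores, matching the
interday aggregation.  The mixed (split-plot) decomposition uses
cell-count-weighted sums of squares, which is exact for the balanced
within factor and the natural weighting for mildly unbalanced groups
(22/20/23).  Partial η² is SS_effect/(SS_effect + SS_error-of-effect).
Sphericity: Greenhouse–Geisser ε (from the pooled group-mean-centered
covariance of the repeated measures) corrects the time and interaction
p-values whenever days > 2; the correction is always recorded in the
result.  Scheffé contrasts test each group pair against
(g−1)·F_{α; g−1, N−g} on subject means, so no contrast can be
significant without omnibus support; Cohen's d uses the pooled SD
(bands: 0.2/0.5/0.8).  First-to-last change scores are oriented so
positive = improvement regardless of whether higher or lower raw scores
are better, and compared across groups by one-way ANOVA with the same
Scheffé contrasts.  Both the mixed ANOVA and the change-score entry
point exist because applied reports use both framings loosely.

## Synthetic cohort generator

The generator exists because raw repeated-testing cohorts of this design
are typically not deposited.  Score of subject s (group g), day d,
trial t:

    y = μ_g + b_s + sign·c_g·e^{−λ_g(d−1)}·(A + a·1{t=1}) + ε,
    b_s ~ N(0, σ_s,g²),   ε ~ N(0, σ_e(d)²)

- μ_g: post-habituation asymptote per group (units of the test);
- A: interday learning amplitude; a: extra trial-1 handicap creating
  intraday test-retest bias that can persist independently of the
  interday decay;
- λ_g (per day) and c_g: group-specific decay rate and amplitude scale —
  children get c = 1.35, young adults 0.75, older adults 1.0 in the
  preset, emulating faster/larger learning from a weaker baseline;
- σ_e(d): per-day residual SD, nonincreasing to emulate shrinking random
  error (heteroscedasticity is per-day only, not per-subject);
- sign = +1 for lower-is-better scores, −1 for higher-is-better, so
  "improvement" always moves scores the right way;
- bounds and censoring applied last (the ruler-drop preset records 51 cm
  for scores beyond the 50-cm ceiling, as a dropped ruler would be).

Exponential decay is a modeling choice — published learning curves of
this shape are shown but not parameterized; the flat-then-cliff bias
sequences some tests show cannot be matched exactly by a single-rate
exponential, and the preset does not try.  All draws flow from one
seeded generator, so equal configs give byte-identical datasets.
`truth_of` returns the analytically implied ground truths (trial-level
ICC σ_s²/(σ_s²+σ_e(d)²), expected day-mean biases
sign·c_g(A + a/2)(e^{−λ(d−1)} − e^{−λd}), folded-normal MAPE
approximations) for parameter-recovery testing.

The preset's baselines, amplitudes and noise schedules are qualitative
scaffolding tuned once to the magnitudes reported for these tasks
(day-1 pooled means near 21 cm / 28 s / 24 s / 43 hits / 570 ms decaying
to day-5 values near 11 / 15 / 19 / 50 / 475, MAPE of tens of percent
for ruler drop down to a few percent for choice reaction); it is not a
fit, and reproducing any specific published table cell is out of scope.
What passing tests on generated cohorts demonstrate is that the
*pipeline* recovers known truths under the design's structure — Gaussian
errors, exponential decay, per-day heteroscedasticity.  Real data can
violate all three (non-normal tails, non-exponential learning,
subject-specific error), so generator-based results say nothing about
any particular instrument's true reliability.

## Numerical choices and problem sizes

- Residual SS in the two-way decomposition is clamped at zero against
  floating-point round-off; the SS identity is tested at 1e-10.
- ICC denominators of exactly zero raise an error rather than returning
  NaN; estimate 1.0 short-circuits the CI to (1, 1).
- Band boundaries: ICC 0.50/0.75/0.90 close the upper band
  (0.75 → good, 0.90 → excellent); η² 0.06/0.14 and d 0.2/0.5/0.8
  likewise.
- Monte-Carlo checks in the test suite use 10,000 replicates for the
  paired-t type-I calibration (vectorized across a replicate axis), 200
  replicates for ICC recovery at the 65-subject scale, 400 replicates
  for the habituation null calibration and 50 seeds for
  stabilization-day recovery — sizes chosen so Monte-Carlo error is
  comfortably below each assertion's tolerance while the suite stays
  fast.

## Known limitations

- Strictly two occasions per comparison: consistency-type ICC(C,1),
  average-measure ICCs and >2-occasion designs are out of scope.
- No extrapolation beyond observed days: if the last comparison still
  fails, the answer is "undetermined", not a forecast.
- The Bland–Altman LoA CIs are the standard approximation, not exact
  intervals.
- The generator's Gaussian noise cannot emulate unknown real-data tails,
  and per-subject learning-rate heterogeneity is not modeled.
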