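# Methods

This note records the statistical procedures implemented in `glycoval`,
the defaults and numerical conventions chosen where several dialects
exist, and what the synthetic-data generators do and do not emulate.

## Data model and units

All paired data are specimen-wise (comparative x, candidate y) values on
one of two HbA1c scales: NGSP percent or IFCC mmol/mol, linked by the NGSP
master equation `NGSP% = 0.09148·IFCC + 2.152`. Differences convert with
the slope alone (the intercept cancels), which is why the ±5 mmol/mol
allowable-error band equals ±0.46 %. Display rounding follows clinical
convention — whole numbers for IFCC, one decimal for NGSP — while JSON
output keeps full precision. Note that clinical usage pairs 47 mmol/mol
with 6.4 % although direct evaluation of the master equation gives 6.45 %;
the package never re-derives such paired display values, it converts
numerically and leaves rounding to the caller.

The difference sign convention is candidate − comparative everywhere, so a
negative bias means the candidate method reads low.

## Passing–Bablok regression

The slope is the shifted median of the N pairwise slopes
S_ij = (y_j−y_i)/(x_j−x_i), i < j: slopes equal to −1 are excluded from N,
K counts slopes below −1, and the median index is offset by K. Identical
points contribute nothing; pairs with equal x and different y contribute
signed infinities that sort beyond all finite slopes. The 1−α CI comes
from the rank statistics w = z_{1−α/2}·√(n(n−1)(2n+5)/18),
M1 = round((N−w)/2) (minimum 1), M2 = N−M1+1, each offset by K; M1 is
rounded to the nearest integer, the standard convention. The intercept is
median(y_i − b·x_i), with CI endpoints computed from the opposite slope
bounds. On noise-free collinear data all pairwise slopes coincide, so the
point estimates equal the generating line and the CIs have zero width.

The bootstrap path uses a fast point-estimate routine (`np.partition`
order-statistic selection instead of a full sort); a unit test pins it as
exactly equal to the full fit.

## Cusum linearity test

Residuals from the fitted line score +√(n_below/n_above) above the line,
−√(n_above/n_below) below, 0 on it; the scores are accumulated in order
of ascending projection onto the fitted line (x + y/slope, ties broken by
x then input index). The statistic max|cusum|/√(n_above+n_below) is
referred to the asymptotic Kolmogorov distribution
p = 2·Σ_{k≥1}(−1)^{k−1}exp(−2k²λ²) (`scipy.special.kolmogorov`). Because
the summed scores end at ~0 by construction, the cusum path is a bridge
and this reference distribution is the natural asymptotic.

Two numerical facts about this dialect, both confirmed against a
permutation oracle of the same statistic: (i) on data whose residual signs
come from a line *fitted to the same data* the test is conservative (the
observed type-I rate on linear 2 %-CV data is well below the nominal 5 %);
(ii) mild curvature needs a moderate sample to register — y = x² over
x = 1..20 yields max|cusum| = 5/√20 ≈ 1.12 (p ≈ 0.16 by both the
asymptotic tail and permutation), while the same curvature over x = 1..50
is rejected decisively (p ≈ 0.005). The test is therefore a guard against
gross nonlinearity, not a sensitive curvature detector.

## Spearman correlation, outlier screens, normality

Spearman ρ uses average ranks for ties (scipy), with a Fisher-z CI using
SE = 1/√(n−3). Tukey fences are Q1 − 1.5·IQR to Q3 + 1.5·IQR with linear
quartile interpolation. Grubbs (two-sided) flags at most the single most
extreme value against the t-based critical value; generalised ESD iterates
the Grubbs statistic up to max_k removals with per-step critical values
λ_i, declaring the largest step whose statistic exceeds its threshold;
with max_k = 1 it reduces exactly to Grubbs. Shapiro–Wilk is delegated to
scipy (`stats.shapiro`); re-deriving the AS R94 coefficients is standard
numerical work peripheral to this package. Screens only ever *report*
candidate outliers — removal is a deliberate user action, never automatic.

## Bland–Altman with nonparametric limits and ATE verdicts

The bias is the arithmetic mean difference with a t-based CI (n−1 df).
Limits of agreement are the empirical 2.5th/97.5th percentiles under the
Hazen rule (1-based rank h = p·n/100 + 0.5, linear interpolation, clamped
to the sample extremes). Percentile CIs are exact binomial order-statistic
intervals: the largest rank l with P(B < l) ≤ α/2 and the smallest rank u
with P(B ≥ u) ≤ α/2 for B ~ Binomial(n, p/100), clipped to the sample when
the tail mass is unattainable. This equal-tailed construction is
conservative; at n = 178 and p = 97.5 the exact designed coverage is
97.4 %, which the coverage test reproduces by simulation. Percentile CIs
are reported as unavailable below n = 20.

The allowable-total-error verdict compares the percentile *point
estimates* to ∓ the ATE half-width; CI-based verdicts are reported
alongside as informational only. An auxiliary OLS of differences on
comparative values (with CI) flags proportional bias.

## Lin's concordance correlation coefficient

ρ_c = 2s_xy/(s_x² + s_y² + (x̄−ȳ)²) with population (1/n) moments;
precision ρ is the Pearson correlation and accuracy C_b = ρ_c/ρ, so the
decomposition ρ_c = ρ·C_b holds to machine precision by construction. The
CI applies Lin's asymptotic variance to arctanh(ρ_c) with n−2 in the
denominator and back-transforms. Strength bands: < 0.90 poor, 0.90–0.95
moderate, 0.95–0.99 substantial, > 0.99 nearly perfect (left-closed at
0.90 and 0.95).

## Mountain plot

Sorted differences at empirical percentiles p_i = 100(i−0.5)/n are folded
to min(p_i, 100−p_i), so values lie in (0, 50], the peak sits at the
median, and a constant bias shifts the peak horizontally.

## Decision-limit bias bootstrap

The candidate method's expected reading at a decision limit is the
full-data Passing–Bablok line evaluated there. Uncertainty comes from
case resampling: specimen pairs are drawn with replacement, the line
refitted, and the prediction recomputed; CIs are the 2.5/97.5 percentiles
of the replicate predictions (percentile bootstrap, not BCa — matching the
"standard bootstrap interval" usage this schema mirrors). Replicates with
degenerate resamples (all x equal) are redrawn with a capped retry count.
Runs are bit-reproducible for a fixed seed within this implementation;
reproducing any other software's RNG stream is explicitly not a goal, and
the conventional seed 978 is recorded in reports only as provenance.
Simulation at study size (n = 178, 2 % CV, 1000 replicates) puts the
interval's coverage of the generating bias at ~95 %, inside the 93–97 %
acceptance band.

## Precision variance components

For a balanced D-day × R-replicate design (default 5×5), a one-way nested
ANOVA with day as the grouping factor gives V_r = MS_within and
V_day = (MS_between − MS_within)/R, truncated at zero when negative
(standard practice; with no true day effect the estimate is negative about
half the time since MS_between/MS_within ~ F(D−1, D(R−1))). V_wl = V_r +
V_day, and CVs are 100·√V divided by the grand mean, so CV_wl² = CV_r² +
CV_day² exactly. Unbalanced designs are rejected rather than approximated.
The single-run-per-day design collapses run and day, so the between
component is labelled "day"; control-material reconstitution variation is
inseparable from it and treated as part of it.

A precision note on the 5×5 design: the repeatability CV rests on
D(R−1) = 20 df and is estimated within ±0.6 CV points in ≈ 99 % of runs
at CV_r = 1.5 %, but the day component rests on only D−1 = 4 df, which by
the delta method puts SD(ĈV_wl) ≈ 0.46 at CV_wl = 2.1 % — so ĈV_wl lands
within ±0.6 points only ≈ 83 % of the time. That dispersion is a property
of the design, not of the estimator: tightening it requires more days, not
a different analysis. The acceptance suite therefore carries one check at
the ±0.6/90 % level for both named CVs (which the 5×5 design cannot meet
on CV_wl, and which is left failing as a faithful record) alongside the
repeatability-only check the design does support.

## Misinterpretation-risk model

A measured value is Normal(R + B, σ) for true value R and absolute bias B
(dataset units; CV terms are percent of R):

- diagnosis: σ = (R/100)·√(CV_wl² + BV_w² + BV_b²), because a diagnostic
  cut-off is interpreted against a population reference, so both
  biological components enter;
- monitoring: σ = (R/100)·√(2(CV_wl² + BV_w²)), the SD of the difference
  of two serial results in the same subject (factor 2, no between-subject
  term).

Under-diagnosis risk at R is P(read < L) = 1 − Φ(((R+B) − L)/σ);
over-diagnosis is P(read > U) = 1 − Φ((U − (R+B))/σ). The numerator
convention is deliberate: the bias shifts the measurement distribution's
mean, so U − (R+B) — not (U − R) + B — is the distance the measurement
must travel; this convention is the one that reproduces the reference
probabilities at both limits (2.5 %/1.0 % at R = 47; 0.1 %/0.2 % at
R = 39). Monitoring risks use z = (Δ ∓ B)/σ_mon. When σ = 0 the Normal
collapses to a point mass and exact indicators are returned. Evaluating
the monitoring formulas with the default constants gives a small nonzero
over-treatment probability (≈ 1 % at R = 47 with B = −1); the
implementation reports what the formulas give and does not force it to
zero. All closed forms are pinned against Monte-Carlo simulation (10⁶
draws, 3-SE tolerance) in the acceptance suite.

Defaults: IFCC — BV_w 1.6 %, BV_b 7.1 %, L 39, U 47, Δ 5 mmol/mol, B −1.0
(the decision-limit bootstrap bias), CV_wl 2.1 % (the within-laboratory CV
of the level nearest the decision region); NGSP — BV_w 1.2 %, BV_b 5.4 %,
L 5.7, U 6.4, Δ 0.46 %, B −0.10, CV_wl 1.26 %. The ideal test sets B = 0
and CV_wl = 0 and is by construction invariant to the analytical terms.
The Harris individuality index BV_w/BV_b (0.23 for the IFCC constants)
classifies HbA1c as highly individual at the ≤ 0.6 threshold.

## Synthetic-data generators

`simulate_comparison` draws true values uniformly over the clinically
observed range (default 30–73 mmol/mol; a clipped lognormal is available
for skewed populations), applies the generating line y_true = intercept +
slope·R, and adds multiplicative noise x = R(1+ε_x),
y = y_true(1+ε_y), ε ~ Normal(0, cv/100) — multiplicative because assay
imprecision is specified as a CV; `heteroscedastic=False` switches to
constant-SD noise anchored at mid-range for edge cases. Defaults are the
study conditions: n = 178, slope 1, intercept −1 mmol/mol, 2 % CV both
methods. `simulate_precision` draws value(d, r) = mean(1 + δ_d + ε_dr)
with δ_d ~ Normal(0, cv_day/100) and ε_dr ~ Normal(0, cv_r/100); defaults
mean 35 mmol/mol, both CVs 1.5 %, 5×5.

What the generators do *not* emulate: haemoglobin-variant interference,
pre-analytical artefacts (haemolysis, sample ageing), instrument drift
within a run, digitisation/rounding of reported results, and any
non-normal error structure. Passing tests therefore demonstrate that the
statistical machinery is correct under its stated model, not that any
particular instrument meets specification on real specimens.

## Problem sizes in the test suite

The acceptance suite runs the property studies at their natural sizes:
Passing–Bablok vs. a loop-transcription oracle at n ≤ 12 over 20 seeds;
Monte-Carlo risk checks at 10⁶ draws; variance-component recovery at the
5×5 design over 500 seeds; bootstrap-coverage at n = 178 over 500 datasets
with 1000 replicates each; percentile-CI coverage over 2000 seeds. The
whole suite completes in a few minutes on one CPU.

## Known limitations

- The Cusum p-value uses the asymptotic Kolmogorov tail; no small-sample
  or permutation option is exposed (the tests use one internally).
- Spearman and CCC intervals are large-sample (Fisher-z) constructions.
- Unbalanced precision designs and replicate-aware limits of agreement
  are out of scope; so are Deming regression, BCa/studentised bootstrap
  intervals, and percentage-difference Bland–Altman variants.
- The risk model assumes normally distributed analytical and biological
  variation with CVs constant in percent terms across the range.
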