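# Methods

## Scope and data model

`layreq` analyzes completely randomized supplementation trials in laying
hens: one unsupplemented control diet plus a grid of nutrient sources ×
added levels, replicated as cage groups observed over consecutive periods.
Raw inputs are replicate-period records (hen-days, egg counts and weights,
feed offered/residual, mortality) and an egg-level quality subsample; all
downstream statistics operate on derived traits keyed by
(treatment, replicate, period), with the replicate as the experimental
unit.

Doses are tracked on three scales: additive inclusion rate (mg product/kg
diet), nominal added element (rate × mass fraction, checked against printed
values to ±0.6 mg/kg — inclusion rates are themselves rounded to whole
mg/kg, so the worst case slightly exceeds half the 1 mg/kg print
precision), and analyzed total concentration in the mixed diet. Dose
-response fits use analyzed totals (the control is shared by every source
arm); the slope-ratio stage defaults to nominal supplemental doses, with
analyzed-minus-basal available.

## Trait definitions

All rates are hen-day based: dividing by realized bird-days makes the
mortality adjustment automatic. FCR is the ratio of summed feed to summed
egg mass — deliberately *not* the mean of per-period ratios, which differs
whenever egg mass varies between periods. The Haugh formula uses
100·log₁₀(h + 7.57 − 1.7·W^0.37); sources that print the exponent as 0.037
with the grouping `(1.7·W)0.037` reflect a typographic collapse of the
standard form, which places the 0.37 exponent on the egg weight alone — the
standard form is implemented. "Overall" rows are recomputed from summed
counts and masses (hen-day weighted); a `simple` switch averages period
values instead, since published summary tables rarely state which
convention they used.

## ANOVA, letters, contrasts

The one-way treatment ANOVA is a fixed-effects OLS cell-means fit
(statsmodels) with SEM = √(MSE/r). Tukey's HSD uses the studentized-range
quantile at the pooled residual df, falling back to the Tukey–Kramer
allowance per pair when replication is unbalanced; the compact letter
display uses the insert-and-absorb algorithm (split every letter containing
a significantly different pair, then drop absorbed subsets), with letters
ordered by descending group mean. Dose trends within each source arm use
orthogonal polynomial contrasts built by Gram–Schmidt on (x, x²) against
the constant vector at the *actual* dose values, so unequal spacing (10.4,
40.2, 70.75, 100.6 …) is handled exactly; contrasts are tested against the
pooled MSE of the full 10-treatment ANOVA.

## Broken-line fitting

For fixed break R both forms are linear in (L, U), so the SSE profile
SSE(R) is computed in closed form on a 0.1 mg/kg grid spanning
[min X + 0.1, max X − 0.1], vectorized across the grid. The minimum is
refined by bounded Brent search in the bracketing grid cell; if refinement
cannot improve on the grid point, the grid point stands, so the fitted SSE
never exceeds the grid scan's minimum. Standard errors come from the
delta-method/Gauss–Newton covariance s²(JᵀJ)⁻¹ at the optimum with
s² = SSE/(N−3). Degenerate inputs are explicit: a constant response
returns U = 0 with R undefined and a `degenerate` flag; fewer than 4
observations or 3 distinct doses raise an identifiability error; a break
estimate within one grid step of the dose range edge sets a `boundary`
flag.

**Flat profiles.** When several candidate breaks attain the minimal SSE
*identically* (tie tolerance 10⁻¹² of the SSE scale — an order of magnitude
above float roundoff, far below any real profile variation), the break is
not identified by the data. This happens structurally whenever at most one
dose lies below the true break: every R between that dose and the next one
reproduces the data exactly. The fitter then reports the *upper edge* of
the minimizing set (the largest dose at which the response could still be
rising, located by bisection on the profile), sets `identifiable=False`,
and records the flat interval. In the reference trial's sulphate arm
(doses 10.4/40.25/70.70/100.25, generative break 40) the noise-free QBL
profile is zero over (10.4, 40.25], so the reported edge is ≈40.25–40.28
rather than a point estimate of 40 — a property of the dose design, not of
the fitter.

Model selection ranks by lowest AIC (= N·ln(SSE/N) + 2P, P = k + 1 and
k = 3 for either form); fits within 2 AIC units are ranked by lower RMSE,
then higher adjusted R², with input order preserved on full ties. A
perfect fit carries an AIC of −∞ as an explicit sentinel. Adjusted R² is
the residual-df form 1 − (1−R²)(N−1)/(N−P); formulae that divide both sums
of squares by N−1 collapse algebraically to plain R² and are not used.

## Slope-ratio assay

OLS with a common intercept and one dose column per source (control rows
all-zero, at most one nonzero column per row; rank-deficient designs raise
an error naming the offending columns). RBE = 100·b_i/b_ref, reference
configurable (organic by default). Confidence limits use Fieller's theorem
on the ratio — unbounded (reported as NaN) when the reference slope is not
significantly nonzero, i.e. g = t²·v_rr/b_ref² ≥ 1 — with delta-method
limits alongside for comparison. Reports round RBE to integer percent;
full precision is retained in the result object.

## Synthetic-trial generator

The generator's defaults *are* the reference trial's conditions: the
10-diet design above, per-source broken-line truths for egg production
(oxide LBL 75.77/−0.07/82; sulphate QBL 78.17/−0.009/40; organic QBL
77.84/−0.014/33), flat truths for egg weight (62.9 g) and feed intake
(115.2 g/b/d) which showed no dose response, and replicate noise
sd = SEM·√6 from the published treatment-mean standard errors (e.g. EP:
1.67·√6 ≈ 4.1 % points). Egg mass and FCR are not simulated directly —
they inherit their dose response through the bookkeeping identities, which
keeps all records internally consistent. Two published generative values
needed repair: the organic-arm egg-mass plateau is printed an order of
magnitude off its trait scale (~49 g/b/d) and is replaced by the arm's
observed plateau 49.0; the organic-arm FCR model prints break 39 in the
formula but 40.0 in the text — the formula's 39 is used.

The control diet belongs to no source arm, so its generative value is the
mean of the three source curves at the basal concentration; when a test
needs an exactly consistent arm (noise-free round trips), it passes the
same curve for every source.

Noise is drawn once per replicate and shared across its periods — the
replicate is the experimental unit and the calibration targets the
between-replicate sd of whole-trial values; an optional per-period jitter
can be layered on. Egg-production draws are clipped to [0, 100] with a
logged count rather than rejected, preserving record bookkeeping. Egg
counts are fractional by default (`egg_count_mode="exact"`), which makes
the noise-free round trip — traits recomputed from simulated records equal
the truth curves — exact to 1e-9 relative; `"integer"` mode rounds daily
cumulative counts (remainder carried forward), quantizing EP by ~0.3 %
points per 28-day period. Egg-quality records are Gaussian around
treatment means (shell weight follows the published RESW slope model) with
physically impossible draws rejected and redrawn under a bounded retry
loop, so inconsistent parameter sets raise instead of spinning.

What the generator does **not** emulate: day-level laying sequences,
moult, mortality dynamics (mortality defaults to zero), between-period
trait drift (aging), or non-Gaussian replicate effects. Passing tests
therefore validate the estimators' arithmetic and their behavior under the
trial's design and noise magnitudes, not robustness to real-data artifacts
such as heteroscedasticity across treatments (the SEM calibration assumes
a pooled MSE) or missing records.

## Problem sizes and numerical choices

Unit and property tests run on the trial's natural sizes (10×6×3 records,
24-point arm fits). The stochastic recovery study uses 500 simulated
trials of the oxide arm (6 replicates × 4 doses, sd 4.1), enough for the
mean and SE of the break estimate to stabilize while the whole suite stays
fast. Profile grid step 0.1 mg/kg; Brent tolerance 1e-8; orthogonality
checks at 1e-12; oracle equivalences (grid scan, normal equations, direct
sums of squares) asserted at 1e-9–1e-10.

## Known limitations

* Break-point SEs use the Gauss–Newton approximation, which understates
  uncertainty when the profile is strongly asymmetric; the flat-profile
  flag covers the extreme case, and profile-based intervals would be the
  natural extension.
* Slope-ratio validity assumes a straight response over the supplemental
  range; when the underlying response plateaus (as the broken-line stage
  concludes), slopes — and hence RBE — depend on the dose range used, which
  is why RBE is reported with its dose encoding.
* Periods are analyzed separately or pooled; no repeated-measures
  correlation structure is modelled.
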