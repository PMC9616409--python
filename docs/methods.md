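# Methods

## Designs and coding

All analysis happens in coded factor units: `actual = center + coded * step`,
with the design step as the unit. A `FactorDefinition` stores the centre,
step and axial magnitude α per factor; the bundled screening mapping places
coded −1/+1 at each factor's low/high setting, and the response-surface
mapping places −2…+2 at five equally spaced actual levels (e.g. peptone
5, 6.25, 7.5, 8.75, 10 g/l; temperature 30–37 °C; agitation 120–200 rpm;
inoculum 1–3 %).

Plackett–Burman designs are built by cycling the classical generator row for
run counts 8, 12, 16, 20 and 24 and closing with an all-minus run; the result
is a saturated, balanced, mutually orthogonal ±1 array (XᵀX = nI), verified
by tests for every supported size. The software that produced the published
tables shuffles run order; the published 12×11 matrix therefore ships as a
fixture in its printed order and satisfies the same invariants.

Central composite designs are emitted factorial block (2ᵏ rows, Yates
order), then 2k axial rows at ±α, then centre rows. α defaults to the
rotatable value (2ᵏ)^¼, which is exactly 2 for k = 4. The *inscribed*
variant is realized purely through the factor mapping — the ±α codes sit at
the experimental bounds — so the coded matrix is the standard CCD.

## Surface fitting and diagnostics

`ResponseSurfaceRegressor` fits the first-order model (screening) or the
full quadratic (1 + k + k(k−1)/2 + k terms) by ordinary least squares; the
solve and per-term t statistics come from `statsmodels.OLS` after an SVD
rank check (tolerance 1e-10 × largest singular value) that names the
collinear terms on failure. Diagnostics:

* R² = 1 − SSE/SST; adjusted R² = 1 − (1 − R²)(n−1)/(n−p);
* PRESS = Σ (eᵢ/(1−hᵢ))², the exact leave-one-out identity via leverages
  hᵢ; predicted R² = 1 − PRESS/SST. PRESS is reported as NaN for a
  saturated fit (every leverage is 1). On orthogonal two-level designs all
  leverages equal p/n, giving the closed form
  predicted R² = 1 − (1 − R²)(n/(n−p))² (`predicted_r2_constant_leverage`).
* ANOVA: whole-model F = (SSR/(p−1))/MSE; per-term partial F = t² on
  (1, n−p) df, which coincides with the sequential decomposition on
  orthogonal designs; tail probabilities from the F distribution.

Tests cross-check the solver against the orthogonal-contrast formula
βᵢ = Σ(xᵢ y)/Σ(xᵢ²) and PRESS against brute-force leave-one-out refits.

## Effect screening

`screen_effects` ranks factors by |coefficient| and selects by backward
elimination. A saturated screen (11 factors, 12 runs) has no residual df,
so elimination starts from the magnitude ranking, keeping the largest
effects until one residual df exists. Each subsequent round refits and, by
default, drops **every** term whose p-value exceeds α, repeating until all
retained terms pass (`drop="all"`); dropping only the single worst term per
round is available as `drop="one"`.

The simultaneous-drop default is a deliberate choice: on the bundled
screening data, one-at-a-time elimination converges to eight retained
factors, because each small effect dropped shrinks the residual mean square
and makes the remaining mid-size effects look significant — an artefact of
near-saturation with tiny replicate error. Judging all terms against the
same round's error variance retains exactly the four factors (peptone,
temperature, agitation, inoculum size) that an exhaustive SSE comparison of
all four-factor submodels also selects, and that the published analysis
carried forward.

## Reconciliation of the screening table

The published screening observations are internally inconsistent: the
orthogonal-contrast intercept of a first-order fit is the response mean,
which is 194.95 for the observations as printed — not the published 186.62 —
and no least-squares fit of the printed data reproduces the published
coefficients or R² family. Replacing run 12's observed value (158.900,
plausibly a transcription slip for 58.9) by 58.952 — the unique value making
the four-factor intercept equal 186.62 — reproduces the published
coefficients (29.81, −85.54, 68.92, 37.04 ≈ printed 37.03) and
R² = 0.9778 / adjusted 0.9651 / predicted 0.9347 exactly. Both versions
ship (`pbd_screen_as_printed.csv`, `pbd_screen_reconciled.csv`); published
*prediction* checks use the printed coefficients, coefficient-*recovery*
checks use the reconciled table. The inconsistency itself is asserted as a
finding in the test suite.

## Optimization

For a single maximize goal the Derringer–Suich desirability
d(y) = ((y−L)/(U−L))^w clipped to [0,1] is monotone in y, so the optimizer
maximizes the predicted response directly and reports d afterwards. Goal
bounds default to the observed response range (L = min, U = max) with
weight 1, the common software default; under these defaults the bundled
optimum has desirability ≈ 0.994. The published value 0.974 is not
derivable from any documented bound choice and is treated as a finding,
not a target.

The search region defaults to the factorial cube [−1,1]ᵏ (the axial box
±α is available), because positive pure-quadratic curvature in the bundled
fit pushes the maximum to the cube boundary — the coded vertex (1,−1,1,1),
decoding to 8.75 g/l peptone, 31.75 °C, 180 rpm, 2.5 % inoculum. The
optimizer is deterministic: an exhaustive coarse grid capped at 2×10⁵
points per pass, iterative zoom around the incumbent down to the target
pitch (default 0.01 coded units), then an L-BFGS-B polish within bounds
(tolerance 1e-8); ties break to the lexicographically smallest point. A
full 0.01 grid in four dimensions (≈1.6×10⁹ points) would add nothing for
these smooth quadratics; correctness is instead certified in tests by a
10⁶-point Monte-Carlo sample and an independent exhaustive 0.05-pitch grid
oracle.

Validation error is 100·|predicted − actual|/predicted — the denominator is
the model prediction, which reproduces the published 1.76 % for
870.65 vs 886.246 (dividing by the actual value would give 1.79).

## Bioassay analytics

* Retention factor, hemolysis inhibition, percent inhibition (DPPH and
  α-glucosidase share one formula) and wound closure are direct ratios,
  with domain checks (positive control/denominators, compound distance not
  exceeding the solvent front).
* **IC50**: replicates are averaged per concentration (sd kept for
  reporting only); the default path fits a four-parameter logistic
  y = bottom + (top−bottom)/(1 + 10^(slope(log₁₀m − log₁₀c))) on log₁₀
  concentration by bounded least squares (bottom, top ∈ [0,100], slope sign
  free so rising inhibition and falling viability curves both fit;
  initialization from log-linear interpolation; convergence tolerance 1e-8)
  and solves the fitted curve for the 50 % absolute response. The
  `interp` method (also the fallback) interpolates linearly in log₁₀
  concentration between the bracketing observations. Observed responses
  must bracket 50 %: an extrapolated IC50 is refused rather than reported —
  slightly stricter than requiring only fit convergence, since an IC50
  outside the tested range is not experimentally supported.
* **MNTD** is the largest tested concentration with mean viability at or
  above a threshold, default 90 % — chosen because a dose showing ~96 %
  viability is conventionally still accepted as non-toxic; the threshold is
  an explicit parameter.
* **MIC/MBC** reduce boolean growth flags: the smallest concentration with
  no broth growth (MIC) / no subculture growth (MBC), reported as
  "> max tested" beyond the series. Only the endpoints were published, so
  the bundled plate file is a synthetic monotone reconstruction consistent
  with them, labelled synthetic.

## Synthetic data

`simulate_surface` draws yᵢ = polynomial(true β, coded rowᵢ) + N(0, σ),
floored at 0 since yields are concentrations — a mild truncation bias at
noise levels comparable to the smallest mean response.
`simulate_dose_response` samples a 4PL forward curve with replicate
Gaussian noise clipped to [bottom, top]. Default truth for surfaces is the
published quadratic coefficient set; the noise default is the residual
standard deviation √(SSE/(n−p)) ≈ 76.6 µg/ml of the bundled fit. Seeding
uses numpy's `SeedSequence` with one substream per scenario kind, so adding
a scenario never perturbs another's draws, and identical seeds reproduce
tables byte-for-byte.

The generators emulate the *statistical* structure the analysis assumes —
polynomial mean surface, homoscedastic Gaussian noise, 4PL dose response —
not real fermentation kinetics: no run-order drift, batch effects,
heteroscedasticity or plate position effects. Passing recovery tests
therefore validates the estimators under their own assumptions, not the
biology.

## Problem sizes and determinism

Everything runs at desk scale: 12- and 30-run fits, 500-replicate
Monte-Carlo recovery (unbiasedness within 3 standard errors,
SE = σ/√(R·Σx²)), 10⁶-point optimization certificates. The full suite and
the acceptance script complete in seconds on one CPU; the only stochastic
pieces are the seeded generators.

## Known limitations

* Fractional factorial / Box–Behnken / D-optimal designs, blocking, and
  lack-of-fit vs pure-error decomposition are out of scope.
* Desirability handles a single response; no multi-response aggregation.
* The 4PL fit reports a point estimate only (no confidence interval), and
  refuses extrapolated IC50s by design.
* Per-term p-value matching against the original software's ANOVA tables is
  not attempted (those tables are not fully available); the supported
  claims are the coefficient, R²-family, prediction, optimum and validation
  values reproduced in the tests.
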