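# fermopt

Statistical design-of-experiments toolkit for optimizing microbial pigment
fermentation, with analytics for the downstream in vitro bioassays.

The package targets the standard two-stage medium-optimization workflow used
for microbial metabolite yields — here, C50 carotenoid (bacterioruberin-type)
production by a marine *Kocuria* isolate:

1. **Screening** — a Plackett–Burman design (PBD) estimates the main effect of
   each of many culture factors (medium components, pH, temperature,
   agitation, inoculum size, incubation time) from ~K+1 runs, via the
   first-order model

   *Y* = β₀ + Σᵢ βᵢ Xᵢ,

   where Xᵢ are coded (−1/+1) factor levels; significant factors are selected
   by backward elimination.
2. **Response-surface modelling** — a central composite inscribed design (CCI)
   over the significant factors supports the full quadratic model

   *Y* = β₀ + Σ βᵢ Xᵢ + Σ βᵢᵢ Xᵢ² + ΣΣ βᵢⱼ Xᵢ Xⱼ + E,

   fit by ordinary least squares with the usual diagnostics (ANOVA, R²,
   adjusted R², PRESS/predicted R², leverages).
3. **Optimization & validation** — the fitted surface is maximized over a
   coded box through a Derringer–Suich desirability function, and the optimum
   is validated against a confirmation run by percent error.

A separate module implements the bioassay analytics used to characterize the
product: TLC retention factor, hemolysis-inhibition and percent-inhibition
formulas (DPPH, α-glucosidase), scratch-assay wound closure, four-parameter
logistic IC50 estimation, maximum non-toxic dose (MNTD), selectivity index,
and MIC/MBC reduction of broth-microdilution plates. A synthetic-data module
generates surfaces and dose–response curves with known truth for testing.

The published 12-run screening table, 30-run response-surface table and
factor-level mappings ship as fixtures, so the whole pipeline reproduces the
published analysis with no downloads.

## Worked example

```python
import numpy as np
from fermopt import fit_least_squares, maximize_surface, validation_error
from fermopt.datasets import load_rsm_experiment, load_rsm_factors

table, _ = load_rsm_experiment()          # 30-run CCI, 4 factors, coded units
fit = fit_least_squares(table, "quadratic")
print(f"intercept {fit.intercept_:.2f}, peptone {fit.coefficients_['peptone']:.2f}")
print(f"R2 {fit.r2_:.4f}  adj {fit.r2_adjusted_:.4f}  pred {fit.r2_predicted_:.4f}")

opt = maximize_surface(fit, factors=load_rsm_factors())
print("coded optimum", opt.coded_point, f"-> {opt.predicted_response:.3f} ug/ml")
print("actual units", opt.actual_point)
print(f"validation error {validation_error(870.65, opt.predicted_response):.2f} %")
```

prints

```
intercept 509.25, peptone 48.81
R2 0.9270  adj 0.8588  pred 0.6600
coded optimum [ 1. -1.  1.  1.] -> 886.246 ug/ml
actual units {'peptone': 8.75, 'temperature': 31.75, 'agitation': 180.0, 'inoculum_size': 2.5}
validation error 1.76 %
```

i.e. the quadratic surface predicts a maximum carotenoid yield of
886.246 µg/ml at 8.75 g/l peptone, 31.75 °C, 180 rpm and 2.5 % inoculum
(the vertex (1, −1, 1, 1) of the coded factorial cube), and a confirmation
run of 870.65 µg/ml deviates from that prediction by 1.76 %.

The same stages are available from the shell:

```bash
fermopt pipeline --out results/          # screen -> fit -> optimize -> validate
fermopt fit --table my_experiment.csv    # run,<factors...>,response CSV
fermopt assay ic50 --curve my_curve.csv  # concentration,rep1,rep2,... CSV
```

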