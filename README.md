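# goalder

Doubly robust estimation of the dose–response function (DRF) for a
**continuous treatment** with **high-dimensional covariates**.

Observational studies with rich covariate information (omics panels,
health-records data) make unconfoundedness plausible, but classical
generalized-propensity-score (GPS) methods then face two hazards: the treatment
model is easily misspecified, and balancing the *wrong* covariates — in
particular instrumental variables, which predict the treatment but not the
outcome — inflates variance without removing bias.  `goalder` implements an
estimator that addresses both at once, together with the comparator and the
Monte-Carlo machinery used to evaluate it.  It is aimed at biostatisticians
and epidemiologists estimating continuous-exposure effects (e.g. epigenetic
age acceleration on disease) from tabular data with many candidate
confounders.

## The method

Given an i.i.d. sample (Tᵢ, Yᵢ, **Z**ᵢ), i = 1…n with continuous treatment T,
outcome Y and p covariates, the target is the dose–response function
E[Y(t)], summarized by the slope η of its linear projection.

1. **Outcome-model-free covariate selection.**  The treatment model
   E[T|Z] = α₀ + Σⱼ Zⱼαⱼ is fitted with a weighted-L1 penalty
   λₙ Σⱼ ŵⱼ|αⱼ|, where ŵⱼ = (dⱼ / maxₖ dₖ)^(−γ) and
   dⱼ = |dcor(Zⱼ, Y | T)| is the *conditional distance correlation* between
   covariate j and the outcome given the treatment.  Covariates carrying no
   outcome information (instruments, noise) receive huge penalties and drop
   out; no outcome regression is ever fitted, which preserves double
   robustness.  λₙ runs over the grid {n⁻¹⁰, …, n⁰·⁴⁹} with γ coupled by
   λₙ·n^(γ/2−1) = n².

2. **Distance-covariance optimal weights (DCOW).**  For each candidate active
   set, subject weights w (wᵢ ≥ 0, Σwᵢ = n, first moments preserved) minimize
   the weighted squared distance covariance between T and the selected
   covariates — removing dependence of *any* order, not just chosen moments.

3. **Tuning by dual-weight distance correlation (DWDC).**  λₙ is chosen to
   minimize Σⱼ dⱼ² · |dcor_w(Zⱼ, T)|: imbalance only matters in proportion to
   a covariate's outcome relevance.

4. **Doubly robust pseudo-outcome.**  With a stacked outcome regression
   μ̂(Z, T) (lasso, gradient-boosted trees, random forest, SVR; nonnegative
   least-squares stacking on out-of-fold predictions),

   θ̂(Tᵢ) = (1/n) Σₖ μ̂(**Z**ₖ, Tᵢ) + (Yᵢ − μ̂(**Z**ᵢ, Tᵢ)) · wᵢ,

   and the DRF slope is the OLS coefficient of θ̂ on T.  The estimate is
   consistent if *either* the balancing weights or the outcome model is
   right.

The `SLDR` comparator replaces steps 1–3 with normal density-ratio GPS
weights w = f(T)/f(T|Z) estimated on **all** covariates — it ignores
instruments, which is exactly why its sampling variance is larger.

## Worked example

```python
import numpy as np
from goalder import GOALDeR, ScenarioSpec, generate_dataset

# a synthetic cohort: Z1, Z2 confounders; Z3, Z4 prognostic; Z5, Z6
# instruments; Z7..Z20 noise; true dose-response slope = 2
data = generate_dataset(ScenarioSpec("SoSt", n=500, p=20, rho=0.0, eta=2.0, seed=1))

model = GOALDeR(data.t, data.y, data.z, fast=True, seed=1)
res = model.fit()
print(res.summary())
```

```
GOALDeR dose-response estimate
============================================
n = 500, p = 20
slope      2.028786  (analytic sd 0.023165)
intercept -0.161895
95% CI (slope, analytic): [1.983383, 2.074189]
selected covariates: Z1, Z2, Z3, Z4
```

The selected set contains the confounders and prognostic covariates and
excludes both instruments; the slope estimate 2.03 recovers the simulated
effect of 2 with its analytic standard error from the pseudo-outcome
regression.  `res.bootstrap(B=100, seed=7)` adds a bootstrap standard error
and percentile interval (the analytic SE is known to understate the
post-selection uncertainty); `res.dwdc_trace()` shows the tuning criterion
along the λ grid, and `goalder.balance_report` gives per-covariate balance
diagnostics.

From the shell, the same interfaces are available as
`goalder fit --data cohort.csv`, `goalder simulate --setting SoSt --n 500
--p 20 --reps 100`, and `goalder diagnose --data cohort.csv`.

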