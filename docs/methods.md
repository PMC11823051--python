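# Methods

This note documents the statistical machinery behind `goalder`: the
estimators, the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions.

## Setting and estimand

Data are an i.i.d. sample (Tᵢ, Yᵢ, **Z**ᵢ) with a continuous treatment T, an
outcome Y, and p pre-treatment covariates.  Under consistency, positivity,
unconfoundedness given **Z**, and no interference, the dose–response function
E[Y(t)] is identified.  The package estimates the slope η of its linear
projection (a polynomial basis of higher degree is available through the
`degree` option, but the linear summary is the default and is what the
simulation study evaluates).

Covariates fall into four functional classes: confounders (affect both T and
Y), prognostic covariates (Y only), instruments (T only), and spurious
covariates (neither).  An optimal weighting scheme balances confounders and
prognostic covariates; balancing instruments inflates variance without
reducing bias, which is why selection is built into the estimator.

## Distance statistics

All dependence measures are distance-correlation based, computed from plain
O(n²) V-statistics with double centering.  The key structural fact used
throughout: the Euclidean distance kernel is conditionally negative definite,
so the negated double-centered distance matrix is positive semidefinite and
the weighted quadratic form

  dcov²_w(X, T) = (1/n²) Σᵢⱼ wᵢwⱼ AᵢⱼBᵢⱼ

(with A, B the double-centered distance matrices) is **convex in w** and
nonnegative for every weight vector.  This is why the biased V-statistic,
not the bias-corrected U-statistic, is used for balance objectives and
balance diagnostics.  Any distance correlation involving a constant variable
is defined as 0 (avoids 0/0).  Degenerate-input floors use a 1e-14 epsilon.

### Conditional distance correlation

The penalty weights need d_j = |dcor(Z_j, Y | T)|, a measure of how much
outcome information a covariate carries once the treatment is held fixed.
The estimator is kernel-based: at each evaluation point t₀, Gaussian
Nadaraya–Watson probability weights vᵢ ∝ K((Tᵢ − t₀)/h) are formed, a
v-weighted distance correlation of (Z_j, Y) with *weighted* double centering
is computed, and the values are averaged over evaluation points.

Defaults and their rationale:

* **Bandwidth** h: Silverman's rule 0.9·min(sd, IQR/1.34)·n^(−1/5) on T —
  the standard density-estimation default for a scalar conditioning
  variable; overridable via `bandwidth`.
* **Evaluation points**: 40 rank-equispaced (quantile) order statistics of T
  (`cdc_eval_points`; `None` uses every observation).  Quantile spacing
  follows the treatment distribution; 40 points track the full-evaluation
  estimate to well within its own Monte-Carlo noise while keeping the cost
  of a p-column profile at O(p·n²·40) BLAS operations.
* **Small-sample bias correction** (on by default): kernel localization
  leaves an effective sample size of order n·h per evaluation point, where
  the plain V-statistic has a substantial positive null bias — conditionally
  independent covariates would score ≈ 0.2 rather than ≈ 0, destroying the
  penalty ordering that selection depends on and making the tuning criterion
  reward balancing instruments.  The exact null expectation of the weighted
  V-statistic, E₀[dcov²_v] = (s₂ − 2s₃ + s₂²)·E[a]·E[b] with s_k = Σᵢ vᵢᵏ
  (E[a], E[b] estimated by v'Dv/(1 − s₂)), is subtracted from the numerator
  and the result clamped at zero.  With the correction, conditionally
  independent covariates score ≈ 0.03 and the outcome-relevant ones remain
  ≈ 0.3–0.5 in the simulated designs.

A constant conditioning variable triggers a logged fall-back to the
unconditional distance correlation.  The estimator is invariant to affine
rescaling of Z and Y by construction.

## Covariate selection (treatment-model adaptive lasso)

The selection problem is

  min_α ‖T − α₀ − Zα‖² + λₙ Σⱼ ŵⱼ|αⱼ|,  ŵⱼ = (dⱼ / maxₖ dₖ)^(−γ).

The *inverse* exponent is used: stronger outcome relevance ⇒ smaller
penalty, so instruments (dⱼ ≈ 0) are penalized out while confounders and
prognostic covariates survive.  A `penalty_direction="direct"` switch
reproduces the opposite sign convention for comparison.  dⱼ = 0 maps to an
infinite penalty and deterministic exclusion; ties in the maximum are broken
by the first index; if every dⱼ is zero the model declines to select
("no covariate related to outcome").

Covariates are standardized and the treatment centered before fitting, so
the penalty weights are comparable across covariates; coefficients are
reported on the original scale.  The weighted problem is solved exactly by
the standard reparameterization (lasso on Zⱼ/ŵⱼ; coordinate descent,
tolerance 1e-7, up to 10⁵ passes), and λ = 0 falls back to least squares.

The λ grid is {n^a} for a ∈ {−10, −5, −2, −1.25, −1, −0.75, −0.5, −0.25,
0.25, 0.49}, with γ coupled to each grid point by λₙ·n^(γ/2−1) = n², i.e.
γ = 2(3 − a); every grid point satisfies γ > 1, inside the region where the
penalty is simultaneously vanishing (λₙ/√n → 0) and selection-consistent
(λₙ·n^(γ/2−1) → ∞).

## Balance weights (DCOW)

For an active set S, weights solve the convex quadratic program

  min_w  dcov²_w(T, Z_S) + (ridge/n)·Σᵢ(wᵢ − 1)²
  s.t.   wᵢ ≥ weight_floor,  Σᵢ wᵢ = n,
         weighted first moments of T and each column of Z_S preserved.

Decorrelating the *distance* dependence removes associations of every
order, so no moment-order choice is needed; the first-moment constraints
pin the location of the weighted marginals, and the distance-covariance
objective handles everything beyond location.  The empty active set returns
uniform weights without solving.

* **ridge (dispersion) penalty, default 0.1**: the ridge trades residual
  treatment–covariate dependence against weight dispersion.  At 1.0 the
  dispersion term dominates and the weights barely move (residual weighted
  dcor ≈ 0.8 of the unweighted value in a one-confounder design); at 0.1
  the residual dependence drops to ≈ 0.3–0.35 of its unweighted value while
  the weights keep sd ≈ 0.6 around 1 — dispersion comparable to routine
  inverse-probability weighting.  Smaller values balance harder at the cost
  of heavier weight tails (positivity strain).
* **weight_floor, default 0** (positivity as wᵢ ≥ 0); a strictly positive
  floor (e.g. 1e-6) is available when downstream code divides by weights.

The QP is solved by a deterministic dense active-set method on the bound
constraints (exact KKT solves, dependent constraint rows dropped by pivoted
QR); there is no randomness and no iteration-dependent tolerance beyond the
1e-9 KKT residual.  Because uniform weights are feasible, the solution's
objective never exceeds the uniform objective, and solutions preserve the
constrained means to < 1e-6.

## Tuning (DWDC)

For each λ on the grid, DCOW weights are computed from its active set and

  DWDC(λ) = Σⱼ₌₁..p dⱼ² · |dcor_w(Zⱼ, T)|

is evaluated over **all** p covariates (the weights depend on the active
set; the summand does not).  The dⱼ are computed once per dataset — they do
not depend on λ — and identical active sets along the grid share one DCOW
solve.  The minimizing λ is selected; exact ties go to the larger λ (the
sparser model).  Imbalance in a covariate only contributes in proportion to
its squared outcome relevance, so the criterion is driven by confounders
and prognostic covariates and is nearly indifferent to instruments and
noise.

## Outcome model and the doubly robust step

μ̂(Z_S, T) is a stacking ensemble over four learner families — L1-penalized
linear regression (5-fold CV over 60 penalties), gradient-boosted trees
(200 depth-3 trees, learning rate 0.1), random forest (200 trees, minimum
leaf 5), and RBF support-vector regression (standardized inputs, C = 1) —
combined by nonnegative least squares on 5-fold out-of-fold predictions and
refit on the full sample.  Exact hyperparameters are conventional defaults,
not tuned per dataset.  A `fast` learner set (lasso + boosted trees) is the
pragmatic choice for simulation studies; the stacked out-of-fold loss stays
within fold noise of the best constituent either way.  All learner seeds
derive from the single model seed, so fits are reproducible.

The pseudo-outcome is

  θ̂(Tᵢ) = (1/n) Σₖ μ̂(**Z**ₖ, Tᵢ) + (Yᵢ − μ̂(**Z**ᵢ, Tᵢ))·wᵢ,

computed via an n×n cross-prediction matrix, and the DRF is the OLS fit of
θ̂ on (1, T).  The reported analytic SE is the conventional OLS slope SE of
that regression — deliberately so, since its undercoverage after selection
is itself one of the findings the package reproduces; no sandwich correction
is applied.  The nonparametric bootstrap (default B = 100) re-runs the
*entire* pipeline — selection, tuning, weighting, outcome fit — on each
resample; both percentile and normal-approximation intervals are reported,
since the reference construction is not pinned down.  Replicate failures
are logged and tolerated up to 10%.

The SL-DR comparator estimates the GPS as Normal(m̂(Z), σ̂) with m̂ fitted by
the same ensemble on all p covariates and σ̂ the residual root mean square;
weights are the density ratio f_T(Tᵢ)/f_{T|Z}(Tᵢ|Zᵢ), rescaled to sum to n
(no truncation: renormalization alone stabilized every simulated design).
Marginal moments use the ddof-0 convention so that an independent treatment
yields exactly unit weights.

## Synthetic-data generator

Covariates are equicorrelated standard Gaussians (one-factor construction,
exactly equivalent to the Cholesky factor of the equicorrelation matrix);
T = m(Z) + N(0,1) and Y = ηT + g(Z) + N(0,1).  Scenario 1 uses linear
(m, g) in three strength patterns (SoSt/SoWt/WoSt; confounders Z1–Z2,
prognostic Z3–Z4, instruments Z5–Z6); scenario 2 passes the first four
covariates through a shared nonlinear block
NL(Z) = exp(Z1/2) + [Z2/(1+exp(Z1)) + 10] + (0.04·Z1·Z3 + 0.6)³ + (Z2+Z4)²
in the treatment model (CoMt), the outcome model (MoCt), or both (MoMt),
with instruments Z7–Z8.  Defaults η = 2, ρ ∈ {0, 0.2, 0.5}, cells
(n, p) = (200, 100), (500, 200), and p = 20 for selection-frequency studies.
Per-replicate seeds are base + index, so any cell is reproducible and
trivially parallelizable.

What the generator does **not** emulate: heteroscedastic or heavy-tailed
noise, discrete or bounded treatments, covariate measurement error, missing
data, and realistic omics correlation structure (blocks, sparsity of true
signals beyond the equicorrelated factor).  Passing tests therefore certify
the estimator's behavior under the stated Gaussian designs, not performance
on any particular real cohort.

## Scale of the reproduction runs

The Monte-Carlo reproductions in `tests/test_acceptance.py` run the
(n = 500, p = 200) estimation cells at 30 replicates (linear design and
comparator) and 12 replicates (misspecified designs) with the fast learner
set, comparing cell means within three Monte-Carlo standard errors at those
replicate counts; selection-frequency cells use 60 replicates, and
`scripts/acceptance.py` uses the full 100.  These sizes were chosen so the
whole suite completes comfortably on a single core while keeping the
Monte-Carlo tolerance meaningfully tight.

## Known limitations

* The analytic SE ignores selection and weighting variability and
  undercovers; the bootstrap is the recommended interval.
* Selection assumes a linear treatment model; when the treatment model is
  nonlinear the selected set is unreliable and only the outcome-model side
  of the double robustness protects the estimate (and neither side does
  when both models are nonlinear — the MoMt breakdown is expected
  behavior).
* The conditional distance correlation of an instrument given the treatment
  is not exactly zero in finite samples (conditioning on a common effect
  induces dependence with the outcome's causes), so instrument exclusion is
  asymptotic in practice, not guaranteed per dataset.
* p ≥ n designs are outside the supported range for the selection step's
  least-squares limit (mirroring the method's own applicability condition).
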