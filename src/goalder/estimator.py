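"""Doubly robust dose-response estimation (pseudo-outcome construction).

The estimand is the dose-response function E[Y(t)] for a continuous
treatment.  Following the two-step doubly robust recipe, a per-subject
pseudo-outcome is built from an outcome regression mu(Z, T) and balance
weights w,

    theta_i = (1/n) sum_k mu(Z_k, T_i)  +  (Y_i - mu(Z_i, T_i)) * w_i,

and then regressed on the treatment; with a linear basis the slope of that
regression is the dose-response parameter.  The estimate is consistent when
either the weights remove treatment-covariate dependence (correct balancing /
GPS side) or the outcome regression is correct -- the double robustness that
the simulation study probes.

Two model classes share this machinery, statsmodels-style:

* :class:`GOALDeR` -- outcome-model-free adaptive-lasso covariate selection,
  DWDC-tuned penalty, distance-covariance optimal balance weights;
* :class:`SLDR` -- the comparator that uses all covariates and normal
  density-ratio GPS weights.

Both ``.fit()`` methods return a :class:`DRFResults` carrying the estimates,
standard errors, diagnostics, ``summary()`` and bootstrap machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .balance import BalanceWeights
from .data import TriSample
from .distance import check_weight_vector
from .ensembles import (
    FAST_LEARNERS,
    FULL_LEARNERS,
    OutcomeModelFit,
    fit_gps_normal,
    fit_outcome_ensemble,
    gps_ratio_weights,
    predict_outcome,
    predict_outcome_matrix,
)
from .selection import DEFAULT_LAMBDA_EXPONENTS, build_selection_path
from .tuning import dwdc_trace, select_lambda

__all__ = [
    "PseudoOutcome",
    "DRFResults",
    "BootstrapResult",
    "GOALDeR",
    "SLDR",
    "build_pseudo_outcome",
    "regress_drf",
    "estimate_goaldr",
    "estimate_sldr",
    "bootstrap_sd",
]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is embedded in the message."""


@dataclass
class PseudoOutcome:
    """Pseudo-outcome and its two components (marginalized + weighted residual)."""

    theta: np.ndarray
    term1: np.ndarray   # (1/n) sum_k mu(Z_k, T_i)
    term2: np.ndarray   # (Y_i - mu(Z_i, T_i)) w_i


def build_pseudo_outcome(
    fit: OutcomeModelFit, t, y, z_active, w
) -> PseudoOutcome:
    """Construct the doubly robust pseudo-outcome."""
    t = np.asarray(t, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = t.shape[0]
    if y.shape[0] != n:
        raise ValueError("t and y must share the sample size")
    w = check_weight_vector(np.asarray(w, float), n)
    cross = predict_outcome_matrix(fit, z_active, t)  # rows: subjects k, cols: T_i
    term1 = cross.mean(axis=0)
    mu_obs = predict_outcome(fit, z_active, t)
    term2 = (y - mu_obs) * w
    return PseudoOutcome(theta=term1 + term2, term1=term1, term2=term2)


def regress_drf(theta, t, degree: int = 1):
    """OLS of the pseudo-outcome on (1, T, ..., T^degree).

    Returns the fitted statsmodels results; the slope on T (coefficient 1) is
    the dose-response parameter under the default linear basis.
    """
    theta = theta.theta if isinstance(theta, PseudoOutcome) else np.asarray(theta, float).ravel()
    t = np.asarray(t, dtype=float).ravel()
    if t.shape[0] != theta.shape[0]:
        raise ValueError("theta and t must share the sample size")
    if t.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    if t.std() <= 1e-14:
        raise ValueError("treatment is constant; dose-response slope undefined")
    if degree < 1:
        raise ValueError("degree must be >= 1")
    X = np.column_stack([t ** k for k in range(1, degree + 1)])
    X = sm.add_constant(X)
    return sm.OLS(theta, X).fit()


@dataclass
class BootstrapResult:
    """Nonparametric bootstrap of the full estimation pipeline."""

    boot_sd: float
    ci_percentile: tuple[float, float]
    ci_normal: tuple[float, float]
    slopes: np.ndarray
    n_failed: int
    ci_level: float = 0.95


class DRFResults:
    """Results of a fitted dose-response model.

    Carries the regression of the pseudo-outcome on the treatment (estimates,
    analytic standard errors, Wald tests), the selected covariates and balance
    weights that produced it, and bootstrap-based uncertainty on demand.
    """

    def __init__(
        self,
        model,
        ols_results,
        pseudo: PseudoOutcome,
        weights: BalanceWeights | np.ndarray,
        *,
        selected: np.ndarray | None = None,
        dwdc_records=None,
        outcome_fit: OutcomeModelFit | None = None,
        ci_level: float = 0.95,
    ):
        self.model = model
        self._ols = ols_results
        self.pseudo = pseudo
        self.weights = weights
        self.selected = None if selected is None else np.asarray(selected, int)
        self.dwdc_records = dwdc_records
        self.outcome_fit = outcome_fit
        self.ci_level = ci_level
        self.boot: BootstrapResult | None = None

    # -- point estimates and analytic inference -------------------------------
    @property
    def method(self) -> str:
        return self.model.method

    @property
    def params(self) -> np.ndarray:
        return np.asarray(self._ols.params)

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    @property
    def slope(self) -> float:
        return float(self.params[1])

    @property
    def bse(self) -> np.ndarray:
        return np.asarray(self._ols.bse)

    @property
    def analytic_sd(self) -> float:
        return float(self.bse[1])

    @property
    def tvalues(self) -> np.ndarray:
        return np.asarray(self._ols.tvalues)

    @property
    def pvalues(self) -> np.ndarray:
        return np.asarray(self._ols.pvalues)

    @property
    def nobs(self) -> int:
        return int(self._ols.nobs)

    def conf_int(self, alpha: float | None = None) -> np.ndarray:
        """Normal-approximation CI for (intercept, slope): est +/- z * sd."""
        alpha = (1.0 - self.ci_level) if alpha is None else alpha
        zq = stats.norm.ppf(1.0 - alpha / 2.0)
        lo = self.params - zq * self.bse
        hi = self.params + zq * self.bse
        return np.column_stack([lo, hi])

    @property
    def boot_sd(self) -> float | None:
        return None if self.boot is None else self.boot.boot_sd

    @property
    def selected_covariates(self) -> list[str]:
        if self.selected is None:
            return list(self.model.data.covariate_names)
        return [self.model.data.covariate_names[j] for j in self.selected]

    def dwdc_trace(self) -> pd.DataFrame | None:
        return None if self.dwdc_records is None else dwdc_trace(self.dwdc_records)

    # -- bootstrap -------------------------------------------------------------
    def bootstrap(self, B: int = 100, seed: int = 0, max_fail: float = 0.1) -> BootstrapResult:
        """Resample subjects and re-run the full pipeline B times."""
        self.boot = _bootstrap_pipeline(self.model, B=B, seed=seed,
                                        ci_level=self.ci_level, max_fail=max_fail)
        return self.boot

    # -- presentation ----------------------------------------------------------
    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            f"{self.method} dose-response estimate",
            "=" * 44,
            f"n = {self.nobs}, p = {self.model.data.p}",
            f"slope     {self.slope: .6f}  (analytic sd {self.analytic_sd:.6f})",
            f"intercept {self.intercept: .6f}",
            f"{int(self.ci_level * 100)}% CI (slope, analytic): "
            f"[{ci[1, 0]:.6f}, {ci[1, 1]:.6f}]",
        ]
        if self.boot is not None:
            lines.append(
                f"bootstrap sd {self.boot.boot_sd:.6f}, percentile CI "
                f"[{self.boot.ci_percentile[0]:.6f}, {self.boot.ci_percentile[1]:.6f}]"
            )
        if self.selected is not None:
            lines.append("selected covariates: " + (", ".join(self.selected_covariates) or "(none)"))
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<DRFResults {self.method}: slope={self.slope:.4f} "
                f"sd={self.analytic_sd:.4f} n={self.nobs}>")


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


class _BaseModel:
    """Shared constructor/validation for the dose-response model classes."""

    method = "base"
    min_n = 30

    def __init__(self, treatment, outcome, covariates, *,
                 covariate_names=None, learners=None, fast: bool = False,
                 folds: int = 5, degree: int = 1, seed: int = 0,
                 ci_level: float = 0.95):
        z = np.asarray(covariates, dtype=float) if covariates is not None else None
        if z is None or z.size == 0:
            raise ValueError("no covariates supplied")
        self.data = TriSample(treatment, outcome, z,
                              covariate_names=list(covariate_names or []))
        if self.data.n < self.min_n:
            raise ValueError(f"{self.method} needs n >= {self.min_n}, got {self.data.n}")
        if learners is None:
            learners = FAST_LEARNERS if fast else FULL_LEARNERS
        self.learners = tuple(learners)
        self.folds = int(folds)
        self.degree = int(degree)
        self.seed = int(seed)
        self.ci_level = float(ci_level)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, treatment: str = "T",
                       outcome: str = "Y", covariates=None, **kwargs):
        tri = TriSample.from_dataframe(df, treatment, outcome, covariates)
        return cls(tri.t, tri.y, tri.z, covariate_names=tri.covariate_names, **kwargs)

    def _clone_kwargs(self) -> dict:
        return dict(learners=self.learners, folds=self.folds, degree=self.degree,
                    seed=self.seed, ci_level=self.ci_level)

    def _rebuild(self, t, y, z):
        raise NotImplementedError


class GOALDeR(_BaseModel):
    """Generalized outcome-adaptive lasso + doubly robust dose-response model.

    Pipeline: conditional-dcor penalty weights -> weighted-lasso selection path
    over the lambda grid -> DWDC tuning -> DCOW balance weights on the selected
    set -> stacked outcome regression on the selected set -> pseudo-outcome ->
    dose-response regression.
    """

    method = "GOALDeR"

    def __init__(self, treatment, outcome, covariates, *,
                 lambda_exponents=DEFAULT_LAMBDA_EXPONENTS,
                 cdc_eval_points: int | None = 40,
                 bandwidth: float | None = None,
                 penalty_direction: str = "inverse",
                 ridge_penalty: float = 0.1,
                 weight_floor: float = 0.0,
                 **kwargs):
        super().__init__(treatment, outcome, covariates, **kwargs)
        self.lambda_exponents = tuple(lambda_exponents)
        self.cdc_eval_points = cdc_eval_points
        self.bandwidth = bandwidth
        self.penalty_direction = penalty_direction
        self.ridge_penalty = float(ridge_penalty)
        self.weight_floor = float(weight_floor)

    def _clone_kwargs(self) -> dict:
        kw = super()._clone_kwargs()
        kw.update(lambda_exponents=self.lambda_exponents,
                  cdc_eval_points=self.cdc_eval_points, bandwidth=self.bandwidth,
                  penalty_direction=self.penalty_direction,
                  ridge_penalty=self.ridge_penalty, weight_floor=self.weight_floor)
        return kw

    def _rebuild(self, t, y, z):
        return GOALDeR(t, y, z, **self._clone_kwargs())

    def select(self):
        """Run only selection + DWDC tuning; returns (best record, all records, path)."""
        tri = self.data
        with _stage("selection-path"):
            path = build_selection_path(
                tri.t, tri.y, tri.z, self.lambda_exponents,
                n_eval=self.cdc_eval_points, bandwidth=self.bandwidth,
                direction=self.penalty_direction,
            )
        with _stage("dwdc-tuning"):
            best, records = select_lambda(
                path, tri.z, tri.y, tri.t,
                ridge_penalty=self.ridge_penalty, weight_floor=self.weight_floor,
            )
        return best, records, path

    def fit(self) -> DRFResults:
        tri = self.data
        best, records, _path = self.select()
        active = best.active
        weights = best.weights
        with _stage("outcome-ensemble"):
            ens = fit_outcome_ensemble(
                tri.z[:, active], tri.t, tri.y,
                learners=self.learners, folds=self.folds, seed=self.seed,
            )
        with _stage("pseudo-outcome"):
            pseudo = build_pseudo_outcome(ens, tri.t, tri.y, tri.z[:, active], weights.w)
        with _stage("drf-regression"):
            ols = regress_drf(pseudo, tri.t, self.degree)
        return DRFResults(self, ols, pseudo, weights, selected=active,
                          dwdc_records=records, outcome_fit=ens, ci_level=self.ci_level)


class SLDR(_BaseModel):
    """Super-learner doubly robust comparator (no covariate selection).

    Pipeline: normal density-ratio GPS weights from an ensemble conditional
    mean of T on all covariates -> stacked outcome regression on all
    covariates -> pseudo-outcome -> dose-response regression.
    """

    method = "SL-DR"

    def _rebuild(self, t, y, z):
        return SLDR(t, y, z, **self._clone_kwargs())

    def fit(self) -> DRFResults:
        tri = self.data
        with _stage("gps-density"):
            gps = fit_gps_normal(tri.z, tri.t, learners=self.learners,
                                 folds=self.folds, seed=self.seed)
            w = gps_ratio_weights(gps, tri.t, tri.z)
        with _stage("outcome-ensemble"):
            ens = fit_outcome_ensemble(tri.z, tri.t, tri.y,
                                       learners=self.learners, folds=self.folds,
                                       seed=self.seed)
        with _stage("pseudo-outcome"):
            pseudo = build_pseudo_outcome(ens, tri.t, tri.y, tri.z, w)
        with _stage("drf-regression"):
            ols = regress_drf(pseudo, tri.t, self.degree)
        return DRFResults(self, ols, pseudo, w, selected=None,
                          outcome_fit=ens, ci_level=self.ci_level)


def _bootstrap_pipeline(model: _BaseModel, *, B: int, seed: int,
                        ci_level: float, max_fail: float) -> BootstrapResult:
    if B < 2:
        raise ValueError("bootstrap needs B >= 2")
    tri = model.data
    rng = np.random.default_rng(seed)
    slopes = []
    failed = 0
    for b in range(B):
        idx = rng.integers(0, tri.n, size=tri.n)
        try:
            res = model._rebuild(tri.t[idx], tri.y[idx], tri.z[idx]).fit()
            slopes.append(res.slope)
        except Exception as exc:  # pragma: no cover - rare replicate failure
            failed += 1
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
    if failed > max_fail * B:
        raise PipelineError(f"[bootstrap] {failed}/{B} replicates failed")
    slopes = np.asarray(slopes)
    sd = float(slopes.std(ddof=1))
    alpha = 1.0 - ci_level
    lo, hi = np.percentile(slopes, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    zq = stats.norm.ppf(1 - alpha / 2)
    center = float(slopes.mean())
    return BootstrapResult(
        boot_sd=sd, ci_percentile=(float(lo), float(hi)),
        ci_normal=(center - zq * sd, center + zq * sd),
        slopes=slopes, n_failed=failed, ci_level=ci_level,
    )


# -- functional entry points ---------------------------------------------------

def estimate_goaldr(t, y, z, **config) -> DRFResults:
    """One-call GOALDeR fit; keyword arguments mirror the model constructor."""
    return GOALDeR(t, y, z, **config).fit()


def estimate_sldr(t, y, z, **config) -> DRFResults:
    """One-call SL-DR fit; keyword arguments mirror the model constructor."""
    return SLDR(t, y, z, **config).fit()


def bootstrap_sd(t, y, z, *, method: str = "goaldr", B: int = 100, seed: int = 0,
                 max_fail: float = 0.1, **config) -> BootstrapResult:
    """Bootstrap the full pipeline on (t, y, z) and return sd and CIs."""
    cls = {"goaldr": GOALDeR, "sldr": SLDR}.get(method.lower())
    if cls is None:
        raise ValueError(f"unknown method {method!r}")
    model = cls(t, y, z, **config)
    return _bootstrap_pipeline(model, B=B, seed=seed,
                               ci_level=model.ci_level, max_fail=max_fail)
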