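"""Outcome-model-free adaptive-lasso selection for the treatment (GPS) model.

The treatment is regressed on the covariates with a weighted L1 penalty

    ||T - a0 - Z a||^2 + lambda_n * sum_j w_hat_j |a_j|,

where the penalty weight w_hat_j = (d_j / max_k d_k)^(-gamma) is built from
d_j = |dcor(Z_j, Y | T)|, the conditional distance correlation between
covariate j and the outcome given the treatment.  Covariates that carry no
outcome information (instruments, noise) receive large -- possibly infinite --
penalties and are pushed out of the model, while confounders and prognostic
covariates survive.  Because d_j is a model-free dependence measure, the
selection never fits an outcome model, which is what preserves double
robustness downstream.

lambda_n is searched over a fixed grid n^a; for each grid point the exponent
gamma is coupled to lambda through  lambda_n * n^(gamma/2 - 1) = n^2, i.e.
gamma = 2 (3 - a), which keeps the pair inside the consistency region
(lambda_n / sqrt(n) -> 0, lambda_n n^(gamma/2 - 1) -> infinity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso

from .distance import conditional_distance_correlation_profile

__all__ = [
    "DEFAULT_LAMBDA_EXPONENTS",
    "PenaltyWeights",
    "LassoFit",
    "SelectionPath",
    "gamma_for_lambda",
    "penalty_from_dcor",
    "compute_penalty_weights",
    "fit_weighted_lasso",
    "build_selection_path",
]

DEFAULT_LAMBDA_EXPONENTS: tuple[float, ...] = (
    -10.0, -5.0, -2.0, -1.25, -1.0, -0.75, -0.5, -0.25, 0.25, 0.49,
)


class NoInformativeCovariateError(ValueError):
    """All conditional distance correlations with the outcome are zero."""


def gamma_for_lambda(exponent: float, n: int) -> float:
    """Exponent-coupling rule: gamma solving lambda_n n^(gamma/2-1) = n^2."""
    if n < 2:
        raise ValueError("n must be at least 2")
    gamma = 2.0 * (3.0 - float(exponent))
    if gamma <= 1.0:
        raise ValueError(f"gamma = {gamma} <= 1 violates the tuning condition")
    return gamma


@dataclass
class PenaltyWeights:
    """Adaptive-lasso penalty weights derived from outcome relevance."""

    w_hat: np.ndarray        # possibly +inf where dcor_raw == 0
    dcor_raw: np.ndarray     # |dcor(Z_j, Y | T)| per covariate
    gamma: float


def penalty_from_dcor(
    dcor_raw: np.ndarray, gamma: float, direction: str = "inverse"
) -> np.ndarray:
    """Map outcome-relevance scores to penalty weights.

    ``inverse`` (default): w_hat_j = (d_j / max d)^(-gamma), so stronger
    outcome relevance means a *smaller* penalty.  ``direct`` reproduces the
    opposite sign convention of the exponent.
    """
    d = np.abs(np.asarray(dcor_raw, dtype=float))
    dmax = d.max() if d.size else 0.0
    if dmax <= 0:
        raise NoInformativeCovariateError("no covariate related to outcome")
    ratio = d / dmax
    if direction == "inverse":
        with np.errstate(divide="ignore"):
            return ratio ** (-float(gamma))
    if direction == "direct":
        return ratio ** float(gamma)
    raise ValueError(f"unknown penalty direction {direction!r}")


def compute_penalty_weights(
    z,
    y,
    t,
    gamma: float,
    *,
    n_eval: int | None = 40,
    bandwidth: float | None = None,
    direction: str = "inverse",
) -> PenaltyWeights:
    """Conditional-distance-correlation penalty weights for the GPS lasso."""
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    d = conditional_distance_correlation_profile(
        z, np.asarray(y, float), np.asarray(t, float), bandwidth=bandwidth, n_eval=n_eval
    )
    return PenaltyWeights(penalty_from_dcor(d, gamma, direction), d, float(gamma))


@dataclass
class LassoFit:
    """A weighted-lasso solution on both the original and standardized scale."""

    coef: np.ndarray          # original covariate scale
    intercept: float
    coef_std: np.ndarray      # standardized-Z scale (penalized problem)
    active: np.ndarray        # indices with nonzero coefficients
    lambda_n: float

    @property
    def active_mask(self) -> np.ndarray:
        p = self.coef.shape[0]
        mask = np.zeros(p, dtype=bool)
        mask[self.active] = True
        return mask


def fit_weighted_lasso(t, z, penalty: PenaltyWeights | np.ndarray, lambda_n: float) -> LassoFit:
    """Solve the weighted-L1 GPS regression by reparameterization.

    Covariates are standardized and the treatment centered before fitting (so
    penalty weights are comparable across covariates); the weighted problem is
    reduced to a plain lasso on Z_tilde_j = Z_j / w_hat_j and mapped back.
    Covariates with infinite penalty (or zero variance) are excluded
    deterministically and reported with a zero coefficient.
    """
    t = np.asarray(t, dtype=float).ravel()
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    n, p = z.shape
    if t.shape[0] != n:
        raise ValueError("t and z must share the sample size")
    if lambda_n < 0:
        raise ValueError("lambda_n must be nonnegative")
    w_hat = penalty.w_hat if isinstance(penalty, PenaltyWeights) else np.asarray(penalty, float)
    if w_hat.shape[0] != p:
        raise ValueError("penalty weight length does not match covariate count")

    mu_z = z.mean(axis=0)
    sd_z = z.std(axis=0)
    t_bar = t.mean()
    tc = t - t_bar
    usable = np.isfinite(w_hat) & (sd_z > 0)

    coef_std = np.zeros(p)
    if usable.any():
        z_std = (z[:, usable] - mu_z[usable]) / sd_z[usable]
        scaled = z_std / w_hat[usable]
        if lambda_n == 0:
            beta, *_ = np.linalg.lstsq(scaled, tc, rcond=None)
        else:
            # sklearn's lasso objective is (1/2n)||r||^2 + alpha ||b||_1
            model = Lasso(
                alpha=lambda_n / (2.0 * n),
                fit_intercept=False,
                tol=1e-7,
                max_iter=100_000,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(scaled, tc)
            beta = model.coef_
        coef_std[usable] = beta / w_hat[usable]

    coef = np.zeros(p)
    coef[usable] = coef_std[usable] / sd_z[usable]
    intercept = float(t_bar - coef @ mu_z)
    active = np.flatnonzero(coef_std != 0.0)
    return LassoFit(coef=coef, intercept=intercept, coef_std=coef_std,
                    active=active, lambda_n=float(lambda_n))


@dataclass
class PathEntry:
    exponent: float
    lambda_n: float
    gamma: float
    fit: LassoFit

    @property
    def active(self) -> np.ndarray:
        return self.fit.active


@dataclass
class SelectionPath:
    """Weighted-lasso fits and active sets across the lambda grid."""

    entries: list[PathEntry]
    dcor_raw: np.ndarray
    n: int
    p: int
    exponents: tuple[float, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            row = {"exponent": e.exponent, "lambda_n": e.lambda_n, "gamma": e.gamma,
                   "active_size": e.active.size}
            row.update({f"sel_{j + 1}": int(j in set(e.active.tolist())) for j in range(self.p)})
            rows.append(row)
        return pd.DataFrame(rows)


def build_selection_path(
    t,
    y,
    z,
    exponents: tuple[float, ...] = DEFAULT_LAMBDA_EXPONENTS,
    *,
    n_eval: int | None = 40,
    bandwidth: float | None = None,
    direction: str = "inverse",
) -> SelectionPath:
    """Fit the weighted lasso at every lambda on the grid.

    The outcome-relevance scores d_j are computed once (they do not depend on
    lambda); only the exponent gamma -- and hence the penalty weights -- varies
    along the grid.
    """
    t = np.asarray(t, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    n, p = z.shape
    d = conditional_distance_correlation_profile(z, y, t, bandwidth=bandwidth, n_eval=n_eval)
    entries = []
    prev_size = None
    for a in sorted(exponents):
        gamma = gamma_for_lambda(a, n)
        w_hat = penalty_from_dcor(d, gamma, direction)
        lam = float(n) ** float(a)
        fit = fit_weighted_lasso(t, z, w_hat, lam)
        if prev_size is not None and fit.active.size > prev_size + p // 2:
            warnings.warn(
                "active-set size increased sharply along the lambda grid",
                RuntimeWarning,
                stacklevel=2,
            )
        prev_size = fit.active.size
        entries.append(PathEntry(exponent=a, lambda_n=lam, gamma=gamma, fit=fit))
    return SelectionPath(entries=entries, dcor_raw=d, n=n, p=p, exponents=tuple(sorted(exponents)))
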