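"""Stacked outcome regression and normal-density GPS weights.

The flexible outcome model mu(Z, T) is a stacking ensemble in the
super-learner style: base learners (L1-penalized linear regression,
gradient-boosted trees, random forest, RBF support-vector regression) are
combined with nonnegative-least-squares weights fitted on K-fold out-of-fold
predictions, then refit on the full sample.  A reduced ``fast`` learner set
(lasso + boosted trees) is provided for simulation studies where the full
four-family ensemble is unnecessarily slow.

For the SL-DR comparator the generalized propensity score is approximated by
a normal density: the conditional mean of T given Z is fitted with the same
ensemble machinery, the residual standard deviation plays the role of the
conditional sd, and the balance weights are the density ratio
f_T(T_i) / f_{T|Z}(T_i | Z_i), rescaled to sum to n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import nnls
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from xgboost import XGBRegressor

from .distance import check_weight_vector

__all__ = [
    "FULL_LEARNERS",
    "FAST_LEARNERS",
    "OutcomeModelFit",
    "GpsDensityFit",
    "fit_outcome_ensemble",
    "predict_outcome",
    "predict_outcome_matrix",
    "fit_gps_normal",
    "gps_ratio_weights",
]

FULL_LEARNERS: tuple[str, ...] = ("lasso", "xgb", "rf", "svr")
FAST_LEARNERS: tuple[str, ...] = ("lasso", "xgb")


def _make_learner(name: str, seed: int):
    if name == "lasso":
        return LassoCV(cv=5, alphas=60, max_iter=20_000, random_state=seed)
    if name == "xgb":
        return XGBRegressor(
            n_estimators=200, max_depth=3, learning_rate=0.1,
            subsample=1.0, colsample_bytree=1.0, tree_method="hist",
            n_jobs=1, random_state=seed, verbosity=0,
        )
    if name == "rf":
        return RandomForestRegressor(n_estimators=200, min_samples_leaf=5,
                                     random_state=seed, n_jobs=1)
    if name == "svr":
        return make_pipeline(StandardScaler(), SVR(C=1.0, epsilon=0.1, gamma="scale"))
    raise ValueError(f"unknown learner {name!r}")


@dataclass
class OutcomeModelFit:
    """Fitted stacking ensemble state."""

    learners: dict = field(default_factory=dict)   # name -> fitted estimator
    stacking_weights: np.ndarray = field(default_factory=lambda: np.array([]))
    learner_names: tuple[str, ...] = ()
    cv_folds: int = 5
    n_features: int = 0
    oof_mse: dict = field(default_factory=dict)
    oof_stacked_mse: float = np.nan


def _design(z, t):
    t = np.asarray(t, dtype=float).ravel()
    if z is None or np.size(z) == 0:
        return t[:, None]
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    return np.column_stack([z, t])


def fit_outcome_ensemble(
    z_active,
    t,
    y,
    *,
    learners: tuple[str, ...] = FULL_LEARNERS,
    folds: int = 5,
    seed: int = 0,
) -> OutcomeModelFit:
    """Fit the stacked outcome regression mu(Z_active, T) ~ Y."""
    y = np.asarray(y, dtype=float).ravel()
    X = _design(z_active, t)
    n = X.shape[0]
    if n < 20:
        raise ValueError("outcome ensemble needs n >= 20")
    if n < 2 * folds:
        raise ValueError(f"n = {n} too small for {folds}-fold stacking")
    if not learners:
        raise ValueError("at least one learner required")

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.zeros((n, len(learners)))
    for k, name in enumerate(learners):
        for tr, te in kf.split(X):
            est = _make_learner(name, seed)
            est.fit(X[tr], y[tr])
            oof[te, k] = est.predict(X[te])

    weights, _ = nnls(oof, y)
    if weights.sum() <= 0:
        # degenerate stacking; fall back to the best single learner
        mse = ((oof - y[:, None]) ** 2).mean(axis=0)
        weights = np.zeros(len(learners))
        weights[int(np.argmin(mse))] = 1.0
    weights = weights / weights.sum()

    fitted = {}
    for name in learners:
        est = _make_learner(name, seed)
        est.fit(X, y)
        fitted[name] = est
    oof_mse = {name: float(((oof[:, k] - y) ** 2).mean()) for k, name in enumerate(learners)}
    oof_stacked_mse = float(((oof @ weights - y) ** 2).mean())
    return OutcomeModelFit(
        learners=fitted, stacking_weights=weights, learner_names=tuple(learners),
        cv_folds=folds, n_features=X.shape[1], oof_mse=oof_mse,
        oof_stacked_mse=oof_stacked_mse,
    )


def _predict_design(fit: OutcomeModelFit, X: np.ndarray) -> np.ndarray:
    preds = np.zeros(X.shape[0])
    for wgt, name in zip(fit.stacking_weights, fit.learner_names):
        if wgt > 0:
            preds += wgt * fit.learners[name].predict(X)
    return preds


def predict_outcome(fit: OutcomeModelFit, z_rows, t) -> np.ndarray:
    """Pointwise predictions mu(z_i, t_i); scalar t is broadcast."""
    z = None if z_rows is None or np.size(z_rows) == 0 else np.asarray(z_rows, float)
    n_rows = (z.shape[0] if z is not None and z.ndim > 0 else None)
    t = np.asarray(t, dtype=float)
    if t.ndim == 0:
        if n_rows is None:
            raise ValueError("scalar t needs covariate rows to broadcast over")
        t = np.full(n_rows, float(t))
    X = _design(z, t)
    if X.shape[1] != fit.n_features:
        raise ValueError(f"expected {fit.n_features} features, got {X.shape[1]}")
    return _predict_design(fit, X)


def predict_outcome_matrix(fit: OutcomeModelFit, z_rows, t_values) -> np.ndarray:
    """Cross-prediction matrix M[k, i] = mu(z_k, t_i) of shape (n_rows, n_t)."""
    t_values = np.asarray(t_values, dtype=float).ravel()
    m = t_values.shape[0]
    if z_rows is None or np.size(z_rows) == 0:
        flat = predict_outcome(fit, None, t_values)
        return np.tile(flat, (1, 1)) if m == 0 else np.broadcast_to(flat, (1, m)).copy()
    z = np.asarray(z_rows, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    n_rows = z.shape[0]
    big_z = np.repeat(z, m, axis=0)
    big_t = np.tile(t_values, n_rows)
    flat = predict_outcome(fit, big_z, big_t)
    return flat.reshape(n_rows, m)


@dataclass
class GpsDensityFit:
    """Normal approximation of marginal and conditional treatment densities."""

    marginal_mean: float
    marginal_sd: float
    mean_model: OutcomeModelFit
    sigma: float


def fit_gps_normal(
    z,
    t,
    *,
    learners: tuple[str, ...] = FULL_LEARNERS,
    folds: int = 5,
    seed: int = 0,
) -> GpsDensityFit:
    """Fit Normal(m(Z), sigma) for T | Z with an ensemble conditional mean."""
    t = np.asarray(t, dtype=float).ravel()
    sd_t = float(t.std())  # ddof=0, matching the conditional residual sd below
    if sd_t <= 0:
        raise ValueError("treatment is constant")
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    if z.shape[1] == 0:
        raise ValueError("GPS model needs at least one covariate")
    # regress T on Z by routing the last covariate column through the
    # ensemble's treatment slot: the design matrix is then exactly Z
    mean_model = fit_outcome_ensemble(
        z[:, :-1], z[:, -1], t, learners=learners, folds=folds, seed=seed
    )
    m_hat = predict_outcome(mean_model, z[:, :-1], z[:, -1])
    sigma = float(np.sqrt(np.mean((t - m_hat) ** 2)))
    if sigma <= 1e-12:
        raise ValueError("degenerate conditional treatment density (sigma = 0)")
    return GpsDensityFit(
        marginal_mean=float(t.mean()), marginal_sd=sd_t,
        mean_model=mean_model, sigma=sigma,
    )


def gps_ratio_weights(fit: GpsDensityFit, t, z) -> np.ndarray:
    """Density-ratio weights f_T(T_i) / f_{T|Z}(T_i|Z_i), rescaled to sum n."""
    t = np.asarray(t, dtype=float).ravel()
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    m_hat = predict_outcome(fit.mean_model, z[:, :-1], z[:, -1])
    num = stats.norm.pdf(t, loc=fit.marginal_mean, scale=fit.marginal_sd)
    den = stats.norm.pdf(t, loc=m_hat, scale=fit.sigma)
    w = num / np.maximum(den, 1e-300)
    w *= t.shape[0] / w.sum()
    return check_weight_vector(w, t.shape[0])
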