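"""Distance-covariance optimal weights (DCOW) for continuous-treatment balance.

Given a treatment vector T and the currently selected covariate block Z_sub,
the DCOW problem finds per-subject weights w that minimize the weighted
squared distance covariance between T and Z_sub,

    (1/n^2) sum_ij w_i w_j A_ij B_ij  +  (ridge/n) sum_i (w_i - 1)^2,

subject to: w_i >= weight_floor, sum_i w_i = n, and preservation of the
weighted first moments of T and of every column of Z_sub.  A and B are the
double-centered Euclidean distance matrices of Z_sub and T, so the quadratic
form is convex (see :mod:`goalder.distance`), and the ridge term keeps the
weights from drifting far from uniform.  Decorrelating the *distances* rather
than fixed cross-moments removes dependence of any order, which is why no
moment-order choice is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from . import _qp
from .distance import (
    check_weight_vector,
    distance_correlation,
    double_center,
    pairwise_distances,
    weighted_distance_correlation,
)

__all__ = ["DcowProblem", "BalanceWeights", "solve_dcow", "dcow_objective", "balance_report"]


@dataclass
class DcowProblem:
    """A DCOW instance: treatment, selected covariates and regularization."""

    t: np.ndarray
    z_sub: np.ndarray
    ridge_penalty: float = 0.1
    weight_floor: float = 0.0

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float).ravel()
        z = np.asarray(self.z_sub, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
        if z.size == 0:
            z = z.reshape(self.t.shape[0], 0)
        self.z_sub = z
        if self.z_sub.shape[0] != self.t.shape[0]:
            raise ValueError("t and z_sub must share the sample size")
        if not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.z_sub)):
            raise ValueError("non-finite values in DCOW inputs")
        if self.ridge_penalty < 0 or self.weight_floor < 0:
            raise ValueError("ridge_penalty and weight_floor must be nonnegative")

    @property
    def n(self) -> int:
        return self.t.shape[0]

    @property
    def q(self) -> int:
        return self.z_sub.shape[1]


@dataclass
class BalanceWeights:
    """Estimated balance weights plus the covariate set that produced them."""

    w: np.ndarray
    selected: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    objective: float = np.nan
    objective_uniform: float = np.nan

    def __post_init__(self):
        self.w = check_weight_vector(self.w)
        self.selected = np.asarray(self.selected, dtype=int)

    @property
    def n(self) -> int:
        return self.w.shape[0]


def dcow_objective(problem: DcowProblem, w: np.ndarray) -> float:
    """Evaluate the DCOW objective (weighted dcov^2 + ridge dispersion)."""
    n = problem.n
    a = double_center(pairwise_distances(problem.z_sub))
    b = double_center(pairwise_distances(problem.t))
    quad = float(w @ (a * b) @ w) / (n * n)
    ridge = problem.ridge_penalty / n * float(np.sum((w - 1.0) ** 2))
    return quad + ridge


def _independent_rows(C: np.ndarray, b: np.ndarray, rtol: float = 1e-10):
    """Drop linearly dependent constraint rows via pivoted QR."""
    if C.shape[0] <= 1:
        return C, b
    _, r, piv = linalg.qr(C.T, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    keep = piv[diag > rtol * max(diag.max(), 1.0)]
    keep.sort()
    return C[keep], b[keep]


def solve_dcow(problem: DcowProblem, *, selected: np.ndarray | None = None) -> BalanceWeights:
    """Solve the DCOW quadratic program.

    With an empty covariate selection the uniform weights (all ones) are
    returned without solving: there is nothing to balance and uniform weights
    satisfy every constraint.  Otherwise the exact KKT/active-set solution is
    computed; because uniform weights are feasible, the objective at the
    solution can never exceed the objective at uniform weights.
    """
    n = problem.n
    if n < 10:
        raise ValueError("DCOW needs n >= 10")
    sel = np.arange(problem.q) if selected is None else np.asarray(selected, dtype=int)
    ones = np.ones(n)
    if problem.q == 0:
        return BalanceWeights(ones, selected=sel)

    a = double_center(pairwise_distances(problem.z_sub))
    b = double_center(pairwise_distances(problem.t))
    n2 = float(n * n)
    quad = (a * b) / n2
    ridge = problem.ridge_penalty / n
    P = quad + quad.T + 2.0 * ridge * np.eye(n)  # 0.5 x'Px == w'Qw + ridge w'w
    qvec = -2.0 * ridge * ones

    # sum-to-n plus first-moment preservation of T and each selected column
    cols = [ones, problem.t] + [problem.z_sub[:, j] for j in range(problem.q)]
    C = np.array([c / max(np.abs(c).max(), 1.0) for c in cols])
    bvec = C @ ones  # uniform weights satisfy every constraint exactly
    C, bvec = _independent_rows(C, bvec)

    w = _qp.solve_qp(P, qvec, C, bvec, np.full(n, problem.weight_floor))
    # tidy numerical noise so WeightVector invariants hold exactly
    w = np.maximum(w, problem.weight_floor)
    w *= n / w.sum()

    obj = dcow_objective(problem, w)
    obj_uniform = dcow_objective(problem, ones)
    if obj > obj_uniform + 1e-9:
        # exact solver should never land here; keep the guarantee regardless
        w, obj = ones, obj_uniform
    return BalanceWeights(w, selected=sel, objective=obj, objective_uniform=obj_uniform)


def balance_report(t, z, w) -> pd.DataFrame:
    """Per-covariate unweighted and weighted distance correlation with T."""
    t = np.asarray(t, dtype=float).ravel()
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    w = check_weight_vector(w, t.shape[0])
    rows = []
    for j in range(z.shape[1]):
        rows.append(
            {
                "covariate": j,
                "dcor_unweighted": distance_correlation(z[:, j], t),
                "dcor_weighted": weighted_distance_correlation(z[:, j], t, w),
            }
        )
    return pd.DataFrame(rows)
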