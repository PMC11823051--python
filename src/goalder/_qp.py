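"""Deterministic dense QP solver for equality constraints plus lower bounds.

Solves  min_x  0.5 x'Px + q'x   s.t.  Cx = b,  x >= lb
by a primal active-set method on the bound constraints: each iteration solves
the KKT system of the equality-constrained subproblem with the currently
pinned bounds, pins newly violated bounds, and releases pinned bounds whose
Lagrange multiplier has the wrong sign.  P must be positive semidefinite
(positive definite on the nullspace of C); the problems built by
:mod:`goalder.balance` always add a ridge term that guarantees this.

There is no randomness; given the same inputs the solution is bit-identical.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

__all__ = ["QPError", "solve_qp"]


class QPError(RuntimeError):
    """Raised when the active-set iteration fails to converge."""


def _kkt_solve(P, q, C, b, pinned, lb):
    """Solve the equality-constrained KKT system with pinned bounds."""
    n = P.shape[0]
    pin_idx = np.flatnonzero(pinned)
    k_eq = C.shape[0]
    m = k_eq + pin_idx.size
    kkt = np.zeros((n + m, n + m))
    kkt[:n, :n] = P
    kkt[:n, n : n + k_eq] = C.T
    kkt[n : n + k_eq, :n] = C
    for r, i in enumerate(pin_idx):
        kkt[i, n + k_eq + r] = 1.0
        kkt[n + k_eq + r, i] = 1.0
    rhs = np.concatenate([-q, b, lb[pin_idx]])
    try:
        sol = linalg.solve(kkt, rhs, assume_a="sym")
    except linalg.LinAlgError:
        sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
    x = sol[:n]
    nu = sol[n : n + k_eq]
    tau = sol[n + k_eq :]  # multipliers of pinned bounds (release if > 0)
    return x, nu, tau, pin_idx


def solve_qp(
    P: np.ndarray,
    q: np.ndarray,
    C: np.ndarray,
    b: np.ndarray,
    lb: np.ndarray,
    *,
    max_iter: int = 200,
    tol: float = 1e-9,
) -> np.ndarray:
    """Minimize 0.5 x'Px + q'x subject to Cx = b and x >= lb."""
    P = np.asarray(P, dtype=float)
    q = np.asarray(q, dtype=float).ravel()
    C = np.atleast_2d(np.asarray(C, dtype=float))
    b = np.asarray(b, dtype=float).ravel()
    n = q.shape[0]
    lb = np.broadcast_to(np.asarray(lb, dtype=float), (n,)).copy()

    pinned = np.zeros(n, dtype=bool)
    for _ in range(max_iter):
        x, _nu, tau, pin_idx = _kkt_solve(P, q, C, b, pinned, lb)
        viol = (x < lb - tol) & ~pinned
        if viol.any():
            pinned |= viol
            continue
        if pin_idx.size:
            worst = np.argmax(tau)
            if tau[worst] > tol:
                pinned[pin_idx[worst]] = False
                continue
        return np.maximum(x, lb)
    raise QPError(f"active-set iteration did not converge in {max_iter} steps")
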