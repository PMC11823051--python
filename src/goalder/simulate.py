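"""Synthetic data generator and Monte-Carlo evaluation harness.

Data-generating process
-----------------------
Covariates are equicorrelated standard Gaussians, Z ~ N(0, Sigma) with unit
variances and off-diagonal correlation rho, sampled through the one-factor
construction sqrt(rho) * common + sqrt(1 - rho) * idiosyncratic.  Treatment
and outcome follow

    T = m(Z) + N(0, 1),        Y = eta * T + g(Z) + N(0, 1),

with (m, g) chosen by the scenario setting:

Scenario 1 (both models linear).  Z1, Z2 are confounders, Z3, Z4 prognostic,
Z5, Z6 instruments, the rest spurious:

* SoSt: m = Z1 + Z2 + Z5 + Z6,            g = Z1 + Z2 + Z3 + Z4
* SoWt: m = 0.5 Z1 + 0.5 Z2 + Z5 + Z6,    g = Z1 + Z2 + Z3 + Z4
* WoSt: m = Z1 + Z2 + Z5 + Z6,            g = 0.5 Z1 + 0.5 Z2 + Z3 + Z4

Scenario 2 (misspecification through a shared nonlinear block)

    NL(Z) = exp(Z1/2) + [Z2 / (1 + exp(Z1)) + 10]
            + (0.04 Z1 Z3 + 0.6)^3 + (Z2 + Z4)^2

* CoMt: m = NL(Z) + Z7 + Z8 (nonlinear GPS), g = Z1 + ... + Z6 (linear)
* MoCt: m = Z1 + Z2 + Z3 + Z4 + Z7 + Z8,     g = NL(Z) + Z5 + Z6
* MoMt: m = NL(Z) + Z7 + Z8,                 g = NL(Z) + Z5 + Z6

The harness runs a method over replicated datasets (seed = base seed +
replicate index, so cells are reproducible) and reports the summary
statistics used throughout the simulation study: mean estimate, empirical SD,
mean analytic SE, mean bootstrap SE, 95% CI coverage, Wald power at the 5%
level, and RMSE = sqrt(mean (eta_hat - eta)^2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .data import TriSample
from .estimator import GOALDeR, SLDR

__all__ = [
    "SCENARIO1_SETTINGS",
    "SCENARIO2_SETTINGS",
    "ScenarioSpec",
    "ReplicationResult",
    "generate_dataset",
    "covariate_roles",
    "run_cell",
    "run_selection_cell",
    "selection_proportions",
    "group_selection_rates",
]

logger = logging.getLogger(__name__)

SCENARIO1_SETTINGS = ("SoSt", "SoWt", "WoSt")
SCENARIO2_SETTINGS = ("CoMt", "MoCt", "MoMt")


@dataclass
class ScenarioSpec:
    """One simulation cell: setting, sample size, dimension, rho, eta, seed."""

    setting: str
    n: int
    p: int
    rho: float = 0.0
    eta: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.setting not in SCENARIO1_SETTINGS + SCENARIO2_SETTINGS:
            raise ValueError(f"unknown setting {self.setting!r}")
        min_p = 6 if self.scenario == 1 else 8
        if self.p < min_p:
            raise ValueError(f"scenario {self.scenario} requires p >= {min_p}")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        if self.n < 2:
            raise ValueError("n must be >= 2")

    @property
    def scenario(self) -> int:
        return 1 if self.setting in SCENARIO1_SETTINGS else 2


def _nl_block(z: np.ndarray) -> np.ndarray:
    z1, z2, z3, z4 = z[:, 0], z[:, 1], z[:, 2], z[:, 3]
    return (
        np.exp(z1 / 2.0)
        + (z2 / (1.0 + np.exp(z1)) + 10.0)
        + (0.04 * z1 * z3 + 0.6) ** 3
        + (z2 + z4) ** 2
    )


def _mean_functions(setting: str):
    lin = {
        "SoSt": ([1, 1, 0, 0, 1, 1], [1, 1, 1, 1, 0, 0]),
        "SoWt": ([0.5, 0.5, 0, 0, 1, 1], [1, 1, 1, 1, 0, 0]),
        "WoSt": ([1, 1, 0, 0, 1, 1], [0.5, 0.5, 1, 1, 0, 0]),
    }
    if setting in lin:
        a, b = lin[setting]

        def m(z, a=np.asarray(a, float)):
            return z[:, : a.size] @ a

        def g(z, b=np.asarray(b, float)):
            return z[:, : b.size] @ b

        return m, g
    if setting == "CoMt":
        return (lambda z: _nl_block(z) + z[:, 6] + z[:, 7],
                lambda z: z[:, :6].sum(axis=1))
    if setting == "MoCt":
        return (lambda z: z[:, :4].sum(axis=1) + z[:, 6] + z[:, 7],
                lambda z: _nl_block(z) + z[:, 4] + z[:, 5])
    if setting == "MoMt":
        return (lambda z: _nl_block(z) + z[:, 6] + z[:, 7],
                lambda z: _nl_block(z) + z[:, 4] + z[:, 5])
    raise ValueError(f"unknown setting {setting!r}")


def generate_dataset(spec: ScenarioSpec) -> TriSample:
    """Draw one dataset; the same spec (including seed) is bit-reproducible."""
    rng = np.random.default_rng(spec.seed)
    common = rng.standard_normal(spec.n)
    idio = rng.standard_normal((spec.n, spec.p))
    z = np.sqrt(spec.rho) * common[:, None] + np.sqrt(1.0 - spec.rho) * idio
    m, g = _mean_functions(spec.setting)
    t = m(z) + rng.standard_normal(spec.n)
    y = spec.eta * t + g(z) + rng.standard_normal(spec.n)
    return TriSample(t, y, z)


def covariate_roles(setting: str, p: int) -> dict[str, np.ndarray]:
    """0-based index groups: confounders, prognostic, instruments, spurious."""
    if setting in SCENARIO1_SETTINGS:
        groups = {"confounder": [0, 1], "prognostic": [2, 3], "instrument": [4, 5]}
        used = 6
    else:
        groups = {"confounder": [0, 1, 2, 3], "prognostic": [4, 5], "instrument": [6, 7]}
        used = 8
    groups["spurious"] = list(range(used, p))
    return {k: np.asarray(v, dtype=int) for k, v in groups.items()}


@dataclass
class ReplicationResult:
    """Per-replicate records and cell-level summary statistics."""

    spec: ScenarioSpec
    method: str
    estimates: np.ndarray
    analytic_sds: np.ndarray
    boot_sds: np.ndarray | None = None
    selection: np.ndarray | None = None   # (replicates, p) 0/1 indicators
    failures: list = field(default_factory=list)
    ci_level: float = 0.95

    @property
    def replicates(self) -> int:
        return self.estimates.shape[0]

    def _coverage_power(self, sds: np.ndarray) -> tuple[float, float]:
        zq = stats.norm.ppf(1.0 - (1.0 - self.ci_level) / 2.0)
        lo = self.estimates - zq * sds
        hi = self.estimates + zq * sds
        coverage = float(np.mean((lo <= self.spec.eta) & (self.spec.eta <= hi)))
        power = float(np.mean((lo > 0.0) | (hi < 0.0)))
        return coverage, power

    def summary(self) -> pd.Series:
        est = self.estimates
        eta = self.spec.eta
        out = {
            "Est": float(est.mean()),
            "Est_Std": float(self.analytic_sds.mean()),
            "emp_std": float(est.std(ddof=1)) if est.size > 1 else 0.0,
            "RMSE": float(np.sqrt(np.mean((est - eta) ** 2))),
        }
        out["coverage"], out["power"] = self._coverage_power(self.analytic_sds)
        if self.boot_sds is not None:
            out["Boot_Std"] = float(self.boot_sds.mean())
            out["Boot_coverage"], out["Boot_power"] = self._coverage_power(self.boot_sds)
        return pd.Series(out)

    def to_frame(self) -> pd.DataFrame:
        data = {"replicate": np.arange(self.replicates),
                "estimate": self.estimates, "analytic_sd": self.analytic_sds}
        if self.boot_sds is not None:
            data["boot_sd"] = self.boot_sds
        df = pd.DataFrame(data)
        if self.selection is not None:
            for j in range(self.selection.shape[1]):
                df[f"sel_Z{j + 1}"] = self.selection[:, j]
        return df


def _fit_replicate(method, tri: TriSample, seed: int, model_kwargs: dict):
    """Dispatch one replicate fit; `method` may be a name or a callable stub."""
    if callable(method):
        out = method(tri, seed)
        if isinstance(out, tuple):
            est, se = out
            return float(est), float(se), None, None
        return float(out.slope), float(out.analytic_sd), None, None
    cls = {"goaldr": GOALDeR, "sldr": SLDR}[method.lower()]
    res = cls(tri.t, tri.y, tri.z, seed=seed, **model_kwargs).fit()
    sel = None
    if res.selected is not None:
        sel = np.zeros(tri.p, dtype=int)
        sel[res.selected] = 1
    return res.slope, res.analytic_sd, sel, res


def run_cell(
    spec: ScenarioSpec,
    method="goaldr",
    replicates: int = 100,
    *,
    boot: bool = False,
    boot_B: int = 100,
    model_kwargs: dict | None = None,
    max_fail: float = 0.1,
) -> ReplicationResult:
    """Run one simulation cell: fresh dataset + fit per replicate."""
    if replicates < 2:
        raise ValueError("replicates must be >= 2")
    model_kwargs = dict(model_kwargs or {})
    estimates, sds, boots, sels, failures = [], [], [], [], []
    method_name = method if isinstance(method, str) else getattr(method, "__name__", "stub")
    for r in range(replicates):
        rep_spec = replace(spec, seed=spec.seed + r)
        tri = generate_dataset(rep_spec)
        try:
            est, se, sel, res = _fit_replicate(method, tri, rep_spec.seed, model_kwargs)
        except Exception as exc:
            failures.append((r, str(exc)))
            logger.warning("replicate %d failed: %s", r, exc)
            continue
        estimates.append(est)
        sds.append(se)
        sels.append(sel)
        if boot and res is not None:
            boots.append(res.bootstrap(B=boot_B, seed=rep_spec.seed).boot_sd)
    if len(failures) > max_fail * replicates:
        raise RuntimeError(f"{len(failures)}/{replicates} replicates failed")
    selection = None
    if sels and all(s is not None for s in sels):
        selection = np.vstack(sels)
    return ReplicationResult(
        spec=spec, method=method_name,
        estimates=np.asarray(estimates), analytic_sds=np.asarray(sds),
        boot_sds=np.asarray(boots) if boots else None,
        selection=selection, failures=failures,
    )


def run_selection_cell(
    spec: ScenarioSpec,
    replicates: int = 100,
    *,
    model_kwargs: dict | None = None,
) -> ReplicationResult:
    """Selection + DWDC tuning only (no outcome ensemble, no estimates).

    Used for covariate-selection frequency studies, where the dose-response
    stage is irrelevant and would dominate the run time.
    """
    model_kwargs = dict(model_kwargs or {})
    sels = []
    for r in range(replicates):
        rep_spec = replace(spec, seed=spec.seed + r)
        tri = generate_dataset(rep_spec)
        model = GOALDeR(tri.t, tri.y, tri.z, seed=rep_spec.seed, **model_kwargs)
        best, _records, _path = model.select()
        ind = np.zeros(tri.p, dtype=int)
        ind[best.active] = 1
        sels.append(ind)
    sel = np.vstack(sels)
    nan = np.full(replicates, np.nan)
    return ReplicationResult(spec=spec, method="goaldr-selection",
                             estimates=nan, analytic_sds=nan, selection=sel)


def selection_proportions(result: ReplicationResult) -> pd.DataFrame:
    """Per-covariate selection frequency with covariate-role grouping."""
    if result.selection is None:
        raise ValueError("result carries no selection indicators")
    freq = result.selection.mean(axis=0)
    roles = covariate_roles(result.spec.setting, result.spec.p)
    role_of = np.empty(result.spec.p, dtype=object)
    for name, idx in roles.items():
        role_of[idx] = name
    return pd.DataFrame(
        {"covariate": [f"Z{j + 1}" for j in range(freq.size)],
         "frequency": freq, "role": role_of}
    )


def group_selection_rates(result: ReplicationResult) -> pd.Series:
    """Mean selection frequency per covariate role."""
    table = selection_proportions(result)
    return table.groupby("role")["frequency"].mean()
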