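"""Shared fixtures: small deterministic datasets and loop-based oracles."""

import numpy as np
import pytest

from goalder.simulate import ScenarioSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def sost_small():
    """One modest SoSt dataset reused by pipeline-level tests."""
    return generate_dataset(ScenarioSpec("SoSt", n=300, p=10, rho=0.0, eta=2.0, seed=7))


# ---------------------------------------------------------------------------
# Independent brute-force oracles (explicit loops; no shared code paths with
# goalder.distance beyond numpy primitives).
# ---------------------------------------------------------------------------

def loop_distance_matrix(x):
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d[i, j] = np.sqrt(np.sum((x[i] - x[j]) ** 2))
    return d


def loop_double_center(d):
    n = d.shape[0]
    out = np.zeros_like(d)
    grand = d.mean()
    for i in range(n):
        for j in range(n):
            out[i, j] = d[i, j] - d[i, :].mean() - d[:, j].mean() + grand
    return out


def loop_dcor(x, y):
    a = loop_double_center(loop_distance_matrix(x))
    b = loop_double_center(loop_distance_matrix(y))
    dcov2 = (a * b).mean()
    dvx = (a * a).mean()
    dvy = (b * b).mean()
    if dvx <= 0 or dvy <= 0:
        return 0.0
    return np.sqrt(max(dcov2 / np.sqrt(dvx * dvy), 0.0))


def loop_weighted_dcov_sq(x, y, w):
    a = loop_double_center(loop_distance_matrix(x))
    b = loop_double_center(loop_distance_matrix(y))
    n = len(w)
    total = 0.0
    for i in range(n):
        for j in range(n):
            total += w[i] * w[j] * a[i, j] * b[i, j]
    return total / n**2


def loop_weighted_dcor(x, y, w):
    num = loop_weighted_dcov_sq(x, y, w)
    dvx = loop_weighted_dcov_sq(x, x, w)
    dvy = loop_weighted_dcov_sq(y, y, w)
    if dvx <= 1e-14 or dvy <= 1e-14:
        return 0.0
    return np.sqrt(min(max(num / np.sqrt(dvx * dvy), 0.0), 1.0))


def random_weight_vector(rng, n):
    w = rng.random(n) + 0.1
    return w * n / w.sum()
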