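import itertools

import numpy as np
import pytest

from merlot.manifold import ManifoldCoords


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def nmi_oracle(a, b):
    """Direct contingency-table NMI with natural-log entropies."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    av, ai = np.unique(a, return_inverse=True)
    bv, bi = np.unique(b, return_inverse=True)
    T = np.zeros((len(av), len(bv)))
    np.add.at(T, (ai, bi), 1)
    P = T / n
    pa, pb = P.sum(1), P.sum(0)
    mi = sum(
        P[i, j] * np.log(P[i, j] / (pa[i] * pb[j]))
        for i in range(len(av))
        for j in range(len(bv))
        if P[i, j] > 0
    )
    ha = -sum(p * np.log(p) for p in pa if p > 0)
    hb = -sum(p * np.log(p) for p in pb if p > 0)
    if ha == 0 or hb == 0:
        return 1.0 if (ha == hb == 0 and np.array_equal(ai, bi)) else 0.0
    return mi / np.sqrt(ha * hb)


def gamma_oracle(x, y):
    """Exhaustive concordant/discordant pair enumeration."""
    C = D = 0
    for (x1, y1), (x2, y2) in itertools.combinations(zip(x, y), 2):
        if x1 == x2 or y1 == y2:
            continue
        if (x1 < x2) == (y1 < y2):
            C += 1
        else:
            D += 1
    return (C - D) / (C + D)


def make_arm(direction, n, length=1.0, noise=0.02, rng=None, origin=None, start=0.0):
    """Points along a straight arm from origin with Gaussian jitter."""
    rng = rng or np.random.default_rng(0)
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    origin = np.zeros(direction.size) if origin is None else np.asarray(origin, float)
    t = np.linspace(start, length, n)
    pts = origin[None, :] + t[:, None] * direction[None, :]
    return pts + rng.normal(0, noise, pts.shape)


@pytest.fixture
def y_cloud(rng):
    """Three noisy arms of 60 cells meeting near the origin, plus arm labels.

    Arms start slightly off-center so every cell's true arm is unambiguous.
    """
    arms = [(1.0, 0.0), (-0.6, 0.8), (-0.6, -0.8)]
    pts = np.vstack([make_arm(d, 60, rng=rng, start=0.06) for d in arms])
    labels = np.repeat([0, 1, 2], 60)
    return ManifoldCoords(pts), labels


@pytest.fixture
def h_cloud(rng):
    """Four-endpoint (H-shaped) cloud: two branchpoints joined by a bar."""
    left, right = np.array([-1.0, 0.0]), np.array([1.0, 0.0])
    parts = [
        make_arm((-0.7, 0.9), 50, rng=rng, origin=left),
        make_arm((-0.7, -0.9), 50, rng=rng, origin=left),
        make_arm((0.7, 0.9), 50, rng=rng, origin=right),
        make_arm((0.7, -0.9), 50, rng=rng, origin=right),
        make_arm((1.0, 0.0), 60, length=2.0, rng=rng, origin=left),
    ]
    return ManifoldCoords(np.vstack(parts))
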