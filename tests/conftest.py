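"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import optimize

from resilnet import (
    TrueNetworkSpec,
    build_true_precision,
    partials_from_precision,
)


# ---------------------------------------------------------------------------
# independent oracle: brute-force Gaussian MLE under precision zero constraints
# ---------------------------------------------------------------------------

def brute_force_constrained_mle(S: np.ndarray, zero_pattern) -> np.ndarray:
    """Numerically maximize the Gaussian likelihood over precision matrices
    with the given zero pattern; returns the implied covariance.

    Parametrizes the free precision entries directly (log-diagonal for
    positivity) and minimizes ``-log|K| + tr(SK)`` with analytic
    gradients. Deliberately independent of the coordinate-regression
    path used by the package.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    zp = {(min(i, j), max(i, j)) for (i, j) in zero_pattern}
    free_pairs = [(i, j) for i in range(p) for j in range(i + 1, p) if (i, j) not in zp]

    def unpack(theta):
        K = np.zeros((p, p))
        K[np.diag_indices(p)] = np.exp(theta[:p])
        for k, (i, j) in enumerate(free_pairs):
            K[i, j] = K[j, i] = theta[p + k]
        return K

    def fun(theta):
        K = unpack(theta)
        try:
            L = np.linalg.cholesky(K)
        except np.linalg.LinAlgError:
            return 1e10, np.zeros_like(theta)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        f = -logdet + float(np.sum(S * K))
        G = S - np.linalg.inv(K)  # gradient of f wrt K
        grad = np.empty_like(theta)
        grad[:p] = np.diag(G) * np.exp(theta[:p])
        for k, (i, j) in enumerate(free_pairs):
            grad[p + k] = 2.0 * G[i, j]
        return f, grad

    theta0 = np.zeros(p + len(free_pairs))
    res = optimize.minimize(
        fun, theta0, jac=True, method="L-BFGS-B",
        options={"maxiter": 10000, "ftol": 1e-15, "gtol": 1e-12},
    )
    K = unpack(res.x)
    return np.linalg.inv(K)


def random_correlation(p: int, seed: int, n: int = 60) -> np.ndarray:
    """A well-conditioned random correlation matrix (from seeded data)."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p)) + 0.4 * rng.standard_normal((n, 1))
    return np.corrcoef(X.T)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_spec() -> TrueNetworkSpec:
    """A small two-community network used by several calibration tests."""
    return TrueNetworkSpec(
        n_items_a=3, n_items_b=5, within_density=0.4,
        bridge_count=3, negative_bridge_count=1,
        weight_range=(0.15, 0.3), seed=11,
    )


@pytest.fixture(scope="session")
def study_spec() -> TrueNetworkSpec:
    """The default-sized 27-node two-community network."""
    return TrueNetworkSpec(seed=3)


def true_edge_set(K: np.ndarray) -> set[tuple[int, int]]:
    W = partials_from_precision(K)
    p = W.shape[0]
    return {(i, j) for i in range(p) for j in range(i + 1, p) if abs(W[i, j]) > 1e-9}


def perturbed_precision_pair(
    n_diff: int = 10, delta: float = 0.2, seed: int = 0,
    n_items_a: int = 7, n_items_b: int = 7,
):
    """Two standardized precision matrices differing in ``n_diff`` edges by ``delta``.

    The second network gains ``n_diff`` extra edges of partial
    correlation ``delta`` on pairs absent from the first. Returns
    ``(K1, K2, planted_pairs)``.
    """
    spec = TrueNetworkSpec(
        n_items_a=n_items_a, n_items_b=n_items_b, within_density=0.2,
        bridge_count=4, negative_bridge_count=1, weight_range=(0.15, 0.3), seed=seed,
    )
    K1 = build_true_precision(spec)
    p = K1.shape[0]
    rng = np.random.default_rng(seed + 1000)
    absent = [(i, j) for i in range(p) for j in range(i + 1, p) if K1[i, j] == 0.0]
    idx = rng.choice(len(absent), size=n_diff, replace=False)
    planted = [absent[k] for k in sorted(idx)]
    K2 = K1.copy()
    for (i, j) in planted:
        K2[i, j] = K2[j, i] = -delta
    if np.linalg.eigvalsh(K2).min() <= 1e-6:
        raise RuntimeError("perturbed precision not PD; choose a different seed")
    sigma = np.linalg.inv(K2)
    d = 1.0 / np.sqrt(np.diag(sigma))
    K2 = np.linalg.inv((sigma * d).T * d)
    K2 = 0.5 * (K2 + K2.T)
    support = K1 != 0
    for (i, j) in planted:
        support[i, j] = support[j, i] = True
    K2[~support & ~np.eye(p, dtype=bool)] = 0.0
    return K1, K2, planted
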