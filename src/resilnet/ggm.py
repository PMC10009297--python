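"""Sparse Gaussian graphical model estimation by recursive significance pruning.

The estimator starts from the saturated partial-correlation network
(standardized negative inverse of the correlation matrix), removes all
edges that are not significant at a given alpha (two-sided Fisher-z
test), refits the model under the implied zero constraints by
covariance selection (maximum likelihood with an exact zero pattern in
the precision matrix), and retests the surviving edges on the refitted
partials — recursively, until a round removes nothing. Pruned edges are
never re-added. Goodness of fit of the final constrained model is
summarized with the usual discrepancy-based indices (chi-square, RMSEA,
CFI, TLI, BIC).

The constrained ML fit uses the coordinate-wise regression algorithm
for covariance selection: cycling over nodes, each node's covariances
with the rest are replaced by the best prediction from its graph
neighbours, which at convergence yields the MLE whose implied
covariance matches the sample values on every retained pair and whose
precision is exactly zero elsewhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats, optimize

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationEstimate",
    "ConstrainedFit",
    "FitIndices",
    "PrunedNetwork",
    "estimate_correlations",
    "saturated_partials",
    "edge_pvalues",
    "fit_constrained_ggm",
    "fit_indices",
    "prune_network",
    "estimate_network",
]


class ConvergenceError(RuntimeError):
    """Raised when the constrained fit does not reach tolerance within the sweep cap."""


# ---------------------------------------------------------------------------
# correlation input
# ---------------------------------------------------------------------------

@dataclass
class CorrelationEstimate:
    """Symmetric correlation matrix with its sample size and method label."""

    matrix: np.ndarray
    n: int
    method: str = "pearson"

    def __post_init__(self) -> None:
        R = np.asarray(self.matrix, dtype=float)
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(R, R.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-8):
            raise ValueError("correlation matrix must have a unit diagonal")
        R = 0.5 * (R + R.T)
        evals = np.linalg.eigvalsh(R)
        if evals.min() < -1e-10:
            logger.warning(
                "correlation matrix indefinite (min eigenvalue %.3e); clipping to PSD", evals.min()
            )
            R = _psd_repair(R)
        self.matrix = R

    @property
    def p(self) -> int:
        return self.matrix.shape[0]


def _psd_repair(R: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    evals, vecs = np.linalg.eigh(R)
    evals = np.clip(evals, floor, None)
    R = (vecs * evals) @ vecs.T
    d = 1.0 / np.sqrt(np.diag(R))
    R = (R * d).T * d
    return 0.5 * (R + R.T)


def _polychoric_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Two-step polychoric correlation for a pair of ordinal variables."""
    from scipy.stats import multivariate_normal, norm

    def cuts(v):
        cats, counts = np.unique(v, return_counts=True)
        cum = np.cumsum(counts)[:-1] / len(v)
        return norm.ppf(np.clip(cum, 1e-6, 1 - 1e-6)), cats

    tx, cx = cuts(x)
    ty, cy = cuts(y)
    table = np.zeros((len(cx), len(cy)))
    for i, cxi in enumerate(cx):
        for j, cyj in enumerate(cy):
            table[i, j] = np.sum((x == cxi) & (y == cyj))
    ax = np.concatenate([[-np.inf], tx, [np.inf]])
    ay = np.concatenate([[-np.inf], ty, [np.inf]])

    def negll(rho):
        mvn = multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]])
        hi = np.clip(ax, -8, 8)
        hj = np.clip(ay, -8, 8)
        grid = mvn.cdf(np.dstack(np.meshgrid(hi, hj, indexing="ij")))
        cell = grid[1:, 1:] - grid[:-1, 1:] - grid[1:, :-1] + grid[:-1, :-1]
        cell = np.clip(cell, 1e-12, None)
        return -np.sum(table * np.log(cell))

    res = optimize.minimize_scalar(negll, bounds=(-0.995, 0.995), method="bounded")
    return float(res.x)


def estimate_correlations(data, method: str = "pearson") -> CorrelationEstimate:
    """Item correlation matrix from a respondent x item response matrix.

    ``method`` is one of ``pearson`` (default, raw scores treated as
    continuous), ``spearman``, or ``polychoric`` (two-step latent
    correlation for ordinal items; markedly slower).
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be a 2-D respondent x item matrix")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more respondents ({n}) than items ({p})")
    sd = X.std(axis=0, ddof=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance item(s) at column(s) {dead.tolist()}")
    if method == "pearson":
        R = np.corrcoef(X.T)
    elif method == "spearman":
        R = stats.spearmanr(X).statistic
        R = np.atleast_2d(R)
        if R.shape == (1, 1):  # p == 2 returns a scalar
            r = float(R)
            R = np.array([[1.0, r], [r, 1.0]])
    elif method == "polychoric":
        R = np.eye(p)
        for i in range(p):
            for j in range(i + 1, p):
                R[i, j] = R[j, i] = _polychoric_corr(X[:, i], X[:, j])
    else:
        raise ValueError(f"unknown correlation method: {method!r}")
    R = 0.5 * (R + R.T)
    np.fill_diagonal(R, 1.0)
    return CorrelationEstimate(matrix=R, n=n, method=method)


# ---------------------------------------------------------------------------
# saturated network and edge tests
# ---------------------------------------------------------------------------

def saturated_partials(corr: CorrelationEstimate | np.ndarray) -> np.ndarray:
    """Partial correlations from the standardized inverse correlation matrix.

    ``w_ij = -kappa_ij / sqrt(kappa_ii kappa_jj)`` with a zero diagonal.
    """
    R = corr.matrix if isinstance(corr, CorrelationEstimate) else np.asarray(corr, float)
    try:
        K = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "correlation matrix is singular; regularized estimation is not supported — "
            "repair the input to positive definite first"
        ) from exc
    d = np.sqrt(np.diag(K))
    W = -K / np.outer(d, d)
    np.fill_diagonal(W, 0.0)
    return 0.5 * (W + W.T)


def edge_pvalues(partials: np.ndarray, n: int, n_items: int | None = None) -> np.ndarray:
    """Two-sided Fisher-z p-values for partial correlations.

    ``z = atanh(w) * sqrt(n - k - 3)`` with ``k = n_items - 2``
    conditioning variables, i.e. an effective factor ``sqrt(n - p - 1)``.
    Diagonal entries are set to 1 by convention.
    """
    W = np.asarray(partials, dtype=float)
    p = W.shape[0] if n_items is None else n_items
    dof = n - p - 1
    if dof <= 0:
        raise ValueError(f"sample size {n} too small for {p} items (need n > p + 1)")
    z = np.arctanh(np.clip(W, -0.999999999, 0.999999999)) * np.sqrt(dof)
    pv = 2.0 * stats.norm.sf(np.abs(z))
    np.fill_diagonal(pv, 1.0)
    return pv


# ---------------------------------------------------------------------------
# constrained ML fit (covariance selection)
# ---------------------------------------------------------------------------

@dataclass
class ConstrainedFit:
    """MLE of a Gaussian model with an exact zero pattern in the precision matrix."""

    sigma: np.ndarray
    loglik: float
    partials: np.ndarray
    precision: np.ndarray
    n_sweeps: int


def gaussian_loglik(S: np.ndarray, sigma: np.ndarray, n: int) -> float:
    """Log-likelihood of n zero-mean Gaussian observations with sample cov S."""
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise np.linalg.LinAlgError("implied covariance not positive definite")
    return float(-0.5 * n * (p * np.log(2 * np.pi) + logdet + np.trace(np.linalg.solve(sigma, S))))


def fit_constrained_ggm(
    S: np.ndarray,
    zero_pattern,
    n: int,
    tol: float = 1e-8,
    max_sweeps: int = 1000,
    warm_start: np.ndarray | None = None,
) -> ConstrainedFit:
    """Covariance selection: Gaussian MLE under precision zero constraints.

    The implied covariance matches ``S`` exactly on the diagonal and on
    every retained (free) pair, while the precision matrix is exactly
    zero on ``zero_pattern``. Solved by cycling coordinate-wise
    regressions over nodes; converged when the largest absolute change
    in the implied covariance over a sweep drops below ``tol``.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    free = np.ones((p, p), dtype=bool)
    np.fill_diagonal(free, False)
    for (i, j) in zero_pattern:
        free[i, j] = free[j, i] = False

    others = [np.delete(np.arange(p), j) for j in range(p)]
    neighbors = [np.flatnonzero(free[:, j]) for j in range(p)]

    if all(len(nb) == p - 1 for nb in neighbors):  # saturated: Sigma = S
        K = np.linalg.inv(S)
        return ConstrainedFit(S.copy(), gaussian_loglik(S, S, n), _partials_of(K), K, 0)

    W = S.copy() if warm_start is None else warm_start.copy()
    np.fill_diagonal(W, np.diag(S))
    n_sweeps = 0
    attained = np.inf
    for n_sweeps in range(1, max_sweeps + 1):
        max_delta = 0.0
        for j in range(p):
            oth = others[j]
            nb = neighbors[j]
            if nb.size == 0:
                new = np.zeros(p - 1)
            else:
                Wnn = W[np.ix_(nb, nb)]
                beta = np.linalg.solve(Wnn, S[nb, j])
                new = W[np.ix_(oth, nb)] @ beta
            delta = np.max(np.abs(new - W[oth, j]))
            if delta > max_delta:
                max_delta = delta
            W[oth, j] = new
            W[j, oth] = new
        attained = max_delta
        if max_delta < tol:
            break
    else:
        raise ConvergenceError(
            f"covariance selection did not converge in {max_sweeps} sweeps "
            f"(attained tolerance {attained:.3e})"
        )

    # precision from the node-wise regression identities; the two estimates
    # of each off-diagonal entry (one per endpoint) agree at convergence
    # and are averaged by the symmetrization
    K = np.zeros((p, p))
    for j in range(p):
        nb = neighbors[j]
        if nb.size == 0:
            K[j, j] = 1.0 / S[j, j]
            continue
        beta = np.linalg.solve(W[np.ix_(nb, nb)], S[nb, j])
        kjj = 1.0 / (S[j, j] - S[nb, j] @ beta)
        K[j, j] = kjj
        K[nb, j] = -beta * kjj
    K = np.where(np.eye(p, dtype=bool), K, 0.5 * (K + K.T))
    K[~free & ~np.eye(p, dtype=bool)] = 0.0
    return ConstrainedFit(W, gaussian_loglik(S, W, n), _partials_of(K), K, n_sweeps)


def _partials_of(K: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(K))
    W = -K / np.outer(d, d)
    np.fill_diagonal(W, 0.0)
    return 0.5 * (W + W.T)


# ---------------------------------------------------------------------------
# fit indices
# ---------------------------------------------------------------------------

@dataclass
class FitIndices:
    """Discrepancy-based goodness-of-fit summary of a pruned model."""

    chi_square: float
    df: int
    log_likelihood: float
    bic: float
    rmsea: float
    cfi: float
    tli: float
    note: str = ""


def fit_indices(
    loglik: float,
    S: np.ndarray,
    sigma: np.ndarray,
    n: int,
    df: int,
    n_retained_edges: int,
    n_scaling: str = "n-1",
) -> FitIndices:
    """Chi-square, RMSEA, CFI, TLI and BIC for a constrained GGM fit.

    Discrepancy ``F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p`` with test
    statistic ``T = (n-1) F`` (or ``n F`` with ``n_scaling="n"``); the
    baseline model is the diagonal (independence) model; BIC counts
    ``p`` variances plus the retained edges as free parameters.
    """
    if df < 0:
        raise ValueError("df must be non-negative")
    if n_scaling not in ("n-1", "n"):
        raise ValueError("n_scaling must be 'n-1' or 'n'")
    m = n - 1 if n_scaling == "n-1" else n  # multiplier for T, T_b and RMSEA
    p = S.shape[0]
    sign_m, logdet_m = np.linalg.slogdet(sigma)
    sign_s, logdet_s = np.linalg.slogdet(S)
    if sign_m <= 0 or sign_s <= 0:
        raise ValueError("S and implied sigma must be positive definite")
    F = logdet_m + np.trace(np.linalg.solve(sigma, S)) - logdet_s - p
    T = m * max(F, 0.0)

    Fb = float(np.sum(np.log(np.diag(S))) - logdet_s)
    Tb = m * max(Fb, 0.0)
    df_b = p * (p - 1) // 2

    rmsea = 0.0 if df == 0 else float(np.sqrt(max(T - df, 0.0) / (df * m)))
    denom = max(Tb - df_b, T - df, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(T - df, 0.0) / denom
    note = ""
    if df == 0:
        tli = 1.0
        note = "TLI undefined at df=0; reported as 1"
    else:
        ratio_b = Tb / df_b
        tli = float((ratio_b - T / df) / (ratio_b - 1.0))
        if T < df and tli > 1.0:
            note = "chi-square below df; TLI exceeds 1"
    q = p + n_retained_edges
    bic = float(-2.0 * loglik + q * np.log(n))
    return FitIndices(
        chi_square=float(T), df=int(df), log_likelihood=float(loglik),
        bic=bic, rmsea=rmsea, cfi=float(cfi), tli=float(tli), note=note,
    )


# ---------------------------------------------------------------------------
# recursive pruning
# ---------------------------------------------------------------------------

@dataclass
class PrunedNetwork:
    """Sparse partial-correlation network from recursive significance pruning."""

    weights: np.ndarray
    zero_pattern: frozenset
    n: int
    alpha: float
    fit: FitIndices
    iterations: int
    sigma: np.ndarray
    items: list[str] | None = None

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    def edges(self) -> list[tuple[int, int]]:
        """Retained (i < j) pairs with nonzero weight."""
        p = self.p
        return [
            (i, j)
            for i in range(p)
            for j in range(i + 1, p)
            if (i, j) not in self.zero_pattern
        ]


def prune_network(corr: CorrelationEstimate, alpha: float = 0.05, max_rounds: int = 100) -> PrunedNetwork:
    """Recursive significance pruning of the saturated partial-correlation net.

    Each round tests every currently retained edge two-sidedly at
    ``alpha`` (Fisher z); all non-significant edges are removed
    simultaneously, the model is refitted under the accumulated zero
    constraints, and the refitted partials are retested. Stops when a
    round removes nothing. Pruned edges are never re-added.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    R, n, p = corr.matrix, corr.n, corr.p
    W = saturated_partials(corr)
    zero: set[tuple[int, int]] = set()
    fitres: ConstrainedFit | None = None
    rounds = 0
    while rounds < max_rounds:
        rounds += 1
        pv = edge_pvalues(W, n, p)
        to_remove = {
            (i, j)
            for i in range(p)
            for j in range(i + 1, p)
            if (i, j) not in zero and pv[i, j] >= alpha
        }
        if not to_remove:
            if fitres is None:
                fitres = fit_constrained_ggm(R, zero, n)
            break
        zero |= to_remove
        try:
            fitres = fit_constrained_ggm(
                R, zero, n, warm_start=fitres.sigma if fitres is not None else None
            )
        except (ConvergenceError, np.linalg.LinAlgError) as exc:
            raise RuntimeError(f"constrained fit failed in pruning round {rounds}") from exc
        W = fitres.partials
    else:
        raise RuntimeError(f"pruning did not stabilize within {max_rounds} rounds")

    weights = fitres.partials.copy()
    for (i, j) in zero:
        weights[i, j] = weights[j, i] = 0.0
    df = len(zero)
    n_retained = p * (p - 1) // 2 - df
    fi = fit_indices(fitres.loglik, R, fitres.sigma, n, df, n_retained)
    return PrunedNetwork(
        weights=weights,
        zero_pattern=frozenset(zero),
        n=n,
        alpha=alpha,
        fit=fi,
        iterations=rounds,
        sigma=fitres.sigma,
    )


def estimate_network(
    data, alpha: float = 0.05, method: str = "pearson", items: list[str] | None = None
) -> PrunedNetwork:
    """Convenience: correlation estimation followed by recursive pruning."""
    corr = estimate_correlations(data, method=method)
    net = prune_network(corr, alpha=alpha)
    net.items = items
    return net
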