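"""Pairwise tests of between-group network differences.

Three complementary tests are provided for a pair of groups measured on
the same items:

* an overall *structure* test: the symmetric Kullback-Leibler
  divergence between the two groups' pruned-model-implied covariances,
  calibrated by a predictive check that re-simulates both groups from
  the pooled fitted model;
* permutation tests of the *global* expected influence and global
  bridge expected influence (network comparison test);
* permutation tests of every individual edge weight and node
  centrality, with counts of significant differences split into bridge
  and non-bridge edges.

All permutation p-values use the add-one estimator
``(1 + #{null >= observed}) / (1 + n_permutations)`` and therefore
honour the floor ``1/(n_permutations + 1)``. Every permutation re-runs
the full estimation pipeline (correlation, pruning, constrained refit)
so the null distribution reflects the whole procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ggm import estimate_network, PrunedNetwork
from .centrality import expected_influence, bridge_expected_influence

logger = logging.getLogger(__name__)

__all__ = [
    "PairwiseComparison",
    "PPCResult",
    "symmetric_kl",
    "ppc_structure_test",
    "nct_global",
    "nct_local",
    "network_comparison_test",
    "compare_groups",
]


# ---------------------------------------------------------------------------
# symmetric KL divergence
# ---------------------------------------------------------------------------

def symmetric_kl(sigma_a: np.ndarray, sigma_b: np.ndarray) -> float:
    """Symmetrized KL divergence between two zero-mean Gaussians.

    ``KL(a->b) + KL(b->a) = 0.5 [tr(Sb^-1 Sa) + tr(Sa^-1 Sb)] - p``.
    """
    Sa = np.asarray(sigma_a, dtype=float)
    Sb = np.asarray(sigma_b, dtype=float)
    if Sa.shape != Sb.shape or Sa.ndim != 2 or Sa.shape[0] != Sa.shape[1]:
        raise ValueError("covariance matrices must be square and of equal dimension")
    p = Sa.shape[0]
    for name, S in (("a", Sa), ("b", Sb)):
        try:
            np.linalg.cholesky(S)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"covariance {name} is not positive definite") from exc
    val = 0.5 * (np.trace(np.linalg.solve(Sb, Sa)) + np.trace(np.linalg.solve(Sa, Sb))) - p
    return float(max(val, 0.0))


# ---------------------------------------------------------------------------
# posterior-predictive structure test
# ---------------------------------------------------------------------------

@dataclass
class PPCResult:
    kl_observed: float
    kl_p: float
    null: np.ndarray
    n_draws: int


def ppc_structure_test(
    data_a,
    data_b,
    n_draws: int = 1000,
    alpha: float = 0.05,
    method: str = "pearson",
    seed: int | np.random.Generator | None = None,
) -> PPCResult:
    """Predictive check of overall structural difference between two groups.

    The observed statistic is the symmetric KL divergence between the
    two groups' pruned-model-implied covariances. Under the null the
    rows are pooled, the pooled model fitted, and ``n_draws`` replicate
    pairs of Gaussian datasets (sizes ``n_a``, ``n_b``) simulated from
    the pooled fit; each replicate pair is re-estimated with the same
    pipeline and its symmetric KL recorded. This plug-in predictive
    scheme approximates the Bayesian posterior predictive check without
    requiring prior specification.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    Xa = np.asarray(data_a, dtype=float)
    Xb = np.asarray(data_b, dtype=float)
    if Xa.shape[1] != Xb.shape[1]:
        raise ValueError("both groups must be measured on the same items")
    na, nb = len(Xa), len(Xb)
    net_a = estimate_network(Xa, alpha=alpha, method=method)
    net_b = estimate_network(Xb, alpha=alpha, method=method)
    observed = symmetric_kl(net_a.sigma, net_b.sigma)

    pooled = estimate_network(np.vstack([Xa, Xb]), alpha=alpha, method=method)
    L = np.linalg.cholesky(pooled.sigma)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = Xa.shape[1]
    null = np.empty(n_draws)
    for d in range(n_draws):
        Ya = rng.standard_normal((na, p)) @ L.T
        Yb = rng.standard_normal((nb, p)) @ L.T
        sa = estimate_network(Ya, alpha=alpha).sigma
        sb = estimate_network(Yb, alpha=alpha).sigma
        null[d] = symmetric_kl(sa, sb)
    kl_p = (1.0 + np.sum(null >= observed)) / (1.0 + n_draws)
    return PPCResult(kl_observed=observed, kl_p=float(kl_p), null=null, n_draws=n_draws)


# ---------------------------------------------------------------------------
# permutation network comparison test
# ---------------------------------------------------------------------------

@dataclass
class NCTResult:
    """All statistics from one shared permutation stream for a group pair."""

    global_ei_diff: float
    global_ei_p: float
    global_bridge_ei_diff: float
    global_bridge_ei_p: float
    per_edge: pd.DataFrame
    per_node: pd.DataFrame
    edge_diff_count: int
    bridge_edge_diff_count: int
    nonbridge_edge_diff_count: int
    node_ei_diff_count: int
    node_bridge_ei_diff_count: int
    n_permutations: int
    n_failed: int
    net_a: PrunedNetwork = None
    net_b: PrunedNetwork = None


def _net_stats(net: PrunedNetwork, community: dict, items: list[str]):
    net.items = items
    ei = expected_influence(net)
    eib = bridge_expected_influence(net, community, normalize=True)
    return net.weights, ei, eib, float(ei.sum()), float(eib.sum())


def network_comparison_test(
    data_a,
    data_b,
    community: dict,
    items: list[str],
    n_permutations: int = 5000,
    alpha: float = 0.05,
    sig_level: float = 0.05,
    method: str = "pearson",
    seed: int | np.random.Generator | None = None,
    holm: bool = False,
) -> NCTResult:
    """Permutation test of global and element-wise network differences.

    Group labels are shuffled over the pooled rows (original group
    sizes kept) and the full pruning pipeline is re-run per permuted
    split; global statistic differences, per-edge weight differences
    over the union of edges retained in either observed network, and
    per-node EI / bridge-EI differences are all recorded from one
    shared permutation stream. Counts of significant elements use
    uncorrected p-values at ``sig_level``; Holm-adjusted p-values are
    also reported when ``holm`` is set.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    Xa = np.asarray(data_a, dtype=float)
    Xb = np.asarray(data_b, dtype=float)
    if Xa.shape[1] != Xb.shape[1]:
        raise ValueError("both groups must be measured on the same items")
    na, nb = len(Xa), len(Xb)
    p = Xa.shape[1]

    net_a = estimate_network(Xa, alpha=alpha, method=method, items=items)
    net_b = estimate_network(Xb, alpha=alpha, method=method, items=items)
    wa, ei_a, eib_a, g_a, gb_a = _net_stats(net_a, community, items)
    wb, ei_b, eib_b, g_b, gb_b = _net_stats(net_b, community, items)

    union = sorted(set(net_a.edges()) | set(net_b.edges()))
    labels = np.asarray([community[it] for it in items])
    is_bridge = np.array([labels[i] != labels[j] for (i, j) in union], dtype=bool)

    obs_global = abs(g_a - g_b)
    obs_global_bridge = abs(gb_a - gb_b)
    obs_edge = np.array([abs(wa[i, j] - wb[i, j]) for (i, j) in union])
    obs_node_ei = np.abs(ei_a - ei_b)
    obs_node_eib = np.abs(eib_a - eib_b)

    pooled = np.vstack([Xa, Xb])
    ntot = na + nb
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    ge_global = 1
    ge_global_bridge = 1
    ge_edge = np.ones(len(union), dtype=np.int64)
    ge_node_ei = np.ones(p, dtype=np.int64)
    ge_node_eib = np.ones(p, dtype=np.int64)
    n_failed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(ntot)
        try:
            pa = estimate_network(pooled[perm[:na]], alpha=alpha, method=method, items=items)
            pb = estimate_network(pooled[perm[na:]], alpha=alpha, method=method, items=items)
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            n_failed += 1
            if n_failed > max(1, 0.01 * n_permutations):
                raise RuntimeError(
                    f"more than 1% of permutations failed ({n_failed} so far); aborting"
                )
            continue
        wpa, ei_pa, eib_pa, g_pa, gb_pa = _net_stats(pa, community, items)
        wpb, ei_pb, eib_pb, g_pb, gb_pb = _net_stats(pb, community, items)
        ge_global += abs(g_pa - g_pb) >= obs_global
        ge_global_bridge += abs(gb_pa - gb_pb) >= obs_global_bridge
        diff = np.array([abs(wpa[i, j] - wpb[i, j]) for (i, j) in union])
        ge_edge += diff >= obs_edge
        ge_node_ei += np.abs(ei_pa - ei_pb) >= obs_node_ei
        ge_node_eib += np.abs(eib_pa - eib_pb) >= obs_node_eib

    n_ok = n_permutations - n_failed
    denom = 1.0 + n_ok
    p_global = ge_global / denom
    p_global_bridge = ge_global_bridge / denom
    p_edge = ge_edge / denom
    p_node_ei = ge_node_ei / denom
    p_node_eib = ge_node_eib / denom

    per_edge = pd.DataFrame(
        {
            "item_i": [items[i] for (i, j) in union],
            "item_j": [items[j] for (i, j) in union],
            "is_bridge": is_bridge,
            "weight_a": [wa[i, j] for (i, j) in union],
            "weight_b": [wb[i, j] for (i, j) in union],
            "abs_diff": obs_edge,
            "p": p_edge,
        }
    )
    per_node = pd.DataFrame(
        {
            "item": items,
            "community": labels,
            "ei_a": ei_a,
            "ei_b": ei_b,
            "ei_abs_diff": obs_node_ei,
            "ei_p": p_node_ei,
            "bridge_ei_a": eib_a,
            "bridge_ei_b": eib_b,
            "bridge_ei_abs_diff": obs_node_eib,
            "bridge_ei_p": p_node_eib,
        }
    )
    if holm:
        from statsmodels.stats.multitest import multipletests

        if len(per_edge):
            per_edge["p_holm"] = multipletests(per_edge["p"], method="holm")[1]
        per_node["ei_p_holm"] = multipletests(per_node["ei_p"], method="holm")[1]
        per_node["bridge_ei_p_holm"] = multipletests(per_node["bridge_ei_p"], method="holm")[1]

    sig_edges = p_edge < sig_level
    return NCTResult(
        global_ei_diff=obs_global,
        global_ei_p=float(p_global),
        global_bridge_ei_diff=obs_global_bridge,
        global_bridge_ei_p=float(p_global_bridge),
        per_edge=per_edge,
        per_node=per_node,
        edge_diff_count=int(sig_edges.sum()),
        bridge_edge_diff_count=int((sig_edges & is_bridge).sum()),
        nonbridge_edge_diff_count=int((sig_edges & ~is_bridge).sum()),
        node_ei_diff_count=int((p_node_ei < sig_level).sum()),
        node_bridge_ei_diff_count=int((p_node_eib < sig_level).sum()),
        n_permutations=n_permutations,
        n_failed=n_failed,
        net_a=net_a,
        net_b=net_b,
    )


def nct_global(
    data_a,
    data_b,
    community: dict,
    items: list[str],
    statistic: str = "global_ei",
    n_permutations: int = 5000,
    seed=None,
    **kwargs,
) -> tuple[float, float]:
    """Permutation test of one global statistic; returns ``(|diff|, p)``."""
    if statistic not in ("global_ei", "global_bridge_ei"):
        raise ValueError("statistic must be 'global_ei' or 'global_bridge_ei'")
    res = network_comparison_test(
        data_a, data_b, community, items, n_permutations=n_permutations, seed=seed, **kwargs
    )
    if statistic == "global_ei":
        return res.global_ei_diff, res.global_ei_p
    return res.global_bridge_ei_diff, res.global_bridge_ei_p


def nct_local(
    data_a,
    data_b,
    community: dict,
    items: list[str],
    n_permutations: int = 5000,
    seed=None,
    **kwargs,
) -> NCTResult:
    """Element-wise permutation tests (edges, node EI, node bridge EI)."""
    return network_comparison_test(
        data_a, data_b, community, items, n_permutations=n_permutations, seed=seed, **kwargs
    )


# ---------------------------------------------------------------------------
# combined pairwise comparison
# ---------------------------------------------------------------------------

@dataclass
class PairwiseComparison:
    """All between-group tests for one (sorted) pair of groups."""

    group_a: str
    group_b: str
    kl_observed: float
    kl_p: float
    global_ei_diff: float
    global_ei_p: float
    global_bridge_ei_diff: float
    global_bridge_ei_p: float
    edge_diff_count: int
    bridge_edge_diff_count: int
    nonbridge_edge_diff_count: int
    node_ei_diff_count: int
    node_bridge_ei_diff_count: int
    per_edge_p: pd.DataFrame
    per_node_p: pd.DataFrame
    n_permutations: int
    n_ppc_draws: int
    seed: int | None

    def summary(self) -> dict:
        return {
            "group_a": self.group_a,
            "group_b": self.group_b,
            "kl_observed": self.kl_observed,
            "kl_p": self.kl_p,
            "global_ei_diff": self.global_ei_diff,
            "global_ei_p": self.global_ei_p,
            "global_bridge_ei_diff": self.global_bridge_ei_diff,
            "global_bridge_ei_p": self.global_bridge_ei_p,
            "edge_diff_count": self.edge_diff_count,
            "bridge_edge_diff_count": self.bridge_edge_diff_count,
            "nonbridge_edge_diff_count": self.nonbridge_edge_diff_count,
            "node_ei_diff_count": self.node_ei_diff_count,
            "node_bridge_ei_diff_count": self.node_bridge_ei_diff_count,
            "n_permutations": self.n_permutations,
            "n_ppc_draws": self.n_ppc_draws,
            "seed": self.seed,
        }


def compare_groups(
    data_a,
    data_b,
    community: dict,
    items: list[str],
    label_a: str = "A",
    label_b: str = "B",
    n_permutations: int = 5000,
    n_ppc_draws: int = 1000,
    alpha: float = 0.05,
    sig_level: float = 0.05,
    method: str = "pearson",
    seed: int | None = None,
) -> PairwiseComparison:
    """Full pairwise comparison of two groups (structure, global, local).

    The pair is canonicalized by sorted group label so the result is
    identical for (a, b) and (b, a) under the same seed.
    """
    if label_b < label_a:
        label_a, label_b = label_b, label_a
        data_a, data_b = data_b, data_a
    ss = np.random.SeedSequence(seed)
    rng_nct, rng_ppc = (np.random.default_rng(s) for s in ss.spawn(2))
    nct = network_comparison_test(
        data_a, data_b, community, items,
        n_permutations=n_permutations, alpha=alpha, sig_level=sig_level,
        method=method, seed=rng_nct,
    )
    ppc = ppc_structure_test(
        data_a, data_b, n_draws=n_ppc_draws, alpha=alpha, method=method, seed=rng_ppc
    )
    return PairwiseComparison(
        group_a=label_a,
        group_b=label_b,
        kl_observed=ppc.kl_observed,
        kl_p=ppc.kl_p,
        global_ei_diff=nct.global_ei_diff,
        global_ei_p=nct.global_ei_p,
        global_bridge_ei_diff=nct.global_bridge_ei_diff,
        global_bridge_ei_p=nct.global_bridge_ei_p,
        edge_diff_count=nct.edge_diff_count,
        bridge_edge_diff_count=nct.bridge_edge_diff_count,
        nonbridge_edge_diff_count=nct.nonbridge_edge_diff_count,
        node_ei_diff_count=nct.node_ei_diff_count,
        node_bridge_ei_diff_count=nct.node_bridge_ei_diff_count,
        per_edge_p=nct.per_edge,
        per_node_p=nct.per_node,
        n_permutations=n_permutations,
        n_ppc_draws=n_ppc_draws,
        seed=seed,
    )
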