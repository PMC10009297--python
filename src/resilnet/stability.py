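"""Case-drop bootstrap stability and cross-group variability networks.

The case-drop bootstrap gauges how robust a pruned network is to
sampling: each replicate drops a fixed fraction of respondents at
random, re-runs the whole estimation pipeline on the remainder, and
records which edges survive. Variability networks summarize a set of
group networks by the standard deviation of each edge weight (and each
node's expected influence) across groups, with pruned edges counted as
zero so presence/absence variation contributes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import ceil, floor

import numpy as np
import pandas as pd

from .ggm import estimate_network, PrunedNetwork
from .centrality import expected_influence

logger = logging.getLogger(__name__)

__all__ = [
    "BootstrapResult",
    "VariabilityNetwork",
    "casedrop_bootstrap",
    "variability_network",
    "top_varying_edges",
]


@dataclass
class BootstrapResult:
    """Aggregate of a case-drop bootstrap for one group's network."""

    n_boot: int
    drop_fraction: float
    edge_inclusion: np.ndarray        # p x p proportion of bootstraps retaining each edge
    weight_quantiles: np.ndarray      # p x p x 3 (2.5 / 50 / 97.5 percentiles, zeros included)
    overall_recovery: float           # mean inclusion over full-sample edges
    full_network: PrunedNetwork
    n_failed: int = 0

    def summary_table(self, items: list[str] | None = None) -> pd.DataFrame:
        p = self.edge_inclusion.shape[0]
        names = items if items is not None else [str(i) for i in range(p)]
        rows = []
        for i in range(p):
            for j in range(i + 1, p):
                rows.append(
                    {
                        "item_i": names[i],
                        "item_j": names[j],
                        "inclusion": self.edge_inclusion[i, j],
                        "q025": self.weight_quantiles[i, j, 0],
                        "q50": self.weight_quantiles[i, j, 1],
                        "q975": self.weight_quantiles[i, j, 2],
                    }
                )
        return pd.DataFrame(rows)


def casedrop_bootstrap(
    data,
    n_boot: int = 1000,
    drop_fraction: float = 0.25,
    alpha: float = 0.05,
    method: str = "pearson",
    seed: int | np.random.Generator | None = None,
    max_failure_rate: float = 0.05,
) -> BootstrapResult:
    """Case-drop bootstrap of the pruned network.

    Each replicate drops ``floor(drop_fraction * n)`` distinct
    respondents uniformly at random (without replacement), re-estimates
    the network on the remainder with the same pipeline, and records
    retained edges and weights. Replicates whose estimation fails are
    skipped and counted; more than ``max_failure_rate`` failures aborts.
    """
    if not 0.0 <= drop_fraction < 1.0:
        raise ValueError("drop_fraction must lie in [0, 1)")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    n_drop = int(floor(drop_fraction * n))
    full = estimate_network(X, alpha=alpha, method=method)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    retained = np.zeros((p, p))
    weights = np.zeros((n_boot, p, p))
    n_failed = 0
    n_ok = 0
    for b in range(n_boot):
        keep = np.sort(rng.choice(n, size=n - n_drop, replace=False))
        try:
            net = estimate_network(X[keep], alpha=alpha, method=method)
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            n_failed += 1
            if n_failed > max_failure_rate * n_boot:
                raise RuntimeError(
                    f"{n_failed}/{b + 1} bootstrap replicates failed "
                    f"(limit {max_failure_rate:.0%}); aborting"
                )
            continue
        retained += net.weights != 0
        weights[n_ok] = net.weights
        n_ok += 1

    inclusion = retained / max(n_ok, 1)
    quants = np.percentile(weights[:n_ok], [2.5, 50.0, 97.5], axis=0).transpose(1, 2, 0)
    full_edges = full.edges()
    overall = (
        float(np.mean([inclusion[i, j] for (i, j) in full_edges])) if full_edges else float("nan")
    )
    return BootstrapResult(
        n_boot=n_boot,
        drop_fraction=drop_fraction,
        edge_inclusion=inclusion,
        weight_quantiles=quants,
        overall_recovery=overall,
        full_network=full,
        n_failed=n_failed,
    )


@dataclass
class VariabilityNetwork:
    """Across-group standard deviations of edges and node expected influence."""

    edge_sd: np.ndarray
    node_ei_sd: np.ndarray
    groups_included: list[str]
    items: list[str] | None = None

    def edge_table(self, community: dict | None = None) -> pd.DataFrame:
        p = self.edge_sd.shape[0]
        names = self.items if self.items is not None else [str(i) for i in range(p)]
        rows = []
        for i in range(p):
            for j in range(i + 1, p):
                row = {"item_i": names[i], "item_j": names[j], "sd": self.edge_sd[i, j]}
                if community is not None:
                    row["is_bridge"] = community[names[i]] != community[names[j]]
                rows.append(row)
        return pd.DataFrame(rows)


def variability_network(
    nets: list[PrunedNetwork],
    centralities: list[np.ndarray] | None = None,
    groups: list[str] | None = None,
) -> VariabilityNetwork:
    """Edge-wise and node-wise SD across a set of group networks.

    Sample standard deviations (n_groups - 1 denominator); pruned edges
    contribute weight zero, so presence/absence differences count as
    variability.
    """
    if len(nets) < 2:
        raise ValueError("need at least 2 networks")
    p = nets[0].p
    items = nets[0].items
    for net in nets[1:]:
        if net.p != p or (items is not None and net.items is not None and net.items != items):
            raise ValueError("all networks must share the same node set")
    stack = np.stack([net.weights for net in nets])
    edge_sd = stack.std(axis=0, ddof=1)
    np.fill_diagonal(edge_sd, 0.0)
    if centralities is None:
        centralities = [expected_influence(net) for net in nets]
    ei_stack = np.stack([np.asarray(c, dtype=float) for c in centralities])
    node_sd = ei_stack.std(axis=0, ddof=1)
    labels = groups if groups is not None else [str(k) for k in range(len(nets))]
    return VariabilityNetwork(edge_sd=edge_sd, node_ei_sd=node_sd, groups_included=list(labels), items=items)


def top_varying_edges(
    var: VariabilityNetwork, fraction: float = 0.25, community: dict | None = None
) -> pd.DataFrame:
    """The top fraction of nonzero-SD edges, ranked by descending SD.

    Returns ``ceil(fraction * n_nonzero)`` edges; ties broken by the
    lexicographic node pair for determinism.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    table = var.edge_table(community=community)
    nonzero = table[table["sd"] > 0].copy()
    if nonzero.empty:
        return nonzero
    nonzero = nonzero.sort_values(
        by=["sd", "item_i", "item_j"], ascending=[False, True, True], kind="mergesort"
    )
    k = ceil(fraction * len(nonzero))
    return nonzero.head(k).reset_index(drop=True)
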