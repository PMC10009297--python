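"""Expected influence and bridge expected influence centrality.

Expected influence (EI) is the signed one-step sum of a node's edge
weights; unlike strength it preserves the sign of negative edges, which
matters when some associations are inhibitory. Bridge expected
influence restricts the sum to edges crossing between the two item
communities and is normalized by the size of the *other* community so
the two unequally sized domains are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ggm import PrunedNetwork

__all__ = [
    "CentralityTable",
    "expected_influence",
    "bridge_expected_influence",
    "within_expected_influence",
    "global_indices",
    "centrality_table",
]


def _communities(net: PrunedNetwork, community: dict) -> tuple[list[str], np.ndarray]:
    items = net.items if net.items is not None else [str(i) for i in range(net.p)]
    unmapped = [it for it in items if it not in community]
    if unmapped:
        raise ValueError(f"nodes not mapped to a community: {unmapped}")
    labels = np.asarray([community[it] for it in items])
    return items, labels


def expected_influence(net: PrunedNetwork) -> np.ndarray:
    """One-step expected influence: signed sum of each node's edge weights."""
    return net.weights.sum(axis=1)


def within_expected_influence(net: PrunedNetwork, community: dict) -> np.ndarray:
    """Signed sum of each node's edges to its own community."""
    _, labels = _communities(net, community)
    same = labels[:, None] == labels[None, :]
    return (net.weights * same).sum(axis=1)


def bridge_expected_influence(
    net: PrunedNetwork, community: dict, normalize: bool = True
) -> np.ndarray:
    """Signed sum of each node's edges to the other community.

    With ``normalize`` the sum is divided by the number of nodes in the
    other community, equalizing the two domains' unequal item counts.
    """
    _, labels = _communities(net, community)
    cross = labels[:, None] != labels[None, :]
    raw = (net.weights * cross).sum(axis=1)
    if not normalize:
        return raw
    other_size = np.array([np.sum(labels != lab) for lab in labels], dtype=float)
    if np.any(other_size == 0):
        raise ValueError("normalization undefined with a single community")
    return raw / other_size


def global_indices(net: PrunedNetwork, community: dict) -> dict:
    """Global EI, global bridge EI and per-community sums/averages.

    Global expected influence (EI_G) is the sum of node EIs (each edge
    counted at both endpoints); global bridge expected influence
    (EI_BG) is the sum of node *normalized* bridge EIs.
    """
    items, labels = _communities(net, community)
    ei = expected_influence(net)
    eib = bridge_expected_influence(net, community, normalize=True)
    out = {
        "ei_global": float(ei.sum()),
        "ei_bridge_global": float(eib.sum()),
        "community_sums": {},
        "community_means": {},
    }
    for lab in sorted(set(labels.tolist())):
        mask = labels == lab
        out["community_sums"][lab] = float(ei[mask].sum())
        out["community_means"][lab] = float(ei[mask].mean())
    return out


@dataclass
class CentralityTable:
    """Per-node centralities plus the global and per-community aggregates."""

    table: pd.DataFrame
    ei_global: float
    ei_bridge_global: float
    group_sums: dict[str, float]
    group_means: dict[str, float]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def centrality_table(net: PrunedNetwork, community: dict) -> CentralityTable:
    """All centrality indices for one pruned network, as a tidy table."""
    items, labels = _communities(net, community)
    ei = expected_influence(net)
    ei_within = within_expected_influence(net, community)
    eib_raw = bridge_expected_influence(net, community, normalize=False)
    eib_norm = bridge_expected_influence(net, community, normalize=True)
    table = pd.DataFrame(
        {
            "item": items,
            "community": labels,
            "ei": ei,
            "ei_within": ei_within,
            "ei_bridge_raw": eib_raw,
            "ei_bridge_norm": eib_norm,
        }
    )
    glob = global_indices(net, community)
    return CentralityTable(
        table=table,
        ei_global=glob["ei_global"],
        ei_bridge_global=glob["ei_bridge_global"],
        group_sums=glob["community_sums"],
        group_means=glob["community_means"],
    )
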