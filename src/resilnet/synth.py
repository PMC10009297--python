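"""Synthetic multi-group ordinal survey data with known network ground truth.

The generator mirrors the structure of a two-domain resilience survey:
two item communities (intrapersonal skills vs social-ecological
resources) with sparse positive within-community partial correlations,
a small number of between-community "bridge" edges (optionally
negative), latent-Gaussian responses discretized to a 5-point ordinal
scale, and a configurable fraction of disengaged "straight-lining"
respondents who give one constant answer to every item.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import SurveyDataset

__all__ = [
    "TrueNetworkSpec",
    "GroupSpec",
    "StudyTruth",
    "build_true_precision",
    "partials_from_precision",
    "sample_ordinal_group",
    "generate_study",
    "default_thresholds",
]

#: Latent cut-points giving a mildly right-shifted Likert response
#: distribution (category probabilities 0.15/0.25/0.30/0.20/0.10).
DEFAULT_THRESHOLD_QUANTILES = (0.15, 0.40, 0.70, 0.90)


def default_thresholds(quantiles=DEFAULT_THRESHOLD_QUANTILES) -> np.ndarray:
    return stats.norm.ppf(np.asarray(quantiles, dtype=float))


@dataclass(frozen=True)
class TrueNetworkSpec:
    """Ground-truth sparse partial-correlation network for one group.

    Nodes split into community A (default 10 items, intrapersonal) and
    community B (default 17 items, social-ecological). Within-community
    edges are always positive; only bridges may be negative.
    """

    n_items_a: int = 10
    n_items_b: int = 17
    within_density: float = 0.15
    bridge_count: int = 8
    negative_bridge_count: int = 1
    weight_range: tuple[float, float] = (0.1, 0.35)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_items_a < 1 or self.n_items_b < 1:
            raise ValueError("both communities need at least one item")
        if not 0.0 <= self.within_density <= 1.0:
            raise ValueError("within_density must lie in [0, 1]")
        if self.bridge_count < 0 or self.negative_bridge_count < 0:
            raise ValueError("edge counts must be non-negative")
        if self.negative_bridge_count > self.bridge_count:
            raise ValueError("negative_bridge_count cannot exceed bridge_count")
        if self.bridge_count > self.n_items_a * self.n_items_b:
            raise ValueError("more bridges requested than between-community pairs exist")
        lo, hi = self.weight_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("weight_range must satisfy 0 < lo <= hi < 1")

    @property
    def n_items(self) -> int:
        return self.n_items_a + self.n_items_b


@dataclass(frozen=True)
class GroupSpec:
    """One group's sample: its true network, size, response style and noise."""

    group_id: str
    network: TrueNetworkSpec
    n_respondents: int
    thresholds: tuple[float, ...] | None = None
    straightliner_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_respondents < 1:
            raise ValueError("n_respondents must be >= 1")
        if not 0.0 <= self.straightliner_rate < 1.0:
            raise ValueError("straightliner_rate must lie in [0, 1)")
        if self.thresholds is not None:
            t = np.asarray(self.thresholds, dtype=float)
            if np.any(np.diff(t) <= 0):
                raise ValueError("thresholds must be strictly increasing")

    def resolved_thresholds(self, categories: int = 5) -> np.ndarray:
        if self.thresholds is None:
            t = default_thresholds()
        else:
            t = np.asarray(self.thresholds, dtype=float)
        if len(t) != categories - 1:
            raise ValueError(f"need {categories - 1} thresholds for {categories} categories")
        return t


@dataclass
class StudyTruth:
    """Ground truth retained alongside a generated study, for test harnesses."""

    precisions: dict[str, np.ndarray]
    partials: dict[str, np.ndarray]
    thresholds: dict[str, np.ndarray]
    straightliner_rows: dict[str, np.ndarray]
    seeds: dict[str, int]
    items: list[str]
    community: dict[str, str]

    def true_edges(self, group_id: str, min_abs: float = 0.0) -> set[tuple[int, int]]:
        w = self.partials[group_id]
        p = w.shape[0]
        return {
            (i, j)
            for i in range(p)
            for j in range(i + 1, p)
            if abs(w[i, j]) > max(min_abs, 1e-12)
        }

    def to_json(self, path) -> None:
        payload = {
            "items": self.items,
            "community": self.community,
            "groups": {
                g: {
                    "precision": self.precisions[g].tolist(),
                    "partials": self.partials[g].tolist(),
                    "thresholds": self.thresholds[g].tolist(),
                    "straightliner_rows": self.straightliner_rows[g].tolist(),
                    "seed": int(self.seeds[g]),
                }
                for g in self.precisions
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _choose_pairs(rng: np.random.Generator, pairs: list[tuple[int, int]], k: int):
    if k > len(pairs):
        raise ValueError(f"requested {k} edges but only {len(pairs)} pairs available")
    idx = rng.choice(len(pairs), size=k, replace=False)
    return [pairs[i] for i in sorted(idx)]


def build_true_precision(spec: TrueNetworkSpec) -> np.ndarray:
    """Construct the standardized precision matrix for a :class:`TrueNetworkSpec`.

    The matrix starts from the identity with off-diagonal entries
    ``-w_ij`` on the sampled edge support (so the implied partial
    correlation of edge (i, j) is ``w_ij``). If the result is not
    positive definite, an increasing ridge is added to the diagonal
    (doubling from 0.05, at most 20 attempts) and the matrix is then
    re-standardized so the implied covariance has a unit diagonal; the
    standardization preserves the support, the edge signs and the
    partial-correlation values up to the uniform ridge shrinkage.
    """
    rng = np.random.default_rng(spec.seed)
    na, nb, p = spec.n_items_a, spec.n_items_b, spec.n_items

    pairs_a = [(i, j) for i in range(na) for j in range(i + 1, na)]
    pairs_b = [(i, j) for i in range(na, p) for j in range(i + 1, p)]
    pairs_bridge = [(i, j) for i in range(na) for j in range(na, p)]

    k_a = int(round(spec.within_density * len(pairs_a)))
    k_b = int(round(spec.within_density * len(pairs_b)))
    edges_a = _choose_pairs(rng, pairs_a, k_a)
    edges_b = _choose_pairs(rng, pairs_b, k_b)
    bridges = _choose_pairs(rng, pairs_bridge, spec.bridge_count)

    lo, hi = spec.weight_range
    K = np.eye(p)
    for (i, j) in edges_a + edges_b:
        K[i, j] = K[j, i] = -rng.uniform(lo, hi)
    neg_idx = set(
        rng.choice(len(bridges), size=spec.negative_bridge_count, replace=False).tolist()
        if bridges
        else []
    )
    for b, (i, j) in enumerate(bridges):
        w = rng.uniform(lo, hi)
        if b in neg_idx:
            w = -w
        K[i, j] = K[j, i] = -w

    # PD repair: ridge the diagonal in doublings starting at 0.05.
    delta, attempts = 0.05, 0
    while np.linalg.eigvalsh(K).min() <= 1e-6:
        attempts += 1
        if attempts > 20:
            raise RuntimeError("positive-definite repair failed after 20 ridge attempts")
        K = K + delta * np.eye(p)
        delta *= 2.0

    # Re-standardize so the implied covariance has unit diagonal.
    sigma = np.linalg.inv(K)
    d = 1.0 / np.sqrt(np.diag(sigma))
    K = np.linalg.inv((sigma * d).T * d)
    K = 0.5 * (K + K.T)
    # restore exact zeros blurred by the double inversion
    support = np.eye(p, dtype=bool)
    for (i, j) in edges_a + edges_b + bridges:
        support[i, j] = support[j, i] = True
    K[~support] = 0.0
    return K


def partials_from_precision(K: np.ndarray) -> np.ndarray:
    """Partial correlations ``-k_ij / sqrt(k_ii k_jj)`` with a zero diagonal."""
    d = np.sqrt(np.diag(K))
    W = -K / np.outer(d, d)
    np.fill_diagonal(W, 0.0)
    return W


def sample_ordinal_group(
    precision: np.ndarray,
    n: int,
    thresholds: np.ndarray,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw ordinal item responses from a latent Gaussian graphical model.

    Latent rows come from the zero-mean Gaussian whose covariance is the
    (unit-diagonal standardized) inverse of ``precision``; each latent
    value is mapped to category ``1..len(thresholds)+1`` by the
    threshold interval it falls in.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    precision = np.asarray(precision, dtype=float)
    try:
        np.linalg.cholesky(precision)
    except np.linalg.LinAlgError as exc:
        raise ValueError("precision matrix must be positive definite") from exc
    sigma = np.linalg.inv(precision)
    d = 1.0 / np.sqrt(np.diag(sigma))
    sigma = (sigma * d).T * d
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = np.linalg.cholesky(sigma)
    latent = rng.standard_normal((n, precision.shape[0])) @ L.T
    return np.searchsorted(np.asarray(thresholds, dtype=float), latent).astype(np.int64) + 1


def generate_study(
    groups: list[GroupSpec],
    seed: int = 0,
    categories: int = 5,
    age_range: tuple[int, int] = (20, 29),
) -> tuple[SurveyDataset, StudyTruth]:
    """Assemble a multi-group survey dataset with retained ground truth.

    Straight-liners are injected after sampling: for each affected
    respondent the whole row is overwritten with a single constant
    category drawn uniformly, emulating disengaged responding rather
    than a trait. Ages are uniform integers on ``age_range`` (closed),
    sex labels follow a fixed 52/47.3/0.7 split.
    """
    ids = [g.group_id for g in groups]
    if len(set(ids)) != len(ids):
        raise ValueError("group_ids must be unique")
    if not groups:
        raise ValueError("at least one group required")

    first = groups[0].network
    items = [f"R{i + 1}" for i in range(first.n_items_a)] + [
        f"A{i + 1}" for i in range(first.n_items_b)
    ]
    community = {name: ("RRM" if name.startswith("R") else "ARM") for name in items}

    streams = np.random.SeedSequence(seed).spawn(len(groups))
    frames = []
    truth = StudyTruth(
        precisions={}, partials={}, thresholds={}, straightliner_rows={},
        seeds={}, items=items, community=community,
    )
    offset = 0
    for g, ss in zip(groups, streams):
        if g.network.n_items != first.n_items:
            raise ValueError("all groups must share the same item set")
        rng = np.random.default_rng(ss)
        K = build_true_precision(g.network)
        thresholds = g.resolved_thresholds(categories)
        X = sample_ordinal_group(K, g.n_respondents, thresholds, rng)

        n_straight = int(np.floor(g.straightliner_rate * g.n_respondents))
        rows = np.sort(rng.choice(g.n_respondents, size=n_straight, replace=False))
        for r in rows:
            X[r, :] = rng.integers(1, categories + 1)

        age = rng.integers(age_range[0], age_range[1] + 1, size=g.n_respondents)
        sex = rng.choice(
            ["female", "male", "other"], size=g.n_respondents, p=[0.52, 0.4729, 0.0071]
        )
        frame = pd.DataFrame(
            {
                "respondent_id": np.arange(offset, offset + g.n_respondents),
                "group": g.group_id,
                "age": age,
                "sex": sex,
            }
        )
        frame[items] = X
        frames.append(frame)
        offset += g.n_respondents

        truth.precisions[g.group_id] = K
        truth.partials[g.group_id] = partials_from_precision(K)
        truth.thresholds[g.group_id] = thresholds
        truth.straightliner_rows[g.group_id] = rows
        truth.seeds[g.group_id] = int(g.network.seed)

    table = pd.concat(frames, ignore_index=True)
    data = SurveyDataset(table=table, community=community, categories=categories)
    return data, truth
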