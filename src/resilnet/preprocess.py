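"""Sample cleaning and measure screening for ordinal survey data.

Covers the standard data-quality steps taken before psychometric
network estimation: exclusion of straight-lining respondents (one
constant answer across all items), restriction to an age window,
0-100 rescaling of scale sums, internal consistency (Cronbach's alpha)
and screening for topologically overlapping (near-redundant) item
pairs via the Hittner back-transformed-z test for dependent
correlations, as used by the goldbricker procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import json
import numpy as np
import pandas as pd
from scipy import stats

from .datasets import SurveyDataset

__all__ = [
    "CleaningReport",
    "filter_straightliners",
    "filter_age",
    "rescale_scores",
    "cronbach_alpha",
    "detect_topological_overlap",
    "hittner_dependent_corr_test",
    "clean",
]


@dataclass
class CleaningReport:
    """Accounting of sample cleaning and measure screening."""

    n_input: int
    n_excluded_age: int
    n_excluded_straightline: int
    n_final: int
    flagged_overlap_pairs: list[dict] = field(default_factory=list)
    alpha_by_scale: dict[str, float] = field(default_factory=dict)
    correlation_kind: str = "pearson"

    def __post_init__(self) -> None:
        if self.n_input != self.n_final + self.n_excluded_age + self.n_excluded_straightline:
            raise ValueError("cleaning counts do not add up")
        if min(self.n_input, self.n_final, self.n_excluded_age, self.n_excluded_straightline) < 0:
            raise ValueError("counts must be non-negative")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def filter_straightliners(data: SurveyDataset) -> tuple[SurveyDataset, int]:
    """Drop respondents who gave the identical answer to every item.

    Straight-lining is judged over the union of all items (both
    measures at once); per-scale constancy alone is not exclusion-worthy.
    """
    resp = data.responses.to_numpy()
    constant = (resp == resp[:, [0]]).all(axis=1) if resp.shape[1] > 1 else np.ones(len(resp), bool)
    kept = data.subset(~constant)
    return kept, int(constant.sum())


def filter_age(data: SurveyDataset, min_age: int, max_age: int) -> SurveyDataset:
    """Retain respondents with ``min_age <= age <= max_age`` (closed interval)."""
    if min_age > max_age:
        raise ValueError("min_age must not exceed max_age")
    age = data.table["age"].to_numpy()
    return data.subset((age >= min_age) & (age <= max_age))


def rescale_scores(scale_scores, min_possible: float, max_possible: float) -> np.ndarray:
    """Rescale raw scale sums onto 0-100 for comparison across measures."""
    if max_possible <= min_possible:
        raise ValueError("max_possible must exceed min_possible")
    x = np.asarray(scale_scores, dtype=float)
    if np.any(x < min_possible) or np.any(x > max_possible):
        raise ValueError("score outside the possible range for this scale")
    return (x - min_possible) / (max_possible - min_possible) * 100.0


def cronbach_alpha(items) -> float:
    """Cronbach's alpha: ``k/(k-1) * (1 - sum(item var) / var(row sums))``.

    Sample variances (n-1 denominator) are used throughout.
    """
    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 items and 2 respondents")
    k = X.shape[1]
    item_var = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total score variance is zero; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


def hittner_dependent_corr_test(r_jk: float, r_jh: float, r_kh: float, n: int) -> tuple[float, float]:
    """Hittner back-transformed-z test for two dependent overlapping correlations.

    Compares ``r_jk`` and ``r_jh`` (sharing the common variable j) in a
    sample of size ``n``; ``r_kh`` is the correlation of the two
    non-shared variables. Returns ``(z, two-sided p)``.
    """
    clip = 0.999999
    z1 = np.arctanh(np.clip(r_jk, -clip, clip))
    z2 = np.arctanh(np.clip(r_jh, -clip, clip))
    rm = np.tanh(0.5 * (z1 + z2))  # back-transformed average correlation
    c = (r_kh * (1 - 2 * rm**2) - 0.5 * rm**2 * (1 - 2 * rm**2 - r_kh**2)) / (1 - rm**2) ** 2
    if c >= 1.0:  # degenerate (e.g. duplicated items): no detectable difference
        return 0.0, 1.0
    z = (z1 - z2) * np.sqrt((n - 3) / (2.0 - 2.0 * c))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def detect_topological_overlap(
    items,
    r_threshold: float = 0.7,
    unique_frac: float = 0.2,
    alpha: float = 0.05,
    item_names: list[str] | None = None,
) -> list[dict]:
    """Flag near-redundant item pairs (goldbricker-style screening).

    An item pair with ``|r| >= r_threshold`` is compared against every
    third item: the pair's two correlations with that item are tested
    for difference with :func:`hittner_dependent_corr_test`. A
    comparison is "unique" when the test is significant at ``alpha``;
    the pair is flagged when the fraction of unique comparisons falls
    below ``unique_frac``.
    """
    X = np.asarray(items, dtype=float)
    n, k = X.shape
    if k < 3:
        raise ValueError("need at least 3 items to assess topological overlap")
    names = item_names if item_names is not None else [str(i) for i in range(k)]
    R = np.corrcoef(X.T)
    flagged = []
    for a in range(k):
        for b in range(a + 1, k):
            if abs(R[a, b]) < r_threshold:
                continue
            n_unique = 0
            n_comp = 0
            for c in range(k):
                if c in (a, b):
                    continue
                _, p = hittner_dependent_corr_test(R[c, a], R[c, b], R[a, b], n)
                n_comp += 1
                n_unique += p < alpha
            frac = n_unique / n_comp
            if frac < unique_frac:
                flagged.append(
                    {
                        "item_i": names[a],
                        "item_j": names[b],
                        "r": float(R[a, b]),
                        "unique_fraction": float(frac),
                    }
                )
    return flagged


def clean(
    data: SurveyDataset,
    min_age: int = 20,
    max_age: int = 29,
    goldbricker_r: float = 0.7,
    goldbricker_unique_frac: float = 0.2,
    goldbricker_alpha: float = 0.05,
) -> tuple[SurveyDataset, CleaningReport]:
    """Full cleaning pass: age window, straight-liner removal, screening.

    The order follows the usual survey workflow: restrict to the age
    window first, then exclude straight-liners from that subset, then
    compute per-scale internal consistency and overlap flags on the
    final sample.
    """
    n_input = data.n
    aged = filter_age(data, min_age, max_age)
    n_excluded_age = n_input - aged.n
    final, n_straight = filter_straightliners(aged)

    alphas = {}
    for comm in final.communities():
        cols = final.items_in(comm)
        if len(cols) >= 2 and final.n >= 2:
            alphas[comm] = cronbach_alpha(final.table[cols])
    flagged = (
        detect_topological_overlap(
            final.response_matrix(),
            r_threshold=goldbricker_r,
            unique_frac=goldbricker_unique_frac,
            alpha=goldbricker_alpha,
            item_names=final.items,
        )
        if final.n >= 10
        else []
    )
    report = CleaningReport(
        n_input=n_input,
        n_excluded_age=n_excluded_age,
        n_excluded_straightline=n_straight,
        n_final=final.n,
        flagged_overlap_pairs=flagged,
        alpha_by_scale=alphas,
    )
    return final, report
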