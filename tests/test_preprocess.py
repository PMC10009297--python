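"""Cleaning and measure-screening: filters, alpha, overlap detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from resilnet import (
    SurveyDataset,
    filter_straightliners,
    filter_age,
    rescale_scores,
    cronbach_alpha,
    detect_topological_overlap,
    clean,
)


def make_dataset(resp: np.ndarray, ages=None, group="g") -> SurveyDataset:
    n, k = resp.shape
    table = pd.DataFrame(
        {
            "respondent_id": np.arange(n),
            "group": group,
            "age": ages if ages is not None else np.full(n, 25),
            "sex": "female",
        }
    )
    items = [f"R{i+1}" for i in range(k)]
    table[items] = resp
    comm = {it: ("RRM" if i < k // 2 + 1 else "ARM") for i, it in enumerate(items)}
    return SurveyDataset(table=table, community=comm)


class TestFilters:
    def test_straightliner_removed(self):
        resp = np.array([[1, 2, 3], [3, 3, 3], [2, 1, 2]])
        kept, n_exc = filter_straightliners(make_dataset(resp))
        assert n_exc == 1
        assert kept.n == 2
        assert kept.table["respondent_id"].tolist() == [0, 2]

    def test_no_constant_rows_is_identity(self):
        resp = np.array([[1, 2, 3], [2, 1, 3]])
        kept, n_exc = filter_straightliners(make_dataset(resp))
        assert n_exc == 0 and kept.n == 2

    def test_all_constant_leaves_empty(self):
        resp = np.tile([[4]], (3, 5))
        kept, n_exc = filter_straightliners(make_dataset(resp))
        assert n_exc == 3 and kept.n == 0

    def test_age_closed_interval(self):
        resp = np.tile([[1, 2, 3]], (4, 1))
        data = make_dataset(resp, ages=[19, 20, 29, 30])
        out = filter_age(data, 20, 29)
        assert out.table["age"].tolist() == [20, 29]
        assert filter_age(data, 0, 99).n == 4
        assert filter_age(data, 40, 50).n == 0

    def test_inverted_bounds_rejected(self):
        data = make_dataset(np.tile([[1, 2, 3]], (2, 1)))
        with pytest.raises(ValueError):
            filter_age(data, 29, 20)

    def test_filters_idempotent(self):
        rng = np.random.default_rng(0)
        resp = rng.integers(1, 6, (30, 5))
        resp[3] = 2
        data = make_dataset(resp, ages=rng.integers(18, 32, 30))
        once, _ = filter_straightliners(data)
        twice, n2 = filter_straightliners(once)
        assert n2 == 0 and twice.table.equals(once.table)
        aged = filter_age(data, 20, 29)
        assert filter_age(aged, 20, 29).table.equals(aged.table)


class TestRescaleScores:
    @pytest.mark.parametrize(
        "score,expected", [(17, 0.0), (85, 100.0), (51, 50.0)]
    )
    def test_scale_sum_rescaling(self, score, expected):
        assert rescale_scores([score], 17, 85)[0] == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rescale_scores([16], 17, 85)
        with pytest.raises(ValueError):
            rescale_scores([10], 17, 5)


class TestCronbachAlpha:
    def _two_items_r(self, r, n=2000, seed=0):
        rng = np.random.default_rng(seed)
        z1 = rng.standard_normal(n)
        z2 = rng.standard_normal(n)
        # exact orthonormalization so the sample correlation is exactly r
        z1 = (z1 - z1.mean()) / z1.std(ddof=1)
        z2 = z2 - z2.mean()
        z2 -= z1 * (z1 @ z2) / (z1 @ z1)
        z2 /= z2.std(ddof=1)
        x2 = r * z1 + np.sqrt(1 - r**2) * z2
        return np.column_stack([z1, x2 / x2.std(ddof=1)])

    def test_two_standardized_items_r_half(self):
        X = self._two_items_r(0.5)
        assert cronbach_alpha(X) == pytest.approx(2.0 / 3.0, abs=1e-10)

    def test_uncorrelated_items_alpha_near_zero(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20000, 6))
        assert abs(cronbach_alpha(X)) < 0.05

    def test_duplicated_item_alpha_one(self):
        x = np.arange(10.0)
        assert cronbach_alpha(np.column_stack([x, x])) == pytest.approx(1.0)

    def test_zero_total_variance_rejected(self):
        X = np.array([[1.0, 2.0], [2.0, 1.0], [1.5, 1.5]])
        with pytest.raises(ValueError):
            cronbach_alpha(X)

    @settings(derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000), shift=st.integers(-5, 5))
    def test_invariant_to_item_order_and_constant_shift(self, seed, shift):
        rng = np.random.default_rng(seed)
        X = rng.integers(1, 6, (40, 5)).astype(float)
        if X.sum(axis=1).var(ddof=1) == 0:
            return
        a = cronbach_alpha(X)
        perm = rng.permutation(5)
        assert cronbach_alpha(X[:, perm]) == pytest.approx(a, abs=1e-12)
        assert cronbach_alpha(X + shift) == pytest.approx(a, abs=1e-10)


class TestTopologicalOverlap:
    def test_duplicate_items_flagged(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((500, 9))
        X = np.column_stack([X, X[:, 0]])  # exact duplicate of item 0
        flagged = detect_topological_overlap(X)
        pairs = {(f["item_i"], f["item_j"]) for f in flagged}
        assert ("0", "9") in pairs
        dup = next(f for f in flagged if (f["item_i"], f["item_j"]) == ("0", "9"))
        assert dup["unique_fraction"] == 0.0

    def test_uncorrelated_items_nothing_flagged(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((300, 8))
        assert detect_topological_overlap(X) == []

    def test_distinct_profiles_not_flagged(self):
        # a highly correlated pair whose external correlation profiles differ
        rng = np.random.default_rng(4)
        n = 1000
        latent = rng.standard_normal(n)
        x1 = latent + 0.45 * rng.standard_normal(n)
        x2 = latent + 0.45 * rng.standard_normal(n)
        others = np.column_stack(
            [0.9 * x1 + 0.8 * rng.standard_normal(n) for _ in range(5)]
        )
        X = np.column_stack([x1, x2, others])
        r12 = np.corrcoef(x1, x2)[0, 1]
        assert r12 >= 0.7
        flagged = detect_topological_overlap(X)
        assert ("0", "1") not in {(f["item_i"], f["item_j"]) for f in flagged}

    def test_symmetric_in_pair_order(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((400, 6))
        X = np.column_stack([X, X[:, 2] + 0.1 * rng.standard_normal(400)])
        f1 = detect_topological_overlap(X)
        Xsw = X[:, [6, 1, 2, 3, 4, 5, 0]]  # swap the flagged pair's positions
        f2 = detect_topological_overlap(Xsw)
        frac1 = {frozenset((f["item_i"], f["item_j"])): f["unique_fraction"] for f in f1}
        # pair (2, 6) becomes (2, 0) after the swap; unique fractions must agree
        key1 = frozenset(("2", "6"))
        key2 = frozenset(("2", "0"))
        if key1 in frac1:
            frac2 = {frozenset((f["item_i"], f["item_j"])): f["unique_fraction"] for f in f2}
            assert frac2[key2] == pytest.approx(frac1[key1], abs=1e-12)

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            detect_topological_overlap(np.random.default_rng(0).standard_normal((50, 2)))


class TestCleanEndToEnd:
    def test_accounting_identity(self):
        rng = np.random.default_rng(6)
        resp = rng.integers(1, 6, (200, 6))
        resp[:5] = 3  # straightliners
        ages = rng.integers(18, 32, 200)
        ages[:5] = 25  # keep straightliners inside the age window
        data = make_dataset(resp, ages=ages)
        cleaned, report = clean(data)
        assert report.n_input == 200
        assert report.n_input == report.n_final + report.n_excluded_age + report.n_excluded_straightline
        assert report.n_excluded_straightline >= 5
        assert set(report.alpha_by_scale) == {"RRM", "ARM"}
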