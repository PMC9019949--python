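"""Ranking loss, per-target correlation, KS statistic, and skewness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diffqa.metrics import (
    MetricError,
    PoolModel,
    TargetPool,
    evaluate,
    ks_two_sample,
    per_target_pcc,
    random_selector_loss,
    ranking_loss,
    skewness,
)


def pool(true, pred, target_id="T1"):
    return TargetPool(target_id, [
        PoolModel(f"m{i:02d}", t, p) for i, (t, p) in enumerate(zip(true, pred))
    ])


def brute_force_ranking_loss(true, pred):
    best = max(true)
    top = max(range(len(pred)), key=lambda i: (pred[i], -i))
    # emulate the lexicographic tie-break on m00 < m01 < ...
    top = min(
        (i for i in range(len(pred)) if pred[i] == max(pred)),
    )
    return abs(best - true[top])


def grid_ks(s1, s2):
    """Dense-grid ECDF scan oracle for the two-sample KS statistic."""
    s1, s2 = np.sort(s1), np.sort(s2)
    lo = min(s1[0], s2[0]) - 1.0
    hi = max(s1[-1], s2[-1]) + 1.0
    grid = np.concatenate([np.linspace(lo, hi, 20001), s1, s2])
    f1 = np.searchsorted(s1, grid, side="right") / len(s1)
    f2 = np.searchsorted(s2, grid, side="right") / len(s2)
    return float(np.max(np.abs(f1 - f2)))


class TestRankingLoss:
    def test_hand_worked_example(self):
        assert ranking_loss(pool([0.8, 0.6, 0.7], [0.5, 0.9, 0.4])) == \
            pytest.approx(0.2)

    def test_zero_when_best_is_selected(self):
        assert ranking_loss(pool([0.3, 0.9, 0.5], [0.1, 0.8, 0.2])) == 0.0

    def test_single_model_pool(self):
        assert ranking_loss(pool([0.4], [0.99])) == 0.0

    def test_tie_broken_by_model_id(self):
        p = pool([0.2, 0.9, 0.6], [0.7, 0.7, 0.7])
        # all tied: lexicographically smallest id m00 is selected
        assert p.selected().model_id == "m00"
        assert ranking_loss(p) == pytest.approx(0.7)

    def test_missing_prediction_named(self):
        p = TargetPool("T9", [PoolModel("mA", 0.5, 0.2),
                              PoolModel("mB", 0.6, None)])
        with pytest.raises(MetricError, match="mB"):
            ranking_loss(p)

    def test_invariant_under_monotone_transform(self, rng):
        for _ in range(20):
            true = rng.uniform(0, 1, 6)
            pred = rng.uniform(0, 1, 6)
            base = ranking_loss(pool(true, pred))
            warped = ranking_loss(pool(true, np.exp(3 * pred)))
            assert base == pytest.approx(warped)

    def test_matches_brute_force_on_random_pools(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 8))
            true = rng.uniform(0, 1, n).round(3)
            pred = rng.uniform(0, 1, n).round(1)  # coarse: forces ties
            assert ranking_loss(pool(true, pred)) == pytest.approx(
                brute_force_ranking_loss(list(true), list(pred))
            )


class TestPerTargetPCC:
    def test_perfect_correlation(self):
        t = [0.1, 0.5, 0.9]
        assert per_target_pcc(pool(t, t)) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        t = np.array([0.1, 0.5, 0.9])
        assert per_target_pcc(pool(t, 1 - t)) == pytest.approx(-1.0)

    def test_five_point_textbook_formula(self, rng):
        true = rng.uniform(0, 1, 5)
        pred = rng.uniform(0, 1, 5)
        num = np.mean((pred - pred.mean()) * (true - true.mean()))
        den = pred.std() * true.std()
        assert per_target_pcc(pool(true, pred)) == pytest.approx(num / den)

    def test_undefined_for_constant_or_tiny_pools(self):
        assert np.isnan(per_target_pcc(pool([0.5], [0.5])))
        assert np.isnan(per_target_pcc(pool([0.2, 0.8], [0.5, 0.5])))


class TestKSTwoSample:
    def test_identical_samples(self):
        d, p = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0
        assert p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        d, _ = ks_two_sample([0.0, 0.1, 0.2], [5.0, 6.0])
        assert d == 1.0

    def test_shifted_triplet_fixture(self):
        d, _ = ks_two_sample([1, 2, 3], [2, 3, 4])
        assert d == pytest.approx(1.0 / 3.0)

    def test_symmetric_in_arguments(self, rng):
        a, b = rng.normal(size=12), rng.normal(1, 2, size=9)
        d1, p1 = ks_two_sample(a, b)
        d2, p2 = ks_two_sample(b, a)
        assert d1 == d2 and p1 == p2

    def test_matches_grid_oracle(self, rng):
        for _ in range(100):
            n, m = int(rng.integers(2, 15)), int(rng.integers(2, 15))
            a = rng.normal(size=n).round(2)  # rounding forces shared points
            b = rng.normal(0.5, 1.5, size=m).round(2)
            d, _ = ks_two_sample(a, b)
            assert 0.0 <= d <= 1.0
            assert d == pytest.approx(grid_ks(a, b), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(MetricError):
            ks_two_sample([], [1.0])


class TestSkewness:
    def test_symmetric_sample_is_zero(self):
        assert skewness([-1.0, 0.0, 1.0]) == pytest.approx(0.0)

    def test_printed_formula_fixture(self):
        # {1,2,3,4,10}: mean 4, third central moment 36, variance 10
        assert skewness([1, 2, 3, 4, 10]) == pytest.approx(36 / 10**1.5)

    def test_matches_direct_formula(self, rng):
        for _ in range(100):
            x = rng.normal(size=int(rng.integers(3, 30)))
            xb = x.mean()
            expected = np.mean((x - xb) ** 3) / np.mean((x - xb) ** 2) ** 1.5
            assert skewness(x) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-10, 10), min_size=3, max_size=20),
           st.floats(-5, 5), st.floats(0.1, 10))
    def test_translation_and_scale_invariance(self, xs, shift, scale):
        x = np.asarray(xs)
        if np.ptp(x) == 0 or np.std(x) < 1e-3:
            return
        base = skewness(x)
        assert skewness(x * scale + shift) == pytest.approx(base, abs=1e-6)
        assert skewness(-x) == pytest.approx(-base, abs=1e-6)

    def test_zero_variance_rejected(self):
        with pytest.raises(MetricError, match="zero-variance"):
            skewness([2.0, 2.0, 2.0])


class TestEvaluate:
    def _pools(self, rng, k=3):
        out = []
        for t in range(k):
            n = int(rng.integers(3, 7))
            true = rng.uniform(0, 1, n)
            pred = rng.uniform(0, 1, n)
            out.append(pool(true, pred, target_id=f"T{t}"))
        return out

    def test_perfect_predictor(self, rng):
        pools = []
        for t in range(3):
            true = rng.uniform(0, 1, 5)
            pools.append(pool(true, true, target_id=f"T{t}"))
        report = evaluate(pools)
        assert report.mean_ranking_loss == 0.0
        assert report.mean_pcc == pytest.approx(1.0)
        ks2 = next(r for r in report.ks_results
                   if r["label"] == "best_vs_selected")
        assert ks2["d_statistic"] == 0.0

    def test_composition_matches_individual_calls(self, rng):
        pools = self._pools(rng)
        report = evaluate(pools)
        losses = [ranking_loss(p) for p in pools]
        pccs = [per_target_pcc(p) for p in pools]
        assert report.mean_ranking_loss == pytest.approx(np.mean(losses))
        assert report.mean_pcc == pytest.approx(np.mean(pccs))
        if np.ptp(losses) > 0:
            assert report.loss_skewness == pytest.approx(skewness(losses))
        else:
            assert np.isnan(report.loss_skewness)
        all_true = [m.true_gdtts for p in pools for m in p.models]
        all_pred = [m.predicted_gdtts for p in pools for m in p.models]
        d, p = ks_two_sample(all_true, all_pred)
        ks1 = next(r for r in report.ks_results if r["label"] == "all_scores")
        assert ks1["d_statistic"] == pytest.approx(d)
        assert ks1["p_value"] == pytest.approx(p)

    def test_mean_loss_unweighted_by_pool_size(self, rng):
        big = pool(rng.uniform(0, 1, 20), rng.uniform(0, 1, 20), "big")
        small = pool([0.9, 0.1], [0.1, 0.9], "small")
        report = evaluate([big, small])
        expected = (ranking_loss(big) + ranking_loss(small)) / 2
        assert report.mean_ranking_loss == pytest.approx(expected)

    def test_order_invariance(self, rng):
        pools = self._pools(rng, k=4)
        r1 = evaluate(pools)
        r2 = evaluate(pools[::-1])
        assert r1.mean_ranking_loss == pytest.approx(r2.mean_ranking_loss)
        assert r1.mean_pcc == pytest.approx(r2.mean_pcc)
        assert r1.loss_skewness == pytest.approx(r2.loss_skewness)

    def test_empty_pool_list_rejected(self):
        with pytest.raises(MetricError):
            evaluate([])


class TestRandomSelector:
    def test_enumeration(self):
        p1 = pool([0.9, 0.5, 0.1], [0, 0, 0], "a")  # mean gap 0.4
        p2 = pool([0.8, 0.8], [0, 0], "b")          # mean gap 0.0
        assert random_selector_loss([p1, p2]) == pytest.approx(0.2)
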