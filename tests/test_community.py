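"""Rarefaction, similarity metrics, bootstrap CIs, OTU accounting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from porebiofilm.community import (
    abundance_correlation,
    bootstrap_ci,
    bray_curtis,
    jaccard,
    rarefy,
    remove_singletons,
    shared_unique_counts,
)


class TestRarefy:
    def test_every_sample_sums_to_depth(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({
            "a": rng.integers(0, 400, 50), "b": rng.integers(0, 400, 50),
        })
        table += 2  # no singletons
        out = rarefy(table, depth=1000, seed=1)
        assert (out.sum() == 1000).all()

    def test_sample_at_exact_depth_keeps_all_reads(self):
        table = pd.DataFrame({"a": [3000, 1500, 500]})
        out = rarefy(table, depth=5000, seed=0)
        assert out["a"].tolist() == [3000, 1500, 500]

    def test_shallow_sample_dropped_with_warning(self):
        table = pd.DataFrame({"deep": [6000, 0], "shallow": [100, 100]})
        with pytest.warns(UserWarning, match="shallow"):
            out = rarefy(table, depth=5000, seed=0)
        assert list(out.columns) == ["deep"]

    def test_singletons_removed_before_rarefaction(self):
        table = pd.DataFrame({"a": [6000, 1, 0], "b": [6000, 0, 1]},
                             index=["keep", "single1", "single2"])
        out = rarefy(table, depth=5000, seed=0)
        assert list(out.index) == ["keep"]

    def test_deterministic_per_seed(self):
        table = pd.DataFrame({"a": np.arange(2, 52)})
        o1 = rarefy(table, depth=500, seed=7)
        o2 = rarefy(table, depth=500, seed=7)
        assert o1.equals(o2)

    def test_subsampling_matches_hypergeometric_expectation(self):
        """Mean rarefied count of each OTU over many seeds approaches
        depth * (count / total) — the without-replacement expectation."""
        counts = np.array([600, 300, 100])
        table = pd.DataFrame({"a": counts})
        depth = 200
        draws = np.array([
            rarefy(table, depth=depth, seed=s, drop_singletons=False)["a"].to_numpy()
            for s in range(500)
        ])
        expect = depth * counts / counts.sum()
        sd = np.sqrt(depth * (counts / counts.sum()) * (1 - counts / counts.sum()))
        assert np.all(np.abs(draws.mean(axis=0) - expect) < 4 * sd / np.sqrt(500))

    def test_bad_depth_rejected(self):
        with pytest.raises(ValueError):
            rarefy(pd.DataFrame({"a": [10]}), depth=0)


class TestMetrics:
    def test_jaccard_hand_value(self):
        # A = {1,2,3}, B = {2,3,4} -> 2/4
        assert jaccard([5, 1, 2, 0], [0, 3, 9, 2]) == pytest.approx(0.5)

    def test_bray_curtis_hand_value(self, toy_otu_table):
        # (0.5,0.5,0) vs (0.25,0.25,0.5) -> 1 - 1/2
        assert bray_curtis(toy_otu_table["A"], toy_otu_table["B"]) == pytest.approx(0.5)

    @pytest.mark.parametrize("metric", [jaccard, bray_curtis])
    def test_identical_and_disjoint(self, metric):
        assert metric([3, 2, 1, 0], [3, 2, 1, 0]) == pytest.approx(1.0)
        assert metric([3, 2, 0, 0], [0, 0, 1, 5]) == pytest.approx(0.0)

    def test_empty_inputs_are_nan(self):
        assert np.isnan(jaccard([0, 0], [0, 0]))
        assert np.isnan(bray_curtis([0, 0], [1, 0]))

    def test_agreement_with_scipy_distances(self):
        """Cross-check both metrics against scipy's distance functions."""
        from scipy.spatial import distance

        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.integers(0, 30, 25)
            y = rng.integers(0, 30, 25)
            if x.sum() == 0 or y.sum() == 0:
                continue
            p, q = x / x.sum(), y / y.sum()
            assert bray_curtis(x, y) == pytest.approx(1 - distance.braycurtis(p, q))
            assert jaccard(x, y) == pytest.approx(1 - distance.jaccard(x > 0, y > 0))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 50), st.integers(0, 50)),
                    min_size=2, max_size=30))
    def test_symmetry_and_bounds(self, pairs):
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        for metric in (jaccard, bray_curtis):
            v = metric(x, y)
            if np.isnan(v):
                continue
            assert 0.0 <= v <= 1.0
            assert metric(y, x) == pytest.approx(v)

    def test_rarefied_metric_converges_to_full_depth_value(self):
        rng = np.random.default_rng(11)
        table = pd.DataFrame({
            "a": rng.multinomial(30000, np.full(40, 1 / 40)),
            "b": rng.multinomial(30000, np.linspace(1, 4, 40) / np.linspace(1, 4, 40).sum()),
        })
        full = bray_curtis(table["a"], table["b"])
        deep = rarefy(table, depth=29000, seed=0, drop_singletons=False)
        shallow = rarefy(table, depth=2000, seed=0, drop_singletons=False)
        err_deep = abs(bray_curtis(deep["a"], deep["b"]) - full)
        err_shallow = abs(bray_curtis(shallow["a"], shallow["b"]) - full)
        assert err_deep < err_shallow


class TestBootstrap:
    def test_identical_abundant_samples_ci_is_unity(self):
        table = pd.DataFrame({"a": [400, 300, 300], "b": [400, 300, 300]})
        res = bootstrap_ci(table, "a", "b", metric="jaccard", n=200, seed=0)
        assert res.ci_low == res.ci_high == res.estimate == 1.0

    @pytest.mark.parametrize("metric", ["jaccard", "bray_curtis"])
    @pytest.mark.parametrize("variant", ["reads", "otus"])
    def test_ci_bounds_ordered_within_unit_interval(self, metric, variant):
        rng = np.random.default_rng(3)
        table = pd.DataFrame({"a": rng.integers(0, 100, 40),
                              "b": rng.integers(0, 100, 40)})
        res = bootstrap_ci(table, "a", "b", metric=metric, n=300, seed=1,
                           variant=variant)
        assert 0.0 <= res.ci_low <= res.ci_high <= 1.0

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(8)
        table = pd.DataFrame({"a": rng.integers(1, 50, 30),
                              "b": rng.integers(1, 50, 30)})
        r1 = bootstrap_ci(table, "a", "b", metric="bray_curtis", n=300, seed=5)
        r2 = bootstrap_ci(table, "a", "b", metric="bray_curtis", n=300, seed=5)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)

    def test_invalid_inputs_rejected(self):
        table = pd.DataFrame({"a": [5], "b": [5]})
        with pytest.raises(ValueError):
            bootstrap_ci(table, "a", "b", metric="nope")
        with pytest.raises(ValueError):
            bootstrap_ci(table, "a", "b", n=1)
        with pytest.raises(ValueError):
            bootstrap_ci(table, "a", "b", variant="rows")


class TestAccounting:
    def test_identical_tables_fully_shared(self):
        shared, ua, ub, frac = shared_unique_counts([5, 3, 0], [5, 3, 0])
        assert (shared, ua, ub) == (2, 0, 0)
        assert frac == 1.0

    def test_empty_second_sample(self):
        shared, ua, ub, _ = shared_unique_counts([5, 3, 1], [0, 0, 0])
        assert shared == 0 and ua == 3 and ub == 0

    def test_known_tails(self):
        shared, ua, ub, frac = shared_unique_counts([90, 90, 5, 0], [80, 100, 0, 3])
        assert (shared, ua, ub) == (2, 1, 1)
        assert frac == pytest.approx(360 / 368)

    def test_singleton_removal_is_global(self):
        table = pd.DataFrame({"a": [1, 0, 4], "b": [0, 1, 4]})
        out = remove_singletons(table)
        assert len(out) == 1


class TestAbundanceCorrelation:
    def test_self_correlation_is_one(self):
        table = pd.DataFrame({"a": [10, 20, 30, 40], "b": [10, 20, 30, 40]})
        r, n = abundance_correlation(table, "a", "b")
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_shuffled_profile_decorrelates(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(0, 2, 300)
        table = pd.DataFrame({"a": x, "b": rng.permutation(x)})
        r, _ = abundance_correlation(table, "a", "b")
        assert abs(r) < 0.3

    def test_family_aggregation(self):
        table = pd.DataFrame({"a": [10, 20, 5, 5], "b": [12, 18, 4, 6]},
                             index=["o1", "o2", "o3", "o4"])
        tax = pd.Series(["F1", "F1", "F2", "F3"], index=table.index)
        r, n = abundance_correlation(table, "a", "b", taxonomy=tax)
        assert n == 3
        assert r > 0.9

    def test_too_few_categories_rejected(self):
        table = pd.DataFrame({"a": [1, 2], "b": [2, 1]})
        with pytest.raises(ValueError):
            abundance_correlation(table, "a", "b")

    def test_noisy_shared_profile_highly_correlated(self):
        rng = np.random.default_rng(4)
        base = rng.lognormal(0, 2, 400)
        p = base / base.sum()
        table = pd.DataFrame({
            "BB": rng.multinomial(50000, p),
            "streamer": rng.multinomial(50000, p),
        })
        r, _ = abundance_correlation(table, "BB", "streamer")
        assert r > 0.9
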