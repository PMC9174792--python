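import dendropy
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from exomedium.exoprofile import (
    CALL_DEPLETED,
    CALL_PRODUCED,
    CALL_UNCHANGED,
    blank_ratio_filter,
    blank_subtract,
    cluster_profiles,
    count_significant,
    depletion_test,
    fold_change,
    isolate_mean_profiles,
    normalize,
    ranksum_z,
)

from conftest import make_peak_table


def one_isolate_table(isolate_reps, control_reps, metabolite="m"):
    return make_peak_table(
        {metabolite: {"isoA": list(isolate_reps)}},
        control_values={metabolite: list(control_reps)},
    )


class TestBlankSubtract:
    def test_mean_background_removed_and_clipped(self):
        t = make_peak_table(
            {"m1": {"isoA": [250.0, 250.0]}, "m2": {"isoA": [250.0, 250.0]}},
            control_values={"m1": [250.0, 250.0], "m2": [250.0, 250.0]},
            blank_values={"m1": [100.0, 100.0], "m2": [300.0, 300.0]},
        )
        out = blank_subtract(t)
        assert not out.blank_columns
        assert np.allclose(out.data.loc["m1"], 150.0)
        assert np.allclose(out.data.loc["m2"], 0.0)  # clipped, not negative

    def test_table_without_blanks_unchanged_with_warning(self):
        t = one_isolate_table([1.0, 2.0], [1.0, 2.0])
        with pytest.warns(UserWarning, match="blank"):
            out = blank_subtract(t)
        assert out.data.equals(t.data)


class TestBlankRatioFilter:
    def test_boundary_is_inclusive(self):
        t = make_peak_table(
            {"weak": {"isoA": [900.0, 900.0]}, "edge": {"isoA": [1000.0, 1000.0]},
             "clean": {"isoA": [50.0, 50.0]}},
            control_values={"weak": [10.0, 10.0], "edge": [10.0, 10.0], "clean": [50.0, 50.0]},
            blank_values={"weak": [100.0, 100.0], "edge": [100.0, 100.0], "clean": [0.0, 0.0]},
        )
        with pytest.warns(UserWarning, match="weak"):
            out = blank_ratio_filter(t, ratio=10.0)
        assert list(out.data.index) == ["edge", "clean"]  # 900 < 10x100 removed; 1000 kept; blank 0 kept


class TestNormalize:
    def test_control_max_set_to_100(self):
        t = make_peak_table(
            {"m": {"isoA": [500.0, 500.0, 500.0]}},
            control_values={"m": [1500.0, 2000.0, 1800.0]},
        )
        norm = normalize(t)
        assert sorted(norm.data.loc["m", norm.control_columns]) == [75.0, 90.0, 100.0]
        assert np.allclose(norm.data.loc["m", ["isoA_r1", "isoA_r2", "isoA_r3"]], 25.0)

    def test_all_zero_feature_masked_not_divided(self):
        t = make_peak_table(
            {"zero": {"isoA": [5.0, 5.0]}, "ok": {"isoA": [5.0, 5.0]}},
            control_values={"zero": [0.0, 0.0], "ok": [10.0, 10.0]},
        )
        norm = normalize(t)
        assert bool(norm.masked["zero"]) and not bool(norm.masked["ok"])
        assert np.allclose(norm.data.loc["zero"], t.data.loc["zero"])  # untouched

    def test_normalize_is_idempotent(self):
        rng = np.random.default_rng(0)
        from conftest import random_peak_table

        t = random_peak_table(rng)
        once = normalize(t)
        twice = normalize(
            type(t)(data=once.data, samples=once.samples, quant_type=once.quant_type)
        )
        assert np.allclose(once.data.to_numpy(), twice.data.to_numpy())


@settings(max_examples=120, derandomize=True, deadline=None)
@given(
    seed=st.integers(0, 10_000),
    scale=st.floats(1e-3, 1e6, allow_nan=False, allow_infinity=False),
)
def test_scale_invariance_of_normalization_and_calls(seed, scale):
    """Scaling a feature's raw row leaves its normalized row, fold changes
    and utilization calls unchanged."""
    rng = np.random.default_rng(seed)
    from conftest import random_peak_table

    t = random_peak_table(rng, n_met=4, n_iso=2)
    t2 = type(t)(data=t.data.copy(), samples=t.samples, quant_type=None)
    t2.data.iloc[0] = t2.data.iloc[0] * scale
    n1, n2 = normalize(t), normalize(t2)
    assert np.allclose(n1.data.to_numpy(), n2.data.to_numpy(), rtol=1e-9)
    f1, f2 = fold_change(n1), fold_change(n2)
    assert np.allclose(f1.log2.to_numpy(), f2.log2.to_numpy(), rtol=1e-9, atol=1e-12)
    c1 = depletion_test(n1).calls
    c2 = depletion_test(n2).calls
    assert c1.equals(c2)


class TestFoldChange:
    def test_quarter_abundance_is_minus_two(self):
        t = make_peak_table(
            {"m": {"isoA": [25.0, 25.0, 25.0]}}, control_values={"m": [100.0, 100.0, 100.0]}
        )
        fc = fold_change(normalize(t))
        assert fc.log2.loc["m", "isoA"] == pytest.approx(-2.0)

    def test_equal_means_give_exact_zero(self):
        t = make_peak_table(
            {"m": {"isoA": [90.0, 110.0]}}, control_values={"m": [80.0, 120.0]}
        )
        fc = fold_change(normalize(t))
        assert fc.log2.loc["m", "isoA"] == 0.0

    def test_floor_applied_to_fully_depleted(self):
        t = make_peak_table(
            {"gone": {"isoA": [0.0, 0.0, 0.0]}, "half": {"isoA": [50.0, 50.0, 50.0]}},
            control_values={"gone": [100.0] * 3, "half": [100.0] * 3},
        )
        fc = fold_change(normalize(t))
        # floor = half the smallest nonzero normalized value (50) = 25
        assert fc.floor == pytest.approx(25.0)
        assert fc.log2.loc["gone", "isoA"] == pytest.approx(np.log2(25.0 / 100.0))


class TestDepletionTest:
    def test_complete_separation_n3_is_significant_only_approximately(self):
        """At n=3 vs 3 the normal-approximation two-sided p is ~0.0495 while
        the exact rank-sum distribution cannot go below 0.10."""
        z, p = ranksum_z(np.array([1.0, 2.0, 3.0]), np.array([10.0, 11.0, 12.0]))
        assert p == pytest.approx(0.0495, abs=5e-4)
        exact = stats.mannwhitneyu(
            [1.0, 2.0, 3.0], [10.0, 11.0, 12.0], method="exact", alternative="two-sided"
        ).pvalue
        assert exact == pytest.approx(0.10, abs=1e-12)

    def test_matches_scipy_ranksums_including_ties(self):
        rng = np.random.default_rng(1)
        for n1, n2 in [(3, 3), (3, 18), (5, 5), (4, 9)]:
            for _ in range(25):
                x, y = rng.normal(size=n1), rng.normal(size=n2)
                if rng.random() < 0.4:
                    y[: min(2, n2)] = x[0]  # midrank ties across groups
                z, p = ranksum_z(x, y)
                ref = stats.ranksums(x, y)
                assert z == pytest.approx(ref.statistic, abs=1e-12)
                assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_depleted_and_produced_directions(self):
        t = make_peak_table(
            {"down": {"isoA": [1.0, 2.0, 3.0]}, "up": {"isoA": [201.0, 202.0, 203.0]}},
            control_values={"down": [100.0, 101.0, 102.0], "up": [100.0, 101.0, 102.0]},
        )
        calls = depletion_test(normalize(t), alpha=0.05)
        assert calls.calls.loc["down", "isoA"] == CALL_DEPLETED
        assert calls.calls.loc["up", "isoA"] == CALL_PRODUCED

    def test_identical_values_unchanged_with_p_one(self):
        t = make_peak_table(
            {"m": {"isoA": [100.0, 100.0, 100.0]}}, control_values={"m": [100.0] * 3}
        )
        calls = depletion_test(normalize(t))
        assert calls.calls.loc["m", "isoA"] == CALL_UNCHANGED
        assert calls.pvalues.loc["m", "isoA"] == pytest.approx(1.0)

    def test_calls_partition_and_direction_consistency(self):
        rng = np.random.default_rng(7)
        from conftest import random_peak_table

        t = random_peak_table(rng, n_met=12, n_iso=4, n_rep=3, n_ctrl=5)
        norm = normalize(t)
        calls = depletion_test(norm)
        fc = fold_change(norm)
        n_total = (
            count_significant(calls, CALL_DEPLETED)
            + count_significant(calls, CALL_PRODUCED)
            + count_significant(calls, CALL_UNCHANGED)
        )
        assert (n_total == (~norm.masked).sum()).all()
        for iso in calls.calls.columns:
            dep = calls.calls[iso] == CALL_DEPLETED
            pro = calls.calls[iso] == CALL_PRODUCED
            assert (fc.log2.loc[dep, iso] < 0).all()
            assert (fc.log2.loc[pro, iso] > 0).all()

    def test_single_replicate_isolate_masked(self):
        t = make_peak_table(
            {"m": {"solo": [10.0], "ok": [10.0, 11.0, 12.0]}},
            control_values={"m": [100.0] * 3},
        )
        with pytest.warns(UserWarning, match="solo"):
            calls = depletion_test(normalize(t))
        assert calls.calls.loc["m", "solo"] is np.nan or calls.calls.isna().loc["m", "solo"]


class TestClustering:
    def test_identical_profiles_zero_disjoint_profiles_one(self):
        import pandas as pd

        m = pd.DataFrame(
            {"a": [1.0, 2.0, 0.0, 0.0], "b": [1.0, 2.0, 0.0, 0.0], "c": [0.0, 0.0, 3.0, 4.0]}
        )
        res = cluster_profiles(m)
        assert res.distance.loc["a", "b"] == pytest.approx(0.0)
        assert res.distance.loc["a", "c"] == pytest.approx(1.0)

    def test_well_separated_pairs_join_first(self):
        import pandas as pd

        m = pd.DataFrame(
            {
                "a1": [10.0, 11.0, 0.1, 0.2], "a2": [10.5, 10.8, 0.15, 0.1],
                "b1": [0.1, 0.2, 10.0, 11.0], "b2": [0.2, 0.1, 10.2, 10.9],
            }
        )
        res = cluster_profiles(m)
        # brute-force check: the two smallest dissimilarities are the pairs
        tri = res.distance.where(np.triu(np.ones(res.distance.shape, bool), 1))
        best = tri.stack().nsmallest(2)
        assert {frozenset(k) for k in best.index} == {
            frozenset({"a1", "a2"}), frozenset({"b1", "b2"}),
        }
        first_merges = res.linkage[:2, :2].astype(int)
        labels = list(m.columns)
        merged = {frozenset(labels[i] for i in row) for row in first_merges}
        assert merged == {frozenset({"a1", "a2"}), frozenset({"b1", "b2"})}

    def test_negative_input_rejected_with_guidance(self):
        import pandas as pd

        m = pd.DataFrame({"a": [-1.0, 2.0], "b": [1.0, 2.0]})
        with pytest.raises(ValueError, match="normalized"):
            cluster_profiles(m)

    def test_newick_parses_with_all_leaves(self):
        import pandas as pd

        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.uniform(0, 100, (6, 5)), columns=[f"i{k}" for k in range(5)])
        res = cluster_profiles(m)
        tree = dendropy.Tree.get(data=res.newick, schema="newick", preserve_underscores=True)
        assert sorted(l.taxon.label for l in tree.leaf_node_iter()) == sorted(m.columns)


@settings(max_examples=120, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10_000), n=st.integers(2, 6), m=st.integers(2, 8))
def test_braycurtis_bounds_symmetry_zero_diagonal(seed, n, m):
    import pandas as pd

    rng = np.random.default_rng(seed)
    mat = pd.DataFrame(rng.uniform(0, 100, (m, n)), columns=[f"i{k}" for k in range(n)])
    d = cluster_profiles(mat).distance.to_numpy()
    assert (d >= -1e-12).all() and (d <= 1 + 1e-12).all()
    assert np.allclose(d, d.T)
    assert np.allclose(np.diag(d), 0.0)


def test_mean_profiles_are_nonnegative_and_control_scaled(toy_peaks):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t = blank_subtract(toy_peaks)
    norm = normalize(t)
    means = isolate_mean_profiles(norm)
    assert (means.to_numpy() >= 0).all()
    assert set(means.columns) == {"iso_1", "iso_2"}
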