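"""Proportions, exact binomial intervals, inverse-degree weighted estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.proportion import proportion_confint

from rdscompare import (
    clopper_pearson_ci,
    proportion,
    rds_weighted_ci,
    rds_weighted_proportion,
    rds_weights,
    weighted_mean_se,
)
from rdscompare.errors import (
    ClusteringError,
    CompletenessError,
    InputError,
    WeightError,
)


class TestProportion:
    @pytest.mark.parametrize(
        "x,n,expected",
        [(49, 374, 13.1), (0, 50, 0.0), (82, 400, 20.5), (247, 400, 61.8)],
    )
    def test_printed_values(self, x, n, expected):
        assert proportion(x, n) == pytest.approx(expected, abs=0.05)

    def test_zero_denominator(self):
        with pytest.raises(InputError):
            proportion(0, 0)

    def test_numerator_bounds(self):
        with pytest.raises(InputError):
            proportion(5, 4)


class TestClopperPearson:
    @pytest.mark.parametrize(
        "x,n,lo,hi",
        [
            (32, 49, 50.4, 78.3),
            (247, 400, 56.8, 66.5),
            (14, 49, 16.6, 43.3),
            (82, 400, 16.6, 24.8),
        ],
    )
    def test_printed_intervals(self, x, n, lo, hi):
        got = clopper_pearson_ci(x, n)
        assert got[0] == pytest.approx(lo, abs=0.05)
        assert got[1] == pytest.approx(hi, abs=0.05)

    def test_boundary_closed_forms(self):
        # x=0: upper = 100 (1 - (alpha/2)^(1/n)); x=n: lower mirrors it
        lo, hi = clopper_pearson_ci(0, 10)
        assert lo == 0.0
        assert hi == pytest.approx(100 * (1 - 0.025 ** (1 / 10)), abs=1e-9)
        lo, hi = clopper_pearson_ci(49, 49)
        assert hi == 100.0
        assert lo == pytest.approx(100 * 0.025 ** (1 / 49), abs=1e-9)

    @pytest.mark.parametrize("x,n", [(0, 7), (3, 7), (7, 7), (12, 49), (200, 400)])
    def test_matches_independent_implementation(self, x, n):
        lo, hi = clopper_pearson_ci(x, n)
        ref_lo, ref_hi = proportion_confint(x, n, alpha=0.05, method="beta")
        assert lo == pytest.approx(100 * ref_lo, abs=1e-9)
        assert hi == pytest.approx(100 * ref_hi, abs=1e-9)

    def test_interval_contains_point_estimate(self):
        for n in (5, 49, 400):
            for x in range(n + 1):
                lo, hi = clopper_pearson_ci(x, n)
                assert lo <= proportion(x, n) <= hi

    def test_invalid_level(self):
        with pytest.raises(InputError):
            clopper_pearson_ci(1, 10, level=1.5)


class TestWeights:
    def test_equal_degrees_give_equal_weights(self):
        wv = rds_weights({"a": 2, "b": 2, "c": 2})
        assert all(w == pytest.approx(1 / 3) for w in wv.weights.values())

    def test_inverse_proportionality(self):
        wv = rds_weights({"a": 1, "b": 3})
        assert wv.weights["a"] == pytest.approx(0.75)
        assert wv.weights["b"] == pytest.approx(0.25)

    def test_invalid_degree_names_participant(self):
        with pytest.raises(WeightError, match="bad"):
            rds_weights({"ok": 2, "bad": 0})

    def test_weights_normalised(self):
        wv = rds_weights({f"p{i}": i + 1 for i in range(40)})
        assert sum(wv.weights.values()) == pytest.approx(1.0, abs=1e-12)

    def test_degree_cap(self):
        capped = rds_weights({"a": 1, "b": 1000}, cap=10)
        assert capped.weights["b"] == pytest.approx((1 / 10) / (1 + 1 / 10))


class TestWeightedProportion:
    def test_equal_degrees_reduce_to_unweighted_bitwise(self):
        wv = rds_weights({"a": 5, "b": 5, "c": 5})
        est = rds_weighted_proportion({"a": "A", "b": "A", "c": "B"}, wv)
        assert est["A"].estimate == proportion(2, 3)
        assert est["B"].estimate == proportion(1, 3)

    def test_hand_computed_inverse_degree_ratio(self):
        # degrees (1, 3): P(A) = (1/1) / (1/1 + 1/3) = 0.75
        wv = rds_weights({"a": 1, "b": 3})
        est = rds_weighted_proportion({"a": "A", "b": "B"}, wv)
        assert est["A"].estimate == pytest.approx(75.0)

    def test_degenerate_single_category(self):
        wv = rds_weights({"a": 1, "b": 4})
        est = rds_weighted_proportion({"a": "A", "b": "A"}, wv)
        assert est["A"].estimate == pytest.approx(100.0)

    def test_estimates_sum_to_100(self):
        rng = np.random.default_rng(5)
        wv = rds_weights({f"p{i}": int(d) for i, d in
                          enumerate(rng.integers(1, 30, size=200))})
        values = {f"p{i}": "abc"[int(rng.integers(3))] for i in range(200)}
        est = rds_weighted_proportion(values, wv)
        assert sum(e.estimate for e in est.values()) == pytest.approx(100.0)

    def test_missing_value_is_completeness_error(self):
        wv = rds_weights({"a": 1, "b": 3})
        with pytest.raises(CompletenessError):
            rds_weighted_proportion({"a": "A"}, wv)


@settings(derandomize=True, max_examples=150)
@given(
    st.lists(
        st.tuples(st.integers(1, 500), st.sampled_from("ABC")),
        min_size=1,
        max_size=60,
    )
)
def test_weighted_prevalences_partition_unity(items):
    """For any degrees and category labels, the weighted prevalences are
    within [0, 100] each and sum to 100 over categories."""
    degrees = {f"p{i}": d for i, (d, _) in enumerate(items)}
    values = {f"p{i}": c for i, (_, c) in enumerate(items)}
    est = rds_weighted_proportion(values, rds_weights(degrees))
    assert sum(e.estimate for e in est.values()) == pytest.approx(100.0)
    for e in est.values():
        assert 0.0 <= e.estimate <= 100.0
        assert e.x <= e.n


@settings(derandomize=True, max_examples=100)
@given(st.integers(1, 400).flatmap(
    lambda n: st.tuples(st.just(n), st.integers(0, n))))
def test_exact_interval_always_brackets_the_proportion(xn):
    n, x = xn
    lo, hi = clopper_pearson_ci(x, n)
    assert lo <= proportion(x, n) <= hi
    assert 0.0 <= lo and hi <= 100.0


class TestWeightedCI:
    def _balanced(self, n, rng, p=0.4):
        # equal degrees, chains of two, Bernoulli(p) values
        degrees = {f"p{i}": 4 for i in range(n)}
        chains = {f"p{i}": f"c{i // 2}" for i in range(n)}
        values = {f"p{i}": "A" if rng.random() < p else "B" for i in range(n)}
        return rds_weights(degrees, chains), values

    def test_approaches_wald_interval_under_srs(self):
        rng = np.random.default_rng(11)
        wv, values = self._balanced(1000, rng)
        est = rds_weighted_ci(values, wv)["A"]
        p = est.estimate / 100
        half = 1.959963984540054 * np.sqrt(p * (1 - p) / 1000)
        assert est.ci_low == pytest.approx(100 * (p - half), abs=0.5)
        assert est.ci_high == pytest.approx(100 * (p + half), abs=0.5)

    def test_zero_prevalence_interval_pinned_at_zero(self):
        wv = rds_weights({"a": 2, "b": 2, "c": 2, "d": 2},
                         {"a": "c1", "b": "c1", "c": "c2", "d": "c2"})
        est = rds_weighted_ci({k: "B" for k in "abcd"}, wv)
        assert "A" not in est
        assert est["B"].ci_low == est["B"].ci_high == pytest.approx(100.0)

    def test_identical_chains_contribute_zero_between_cluster_variance(self):
        wv = rds_weights({"a1": 2, "a2": 4, "b1": 2, "b2": 4},
                         {"a1": "c1", "a2": "c1", "b1": "c2", "b2": "c2"})
        est = rds_weighted_ci({"a1": "A", "a2": "B", "b1": "A", "b2": "B"}, wv)
        assert est["A"].se == pytest.approx(0.0, abs=1e-12)
        assert est["A"].ci_low == est["A"].ci_high == est["A"].estimate

    def test_single_chain_rejected(self):
        wv = rds_weights({"a": 1, "b": 2}, {"a": "c1", "b": "c1"})
        with pytest.raises(ClusteringError):
            rds_weighted_ci({"a": "A", "b": "B"}, wv)

    def test_singleton_chain_rejected(self):
        wv = rds_weights({"a": 1, "b": 2, "c": 2},
                         {"a": "c1", "b": "c1", "c": "c2"})
        with pytest.raises(ClusteringError, match="single"):
            rds_weighted_ci({"a": "A", "b": "B", "c": "A"}, wv)

    def test_interval_ordering_and_range(self):
        rng = np.random.default_rng(3)
        wv, values = self._balanced(60, rng, p=0.2)
        for est in rds_weighted_ci(values, wv).values():
            assert 0 <= est.ci_low <= est.estimate <= est.ci_high <= 100


class TestWeightedMean:
    def test_equal_weights_reduce_to_arithmetic_mean(self):
        wv = rds_weights({"a": 2, "b": 2, "c": 2})
        mean, se = weighted_mean_se({"a": 1.0, "b": 2.0, "c": 6.0}, wv)
        assert mean == pytest.approx(3.0)
        assert se == pytest.approx(np.std([1, 2, 6], ddof=1) / np.sqrt(3))

    def test_hand_computed_weighted_mean(self):
        wv = rds_weights({"a": 1, "b": 3})
        mean, _ = weighted_mean_se({"a": 10.0, "b": 30.0}, wv)
        assert mean == pytest.approx(15.0)

    def test_constant_values_have_zero_se(self):
        wv = rds_weights({"a": 1, "b": 5, "c": 2})
        _, se = weighted_mean_se({k: 7.0 for k in "abc"}, wv)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_empty_input_rejected(self):
        from rdscompare import WeightVector

        with pytest.raises(InputError):
            weighted_mean_se({}, WeightVector({}))
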