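"""Class comparison, overlap metric, concordance and sample-size formula."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lungsig import (
    class_comparison,
    concordance_table,
    overlap_percent,
    required_sample_size,
)


def two_group_matrix(case_rows, ctrl_rows, features=None):
    case = np.atleast_2d(case_rows)
    ctrl = np.atleast_2d(ctrl_rows)
    values = np.hstack([case, ctrl])
    cols = [f"c{j}" for j in range(case.shape[1])] + [
        f"k{j}" for j in range(ctrl.shape[1])
    ]
    matrix = pd.DataFrame(values, columns=cols, index=features)
    labels = pd.Series(["case"] * case.shape[1] + ["control"] * ctrl.shape[1],
                       index=cols)
    return matrix, labels


class TestClassComparison:
    def test_identical_groups_not_significant(self):
        matrix, labels = two_group_matrix([[1.0, 2, 3]], [[1.0, 2, 3]])
        res = class_comparison(matrix, labels, alpha=0.05)
        assert res.table["t"].iloc[0] == 0
        assert res.table["p"].iloc[0] == pytest.approx(1.0)
        assert res.significant == []

    def test_pooled_t_against_numerical_cdf_oracle(self):
        matrix, labels = two_group_matrix([[2.0, 2.2, 1.8]], [[3.0, 3.2, 2.8]])
        res = class_comparison(matrix, labels)
        t = res.table["t"].iloc[0]
        assert t == pytest.approx(-6.1237, abs=1e-4)
        assert res.table["df"].iloc[0] == 4
        assert res.table["p"].iloc[0] == pytest.approx(
            2 * stats.t.cdf(t, 4), rel=1e-9
        )
        assert res.table["p"].iloc[0] == pytest.approx(0.0036, abs=2e-4)

    def test_zero_pooled_variance_reports_na_and_is_excluded(self):
        matrix, labels = two_group_matrix([[1.0, 1.0]], [[2.0, 2.0]])
        res = class_comparison(matrix, labels, alpha=0.5)
        assert np.isnan(res.table["p"].iloc[0])
        assert res.significant == []

    def test_group_of_one_rejected(self):
        matrix, labels = two_group_matrix([[1.0]], [[2.0, 3.0]])
        with pytest.raises(ValueError, match=">= 2 arrays"):
            class_comparison(matrix, labels)

    def test_welch_switch_changes_df(self):
        rng = np.random.default_rng(0)
        matrix, labels = two_group_matrix(rng.normal(0, 1, (1, 10)),
                                          rng.normal(0, 5, (1, 4)))
        pooled = class_comparison(matrix, labels)
        welch = class_comparison(matrix, labels, equal_var=False)
        assert welch.table["df"].iloc[0] < pooled.table["df"].iloc[0]

    def test_null_pvalues_uniform(self):
        """Under exchangeable groups the p-value distribution is uniform
        (KS test across features, several seeds)."""
        ok = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            matrix, labels = two_group_matrix(
                rng.normal(8, 1, (400, 10)), rng.normal(8, 1, (400, 10))
            )
            p = class_comparison(matrix, labels).table["p"].dropna()
            ok += stats.kstest(p, "uniform").pvalue > 0.01
        assert ok >= 9


class TestOverlapPercent:
    def test_printed_single_run_worked_example(self):
        a = [f"f{i}" for i in range(340)]
        b = [f"f{i}" for i in range(22, 22 + 318)] + [f"g{i}" for i in range(74)]
        assert len(set(a) & set(b)) == 318 and len(b) == 392
        assert overlap_percent(a, b) == 76.8

    def test_cross_run_sizes_give_56_4(self):
        a = set(range(273))
        b = set(range(256)) | {f"x{i}" for i in range(181)}
        assert overlap_percent(a, b) == 56.4

    def test_equal_nonempty_sets_give_100(self):
        assert overlap_percent({"a", "b"}, {"b", "a"}) == 100.0

    def test_both_empty_defined_as_zero(self):
        assert overlap_percent([], []) == 0.0

    @given(st.sets(st.integers(0, 50)), st.sets(st.integers(0, 50)))
    @settings(deadline=None, max_examples=100)
    def test_symmetric_and_bounded(self, a, b):
        o = overlap_percent(a, b)
        assert o == overlap_percent(b, a)
        assert 0.0 <= o <= 100.0

    def test_monotone_in_intersection_at_fixed_sizes(self):
        base = set(range(10))
        overlaps = [
            overlap_percent(base, set(range(k)) | set(range(100, 110 - k)))
            for k in range(11)
        ]
        assert overlaps == sorted(overlaps)


class TestConcordance:
    def test_identical_lists_give_100(self, ordering_sim):
        matrix = ordering_sim["combat"]
        ann = ordering_sim["annotation"]
        rep = concordance_table({"m1": matrix, "m2": matrix}, ann)
        pd.testing.assert_frame_equal(
            rep.overlap.loc[["m1"]].rename(index={"m1": "m2"}),
            rep.overlap.loc[["m2"]],
        )
        assert rep.method_pairwise["SCLC_single"]["m1|m2"] == 100.0

    def test_empty_lists_reported_as_zero_with_note(self):
        rng = np.random.default_rng(1)
        from lungsig import SimulationConfig, preprocess_spot_table, simulate_dataset

        cfg = SimulationConfig(n_features=40, frac_reactive=0.0,
                               batch_add_sd=0.0, batch_mult_shape=None,
                               session_shift=0.0, missing_rate=0.0, seed=5)
        spots, ann, _ = simulate_dataset(cfg)
        matrix, _ = preprocess_spot_table(spots)
        rep = concordance_table({"null": matrix}, ann)
        assert (rep.overlap.loc["null"] == 0.0).all()
        assert any("empty lists" in n for n in rep.notes)

    def test_mismatched_feature_sets_rejected(self, ordering_sim):
        matrix = ordering_sim["matrix"]
        with pytest.raises(ValueError, match="feature set"):
            concordance_table(
                {"a": matrix, "b": matrix.iloc[:-1]}, ordering_sim["annotation"]
            )


class TestSampleSize:
    def test_printed_median_variance_gives_21_per_class(self):
        assert required_sample_size(sigma=0.414) == 21

    def test_class_difference_is_log2_of_fold_change_1_5(self):
        assert round(np.log2(1.5), 3) == 0.585

    def test_doubling_delta_shrinks_n_fourfold(self):
        n1 = required_sample_size(sigma=1.0, delta_log2=0.5)
        n4 = required_sample_size(sigma=1.0, delta_log2=1.0)
        assert n1 / n4 == pytest.approx(4.0, rel=0.1)

    def test_huge_effect_hits_the_floor(self):
        assert required_sample_size(sigma=0.1, delta_log2=50.0) == 2

    def test_matches_numeric_inversion_oracle(self):
        """n is the smallest integer whose normal-approximation power
        reaches the target."""
        sigma, delta, alpha, power = 0.414, 0.585, 0.001, 0.9
        n = required_sample_size(sigma=sigma)
        from scipy.stats import norm

        def approx_power(n):
            ncp = delta / (sigma * np.sqrt(2.0 / n))
            crit = norm.ppf(1 - alpha / 2)
            return norm.sf(crit - ncp)

        assert approx_power(n) >= power
        assert approx_power(n - 1) < power

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            required_sample_size(sigma=0.0)
        with pytest.raises(ValueError):
            required_sample_size(sigma=1.0, power=1.5)
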