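"""Accuracy calibration, ICC, group comparisons, LS means, power, Spearman."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bonemicrokit import (
    PowerSpec,
    accuracy_calibration,
    adjusted_lsmeans,
    icc_oneway,
    spearman_assoc,
    ttest_power,
    unadjusted_group_compare,
)
from bonemicrokit import reference_data as ref
from bonemicrokit.phantoms import simulate_measure_table, simulate_replicates
from bonemicrokit.statsval import (
    DegenerateDataError,
    compare_measures,
    effect_size_from_summaries,
)
from bonemicrokit.volume import ConfigurationError


class TestAccuracyCalibration:
    def test_perfect_line_recovered(self):
        x = np.arange(10.0)
        y = 3.0 * x - 2.0
        res = accuracy_calibration(x, y)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(3.0) and res.intercept == pytest.approx(-2.0)

    def test_published_line_maps_ct_mean_to_reference_mean(self):
        # the OLS centroid identity exercised against the published
        # accuracy-study rows: intercept + slope * (CT mean) = reference mean
        row = ref.ACCURACY_TABLE.loc["tb_th"]
        pred = row.intercept + row.slope * row.ct_mean
        assert round(pred, 1) == row.ref_mean  # 124.6 um
        row = ref.ACCURACY_TABLE.loc["tb_na"]
        assert round(row.intercept + row.slope * row.ct_mean, 2) == row.ref_mean  # 0.72

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=50)
        y = 2 * x + rng.normal(size=50)
        res = accuracy_calibration(x, y)
        n = len(x)
        slope = (n * (x * y).sum() - x.sum() * y.sum()) / (n * (x * x).sum() - x.sum() ** 2)
        intercept = y.mean() - slope * x.mean()
        assert res.slope == pytest.approx(slope, abs=1e-9)
        assert res.intercept == pytest.approx(intercept, abs=1e-9)
        assert res.predict(x.mean()) == pytest.approx(y.mean(), abs=1e-9)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateDataError):
            accuracy_calibration(np.ones(5), np.arange(5.0))


class TestIcc:
    def test_identical_replicates_give_one(self):
        v = np.tile(np.arange(10.0)[:, None], (1, 3))
        assert icc_oneway(v).icc == 1.0

    def test_parameter_recovery(self):
        v = simulate_replicates(200, 3, var_between=0.8, var_within=0.2, seed=4)
        res = icc_oneway(v)
        assert res.icc == pytest.approx(0.8, abs=0.05)
        assert res.ci_low <= res.icc <= res.ci_high

    def test_null_data_near_zero(self):
        v = simulate_replicates(200, 3, var_between=0.0, var_within=1.0, seed=5)
        res = icc_oneway(v)
        assert res.ci_low <= 0.0 <= res.ci_high or abs(res.icc) < 0.1

    def test_shift_and_scale_invariance(self):
        v = simulate_replicates(50, 3, 0.7, 0.3, seed=6)
        base = icc_oneway(v).icc
        assert icc_oneway(v + 100.0).icc == pytest.approx(base, abs=1e-12)
        assert icc_oneway(v * 3.0).icc == pytest.approx(base, abs=1e-12)

    def test_constant_data_raises(self):
        with pytest.raises(DegenerateDataError):
            icc_oneway(np.ones((5, 3)))


class TestGroupComparison:
    def test_published_effect_sizes_recomputed(self):
        # Cohen's d from printed mean differences and pooled SDs
        t = ref.GROUP_COMPARISON_TABLE
        for meas, printed in [("tb_vbmd", 1.25), ("tb_tbmd", 1.39),
                              ("tb_pw", 1.22), ("tb_sp", -1.03)]:
            d = effect_size_from_summaries(t.loc[meas, "mean_difference"],
                                           t.loc[meas, "pooled_sd"])
            assert round(d, 2) == printed

    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0])
        res = unadjusted_group_compare(a, a.copy())
        assert res.mean_difference == 0.0 and res.effect_size == 0.0
        assert res.t_p_value == pytest.approx(1.0)

    def test_hand_computed_small_case(self):
        res = unadjusted_group_compare([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        # pooled sd = 1, se = sqrt(2/3), t = -3/se
        t_exp = -3.0 / np.sqrt(2.0 / 3.0)
        p_exp = 2 * stats.t.sf(abs(t_exp), df=4)
        assert res.pooled_sd == pytest.approx(1.0)
        assert res.effect_size == pytest.approx(-3.0)
        assert res.t_p_value == pytest.approx(p_exp, abs=1e-12)

    def test_table_level_wrapper(self):
        df = simulate_measure_table(10, 12, effect_size=1.0, seed=3)
        out = compare_measures(df, group="group", measures=("tb_vbmd",))
        assert len(out) == 1
        assert out.loc[0, "effect_size"] == pytest.approx(
            out.loc[0, "mean_difference"] / out.loc[0, "pooled_sd"]
        )


class TestAdjustedLsMeans:
    def test_balanced_covariate_equals_raw_means(self):
        rng = np.random.default_rng(12)
        rows = []
        for g in ("a", "b"):
            for cov in (0, 1):
                for i in range(10):
                    rows.append({"group": g, "covariate": cov,
                                 "value": rng.normal(5 if g == "a" else 3)})
        df = pd.DataFrame(rows)
        res = adjusted_lsmeans(df, "value", "group", ["covariate"])
        raw_a = df.loc[df.group == "a", "value"].mean()
        raw_b = df.loc[df.group == "b", "value"].mean()
        assert res.ls_mean_a == pytest.approx(raw_a, abs=1e-9)
        assert res.ls_mean_b == pytest.approx(raw_b, abs=1e-9)

    def test_recovers_generator_effect(self):
        df = simulate_measure_table(60, 60, effect_size=10.0, covariate_effect=5.0,
                                    covariate_imbalance=0.4, sd=1.0, seed=13)
        res = adjusted_lsmeans(df, "value", "group", ["covariate"])
        # groups sorted: a - b; generator puts +10 sd on group a
        assert res.ls_mean_difference == pytest.approx(10.0, abs=0.5)
        assert res.effect_size == pytest.approx(res.ls_mean_difference / np.sqrt(res.mse))

    def test_without_covariate_matches_unadjusted(self):
        df = simulate_measure_table(15, 20, effect_size=1.0, seed=14)
        res = adjusted_lsmeans(df, "value", "group", [])
        a = df.loc[df.group == "a", "value"].to_numpy()
        b = df.loc[df.group == "b", "value"].to_numpy()
        gc = unadjusted_group_compare(a, b)
        assert res.ls_mean_difference == pytest.approx(gc.mean_difference, abs=1e-9)
        assert res.t_p_value == pytest.approx(gc.t_p_value, abs=1e-9)


class TestPower:
    def test_null_effect_gives_alpha(self):
        assert ttest_power(PowerSpec(0.0, 9, 21)) == pytest.approx(0.05, abs=1e-9)

    def test_published_powers(self):
        assert round(ttest_power(PowerSpec(1.0, 9, 21)), 2) == 0.68
        assert round(ttest_power(PowerSpec(1.10, 9, 21)), 2) == 0.76

    def test_monotone_in_effect_and_n(self):
        p = [ttest_power(PowerSpec(d, 9, 21)) for d in (0.5, 1.0, 1.5)]
        assert p[0] < p[1] < p[2]
        q = [ttest_power(PowerSpec(1.0, n, n)) for n in (5, 10, 20)]
        assert q[0] < q[1] < q[2]

    def test_threshold_ordering_at_published_design(self):
        # 1.15 is the smallest tabulated effect size with power above 0.8
        assert ttest_power(PowerSpec(1.15, 9, 21)) > ttest_power(PowerSpec(1.10, 9, 21))
        assert ttest_power(PowerSpec(1.15, 9, 21)) > 0.78


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.arange(10.0)
        assert spearman_assoc(x, np.exp(x)) == pytest.approx(1.0)
        assert spearman_assoc(x, -np.exp(x)) == pytest.approx(-1.0)

    def test_tied_example_matches_rank_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0])
        y = np.array([10.0, 20.0, 25.0, 20.0])
        # average ranks: x -> [1, 2.5, 2.5, 4]; y -> [1, 2.5, 4, 2.5]
        rx = np.array([1, 2.5, 2.5, 4])
        ry = np.array([1, 2.5, 4, 2.5])
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman_assoc(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_constant_raises(self):
        with pytest.raises(DegenerateDataError):
            spearman_assoc(np.ones(5), np.arange(5.0))


class TestIccTwoWay:
    def test_twoway_close_to_oneway_without_occasion_effect(self):
        v = simulate_replicates(100, 3, 0.8, 0.2, seed=31)
        one = icc_oneway(v)
        two = icc_oneway(v, model="twoway_random")
        assert two.model == "twoway_random"
        assert two.icc == pytest.approx(one.icc, abs=0.05)

    def test_unknown_model_rejected(self):
        v = simulate_replicates(10, 3, 0.5, 0.5, seed=32)
        with pytest.raises(ConfigurationError):
            icc_oneway(v, model="threeway")
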