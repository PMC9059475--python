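"""Group statistics, fold changes, report assembly."""

import numpy as np
import pytest

from osteomech import stats
from osteomech.errors import (
    ConfigurationError,
    DataError,
    InsufficientDataError,
    UndefinedMetricError,
)


class TestPercentDifference:
    def test_reported_load_contrast(self):
        assert stats.percent_difference(27.0, 18.0) == pytest.approx(50.0)

    def test_reported_strain_contrast(self):
        assert round(stats.percent_difference(0.57, 0.44), 1) == 29.5

    def test_identity(self):
        assert stats.percent_difference(3.3, 3.3) == 0.0

    def test_zero_reference_raises(self):
        with pytest.raises(UndefinedMetricError):
            stats.percent_difference(1.0, 0.0)

    def test_reciprocal_relation(self):
        d1 = stats.percent_difference(27.0, 18.0)
        d2 = stats.percent_difference(18.0, 27.0)
        assert (1 + d1 / 100) * (1 + d2 / 100) == pytest.approx(1.0)


class TestTTest:
    def test_identical_groups(self):
        t, p = stats.ttest_unpaired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_case(self):
        # x = {1,2,3}, y = {4,5,6}: pooled SD 1, SE sqrt(2/3), t = -3/0.8165
        t, p = stats.ttest_unpaired([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 8), rng.normal(1, 1, 9)
        t1, p1 = stats.ttest_unpaired(x, y)
        t2, p2 = stats.ttest_unpaired(y, x)
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)

    def test_power_on_separated_groups(self):
        # analytic power at d = 2, n = 10/10, alpha = 0.01 is ~0.94
        # (noncentral t, ncp = 2/sqrt(0.2) = 4.47); check within binomial range
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(200):
            x = rng.normal(0, 1, 10)
            y = rng.normal(2, 1, 10)
            if stats.ttest_unpaired(x, y)[1] < 0.01:
                hits += 1
        assert hits >= 175

    def test_degenerate_zero_variance(self):
        assert stats.ttest_unpaired([1.0, 1.0], [1.0, 1.0]) == (0.0, 1.0)
        t, p = stats.ttest_unpaired([1.0, 1.0], [2.0, 2.0])
        assert p == 0.0

    def test_too_small_groups_signal(self):
        with pytest.raises(InsufficientDataError):
            stats.ttest_unpaired([1.0], [2.0, 3.0])


class TestAnova:
    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 7), rng.normal(0.5, 1, 8)
        t, _ = stats.ttest_unpaired(x, y)
        f, _ = stats.anova_oneway([x, y])
        assert f == pytest.approx(t**2, rel=1e-9)

    def test_three_group_brute_force_oracle(self):
        groups = [np.array([1.0, 2, 3]), np.array([2.0, 3, 4]), np.array([6.0, 7, 8])]
        f, p = stats.anova_oneway(groups)
        allv = np.concatenate(groups)
        grand = allv.mean()
        ss_b = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_w = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_oracle = (ss_b / 2) / (ss_w / (len(allv) - 3))
        assert f == pytest.approx(f_oracle, rel=1e-12)

    def test_identical_constant_groups_degenerate(self):
        f, p = stats.anova_oneway([[1.0, 1.0], [1.0, 1.0]])
        assert p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(DataError):
            stats.anova_oneway([[1.0, 2.0]])


class TestDdct:
    def test_textbook_example(self):
        records = [
            stats.CtRecord("cal", 27.0, 20.0, "calibrator"),  # dCt 7
            stats.CtRecord("s1", 25.0, 20.0, "test"),  # dCt 5 -> ddCt -2 -> fold 4
        ]
        folds = stats.ddct_fold_change(records)
        assert folds["s1"] == pytest.approx(4.0)

    def test_sample_equal_to_calibrator(self):
        records = [
            stats.CtRecord("cal", 24.0, 20.0, "calibrator"),
            stats.CtRecord("s1", 24.0, 20.0, "test"),
        ]
        assert stats.ddct_fold_change(records)["s1"] == pytest.approx(1.0)

    def test_reference_shift_invariance(self):
        # adding a constant to all reference-gene Cts leaves folds unchanged
        base = [
            stats.CtRecord("cal", 27.0, 20.0, "calibrator"),
            stats.CtRecord("s1", 25.0, 19.0, "test"),
        ]
        shifted = [
            stats.CtRecord("cal", 27.0, 23.0, "calibrator"),
            stats.CtRecord("s1", 25.0, 22.0, "test"),
        ]
        assert stats.ddct_fold_change(base)["s1"] == pytest.approx(
            stats.ddct_fold_change(shifted)["s1"]
        )

    def test_synthetic_twofold_upregulation(self):
        rng = np.random.default_rng(4)
        records = []
        for i in range(8):
            records.append(
                stats.CtRecord(f"c{i}", 26.0 + rng.normal(0, 0.1), 20.0 + rng.normal(0, 0.1), "calibrator")
            )
        for i in range(8):
            # one cycle earlier on the target = 2x expression
            records.append(
                stats.CtRecord(f"t{i}", 25.0 + rng.normal(0, 0.1), 20.0 + rng.normal(0, 0.1), "test")
            )
        folds = stats.ddct_fold_change(records)
        mean_fold = np.mean([v for k, v in folds.items() if k.startswith("t")])
        assert mean_fold == pytest.approx(2.0, rel=0.15)

    def test_no_calibrator_rejected(self):
        with pytest.raises(ConfigurationError):
            stats.ddct_fold_change([stats.CtRecord("s", 25.0, 20.0, "test")])


class TestRatioMetric:
    def test_simple_ratio(self):
        out = stats.ratio_metric(
            stats.GroupSample("n", [2.0, 2.0, 2.0]),
            stats.GroupSample("d", [1.0, 1.0, 1.0]),
            n_boot=100,
        )
        assert out["ratio"] == pytest.approx(2.0)
        assert out["ci_low"] <= 2.0 <= out["ci_high"]

    def test_equal_groups_ratio_one(self):
        g = stats.GroupSample("g", [1.5, 2.5, 2.0])
        assert stats.ratio_metric(g, g, n_boot=50)["ratio"] == pytest.approx(1.0)

    def test_doubled_rankl_doubles_ratio(self):
        rng = np.random.default_rng(7)
        opg = rng.normal(1.0, 0.05, 10)
        wt = stats.ratio_metric(
            stats.GroupSample("rankl", rng.normal(1.0, 0.05, 10)),
            stats.GroupSample("opg", opg),
            n_boot=100,
        )["ratio"]
        ko = stats.ratio_metric(
            stats.GroupSample("rankl", rng.normal(2.0, 0.1, 10)),
            stats.GroupSample("opg", opg),
            n_boot=100,
        )["ratio"]
        assert ko / wt == pytest.approx(2.0, rel=0.15)


class TestBuildReport:
    def test_morphometry_only_report(self):
        metrics = {
            name: ([1.0, 1.1], [0.5, 0.6])
            for name in ("bvtv", "bstv", "tb_n", "tb_th", "tb_sp", "smi", "ct_th")
        }
        report = stats.build_report({"morphometry": metrics})
        assert len(report["contrasts"]) == 7
        assert all("percent_difference" in row for row in report["contrasts"])

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            stats.build_report({})
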