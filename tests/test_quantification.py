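import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from specuniq import PipelineConfig, SampleMeta, welch_t
from specuniq.quantification import (
    exclude_outliers,
    fold_changes,
    normalize_counts,
    quantify,
    significance_gate,
    welch_from_moments,
)

CFG = PipelineConfig(seed=0)


def _counts(values, samples):
    return pd.DataFrame(values, columns=samples, dtype=float)


class TestNormalize:
    def test_total_count_scales_to_grand_mean(self):
        counts = _counts([[60, 120], [40, 80]], ["s1", "s2"])  # totals 100, 200
        normed = normalize_counts(counts, "total_count")
        assert normed["s1"].sum() == pytest.approx(150)
        assert normed["s2"].sum() == pytest.approx(150)
        assert normed.loc[0, "s1"] == pytest.approx(60 * 1.5)
        assert normed.loc[0, "s2"] == pytest.approx(120 * 0.75)

    def test_none_is_identity(self):
        counts = _counts([[1, 2], [3, 4]], ["s1", "s2"])
        pd.testing.assert_frame_equal(normalize_counts(counts, "none"), counts)

    def test_equal_totals_are_untouched(self):
        counts = _counts([[5, 5], [5, 5]], ["s1", "s2"])
        pd.testing.assert_frame_equal(
            normalize_counts(counts, "total_count"), counts
        )

    def test_zero_total_sample_is_an_error(self):
        counts = _counts([[1, 0], [1, 0]], ["s1", "s2"])
        with pytest.raises(ValueError, match="zero total"):
            normalize_counts(counts, "total_count")


class TestOutliers:
    def _records(self, rng, n=200):
        """Poisson-like mean/SD pairs: SD tracks sqrt(mean)."""
        m = rng.uniform(5, 200, n)
        s = np.sqrt(m) * rng.lognormal(0, 0.1, n)
        return pd.DataFrame(
            {"log_mean": np.log10(m + 0.5), "log_sd": np.log10(s + 0.5)}
        )

    def test_inflated_variance_protein_flagged(self):
        rng = np.random.default_rng(1)
        rec = self._records(rng)
        rec.loc[0, "log_sd"] = np.log10(100 * np.sqrt(10 ** rec.loc[0, "log_mean"]))
        flags = exclude_outliers(rec, CFG)
        assert flags[0]
        assert flags[1:].sum() == 0

    def test_identical_proteins_give_no_outliers(self):
        rec = pd.DataFrame({"log_mean": [1.0] * 20, "log_sd": [0.5] * 20})
        assert not exclude_outliers(rec, CFG).any()

    def test_huge_threshold_flags_nothing(self):
        rng = np.random.default_rng(2)
        rec = self._records(rng)
        cfg = PipelineConfig(outlier_sd=1e9)
        assert not exclude_outliers(rec, cfg).any()

    def test_small_input_skips_with_warning(self):
        rec = pd.DataFrame({"log_mean": [1, 2], "log_sd": [0.1, 0.2]})
        with pytest.warns(UserWarning, match="skipped"):
            flags = exclude_outliers(rec, CFG)
        assert not flags.any()


class TestFoldChanges:
    def _rec(self, ma, mc):
        return pd.DataFrame({"mean_atrophic": [ma], "mean_cancer": [mc]})

    def test_finite_ratio_and_threshold(self):
        out = fold_changes(self._rec(2.0, 5.0), CFG)
        assert out.loc[0, "fold_change"] == pytest.approx(2.5)
        assert out.loc[0, "upregulated"]

    def test_zero_control_mean_is_infinite_and_not_upregulated(self):
        out = fold_changes(self._rec(0.0, 3.0), CFG)
        assert math.isinf(out.loc[0, "fold_change"])
        assert not out.loc[0, "upregulated"]

    def test_equal_means_not_upregulated(self):
        out = fold_changes(self._rec(4.0, 4.0), CFG)
        assert out.loc[0, "fold_change"] == pytest.approx(1.0)
        assert not out.loc[0, "upregulated"]

    def test_absent_everywhere_is_excluded(self):
        out = fold_changes(self._rec(0.0, 0.0), CFG)
        assert math.isnan(out.loc[0, "fold_change"])

    def test_raising_threshold_shrinks_upregulated_set(self):
        rng = np.random.default_rng(3)
        rec = pd.DataFrame(
            {
                "mean_atrophic": rng.uniform(0, 10, 100),
                "mean_cancer": rng.uniform(0, 10, 100),
            }
        )
        sets = []
        for fc_min in (1.2, 1.7, 2.5, 4.0):
            cfg = PipelineConfig(fold_change_min=fc_min)
            out = fold_changes(rec, cfg)
            sets.append(set(out.index[out["upregulated"]]))
        for smaller, larger in zip(sets[1:], sets):
            assert smaller <= larger

    def test_fc_invariant_to_global_scaling(self):
        rng = np.random.default_rng(4)
        rec = pd.DataFrame(
            {
                "mean_atrophic": rng.uniform(1, 10, 50),
                "mean_cancer": rng.uniform(1, 10, 50),
            }
        )
        fc1 = fold_changes(rec, CFG)["fold_change"]
        fc2 = fold_changes(rec * 7.0, CFG)["fold_change"]
        assert np.allclose(fc1, fc2)


def _meta8():
    rows = [
        ("A1", "atrophic", "none"),
        ("A2", "atrophic", "none"),
        ("A3", "atrophic", "none"),
        ("A4", "atrophic", "none"),
        ("E1", "cancer", "type1"),
        ("E2", "cancer", "type1"),
        ("S1", "cancer", "type2"),
        ("S2", "cancer", "type2"),
    ]
    return [SampleMeta(s, g, t, 60, 25) for s, g, t in rows]


class TestSignificanceGate:
    def test_planted_eightfold_shift_is_detected(self):
        """Status effect on an 8-fold shift at depth 30 is found in ≥95% of 200."""
        rng = np.random.default_rng(5)
        meta = _meta8()
        n_rep = 200
        counts = pd.DataFrame(
            np.c_[rng.poisson(30, (n_rep, 4)), rng.poisson(240, (n_rep, 4))],
            columns=[m.sample_id for m in meta],
        )
        res = significance_gate(counts, meta, CFG, method="two_way_anova")
        assert (res["p_gate"] < 0.01).mean() >= 0.95

    def test_identical_groups_give_large_p(self):
        meta = _meta8()
        counts = pd.DataFrame(
            [[10.0] * 8], columns=[m.sample_id for m in meta]
        )
        res = significance_gate(counts, meta, CFG, method="two_way_anova")
        assert res.loc[0, "p_gate"] >= 0.5
        assert res.loc[0, "gate_flagged"]

    def test_welch_gate_consistent_with_cohort_welch(self, table1_meta):
        """welch_log on a BMI-valued row equals Welch's t on the log values."""
        meta = _meta8()
        bmi = [19.0, 22.0, 26.0, 24.0, 24.0, 42.0, 38.0, 40.0]
        counts = pd.DataFrame([bmi], columns=[m.sample_id for m in meta])
        res = significance_gate(counts, meta, CFG, method="welch_log")
        y = np.log10(np.array(bmi) + CFG.pseudocount)
        expected = stats.ttest_ind(y[:4], y[4:], equal_var=False).pvalue
        assert res.loc[0, "p_gate"] == pytest.approx(expected, abs=1e-12)
        # and the shared Welch kernel reproduces the raw-value cohort test
        cohort = welch_t(table1_meta, "bmi")
        scipy_p = stats.ttest_ind(
            [19, 22, 26, 24], [24, 42, 38, 40], equal_var=False
        ).pvalue
        assert cohort.p == pytest.approx(scipy_p, abs=1e-12)


class TestWelchFromMoments:
    def test_matches_scipy(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(0, 1, 10), rng.normal(1, 2, 7)
        t, df, p = welch_from_moments(
            x.mean(), x.var(ddof=1), len(x), y.mean(), y.var(ddof=1), len(y)
        )
        ref = stats.ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)


class TestQuantifyEndToEnd:
    def test_planted_fold_recovery(self):
        """Median relative error of planted fold-3 proteins stays under 15%."""
        rng = np.random.default_rng(7)
        meta = _meta8()
        depth = 30
        n = 200
        base = rng.lognormal(0, 0.5, n)
        counts = pd.DataFrame(
            np.c_[
                rng.poisson(np.tile(depth * base, (4, 1)).T),
                rng.poisson(np.tile(3 * depth * base, (4, 1)).T),
            ],
            columns=[m.sample_id for m in meta],
            index=[f"G{i}" for i in range(n)],
        )
        quant = quantify(counts, meta, CFG)
        rel_err = np.abs(quant["fold_change"] - 3.0) / 3.0
        assert np.median(rel_err) <= 0.15
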