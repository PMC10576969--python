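"""Calibration statistics against independent closed-form oracles."""

import numpy as np
import pytest
from scipy import stats as sps

from vmescan.calibration import (
    CalibrationError,
    covariate_regression,
    derive_thresholds,
    oneway_anova,
    run_calibration_report,
    summarize_by_label,
    tukey_hsd,
)

# ---------------------------------------------------------------------------
# Independent oracles (direct summation / closed forms)
# ---------------------------------------------------------------------------

def anova_oracle(groups):
    """F and p by direct sum-of-squares summation."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = len(groups) - 1, len(all_vals) - len(groups)
    f_stat = (ssb / df_b) / (ssw / df_w)
    return f_stat, sps.f.sf(f_stat, df_b, df_w)


def regression_oracle(x, y):
    """Slope and p via the correlation-coefficient t formula."""
    r = np.corrcoef(x, y)[0, 1]
    n = len(x)
    slope = r * y.std(ddof=1) / x.std(ddof=1)
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
    return slope, 2 * sps.t.sf(abs(t), n - 2)


def _labelled(groups):
    values = np.concatenate(groups)
    labels = sum(([lab] * len(g) for lab, g in zip(("Yes", "Maybe", "No"), groups)), [])
    return values, labels


# ---------------------------------------------------------------------------

class TestSummaries:
    def test_mean_and_sample_sd(self):
        out, n_unlab = summarize_by_label([1.0, 2.0, 3.0], ["Yes"] * 3)
        assert out["Yes"].mean == pytest.approx(2.0)
        assert out["Yes"].sd == pytest.approx(1.0)  # n-1 denominator
        assert n_unlab == 0

    def test_singleton_group_has_no_sd(self):
        out, _ = summarize_by_label([5.0, 1.0], ["Yes", "No"])
        assert out["Yes"].n == 1 and out["Yes"].sd is None
        assert out["Yes"].min == out["Yes"].mean == out["Yes"].max == 5.0

    def test_unlabelled_records_counted_separately(self):
        out, n_unlab = summarize_by_label([1.0, 2.0, 9.0], ["Yes", "Yes", None])
        assert out["Yes"].n == 2 and n_unlab == 1

    def test_all_unlabelled_errors(self):
        with pytest.raises(CalibrationError):
            summarize_by_label([1.0], [None])


class TestAnova:
    def test_equal_means_give_f_zero(self):
        values, labels = _labelled([np.array([1.0, 2, 3]), np.array([3.0, 2, 1])])
        res = oneway_anova(values, labels)
        assert res.F == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_f_of_8(self):
        """A=[0,2], B=[4,6]: SSB=16, SSW=4 -> F=8 on df (1, 2)."""
        values, labels = _labelled([np.array([0.0, 2.0]), np.array([4.0, 6.0])])
        res = oneway_anova(values, labels)
        assert res.F == pytest.approx(8.0)
        assert (res.df_between, res.df_within) == (1, 2)
        # With k=2 the F test equals a pooled two-sample t test: F = t².
        t_p = sps.ttest_ind([0.0, 2.0], [4.0, 6.0], equal_var=True).pvalue
        assert res.p == pytest.approx(t_p, abs=1e-12)
        assert res.p == pytest.approx(sps.f.sf(8.0, 1, 2), abs=1e-12)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            k = int(rng.integers(2, 4))
            groups = [rng.normal(rng.uniform(-2, 2), 1.0,
                                 size=int(rng.integers(2, 9)))
                      for _ in range(k)]
            values, labels = _labelled(groups)
            res = oneway_anova(values, labels)
            f_exp, p_exp = anova_oracle(groups)
            assert abs(res.F - f_exp) < 1e-9
            assert res.p == pytest.approx(p_exp, abs=1e-9)

    def test_degenerate_singletons_error(self):
        with pytest.raises(CalibrationError):
            oneway_anova([1.0, 2.0], ["Yes", "No"])

    def test_single_group_errors(self):
        with pytest.raises(CalibrationError):
            oneway_anova([1.0, 2.0], ["Yes", "Yes"])


class TestTukey:
    def test_identical_constant_groups_p_one(self):
        values, labels = _labelled([np.full(4, 2.0), np.full(4, 2.0), np.full(3, 2.0)])
        res = tukey_hsd(values, labels)
        assert all(p.p_adj == 1.0 for p in res.pairs)
        assert len(res.pairs) == 3  # one entry per unordered pair

    def test_k2_equals_pooled_t(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a = rng.normal(0, 1, size=int(rng.integers(3, 10)))
            b = rng.normal(0.5, 1, size=int(rng.integers(3, 10)))
            values, labels = _labelled([a, b])
            p_tukey = tukey_hsd(values, labels).p_for("Yes", "Maybe")
            p_t = sps.ttest_ind(a, b, equal_var=True).pvalue
            assert p_tukey == pytest.approx(p_t, abs=1e-7)

    def test_wide_separation_tiny_p(self):
        rng = np.random.default_rng(1)
        values, labels = _labelled([rng.normal(0, 1, 10), rng.normal(1000, 1, 10)])
        assert tukey_hsd(values, labels).p_for("Yes", "Maybe") < 1e-6

    def test_invariance_to_relabeling_and_shift(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(m, 1, 8) for m in (0.0, 0.5, 2.0)]
        values, labels = _labelled(groups)
        base = {frozenset((p.label_a, p.label_b)): p.p_adj
                for p in tukey_hsd(values, labels).pairs}
        # Shift every value by a constant.
        shifted = {frozenset((p.label_a, p.label_b)): p.p_adj
                   for p in tukey_hsd(values + 100.0, labels).pairs}
        assert all(shifted[k] == pytest.approx(base[k], abs=1e-10) for k in base)
        # Swap the group names: p-values follow the groups.
        swap = {"Yes": "No", "No": "Yes", "Maybe": "Maybe"}
        relabelled = tukey_hsd(values, [swap[l] for l in labels])
        assert relabelled.p_for("No", "Maybe") == pytest.approx(
            base[frozenset(("Yes", "Maybe"))], abs=1e-10)


class TestRegression:
    def test_constant_response(self):
        res = covariate_regression([2.0] * 5, [1.0, 2, 3, 4, 5])
        assert res.slope == 0.0 and res.p == 1.0

    def test_matches_r_to_t_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(5, 40))
            x = rng.uniform(0, 10, n)
            y = 0.3 * x + rng.normal(0, 1, n)
            res = covariate_regression(y, x)
            slope_exp, p_exp = regression_oracle(x, y)
            assert res.slope == pytest.approx(slope_exp, rel=1e-9)
            assert res.p == pytest.approx(p_exp, rel=1e-6, abs=1e-12)

    def test_missing_covariates_dropped_and_counted(self):
        res = covariate_regression([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, None])
        assert res.n == 3 and res.n_dropped == 1

    def test_zero_covariate_variance_errors(self):
        with pytest.raises(CalibrationError):
            covariate_regression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestThresholdEstimators:
    def test_midpoint_of_printed_means(self):
        # Group means 6.00 (Yes) and 2.32 (No) -> midpoint 4.16 /m².
        values = [6.0, 6.0, 2.32, 2.32]
        labels = ["Yes", "Yes", "No", "No"]
        est = derive_thresholds(values, labels, method="midpoint_means")
        assert est.value == pytest.approx(4.16)

    def test_no_quantile_lower_interpolation(self):
        values = [0.0, 0.0, 0.0, 10.0, 99.0]
        labels = ["No", "No", "No", "No", "Yes"]
        est = derive_thresholds(values, labels, method="no_quantile", q=0.5)
        assert est.value == 0.0  # median with lower interpolation

    def test_min_misclassification_matches_exhaustive_search(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            yes = rng.gamma(4.0, 2.0, size=int(rng.integers(3, 20)))
            no = rng.gamma(1.5, 1.0, size=int(rng.integers(3, 20)))
            values = np.concatenate([yes, no])
            labels = ["Yes"] * len(yes) + ["No"] * len(no)
            est = derive_thresholds(values, labels, method="min_misclassification")
            errs = {float(c): int((no >= c).sum()) + int((yes < c).sum())
                    for c in np.unique(values)}
            best = min(errs.values())
            assert errs[est.value] == best
            assert est.value == min(c for c, e in errs.items() if e == best)

    def test_min_misclassification_separated_gap(self):
        values = [0.1, 0.2, 5.0, 6.0]
        labels = ["No", "No", "Yes", "Yes"]
        est = derive_thresholds(values, labels, method="min_misclassification")
        assert est.value == 5.0  # lowest observed cut with zero error

    def test_maybe_records_excluded(self):
        est = derive_thresholds([6.0, 100.0, 2.0], ["Yes", "Maybe", "No"],
                                method="midpoint_means")
        assert est.value == pytest.approx(4.0)
        assert (est.n_yes, est.n_no) == (1, 1)

    def test_midpoint_monotone_in_yes_values(self):
        rng = np.random.default_rng(9)
        yes = rng.uniform(2, 8, 10)
        no = rng.uniform(0, 2, 10)
        values = np.concatenate([yes, no])
        labels = ["Yes"] * 10 + ["No"] * 10
        base = derive_thresholds(values, labels, method="midpoint_means").value
        raised = derive_thresholds(np.concatenate([yes + 1.0, no]), labels,
                                   method="midpoint_means").value
        assert raised >= base

    def test_empty_contrast_group_errors(self):
        with pytest.raises(CalibrationError):
            derive_thresholds([1.0, 2.0], ["Yes", "Maybe"], method="midpoint_means")


class TestReport:
    def test_label_dependent_means_reject_strongly(self, registry):
        from vmescan.synthetic import make_fixture

        ds = make_fixture("study_like", seed=4)
        report = run_calibration_report(
            ds, registry,
            threshold_methods=("midpoint_means", "no_quantile",
                               "min_misclassification"))
        assert report.n_images_input == 1273
        assert report.n_removed_area_filter == 38
        for metric in ("overall_density", "Alcyonacea", "Scleractinia"):
            assert report.metrics[metric].anova.p < 0.01
        thr = {t.method: t.value
               for t in report.metrics["overall_density"].thresholds}
        assert set(thr) == {"midpoint_means", "no_quantile", "min_misclassification"}
        assert all(v > 0 for v in thr.values())

    def test_report_serializes(self, registry, tiny, tmp_path):
        report = run_calibration_report(tiny, registry)
        report.to_json(tmp_path / "r.json")
        report.write_tables(tmp_path)
        assert (tmp_path / "r.json").exists()
        assert (tmp_path / "summary_stats.csv").exists()
        assert (tmp_path / "anova.csv").exists()
        assert (tmp_path / "tukey_hsd.csv").exists()
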