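"""Agreement and reproducibility statistics: paired t, Shapiro-Wilk,
ICC(A,1), Bland-Altman and the paired sample-size computation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import centroidtrack as ct


def brute_force_icc_a1(table: np.ndarray) -> float:
    """Independent ICC(A,1) oracle: explicit two-way ANOVA sums of squares
    computed with plain loops."""
    n, k = table.shape
    grand = table.sum() / (n * k)
    ss_rows = sum(k * (row.mean() - grand) ** 2 for row in table)
    ss_cols = sum(n * (table[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((x - grand) ** 2 for x in table.ravel())
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestPairedT:
    def test_zero_differences(self):
        res = ct.paired_t(ct.PairedSeries([1, 2, 3, 4], [1, 2, 3, 4]))
        assert res.t == 0.0
        assert res.p == 1.0

    def test_closed_form_example(self):
        # d = (1, 2, 3): mean 2, SD 1, SE 1/sqrt(3), t = 2 sqrt(3), df 2
        res = ct.paired_t(ct.PairedSeries([2, 4, 6], [1, 2, 3]))
        assert res.mean == pytest.approx(2.0)
        assert res.sd == pytest.approx(1.0)
        assert res.se == pytest.approx(1 / math.sqrt(3))
        assert res.t == pytest.approx(2 * math.sqrt(3))
        assert res.df == 2
        assert res.p == pytest.approx(2 * sps.t.sf(2 * math.sqrt(3), 2))

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(2, 25))
        res = ct.paired_t(ct.PairedSeries(a, b))
        t_ref, p_ref = sps.ttest_rel(a, b)
        assert res.t == pytest.approx(t_ref, abs=1e-12)
        assert res.p == pytest.approx(p_ref, abs=1e-12)

    def test_ci_uses_t_quantile(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(2, 12))
        res = ct.paired_t(ct.PairedSeries(a, b))
        tcrit = sps.t.ppf(0.975, 11)
        assert res.ci_low == pytest.approx(res.mean - tcrit * res.se)
        assert res.ci_high == pytest.approx(res.mean + tcrit * res.se)

    def test_degenerate_zero_variance_nonzero_mean(self):
        res = ct.paired_t(ct.PairedSeries([2, 2, 2], [1, 1, 1]))
        assert res.degenerate
        assert math.isinf(res.t)

    def test_null_p_values_are_uniform(self):
        # calibration: under H0 the p-value is U(0,1)
        rng = np.random.default_rng(42)
        pvals = []
        for _ in range(2000):
            d = rng.normal(size=20)
            pvals.append(ct.paired_t(ct.PairedSeries(d, np.zeros(20))).p)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01
        rejection = np.mean(np.asarray(pvals) < 0.05)
        assert rejection == pytest.approx(0.05, abs=0.02)

    def test_too_short_series_refused(self):
        with pytest.raises(ValueError):
            ct.PairedSeries([1.0], [2.0])


class TestShapiro:
    def test_uniform_sample_rejected(self):
        rng = np.random.default_rng(3)
        _, p = ct.shapiro_normality(rng.uniform(size=5000))
        assert p < 0.001

    def test_type_one_error_rate_near_nominal(self):
        rng = np.random.default_rng(5)
        rejections = sum(
            ct.shapiro_normality(rng.normal(size=50))[1] < 0.05
            for _ in range(200))
        assert rejections / 200 == pytest.approx(0.05, abs=0.03)

    def test_minimum_sample_size(self):
        with pytest.raises(ct.CentroidTrackError):
            ct.shapiro_normality([1.0, 2.0])

    def test_constant_input_refused(self):
        with pytest.raises(ct.CentroidTrackError):
            ct.shapiro_normality([1.0, 1.0, 1.0, 1.0])


class TestICC:
    def test_identical_raters_give_one(self):
        res = ct.icc_agreement(np.array([[1, 1], [2, 2], [3, 3], [4, 4.0]]))
        assert res.icc == pytest.approx(1.0)

    def test_shifted_rater_hand_anova(self):
        table = np.array([[1, 2], [2, 3], [3, 4], [4, 5.0]])
        res = ct.icc_agreement(table)
        assert res.icc == pytest.approx(brute_force_icc_a1(table), abs=1e-12)

    def test_independent_noise_gives_near_zero(self):
        rng = np.random.default_rng(11)
        table = np.column_stack([rng.normal(size=100),
                                 rng.normal(size=100)])
        assert abs(ct.icc_agreement(table).icc) < 0.2

    @pytest.mark.parametrize("n,k", list(itertools.product((2, 3, 4, 6),
                                                           (2, 3))))
    def test_brute_force_equivalence_all_small_shapes(self, n, k):
        rng = np.random.default_rng(n * 10 + k)
        for _ in range(20):
            table = rng.normal(size=(n, k))
            got = ct.icc_agreement(table).icc
            expected = np.clip(brute_force_icc_a1(table), -1.0, 1.0)
            assert got == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        subj = rng.normal(size=12)
        table = np.column_stack([subj + rng.normal(0, 0.1, 12),
                                 subj + rng.normal(0, 0.1, 12)])
        frame = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 2),
            "rater": np.tile(["a", "b"], 12),
            "score": table.ravel()})
        ref = pingouin.intraclass_corr(frame, targets="subject",
                                       raters="rater", ratings="score")
        icc_a1 = ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].item()
        assert ct.icc_agreement(table).icc == pytest.approx(icc_a1,
                                                            abs=1e-9)

    def test_degenerate_without_subject_variance(self):
        res = ct.icc_agreement(np.array([[1, 2], [1, 2], [1, 2.0]]))
        assert res.degenerate

    def test_incomplete_table_refused(self):
        with pytest.raises(ValueError):
            ct.icc_agreement(np.array([[1.0, np.nan], [2, 2]]))


class TestBlandAltman:
    def test_identical_series(self):
        res = ct.bland_altman(ct.PairedSeries([1, 2, 3.0], [1, 2, 3.0]))
        assert res.mean_diff == 0.0
        assert res.loa_low == 0.0 and res.loa_high == 0.0
        assert res.coverage == 1.0

    def test_closed_form_two_points(self):
        # d = (1, -1): mean 0, SD sqrt(2), LoA = +/- 1.96 sqrt(2)
        res = ct.bland_altman(ct.PairedSeries([1.0, -1.0], [0.0, 0.0]))
        assert res.mean_diff == pytest.approx(0.0)
        assert res.loa_high == pytest.approx(1.96 * math.sqrt(2))
        assert res.loa_low == pytest.approx(-1.96 * math.sqrt(2))

    def test_normal_coverage_near_95_percent(self):
        rng = np.random.default_rng(8)
        d = rng.normal(0.0, 0.1, 10000)
        res = ct.bland_altman(ct.PairedSeries(d, np.zeros_like(d)))
        assert res.coverage == pytest.approx(0.95, abs=0.01)

    def test_plot_data_exported(self):
        res = ct.bland_altman(ct.PairedSeries([1, 2, 3.0], [2, 2, 2.0]))
        assert len(res.means) == 3 and len(res.diffs) == 3
        np.testing.assert_allclose(res.diffs, [-1, 0, 1])


class TestRequiredN:
    def test_normal_approximation_lower_bound(self):
        delta, sd, power, alpha = 0.4, 0.4, 0.95, 0.05
        n = ct.required_n_paired(delta, sd, power, alpha)
        z = sps.norm.ppf(1 - alpha / 2) + sps.norm.ppf(power)
        assert n >= (z * sd / delta) ** 2

    def test_power_simulation_cross_check(self):
        # achieved power at the returned n, and insufficiency at n - 1
        delta, sd, power, alpha = 0.4, 0.4, 0.95, 0.05
        n = ct.required_n_paired(delta, sd, power, alpha)
        rng = np.random.default_rng(17)

        def simulated_power(m: int, reps: int = 20000) -> float:
            d = rng.normal(delta, sd, size=(reps, m))
            t = d.mean(axis=1) / (d.std(axis=1, ddof=1) / math.sqrt(m))
            crit = sps.t.ppf(1 - alpha / 2, m - 1)
            return float((np.abs(t) > crit).mean())

        assert simulated_power(n) >= power - 0.01
        assert simulated_power(n - 1) < power + 0.01

    def test_doubling_sd_roughly_quadruples_n(self):
        # the exact noncentral-t requirement approaches the 4x asymptote
        # from below (n1=16, n2=54 -> ratio 3.375 at these magnitudes)
        n1 = ct.required_n_paired(0.4, 0.4, 0.95, 0.05)
        n2 = ct.required_n_paired(0.4, 0.8, 0.95, 0.05)
        assert n1 == 16 and n2 == 54
        assert 3.0 <= n2 / n1 <= 4.2

    def test_invalid_inputs_refused(self):
        with pytest.raises(ValueError):
            ct.required_n_paired(0.0, 0.4)
        with pytest.raises(ValueError):
            ct.required_n_paired(0.4, 0.4, power=1.5)


class TestValidationReport:
    @staticmethod
    def synthetic_cases(seed: int = 0) -> pd.DataFrame:
        rng = np.random.default_rng(seed)
        rows = []
        for roi in ("maxilla", "mandible"):
            for axis in ("x", "y", "z"):
                planned = rng.uniform(-10, 10, 8)
                for rep in (0, 1):
                    measured = planned + rng.normal(0, 0.05, 8)
                    for patient, (p, m) in enumerate(zip(planned, measured)):
                        rows.append({"patient": patient, "roi": roi,
                                     "axis": axis, "replicate": rep,
                                     "planned": p, "measured": m})
        return pd.DataFrame(rows)

    def test_report_shapes_and_consistency(self):
        report = ct.build_validation_report(self.synthetic_cases())
        assert len(report.accuracy) == 2 * 3 * 2       # roi x axis x rep
        assert len(report.reproducibility) == 2 * 3    # roi x axis
        for _, row in report.accuracy.iterrows():
            tcrit = sps.t.ppf(0.975, row["n"] - 1)
            assert row["ci_low"] == pytest.approx(
                row["mean_diff"] - tcrit * row["se"], abs=1e-9)
        for _, row in report.reproducibility.iterrows():
            assert -1.0 <= row["icc_a1"] <= 1.0
            assert row["ba_loa_low"] <= row["ba_mean_diff"] \
                <= row["ba_loa_high"]

    def test_high_agreement_detected(self):
        report = ct.build_validation_report(self.synthetic_cases())
        assert (report.reproducibility["icc_a1"] > 0.99).all()

    def test_round_trips_through_long_format(self):
        cfg = ct.StudyConfig(
            n_patients=2, n_replicates=2, rois=("maxilla",), n_faces=800,
            icp=ct.ICPConfig(n_samples=800, max_iter=50, tol_mm=5e-5,
                             n_candidates=6))
        result = ct.run_validation_study(cfg, seed=9)
        long = ct.cases_to_long(result.cases)
        report = ct.build_validation_report(long)
        assert not report.accuracy.empty
        assert json_ok(report.to_json())

    def test_missing_columns_refused(self):
        with pytest.raises(ValueError):
            ct.build_validation_report(pd.DataFrame({"roi": ["maxilla"]}))


def json_ok(payload: str) -> bool:
    import json
    json.loads(payload)
    return True
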