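"""HRF, GLM fitting, group statistics, FDR, correlations and power analysis."""

import itertools

from hypothesis import given, settings
from hypothesis import strategies as st

import numpy as np
import pytest
from scipy import stats

from nirsicpp import (
    PowerSpec,
    assumption_checks,
    build_design,
    canonical_hrf,
    fdr_adjust,
    fit_glm,
    group_t_map,
    marker_correlation,
    paired_t_map,
    required_sample_size,
)
from nirsicpp.activation import two_sample_t_power


class TestCanonicalHRF:
    def test_peak_normalized(self, hrf):
        assert np.max(hrf.samples) == pytest.approx(1.0)

    def test_peak_time_in_physiological_range(self, hrf):
        assert 4.0 <= hrf.peak_time_s <= 8.0

    def test_zero_at_onset(self, hrf):
        assert hrf.samples[0] == pytest.approx(0.0, abs=1e-12)

    def test_undershoot_present(self, hrf):
        assert np.min(hrf.samples) < 0


class TestBuildDesign:
    def test_default_shape(self, paradigm, hrf):
        X = build_design(paradigm, hrf)
        assert X.X.shape == (128, 3)
        assert X.labels == ("intercept", "MA", "rest")

    def test_no_rest_blocks(self, hrf):
        from nirsicpp.records import BlockEvent, ParadigmSpec

        events = tuple(
            BlockEvent("MA", 32 * k, 30) for k in range(4)
        )
        p = ParadigmSpec(sampling_rate=1.0, block_events=events, n_trials=4)
        X = build_design(p, hrf)
        assert X.X.shape[1] == 2
        assert "rest" not in X.labels

    def test_disjoint_preconvolution_support(self, paradigm):
        ma = paradigm.boxcar("MA")
        rest = paradigm.boxcar("rest")
        assert np.all(ma * rest == 0)

    def test_drift_columns(self, paradigm, hrf):
        X = build_design(paradigm, hrf, drift_order=2)
        assert X.labels == ("intercept", "drift1", "drift2", "MA", "rest")


class TestFitGLM:
    def test_noiseless_recovery(self, paradigm, hrf):
        X = build_design(paradigm, hrf)
        beta_true = np.array([0.5, 2.0, 1.0])
        y = X.X @ beta_true
        res = fit_glm(y, X)
        assert np.allclose(res.beta[0], beta_true, atol=1e-10)

    def test_residuals_orthogonal_to_design(self, paradigm, hrf):
        X = build_design(paradigm, hrf)
        rng = np.random.default_rng(0)
        y = rng.normal(size=(3, 128))
        res = fit_glm(y, X)
        resid = y - res.beta @ X.X.T
        assert np.allclose(resid @ X.X, 0, atol=1e-9)

    def test_unbiased_under_noise(self, paradigm, hrf):
        X = build_design(paradigm, hrf)
        rng = np.random.default_rng(1)
        betas = []
        for _ in range(500):
            y = rng.normal(size=128)
            betas.append(fit_glm(y, X).beta_for("MA")[0])
        betas = np.array(betas)
        se = betas.std(ddof=1) / np.sqrt(len(betas))
        assert abs(betas.mean()) < 2.5 * se + 1e-12

    def test_rank_deficient_design_named(self, paradigm, hrf):
        from nirsicpp.activation import DesignMatrix

        X = build_design(paradigm, hrf)
        bad = DesignMatrix(
            X=np.column_stack([X.X, X.X[:, 1]]), labels=X.labels + ("MA_copy",)
        )
        with pytest.raises(ValueError, match="MA"):
            fit_glm(np.zeros(128), bad)

    def test_ci_coverage(self, paradigm, hrf):
        """95% CIs for β_MA cover the truth at nominal rate (t quantiles)."""
        X = build_design(paradigm, hrf)
        rng = np.random.default_rng(2)
        beta_true = 0.7
        tcrit = stats.t.ppf(0.975, 128 - 3)
        covered = 0
        n_rep = 500
        task = X.X[:, X.column("MA")]
        for _ in range(n_rep):
            y = beta_true * task + rng.normal(0, 1.0, 128)
            res = fit_glm(y, X)
            b = res.beta_for("MA")[0]
            se = res.beta_se("MA")[0]
            if b - tcrit * se <= beta_true <= b + tcrit * se:
                covered += 1
        assert 0.92 <= covered / n_rep <= 0.98


class TestFDR:
    def test_hand_computed_example(self):
        assert np.allclose(fdr_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert fdr_adjust(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_all_ones(self):
        assert np.allclose(fdr_adjust(np.ones(5)), 1.0)

    def test_matches_brute_force_on_permutations(self):
        """BH step-up definition: adj_(i) = min_{j>=i} p_(j)·m/j, on all orders."""

        def brute(p):
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            for rank, idx in enumerate(order, start=1):
                adj[idx] = min(
                    min(p[order[j]] * m / (j + 1) for j in range(rank - 1, m)), 1.0
                )
            return adj

        rng = np.random.default_rng(3)
        base = rng.uniform(0, 1, 6)
        for perm in itertools.permutations(range(6)):
            p = base[list(perm)]
            assert np.allclose(fdr_adjust(p), brute(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust(np.array([0.1, 1.2]))

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20)
    )
    def test_adjustment_properties(self, p_list):
        """Adjusted p-values stay in [p, 1] and preserve the p-value order."""
        p = np.array(p_list)
        adj = fdr_adjust(p)
        assert np.all(adj >= p - 1e-12) and np.all(adj <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestTTestMaps:
    def test_identical_paired_data(self):
        rng = np.random.default_rng(4)
        b = rng.normal(size=(10, 5))
        m = paired_t_map(b, b)
        assert np.allclose(m.t, 0) and np.allclose(m.p_raw, 1)
        assert not m.significant.any()

    def test_constant_shift_degenerate(self):
        b = np.zeros((5, 3))
        with pytest.raises(ValueError, match="undefined"):
            paired_t_map(b + 1.0, b)

    def test_paired_matches_closed_form(self):
        task = np.array([[1.0], [2.0], [4.0]])
        rest = np.array([[0.5], [1.0], [2.0]])
        d = (task - rest).ravel()
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        m = paired_t_map(task, rest)
        assert m.t[0] == pytest.approx(t_expected, abs=1e-12)

    def test_two_sample_matches_closed_form(self):
        a = np.array([[1.0], [2.0], [3.0]])
        b = np.array([[2.0], [4.0], [9.0]])
        sp = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        t_expected = (a.mean() - b.mean()) / (sp * np.sqrt(2.0 / 3.0))
        m = group_t_map(a, b)
        assert m.t[0] == pytest.approx(t_expected, abs=1e-12)

    def test_identical_groups_zero_t(self):
        rng = np.random.default_rng(5)
        b = rng.normal(size=(8, 4))
        m = group_t_map(b, b)
        assert np.allclose(m.t, 0)

    def test_localized_effect_detected(self):
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(20):
            a = rng.normal(0, 1, (40, 10))
            b = rng.normal(0, 1, (40, 10))
            b[:, 5] += 1.2
            m = group_t_map(a, b)
            if m.significant[5] and m.significant.sum() == 1:
                hits += 1
        assert hits >= 15

    def test_paired_power_at_large_effect(self):
        rng = np.random.default_rng(7)
        detected = 0
        n_rep = 100
        for _ in range(n_rep):
            rest = rng.normal(0, 1, (50, 10))
            task = rest + rng.normal(1.0, 1.0, (50, 10))  # d = 1
            m = paired_t_map(task, rest)
            if m.significant.all():
                detected += 1
        assert detected / n_rep > 0.95


class TestAssumptionChecks:
    def test_gaussian_sample_near_normal(self):
        rng = np.random.default_rng(8)
        b = {"normal": rng.normal(size=(80, 3)), "ICPP": rng.normal(size=(80, 3))}
        rep = assumption_checks(b)
        assert np.all(rep["shapiro"]["normal"]["W"] > 0.95)
        assert np.all(rep["levene"]["p"] > 0.01)

    def test_identical_groups_levene_zero(self):
        rng = np.random.default_rng(9)
        b = rng.normal(size=(30, 2))
        rep = assumption_checks({"a": b, "b": b})
        assert np.allclose(rep["levene"]["stat"], 0)
        assert np.allclose(rep["levene"]["p"], 1)

    def test_heavy_tails_detected(self):
        rng = np.random.default_rng(10)
        rejections = 0
        for _ in range(100):
            cauchy = stats.cauchy.rvs(size=(200, 1), random_state=rng)
            rep = assumption_checks({"g": cauchy, "h": rng.normal(size=(200, 1))})
            if rep["shapiro"]["g"]["p"][0] < 0.05:
                rejections += 1
        assert rejections > 90

    def test_constant_input_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assumption_checks({"a": np.ones((5, 1)), "b": np.ones((5, 1))})


class TestMarkerCorrelation:
    def test_perfect_linear(self):
        beta = np.array([1.0, 2.0, 3.0, 4.0])
        r, p = marker_correlation(beta, 2 * beta + 1)
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        beta = np.array([1.0, 2.0, 3.0, 5.0])
        r, _ = marker_correlation(beta, -beta)
        assert r == pytest.approx(-1.0)

    def test_null_mean_near_zero(self):
        rng = np.random.default_rng(11)
        rs = [
            marker_correlation(rng.normal(size=30), rng.normal(size=30))[0]
            for _ in range(1000)
        ]
        assert abs(np.mean(rs)) < 0.02

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            marker_correlation(np.ones(5), np.arange(5.0))


class TestSampleSize:
    def test_study_configuration_noncentral_t(self):
        n = required_sample_size(PowerSpec(0.05, 0.80, 0.5), "noncentral_t")
        assert n == 64

    def test_normal_approximation(self):
        n = required_sample_size(PowerSpec(0.05, 0.80, 0.5), "normal_approx")
        assert n == 63

    def test_quadratic_scaling_in_effect_size(self):
        n1 = required_sample_size(PowerSpec(0.05, 0.80, 0.5), "normal_approx")
        n2 = required_sample_size(PowerSpec(0.05, 0.80, 1.0), "normal_approx")
        assert n2 == int(np.ceil(n1 / 4)) or abs(n2 - n1 / 4) < 1

    def test_matches_statsmodels_oracle(self):
        """Independent check of the noncentral-t power solution."""
        from statsmodels.stats.power import TTestIndPower

        sm_n = TTestIndPower().solve_power(effect_size=0.5, alpha=0.05, power=0.80,
                                           alternative="two-sided")
        assert required_sample_size(PowerSpec(0.05, 0.80, 0.5), "noncentral_t") == int(
            np.ceil(sm_n)
        )

    def test_power_monotone_in_n(self):
        spec = PowerSpec(0.05, 0.80, 0.5)
        powers = [two_sample_t_power(n, spec) for n in (10, 30, 64, 100)]
        assert all(a < b for a, b in zip(powers, powers[1:]))
        assert two_sample_t_power(64, spec) >= 0.80 > two_sample_t_power(63, spec)

    def test_zero_effect_rejected(self):
        with pytest.raises(ValueError):
            PowerSpec(0.05, 0.80, 0.0)
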