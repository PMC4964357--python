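"""Condition averaging, amplitude scoring, effect sizes and the bootstrap
Monte Carlo waveform test (with exhaustive-enumeration and calibration oracles)."""

import numpy as np
import pytest

import fernpipe as fp
from fernpipe.containers import EpochSet
from fernpipe.erp_stats import (
    AnalysisConfig,
    average_condition,
    cohens_d,
    covariate_checks,
    difference_topography,
    fern_amplitude,
    montecarlo_bootstrap_test,
)


def _epochs(toy_montage, data, labels):
    times = (np.arange(data.shape[2]) - 51) / 256.0 * 1000.0
    return EpochSet(
        data=data, times=times, labels=np.array(labels, dtype=object),
        montage=toy_montage, fs=256.0,
    )


class TestAveraging:
    def test_two_identical_epochs_average_to_either(self, toy_montage):
        x = np.random.default_rng(0).normal(size=(1, 3, 255))
        ep = _epochs(toy_montage, np.repeat(x, 2, axis=0), ["a", "a"])
        erp = average_condition(ep, "a")
        assert np.allclose(erp.data, x[0])
        assert erp.n_epochs == 2

    def test_opposite_epochs_cancel(self, toy_montage):
        x = np.ones((1, 3, 255))
        ep = _epochs(toy_montage, np.concatenate([x, -x]), ["a", "a"])
        assert np.allclose(average_condition(ep, "a").data, 0.0)

    def test_rejected_epochs_never_enter_averages(self, toy_montage):
        data = np.zeros((3, 3, 255))
        data[2] = 1000.0
        ep = _epochs(toy_montage, data, ["a"] * 3)
        ep.rejected[2] = True
        assert np.allclose(average_condition(ep, "a").data, 0.0)

    def test_missing_condition_raises_with_name(self, toy_montage):
        ep = _epochs(toy_montage, np.zeros((2, 3, 255)), ["a", "a"])
        with pytest.raises(ValueError, match="b"):
            average_condition(ep, "b")

    def test_pooling_two_options(self, toy_montage):
        data = np.zeros((4, 3, 255))
        data[:2] = 1.0
        data[2:] = 3.0
        ep = _epochs(toy_montage, data, ["o1", "o1", "o2", "o2"])
        erp = average_condition(ep, ["o1", "o2"])
        assert np.allclose(erp.data, 2.0)
        assert erp.options == ("o1", "o2")


class TestFernAmplitude:
    def test_constant_waveform_returns_constant(self, toy_montage):
        ep = _epochs(toy_montage, np.full((2, 3, 255), 4.2), ["a", "a"])
        erp = average_condition(ep, "a")
        assert fern_amplitude(erp) == pytest.approx(4.2)

    def test_zero_waveform_returns_zero(self, toy_montage):
        ep = _epochs(toy_montage, np.zeros((2, 3, 255)), ["a", "a"])
        assert fern_amplitude(average_condition(ep, "a")) == 0.0

    def test_sinusoid_closed_form(self, toy_montage):
        """Mean over [250, 400) ms of sin(2*pi*(t-250)/300): the analytic mean
        of a half-period sine over the window is 2/pi."""
        times = (np.arange(255) - 51) / 256.0 * 1000.0
        wave = np.where(
            (times >= 250) & (times < 400),
            np.sin(2 * np.pi * (times - 250.0) / 300.0),
            0.0,
        )
        data = np.tile(wave, (1, 3, 1))
        ep = _epochs(toy_montage, data, ["a"])
        got = fern_amplitude(average_condition(ep, "a"))
        assert got == pytest.approx(2 / np.pi, rel=0.02)

    def test_window_outside_epoch_raises(self, toy_montage):
        ep = _epochs(toy_montage, np.zeros((2, 3, 255)), ["a", "a"])
        cfg = AnalysisConfig(fern_window_ms=(2000.0, 2100.0))
        with pytest.raises(ValueError):
            fern_amplitude(average_condition(ep, "a"), cfg)


class TestCohensD:
    def test_equal_means_give_zero(self):
        assert cohens_d([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]) == pytest.approx(0.0)

    def test_unit_pooled_sd_unit_difference(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1.0, 1.0, 4000)
        b = rng.normal(0.0, 1.0, 4000)
        assert cohens_d(a, b) == pytest.approx(1.0, abs=0.06)

    def test_hand_computed_example(self):
        # a={1,2,3}, b={3,4,5}: means 2 and 4, each var 1, pooled SD 1 -> d=-2
        assert cohens_d([1.0, 2.0, 3.0], [3.0, 4.0, 5.0]) == pytest.approx(-2.0)

    def test_zero_pooled_sd_reported_as_nan(self):
        assert np.isnan(cohens_d([1.0, 1.0], [1.0, 1.0]))

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1.0], [2.0, 3.0])


class TestMonteCarloTest:
    CFG = AnalysisConfig(fern_window_ms=(0.0, 40.0), n_resamples=2000, seed=0)

    def test_identical_conditions_yield_null_result(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(10, 40))
        res = montecarlo_bootstrap_test(a, a.copy(), self.CFG, times=np.arange(40.0))
        assert np.allclose(res.t_obs, 0.0)
        assert np.all(res.p > 0.9)
        assert res.extents_ms == []
        assert not res.significant

    def test_constant_identical_data_degenerate_t_zero(self):
        a = np.full((5, 40), 2.0)
        res = montecarlo_bootstrap_test(a, a.copy(), self.CFG, times=np.arange(40.0))
        assert np.allclose(res.t_obs, 0.0)

    def test_huge_separation_detected_everywhere(self):
        rng = np.random.default_rng(2)
        a = rng.normal(5.0, 1.0, size=(15, 40))
        b = rng.normal(0.0, 1.0, size=(15, 40))
        res = montecarlo_bootstrap_test(a, b, self.CFG, times=np.arange(40.0))
        assert res.mask.all() and res.mask_corrected.all()
        assert res.extents_ms == [(0.0, 39.0)]
        assert res.p_at_max < 0.01
        assert res.d_at_max > 3.0

    def test_exhaustive_enumeration_oracle_tiny_n(self):
        """n=3/3 distinct values: enumerate all 6^6 with-replacement resamples
        to get the exact bootstrap-null p; the Monte Carlo estimate must agree
        within 3 standard Monte Carlo errors."""
        a = np.array([0.1, 1.3, 2.7])
        b = np.array([2.1, 3.9, 5.2])
        pooled = np.concatenate([a, b])

        def tstat(x, y):
            sp2 = (x.var(ddof=1) + y.var(ddof=1)) / 2.0
            if sp2 == 0:
                return 0.0
            return (x.mean() - y.mean()) / np.sqrt(sp2 * (2.0 / 3.0))

        t_obs = tstat(a, b)
        idx = np.indices((6,) * 6).reshape(6, -1).T  # all 46656 resamples
        draws = pooled[idx]
        ga, gb = draws[:, :3], draws[:, 3:]
        sp2 = (ga.var(axis=1, ddof=1) + gb.var(axis=1, ddof=1)) / 2.0
        denom = np.sqrt(sp2 * (2.0 / 3.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_null = np.where(denom > 0, (ga.mean(1) - gb.mean(1)) / np.where(denom > 0, denom, 1), 0.0)
        p_exact = np.mean(np.abs(t_null) >= abs(t_obs))

        B = 5000
        cfg = AnalysisConfig(fern_window_ms=(0.0, 1.0), n_resamples=B, seed=7)
        res = montecarlo_bootstrap_test(a[:, None], b[:, None], cfg, times=np.array([0.5]))
        se = np.sqrt(p_exact * (1 - p_exact) / B)
        assert abs(res.p_at_max - p_exact) <= 3 * se + 2.0 / B

    def test_permutation_null_variant_close_to_bootstrap(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.8, 1.0, size=(12, 1))
        b = rng.normal(0.0, 1.0, size=(12, 1))
        cfg = AnalysisConfig(fern_window_ms=(0.0, 1.0), n_resamples=4000, seed=1)
        p_boot = montecarlo_bootstrap_test(a, b, cfg, times=np.array([0.5])).p_at_max
        p_perm = montecarlo_bootstrap_test(a, b, cfg, times=np.array([0.5]), null="permutation").p_at_max
        assert abs(p_boot - p_perm) < 0.06

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(8, 20))
        b = rng.normal(size=(8, 20))
        cfg = AnalysisConfig(fern_window_ms=(0.0, 20.0), n_resamples=500, seed=11)
        r1 = montecarlo_bootstrap_test(a, b, cfg, times=np.arange(20.0))
        r2 = montecarlo_bootstrap_test(a, b, cfg, times=np.arange(20.0))
        assert np.array_equal(r1.p, r2.p)

    def test_small_resample_count_warns(self):
        a = np.zeros((3, 2)) + np.arange(3)[:, None]
        cfg = AnalysisConfig(fern_window_ms=(0.0, 2.0), n_resamples=50)
        with pytest.warns(UserWarning):
            montecarlo_bootstrap_test(a, a + 1, cfg, times=np.array([0.5, 1.5]))

    def test_unequal_group_sizes_allowed(self):
        rng = np.random.default_rng(5)
        res = montecarlo_bootstrap_test(
            rng.normal(size=(14, 5)), rng.normal(size=(7, 5)),
            AnalysisConfig(fern_window_ms=(0.0, 5.0), n_resamples=300, seed=0),
            times=np.arange(5.0),
        )
        assert res.n_a == 14 and res.n_b == 7

    def test_power_monotone_in_effect_and_sample_size(self):
        """Rejection rate non-decreasing along a 3x3 (effect x n) grid."""
        rng = np.random.default_rng(6)
        cfg0 = AnalysisConfig(fern_window_ms=(0.0, 1.0), n_resamples=300)
        rates = np.zeros((3, 3))
        for i, eff in enumerate((0.0, 1.0, 2.5)):
            for j, n in enumerate((6, 12, 24)):
                hits = 0
                for rep in range(40):
                    a = rng.normal(eff, 1.0, size=(n, 1))
                    b = rng.normal(0.0, 1.0, size=(n, 1))
                    cfg = AnalysisConfig(
                        fern_window_ms=(0.0, 1.0), n_resamples=300,
                        seed=int(rng.integers(2**31)),
                    )
                    res = montecarlo_bootstrap_test(a, b, cfg, times=np.array([0.5]))
                    hits += res.p_at_max < cfg.alpha
                rates[i, j] = hits / 40
        slack = 0.12  # Monte Carlo noise on 40 replicates
        assert np.all(np.diff(rates, axis=0) >= -slack)  # effect size
        assert np.all(np.diff(rates, axis=1) >= -slack)  # sample size
        assert rates[0].max() < 0.2 and rates[2, 2] > 0.9


class TestTopography:
    def test_equal_erps_give_zero_map(self, toy_montage):
        ep = _epochs(toy_montage, np.random.default_rng(0).normal(size=(4, 3, 255)), ["a"] * 4)
        erp = average_condition(ep, "a")
        assert np.allclose(difference_topography(erp, erp, 300.0), 0.0)

    def test_uniform_offset_gives_uniform_map(self, toy_montage):
        data = np.random.default_rng(1).normal(size=(2, 3, 255))
        ep_a = _epochs(toy_montage, data + 1.0, ["a", "a"])
        ep_b = _epochs(toy_montage, data, ["a", "a"])
        m = difference_topography(average_condition(ep_a, "a"), average_condition(ep_b, "a"), 300.0)
        assert np.allclose(m, 1.0)

    def test_acc_difference_peaks_frontal_midline(self, noiseless_control_epochs, montage):
        from conftest import igt_condition_labels

        loss, win = igt_condition_labels(noiseless_control_epochs, "hf")
        erp_a = average_condition(noiseless_control_epochs, loss)
        erp_b = average_condition(noiseless_control_epochs, win)
        m = difference_topography(erp_a, erp_b, erp_a.times[np.argmin(erp_a.channel("Fz"))])
        k = int(np.argmax(np.abs(m)))
        pos = montage.positions[k]
        assert pos[1] > 0  # anterior
        assert abs(pos[0]) < 0.35 * np.linalg.norm(pos)  # near midline

    def test_out_of_epoch_time_raises(self, toy_montage):
        ep = _epochs(toy_montage, np.zeros((2, 3, 255)), ["a", "a"])
        erp = average_condition(ep, "a")
        with pytest.raises(ValueError):
            difference_topography(erp, erp, 5000.0)


class TestCovariates:
    def test_constant_measure_flagged_undefined(self):
        out = covariate_checks(np.ones(10), np.linspace(8, 15, 10), np.array(["M"] * 5 + ["F"] * 5))
        assert out["undefined"] and out["age_correlation"] is None

    def test_measure_equal_to_age_gives_perfect_correlation(self):
        ages = np.linspace(8, 15, 12)
        out = covariate_checks(ages.copy(), ages, np.array(["M", "F"] * 6))
        assert out["age_correlation"] == pytest.approx(1.0)

    def test_age_independent_measures_rarely_significant(self):
        rng = np.random.default_rng(0)
        hits = 0
        n_seeds = 40
        for _ in range(n_seeds):
            out = covariate_checks(
                rng.normal(size=20), rng.uniform(8, 15, 20),
                np.array(["M"] * 14 + ["F"] * 6),
            )
            hits += out["age_p"] > 0.05
        assert hits / n_seeds >= 0.85
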