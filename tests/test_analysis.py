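"""Binned hit rates and cosine fitting, checked against brute-force fits."""

import numpy as np
import pytest

from percosc import (
    BinnedPerformance,
    ExperimentConfig,
    ObserverModel,
    PhaseBinning,
    bin_performance,
    circular_distance,
    fit_cosine,
    group_average_bins,
    modulation_depth,
    simulate_experiment,
)

CENTERS8 = PhaseBinning(8).bin_centers


def brute_force_cosine_fit(centers, rates, phase_step=1e-3):
    """Independent least-squares oracle: grid over the preferred phase, exact
    2-parameter linear fit of baseline and (sign-free) amplitude at each
    candidate phase, keep the global minimum."""
    thetas = np.arange(-np.pi, np.pi, phase_step)
    cosm = np.cos(centers[None, :] - thetas[:, None])  # (T, K)
    K = len(centers)
    s1 = cosm.sum(axis=1)
    s2 = (cosm**2).sum(axis=1)
    h_sum = rates.sum()
    hc = cosm @ rates
    det = K * s2 - s1**2
    amp = (K * hc - s1 * h_sum) / det
    base = (h_sum - amp * s1) / K
    resid = ((rates[None, :] - base[:, None] - amp[:, None] * cosm) ** 2).sum(axis=1)
    i = int(np.argmin(resid))
    theta, a = thetas[i], amp[i]
    if a < 0:
        a, theta = -a, theta - np.pi if theta >= 0 else theta + np.pi
    return base[i], a, theta, resid[i]


def binned_from_rates(rates, n_per_bin=100):
    rates = np.asarray(rates, dtype=float)
    hits = np.round(rates * n_per_bin).astype(int)
    return BinnedPerformance(
        "1", CENTERS8[: len(rates)], np.full(len(rates), n_per_bin), hits
    )


class TestBinPerformance:
    def test_counts_are_conserved(self, small_datasets, config):
        ds = small_datasets[0]
        for pid in config.position_ids:
            binned = bin_performance(ds, pid, config.binning)
            total = sum(1 for t in ds.targets if t.position_id == pid)
            assert int(np.sum(binned.n_targets)) == total
            assert np.all(binned.n_hits <= binned.n_targets)

    def test_simple_rates(self):
        b = BinnedPerformance("1", CENTERS8, np.full(8, 4), np.array([2] * 8))
        np.testing.assert_allclose(b.hit_rate, 0.5)

    def test_missing_position_raises(self, small_datasets, config):
        with pytest.raises(ValueError):
            bin_performance(small_datasets[0], "nope", config.binning)


class TestFitCosine:
    def test_flat_input_is_degenerate_with_zero_phase(self):
        fit = fit_cosine(binned_from_rates(np.full(8, 0.5)))
        assert fit.baseline == pytest.approx(0.5)
        assert fit.half_amplitude == pytest.approx(0.0, abs=1e-12)
        assert fit.preferred_phase == 0.0
        assert fit.degenerate

    def test_exact_recovery_of_a_noiseless_cosine(self):
        rates = 0.5 + 0.11 * np.cos(CENTERS8 - np.pi / 4)
        b = BinnedPerformance("1", CENTERS8, np.full(8, 1), None, hit_rate=rates)
        fit = fit_cosine(b)
        assert fit.baseline == pytest.approx(0.5, abs=1e-12)
        assert fit.half_amplitude == pytest.approx(0.11, abs=1e-12)
        assert fit.preferred_phase == pytest.approx(np.pi / 4, abs=1e-12)
        assert modulation_depth(fit) == pytest.approx(0.22, abs=1e-12)

    def test_recovery_at_arbitrary_phase_and_amplitude(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            base = rng.uniform(0.3, 0.7)
            amp = rng.uniform(0, min(base, 1 - base))
            theta = rng.uniform(-np.pi, np.pi)
            rates = base + amp * np.cos(CENTERS8 - theta)
            fit = fit_cosine(
                BinnedPerformance("1", CENTERS8, np.full(8, 1), None, hit_rate=rates)
            )
            assert fit.baseline == pytest.approx(base, abs=1e-10)
            assert fit.half_amplitude == pytest.approx(amp, abs=1e-10)
            if amp > 1e-9:
                assert circular_distance(fit.preferred_phase, theta) < 1e-8

    def test_agrees_with_brute_force_least_squares(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            rates = rng.uniform(0, 1, size=8)
            fit = fit_cosine(
                BinnedPerformance("1", CENTERS8, np.full(8, 1), None, hit_rate=rates)
            )
            base, amp, theta, _ = brute_force_cosine_fit(CENTERS8, rates)
            assert fit.baseline == pytest.approx(base, abs=1e-3)
            assert fit.half_amplitude == pytest.approx(amp, abs=1e-3)
            assert circular_distance(fit.preferred_phase, theta) < 2e-3

    def test_two_bin_amplitude_is_half_the_rate_difference(self):
        centers = PhaseBinning(2).bin_centers
        b = BinnedPerformance("1", centers, np.full(2, 10), np.array([3, 7]))
        fit = fit_cosine(b)
        assert fit.half_amplitude == pytest.approx(0.5 * abs(0.7 - 0.3))

    def test_empty_bins_excluded_with_warning(self):
        n = np.array([10, 10, 10, 10, 0, 10, 10, 10])
        h = np.array([5, 6, 7, 6, 0, 4, 3, 4])
        with pytest.warns(UserWarning, match="empty bin"):
            fit = fit_cosine(BinnedPerformance("1", CENTERS8, n, h))
        assert np.isfinite(fit.half_amplitude)

    def test_too_few_bins_raise(self):
        n = np.array([10, 10, 0, 0, 0, 0, 0, 0])
        h = np.array([5, 6, 0, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError):
            fit_cosine(BinnedPerformance("1", CENTERS8, n, h))

    def test_ceiling_performance_has_zero_amplitude(self):
        b = BinnedPerformance("1", CENTERS8, np.full(8, 5), np.full(8, 5))
        fit = fit_cosine(b)
        assert np.all(b.hit_rate == 1.0)
        assert fit.half_amplitude == pytest.approx(0.0, abs=1e-12)


class TestGroupAverage:
    def test_identical_subjects_average_to_themselves(self):
        b = binned_from_rates(0.5 + 0.1 * np.cos(CENTERS8))
        g = group_average_bins([b, b, b])
        np.testing.assert_allclose(g.hit_rate, b.hit_rate)
        np.testing.assert_array_equal(g.n_targets, 3 * np.asarray(b.n_targets))

    def test_unweighted_mean_and_permutation_invariance(self):
        b1 = binned_from_rates(np.full(8, 0.4), n_per_bin=10)
        b2 = binned_from_rates(np.full(8, 0.6), n_per_bin=1000)
        g12 = group_average_bins([b1, b2])
        g21 = group_average_bins([b2, b1])
        np.testing.assert_allclose(g12.hit_rate, 0.5)  # unweighted despite counts
        np.testing.assert_allclose(g12.hit_rate, g21.hit_rate)

    def test_group_fit_equals_individual_fit_for_identical_subjects(self):
        b = binned_from_rates(0.5 + 0.12 * np.cos(CENTERS8 + 1.0))
        fit_one = fit_cosine(b)
        fit_grp = fit_cosine(group_average_bins([b, b]))
        assert fit_grp.half_amplitude == pytest.approx(fit_one.half_amplitude)
        assert fit_grp.preferred_phase == pytest.approx(fit_one.preferred_phase)

    def test_binning_mismatch_rejected(self):
        b8 = binned_from_rates(np.full(8, 0.5))
        b4 = BinnedPerformance("1", PhaseBinning(4).bin_centers, np.full(4, 10), np.full(4, 5))
        with pytest.raises(ValueError):
            group_average_bins([b8, b4])


class TestGenerativeRecovery:
    def test_modulation_and_phase_recovered_from_simulation(self):
        """A simulated observer's injected modulation depth and preferred
        phase are recovered by the binning + cosine fit pipeline."""
        cfg = ExperimentConfig(positions=ExperimentConfig().positions[:1])
        m, theta = 0.4, 1.0
        obs = ObserverModel(
            threshold_per_position={"1": 100.0},
            modulation_depth_per_position={"1": m},
            preferred_phase_per_position={"1": theta},
            lapse_rate=0.02,
        )
        ds = simulate_experiment(cfg, obs, 1, 150, 9)[0]
        fit = fit_cosine(bin_performance(ds, "1", cfg.binning))
        injected_depth = 0.5 * m  # staircase holds the mean hit rate at 0.5
        sem = np.sqrt(0.25 / 150) * np.sqrt(2 / 8) * 2  # peak-to-trough noise scale
        assert abs(fit.peak_to_trough - injected_depth) < 3 * max(sem, 0.02)
        assert circular_distance(fit.preferred_phase, theta) < np.pi / 8
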