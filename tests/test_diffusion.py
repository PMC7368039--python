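"""MSD computation against a brute-force oracle, model fits, ensemble
statistics, and periodic-boundary unwrapping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hsafm_spt import (
    Detection,
    MSDCurve,
    Trajectory,
    composition_trend,
    compute_msd,
    fit_brownian,
    fit_directed,
    fit_lognormal,
    simulate_trajectories,
    unwrap_periodic,
    wrap_periodic,
)
from hsafm_spt.diffusion import TrackTooShortError

from conftest import free_config


def brute_force_msd(frames, pos, dt):
    """All-pairs double-loop oracle for the time-averaged MSD."""
    frames = np.asarray(frames)
    lags, msds, counts = [], [], []
    for k in range(1, frames[-1] - frames[0] + 1):
        sq = []
        for i in range(len(frames)):
            for j in range(len(frames)):
                if frames[j] - frames[i] == k:
                    sq.append(((pos[j] - pos[i]) ** 2).sum())
        if sq:
            lags.append(k * dt)
            msds.append(np.mean(sq))
            counts.append(len(sq))
    return np.array(lags), np.array(msds), np.array(counts)


class TestComputeMSD:
    def test_stationary_track_has_zero_msd(self):
        pos = np.zeros((20, 2))
        curve = compute_msd(pos, 0.5)
        np.testing.assert_allclose(curve.msd_nm2, 0.0)

    def test_unit_steps_match_hand_computation(self):
        # (0,0),(1,0),(2,0),(3,0) at unit lags -> MSD 1, 4, 9
        pos = np.array([[0, 0], [1, 0], [2, 0], [3, 0]], dtype=float)
        curve = compute_msd(pos, 1.0)
        np.testing.assert_allclose(curve.lag_s, [1, 2, 3])
        np.testing.assert_allclose(curve.msd_nm2, [1, 4, 9])
        np.testing.assert_allclose(curve.n_pairs, [3, 2, 1])

    def test_ballistic_track_is_exactly_quadratic(self):
        v, dt = 7.0, 0.5
        t = np.arange(30) * dt
        pos = np.stack([v * t, np.zeros_like(t)], axis=1)
        curve = compute_msd(pos, dt)
        np.testing.assert_allclose(curve.msd_nm2, (v * curve.lag_s) ** 2,
                                   rtol=1e-12)

    def test_too_short_track_raises(self):
        with pytest.raises(TrackTooShortError):
            compute_msd(np.zeros((3, 2)), 0.5)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_on_random_tracks(self, data):
        n = data.draw(st.integers(min_value=4, max_value=50))
        seed = data.draw(st.integers(min_value=0, max_value=2 ** 31 - 1))
        rng = np.random.default_rng(seed)
        pos = rng.normal(0, 10, size=(n, 2))
        curve = compute_msd(pos, 0.5)
        lags, msds, counts = brute_force_msd(np.arange(n), pos, 0.5)
        np.testing.assert_allclose(curve.lag_s, lags)
        np.testing.assert_allclose(curve.msd_nm2, msds, rtol=1e-10)
        np.testing.assert_array_equal(curve.n_pairs, counts)

    def test_gap_pairs_excluded_matches_brute_force(self):
        rng = np.random.default_rng(5)
        frames = np.array([0, 1, 2, 4, 5, 8, 9, 10])
        pos = rng.normal(0, 5, size=(len(frames), 2))
        dets = [Detection(frame=int(f), x_nm=p[0], y_nm=p[1],
                          peak_height_nm=2.9) for f, p in zip(frames, pos)]
        track = Trajectory(particle_id=0, detections=dets,
                           gaps=[3, 6, 7])
        curve = compute_msd(track, 0.5)
        lags, msds, counts = brute_force_msd(frames, pos, 0.5)
        np.testing.assert_allclose(curve.lag_s, lags)
        np.testing.assert_allclose(curve.msd_nm2, msds, rtol=1e-10)
        np.testing.assert_array_equal(curve.n_pairs, counts)


def _curve(lag, msd):
    return MSDCurve(lag_s=np.asarray(lag, float), msd_nm2=np.asarray(msd, float),
                    n_pairs=np.arange(len(lag), 0, -1))


class TestBrownianFit:
    def test_exact_linear_curve_recovers_D(self):
        # slope 4*D with D = 0.5 um^2/s = 5e5 nm^2/s
        lag = np.arange(1, 13) * 0.5
        est = fit_brownian(_curve(lag, 4 * 5e5 * lag))
        assert est.D_um2_s == pytest.approx(0.5, rel=1e-9)
        assert est.intercept_nm2 == pytest.approx(0.0, abs=1e-6)
        assert not est.clamped_D

    def test_thirty_lag_curve_fits_first_ten(self):
        lag = np.arange(1, 31) * 0.5
        est = fit_brownian(_curve(lag, 4e3 * lag))
        assert list(est.fit_lags) == list(range(10))

    def test_intercept_absorbed_without_biasing_D(self):
        lag = np.arange(1, 13) * 0.5
        est = fit_brownian(_curve(lag, 4 * 2e3 * lag + 8.0))
        assert est.intercept_nm2 == pytest.approx(8.0, rel=1e-6)
        assert est.D_um2_s == pytest.approx(2e3 / 1e6, rel=1e-9)

    def test_slope_unit_identity(self):
        # a slope of 4 nm^2/s is exactly D = 1e-6 um^2/s
        lag = np.arange(1, 10) * 1.0
        est = fit_brownian(_curve(lag, 4.0 * lag), fit_intercept=False)
        assert est.D_um2_s == pytest.approx(1e-6, rel=1e-12)

    def test_negative_slope_clamps_to_zero_with_flag(self):
        lag = np.arange(1, 13) * 0.5
        est = fit_brownian(_curve(lag, np.maximum(100.0 - 4 * lag, 1.0)))
        assert est.D_um2_s == 0.0
        assert est.clamped_D

    def test_too_few_lags_raises(self):
        with pytest.raises(TrackTooShortError):
            fit_brownian(_curve([1, 2, 3], [1, 2, 3]))


class TestDirectedFit:
    def test_noiseless_directed_curve_recovered_exactly(self):
        D, v = 1.0, 50.0  # um^2/s, nm/s
        lag = np.arange(1, 19) * 0.5
        msd = 4 * D * 1e6 * lag + (v * lag) ** 2
        est = fit_directed(_curve(lag, msd))
        assert est.D_um2_s == pytest.approx(D, rel=1e-6)
        assert est.v_nm_s == pytest.approx(v, rel=1e-6)

    def test_pure_brownian_curve_gives_zero_drift(self):
        lag = np.arange(1, 19) * 0.5
        msd = 4 * 2e3 * lag
        est_d = fit_directed(_curve(lag, msd))
        est_b = fit_brownian(_curve(lag, msd))
        assert est_d.v_nm_s == pytest.approx(0.0, abs=0.01)
        assert est_d.D_um2_s == pytest.approx(est_b.D_um2_s, rel=1e-6)

    def test_pure_ballistic_curve_gives_zero_D(self):
        v = 25.0
        lag = np.arange(1, 19) * 0.5
        est = fit_directed(_curve(lag, (v * lag) ** 2))
        assert est.D_um2_s == pytest.approx(0.0, abs=1e-12)
        assert est.v_nm_s == pytest.approx(v, rel=1e-6)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_directed_rss_never_exceeds_brownian_rss(self, seed):
        rng = np.random.default_rng(seed)
        lag = np.arange(1, 25) * 0.5
        msd = np.abs(4e3 * lag + rng.normal(0, 300, lag.size)) + 1e-3 * np.arange(lag.size)
        curve = _curve(lag, msd)
        assert fit_directed(curve).rss_nm4 <= fit_brownian(curve).rss_nm4 + 1e-6

    def test_drift_speed_recovered_from_simulated_trajectories(self):
        # ensemble of drifting Brownian tracks: v within 20% at 200 frames
        v_true = 10.0
        cfg = free_config(n_frames=200, n_particles=40, D_true_um2_s=1e-4,
                          drift_velocity_nm_s=(8.0, -6.0), seed=23)
        truth = simulate_trajectories(cfg)
        vs = []
        for p in range(cfg.n_particles):
            pos = np.stack([truth.x_nm[p], truth.y_nm[p]], axis=1)
            vs.append(fit_directed(compute_msd(pos, 0.5)).v_nm_s)
        assert np.mean(vs) == pytest.approx(v_true, rel=0.2)


class TestEnsembleStats:
    def test_identical_values_have_zero_spread(self):
        stats = fit_lognormal([3e-4] * 5)
        assert stats.sigma_log == 0.0
        assert np.exp(stats.mu_log) == pytest.approx(3e-4, rel=1e-12)

    def test_recovers_known_lognormal_parameters(self, rng):
        mu, sigma = np.log(3e-4), 0.8
        sample = rng.lognormal(mu, sigma, size=10_000)
        stats = fit_lognormal(sample)
        # within 3 standard errors of the MLE
        assert abs(stats.mu_log - mu) < 3 * sigma / np.sqrt(sample.size)
        assert abs(stats.sigma_log - sigma) < 3 * sigma / np.sqrt(2 * sample.size)

    def test_nonpositive_values_excluded_and_counted(self):
        stats = fit_lognormal([1e-4, 2e-4, 3e-4, 0.0, -1e-5])
        assert stats.n == 3
        assert stats.n_excluded == 2

    def test_fewer_than_three_positive_values_raises(self):
        with pytest.raises(ValueError, match="3 positive"):
            fit_lognormal([1e-4, 2e-4, 0.0])

    def test_mean_reported_is_arithmetic_mean(self):
        vals = [1e-4, 4e-4]
        stats = fit_lognormal(vals + [2e-4])
        assert stats.arithmetic_mean_D == pytest.approx(np.mean(vals + [2e-4]))


class TestCompositionTrend:
    def test_strictly_decreasing_means_give_decreasing_verdict(self):
        ens = [fit_lognormal([d, d * 1.1, d * 0.9], dmpc_fraction=f)
               for d, f in zip([8e-4, 5e-4, 3e-4], [10, 20, 30])]
        assert composition_trend(ens)["verdict"] == "decreasing"

    def test_increasing_means_give_increasing_verdict(self):
        ens = [fit_lognormal([d, d * 1.1, d * 0.9], dmpc_fraction=f)
               for d, f in zip([3e-4, 5e-4, 8e-4], [10, 20, 30])]
        assert composition_trend(ens)["verdict"] == "increasing"

    def test_single_composition_gives_none(self):
        ens = [fit_lognormal([1e-4, 2e-4, 3e-4], dmpc_fraction=20)]
        assert composition_trend(ens)["verdict"] == "none"


class TestPeriodicUnwrap:
    def test_no_crossing_is_identity(self):
        x = np.array([1.0, 1.5, 2.0, 1.2])
        np.testing.assert_allclose(unwrap_periodic(x, 9.4), x)

    def test_hand_computed_boundary_crossing(self):
        # 4.6, 4.7, -4.6 in a 9.4 nm box: -4.6 is one step of +0.1 past 4.7
        x = np.array([4.6, 4.7, -4.6])
        np.testing.assert_allclose(unwrap_periodic(x, 9.4), [4.6, 4.7, 4.8],
                                   rtol=1e-12)

    def test_half_box_displacement_resolves_positive(self):
        x = np.array([0.0, 4.7])  # exactly box/2 in a 9.4 box
        np.testing.assert_allclose(unwrap_periodic(x, 9.4), [0.0, 4.7])

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_wrap_of_unwrap_restores_original(self, seed):
        rng = np.random.default_rng(seed)
        box = np.array([9.4, 9.4, 8.4])
        raw = rng.uniform(-box / 2, box / 2, size=(30, 3))
        # make a wrapped series (raw is already inside the box)
        unwrapped = unwrap_periodic(raw, box)
        rewrapped = wrap_periodic(unwrapped, box)
        np.testing.assert_allclose(rewrapped, wrap_periodic(raw, box),
                                   atol=1e-9)

    def test_bad_box_rejected(self):
        with pytest.raises(ValueError):
            unwrap_periodic(np.zeros((5, 2)), [0.0, 9.4])


class TestEnsembleRecovery:
    def test_mean_D_within_quarter_of_truth_across_levels(self):
        # the spec regime: 100 tracks x 200 frames at 0.5 s
        for D_true in (1e-4, 5e-4, 1e-3):
            cfg = free_config(n_frames=200, n_particles=100,
                              D_true_um2_s=D_true, seed=101)
            truth = simulate_trajectories(cfg)
            Ds = []
            for p in range(cfg.n_particles):
                pos = np.stack([truth.x_nm[p], truth.y_nm[p]], axis=1)
                Ds.append(fit_brownian(compute_msd(pos, 0.5)).D_um2_s)
            assert np.mean(Ds) == pytest.approx(D_true, rel=0.25)
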