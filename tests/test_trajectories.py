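import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.linalg import cholesky, toeplitz

from spt_audit.trajectories import (
    InitialPositionPrior,
    MotionParams,
    TimeGrid,
    Trajectory,
    center_and_rescale,
    draw_drift_velocity,
    draw_initial_position,
    msd_curve,
    sbm_diffusivity,
    simulate,
    simulate_attm,
    simulate_bm,
    simulate_ctrw,
    simulate_dbm,
    simulate_fbm,
    simulate_lw,
    simulate_sbm,
    _fgn_autocov,
    _fgn_davies_harte,
)

ORIGIN = np.zeros(3)


class TestTimeGrid:
    def test_reference_grid_structure(self):
        grid = TimeGrid(15, 10)
        t = grid.times
        assert t.shape == (15, 10)
        flat = grid.flat_times
        assert np.all(np.diff(flat) > 0)
        # intraframe span never exceeds the exposure window
        assert np.all(t[:, -1] - t[:, 0] <= grid.exposure + 1e-12)
        # successive frame starts differ by the frame period
        assert np.allclose(np.diff(t[:, 0]), grid.frame_period)
        assert grid.dead_time == pytest.approx(0.003)

    @given(
        n=st.integers(1, 40),
        k=st.integers(1, 20),
        t_f=st.floats(1e-3, 1.0),
        frac=st.floats(0.1, 1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_grid_invariants_hold_for_any_timing(self, n, k, t_f, frac):
        grid = TimeGrid(n, k, t_f, frac * t_f)
        flat = grid.flat_times
        assert np.all(np.diff(flat) > 0)
        assert np.all(grid.times[:, -1] - grid.times[:, 0] <= grid.exposure + 1e-12)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_frames": 0, "k_interp": 1},
            {"n_frames": 1, "k_interp": 0},
            {"n_frames": 1, "k_interp": 1, "frame_period": 0.01, "exposure": 0.02},
            {"n_frames": 1, "k_interp": 1, "frame_period": -1.0},
        ],
    )
    def test_invalid_grids_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TimeGrid(**kwargs)


class TestInitialPosition:
    def test_degenerate_widths_return_mean_exactly(self):
        prior = InitialPositionPrior((2.13, 2.13, 0.0), 0.0, 0.0)
        assert np.array_equal(draw_initial_position(prior, 0), [2.13, 2.13, 0.0])

    def test_sample_variances_match_prior_covariance(self):
        prior = InitialPositionPrior((0.0, 0.0, 0.0), 0.1, 0.4)
        rng = np.random.default_rng(7)
        draws = np.array([draw_initial_position(prior, rng) for _ in range(10**5)])
        var = draws.var(axis=0)
        assert np.allclose(var, [0.01, 0.01, 0.16], rtol=0.05)

    def test_sample_mean_within_clt_bound(self):
        mu = (2.13, 2.13, 0.0)
        prior = InitialPositionPrior(mu, 0.1, 0.4)
        rng = np.random.default_rng(11)
        draws = np.array([draw_initial_position(prior, rng) for _ in range(10**5)])
        se = np.array([0.1, 0.1, 0.4]) / math.sqrt(10**5)
        assert np.all(np.abs(draws.mean(axis=0) - mu) < 3 * se)

    def test_negative_width_rejected(self):
        with pytest.raises(ValueError):
            InitialPositionPrior((0, 0, 0), -0.1, 0.4)

    def test_out_of_plane_mean_rejected(self):
        with pytest.raises(ValueError):
            InitialPositionPrior((0, 0, 0.5), 0.1, 0.4)


class TestBM:
    def test_zero_diffusivity_is_constant(self):
        grid = TimeGrid(4, 3)
        traj = simulate_bm([1.0, 2.0, 3.0], grid, 0.0, 0)
        assert np.allclose(traj.positions, [1.0, 2.0, 3.0])

    def test_negative_diffusivity_rejected(self):
        with pytest.raises(ValueError):
            simulate_bm(ORIGIN, TimeGrid(2, 1), -1.0, 0)

    def test_single_step_second_moment(self):
        # 10^4 replicate steps of dt = 0.033 s at D = 1: E|dR|^2 = 6 D dt
        grid = TimeGrid(10001, 1, 0.033, 0.033)
        traj = simulate_bm(ORIGIN, grid, 1.0, 5)
        steps = np.diff(traj.flat_positions, axis=0)
        msq = np.mean(np.sum(steps**2, axis=1))
        assert msq == pytest.approx(6 * 1.0 * 0.033, rel=0.02)

    def test_increments_pass_gaussian_moment_checks(self):
        grid = TimeGrid(20001, 1, 0.033, 0.033)
        traj = simulate_bm(ORIGIN, grid, 1.0, 9)
        steps = np.diff(traj.flat_positions, axis=0)
        n = len(steps)
        for ax in range(3):
            assert abs(stats.skew(steps[:, ax])) < 4 * math.sqrt(6.0 / n)
            assert abs(stats.kurtosis(steps[:, ax])) < 4 * math.sqrt(24.0 / n)

    def test_bit_for_bit_reproducible(self):
        grid = TimeGrid(6, 4)
        a = simulate_bm(ORIGIN, grid, 1.0, 42)
        b = simulate_bm(ORIGIN, grid, 1.0, 42)
        assert np.array_equal(a.positions, b.positions)


class TestDBM:
    def test_zero_drift_identical_to_bm_same_seed(self):
        grid = TimeGrid(8, 5)
        bm = simulate_bm(ORIGIN, grid, 1.0, 3)
        dbm = simulate_dbm(ORIGIN, grid, 1.0, (0.0, 0.0, 0.0), 3)
        assert np.array_equal(bm.positions, dbm.positions)

    def test_mean_displacement_matches_drift(self):
        grid = TimeGrid(10001, 1, 0.033, 0.033)
        traj = simulate_dbm(ORIGIN, grid, 1.0, (1.0, 1.0, 0.0), 13)
        steps = np.diff(traj.flat_positions, axis=0)
        se = math.sqrt(2 * 1.0 * 0.033 / len(steps))
        mean = steps.mean(axis=0)
        assert np.all(np.abs(mean - [0.033, 0.033, 0.0]) < 3 * se)

    def test_drawn_drift_is_azimuthal(self):
        for seed in range(50):
            v = draw_drift_velocity(seed)
            assert v[2] == 0.0
            assert 0 < v[0] <= 1.0
            assert v[0] == v[1]


class TestATTM:
    def test_sojourns_satisfy_deterministic_mapping(self):
        grid = TimeGrid(20, 2)
        traj = simulate_attm(ORIGIN, grid, 0.8, 1.2, 0, tau_unit=0.033)
        p = traj.ground_truth_params
        for d, tau in zip(p["patch_d"], p["patch_tau"]):
            assert tau == pytest.approx(d ** (-1.2) * 0.033)

    def test_degenerate_support_reduces_to_single_diffusivity_bm(self):
        grid = TimeGrid(5001, 1, 0.01, 0.01)
        traj = simulate_attm(
            ORIGIN, grid, 0.8, 1.2, 17, d_support=(0.25, 0.25), d_scale=1.0
        )
        steps = np.diff(traj.flat_positions, axis=0)
        msq = np.mean(np.sum(steps**2, axis=1))
        assert msq == pytest.approx(6 * 0.25 * 0.01, rel=0.1)

    def test_ensemble_msd_slope_near_sigma_over_gamma(self):
        grid = TimeGrid(200, 1, 0.5, 0.5)
        trajs = [
            simulate_attm(
                ORIGIN, grid, 0.8, 1.0, s, d_support=(1e-3, 1.0), tau_unit=1.0
            )
            for s in range(400)
        ]
        _, _, slope = msd_curve(trajs)
        assert slope == pytest.approx(0.8, abs=0.1)

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError):
            simulate_attm(ORIGIN, TimeGrid(2, 1), 0.8, 2.0, 0)


class TestCTRW:
    def test_trapped_walker_stays_at_start(self):
        grid = TimeGrid(5, 2)
        # minimum waiting time exceeds the whole observation window
        traj = simulate_ctrw(ORIGIN, grid, 0.5, 1.0, 0.01, 0, tau_min=10.0)
        assert np.allclose(traj.positions, ORIGIN)

    def test_waiting_time_survival_tail_slope(self):
        rng = np.random.default_rng(3)
        waits = 1.0 * rng.uniform(size=10**5) ** (-1.0 / 0.5)
        # empirical log-survival slope over the sampled tail
        q = np.quantile(waits, np.linspace(0.5, 0.99, 30))
        surv = np.array([(waits > x).mean() for x in q])
        slope = np.polyfit(np.log(q), np.log(surv), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.03)

    def test_jump_second_moment(self):
        grid = TimeGrid(2, 1)
        rng = np.random.default_rng(4)
        traj = simulate_ctrw(ORIGIN, grid, 0.5, 1.0, 0.033, rng, tau_min=1e-9)
        # oracle on the raw jump generator: 10^5 draws of N(0, 2 I D tau0)
        jumps = rng.standard_normal((10**5, 3)) * math.sqrt(2 * 1.0 * 0.033)
        assert np.mean(np.sum(jumps**2, axis=1)) == pytest.approx(
            6 * 1.0 * 0.033, rel=0.02
        )
        assert traj.positions.shape == (2, 1, 3)

    def test_ensemble_msd_slope_near_alpha(self):
        grid = TimeGrid(100, 1, 0.1, 0.1)
        trajs = [
            simulate_ctrw(ORIGIN, grid, 0.5, 1.0, 0.1, s, tau_min=0.02)
            for s in range(500)
        ]
        _, _, slope = msd_curve(trajs, min_lag=3)
        assert slope == pytest.approx(0.5, abs=0.15)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            simulate_ctrw(ORIGIN, TimeGrid(2, 1), 1.5, 1.0, 0.01, 0)


class TestFBM:
    def test_autocov_vanishes_at_half(self):
        g = _fgn_autocov(10, 0.5)
        assert g[0] == pytest.approx(1.0)
        assert np.allclose(g[1:], 0.0, atol=1e-12)

    def test_autocov_formula_at_unit_hurst(self):
        # H = 1 is outside the valid sampling range; algebra check only
        g = _fgn_autocov(6, 1.0)
        assert np.allclose(g, 1.0)

    def test_lag_one_increment_correlation(self):
        rng = np.random.default_rng(0)
        x = _fgn_davies_harte(64, 0.7, 10_000, rng)  # unit-variance columns
        prods = (x[:-1] * x[1:]).ravel()
        expected = 2**0.4 - 1.0
        se = prods.std() / math.sqrt(len(prods))
        assert prods.mean() == pytest.approx(expected, abs=3 * se)

    def test_covariance_matches_cholesky_oracle(self):
        # independent oracle: dense Cholesky factor of the Toeplitz fGn covariance
        L, H = 64, 0.7
        g = _fgn_autocov(L, H)
        chol = cholesky(toeplitz(g[:L]), lower=True)
        rng = np.random.default_rng(10)
        oracle = (chol @ rng.standard_normal((L, 4000))).T
        dh = _fgn_davies_harte(L, H, 4000, np.random.default_rng(11)).T
        for lag in (0, 1, 5, 20):
            a = np.mean(oracle[:, :-lag or None] * oracle[:, lag:])
            b = np.mean(dh[:, :-lag or None] * dh[:, lag:])
            se = 2.0 / math.sqrt(4000 * (L - lag))
            assert abs(a - b) < 4 * se

    def test_half_hurst_variance_matches_bm(self):
        grid = TimeGrid(2001, 1, 0.01, 0.01)
        traj = simulate_fbm(ORIGIN, grid, 0.5, 1.0, 21)
        steps = np.diff(traj.flat_positions, axis=0)
        assert np.mean(np.sum(steps**2, axis=1)) == pytest.approx(
            6 * 1.0 * 0.01, rel=0.1
        )

    def test_invalid_hurst_rejected(self):
        for h in (0.0, 1.0, 1.3):
            with pytest.raises(ValueError):
                simulate_fbm(ORIGIN, TimeGrid(2, 1), h, 1.0, 0)

    def test_msd_slope_tracks_twice_hurst(self):
        grid = TimeGrid(100, 1, 0.1, 0.1)
        trajs = [simulate_fbm(ORIGIN, grid, 0.25, 1.0, s) for s in range(300)]
        _, _, slope = msd_curve(trajs)
        assert slope == pytest.approx(0.5, abs=0.1)


class TestLW:
    def test_single_flight_is_straight_at_constant_speed(self):
        grid = TimeGrid(10, 2)
        traj = simulate_lw(ORIGIN, grid, 0.5, 2.0, 0, tau_min=100.0)
        flat = traj.flat_positions
        dts = np.diff(grid.flat_times)
        speeds = np.linalg.norm(np.diff(flat, axis=0), axis=1) / dts
        assert np.allclose(speeds, 2.0)

    def test_ballistic_regime_slope(self):
        grid = TimeGrid(100, 1, 0.1, 0.1)
        trajs = [simulate_lw(ORIGIN, grid, 0.5, 1.0, s) for s in range(400)]
        _, _, slope = msd_curve(trajs)
        assert slope == pytest.approx(2.0, abs=0.15)

    def test_superdiffusive_regime_slope(self):
        grid = TimeGrid(100, 1, 0.1, 0.1)
        trajs = [simulate_lw(ORIGIN, grid, 1.5, 1.0, s) for s in range(800)]
        _, _, slope = msd_curve(trajs)
        assert slope == pytest.approx(1.5, abs=0.15)

    def test_invalid_exponent_rejected(self):
        with pytest.raises(ValueError):
            simulate_lw(ORIGIN, TimeGrid(2, 1), 2.5, 1.0, 0)


class TestSBM:
    def test_alpha_one_is_bm_with_half_diffusivity(self):
        grid = TimeGrid(6, 4)
        sbm = simulate_sbm(ORIGIN, grid, 1.0, 33)
        bm = simulate_bm(ORIGIN, grid, 0.5, 33)
        assert sbm.ground_truth_params["d_alpha"] == pytest.approx(0.5)
        assert np.array_equal(sbm.positions, bm.positions)

    def test_ensemble_msd_matches_closed_form(self):
        grid = TimeGrid(100, 1, 0.1, 0.1)
        trajs = [simulate_sbm(ORIGIN, grid, 0.5, s) for s in range(2000)]
        lags, msd, _ = msd_curve(trajs)
        d_a = sbm_diffusivity(0.5)
        t0 = grid.flat_times[0]
        pred = 6 * d_a * ((t0 + lags) ** 0.5 - t0**0.5)
        assert np.allclose(msd, pred, rtol=0.1)

    def test_boundary_alpha(self):
        grid = TimeGrid(3, 1)
        simulate_sbm(ORIGIN, grid, 2.0, 0)  # accepted
        with pytest.raises(ValueError):
            simulate_sbm(ORIGIN, grid, 2.01, 0)
        with pytest.raises(ValueError):
            simulate_sbm(ORIGIN, grid, 0.0, 0)


class TestBrownianLimits:
    """Each simulator's Brownian parameterization matches BM step moments."""

    @pytest.mark.parametrize(
        "label,make",
        [
            ("DBM_v0", lambda g, s: simulate_dbm(ORIGIN, g, 0.5, (0, 0, 0), s)),
            ("FBM_h05", lambda g, s: simulate_fbm(ORIGIN, g, 0.5, 0.5, s)),
            ("SBM_a1", lambda g, s: simulate_sbm(ORIGIN, g, 1.0, s)),
            (
                "ATTM_deg",
                lambda g, s: simulate_attm(
                    ORIGIN, g, 0.8, 1.2, s, d_support=(0.5, 0.5), d_scale=1.0
                ),
            ),
        ],
    )
    def test_brownian_limit_moments(self, label, make):
        grid = TimeGrid(2001, 1, 0.01, 0.01)
        ref = simulate_bm(ORIGIN, grid, 0.5, 999)
        steps_ref = np.diff(ref.flat_positions, axis=0).ravel()
        steps = np.diff(make(grid, 1000).flat_positions, axis=0).ravel()
        se = math.sqrt(steps.var() / len(steps) + steps_ref.var() / len(steps_ref))
        assert abs(steps.mean() - steps_ref.mean()) < 4 * se
        assert steps.var() == pytest.approx(steps_ref.var(), rel=0.1)
        _, p = stats.ks_2samp(steps, steps_ref)
        assert p > 1e-4


class TestCenterAndRescale:
    def test_straight_line_scaled_to_target_span(self):
        grid = TimeGrid(100, 1, 0.1, 0.1)
        pos = np.zeros((100, 1, 3))
        pos[:, 0, 0] = np.linspace(0, 100.0, 100)  # 100 um line along x
        traj = Trajectory(pos, grid, "LW")
        out = center_and_rescale(traj, 4.26, margin=0.1)
        span = np.ptp(out.flat_positions[:, 0])
        assert span == pytest.approx(4.26 * 0.8)

    def test_trajectory_already_inside_only_translated(self):
        grid = TimeGrid(10, 1, 0.1, 0.1)
        rng = np.random.default_rng(0)
        pos = 0.1 * rng.standard_normal((10, 1, 3))
        traj = Trajectory(pos, grid, "BM")
        out = center_and_rescale(traj, 4.26, margin=0.1)
        shifted = out.flat_positions - out.flat_positions.mean(axis=0)
        original = traj.flat_positions - traj.flat_positions.mean(axis=0)
        assert np.allclose(shifted, original)
        assert np.allclose(out.flat_positions[:, :2].mean(axis=0), 2.13)

    def test_constant_trajectory_moved_to_centre(self):
        grid = TimeGrid(4, 2)
        traj = Trajectory(np.full((4, 2, 3), 7.0), grid, "BM")
        out = center_and_rescale(traj, 4.0, margin=0.1)
        assert np.allclose(out.positions[..., :2], 2.0)
        assert np.allclose(out.positions[..., 2], 0.0)

    def test_invalid_margin_rejected(self):
        grid = TimeGrid(2, 1)
        traj = Trajectory(np.zeros((2, 1, 3)), grid, "BM")
        with pytest.raises(ValueError):
            center_and_rescale(traj, 4.0, margin=0.6)


class TestMsdCurve:
    def test_bm_slope_near_one(self, uniform_grid):
        trajs = [simulate_bm(ORIGIN, uniform_grid, 1.0, s) for s in range(300)]
        _, _, slope = msd_curve(trajs)
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_constant_trajectories_flagged(self, uniform_grid):
        trajs = [
            Trajectory(np.zeros((100, 1, 3)), uniform_grid, "BM") for _ in range(3)
        ]
        lags, msd, slope = msd_curve(trajs)
        assert np.all(msd == 0)
        assert slope is None

    def test_single_point_rejected(self):
        grid = TimeGrid(1, 1)
        traj = Trajectory(np.zeros((1, 1, 3)), grid, "BM")
        with pytest.raises(ValueError):
            msd_curve([traj])


class TestDispatchAndReproducibility:
    @pytest.mark.parametrize("model", ["BM", "DBM", "ATTM", "CTRW", "FBM", "LW", "SBM"])
    def test_all_models_reproducible_from_seed(self, model):
        grid = TimeGrid(6, 4)
        params = MotionParams(model=model, hurst=0.3, sbm_alpha=0.5)
        a = simulate(ORIGIN, grid, params, 77)
        b = simulate(ORIGIN, grid, params, 77)
        assert np.array_equal(a.positions, b.positions)
        assert a.model_label == model
        assert a.positions.shape == (6, 4, 3)
        assert np.all(np.isfinite(a.positions))
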