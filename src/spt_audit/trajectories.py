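"""Single-particle 3D trajectory simulators on a frame/interpolation time grid.

Seven motion models are provided: Brownian motion (BM), drifted BM (DBM),
annealed transient time motion (ATTM), continuous-time random walks (CTRW),
fractional BM (FBM, sampled by circulant embedding), Lévy walks (LW) and
scaled BM (SBM).  All simulators place the particle at a caller-supplied
initial position and populate positions on the acquisition grid: ``K``
interpolation points per frame spread uniformly over the exposure window,
with the detector dead time inserted between frames.

Positions are in micrometres, times in seconds, diffusivities in µm²/s.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.linalg import cholesky, toeplitz

__all__ = [
    "TimeGrid",
    "Trajectory",
    "MotionParams",
    "InitialPositionPrior",
    "draw_initial_position",
    "draw_drift_velocity",
    "simulate",
    "simulate_bm",
    "simulate_dbm",
    "simulate_attm",
    "simulate_ctrw",
    "simulate_fbm",
    "simulate_lw",
    "simulate_sbm",
    "center_and_rescale",
    "msd_curve",
    "MODEL_NAMES",
]

MODEL_NAMES = ("BM", "DBM", "ATTM", "CTRW", "FBM", "LW", "SBM")


def _rng(seed) -> np.random.Generator:
    """Coerce an integer seed or an existing Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# time grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeGrid:
    """Acquisition time grid: N frames with K intraframe interpolation points.

    The K points sit at the midpoints of K equal sub-intervals of each
    frame's exposure window, so successive intraframe points are spaced
    ``exposure / k_interp`` apart and the step bridging two frames spans the
    dead time ``frame_period - exposure`` in addition.
    """

    n_frames: int
    k_interp: int
    frame_period: float = 0.033
    exposure: float = 0.030

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError(f"n_frames must be >= 1, got {self.n_frames}")
        if self.k_interp < 1:
            raise ValueError(f"k_interp must be >= 1, got {self.k_interp}")
        if self.frame_period <= 0:
            raise ValueError("frame_period must be positive")
        if not 0 < self.exposure <= self.frame_period:
            raise ValueError(
                f"exposure must lie in (0, frame_period={self.frame_period}], "
                f"got {self.exposure}"
            )

    @property
    def dead_time(self) -> float:
        return self.frame_period - self.exposure

    @property
    def times(self) -> np.ndarray:
        """(N, K) matrix of sample times in seconds."""
        n = np.arange(self.n_frames)[:, None]
        k = np.arange(self.k_interp)[None, :]
        return n * self.frame_period + (k + 0.5) * self.exposure / self.k_interp

    @property
    def flat_times(self) -> np.ndarray:
        return self.times.reshape(-1)

    @property
    def n_points(self) -> int:
        return self.n_frames * self.k_interp

    def to_dict(self) -> dict:
        return {
            "n_frames": self.n_frames,
            "k_interp": self.k_interp,
            "frame_period_s": self.frame_period,
            "exposure_s": self.exposure,
        }


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Positions of one particle on a :class:`TimeGrid`.

    ``positions`` has shape (N, K, 3) in micrometres.
    """

    positions: np.ndarray
    grid: TimeGrid
    model_label: str = "BM"
    ground_truth_params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        expected = (self.grid.n_frames, self.grid.k_interp, 3)
        if self.positions.shape != expected:
            raise ValueError(
                f"positions shape {self.positions.shape} inconsistent with grid "
                f"{expected}"
            )
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite entries")

    @property
    def flat_positions(self) -> np.ndarray:
        return self.positions.reshape(-1, 3)

    def mean_lateral(self) -> np.ndarray:
        return self.flat_positions[:, :2].mean(axis=0)


@dataclass(frozen=True)
class InitialPositionPrior:
    """Gaussian prior for the first position, centred on the optical axis."""

    mu: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sigma_xy: float = 0.0963
    sigma_z: float = 0.3738

    def __post_init__(self):
        if self.sigma_xy < 0 or self.sigma_z < 0:
            raise ValueError("PSF widths must be non-negative")
        if self.mu[2] != 0.0:
            raise ValueError("prior mean must lie in the focal plane (mu_z = 0)")


@dataclass(frozen=True)
class MotionParams:
    """Motion-model parameter record, dispatched by :func:`simulate`.

    Only the fields relevant to ``model`` are consulted.
    """

    model: Literal["BM", "DBM", "ATTM", "CTRW", "FBM", "LW", "SBM"] = "BM"
    diffusivity: float = 1.0
    drift_velocity: tuple[float, float, float] = (0.5, 0.5, 0.0)
    attm_sigma_exp: float = 0.8
    attm_gamma: float = 1.2
    ctrw_alpha: float = 0.7
    tau0: float = 0.003
    hurst: float = 0.5
    lw_sigma_exp: float = 1.5
    speed: float = 1.0
    sbm_alpha: float = 1.0

    def __post_init__(self):
        if self.model not in MODEL_NAMES:
            raise ValueError(f"unknown motion model {self.model!r}")

    def to_dict(self) -> dict:
        d = {"model": self.model}
        if self.model in ("BM", "DBM", "CTRW", "FBM"):
            d["diffusivity_um2_s"] = self.diffusivity
        if self.model == "DBM":
            d["drift_velocity_um_s"] = list(self.drift_velocity)
        if self.model == "ATTM":
            d["attm_sigma_exp"] = self.attm_sigma_exp
            d["attm_gamma"] = self.attm_gamma
        if self.model == "CTRW":
            d["ctrw_alpha"] = self.ctrw_alpha
            d["tau0_s"] = self.tau0
        if self.model == "FBM":
            d["hurst"] = self.hurst
        if self.model == "LW":
            d["lw_sigma_exp"] = self.lw_sigma_exp
            d["speed_um_s"] = self.speed
        if self.model == "SBM":
            d["sbm_alpha"] = self.sbm_alpha
        return d


# ---------------------------------------------------------------------------
# initial position
# ---------------------------------------------------------------------------


def draw_initial_position(prior: InitialPositionPrior, rng_seed) -> np.ndarray:
    """Sample the first position from N(mu, diag(sxy^2, sxy^2, sz^2))."""
    rng = _rng(rng_seed)
    scale = np.array([prior.sigma_xy, prior.sigma_xy, prior.sigma_z])
    return np.asarray(prior.mu, dtype=float) + scale * rng.standard_normal(3)


def draw_drift_velocity(rng_seed) -> np.ndarray:
    """Draw an in-plane drift v (x̂ + ŷ) with speed v ~ U(0, 1] µm/s.

    The open lower limit is enforced at machine precision: a draw of exactly
    zero is replaced by ``eps``.
    """
    rng = _rng(rng_seed)
    v = 1.0 - rng.uniform(0.0, 1.0)  # in (0, 1]
    v = max(v, np.finfo(float).eps)
    return np.array([v, v, 0.0])


# ---------------------------------------------------------------------------
# shared Gaussian-increment core
# ---------------------------------------------------------------------------


def _gaussian_path(
    r1: np.ndarray,
    grid: TimeGrid,
    step_std: np.ndarray,
    rng: np.random.Generator,
    drift: np.ndarray | None = None,
) -> np.ndarray:
    """Cumulate independent Gaussian increments with per-step std (L-1,)."""
    n_steps = grid.n_points - 1
    pos = np.empty((grid.n_points, 3))
    pos[0] = r1
    if n_steps:
        incr = rng.standard_normal((n_steps, 3)) * step_std[:, None]
        if drift is not None:
            incr += drift
        pos[1:] = r1 + np.cumsum(incr, axis=0)
    return pos.reshape(grid.n_frames, grid.k_interp, 3)


def _as_r1(r1) -> np.ndarray:
    r1 = np.asarray(r1, dtype=float).reshape(3)
    if not np.all(np.isfinite(r1)):
        raise ValueError("initial position must be finite")
    return r1


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------


def simulate_bm(r1, grid: TimeGrid, diffusivity: float, rng_seed) -> Trajectory:
    """Brownian motion: increments N(0, 2 I D Δt) about the previous position."""
    if diffusivity < 0:
        raise ValueError(f"diffusivity must be >= 0, got {diffusivity}")
    r1 = _as_r1(r1)
    rng = _rng(rng_seed)
    dts = np.diff(grid.flat_times)
    std = np.sqrt(2.0 * diffusivity * dts)
    pos = _gaussian_path(r1, grid, std, rng)
    return Trajectory(pos, grid, "BM", {"diffusivity": diffusivity})


def simulate_dbm(r1, grid: TimeGrid, diffusivity: float, velocity, rng_seed) -> Trajectory:
    """Drifted BM: BM increments plus deterministic flow v Δt.

    Uses the same random stream discipline as :func:`simulate_bm`, so with
    ``velocity = 0`` and an identical seed the output is bit-identical to BM.
    """
    if diffusivity < 0:
        raise ValueError(f"diffusivity must be >= 0, got {diffusivity}")
    r1 = _as_r1(r1)
    v = np.asarray(velocity, dtype=float).reshape(3)
    rng = _rng(rng_seed)
    dts = np.diff(grid.flat_times)
    std = np.sqrt(2.0 * diffusivity * dts)
    pos = _gaussian_path(r1, grid, std, rng, drift=v[None, :] * dts[:, None])
    return Trajectory(
        pos, grid, "DBM", {"diffusivity": diffusivity, "velocity": v.tolist()}
    )


def simulate_attm(
    r1,
    grid: TimeGrid,
    sigma_exp: float,
    gamma_exp: float,
    rng_seed,
    d_support: tuple[float, float] = (1e-3, 1.0),
    d_scale: float = 1.0,
    tau_unit: float | None = None,
) -> Trajectory:
    """Annealed transient time motion: piecewise BM with power-law diffusivity.

    Local dimensionless diffusivities d are drawn from P(d) ∝ d^(ς-1)
    truncated to ``d_support`` (inverse-CDF sampling); the patch persists for
    a sojourn τ = d^(-γ) · tau_unit after which d is redrawn, in continuous
    time.  The physical patch diffusivity is ``d_scale * d`` µm²/s and the
    effective anomalous exponent is α = ς/γ.
    """
    if sigma_exp <= 0:
        raise ValueError(f"sigma_exp must be > 0, got {sigma_exp}")
    if not sigma_exp < gamma_exp < sigma_exp + 1:
        raise ValueError(
            f"gamma must lie in (sigma_exp, sigma_exp + 1) = "
            f"({sigma_exp}, {sigma_exp + 1}), got {gamma_exp}"
        )
    d_lo, d_hi = d_support
    if not 0 < d_lo <= d_hi:
        raise ValueError(f"invalid diffusivity support {d_support}")
    r1 = _as_r1(r1)
    rng = _rng(rng_seed)
    if tau_unit is None:
        tau_unit = grid.frame_period

    t = grid.flat_times
    span = t[-1] - t[0]

    # continuous-time patch sequence covering the observation window
    patch_d, patch_tau = [], []
    elapsed = 0.0
    while elapsed <= span:
        u = rng.uniform()
        if d_hi == d_lo:
            d = d_lo
        else:
            d = (d_lo**sigma_exp + u * (d_hi**sigma_exp - d_lo**sigma_exp)) ** (
                1.0 / sigma_exp
            )
        tau = d ** (-gamma_exp) * tau_unit
        patch_d.append(d)
        patch_tau.append(tau)
        elapsed += tau

    # cumulative integral of D(t) at the patch knots -> per-interval variance
    knots = np.concatenate([[0.0], np.cumsum(patch_tau)]) + t[0]
    cum = np.concatenate([[0.0], np.cumsum(np.array(patch_d) * np.array(patch_tau))])
    cum_at = np.interp(t, knots, cum) * d_scale
    var = 2.0 * np.diff(cum_at)  # per axis, per grid interval
    pos = _gaussian_path(r1, grid, np.sqrt(var), rng)
    return Trajectory(
        pos,
        grid,
        "ATTM",
        {
            "sigma_exp": sigma_exp,
            "gamma_exp": gamma_exp,
            "d_support": tuple(d_support),
            "d_scale": d_scale,
            "tau_unit": tau_unit,
            "patch_d": patch_d,
            "patch_tau": patch_tau,
            "alpha": sigma_exp / gamma_exp,
        },
    )


def simulate_ctrw(
    r1,
    grid: TimeGrid,
    alpha: float,
    diffusivity: float,
    tau0: float,
    rng_seed,
    tau_min: float | None = None,
) -> Trajectory:
    """Continuous-time random walk: Pareto waits decoupled from Gaussian jumps.

    Waiting times have density ∝ τ^-(α+1) with lower cutoff ``tau_min``
    (default: one interpolation interval); jumps are N(0, 2 I D τ0) and the
    position is piecewise-constant between jump events.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if diffusivity <= 0:
        raise ValueError(f"diffusivity must be > 0, got {diffusivity}")
    if tau0 <= 0:
        raise ValueError(f"tau0 must be > 0, got {tau0}")
    r1 = _as_r1(r1)
    rng = _rng(rng_seed)
    if tau_min is None:
        tau_min = grid.exposure / grid.k_interp

    t = grid.flat_times
    span = t[-1] - t[0]
    waits = []
    elapsed = 0.0
    while elapsed <= span:
        w = tau_min * rng.uniform() ** (-1.0 / alpha)  # Pareto(alpha, tau_min)
        waits.append(w)
        elapsed += w
    event_times = t[0] + np.cumsum(waits)
    jumps = rng.standard_normal((len(waits), 3)) * math.sqrt(
        2.0 * diffusivity * tau0
    )
    cum_jumps = np.vstack([np.zeros(3), np.cumsum(jumps, axis=0)])
    n_done = np.searchsorted(event_times, t, side="right")
    pos = r1 + cum_jumps[n_done]
    return Trajectory(
        pos.reshape(grid.n_frames, grid.k_interp, 3),
        grid,
        "CTRW",
        {
            "alpha": alpha,
            "diffusivity": diffusivity,
            "tau0": tau0,
            "tau_min": tau_min,
            "n_jumps": int(n_done[-1]),
        },
    )


def _fgn_autocov(n_lags: int, hurst: float) -> np.ndarray:
    """Autocovariance γ_ℓ of unit-variance fractional Gaussian noise, ℓ=0..n."""
    k = np.arange(n_lags + 1, dtype=float)
    h2 = 2.0 * hurst
    return 0.5 * (np.abs(k + 1) ** h2 - 2 * np.abs(k) ** h2 + np.abs(k - 1) ** h2)


def _fgn_davies_harte(
    n_steps: int, hurst: float, n_axes: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample (n_steps, n_axes) columns of unit-variance fGn.

    The circulant embedding of circ(γ_ℓ) is diagonalized by FFT; complex
    white noise is scaled by the eigenvalue square roots and transformed
    back, the real part giving exact stationary Gaussian noise with
    autocovariance γ_ℓ.  Falls back to a dense Cholesky factorization (with a
    warning) if the embedding has a negative eigenvalue.
    """
    g = _fgn_autocov(n_steps, hurst)
    row = np.concatenate([g, g[-2:0:-1]]) if n_steps > 1 else g[:1]
    lam = np.fft.fft(row).real
    if lam.min() < -1e-8 * max(lam.max(), 1.0):
        warnings.warn(
            "negative circulant eigenvalue in circulant embedding; "
            "falling back to exact Cholesky sampling",
            RuntimeWarning,
        )
        cov = toeplitz(g[:n_steps])
        chol = cholesky(cov, lower=True)
        return chol @ rng.standard_normal((n_steps, n_axes))
    lam = np.clip(lam, 0.0, None)
    m = len(row)
    z = rng.standard_normal((m, n_axes)) + 1j * rng.standard_normal((m, n_axes))
    x = np.fft.fft(np.sqrt(lam / m)[:, None] * z, axis=0)
    return x[:n_steps].real


def simulate_fbm(r1, grid: TimeGrid, hurst: float, diffusivity: float, rng_seed) -> Trajectory:
    """Fractional BM via circulant-embedding sampling of fractional noise.

    Per-axis increments over the uniform simulation step δ are fGn scaled by
    sqrt(2 D) δ^H, so Var(R_t - R_1) = 2 D (t - t_1)^(2H) per axis; the three
    axes are independent.  Grid times must (up to rounding) sit on a uniform
    lattice of pitch ``exposure / k_interp``; the dead-time gap is snapped to
    the nearest lattice point.
    """
    if not 0 < hurst < 1:
        raise ValueError(f"hurst must lie in (0, 1), got {hurst}")
    if diffusivity <= 0:
        raise ValueError(f"diffusivity must be > 0, got {diffusivity}")
    r1 = _as_r1(r1)
    rng = _rng(rng_seed)

    t = grid.flat_times
    if grid.n_points == 1:
        return Trajectory(
            np.tile(r1, (1, 1, 1)), grid, "FBM",
            {"hurst": hurst, "diffusivity": diffusivity},
        )
    delta = grid.exposure / grid.k_interp
    idx = np.rint((t - t[0]) / delta).astype(int)
    if np.any(np.diff(idx) < 1):
        raise ValueError("grid times too close for FBM lattice resolution")
    n_steps = idx[-1]
    fgn = _fgn_davies_harte(n_steps, hurst, 3, rng)
    incr = math.sqrt(2.0 * diffusivity) * delta**hurst * fgn
    path = np.vstack([np.zeros(3), np.cumsum(incr, axis=0)])
    pos = r1 + path[idx]
    return Trajectory(
        pos.reshape(grid.n_frames, grid.k_interp, 3),
        grid,
        "FBM",
        {"hurst": hurst, "diffusivity": diffusivity, "lattice_step": delta},
    )


def simulate_lw(
    r1,
    grid: TimeGrid,
    sigma_exp: float,
    speed: float,
    rng_seed,
    tau_min: float | None = None,
) -> Trajectory:
    """Lévy walk: ballistic flights of Pareto-distributed duration.

    Each flight moves at constant speed along a direction sampled
    isotropically from the unit sphere; positions are linear within flights.
    Anomalous exponent: α = 2 for ς in (0, 1), α = 3 - ς for ς in (1, 2).
    """
    if not 0 < sigma_exp < 2:
        raise ValueError(f"sigma_exp must lie in (0, 2), got {sigma_exp}")
    if speed <= 0:
        raise ValueError(f"speed must be > 0, got {speed}")
    r1 = _as_r1(r1)
    rng = _rng(rng_seed)
    if tau_min is None:
        tau_min = grid.exposure / grid.k_interp

    t = grid.flat_times
    span = t[-1] - t[0]
    durations = []
    elapsed = 0.0
    while elapsed <= span:
        d = tau_min * rng.uniform() ** (-1.0 / sigma_exp)
        durations.append(d)
        elapsed += d
    durations = np.array(durations)
    dirs = rng.standard_normal((len(durations), 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    knots_t = np.concatenate([[0.0], np.cumsum(durations)]) + t[0]
    knots_r = np.vstack(
        [np.zeros(3), np.cumsum(speed * durations[:, None] * dirs, axis=0)]
    )
    pos = r1 + np.column_stack(
        [np.interp(t, knots_t, knots_r[:, ax]) for ax in range(3)]
    )
    return Trajectory(
        pos.reshape(grid.n_frames, grid.k_interp, 3),
        grid,
        "LW",
        {
            "sigma_exp": sigma_exp,
            "speed": speed,
            "tau_min": tau_min,
            "n_flights": len(durations),
        },
    )


def sbm_diffusivity(alpha: float) -> float:
    """Age-dependent diffusion coefficient D_α = 1 / (2 Γ(1 + α))."""
    return 1.0 / (2.0 * math.gamma(1.0 + alpha))


def simulate_sbm(
    r1, grid: TimeGrid, alpha: float, rng_seed, increment_convention: str = "power_of_time"
) -> Trajectory:
    """Scaled BM: independent Gaussian increments with ageing covariance.

    With the default ``power_of_time`` convention the per-axis increment
    variance is 2 D_α (t_ℓ^α - t_{ℓ-1}^α), making the ensemble MSD exactly
    6 D_α t^α; the alternative ``power_of_lag`` convention uses
    2 D_α (Δt_ℓ)^α.  D_α = 1 / (2 Γ(1 + α)).
    """
    if not 0 < alpha <= 2:
        raise ValueError(f"alpha must lie in (0, 2], got {alpha}")
    if increment_convention not in ("power_of_time", "power_of_lag"):
        raise ValueError(f"unknown increment convention {increment_convention!r}")
    r1 = _as_r1(r1)
    rng = _rng(rng_seed)
    d_alpha = sbm_diffusivity(alpha)
    t = grid.flat_times
    if increment_convention == "power_of_time":
        var = 2.0 * d_alpha * np.diff(t**alpha)
    else:
        var = 2.0 * d_alpha * np.diff(t) ** alpha
    pos = _gaussian_path(r1, grid, np.sqrt(var), rng)
    return Trajectory(
        pos,
        grid,
        "SBM",
        {"alpha": alpha, "d_alpha": d_alpha, "increment_convention": increment_convention},
    )


_SIMULATORS = {
    "BM": lambda r1, g, p, s: simulate_bm(r1, g, p.diffusivity, s),
    "DBM": lambda r1, g, p, s: simulate_dbm(r1, g, p.diffusivity, p.drift_velocity, s),
    "ATTM": lambda r1, g, p, s: simulate_attm(r1, g, p.attm_sigma_exp, p.attm_gamma, s),
    "CTRW": lambda r1, g, p, s: simulate_ctrw(r1, g, p.ctrw_alpha, p.diffusivity, p.tau0, s),
    "FBM": lambda r1, g, p, s: simulate_fbm(r1, g, p.hurst, p.diffusivity, s),
    "LW": lambda r1, g, p, s: simulate_lw(r1, g, p.lw_sigma_exp, p.speed, s),
    "SBM": lambda r1, g, p, s: simulate_sbm(r1, g, p.sbm_alpha, s),
}


def simulate(r1, grid: TimeGrid, params: MotionParams, rng_seed) -> Trajectory:
    """Dispatch to the simulator named by ``params.model``."""
    return _SIMULATORS[params.model](r1, grid, params, rng_seed)


# ---------------------------------------------------------------------------
# post-processing
# ---------------------------------------------------------------------------


def center_and_rescale(
    traj: Trajectory, roi_extent: float, margin: float = 0.1
) -> Trajectory:
    """Shrink persistent trajectories into the ROI and centre their centroid.

    A single uniform scalar (never > 1) is applied to all three axes so the
    larger lateral coordinate span fits within ``roi_extent * (1 - 2 margin)``;
    the lateral centroid is then translated to the ROI centre and the axial
    centroid to the focal plane.
    """
    if roi_extent <= 0:
        raise ValueError("roi_extent must be positive")
    if not 0 <= margin < 0.5:
        raise ValueError(f"margin must lie in [0, 0.5), got {margin}")
    flat = traj.flat_positions
    span = np.ptp(flat[:, :2], axis=0).max()
    target = roi_extent * (1.0 - 2.0 * margin)
    scale = 1.0 if span <= 0 else min(1.0, target / span)
    centroid = flat.mean(axis=0)
    centre = np.array([roi_extent / 2.0, roi_extent / 2.0, 0.0])
    pos = (traj.positions - centroid) * scale + centre
    params = dict(traj.ground_truth_params)
    params["rescale"] = {"scale": scale, "roi_extent": roi_extent, "margin": margin}
    return Trajectory(pos, traj.grid, traj.model_label, params)


def msd_curve(
    trajectories: Sequence[Trajectory],
    max_lag: int | None = None,
    mode: str = "ensemble",
    min_lag: int = 1,
) -> tuple[np.ndarray, np.ndarray, float | None]:
    """Ensemble MSD (optionally time-averaged) with a fitted log-log slope.

    ``mode='ensemble'`` averages |R(t) - R(t_first)|² over the ensemble only,
    which recovers the anomalous exponent for ageing, weakly non-ergodic
    processes (CTRW, SBM, ATTM).  ``mode='time_averaged'`` additionally
    averages over sliding windows; for those models its slope approaches 1
    regardless of the exponent.  Lags are counted in grid steps and converted
    to seconds with the mean step duration (exact on uniform grids).  Returns
    ``(lag_s, msd_um2, slope)``; the slope is ``None`` (flagged) when the MSD
    is degenerate.
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    if mode not in ("ensemble", "time_averaged"):
        raise ValueError(f"unknown MSD mode {mode!r}")
    n_pts = trajectories[0].grid.n_points
    if n_pts < 2:
        raise ValueError("trajectories must have at least two time points")
    if max_lag is None:
        max_lag = n_pts // 2
    max_lag = min(max_lag, n_pts - 1)
    dt = float(np.mean(np.diff(trajectories[0].grid.flat_times)))
    lags = np.arange(1, max_lag + 1)
    msd = np.zeros(max_lag)
    for traj in trajectories:
        flat = traj.flat_positions
        if mode == "ensemble":
            d = flat[lags] - flat[0]
            msd += np.sum(d * d, axis=1)
        else:
            for i, m in enumerate(lags):
                d = flat[m:] - flat[:-m]
                msd[i] += np.mean(np.sum(d * d, axis=1))
    msd /= len(trajectories)
    lag_s = lags * dt
    sel = lags >= min_lag
    if np.any(msd[sel] <= 0):
        return lag_s, msd, None
    slope = float(np.polyfit(np.log(lag_s[sel]), np.log(msd[sel]), 1)[0])
    return lag_s, msd, slope
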