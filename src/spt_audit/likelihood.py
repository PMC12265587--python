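"""Decomposed log-likelihood of a widefield SPT image stack.

The log-likelihood splits into three additive terms: an initial-position
Gaussian term, a pixel-wise Gamma emission term, and a motion
(transition-density) term.  The initial-position term is booked on the
emission side of the contribution accounting; the contribution fraction of
the emission side uses absolute values of the two signed log-terms,

    emission_fraction = |ln_initial + ln_emission| / (|..| + |ln_motion|).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from spt_audit.imaging import (
    CameraParams,
    EmissionParams,
    ExpectedSignalStack,
    ImageStack,
    OpticsParams,
    expected_signal,
)
from spt_audit.trajectories import InitialPositionPrior, Trajectory, sbm_diffusivity

__all__ = [
    "LogLikDecomposition",
    "log_initial",
    "log_emission",
    "log_motion_bm",
    "log_motion_alt",
    "decompose",
    "emission_fraction",
    "fit_bm_diffusivity",
]

DEFAULT_W_FLOOR = 1e-3  # ADU floor applied inside ln(w)


@dataclass(frozen=True)
class LogLikDecomposition:
    """The three signed terms of the log-likelihood plus bookkeeping."""

    ln_initial: float
    ln_emission_pixels: float
    ln_motion: float
    n_clipped: int = 0

    @property
    def ln_total(self) -> float:
        return self.ln_initial + self.ln_emission_pixels + self.ln_motion

    @property
    def ln_emission_side(self) -> float:
        return self.ln_initial + self.ln_emission_pixels

    @property
    def emission_fraction(self) -> float:
        return emission_fraction(self.ln_emission_side, self.ln_motion)

    @property
    def motion_fraction(self) -> float:
        return 1.0 - self.emission_fraction


def emission_fraction(ln_emission_side: float, ln_motion: float) -> float:
    """|emission-side| share of the total absolute log-probability."""
    a = abs(ln_emission_side)
    b = abs(ln_motion)
    if a + b == 0:
        return 0.5
    return a / (a + b)


def log_initial(r1, prior: InitialPositionPrior) -> float:
    """Log-density of the trivariate Gaussian initial-position prior at R1."""
    if prior.sigma_xy <= 0 or prior.sigma_z <= 0:
        raise ValueError("prior widths must be strictly positive")
    r1 = np.asarray(r1, dtype=float).reshape(3)
    mu = np.asarray(prior.mu)
    norm = -math.log((2.0 * math.pi) ** 1.5 * prior.sigma_xy**2 * prior.sigma_z)
    quad = (
        ((r1[0] - mu[0]) ** 2 + (r1[1] - mu[1]) ** 2) / (2.0 * prior.sigma_xy**2)
        + r1[2] ** 2 / (2.0 * prior.sigma_z**2)
    )
    return norm - quad


def gamma_logpdf(w, shape, scale) -> np.ndarray:
    """Elementwise log Gamma(shape, scale) density, stable via ``gammaln``."""
    w = np.asarray(w, dtype=float)
    shape = np.asarray(shape, dtype=float)
    return (shape - 1.0) * np.log(w) - w / scale - shape * np.log(scale) - gammaln(shape)


def log_emission(
    w: ImageStack | np.ndarray,
    u: ExpectedSignalStack | np.ndarray,
    camera: CameraParams,
    w_floor: float = DEFAULT_W_FLOOR,
) -> tuple[float, int]:
    """Pixel-wise Gamma emission log-likelihood and the number of clipped pixels.

    Each pixel contributes log Gamma(w; shape = β u / 2, scale = 2 G / φ).
    Counts below ``w_floor`` ADU are clipped up to the floor before the
    logarithm (the density diverges at w = 0 when the shape is below 1);
    pixels with zero expected signal must record 0 ADU and contribute 0.
    """
    warr = w.w if isinstance(w, ImageStack) else np.asarray(w, dtype=float)
    uarr = u.u if isinstance(u, ExpectedSignalStack) else np.asarray(u, dtype=float)
    if warr.shape != uarr.shape:
        raise ValueError(f"shape mismatch: w {warr.shape} vs u {uarr.shape}")
    shape = 0.5 * camera.quantum_efficiency * uarr
    dark = shape == 0
    if np.any(dark):
        if np.any(warr[dark] > w_floor):
            raise ValueError("non-zero counts recorded on pixels with zero signal")
    n_clipped = int(np.count_nonzero(warr < w_floor) - np.count_nonzero(warr[dark] < w_floor))
    wc = np.maximum(warr, w_floor)
    ll = gamma_logpdf(wc[~dark], shape[~dark], camera.adu_scale)
    return float(np.sum(ll)), n_clipped


def _steps(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Consecutive displacements (L-1, 3) and lags (L-1,) over the flat grid."""
    flat = traj.flat_positions
    dts = np.diff(traj.grid.flat_times)
    if np.any(dts <= 0):
        raise ValueError("grid times must be strictly increasing")
    return np.diff(flat, axis=0), dts


def log_motion_bm(traj: Trajectory, diffusivity: float) -> float:
    """BM transition log-density summed over consecutive (n, k) steps.

    The step bridging frames n-1 and n uses the lag spanning the dead time.
    Each step contributes -[|ΔR|²/(4 D Δt) + (3/2) ln(4 π D Δt)].
    """
    if diffusivity <= 0:
        raise ValueError(f"diffusivity must be > 0, got {diffusivity}")
    if traj.grid.n_points < 2:
        raise ValueError("need at least two time points")
    dr, dts = _steps(traj)
    sq = np.sum(dr * dr, axis=1)
    return float(
        -np.sum(sq / (4.0 * diffusivity * dts))
        - 1.5 * np.sum(np.log(4.0 * math.pi * diffusivity * dts))
    )


def fit_bm_diffusivity(traj: Trajectory, d_min: float = 1e-6) -> float:
    """Maximum-likelihood BM diffusivity, D̂ = mean(|ΔR|² / (6 Δt))."""
    dr, dts = _steps(traj)
    sq = np.sum(dr * dr, axis=1)
    return max(float(np.mean(sq / dts) / 6.0), d_min)


def log_motion_alt(traj: Trajectory, model: str, params: dict) -> float:
    """Exact Gaussian motion log-density for DBM, SBM or FBM.

    DBM: BM density about the drifted mean.  SBM: independent increments with
    per-axis variance 2 D_α (t_ℓ^α - t_{ℓ-1}^α).  FBM: dense per-axis
    multivariate normal with covariance D [(s_i)^{2H} + (s_j)^{2H} -
    |s_i - s_j|^{2H}] of positions relative to R1 (limited to 512 points).
    """
    flat = traj.flat_positions
    t = traj.grid.flat_times
    if model == "DBM":
        v = np.asarray(params["velocity"], dtype=float).reshape(3)
        d = float(params["diffusivity"])
        if d <= 0:
            raise ValueError("diffusivity must be > 0")
        dr, dts = _steps(traj)
        dr = dr - v[None, :] * dts[:, None]
        sq = np.sum(dr * dr, axis=1)
        return float(
            -np.sum(sq / (4.0 * d * dts))
            - 1.5 * np.sum(np.log(4.0 * math.pi * d * dts))
        )
    if model == "SBM":
        alpha = float(params["alpha"])
        if not 0 < alpha <= 2:
            raise ValueError("alpha must lie in (0, 2]")
        d_alpha = sbm_diffusivity(alpha)
        var = 2.0 * d_alpha * np.diff(t**alpha)
        if np.any(var <= 0):
            raise ValueError("degenerate SBM step variance")
        dr = np.diff(flat, axis=0)
        sq = np.sum(dr * dr, axis=1)
        return float(
            -np.sum(sq / (2.0 * var)) - 1.5 * np.sum(np.log(2.0 * math.pi * var))
        )
    if model == "FBM":
        hurst = float(params["hurst"])
        d = float(params["diffusivity"])
        if not 0 < hurst < 1 or d <= 0:
            raise ValueError("invalid FBM parameters")
        if traj.grid.n_points > 512:
            raise ValueError("FBM dense covariance limited to 512 time points")
        s = t[1:] - t[0]
        h2 = 2.0 * hurst
        cov = d * (
            s[:, None] ** h2 + s[None, :] ** h2 - np.abs(s[:, None] - s[None, :]) ** h2
        )
        y = flat[1:] - flat[0]
        chol = np.linalg.cholesky(cov)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        sol = np.linalg.solve(chol, y)
        quad = np.sum(sol * sol)
        m = cov.shape[0]
        return float(-0.5 * quad - 1.5 * logdet - 1.5 * m * math.log(2.0 * math.pi))
    raise ValueError(f"no exact motion density available for model {model!r}")


def motion_loglik(traj: Trajectory, diffusivity: float | None = None) -> float:
    """Motion log-density using the trajectory's own law when available.

    BM/DBM/SBM/FBM use their exact Gaussian forms with the recorded
    ground-truth parameters; other models fall back to the BM density at the
    trajectory's maximum-likelihood diffusivity (or ``diffusivity`` if given).
    """
    p = traj.ground_truth_params
    if traj.model_label == "BM" and "diffusivity" in p:
        return log_motion_bm(traj, p["diffusivity"])
    if traj.model_label in ("DBM", "SBM", "FBM"):
        return log_motion_alt(traj, traj.model_label, p)
    d = diffusivity if diffusivity is not None else fit_bm_diffusivity(traj)
    return log_motion_bm(traj, d)


def decompose(
    stack: ImageStack,
    traj: Trajectory,
    optics: OpticsParams,
    camera: CameraParams,
    emission: EmissionParams,
    prior: InitialPositionPrior,
    diffusivity: float | None = None,
    motion_model: str = "auto",
    w_floor: float = DEFAULT_W_FLOOR,
) -> LogLikDecomposition:
    """Evaluate all three log-likelihood terms of a stack at a trajectory.

    The expected signal is recomputed from the trajectory on the stack's own
    pixel grid.  ``motion_model='auto'`` scores the motion term under the
    trajectory's own transition density when it has an exact Gaussian form
    and under BM (at the ML diffusivity unless ``diffusivity`` is given)
    otherwise; ``motion_model='BM'`` forces the BM density.
    """
    centre = (
        float(stack.x_edges[0] + stack.x_edges[-1]) / 2.0,
        float(stack.y_edges[0] + stack.y_edges[-1]) / 2.0,
    )
    u = expected_signal(traj, optics, camera, emission, centre_xy=centre)
    ln_init = log_initial(traj.positions[0, 0], prior)
    ln_emit, n_clipped = log_emission(stack, u, camera, w_floor=w_floor)
    if motion_model == "BM":
        d = diffusivity if diffusivity is not None else fit_bm_diffusivity(traj)
        ln_motion = log_motion_bm(traj, d)
    elif motion_model == "auto":
        ln_motion = motion_loglik(traj, diffusivity)
    else:
        raise ValueError(f"unknown motion_model {motion_model!r}")
    return LogLikDecomposition(ln_init, ln_emit, ln_motion, n_clipped)
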