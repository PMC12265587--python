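"""EMCCD imaging forward model.

Renders a trajectory into an expected photon image through a
pixel-integrated 3D Gaussian PSF (lateral width broadened by defocus) plus a
uniform background, then corrupts the expectation with the high-gain EMCCD
Gamma measurement model: w ~ Gamma(shape = beta*u/2, scale = 2*G/phi).

Image arrays are indexed ``[frame, row, col]`` with the row axis along y and
the column axis along x; the ROI's lower-left pixel corner sits at the
stored edge origin (micrometres).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from spt_audit.trajectories import Trajectory, _rng

__all__ = [
    "OpticsParams",
    "CameraParams",
    "EmissionParams",
    "ExpectedSignalStack",
    "ImageStack",
    "derive_psf_widths",
    "pixel_psf_integral",
    "expected_signal",
    "emccd_sample",
    "render_stack",
    "MIN_RELIABLE_GAIN",
]

#: below this electron-multiplying gain the pure-Gamma measurement model is
#: no longer an accurate stand-in for the full Poisson-Gamma-Normal chain
MIN_RELIABLE_GAIN = 210.0

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class OpticsParams:
    """Objective / emission optics.  Widths derive from (NA, n, λ) unless set."""

    numerical_aperture: float = 1.45
    refractive_index: float = 1.515
    wavelength_nm: float = 665.0
    magnification: float = 100.0
    sigma_xy_um: float | None = None
    sigma_z_um: float | None = None

    def __post_init__(self):
        if self.numerical_aperture > self.refractive_index:
            raise ValueError(
                f"numerical aperture {self.numerical_aperture} exceeds the "
                f"immersion refractive index {self.refractive_index}"
            )
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")

    @property
    def psf_widths_um(self) -> tuple[float, float]:
        return derive_psf_widths(self)


def derive_psf_widths(optics: OpticsParams) -> tuple[float, float]:
    """Gaussian-approximation PSF widths (µm): σ_xy = 0.21 λ/NA, σ_z = 0.78 n λ/NA².

    Explicit ``sigma_xy_um`` / ``sigma_z_um`` overrides pass through untouched.
    """
    lam_um = optics.wavelength_nm * 1e-3
    sxy = optics.sigma_xy_um
    sz = optics.sigma_z_um
    if sxy is None:
        sxy = 0.21 * lam_um / optics.numerical_aperture
    if sz is None:
        sz = 0.78 * optics.refractive_index * lam_um / optics.numerical_aperture**2
    return float(sxy), float(sz)


@dataclass(frozen=True)
class CameraParams:
    """EMCCD detector parameters (effective pixel size, i.e. at the sample)."""

    gain: float = 350.0
    conversion: float = 3.5  # e-/ADU
    quantum_efficiency: float = 0.95
    pixels_per_side: int = 32
    pixel_size_um: float = 0.133
    frame_period_s: float = 0.033
    exposure_s: float = 0.030

    def __post_init__(self):
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.conversion <= 0:
            raise ValueError("conversion factor must be positive")
        if not 0 < self.quantum_efficiency <= 1:
            raise ValueError(
                f"quantum_efficiency must lie in (0, 1], got {self.quantum_efficiency}"
            )
        if self.pixels_per_side < 1 or self.pixel_size_um <= 0:
            raise ValueError("invalid pixel geometry")
        if not 0 < self.exposure_s <= self.frame_period_s:
            raise ValueError("exposure must lie in (0, frame_period]")

    @property
    def roi_extent_um(self) -> float:
        return self.pixels_per_side * self.pixel_size_um

    @property
    def adu_scale(self) -> float:
        """Gamma scale parameter 2 G / φ (ADU per photoelectron pair)."""
        return 2.0 * self.gain / self.conversion


@dataclass(frozen=True)
class EmissionParams:
    photon_rate: float = 1e4  # 1/s
    background_flux: float = 1e5  # 1/µm² s
    n_emitters: int = 1

    def __post_init__(self):
        if self.photon_rate < 0 or self.background_flux < 0:
            raise ValueError("photon rates must be non-negative")
        if self.n_emitters != 1:
            raise ValueError("only single-emitter rendering is supported (M = 1)")


@dataclass
class ExpectedSignalStack:
    """Expected photon count per pixel per frame, with pixel edge coordinates."""

    u: np.ndarray  # (N, npix, npix)
    x_edges: np.ndarray  # (npix + 1,) µm
    y_edges: np.ndarray  # (npix + 1,) µm

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 3 or self.u.shape[1] != self.u.shape[2]:
            raise ValueError(f"u must be (N, P, P), got {self.u.shape}")
        if np.any(self.u < 0) or not np.all(np.isfinite(self.u)):
            raise ValueError("expected signal must be finite and non-negative")


@dataclass
class ImageStack:
    """Measured EMCCD counts in ADU, one page per frame."""

    w: np.ndarray  # (N, npix, npix)
    x_edges: np.ndarray
    y_edges: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 3 or self.w.shape[1] != self.w.shape[2]:
            raise ValueError(f"w must be (N, P, P), got {self.w.shape}")
        if np.any(self.w < 0):
            raise ValueError("ADU counts must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.w.shape[0]


def defocused_width(sigma_xy: float, sigma_z: float, z) -> np.ndarray:
    """Lateral PSF width broadened by defocus: σ_xy sqrt(1 + (Z/σ_z)²)."""
    return sigma_xy * np.sqrt(1.0 + (np.asarray(z, dtype=float) / sigma_z) ** 2)


def pixel_psf_integral(
    x_edges: np.ndarray,
    y_edges: np.ndarray,
    position,
    sigma_xy: float,
    sigma_z: float,
) -> np.ndarray:
    """Fraction of a unit emitter's photons landing in each pixel.

    Integrates the defocus-broadened 2D Gaussian centred at ``position``
    (X, Y, Z) over the pixel rectangles defined by the edge arrays, via
    error-function differences.  Values lie in [0, 1] and sum to 1 over an
    infinite plane.  Returns an array of shape (len(y_edges)-1,
    len(x_edges)-1); scalar edges for a single pixel are accepted.
    """
    x_edges = np.atleast_1d(np.asarray(x_edges, dtype=float))
    y_edges = np.atleast_1d(np.asarray(y_edges, dtype=float))
    if len(x_edges) < 2 or len(y_edges) < 2:
        raise ValueError("need at least two edges per axis")
    if np.any(np.diff(x_edges) <= 0) or np.any(np.diff(y_edges) <= 0):
        raise ValueError("pixel edges must be strictly increasing")
    x, y, z = np.asarray(position, dtype=float).reshape(3)
    sig = float(defocused_width(sigma_xy, sigma_z, z))
    cx = 0.5 * erf((x_edges - x) / (_SQRT2 * sig))
    cy = 0.5 * erf((y_edges - y) / (_SQRT2 * sig))
    return np.outer(np.diff(cy), np.diff(cx))


def _frame_fractions(
    positions: np.ndarray,
    x_edges: np.ndarray,
    y_edges: np.ndarray,
    sigma_xy: float,
    sigma_z: float,
) -> np.ndarray:
    """Summed PSF pixel fractions over one frame's (K, 3) positions."""
    z = positions[:, 2]
    sig = (sigma_xy * np.sqrt(1.0 + (z / sigma_z) ** 2))[:, None]
    nx = len(x_edges)
    # single erf dispatch over both axes
    args = np.empty((len(positions), nx + len(y_edges)))
    args[:, :nx] = x_edges[None, :] - positions[:, 0:1]
    args[:, nx:] = y_edges[None, :] - positions[:, 1:2]
    c = erf(args / (_SQRT2 * sig))
    fx = c[:, 1:nx] - c[:, : nx - 1]
    fy = c[:, nx + 1 :] - c[:, nx:-1]
    return 0.25 * (fy.T @ fx)  # (npix_y, npix_x), summed over K


def roi_edges(
    camera: CameraParams, centre_xy=None
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel edge coordinates for an ROI centred on ``centre_xy`` (µm)."""
    extent = camera.roi_extent_um
    if centre_xy is None:
        centre_xy = (extent / 2.0, extent / 2.0)
    edges = np.arange(camera.pixels_per_side + 1) * camera.pixel_size_um
    x_edges = edges + (centre_xy[0] - extent / 2.0)
    y_edges = edges + (centre_xy[1] - extent / 2.0)
    return x_edges, y_edges


def expected_signal(
    traj: Trajectory,
    optics: OpticsParams,
    camera: CameraParams,
    emission: EmissionParams,
    centre_xy=None,
) -> ExpectedSignalStack:
    """Expected photon count u[n, p] = F A_p τ + (H τ / K) Σ_k PSF mass.

    The exposure-time integral of the moving PSF is discretized as the
    average over the K intraframe positions; the background term uses the
    pixel area A_p = Δs² and the exposure τ = t_E.  The ROI is centred on the
    trajectory's mean lateral position unless ``centre_xy`` is given.
    """
    grid = traj.grid
    if not (
        math.isclose(grid.frame_period, camera.frame_period_s)
        and math.isclose(grid.exposure, camera.exposure_s)
    ):
        raise ValueError("trajectory grid timing inconsistent with camera timing")
    sigma_xy, sigma_z = derive_psf_widths(optics)
    if centre_xy is None:
        centre_xy = traj.mean_lateral()
    x_edges, y_edges = roi_edges(camera, centre_xy)
    tau = camera.exposure_s
    bg = emission.background_flux * camera.pixel_size_um**2 * tau
    per_position = emission.photon_rate * tau / grid.k_interp
    npix = camera.pixels_per_side
    u = np.empty((grid.n_frames, npix, npix))
    for n in range(grid.n_frames):
        u[n] = bg + per_position * _frame_fractions(
            traj.positions[n], x_edges, y_edges, sigma_xy, sigma_z
        )
    return ExpectedSignalStack(u, x_edges, y_edges)


def emccd_sample(
    u: ExpectedSignalStack | np.ndarray, camera: CameraParams, rng_seed
) -> np.ndarray:
    """Gamma-corrupt an expected-photon stack: w ~ Gamma(β u / 2, 2 G / φ).

    Pixels with exactly zero expectation emit exactly 0 ADU (degenerate
    Gamma).  Warns when the gain is below the high-gain validity threshold.
    """
    if camera.gain < MIN_RELIABLE_GAIN:
        warnings.warn(
            f"gain {camera.gain} is below {MIN_RELIABLE_GAIN}; the pure-Gamma "
            "measurement model may be inaccurate",
            UserWarning,
        )
    arr = u.u if isinstance(u, ExpectedSignalStack) else np.asarray(u, dtype=float)
    if np.any(arr < 0):
        raise ValueError("expected signal must be non-negative")
    rng = _rng(rng_seed)
    shape = 0.5 * camera.quantum_efficiency * arr
    w = np.zeros_like(arr)
    pos = shape > 0
    w[pos] = rng.gamma(shape[pos], camera.adu_scale)
    return w


def render_stack(
    traj: Trajectory,
    optics: OpticsParams,
    camera: CameraParams,
    emission: EmissionParams,
    rng_seed: int,
    centre_xy=None,
) -> ImageStack:
    """Compose :func:`expected_signal` and :func:`emccd_sample` into a stack."""
    u = expected_signal(traj, optics, camera, emission, centre_xy=centre_xy)
    w = emccd_sample(u, camera, rng_seed)
    metadata = {
        "seed": rng_seed if isinstance(rng_seed, (int, np.integer)) else None,
        "model": traj.model_label,
        "ground_truth_params": traj.ground_truth_params,
        "grid": traj.grid.to_dict(),
        "optics": {
            "numerical_aperture": optics.numerical_aperture,
            "refractive_index": optics.refractive_index,
            "wavelength_nm": optics.wavelength_nm,
            "magnification": optics.magnification,
            "sigma_xy_um": derive_psf_widths(optics)[0],
            "sigma_z_um": derive_psf_widths(optics)[1],
        },
        "camera": {
            "gain": camera.gain,
            "conversion_e_per_adu": camera.conversion,
            "quantum_efficiency": camera.quantum_efficiency,
            "pixels_per_side": camera.pixels_per_side,
            "pixel_size_um": camera.pixel_size_um,
            "frame_period_s": camera.frame_period_s,
            "exposure_s": camera.exposure_s,
        },
        "emission": {
            "photon_rate_per_s": emission.photon_rate,
            "background_flux_per_um2_s": emission.background_flux,
            "n_emitters": emission.n_emitters,
        },
    }
    return ImageStack(w, u.x_edges, u.y_edges, metadata)
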