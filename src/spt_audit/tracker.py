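"""Metropolis-within-Gibbs trajectory inference from an EMCCD image stack.

The sampler targets the full decomposed log-posterior — initial-position
Gaussian, pixel-wise Gamma emission term and a Brownian-motion transition
density — over the (N, K, 3) position array, optionally sampling the BM
diffusivity with a log-uniform prior.  Each iteration sweeps every frame
with three block proposals (rigid shift, per-point jitter, and a
Brownian-bridge independence draw whose prior ratio cancels its proposal
density), attempts an intraframe order reversal (the emission term is
permutation-symmetric in k), and, when D is sampled, a Metropolis step on
ln D plus a joint (D, intraframe-roughness) scaling move that decouples the
funnel between diffusivity and path roughness.  Random-walk proposal scales
adapt toward a 20-40% acceptance rate during the first third of the chain
and are frozen afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf, gammaln

from spt_audit.imaging import (
    CameraParams,
    EmissionParams,
    ImageStack,
    OpticsParams,
    derive_psf_widths,
)
from spt_audit.likelihood import DEFAULT_W_FLOOR, log_initial
from spt_audit.trajectories import InitialPositionPrior, TimeGrid, Trajectory, _rng

__all__ = [
    "PosteriorChain",
    "CredibleBands",
    "mcmc_track",
    "remove_burn_in",
    "credible_bands",
    "coverage_fraction",
]


@dataclass
class PosteriorChain:
    """MCMC samples of trajectories with per-sample log-probabilities."""

    samples: np.ndarray  # (S, N, K, 3)
    logliks: np.ndarray  # (S,)
    sampled_d: np.ndarray | None  # (S,) µm²/s, None when D is fixed
    acceptance: dict = field(default_factory=dict)
    seed: int | None = None
    grid: TimeGrid | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.samples) < 1:
            raise ValueError("chain must contain at least one sample")
        if not np.all(np.isfinite(self.logliks)):
            raise ValueError("log-likelihoods must be finite")

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass
class CredibleBands:
    """Equal-tailed per-frame, per-axis credible bounds at a stated level."""

    lower: np.ndarray  # (N, n_axes)
    upper: np.ndarray
    level: float
    axes: tuple[int, ...] = (0, 1)

    def __post_init__(self):
        if np.any(self.lower > self.upper):
            raise ValueError("lower bounds exceed upper bounds")


class _EmissionScorer:
    """Cached per-frame Gamma emission log-likelihood for proposal scoring."""

    def __init__(self, stack, optics, camera, emission, k_interp, w_floor):
        self.x_edges = np.asarray(stack.x_edges, dtype=float)
        self.y_edges = np.asarray(stack.y_edges, dtype=float)
        self.sigma_xy, self.sigma_z = derive_psf_widths(optics)
        self.beta = camera.quantum_efficiency
        self.scale = camera.adu_scale
        self.log_scale = math.log(self.scale)
        self.bg = emission.background_flux * camera.pixel_size_um**2 * camera.exposure_s
        self.per_position = emission.photon_rate * camera.exposure_s / k_interp
        w = np.maximum(stack.w, w_floor)
        self.logw = np.log(w)  # (N, P, P)
        self.wsum = stack.w.sum(axis=(1, 2)) / self.scale
        # constants folded out of the per-proposal evaluation:
        #   ll = sum[(shape - 1) log w] - wsum - log_scale sum[shape] - sum[gammaln]
        self._shape_bg = 0.5 * self.beta * self.bg
        self._shape_sig = 0.5 * self.beta * self.per_position
        self._logw_net = self.logw - self.log_scale  # (N, P, P)
        self._const = -self.logw.sum(axis=(1, 2)) - self.wsum
        # full-frame log-likelihood if every pixel saw background only;
        # per-proposal work is then confined to the PSF support rectangle
        npix = self.logw.shape[1]
        self._gl_bg = float(gammaln(self._shape_bg)) if self._shape_bg > 0 else 0.0
        self._bg_ll = (
            self._shape_bg * self._logw_net.sum(axis=(1, 2))
            - npix * npix * self._gl_bg
            + self._const
        )

    def frame_loglik(self, n: int, positions: np.ndarray) -> float:
        if self._shape_sig == 0.0:
            return float(self._bg_ll[n])
        z = positions[:, 2]
        sig = (self.sigma_xy * np.sqrt(1.0 + (z / self.sigma_z) ** 2))[:, None]
        nx = len(self.x_edges)
        args = np.empty((len(positions), nx + len(self.y_edges)))
        args[:, :nx] = self.x_edges[None, :] - positions[:, 0:1]
        args[:, nx:] = self.y_edges[None, :] - positions[:, 1:2]
        c = erf(args / (math.sqrt(2.0) * sig))
        fx = c[:, 1:nx] - c[:, : nx - 1]
        fy = c[:, nx + 1 :] - c[:, nx:-1]
        # support rectangle: pixels whose PSF mass is numerically negligible
        # contribute exactly the precomputed background terms
        thr = 4e-15
        cx = np.flatnonzero(fx.max(axis=0) > thr)
        cy = np.flatnonzero(fy.max(axis=0) > thr)
        if len(cx) == 0 or len(cy) == 0:
            return float(self._bg_ll[n])
        xs = slice(cx[0], cx[-1] + 1)
        ys = slice(cy[0], cy[-1] + 1)
        f = 0.25 * (fy[:, ys].T @ fx[:, xs])
        shape = self._shape_bg + self._shape_sig * f
        lw = self._logw_net[n, ys, xs]
        npr = f.size
        return float(
            self._bg_ll[n]
            + ((shape - self._shape_bg) * lw).sum()
            - gammaln(shape).sum()
            + npr * self._gl_bg
        )


def _motion_term(flat: np.ndarray, dts: np.ndarray, d: float) -> float:
    dr = flat[1:] - flat[:-1]
    sq = (dr * dr).sum(axis=1)
    return float(
        -(sq / dts).sum() / (4.0 * d) - 1.5 * np.log(4.0 * math.pi * d * dts).sum()
    )


def _quad_sum(flat: np.ndarray, dts: np.ndarray) -> float:
    """Sum of |dR|^2 / dt over consecutive steps."""
    dr = flat[1:] - flat[:-1]
    return float(((dr * dr).sum(axis=1) / dts).sum())


def _local_quad(prev, block, nxt, dts_loc: np.ndarray, buf: np.ndarray) -> float:
    """Quadratic form of the steps touching one frame block."""
    i = 0
    if prev is not None:
        buf[0] = prev
        i = 1
    k = len(block)
    buf[i : i + k] = block
    m = i + k
    if nxt is not None:
        buf[m] = nxt
        m += 1
    dr = buf[1:m] - buf[: m - 1]
    return float(((dr * dr).sum(axis=1) / dts_loc).sum())


def _bridge_proposal(
    prev, nxt, k: int, dts_loc: np.ndarray, d: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw a frame's K positions from the BM prior conditioned on neighbours.

    With both neighbours present this is the Brownian bridge; edge frames
    use a free backward/forward walk from the single anchor.  Because the
    proposal equals the motion-prior conditional, the Metropolis ratio for
    this move reduces to the emission-term delta.
    """
    block = np.empty((k, 3))
    xi = rng.standard_normal((k, 3))
    if prev is not None and nxt is not None:
        x = prev
        t_rem = float(dts_loc.sum())
        for j in range(k):
            dt = dts_loc[j]
            frac = dt / t_rem
            x = x + (nxt - x) * frac + math.sqrt(2.0 * d * dt * (1.0 - frac)) * xi[j]
            block[j] = x
            t_rem -= dt
    elif nxt is not None:  # first frame: walk backwards from the right anchor
        steps = np.sqrt(2.0 * d * dts_loc)[:, None] * xi
        block[::-1] = nxt + np.cumsum(steps[::-1], axis=0)
    elif prev is not None:  # last frame: walk forwards from the left anchor
        steps = np.sqrt(2.0 * d * dts_loc)[:, None] * xi
        block[:] = prev + np.cumsum(steps, axis=0)
    else:
        raise ValueError("bridge proposal needs at least one anchor")
    return block


def _init_centroids(stack: ImageStack, camera: CameraParams, emission, beta) -> np.ndarray:
    """Background-subtracted brightness centroid per frame (N, 2).

    The centroid is restricted to a small window around the brightest
    (box-smoothed) pixel so that background shot noise across the full ROI
    does not drag the estimate toward the ROI centre.
    """
    from scipy.ndimage import uniform_filter

    bg_adu = (
        emission.background_flux
        * camera.pixel_size_um**2
        * camera.exposure_s
        * beta
        * camera.gain
        / camera.conversion
    )
    xc = 0.5 * (stack.x_edges[:-1] + stack.x_edges[1:])
    yc = 0.5 * (stack.y_edges[:-1] + stack.y_edges[1:])
    npix = len(xc)
    out = np.empty((stack.n_frames, 2))
    centre = (
        0.5 * (stack.x_edges[0] + stack.x_edges[-1]),
        0.5 * (stack.y_edges[0] + stack.y_edges[-1]),
    )
    half = 3  # centroid window half-width in pixels
    for n in range(stack.n_frames):
        excess = stack.w[n] - bg_adu
        smooth = uniform_filter(excess, size=3, mode="nearest")
        iy, ix = np.unravel_index(np.argmax(smooth), smooth.shape)
        ys = slice(max(iy - half, 0), min(iy + half + 1, npix))
        xs = slice(max(ix - half, 0), min(ix + half + 1, npix))
        win = np.maximum(excess[ys, xs], 0.0)
        mass = win.sum()
        if mass <= 0:
            out[n] = centre
        else:
            out[n, 0] = (win.sum(axis=0) * xc[xs]).sum() / mass
            out[n, 1] = (win.sum(axis=1) * yc[ys]).sum() / mass
    return out


def mcmc_track(
    stack: ImageStack,
    optics: OpticsParams,
    camera: CameraParams,
    emission: EmissionParams,
    prior: InitialPositionPrior,
    k_interp: int | None = None,
    n_iter: int = 6000,
    rng_seed: int = 0,
    sample_d: bool = True,
    d_init: float | None = None,
    d_bounds: tuple[float, float] = (1e-3, 1e2),
    w_floor: float = DEFAULT_W_FLOOR,
) -> PosteriorChain:
    """Sample trajectories from the BM-model posterior of an image stack.

    ``k_interp`` defaults to the value recorded in the stack metadata.  When
    ``sample_d`` is true the BM diffusivity is sampled by a Metropolis step
    on ln D with a log-uniform prior over ``d_bounds``; otherwise D is fixed
    at ``d_init``.
    """
    if n_iter < 10:
        raise ValueError("n_iter too small")
    if k_interp is None:
        k_interp = int(stack.metadata.get("grid", {}).get("k_interp", 1))
    n_frames = stack.n_frames
    grid = TimeGrid(n_frames, k_interp, camera.frame_period_s, camera.exposure_s)
    dts = np.diff(grid.flat_times)
    rng = _rng(rng_seed)
    scorer = _EmissionScorer(stack, optics, camera, emission, k_interp, w_floor)

    # initialization: linear interpolation through per-frame brightness
    # centroids (flat initial paths would drive a sampled D to collapse)
    centroids = _init_centroids(stack, camera, emission, scorer.beta)
    frame_mid = grid.times.mean(axis=1)
    flat_t = grid.flat_times
    r = np.zeros((n_frames, k_interp, 3))
    for ax in range(2):
        r[:, :, ax] = np.interp(flat_t, frame_mid, centroids[:, ax]).reshape(
            n_frames, k_interp
        )
    if n_frames > 1:
        dc = np.diff(centroids, axis=0)
        d_hat = float(np.mean(np.sum(dc * dc, axis=1)) / (4.0 * camera.frame_period_s))
    else:
        d_hat = 1.0
    d = float(np.clip(d_init if d_init is not None else d_hat, *d_bounds))
    if not sample_d and d_init is not None:
        d = float(d_init)

    le = np.array([scorer.frame_loglik(n, r[n]) for n in range(n_frames)])
    flat = r.reshape(-1, 3)
    ln_motion = _motion_term(flat, dts, d) if n_frames * k_interp > 1 else 0.0
    ln_init = log_initial(r[0, 0], prior)

    # diagnostic: mean per-frame peak vs the expected background extreme
    bg_adu = scorer.bg * scorer.beta * camera.gain / camera.conversion
    bg_sd = math.sqrt(0.5 * scorer.beta * max(scorer.bg, 1e-12)) * scorer.scale
    npix2 = stack.w.shape[1] * stack.w.shape[2]
    bg_extreme = bg_adu + bg_sd * math.sqrt(2.0 * math.log(max(npix2, 2)))
    peak = float(np.mean(stack.w.max(axis=(1, 2))))
    low_information = bool(peak < bg_extreme + bg_sd)

    k = k_interp
    scale_rigid = np.full(n_frames, 0.05)
    scale_jitter = np.full(n_frames, 0.05)
    z_factor = 4.0
    d_step = 0.3
    n_warm = n_iter // 3
    adapt_every = 50
    acc = {
        "rigid": np.zeros(2),
        "jitter": np.zeros(2),
        "bridge": np.zeros(2),
        "d": np.zeros(2),
        "scale": np.zeros(2),
    }
    win = {"rigid": np.zeros((n_frames, 2)), "jitter": np.zeros((n_frames, 2)), "d": np.zeros(2)}

    samples = np.empty((n_iter, n_frames, k, 3))
    logliks = np.empty(n_iter)
    sampled_d = np.empty(n_iter) if sample_d else None
    lo, hi = math.log(d_bounds[0]), math.log(d_bounds[1])
    n_steps = len(dts)
    sumlog_dts = float(np.log(dts).sum()) if n_steps else 0.0
    buf = np.empty((k + 2, 3))
    log_uniform = lambda: math.log(rng.uniform())

    for it in range(n_iter):
        # one full cycle applies every move kind to every frame
        for kind in ("rigid", "jitter", "bridge"):
            for n in range(n_frames):
                prev = r[n - 1, -1] if n > 0 else None
                nxt = r[n + 1, 0] if n < n_frames - 1 else None
                i0 = n * k
                dts_loc = dts[max(i0 - 1, 0) : min(i0 + k, n_steps)]
                move = kind
                if move == "bridge" and (prev is None and nxt is None):
                    move = "rigid"
                cur = r[n]
                if move == "rigid":
                    step = scale_rigid[n] * rng.standard_normal(3)
                    step[2] *= z_factor
                    block = cur + step
                    # intraframe steps are shift-invariant: only the two
                    # boundary steps contribute to the motion delta
                    dquad = 0.0
                    if prev is not None:
                        a = block[0] - prev
                        b = cur[0] - prev
                        dquad += ((a @ a) - (b @ b)) / dts[i0 - 1]
                    if nxt is not None:
                        a = nxt - block[-1]
                        b = nxt - cur[-1]
                        dquad += ((a @ a) - (b @ b)) / dts[i0 + k - 1]
                    dmotion = -dquad / (4.0 * d)
                elif move == "jitter":
                    step = scale_jitter[n] * rng.standard_normal((k, 3))
                    step[:, 2] *= z_factor
                    block = cur + step
                    dmotion = (
                        -(
                            _local_quad(prev, block, nxt, dts_loc, buf)
                            - _local_quad(prev, cur, nxt, dts_loc, buf)
                        )
                        / (4.0 * d)
                        if len(dts_loc)
                        else 0.0
                    )
                else:
                    block = _bridge_proposal(prev, nxt, k, dts_loc, d, rng)
                    # the motion-prior ratio cancels the proposal density
                    dmotion = 0.0
                le_prop = scorer.frame_loglik(n, block)
                delta = le_prop - le[n] + dmotion
                if n == 0:
                    delta += log_initial(block[0], prior) - ln_init
                accepted = log_uniform() < delta
                if move in win:
                    win[move][n, 0] += accepted
                    win[move][n, 1] += 1
                acc[move][0] += accepted
                acc[move][1] += 1
                if accepted:
                    r[n] = block
                    le[n] = le_prop
                    if n == 0:
                        ln_init = log_initial(block[0], prior)
        # intraframe order-reversal: the emission term is exactly symmetric
        # under permutations of a frame's K positions, so this mixes the
        # ordering modes at the cost of the motion delta alone
        if k > 1:
            for n in range(n_frames):
                prev = r[n - 1, -1] if n > 0 else None
                nxt = r[n + 1, 0] if n < n_frames - 1 else None
                i0 = n * k
                dts_loc = dts[max(i0 - 1, 0) : min(i0 + k, n_steps)]
                if not len(dts_loc):
                    continue
                block = r[n, ::-1].copy()
                delta = (
                    -(
                        _local_quad(prev, block, nxt, dts_loc, buf)
                        - _local_quad(prev, r[n], nxt, dts_loc, buf)
                    )
                    / (4.0 * d)
                )
                if n == 0:
                    delta += log_initial(block[0], prior) - ln_init
                if log_uniform() < delta:
                    r[n] = block
                    if n == 0:
                        ln_init = log_initial(r[n, 0], prior)

        quad = _quad_sum(r.reshape(-1, 3), dts) if n_steps else 0.0
        if sample_d:
            ln_d_prop = math.log(d) + d_step * rng.standard_normal()
            if lo <= ln_d_prop <= hi:
                d_prop = math.exp(ln_d_prop)
                delta = -0.25 * quad * (1.0 / d_prop - 1.0 / d) - 1.5 * n_steps * (
                    ln_d_prop - math.log(d)
                )
                accepted = log_uniform() < delta
                win["d"][0] += accepted
                win["d"][1] += 1
                acc["d"][0] += accepted
                acc["d"][1] += 1
                if accepted:
                    d = d_prop

            # joint (D, roughness) scaling move: rescales intraframe
            # deviations about each frame mean by s while mapping D -> s^2 D,
            # stepping along the funnel axis that couples the two
            s = math.exp(0.15 * rng.standard_normal())
            d_prop = d * s * s
            if lo <= math.log(d_prop) <= hi and k > 1:
                means = r.mean(axis=1, keepdims=True)
                r_prop = means + s * (r - means)
                le_prop_all = np.array(
                    [scorer.frame_loglik(n, r_prop[n]) for n in range(n_frames)]
                )
                ln_init_prop = log_initial(r_prop[0, 0], prior)
                quad_prop = _quad_sum(r_prop.reshape(-1, 3), dts)
                delta = (
                    le_prop_all.sum()
                    - le.sum()
                    - 0.25 * (quad_prop / d_prop - quad / d)
                    - 1.5 * n_steps * math.log(d_prop / d)
                    + ln_init_prop
                    - ln_init
                    + 3.0 * n_frames * (k - 1) * math.log(s)  # Jacobian
                )
                accepted = log_uniform() < delta
                acc["scale"][0] += accepted
                acc["scale"][1] += 1
                if accepted:
                    r = r_prop
                    le = le_prop_all
                    ln_init = ln_init_prop
                    d = d_prop
                    quad = quad_prop

        # adapt proposal scales toward ~30% acceptance during warm-up
        if it < n_warm and (it + 1) % adapt_every == 0:
            for nm, scales in (("rigid", scale_rigid), ("jitter", scale_jitter)):
                rates = win[nm][:, 0] / np.maximum(win[nm][:, 1], 1)
                scales *= np.exp(rates - 0.3)
                win[nm][:] = 0
            if win["d"][1] > 0:
                d_step *= math.exp(win["d"][0] / win["d"][1] - 0.3)
                win["d"][:] = 0

        samples[it] = r
        ln_motion = (
            -0.25 * quad / d
            - 1.5 * (n_steps * math.log(4.0 * math.pi * d) + sumlog_dts)
            if n_steps
            else 0.0
        )
        logliks[it] = ln_init + le.sum() + ln_motion
        if sample_d:
            sampled_d[it] = d

    acceptance = {
        nm: float(a[0] / a[1]) if a[1] else float("nan") for nm, a in acc.items()
    }
    return PosteriorChain(
        samples,
        logliks,
        sampled_d,
        acceptance=acceptance,
        seed=rng_seed if isinstance(rng_seed, int) else None,
        grid=grid,
        diagnostics={"low_information": low_information, "d_init": d_hat},
    )


def remove_burn_in(chain: PosteriorChain, burn_range: tuple[int, int] = (2000, 6000)) -> PosteriorChain:
    """Retain the 1-based inclusive iteration window ``burn_range``.

    ``(3000, 6000)`` on a 6000-sample chain keeps 3001 samples; ``(1, S)`` is
    the identity.  The upper bound is clipped to the chain length.
    """
    lo, hi = burn_range
    hi = min(hi, chain.n_samples)
    if lo < 1 or lo > hi:
        raise ValueError(f"empty burn-in window {burn_range} for chain of {chain.n_samples}")
    sl = slice(lo - 1, hi)
    return PosteriorChain(
        chain.samples[sl],
        chain.logliks[sl],
        None if chain.sampled_d is None else chain.sampled_d[sl],
        acceptance=chain.acceptance,
        seed=chain.seed,
        grid=chain.grid,
        diagnostics=dict(chain.diagnostics),
    )


def _central_k(samples: np.ndarray) -> np.ndarray:
    """Per-frame positions at the frame's central interpolation index."""
    k = samples.shape[2]
    return samples[:, :, (k - 1) // 2, :]


def credible_bands(
    chain: PosteriorChain,
    level: float = 0.98,
    axes: tuple[int, ...] = (0, 1),
    summary: str = "central",
) -> CredibleBands:
    """Equal-tailed per-axis percentile interval at ``level``.

    ``summary='central'`` summarizes each frame at its central interpolation
    time, giving (N, n_axes) bounds; ``summary='interp'`` keeps every
    in-frame interpolated position, giving (N, K, n_axes) bounds.
    ``level=1`` returns the min/max envelope.  Requires at least 100 samples.
    """
    if not 0 < level <= 1:
        raise ValueError("level must lie in (0, 1]")
    if summary not in ("central", "interp"):
        raise ValueError(f"unknown summary {summary!r}")
    if chain.n_samples < 100:
        raise ValueError(f"need >= 100 post-burn-in samples, have {chain.n_samples}")
    if summary == "central":
        pts = _central_k(chain.samples)[:, :, list(axes)]  # (S, N, n_axes)
    else:
        pts = chain.samples[:, :, :, list(axes)]  # (S, N, K, n_axes)
    tail = (1.0 - level) / 2.0
    lower = np.quantile(pts, tail, axis=0)
    upper = np.quantile(pts, 1.0 - tail, axis=0)
    return CredibleBands(lower, upper, level, tuple(axes))


def coverage_fraction(
    bands: CredibleBands, truth: Trajectory, axes: tuple[int, ...] | None = None
) -> float:
    """Fraction of true positions inside the bands on every listed axis.

    The scored positions follow the bands' summary convention: per-frame
    central-time positions for (N, n_axes) bands, or every in-frame
    interpolated position for (N, K, n_axes) bands.
    """
    if axes is None:
        axes = bands.axes
    if bands.lower.ndim == 3:
        true_pts = truth.positions[:, :, list(axes)]  # (N, K, n_axes)
    else:
        true_pts = _central_k(truth.positions[None, ...])[0][:, list(axes)]
    if true_pts.shape != bands.lower.shape:
        raise ValueError(
            f"frame mismatch: truth {true_pts.shape} vs bands {bands.lower.shape}"
        )
    inside = (true_pts >= bands.lower) & (true_pts <= bands.upper)
    return float(np.mean(np.all(inside, axis=-1)))
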