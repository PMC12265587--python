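"""Configuration, file formats and deterministic test fixtures.

Conventions: continuous positions in micrometres with the ROI's lower-left
pixel corner at the stored edge origin; frame and interpolation indices are
1-based in CSV files; TIFF stacks store float32 ADU with a JSON metadata
sidecar so likelihood values round-trip exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from spt_audit.imaging import (
    CameraParams,
    EmissionParams,
    ImageStack,
    OpticsParams,
    render_stack,
)
from spt_audit.tracker import PosteriorChain
from spt_audit.trajectories import (
    InitialPositionPrior,
    MotionParams,
    TimeGrid,
    Trajectory,
    draw_initial_position,
    simulate,
    simulate_bm,
)

__all__ = [
    "RunConfig",
    "SamplerParams",
    "default_config",
    "load_config",
    "save_config",
    "write_stack",
    "read_stack",
    "write_traj",
    "read_traj",
    "write_chain",
    "read_chain",
    "make_fixtures",
]


class ConfigError(ValueError):
    """Configuration validation failure, reported with a field path."""


@dataclass(frozen=True)
class SamplerParams:
    n_iter: int = 6000
    burn_lo: int = 2000
    burn_hi: int = 6000
    sample_diffusivity: bool = True
    d_bounds: tuple[float, float] = (1e-3, 1e2)

    def __post_init__(self):
        if self.n_iter < 10:
            raise ConfigError("sampler.n_iter must be >= 10")
        if not 1 <= self.burn_lo <= self.burn_hi:
            raise ConfigError("sampler burn-in window is empty")


@dataclass(frozen=True)
class RunConfig:
    """Bundle of every parameter record needed to run a full experiment."""

    grid: TimeGrid = field(default_factory=lambda: TimeGrid(15, 10))
    motion: MotionParams = field(default_factory=MotionParams)
    optics: OpticsParams = field(default_factory=OpticsParams)
    camera: CameraParams = field(default_factory=CameraParams)
    emission: EmissionParams = field(default_factory=EmissionParams)
    sampler: SamplerParams = field(default_factory=SamplerParams)
    seed: int = 0

    def prior(self) -> InitialPositionPrior:
        """Initial-position prior centred on the ROI midpoint."""
        sxy, sz = self.optics.psf_widths_um
        c = self.camera.roi_extent_um / 2.0
        return InitialPositionPrior((c, c, 0.0), sxy, sz)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)


def default_config() -> RunConfig:
    """Reference parameterization (widefield EMCCD defaults, N=15, K=10, D=1)."""
    return RunConfig()


# --- serialization ---------------------------------------------------------

_SECTION_FIELDS = {
    "grid": {
        "n_frames": ("n_frames", int),
        "k_interp": ("k_interp", int),
        "frame_period_s": ("frame_period", float),
        "exposure_s": ("exposure", float),
    },
    "motion": {
        "model": ("model", str),
        "diffusivity_um2_s": ("diffusivity", float),
        "drift_velocity_um_s": ("drift_velocity", lambda v: tuple(float(x) for x in v)),
        "attm_sigma_exp": ("attm_sigma_exp", float),
        "attm_gamma": ("attm_gamma", float),
        "ctrw_alpha": ("ctrw_alpha", float),
        "tau0_s": ("tau0", float),
        "hurst": ("hurst", float),
        "lw_sigma_exp": ("lw_sigma_exp", float),
        "speed_um_s": ("speed", float),
        "sbm_alpha": ("sbm_alpha", float),
    },
    "optics": {
        "numerical_aperture": ("numerical_aperture", float),
        "refractive_index": ("refractive_index", float),
        "wavelength_nm": ("wavelength_nm", float),
        "magnification": ("magnification", float),
        "sigma_xy_um": ("sigma_xy_um", lambda v: None if v is None else float(v)),
        "sigma_z_um": ("sigma_z_um", lambda v: None if v is None else float(v)),
    },
    "camera": {
        "gain": ("gain", float),
        "conversion_e_per_adu": ("conversion", float),
        "quantum_efficiency": ("quantum_efficiency", float),
        "pixels_per_side": ("pixels_per_side", int),
        "pixel_size_um": ("pixel_size_um", float),
        "frame_period_s": ("frame_period_s", float),
        "exposure_s": ("exposure_s", float),
    },
    "emission": {
        "photon_rate_per_s": ("photon_rate", float),
        "background_flux_per_um2_s": ("background_flux", float),
        "n_emitters": ("n_emitters", int),
    },
    "sampler": {
        "n_iter": ("n_iter", int),
        "burn_lo": ("burn_lo", int),
        "burn_hi": ("burn_hi", int),
        "sample_diffusivity": ("sample_diffusivity", bool),
        "d_bounds": ("d_bounds", lambda v: tuple(float(x) for x in v)),
    },
}

_SECTION_TYPES = {
    "grid": TimeGrid,
    "motion": MotionParams,
    "optics": OpticsParams,
    "camera": CameraParams,
    "emission": EmissionParams,
    "sampler": SamplerParams,
}


def config_to_dict(config: RunConfig) -> dict:
    out: dict = {"seed": config.seed}
    for section, fields in _SECTION_FIELDS.items():
        obj = getattr(config, section)
        sec = {}
        for key, (attr, _) in fields.items():
            val = getattr(obj, attr)
            if isinstance(val, tuple):
                val = list(val)
            sec[key] = val
        out[section] = sec
    return out


def config_from_dict(data: dict | None) -> RunConfig:
    """Build a validated config, filling defaults and rejecting unknown keys."""
    data = dict(data or {})
    kwargs: dict = {}
    seed = data.pop("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError("seed: must be an integer")
    kwargs["seed"] = seed
    for section, fields in _SECTION_FIELDS.items():
        raw = data.pop(section, None)
        if raw is None:
            continue
        if not isinstance(raw, dict):
            raise ConfigError(f"{section}: expected a mapping")
        sec_kwargs = {}
        for key, value in raw.items():
            if key not in fields:
                raise ConfigError(f"{section}.{key}: unknown field")
            attr, conv = fields[key]
            try:
                sec_kwargs[attr] = conv(value)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"{section}.{key}: {exc}") from exc
        try:
            kwargs[section] = _SECTION_TYPES[section](**sec_kwargs)
        except ValueError as exc:
            raise ConfigError(f"{section}: {exc}") from exc
    if data:
        raise ConfigError(f"unknown top-level keys: {sorted(data)}")
    return RunConfig(**kwargs)


def load_config(path) -> RunConfig:
    """Read a YAML/JSON config; an empty file yields the full default set."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is not None and not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    return config_from_dict(data)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


# --- image stacks ----------------------------------------------------------


def write_stack(stack: ImageStack, path) -> None:
    """Multi-frame float32 TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.w.astype(np.float32), photometric="minisblack")
    sidecar = {
        "x_edges_um": stack.x_edges.tolist(),
        "y_edges_um": stack.y_edges.tolist(),
        "metadata": stack.metadata,
        "shape": list(stack.w.shape),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, default=float))


def read_stack(path) -> ImageStack:
    path = Path(path)
    w = np.asarray(tifffile.imread(path), dtype=np.float32)
    if w.ndim == 2:
        w = w[None, ...]
    sidecar = json.loads(path.with_suffix(".json").read_text())
    if list(w.shape) != sidecar["shape"]:
        raise ValueError(
            f"TIFF shape {list(w.shape)} does not match sidecar {sidecar['shape']}"
        )
    return ImageStack(
        w.astype(float),
        np.asarray(sidecar["x_edges_um"], dtype=float),
        np.asarray(sidecar["y_edges_um"], dtype=float),
        sidecar["metadata"],
    )


# --- trajectories ----------------------------------------------------------


def write_traj(traj: Trajectory, path, seed: int | None = None) -> None:
    """CSV with 1-based frame/interp indices and a JSON sidecar for the grid."""
    grid = traj.grid
    n_idx, k_idx = np.meshgrid(
        np.arange(1, grid.n_frames + 1), np.arange(1, grid.k_interp + 1), indexing="ij"
    )
    df = pd.DataFrame(
        {
            "frame": n_idx.ravel(),
            "interp": k_idx.ravel(),
            "t_s": grid.flat_times,
            "x_um": traj.flat_positions[:, 0],
            "y_um": traj.flat_positions[:, 1],
            "z_um": traj.flat_positions[:, 2],
            "model": traj.model_label,
            "seed": -1 if seed is None else seed,
        }
    )
    path = Path(path)
    df.to_csv(path, index=False)
    sidecar = {
        "grid": grid.to_dict(),
        "model": traj.model_label,
        "ground_truth_params": traj.ground_truth_params,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, default=float))


def read_traj(path) -> Trajectory:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    g = sidecar["grid"]
    grid = TimeGrid(
        int(g["n_frames"]), int(g["k_interp"]), g["frame_period_s"], g["exposure_s"]
    )
    if len(df) != grid.n_points:
        raise ValueError(f"CSV has {len(df)} rows, grid expects {grid.n_points}")
    df = df.sort_values(["frame", "interp"])
    pos = df[["x_um", "y_um", "z_um"]].to_numpy().reshape(
        grid.n_frames, grid.k_interp, 3
    )
    return Trajectory(pos, grid, sidecar["model"], sidecar.get("ground_truth_params", {}))


# --- chains ----------------------------------------------------------------


def write_chain(chain: PosteriorChain, path) -> None:
    path = Path(path)
    grid = chain.grid
    payload = {
        "samples": chain.samples,
        "logliks": chain.logliks,
        "acceptance_keys": np.array(sorted(chain.acceptance), dtype=object),
        "acceptance_vals": np.array(
            [chain.acceptance[k] for k in sorted(chain.acceptance)]
        ),
        "seed": np.array(-1 if chain.seed is None else chain.seed),
    }
    if chain.sampled_d is not None:
        payload["sampled_d"] = chain.sampled_d
    if grid is not None:
        payload["grid"] = np.array(
            [grid.n_frames, grid.k_interp, grid.frame_period, grid.exposure]
        )
    np.savez_compressed(path, **payload)


def read_chain(path) -> PosteriorChain:
    with np.load(path, allow_pickle=True) as data:
        grid = None
        if "grid" in data:
            g = data["grid"]
            grid = TimeGrid(int(g[0]), int(g[1]), float(g[2]), float(g[3]))
        acceptance = dict(
            zip([str(k) for k in data["acceptance_keys"]], data["acceptance_vals"])
        )
        seed = int(data["seed"])
        return PosteriorChain(
            data["samples"],
            data["logliks"],
            data["sampled_d"] if "sampled_d" in data else None,
            acceptance=acceptance,
            seed=None if seed < 0 else seed,
            grid=grid,
        )


# --- fixtures --------------------------------------------------------------


def make_fixtures(seed: int = 0, outdir=None) -> dict:
    """Deterministic miniature assets for tests.

    Returns (and optionally writes) a 5-frame BM stack, one 64-step
    trajectory per motion model, and a 500-sample toy chain.
    """
    config = default_config().replace(grid=TimeGrid(5, 4))
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(10)
    prior = config.prior()
    r1 = draw_initial_position(prior, int(seeds[0]))
    traj = simulate_bm(r1, config.grid, 1.0, int(seeds[1]))
    stack = render_stack(
        traj, config.optics, config.camera, config.emission, int(seeds[2])
    )

    traj_grid = TimeGrid(16, 4)  # 64 steps
    trajs = {}
    for i, model in enumerate(
        ("BM", "DBM", "ATTM", "CTRW", "FBM", "LW", "SBM")
    ):
        params = MotionParams(model=model, hurst=0.3, sbm_alpha=0.5)
        r1m = draw_initial_position(prior, int(seeds[3]) + i)
        trajs[model] = simulate(r1m, traj_grid, params, int(seeds[4]) + i)

    rng = np.random.default_rng(int(seeds[5]))
    toy_samples = rng.normal(2.1, 0.05, size=(500, 5, 4, 3))
    toy = PosteriorChain(
        toy_samples,
        rng.normal(-1e5, 10.0, size=500),
        None,
        acceptance={"rigid": 0.3},
        seed=int(seeds[5]),
        grid=config.grid,
    )
    out = {"stack": stack, "stack_traj": traj, "trajectories": trajs, "chain": toy}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_stack(stack, outdir / "bm_stack.tiff")
        write_traj(traj, outdir / "bm_stack_traj.csv", seed=seed)
        for model, tr in trajs.items():
            write_traj(tr, outdir / f"traj_{model.lower()}.csv", seed=seed)
        write_chain(toy, outdir / "toy_chain.npz")
    return out
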