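"""Headline experiments: contribution audits, parameter sweeps and coverage.

Two experiment families are orchestrated here.  The contribution audit
simulates a trajectory, renders its EMCCD stack and decomposes the
log-likelihood at the ground truth, tabulating the emission-side and motion
terms per motion model and per swept parameter.  The coverage experiment
re-infers trajectories from rendered stacks under a BM-model likelihood and
scores 98% credible-interval coverage of the true in-frame positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from spt_audit.imaging import render_stack
from spt_audit.io import RunConfig, default_config
from spt_audit.likelihood import decompose
from spt_audit.tracker import (
    PosteriorChain,
    coverage_fraction,
    credible_bands,
    mcmc_track,
    remove_burn_in,
)
from spt_audit.trajectories import (
    MODEL_NAMES,
    MotionParams,
    TimeGrid,
    Trajectory,
    center_and_rescale,
    draw_drift_velocity,
    draw_initial_position,
    simulate,
)

__all__ = [
    "SweepSpec",
    "DEFAULT_SWEEPS",
    "run_reference_audit",
    "run_sweep",
    "run_coverage_experiment",
    "orders_of_magnitude_report",
    "posterior_mean_trajectory",
    "audit_replicate",
]

#: one-at-a-time sweep values used by the acceptance experiments
DEFAULT_SWEEPS = {
    "N": [5, 15, 30],
    "D": [0.05, 1.0, 10.0],
    "H": [1e3, 1e4, 1e5],
    "F": [1e3, 1e4, 1e5],
    "G": [210.0, 350.0, 700.0],
    "beta": [0.7, 0.95],
}

TABLE_COLUMNS = [
    "model",
    "parameter",
    "value",
    "replicate",
    "ln_initial",
    "ln_emission_pixels",
    "ln_emission_side",
    "ln_motion",
    "emission_fraction",
    "n_clipped",
]


@dataclass(frozen=True)
class SweepSpec:
    """One-at-a-time parameter sweep around a fixed reference configuration."""

    parameter: str
    values: tuple
    config: RunConfig = field(default_factory=default_config)
    replicates: int = 10
    base_seed: int = 0
    model: str = "BM"

    def __post_init__(self):
        if self.parameter not in _SWEEP_SETTERS:
            raise ValueError(
                f"unknown sweep parameter {self.parameter!r}; "
                f"choose from {sorted(_SWEEP_SETTERS)}"
            )
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.values:
            raise ValueError("sweep needs at least one value")


def _set_n(config, v):
    g = config.grid
    return config.replace(grid=TimeGrid(int(v), g.k_interp, g.frame_period, g.exposure))


def _set_k(config, v):
    g = config.grid
    return config.replace(grid=TimeGrid(g.n_frames, int(v), g.frame_period, g.exposure))


def _set_te(config, v):
    g = config.grid
    import dataclasses

    return config.replace(
        grid=TimeGrid(g.n_frames, g.k_interp, g.frame_period, float(v)),
        camera=dataclasses.replace(config.camera, exposure_s=float(v)),
    )


def _set_camera(attr):
    def setter(config, v):
        import dataclasses

        return config.replace(camera=dataclasses.replace(config.camera, **{attr: v}))

    return setter


def _set_emission(attr):
    def setter(config, v):
        import dataclasses

        return config.replace(emission=dataclasses.replace(config.emission, **{attr: v}))

    return setter


def _set_d(config, v):
    import dataclasses

    return config.replace(motion=dataclasses.replace(config.motion, diffusivity=float(v)))


_SWEEP_SETTERS = {
    "N": _set_n,
    "K": _set_k,
    "D": _set_d,
    "H": _set_emission("photon_rate"),
    "F": _set_emission("background_flux"),
    "G": _set_camera("gain"),
    "phi": _set_camera("conversion"),
    "beta": _set_camera("quantum_efficiency"),
    "ds": _set_camera("pixel_size_um"),
    "tE": _set_te,
}


def reference_motion_params(model: str, rng: np.random.Generator) -> MotionParams:
    """Per-model default parameters for the reference audit.

    DBM draws its in-plane drift speed from U(0, 1] per trajectory; the
    other models use fixed repository defaults.
    """
    if model == "DBM":
        v = draw_drift_velocity(rng)
        return MotionParams(model="DBM", diffusivity=1.0, drift_velocity=tuple(v))
    defaults = {
        "BM": MotionParams(model="BM", diffusivity=1.0),
        "ATTM": MotionParams(model="ATTM", attm_sigma_exp=0.8, attm_gamma=1.2),
        "CTRW": MotionParams(model="CTRW", ctrw_alpha=0.7, diffusivity=1.0, tau0=0.003),
        "FBM": MotionParams(model="FBM", hurst=0.3, diffusivity=1.0),
        "LW": MotionParams(model="LW", lw_sigma_exp=1.5, speed=1.0),
        "SBM": MotionParams(model="SBM", sbm_alpha=1.5),
    }
    return defaults[model]


def _needs_rescale(params: MotionParams) -> bool:
    """Persistent models are shrunk into the ROI before rendering."""
    return params.model == "LW" or (params.model == "SBM" and params.sbm_alpha > 1)


def simulate_for_imaging(
    config: RunConfig, params: MotionParams, rng: np.random.Generator
) -> Trajectory:
    """Draw R1 from the optical-axis prior, simulate, and contain persistent paths."""
    prior = config.prior()
    r1 = draw_initial_position(prior, rng)
    traj = simulate(r1, config.grid, params, rng)
    if _needs_rescale(params):
        traj = center_and_rescale(traj, config.camera.roi_extent_um, margin=0.1)
    return traj


def audit_replicate(config: RunConfig, params: MotionParams, seed: int) -> dict:
    """One simulate → render → decompose pass at the ground-truth trajectory."""
    rng = np.random.default_rng(seed)
    traj = simulate_for_imaging(config, params, rng)
    stack = render_stack(traj, config.optics, config.camera, config.emission, rng)
    dec = decompose(
        stack, traj, config.optics, config.camera, config.emission, config.prior()
    )
    return {
        "ln_initial": dec.ln_initial,
        "ln_emission_pixels": dec.ln_emission_pixels,
        "ln_emission_side": dec.ln_emission_side,
        "ln_motion": dec.ln_motion,
        "emission_fraction": dec.emission_fraction,
        "n_clipped": dec.n_clipped,
    }


def run_reference_audit(
    models=MODEL_NAMES,
    config: RunConfig | None = None,
    replicates: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Contribution audit of every motion model at the reference configuration."""
    if config is None:
        config = default_config()
    rows = []
    children = iter(np.random.SeedSequence(seed).spawn(len(models) * replicates))
    for model in models:
        for rep in range(replicates):
            rng = np.random.default_rng(next(children))
            params = reference_motion_params(model, rng)
            row = audit_replicate(config, params, rng)
            row.update(model=model, parameter="reference", value=np.nan, replicate=rep)
            rows.append(row)
    df = pd.DataFrame(rows)
    return df[TABLE_COLUMNS]


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """One audit per (value, replicate) of a one-at-a-time parameter sweep."""
    setter = _SWEEP_SETTERS[spec.parameter]
    rows = []
    ss = np.random.SeedSequence(spec.base_seed)
    children = ss.spawn(len(spec.values))
    for value, child in zip(spec.values, children):
        config = setter(spec.config, value)
        if spec.parameter == "D":
            params = config.motion
            if params.model != spec.model:
                import dataclasses

                params = dataclasses.replace(params, model=spec.model)
        else:
            params = reference_motion_params(spec.model, np.random.default_rng(0))
            if spec.model == "DBM":
                # sweeps fix the drift at its central value for comparability
                params = MotionParams(
                    model="DBM", diffusivity=1.0, drift_velocity=(0.5, 0.5, 0.0)
                )
        for rep, grandchild in enumerate(child.spawn(spec.replicates)):
            rng = np.random.default_rng(grandchild)
            row = audit_replicate(config, params, rng)
            row.update(
                model=spec.model,
                parameter=spec.parameter,
                value=value,
                replicate=rep,
            )
            rows.append(row)
    df = pd.DataFrame(rows)
    return df[TABLE_COLUMNS]


# --- coverage experiment ---------------------------------------------------

#: 13 anomalous + 2 normal trajectories, mirroring the pooled tracking test
DEFAULT_COVERAGE_ROSTER: tuple[MotionParams, ...] = (
    MotionParams(model="ATTM", attm_sigma_exp=0.8, attm_gamma=1.2),
    MotionParams(model="ATTM", attm_sigma_exp=0.5, attm_gamma=1.0),
    MotionParams(model="CTRW", ctrw_alpha=0.3, diffusivity=1.0, tau0=0.003),
    MotionParams(model="CTRW", ctrw_alpha=0.5, diffusivity=1.0, tau0=0.003),
    MotionParams(model="CTRW", ctrw_alpha=0.7, diffusivity=1.0, tau0=0.003),
    MotionParams(model="FBM", hurst=0.3, diffusivity=1.0),
    MotionParams(model="FBM", hurst=0.6, diffusivity=1.0),
    MotionParams(model="FBM", hurst=0.8, diffusivity=1.0),
    MotionParams(model="LW", lw_sigma_exp=0.5, speed=1.0),
    MotionParams(model="LW", lw_sigma_exp=1.5, speed=1.0),
    MotionParams(model="SBM", sbm_alpha=0.5),
    MotionParams(model="SBM", sbm_alpha=1.5),
    MotionParams(model="SBM", sbm_alpha=2.0),
    MotionParams(model="BM", diffusivity=1.0),
    MotionParams(model="DBM", diffusivity=1.0),
)


def run_coverage_experiment(
    config: RunConfig | None = None,
    roster=DEFAULT_COVERAGE_ROSTER,
    frame_range: tuple[int, int] = (10, 20),
    n_iter: int | None = None,
    level: float = 0.98,
    seed: int = 0,
) -> dict:
    """Simulate → render → track under a BM likelihood → score CI coverage.

    Every trajectory is tracked with the BM motion model regardless of the
    generating model; burn-in removal and chain length follow the sampler
    settings in ``config``.  Returns pooled and per-model coverage.
    """
    if config is None:
        config = default_config()
    if n_iter is None:
        n_iter = config.sampler.n_iter
    burn = (min(config.sampler.burn_lo, n_iter - 100), n_iter)
    ss = np.random.SeedSequence(seed)
    per_traj = []
    n_total = 0
    n_covered = 0
    for idx, (params, child) in enumerate(zip(roster, ss.spawn(len(roster)))):
        rng = np.random.default_rng(child)
        n_frames = int(rng.integers(frame_range[0], frame_range[1] + 1))
        g = config.grid
        cfg = config.replace(
            grid=TimeGrid(n_frames, g.k_interp, g.frame_period, g.exposure)
        )
        if params.model == "DBM":
            params = reference_motion_params("DBM", rng)
        traj = simulate_for_imaging(cfg, params, rng)
        stack = render_stack(traj, cfg.optics, cfg.camera, cfg.emission, rng)
        chain = mcmc_track(
            stack,
            cfg.optics,
            cfg.camera,
            cfg.emission,
            cfg.prior(),
            k_interp=g.k_interp,
            n_iter=n_iter,
            rng_seed=int(child.generate_state(1)[0]),
            sample_d=cfg.sampler.sample_diffusivity,
            d_bounds=cfg.sampler.d_bounds,
        )
        kept = remove_burn_in(chain, burn)
        # per-frame scoring at the central interpolation time; both x and y
        # must fall inside their per-axis equal-tailed bands
        bands = credible_bands(kept, level=level)
        frac = coverage_fraction(bands, traj)
        covered = int(round(frac * n_frames))
        n_total += n_frames
        n_covered += covered
        per_traj.append(
            {
                "index": idx,
                "model": params.model,
                "n_frames": n_frames,
                "n_covered": covered,
                "fraction": frac,
                "low_information": chain.diagnostics.get("low_information", False),
            }
        )
    per_model: dict[str, dict] = {}
    for row in per_traj:
        m = per_model.setdefault(row["model"], {"n_frames": 0, "n_covered": 0})
        m["n_frames"] += row["n_frames"]
        m["n_covered"] += row["n_covered"]
    for m in per_model.values():
        m["fraction"] = m["n_covered"] / m["n_frames"]
    anomalous = [r for r in per_traj if r["model"] not in ("BM", "DBM")]
    return {
        "pooled": {
            "n_frames": n_total,
            "n_covered": n_covered,
            "fraction": n_covered / n_total,
        },
        "anomalous": {
            "n_frames": sum(r["n_frames"] for r in anomalous),
            "n_covered": sum(r["n_covered"] for r in anomalous),
        },
        "per_model": per_model,
        "per_traj": per_traj,
        "level": level,
        "burn_range": list(burn),
        "n_iter": n_iter,
        "seed": seed,
    }


def posterior_mean_trajectory(chain: PosteriorChain) -> Trajectory:
    """Mean of the post-burn-in samples as a Trajectory on the chain's grid."""
    if chain.grid is None:
        raise ValueError("chain carries no grid")
    return Trajectory(chain.samples.mean(axis=0), chain.grid, "posterior_mean")


def orders_of_magnitude_report(table: pd.DataFrame) -> pd.DataFrame:
    """Per-model log10 ratio and log10 difference of the two log-terms.

    ``ratio_order`` is log10(|emission side| / |motion|) and ``diff_order``
    is log10(|emission side - motion|); a zero motion term yields an
    infinite, flagged ratio.
    """
    if table.empty:
        raise ValueError("empty contribution table")
    rows = []
    for model, sub in table.groupby("model"):
        em = sub["ln_emission_side"].abs().mean()
        mo = sub["ln_motion"].abs().mean()
        diff = (sub["ln_emission_side"] - sub["ln_motion"]).abs().mean()
        ratio_order = math.inf if mo == 0 else math.log10(em / mo)
        rows.append(
            {
                "model": model,
                "mean_abs_emission": em,
                "mean_abs_motion": mo,
                "mean_motion_signed": sub["ln_motion"].mean(),
                "ratio_order": ratio_order,
                "diff_order": math.log10(diff) if diff > 0 else -math.inf,
                "zero_motion_flag": mo == 0,
                "emission_fraction": sub["emission_fraction"].mean(),
            }
        )
    return pd.DataFrame(rows)
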