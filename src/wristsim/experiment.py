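"""End-to-end paired ablation experiment over a synthetic cohort.

Mirrors the full protocol: generate a cohort of synthetic specimens,
estimate their moment arms from passive tendon-excursion trials, drive each
specimen through every configured motion with and without the ablated
muscle(s), evaluate forces on the angle grids and per-cycle peaks, and run
the paired Wilcoxon comparisons.

Everything is a pure function of the run configuration, so re-running with
the same configuration reproduces every numeric output bitwise.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .controller import ControllerConfig, SimulationResult, run_controller
from .moment_arms import estimate_specimen_moment_arms
from .specimens import CohortParams, Specimen, cohort_manifest, make_cohort
from .stats import compare_conditions, extract_grid_forces, extract_peaks, summarize_peaks
from .trajectories import Trajectory, angle_grid, generate_trajectory

__all__ = ["ExperimentBundle", "run_paired_experiment", "write_bundle", "run_experiment"]

CONDITIONS = ("intact", "ablated")


@dataclass
class ExperimentBundle:
    """In-memory results of one full paired experiment."""

    config: RunConfig
    cohort: list[Specimen]
    trajectories: dict[str, Trajectory]
    results: dict[tuple[str, str, str], SimulationResult]  # (specimen, motion, condition)
    grid_forces: pd.DataFrame
    peaks: pd.DataFrame
    comparisons: pd.DataFrame

    def result(self, specimen: str, motion: str, condition: str) -> SimulationResult:
        return self.results[(specimen, motion, condition)]


def _controller_config(cfg: RunConfig, ablated: bool) -> ControllerConfig:
    c = cfg.controller
    return ControllerConfig(
        kp=c.kp,
        kd=c.kd,
        dt=c.dt,
        gravity_on=c.gravity_on,
        gravity_feedforward=c.gravity_feedforward,
        ablation=frozenset(cfg.ablation) if ablated else frozenset(),
        mode=c.mode,
        natural_freq_hz=c.natural_freq_hz,
        criterion=cfg.solver.criterion,
        allow_coarse_dt=c.allow_coarse_dt,
    )


def run_paired_experiment(config: RunConfig | None = None) -> ExperimentBundle:
    """Run the intact-vs-ablated experiment defined by ``config``."""
    cfg = config if config is not None else RunConfig()
    params = CohortParams(**cfg.cohort.params_kwargs())
    cohort = make_cohort(cfg.cohort.n, cfg.cohort.base_seed, params)
    trajectories = {
        m: generate_trajectory(m, cfg.trajectory.cycles, cfg.trajectory.period, cfg.trajectory.dt)
        for m in cfg.motions
    }
    ma_root = np.random.SeedSequence([int(cfg.cohort.base_seed), 0x6D61])  # moment-arm noise stream
    ma_children = ma_root.spawn(len(cohort))

    results: dict[tuple[str, str, str], SimulationResult] = {}
    grid_frames, peak_frames = [], []
    for specimen, ma_seed in zip(cohort, ma_children):
        if cfg.moment_arms.source == "estimated":
            fits = estimate_specimen_moment_arms(
                specimen,
                fit_degree=cfg.moment_arms.fit_degree,
                n_points=cfg.moment_arms.n_points,
                noise_sigma=cfg.moment_arms.noise_sigma,
                seed=ma_seed,
            )
        else:
            fits = None
        for motion in cfg.motions:
            traj = trajectories[motion]
            for condition in CONDITIONS:
                result = run_controller(
                    specimen,
                    traj,
                    _controller_config(cfg, ablated=(condition == "ablated")),
                    moment_arm_source=cfg.moment_arms.source,
                    ma_fits=fits,
                    condition="intact" if condition == "intact" else "apl_ablated",
                )
                results[(specimen.id, motion, result.condition)] = result
                grid_frames.append(
                    extract_grid_forces(result, angle_grid(motion), cfg.stats.window_deg)
                )
                peak_frames.append(extract_peaks(result))

    grid_forces = pd.concat(grid_frames, ignore_index=True)
    peaks = pd.concat(peak_frames, ignore_index=True)
    comparisons = compare_conditions(
        grid_forces, peaks, alpha=cfg.stats.alpha, p_method=cfg.stats.p_method
    )
    return ExperimentBundle(
        config=cfg,
        cohort=cohort,
        trajectories=trajectories,
        results=results,
        grid_forces=grid_forces,
        peaks=peaks,
        comparisons=comparisons,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_bundle(bundle: ExperimentBundle, outdir: str | Path, plots: bool = False) -> Path:
    """Serialize a bundle: manifests, trajectories, simulations, comparisons.

    Writes UTF-8 comma-separated CSV with '.' decimals throughout, plus a
    provenance JSON with the configuration, seeds, per-run infeasible-step
    counts, and a checksum of every file written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    p = outdir / "cohort_manifest.csv"
    cohort_manifest(bundle.cohort).to_csv(p, index=False)
    written.append(p)
    for spec in bundle.cohort:
        p = outdir / f"{spec.id}.json"
        spec.to_json(p)
        written.append(p)
    for motion, traj in bundle.trajectories.items():
        p = outdir / f"trajectory_{motion}.csv"
        traj.to_frame().to_csv(p, index=False)
        written.append(p)
    sim_dir = outdir / "simulations"
    sim_dir.mkdir(exist_ok=True)
    infeasible = {}
    tracking = {}
    for (specimen, motion, condition), result in bundle.results.items():
        p = sim_dir / f"{specimen}_{motion}_{condition}.csv"
        result.to_tidy_frame().to_csv(p, index=False)
        written.append(p)
        infeasible[f"{specimen}/{motion}/{condition}"] = result.infeasible_steps
        tracking[f"{specimen}/{motion}/{condition}"] = result.metadata["rms_tracking_error_deg"]
    p = outdir / "grid_forces.csv"
    bundle.grid_forces.to_csv(p, index=False)
    written.append(p)
    p = outdir / "peak_forces.csv"
    bundle.peaks.to_csv(p, index=False)
    written.append(p)
    p = outdir / "comparisons.csv"
    bundle.comparisons.to_csv(p, index=False)
    written.append(p)
    p = outdir / "summary.md"
    p.write_text(summarize_peaks(bundle.comparisons))
    written.append(p)

    if plots:
        from .plotting import plot_grid_forces

        for motion in bundle.trajectories:
            plot_grid_forces(
                bundle.grid_forces, motion, outdir / f"forces_{motion}.png"
            )

    provenance = {
        "wristsim_version": __version__,
        "config": bundle.config.model_dump(),
        "config_sha256": hashlib.sha256(
            json.dumps(bundle.config.model_dump(), sort_keys=True).encode()
        ).hexdigest(),
        "transient_cycles_discarded": 1,
        "infeasible_steps": infeasible,
        "rms_tracking_error_deg": tracking,
        "file_sha256": {f.name: _sha256(f) for f in written},
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True) + "\n")
    return outdir


def run_experiment(config: RunConfig | None = None, outdir: str | Path = "results") -> Path:
    """Run the full experiment and write the output bundle to ``outdir``."""
    bundle = run_paired_experiment(config)
    return write_bundle(bundle, outdir)
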