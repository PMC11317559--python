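"""End-to-end workflow: simulate -> embed -> msm -> coarsen -> path -> forage.

A single YAML config drives the whole chain; one master seed is expanded
into independent per-stage seeds with ``numpy.random.SeedSequence`` (stage
order: data, embed, msm, events, coarsen, path, forage), so any stage can
be rerun in isolation with its recorded seed.  Every run writes a JSON
manifest listing the config hash, the stage seeds, and every file written.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior_events import EventThresholds, compute_signals, detect_events, event_rates
from .coarse_graining import build_hierarchy, dwell_statistics, kinetic_rates, project_labels
from .embedding import delay_embed, partition, select_embedding
from .foraging import (
    average_worm_curve,
    food_encounter_probability,
    probability_matching,
    restrict_chain,
    simulate_constrained_trajectories,
)
from .markov_model import estimate_transition_matrix, implied_timescale_test, spectrum
from .posture_to_path import RFTParams, calibrate_alpha, msd_and_diffusion, posture_to_trajectory
from .synthetic_data import SyntheticWormConfig, generate_posture_series

STAGES = ("data", "embed", "msm", "events", "coarsen", "path", "forage")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-serializable)."""

    out_dir: str = "markovworm_run"
    seed: int = 0
    n_worms: int = 3
    duration_frames: int = 16_000
    dt: float = 1.0 / 16.0
    K_grid: list = field(default_factory=lambda: [1, 2, 4, 6, 8, 11])
    N_grid: list = field(default_factory=lambda: [10, 20, 40, 80])
    tau_grid: list = field(default_factory=lambda: [1, 2, 4, 8, 12, 16])
    n_modes: int = 10
    n_coarse_states: int = 2
    embed_safety_margin: int = 3  # extra delays past the entropy plateau
    alpha: float | None = 30.0
    alpha_grid: list | None = None
    msd_fit_range_s: list = field(default_factory=lambda: [60.0, 100.0])
    forage_r_grid: list = field(default_factory=lambda: [5.0, 10.0, 20.0])
    forage_duration_s: float = 600.0
    forage_reps: int = 20
    sensing_radius: float = 1.0
    stop_after: str | None = None  # e.g. "msm" for a partial run

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic per-stage integer seeds (< 2**31) from one master seed."""
    children = np.random.SeedSequence(master_seed).spawn(len(STAGES))
    return {
        name: int(np.random.default_rng(ss).integers(2**31))
        for name, ss in zip(STAGES, children)
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline stages in dependency order; return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest: dict = {
        "config_hash": config.content_hash(),
        "version": __version__,
        "seeds": seeds,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "files": [],
        "results": {},
    }

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["files"].append(str(path))

    def stop(stage: str) -> bool:
        return config.stop_after == stage

    try:
        # ---- data ----------------------------------------------------
        worms, truths = [], []
        for w in range(config.n_worms):
            cfg = SyntheticWormConfig(
                duration_frames=config.duration_frames,
                dt=config.dt,
                seed=seeds["data"] + w,
            )
            series, gt = generate_posture_series(cfg, worm_id=f"worm{w}")
            worms.append(series)
            truths.append(gt)
            emit(f"worm{w}.csv", series.to_csv)
            emit(f"worm{w}_truth.json", gt.to_json)
        if stop("data"):
            return _finish(manifest, out)

        # ---- embed ---------------------------------------------------
        sel = select_embedding(
            worms, config.K_grid, config.N_grid, seed=seeds["embed"],
            safety_margin=config.embed_safety_margin,
        )
        emit("entropy_table.csv", lambda p: sel.table.to_csv(p, index=False))
        manifest["results"]["K_star"] = sel.K_star
        manifest["results"]["N_star"] = sel.N_star
        spaces = [delay_embed(s, sel.K_star) for s in worms]
        part = partition(spaces, sel.N_star, seed=seeds["embed"])
        emit("partition.h5", part.to_hdf5)
        if stop("embed"):
            return _finish(manifest, out)

        # ---- msm -----------------------------------------------------
        label_seqs = [part.labels_for(s.worm_id) for s in worms]
        its_table, its_diag = implied_timescale_test(
            label_seqs, config.tau_grid, n_modes=3, dt=config.dt
        )
        emit("implied_timescales.csv", lambda p: its_table.to_csv(p, index=False))
        manifest["results"]["implied_timescales"] = its_diag
        tau_star = its_diag.get("recommended_tau_frames", config.tau_grid[0])
        model = estimate_transition_matrix(
            label_seqs, tau_star, n_states=sel.N_star, dt=config.dt
        )
        emit("transition_model.h5", model.to_hdf5)
        spec = spectrum(model, n_modes=config.n_modes)
        manifest["results"]["tau_star_frames"] = int(tau_star)
        manifest["results"]["relaxation_times_s"] = [
            None if np.isnan(v) else float(v) for v in spec.relaxation_times_s
        ]
        if stop("msm"):
            return _finish(manifest, out)

        # ---- events --------------------------------------------------
        rates_all = []
        for series in worms:
            table = detect_events(compute_signals(series), EventThresholds())
            rates_all.append(event_rates(table, seed=seeds["events"]))
        rates = pd.concat(rates_all).groupby("type")["rate_per_s"].mean()
        manifest["results"]["event_rates_per_s"] = rates.to_dict()
        if stop("events"):
            return _finish(manifest, out)

        # ---- coarsen -------------------------------------------------
        hierarchy = build_hierarchy(model, config.n_coarse_states)
        emit("hierarchy.json", hierarchy.to_json)
        coarse2 = hierarchy.labels_at(2)
        coarse_seq = np.concatenate(
            [project_labels(coarse2, seq[:: model.tau_frames]) for seq in label_seqs]
        )
        dwells = dwell_statistics(coarse_seq, model.tau_s, seed=seeds["coarsen"])
        manifest["results"]["dwell"] = {
            "mean_dwell_s": dwells.mean_dwell_s,
            "tau1_s": dwells.tau1_s,
            "tau2_s": dwells.tau2_s,
            "relaxation_time_s": dwells.relaxation_time_s,
        }
        emit("kinetic_rates.csv",
             lambda p: kinetic_rates(coarse_seq, model.tau_s).to_csv(p, index=False))
        if stop("coarsen"):
            return _finish(manifest, out)

        # ---- path ----------------------------------------------------
        params = RFTParams(alpha=config.alpha or 30.0, dt=config.dt)
        traj = posture_to_trajectory(worms[0], params)
        emit("trajectory_worm0.csv", traj.to_csv)
        if config.alpha_grid:
            measured = posture_to_trajectory(worms[0], params)
            a_star, a_table, a_ci = calibrate_alpha(
                worms[0], measured, config.alpha_grid, seed=seeds["path"]
            )
            emit("alpha_scan.csv", lambda p: a_table.to_csv(p, index=False))
            manifest["results"]["alpha_star"] = a_star
        if traj.duration_s > config.msd_fit_range_s[1]:
            curve, fit = msd_and_diffusion(traj, tuple(config.msd_fit_range_s))
            emit("msd_worm0.csv", lambda p: curve.to_csv(p, index=False))
            manifest["results"]["diffusion_D"] = fit.D
        if stop("path"):
            return _finish(manifest, out)

        # ---- forage --------------------------------------------------
        per_state = []
        occupancy = {}
        sym_step = model.tau_frames
        coarse_all = project_labels(coarse2, np.concatenate(
            [seq[::sym_step] for seq in label_seqs]))
        for s in np.unique(coarse2):
            chain = restrict_chain(model, np.flatnonzero(coarse2 == s))
            trajs = simulate_constrained_trajectories(
                chain, part, config.forage_duration_s, config.forage_reps,
                seed=seeds["forage"] + int(s), rft_params=params,
            )
            per_state.append(
                food_encounter_probability(
                    trajs, config.forage_r_grid, config.sensing_radius,
                    seed=seeds["forage"] + 1000 + int(s), state=int(s),
                )
            )
            occupancy[int(s)] = float(np.mean(coarse_all == s))
        per_state = pd.concat(per_state, ignore_index=True)
        emit("foraging.csv", lambda p: per_state.to_csv(p, index=False))
        avg = average_worm_curve(per_state, occupancy)
        emit("foraging_average.csv", lambda p: avg.to_csv(p, index=False))
        match = probability_matching(per_state, occupancy)
        emit("probability_matching.csv", lambda p: match.to_csv(p, index=False))
        manifest["results"]["probability_matching_correlation"] = match.attrs["correlation"]
    except Exception as err:  # annotate stage failures with context
        manifest["error"] = f"{type(err).__name__}: {err}"
        _finish(manifest, out)
        raise
    return _finish(manifest, out)


def _finish(manifest: dict, out: Path) -> dict:
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    path = out / "manifest.json"
    with open(path, "w") as f:
        json.dump(manifest, f, indent=2, default=str)
    manifest["files"].append(str(path))
    return manifest
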