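"""State-constrained simulation and food-finding efficiency.

To probe what each mesoscopic behavioral state is *for*, the worm is
simulated while confined to one state S: new microstates are sampled from
the transition matrix renormalized within S, decoded into postures and
propagated into 2D paths.  Food is scattered uniformly in a disc of radius
r around the start; a trajectory "finds" the food if it passes within a
sensing radius of any food item.  The per-state curves p(food | r, S)
combine with the occupancies pi(S) into the average worm's curve

    p(food | r, average worm) = sum_S pi(S) p(food | r, S),

and at large r the normalized efficiencies can be compared with the
occupancies themselves (probability matching).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .embedding import MicrostatePartition
from .markov_model import TransitionModel, decode_postures
from .posture_to_path import RFTParams, posture_to_trajectory
from .trajectory import Trajectory

__all__ = [
    "ConstrainedChain",
    "restrict_chain",
    "simulate_constrained_symbols",
    "simulate_constrained_trajectories",
    "food_encounter_probability",
    "average_worm_curve",
    "probability_matching",
]


@dataclass
class ConstrainedChain:
    """Transition matrix renormalized within one mesoscopic state."""

    subset: np.ndarray  # microstate indices (original labeling)
    P_S: np.ndarray  # (n_sub, n_sub) row-stochastic, local indexing
    occupancy: np.ndarray  # within-subset visit frequencies (for seeding s0)
    tau_frames: int
    dt: float

    @property
    def n_states(self) -> int:
        return len(self.subset)


def restrict_chain(model: TransitionModel, subset) -> ConstrainedChain:
    """Restrict transition counts to ``subset`` x ``subset`` and renormalize.

    Microstates whose every observed transition leaves the subset get
    all-zero rows; they are dropped (with a warning) until every remaining
    row has support inside the subset.
    """
    subset = np.asarray(sorted(set(int(s) for s in subset)), dtype=int)
    if subset.size == 0:
        raise ValueError("subset is empty")
    counts = model.counts[subset][:, subset].toarray().astype(float)
    keep = np.arange(len(subset))
    dropped_any = False
    while True:
        row_sums = counts[np.ix_(keep, keep)].sum(axis=1)
        alive = row_sums > 0
        if alive.all():
            break
        dropped_any = True
        keep = keep[alive]
        if keep.size == 0:
            raise ValueError("subset has no internal transitions")
    if dropped_any:
        warnings.warn(
            f"{len(subset) - len(keep)} microstates had no internal transitions "
            "and were dropped from the constrained chain"
        )
    sub = counts[np.ix_(keep, keep)]
    P_S = sub / sub.sum(axis=1, keepdims=True)
    occ = sub.sum(axis=1)
    return ConstrainedChain(
        subset=subset[keep],
        P_S=P_S,
        occupancy=occ / occ.sum(),
        tau_frames=model.tau_frames,
        dt=model.dt,
    )


def simulate_constrained_symbols(
    chain: ConstrainedChain, n_steps: int, seed: int = 0, s0: int | None = None
) -> np.ndarray:
    """Sample microstates (original labels) that never leave the subset."""
    rng = np.random.default_rng(seed)
    n = chain.n_states
    cum = np.cumsum(chain.P_S, axis=1)
    cum[:, -1] = 1.0
    if s0 is None:
        s = int(rng.choice(n, p=chain.occupancy))
    else:
        local = np.flatnonzero(chain.subset == s0)
        if local.size == 0:
            raise ValueError(f"initial state {s0} is not in the subset")
        s = int(local[0])
    u = rng.random(n_steps)
    seq = np.empty(n_steps, dtype=np.int64)
    for t in range(n_steps):
        seq[t] = s
        s = int(np.searchsorted(cum[s], u[t], side="right"))
    return chain.subset[seq]


def simulate_constrained_trajectories(
    chain: ConstrainedChain,
    part: MicrostatePartition,
    duration_s: float,
    n_reps: int,
    seed: int = 0,
    rft_params: RFTParams | None = None,
    body_length: float = 1.0,
) -> list[Trajectory]:
    """Symbol simulation -> posture decoding -> RFT path, per replicate."""
    step_s = chain.tau_frames * chain.dt
    n_steps = max(2, int(round(duration_s / step_s)))
    params = rft_params or RFTParams(dt=chain.dt)
    seeds = np.random.SeedSequence(seed).spawn(n_reps)
    trajectories = []
    for rep, ss in enumerate(seeds):
        child = np.random.default_rng(ss)
        sym_seed, dec_seed = child.integers(2**31, size=2)
        symbols = simulate_constrained_symbols(chain, n_steps, seed=int(sym_seed))
        series = decode_postures(symbols, part, chain.tau_frames, seed=int(dec_seed))
        traj = posture_to_trajectory(series, params, body_length=body_length)
        traj.label = f"rep{rep}"
        trajectories.append(traj)
    return trajectories


def food_encounter_probability(
    trajectories: list[Trajectory],
    r_grid,
    sensing_radius: float = 1.0,
    n_food: int = 1,
    n_scatter: int = 100,
    seed: int = 0,
    state: str | int | None = None,
) -> pd.DataFrame:
    """Probability of encountering food in a disc of radius r.

    For each trajectory and each of ``n_scatter`` independent scatters,
    ``n_food`` points are placed uniformly in the disc of radius r around
    the trajectory start; the scatter counts as found when the trajectory
    passes within ``sensing_radius`` of any point.  p is the found fraction
    over all (trajectory, scatter) pairs, with a normal-approximation CI.
    """
    r_grid = sorted(float(r) for r in r_grid)
    if any(r <= 0 for r in r_grid):
        raise ValueError("food patch radii must be positive")
    rng = np.random.default_rng(seed)
    trees = [(cKDTree(t.xy), t.xy[0]) for t in trajectories]
    rows = []
    for r in r_grid:
        found = []
        for tree, origin in trees:
            u = rng.random((n_scatter, n_food))
            ang = rng.uniform(0, 2 * np.pi, (n_scatter, n_food))
            rad = r * np.sqrt(u)
            pts = origin + np.stack([rad * np.cos(ang), rad * np.sin(ang)], axis=-1)
            d, _ = tree.query(pts.reshape(-1, 2))
            hits = (d.reshape(n_scatter, n_food) <= sensing_radius).any(axis=1)
            found.append(hits)
        found = np.concatenate(found)
        p = float(found.mean())
        se = float(np.sqrt(p * (1 - p) / len(found)))
        rows.append(
            {
                "state": state,
                "r": r,
                "p": p,
                "ci_lo": max(0.0, p - 1.96 * se),
                "ci_hi": min(1.0, p + 1.96 * se),
                "n": len(found),
            }
        )
    return pd.DataFrame(rows)


def average_worm_curve(per_state: pd.DataFrame, occupancy: dict) -> pd.DataFrame:
    """p(food | r, average worm) = sum_S pi(S) p(food | r, S)."""
    total = sum(occupancy.values())
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError(f"occupancies must sum to 1, got {total}")
    missing = set(per_state["state"].unique()) - set(occupancy)
    if missing:
        raise ValueError(f"occupancy missing for states {sorted(missing)}")
    rows = []
    for r, grp in per_state.groupby("r"):
        p = sum(occupancy[s] * grp.loc[grp["state"] == s, "p"].iloc[0] for s in occupancy)
        rows.append({"r": r, "p": p})
    return pd.DataFrame(rows)


def probability_matching(
    per_state: pd.DataFrame, occupancy: dict, r_large: float | None = None
) -> pd.DataFrame:
    """Compare normalized food-finding efficiency with state occupancy.

    At the (largest by default) patch radius, e(S) = p(S) / sum_S p(S) is
    set against pi(S); the returned frame carries both plus summary
    attributes ``correlation`` and ``max_abs_discrepancy``.
    """
    states = sorted(per_state["state"].unique(), key=str)
    if set(states) != set(occupancy):
        raise ValueError("state sets of efficiencies and occupancy differ")
    r_large = float(per_state["r"].max()) if r_large is None else float(r_large)
    at_r = per_state[np.isclose(per_state["r"], r_large)]
    p = np.array([at_r.loc[at_r["state"] == s, "p"].iloc[0] for s in states])
    pi = np.array([occupancy[s] for s in states])
    e = p / p.sum() if p.sum() > 0 else np.full(len(p), 1.0 / len(p))
    out = pd.DataFrame({"state": states, "efficiency": e, "occupancy": pi, "p_raw": p})
    out.attrs["r_large"] = r_large
    out.attrs["correlation"] = (
        float(np.corrcoef(e, pi)[0, 1]) if len(states) > 1 and e.std() > 0 and pi.std() > 0
        else np.nan
    )
    out.attrs["max_abs_discrepancy"] = float(np.max(np.abs(e - pi)))
    return out
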