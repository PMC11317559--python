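"""Synthetic posture series, Markov-chain fixtures, and centroid tracks.

Everything downstream (embedding, transition-operator estimation, spectral
coarse-graining, posture-to-path) is tested against generators with known
ground truth, so no recorded worm data are required.

The posture generator emulates the phenomenology of foraging *C. elegans*
in food-free conditions:

* a quasi-periodic locomotory wave appearing as a rotation in the (a1, a2)
  plane, whose rotation direction flips between hidden forward/reversal
  states (sign of the body-wave phase velocity);
* intermittent large-amplitude excursions of a3 (deep turns), shaped as
  raised-cosine pulses;
* low-amplitude noise on a4/a5 and additive observation noise throughout.

The hidden state process is semi-Markov; with the default geometric dwell
times it is exactly Markov at the frame level, which gives a known-truth
case for the embedding selector.  A heavy-tailed (Lomax) dwell option
produces a deliberately non-Markov sequence for implied-timescale
diagnostics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .basis import eigenworm_basis, modes_to_angles
from .posture import PostureSeries
from .trajectory import Trajectory

__all__ = [
    "HiddenState",
    "SyntheticWormConfig",
    "GroundTruth",
    "MarkovFixture",
    "generate_posture_series",
    "generate_markov_fixture",
    "generate_track",
    "sample_markov_sequence",
]


# --------------------------------------------------------------------------
# configuration and ground truth
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class HiddenState:
    """One hidden behavioral regime of the generator.

    ``phase_velocity_hz`` is the rate of increase of the (a1, a2) phase
    angle in cycles/s; the *measured* body-wave phase velocity
    ``omega = -(1/2pi) d/dt atan2(a2, a1)`` is its negative.  Forward
    crawling (positive omega) therefore uses a negative phase velocity.
    """

    name: str
    mean_dwell_frames: float
    phase_velocity_hz: float
    turn_amplitude: float = 0.0


def _default_states() -> tuple[HiddenState, ...]:
    # Dwells: ~7.5 s runs interrupted by ~1.5 s reversals and ~3 s deep
    # turn bouts, the run-and-pirouette structure of off-food foraging.
    # The body wave keeps running through turns: a bend on a frozen wave
    # is a reciprocal stroke and would not reorient under linear drag;
    # these settings reorient the heading enough that centroid tracks
    # turn over from ballistic to diffusive between ~10 and ~100 s.
    return (
        HiddenState("forward", 120.0, -0.45),
        HiddenState("reversal", 24.0, +0.45),
        HiddenState("turn", 48.0, -0.45, turn_amplitude=10.0),
    )


def _default_switch_matrix(n: int) -> np.ndarray:
    if n == 3:
        # forward -> {reversal, turn}; reversals mostly continue into turns
        # (pirouettes); turns mostly resolve into forward runs.
        return np.array(
            [
                [0.0, 0.5, 0.5],
                [0.3, 0.0, 0.7],
                [0.9, 0.1, 0.0],
            ]
        )
    if n == 1:
        return np.ones((1, 1))
    m = np.full((n, n), 1.0 / (n - 1))
    np.fill_diagonal(m, 0.0)
    return m


@dataclass
class SyntheticWormConfig:
    """Study conditions for the synthetic worm.

    Defaults mirror the reference recordings: 35 min at dt = 1/16 s
    (33,600 frames), three hidden regimes (forward / reversal / turn).
    """

    duration_frames: int = 33_600
    dt: float = 1.0 / 16.0
    hidden_states: tuple[HiddenState, ...] = field(default_factory=_default_states)
    noise_sd: float = 0.05
    amplitude: float = 4.0
    seed: int = 0
    switch_matrix: np.ndarray | None = None
    dwell_distribution: str = "geometric"  # or "lomax" (heavy-tailed)
    lomax_shape: float = 1.5
    phase0: float | None = None  # None -> drawn uniformly from the seed
    turn_width_s: float = 3.0
    turn_ventral_fraction: float = 0.5  # probability a turn bends ventrally (+)
    n_segments: int = 32

    def __post_init__(self) -> None:
        if self.duration_frames < 1:
            raise ValueError("duration_frames must be >= 1")
        if not (self.dt > 0):
            raise ValueError("dt must be positive")
        if not self.hidden_states:
            raise ValueError("need at least one hidden state")
        for hs in self.hidden_states:
            if not (hs.mean_dwell_frames > 0):
                raise ValueError(f"state {hs.name!r} has non-positive mean dwell")
        if self.dwell_distribution not in ("geometric", "lomax"):
            raise ValueError(f"unknown dwell distribution {self.dwell_distribution!r}")
        if self.switch_matrix is not None:
            s = np.asarray(self.switch_matrix, dtype=float)
            n = len(self.hidden_states)
            if s.shape != (n, n):
                raise ValueError("switch matrix shape must match the number of states")
            if np.any(s < 0) or (n > 1 and not np.allclose(s.sum(axis=1), 1.0, atol=1e-12)):
                raise ValueError("switch matrix rows must be nonnegative and sum to 1")
            self.switch_matrix = s


@dataclass
class GroundTruth:
    """What the generator actually did, for downstream validation."""

    hidden_label_per_frame: np.ndarray
    state_names: list[str]
    omega_per_state: dict[str, float]
    true_transition_matrix: np.ndarray | None = None  # hidden-level, frame lag 1
    true_diffusion_D: float | None = None
    turn_events: list[tuple[int, int, int]] = field(default_factory=list)
    """Per turn visit: (start frame, end frame, sign) with +1 = ventral."""

    def intervals(self, state: int | str) -> list[tuple[int, int]]:
        """Contiguous [start, end) frame intervals spent in ``state``."""
        if isinstance(state, str):
            state = self.state_names.index(state)
        lab = self.hidden_label_per_frame
        edges = np.flatnonzero(np.diff(lab) != 0) + 1
        starts = np.concatenate([[0], edges])
        ends = np.concatenate([edges, [len(lab)]])
        return [(int(s), int(e)) for s, e in zip(starts, ends) if lab[s] == state]

    def dwell_frames(self, state: int | str | None = None) -> np.ndarray:
        """Dwell durations in frames, optionally restricted to one state."""
        if state is None:
            lab = self.hidden_label_per_frame
            edges = np.flatnonzero(np.diff(lab) != 0) + 1
            bounds = np.concatenate([[0], edges, [len(lab)]])
            return np.diff(bounds)
        return np.array([e - s for s, e in self.intervals(state)])

    def to_json(self, path) -> None:
        payload = {
            "hidden_label_per_frame": self.hidden_label_per_frame.tolist(),
            "state_names": self.state_names,
            "omega_per_state": self.omega_per_state,
            "true_transition_matrix": (
                None
                if self.true_transition_matrix is None
                else self.true_transition_matrix.tolist()
            ),
            "true_diffusion_D": self.true_diffusion_D,
            "turn_events": [list(ev) for ev in self.turn_events],
        }
        with open(path, "w") as f:
            json.dump(payload, f)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as f:
            payload = json.load(f)
        tm = payload["true_transition_matrix"]
        return cls(
            hidden_label_per_frame=np.asarray(payload["hidden_label_per_frame"], dtype=int),
            state_names=payload["state_names"],
            omega_per_state=payload["omega_per_state"],
            true_transition_matrix=None if tm is None else np.asarray(tm),
            true_diffusion_D=payload["true_diffusion_D"],
            turn_events=[tuple(ev) for ev in payload.get("turn_events", [])],
        )


# --------------------------------------------------------------------------
# posture generator
# --------------------------------------------------------------------------
def _sample_dwell(rng: np.random.Generator, cfg: SyntheticWormConfig, mean: float) -> int:
    if cfg.dwell_distribution == "geometric":
        p = min(1.0, 1.0 / mean)
        return int(rng.geometric(p))
    # Lomax (Pareto II) with shape a: mean = scale / (a - 1); heavy tail.
    scale = mean * (cfg.lomax_shape - 1.0)
    return max(1, int(np.ceil(scale * rng.pareto(cfg.lomax_shape))))


def _sample_hidden_labels(rng: np.random.Generator, cfg: SyntheticWormConfig) -> np.ndarray:
    n_states = len(cfg.hidden_states)
    switch = cfg.switch_matrix
    if switch is None:
        switch = _default_switch_matrix(n_states)
    labels = np.empty(cfg.duration_frames, dtype=int)
    t = 0
    state = int(rng.integers(n_states))
    cum = np.cumsum(switch, axis=1)
    while t < cfg.duration_frames:
        dwell = _sample_dwell(rng, cfg, cfg.hidden_states[state].mean_dwell_frames)
        end = min(t + dwell, cfg.duration_frames)
        labels[t:end] = state
        t = end
        if n_states > 1:
            state = int(np.searchsorted(cum[state], rng.random(), side="right"))
    return labels


def _hidden_frame_transition_matrix(cfg: SyntheticWormConfig) -> np.ndarray | None:
    """Frame-lag-1 hidden-state matrix; exact only for geometric dwells."""
    if cfg.dwell_distribution != "geometric":
        return None
    n = len(cfg.hidden_states)
    switch = cfg.switch_matrix
    if switch is None:
        switch = _default_switch_matrix(n)
    P = np.zeros((n, n))
    for i, hs in enumerate(cfg.hidden_states):
        leave = min(1.0, 1.0 / hs.mean_dwell_frames)
        P[i, i] = 1.0 - leave
        if n > 1:
            P[i] += leave * switch[i]
    if n == 1:
        P[0, 0] = 1.0
    return P


def generate_posture_series(
    config: SyntheticWormConfig, worm_id: str = "synthetic-worm"
) -> tuple[PostureSeries, GroundTruth]:
    """Generate a 5-mode posture series plus its hidden-state ground truth.

    (a1, a2) rotate at the active state's phase velocity, a3 carries one
    raised-cosine pulse per visit to a turning state, a4/a5 are pure noise
    channels; observation noise is added to every mode.  Tangent angles are
    attached via the synthetic eigenworm basis so curvature-based event
    detection can run on the output.
    """
    rng = np.random.default_rng(config.seed)
    T = config.duration_frames
    labels = _sample_hidden_labels(rng, config)

    phase0 = rng.uniform(0, 2 * np.pi) if config.phase0 is None else float(config.phase0)
    freqs = np.array([hs.phase_velocity_hz for hs in config.hidden_states])
    dphase = 2 * np.pi * freqs[labels] * config.dt
    phase = phase0 + np.concatenate([[0.0], np.cumsum(dphase[:-1])])

    a = np.zeros((T, 5))
    a[:, 0] = config.amplitude * np.cos(phase)
    a[:, 1] = config.amplitude * np.sin(phase)

    # raised-cosine turn pulses, one per visit, capped at turn_width_s;
    # each visit bends ventrally (+) or dorsally (-) at the configured odds
    gt_tmp = GroundTruth(labels, [hs.name for hs in config.hidden_states], {})
    width_frames = max(2, int(round(config.turn_width_s / config.dt)))
    turn_events: list[tuple[int, int, int]] = []
    for idx, hs in enumerate(config.hidden_states):
        if hs.turn_amplitude == 0.0:
            continue
        for start, end in gt_tmp.intervals(idx):
            span = min(end - start, width_frames)
            sign = 1 if rng.random() < config.turn_ventral_fraction else -1
            u = (np.arange(span) + 0.5) / span
            pulse = abs(hs.turn_amplitude) * 0.5 * (1 - np.cos(2 * np.pi * u))
            a[start : start + span, 2] += sign * pulse
            turn_events.append((int(start), int(start + span), sign))

    if config.noise_sd > 0:
        a += rng.normal(0.0, config.noise_sd, size=a.shape)

    theta = modes_to_angles(a, eigenworm_basis(config.n_segments))
    series = PostureSeries(a=a, dt=config.dt, worm_id=worm_id, theta=theta)
    gt = GroundTruth(
        hidden_label_per_frame=labels,
        state_names=[hs.name for hs in config.hidden_states],
        omega_per_state={hs.name: -hs.phase_velocity_hz for hs in config.hidden_states},
        true_transition_matrix=_hidden_frame_transition_matrix(config),
        turn_events=turn_events,
    )
    return series, gt


# --------------------------------------------------------------------------
# Markov-chain fixtures
# --------------------------------------------------------------------------
@dataclass
class MarkovFixture:
    """Exact transition matrix, its stationary distribution, and a sample."""

    P: np.ndarray
    pi: np.ndarray
    sequence: np.ndarray
    seed: int
    kind: str


def _stationary_of(P: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(P.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def sample_markov_sequence(
    P: np.ndarray, n_steps: int, seed: int, s0: int | None = None
) -> np.ndarray:
    """Sample a symbolic trajectory from a row-stochastic matrix."""
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    rng = np.random.default_rng(seed)
    cum = np.cumsum(P, axis=1)
    cum[:, -1] = 1.0
    seq = np.empty(n_steps, dtype=np.int64)
    s = int(rng.integers(n)) if s0 is None else int(s0)
    u = rng.random(n_steps)
    for t in range(n_steps):
        seq[t] = s
        s = int(np.searchsorted(cum[s], u[t], side="right"))
    return seq


def _fixture_matrix(kind: str, **params) -> np.ndarray:
    if kind == "two_state":
        p = float(params["p01"])
        q = float(params["p10"])
        return np.array([[1 - p, p], [q, 1 - q]])
    if kind == "cycle":
        n = int(params["n_states"])
        return np.roll(np.eye(n), 1, axis=1)
    if kind == "iid_uniform":
        n = int(params["n_states"])
        return np.full((n, n), 1.0 / n)
    if kind == "block":
        sizes = list(params["block_sizes"])
        eps = float(params["eps"])
        n = sum(sizes)
        P = np.zeros((n, n))
        start = 0
        blocks = []
        for sz in sizes:
            blocks.append(np.arange(start, start + sz))
            start += sz
        for b in blocks:
            for i in b:
                P[i, b] = (1 - eps) / len(b)
                outside = np.setdiff1d(np.arange(n), b)
                if len(outside):
                    P[i, outside] = eps / len(outside)
                else:
                    P[i, b] += eps / len(b)
        return P
    if kind == "hierarchical":
        # four blocks in two superblocks: leaks eps_inner to the sibling
        # block, eps_outer to the far superblock (eps_outer << eps_inner).
        sz = int(params["block_size"])
        eps_in = float(params["eps_inner"])
        eps_out = float(params["eps_outer"])
        n = 4 * sz
        P = np.zeros((n, n))
        blocks = [np.arange(k * sz, (k + 1) * sz) for k in range(4)]
        sibling = {0: 1, 1: 0, 2: 3, 3: 2}
        for k, b in enumerate(blocks):
            far = np.concatenate([blocks[j] for j in (range(2, 4) if k < 2 else range(0, 2))])
            for i in b:
                P[i, b] = (1 - eps_in - eps_out) / sz
                P[i, blocks[sibling[k]]] = eps_in / sz
                P[i, far] = eps_out / len(far)
        return P
    if kind == "custom":
        return np.asarray(params["P"], dtype=float)
    raise ValueError(f"unknown fixture kind {kind!r}")


def generate_markov_fixture(
    kind: str, n_steps: int = 0, seed: int = 0, s0: int | None = None, **params
) -> MarkovFixture:
    """Build an exact row-stochastic matrix and (optionally) sample from it.

    Kinds: ``two_state`` (p01, p10), ``cycle`` (n_states), ``iid_uniform``
    (n_states), ``block`` (block_sizes, eps), ``hierarchical`` (block_size,
    eps_inner, eps_outer), ``custom`` (P).
    """
    P = _fixture_matrix(kind, **params)
    if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError("fixture rows must be nonnegative and sum to 1")
    pi = _stationary_of(P)
    seq = (
        sample_markov_sequence(P, n_steps, seed, s0=s0)
        if n_steps > 0
        else np.empty(0, dtype=np.int64)
    )
    return MarkovFixture(P=P, pi=pi, sequence=seq, seed=seed, kind=kind)


# --------------------------------------------------------------------------
# centroid tracks
# --------------------------------------------------------------------------
def generate_track(
    kind: str,
    n_steps: int,
    dt: float = 1.0,
    seed: int = 0,
    D: float = 1.0,
    speed: float = 1.0,
    heading: float = 0.0,
) -> Trajectory:
    """Generate a 2D centroid track with known statistics.

    ``brownian``: isotropic random walk with diffusion coefficient D, so
    MSD(tau) = 4 D tau (per-axis step variance 2 D dt).  ``ballistic``:
    straight motion at ``speed``, so MSD(tau) = speed^2 tau^2.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if not (dt > 0):
        raise ValueError("dt must be positive")
    if kind == "brownian":
        if D < 0:
            raise ValueError("D must be >= 0")
        rng = np.random.default_rng(seed)
        steps = rng.normal(0.0, np.sqrt(2.0 * D * dt), size=(n_steps, 2))
        xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        return Trajectory(xy=xy, dt=dt, label=f"brownian-D{D}")
    if kind == "ballistic":
        if speed < 0:
            raise ValueError("speed must be >= 0")
        t = np.arange(n_steps + 1) * dt
        direction = np.array([np.cos(heading), np.sin(heading)])
        xy = np.outer(t * speed, direction)
        return Trajectory(xy=xy, dt=dt, label=f"ballistic-v{speed}")
    raise ValueError(f"unknown track kind {kind!r}")
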