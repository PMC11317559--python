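"""Maximally predictive delay embedding and microstate partitioning.

Delay-stacking K consecutive posture frames turns instantaneously hidden
dynamical state (e.g. the direction of the body wave) into an observable:
each row of the sequence space is a short posture movie.  Partitioning that
space into N microstates with k-means yields a symbolic dynamics whose
predictability is measured by the entropy rate of its lag-1 Markov chain,

    h = - sum_i pi_i sum_j P_ij log2 P_ij   [bits/frame],

estimated with the plug-in estimator.  The embedding window K* is the
smallest K at which h(K) has stopped decreasing (plateau), and N* is the
largest partition count before finite-size sampling starts to *reduce* the
estimated entropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans, MiniBatchKMeans

from .posture import PostureSeries

__all__ = [
    "DelaySpace",
    "MicrostatePartition",
    "EmbeddingSelection",
    "delay_embed",
    "partition",
    "entropy_rate",
    "select_embedding",
]


@dataclass
class DelaySpace:
    """Windows of K stacked frames: row r = concat of frames r..r+K-1."""

    K: int
    X: np.ndarray  # (T - K + 1, n_modes * K)
    frame_index: np.ndarray  # start frame of each row
    dt: float
    worm_id: str = "worm"

    @property
    def n_windows(self) -> int:
        return self.X.shape[0]


def delay_embed(series: PostureSeries, K: int) -> DelaySpace:
    """Stack K delays of the posture series into a sequence space.

    K = 1 returns the original series; K frames at dt = 1/16 s span
    K/16 s of posture history per row.
    """
    T, d = series.a.shape
    if not (1 <= K <= T):
        raise ValueError(f"K must be in [1, {T}], got {K}")
    windows = np.lib.stride_tricks.sliding_window_view(series.a, (K, d))
    X = windows.reshape(T - K + 1, K * d).copy()
    return DelaySpace(
        K=K, X=X, frame_index=np.arange(T - K + 1), dt=series.dt, worm_id=series.worm_id
    )


@dataclass
class MicrostatePartition:
    """A k-means labeling of delay windows into N microstates.

    Keeps the window matrix so that microstates can later be decoded back
    into posture snippets (each member row stores a K-frame movie).
    """

    N: int
    K: int
    dt: float
    centers: np.ndarray
    labels: np.ndarray
    windows: np.ndarray = field(repr=False)
    kmeans_seed: int = 0
    series_slices: dict[str, slice] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min() < 0 or self.labels.max() >= self.N:
            raise ValueError("labels out of range [0, N)")

    @property
    def n_effective(self) -> int:
        """Number of microstates with at least one member window."""
        return int(len(np.unique(self.labels)))

    def members(self, state: int) -> np.ndarray:
        """Window-row indices belonging to one microstate."""
        return np.flatnonzero(self.labels == state)

    def labels_for(self, worm_id: str) -> np.ndarray:
        if not self.series_slices:
            return self.labels
        return self.labels[self.series_slices[worm_id]]

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("centers", data=self.centers)
            f.create_dataset("labels", data=self.labels)
            f.create_dataset("windows", data=self.windows)
            f.create_dataset("K", data=self.K)
            f.create_dataset("N", data=self.N)
            f.create_dataset("dt", data=self.dt)
            f.create_dataset("seed", data=self.kmeans_seed)
            for worm_id, sl in self.series_slices.items():
                f.attrs[f"slice:{worm_id}"] = (sl.start, sl.stop)

    @classmethod
    def from_hdf5(cls, path) -> "MicrostatePartition":
        with h5py.File(path, "r") as f:
            slices = {
                key.split(":", 1)[1]: slice(int(v[0]), int(v[1]))
                for key, v in f.attrs.items()
                if key.startswith("slice:")
            }
            return cls(
                N=int(f["N"][()]),
                K=int(f["K"][()]),
                dt=float(f["dt"][()]),
                centers=f["centers"][:],
                labels=f["labels"][:],
                windows=f["windows"][:],
                kmeans_seed=int(f["seed"][()]),
                series_slices=slices,
            )


def partition(
    space: DelaySpace | list[DelaySpace],
    N: int,
    seed: int = 0,
    n_init: int = 3,
    minibatch_threshold: int = 256,
) -> MicrostatePartition:
    """Partition a delay space (or pooled spaces) into N microstates.

    Multiple spaces (one per worm) are pooled before fitting so the
    microstate labeling is consistent across worms; per-worm label slices
    are recorded.  k-means++ initialization with ``n_init`` restarts (best
    inertia); for large N a mini-batch variant keeps the fit tractable.
    """
    spaces = [space] if isinstance(space, DelaySpace) else list(space)
    if not spaces:
        raise ValueError("no delay spaces given")
    Ks = {s.K for s in spaces}
    if len(Ks) > 1:
        raise ValueError("all pooled spaces must share the same K")
    X = np.vstack([s.X for s in spaces])
    if N > X.shape[0]:
        raise ValueError(f"N={N} exceeds the number of windows ({X.shape[0]})")
    if N >= minibatch_threshold:
        km = MiniBatchKMeans(
            n_clusters=N, random_state=seed, n_init=n_init, batch_size=4096, max_iter=200
        )
    else:
        km = KMeans(n_clusters=N, random_state=seed, n_init=n_init)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn chatters about memory leaks on MKL
        labels = km.fit_predict(X)
    slices = {}
    start = 0
    for s in spaces:
        slices[s.worm_id] = slice(start, start + s.n_windows)
        start += s.n_windows
    return MicrostatePartition(
        N=N,
        K=spaces[0].K,
        dt=spaces[0].dt,
        centers=km.cluster_centers_,
        labels=labels,
        windows=X,
        kmeans_seed=seed,
        series_slices=slices,
    )


def entropy_rate(labels: np.ndarray, N: int, dt: float | None = None):
    """Plug-in entropy rate of the lag-1 Markov chain of a symbol sequence.

    Returns bits/frame, or a (bits/frame, bits/s) pair when ``dt`` is given.
    Bounded by 0 <= h <= log2(N).
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size < 2:
        raise ValueError("need at least two symbols for an entropy rate")
    if labels.min() < 0 or labels.max() >= N:
        raise ValueError("labels out of range [0, N)")
    pairs = labels[:-1] * N + labels[1:]
    counts = np.bincount(pairs, minlength=N * N).reshape(N, N).astype(float)
    row_tot = counts.sum(axis=1)
    occ = row_tot / row_tot.sum()
    h = 0.0
    nz_rows = np.flatnonzero(row_tot)
    for i in nz_rows:
        p = counts[i, counts[i] > 0] / row_tot[i]
        h -= occ[i] * np.sum(p * np.log2(p))
    h = float(max(h, 0.0))
    if dt is None:
        return h
    return h, h / dt


def _bootstrap_sd(values: np.ndarray, rng: np.random.Generator, n_boot: int = 200) -> float:
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        return 0.0
    means = [
        np.mean(values[rng.integers(len(values), size=len(values))]) for _ in range(n_boot)
    ]
    return float(np.std(means))


@dataclass
class EmbeddingSelection:
    K_star: int
    N_star: int
    table: pd.DataFrame  # columns: K, N, h_bits_per_frame, h_bits_per_s, sd
    diagnostics: dict = field(default_factory=dict)


def _per_worm_entropies(
    series_list: list[PostureSeries], K: int, N: int, seed: int, n_blocks: int = 8
) -> np.ndarray:
    """Entropy rate per worm (or per contiguous block for a single worm)."""
    spaces = [delay_embed(s, K) for s in series_list]
    part = partition(spaces, N, seed=seed)
    if len(series_list) > 1:
        return np.array(
            [entropy_rate(part.labels_for(s.worm_id), N) for s in series_list]
        )
    labels = part.labels
    blocks = np.array_split(labels, n_blocks)
    return np.array([entropy_rate(b, N) for b in blocks if len(b) > 1])


def select_embedding(
    series: PostureSeries | list[PostureSeries],
    K_grid,
    N_grid,
    seed: int = 0,
    safety_margin: int = 0,
) -> EmbeddingSelection:
    """Select (K*, N*) from an entropy-rate table h(K, N).

    N*: largest N whose plateau entropy has not dropped below the
    next-smaller N's by more than that value's bootstrap SD (finite-size
    onset).  K*: smallest K at which |h(K) - h(K+1)| < SD(h(K)) for the
    selected N (plateau), plus an optional safety margin of extra delays.
    """
    series_list = [series] if isinstance(series, PostureSeries) else list(series)
    K_grid = sorted(int(k) for k in K_grid)
    N_grid = sorted(int(n) for n in N_grid)
    if not K_grid or not N_grid:
        raise ValueError("K and N grids must be nonempty")
    rng = np.random.default_rng(seed)
    dt = series_list[0].dt

    rows = []
    h_table: dict[tuple[int, int], tuple[float, float]] = {}
    for K in K_grid:
        for N in N_grid:
            hs = _per_worm_entropies(series_list, K, N, seed)
            h, sd = float(np.mean(hs)), _bootstrap_sd(hs, rng)
            h_table[(K, N)] = (h, sd)
            rows.append(
                {"K": K, "N": N, "h_bits_per_frame": h, "h_bits_per_s": h / dt, "sd": sd}
            )
    table = pd.DataFrame(rows)

    # N*: scan upward at the largest K (deep-embedding plateau values).
    K_ref = K_grid[-1]
    N_star = N_grid[0]
    for prev, cur in zip(N_grid[:-1], N_grid[1:]):
        h_prev, _ = h_table[(K_ref, prev)]
        h_cur, sd_cur = h_table[(K_ref, cur)]
        if h_cur < h_prev - max(sd_cur, 1e-12):
            break
        N_star = cur

    # K*: plateau onset at N*.  A single flat pair can still be a noise
    # coincidence, which is why a safety margin of extra delays past the
    # detected plateau is supported (and used by the pipeline defaults).
    diagnostics: dict = {}
    K_star = K_grid[-1]
    found = False
    for K, K_next in zip(K_grid[:-1], K_grid[1:]):
        h_k, sd_k = h_table[(K, N_star)]
        h_next, _ = h_table[(K_next, N_star)]
        if abs(h_k - h_next) < max(sd_k, 1e-12):
            K_star = K
            found = True
            break
    if not found:
        diagnostics["warning"] = (
            "entropy rate had not plateaued on the K grid; returning the largest K"
        )
        warnings.warn(diagnostics["warning"])
    if safety_margin:
        K_star = min(K_star + safety_margin, K_grid[-1])
    diagnostics["K_ref_for_N"] = K_ref
    return EmbeddingSelection(K_star=K_star, N_star=N_star, table=table, diagnostics=diagnostics)
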