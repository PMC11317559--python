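"""Sparse Markov chain on posture microstates: estimation, spectrum, simulation.

The symbolic posture dynamics obey the master equation

    p_j(t + tau) = sum_i P_ij(tau) p_i(t),

with P the row-stochastic transition matrix counted at lag tau.  The real
parts of its eigenvalues set the relaxation times

    Lambda_i^{-1} = -tau / ln Re(lambda_i)   [seconds],

and the eigenvectors of the reversibilized operator
Pr = (P + Pi^{-1} P^T Pi) / 2 (Pi = diag(pi)) provide the real-valued
reaction coordinates used for metastable coarse-graining.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .embedding import MicrostatePartition
from .posture import PostureSeries

__all__ = [
    "TransitionModel",
    "Spectrum",
    "estimate_transition_matrix",
    "stationary_distribution",
    "spectrum",
    "reversibilize",
    "implied_timescale_test",
    "simulate_symbols",
    "decode_postures",
    "shuffled_eigenvalue_floor",
]

DENSE_THRESHOLD = 600  # below this, eigenproblems are solved densely


@dataclass
class TransitionModel:
    """Row-stochastic transition matrix P(tau) with its raw counts."""

    P: sparse.csr_matrix
    counts: sparse.csr_matrix
    tau_frames: int
    dt: float
    worm_id: str = "ensemble"
    _pi: np.ndarray | None = field(default=None, repr=False)
    _kept: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_states(self) -> int:
        return self.P.shape[0]

    @property
    def tau_s(self) -> float:
        return self.tau_frames * self.dt

    @classmethod
    def from_matrix(
        cls,
        P: np.ndarray,
        tau_frames: int = 1,
        dt: float = 1.0,
        counts_scale: float = 1.0,
        worm_id: str = "exact",
    ) -> "TransitionModel":
        """Wrap an exact row-stochastic matrix (counts = scaled P rows)."""
        P = np.asarray(P, dtype=float)
        if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("matrix rows must be nonnegative and sum to 1")
        sp = sparse.csr_matrix(P)
        return cls(
            P=sp, counts=sparse.csr_matrix(P * counts_scale),
            tau_frames=tau_frames, dt=dt, worm_id=worm_id,
        )

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            for name, mat in (("P", self.P), ("counts", self.counts)):
                g = f.create_group(name)
                g.create_dataset("indptr", data=mat.indptr)
                g.create_dataset("indices", data=mat.indices)
                g.create_dataset("data", data=mat.data)
                g.attrs["shape"] = mat.shape
            f.create_dataset("tau", data=self.tau_frames)
            f.create_dataset("dt", data=self.dt)
            f.attrs["worm_id"] = self.worm_id
            f.create_dataset("pi", data=stationary_distribution(self))

    @classmethod
    def from_hdf5(cls, path) -> "TransitionModel":
        with h5py.File(path, "r") as f:
            mats = {}
            for name in ("P", "counts"):
                g = f[name]
                mats[name] = sparse.csr_matrix(
                    (g["data"][:], g["indices"][:], g["indptr"][:]),
                    shape=tuple(g.attrs["shape"]),
                )
            return cls(
                P=mats["P"],
                counts=mats["counts"],
                tau_frames=int(f["tau"][()]),
                dt=float(f["dt"][()]),
                worm_id=str(f.attrs.get("worm_id", "ensemble")),
            )


def estimate_transition_matrix(
    labels: np.ndarray | list[np.ndarray],
    tau_frames: int,
    n_states: int | None = None,
    dt: float = 1.0,
    worm_id: str = "ensemble",
) -> TransitionModel:
    """Count microstate transitions at lag ``tau_frames`` and row-normalize.

    A list of label sequences (one per worm) pools counts across worms
    before normalization; transitions never cross sequence boundaries.
    """
    if tau_frames < 1:
        raise ValueError("tau must be >= 1 frame")
    seqs = [np.asarray(labels, dtype=int)] if np.ndim(labels[0]) == 0 else [
        np.asarray(s, dtype=int) for s in labels
    ]
    if n_states is None:
        n_states = int(max(s.max() for s in seqs)) + 1
    rows, cols = [], []
    for s in seqs:
        if len(s) > tau_frames:
            rows.append(s[:-tau_frames])
            cols.append(s[tau_frames:])
    if not rows:
        raise ValueError("label sequences shorter than the requested lag")
    i = np.concatenate(rows)
    j = np.concatenate(cols)
    counts = sparse.coo_matrix(
        (np.ones(len(i)), (i, j)), shape=(n_states, n_states)
    ).tocsr()
    if counts.nnz == 0:
        raise ValueError("no transitions observed")
    row_sums = np.asarray(counts.sum(axis=1)).ravel()
    inv = np.zeros_like(row_sums)
    nz = row_sums > 0
    inv[nz] = 1.0 / row_sums[nz]
    P = sparse.diags(inv) @ counts
    return TransitionModel(
        P=P.tocsr(), counts=counts, tau_frames=tau_frames, dt=dt, worm_id=worm_id
    )


# --------------------------------------------------------------------------
# recurrent component and stationary distribution
# --------------------------------------------------------------------------
def largest_recurrent_component(model: TransitionModel) -> np.ndarray:
    """Indices of the largest closed strongly connected component.

    States outside it are transient (or disconnected) and are excluded from
    stationary/spectral quantities.
    """
    if model._kept is not None:
        return model._kept
    n, comp = connected_components(model.P, connection="strong")
    counts = model.counts
    best, best_mass = None, -1.0
    for c in range(n):
        members = np.flatnonzero(comp == c)
        outside = counts[members].sum() - counts[members][:, members].sum()
        if outside > 0:  # not closed: mass leaks out, transient component
            continue
        mass = counts[members].sum()
        if mass > best_mass:
            best, best_mass = members, mass
    if best is None:  # cannot happen for a finite chain, but be safe
        best = np.arange(model.n_states)
    if len(best) < model.n_states:
        warnings.warn(
            f"chain is reducible; restricting to the largest recurrent component "
            f"({len(best)}/{model.n_states} states kept)"
        )
    model._kept = best
    return best


def stationary_distribution(model: TransitionModel) -> np.ndarray:
    """Stationary distribution pi with pi P = pi; zero on transient states."""
    if model._pi is not None:
        return model._pi
    kept = largest_recurrent_component(model)
    P = model.P[kept][:, kept].toarray() if len(kept) <= DENSE_THRESHOLD else None
    if P is not None:
        vals, vecs = np.linalg.eig(P.T)
        k = int(np.argmin(np.abs(vals - 1.0)))
        pi_sub = np.abs(np.real(vecs[:, k]))
    else:
        sub = model.P[kept][:, kept].tocsc()
        vals, vecs = sparse.linalg.eigs(sub.T, k=1, sigma=1.0 + 1e-9)
        pi_sub = np.abs(np.real(vecs[:, 0]))
    pi_sub = pi_sub / pi_sub.sum()
    pi = np.zeros(model.n_states)
    pi[kept] = pi_sub
    model._pi = pi
    return pi


def reversibilize(model: TransitionModel) -> tuple[sparse.csr_matrix, np.ndarray, np.ndarray]:
    """Time-symmetric operator Pr = (P + Pi^-1 P^T Pi)/2 on the recurrent set.

    Returns (Pr, pi_sub, kept_state_indices).  Pr is row-stochastic and
    satisfies detailed balance with respect to pi.
    """
    pi = stationary_distribution(model)
    kept = largest_recurrent_component(model)
    pi_sub = pi[kept]
    P = model.P[kept][:, kept].tocsr()
    D = sparse.diags(pi_sub)
    Dinv = sparse.diags(1.0 / pi_sub)
    Pr = 0.5 * (P + Dinv @ P.T @ D)
    return Pr.tocsr(), pi_sub, kept


def reversible_eigenvectors(
    Pr: sparse.spmatrix | np.ndarray, pi: np.ndarray, n_modes: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Eigenpairs of a reversible operator via the symmetrized problem.

    Solves A = D^{1/2} Pr D^{-1/2} (symmetric), returns (eigenvalues,
    right eigenvectors phi of Pr) sorted by descending eigenvalue and
    normalized to sum_i pi_i phi_i^2 = 1; phi_1 is constant.
    """
    n = Pr.shape[0]
    sq = np.sqrt(pi)
    if sparse.issparse(Pr):
        A = sparse.diags(sq) @ Pr @ sparse.diags(1.0 / sq)
        A = np.asarray(A.todense()) if n <= DENSE_THRESHOLD else A
    else:
        A = sq[:, None] * Pr / sq[None, :]
    if isinstance(A, np.ndarray):
        A = 0.5 * (A + A.T)  # clean up round-off asymmetry
        vals, vecs = np.linalg.eigh(A)
        order = np.argsort(vals)[::-1]
        if n_modes is not None:
            order = order[:n_modes]
        vals, vecs = vals[order], vecs[:, order]
    else:
        k = min(n_modes or n - 2, n - 2)
        sym = 0.5 * (A + A.T)
        vals, vecs = sparse.linalg.eigsh(sym, k=k, which="LA")
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
    phi = vecs / sq[:, None]
    # normalize in the pi-weighted inner product and fix the sign
    for k in range(phi.shape[1]):
        norm = np.sqrt(np.sum(pi * phi[:, k] ** 2))
        if norm > 0:
            phi[:, k] /= norm
        j = int(np.argmax(np.abs(phi[:, k])))
        if phi[j, k] < 0:
            phi[:, k] *= -1
    return vals, phi


@dataclass
class Spectrum:
    """Eigenstructure of P(tau), sorted by descending real part."""

    eigenvalues: np.ndarray  # complex
    relaxation_times_s: np.ndarray  # Lambda_i^{-1}; NaN for the stationary mode
    right_eigenvectors: np.ndarray | None
    phi: np.ndarray  # eigenvectors of the reversibilized operator
    phi_eigenvalues: np.ndarray
    pi: np.ndarray  # stationary distribution on the kept states
    states: np.ndarray  # original indices of the kept states
    tau_s: float


def _relaxation_times(eigenvalues: np.ndarray, tau_s: float) -> np.ndarray:
    out = np.full(len(eigenvalues), np.nan)
    re = np.real(eigenvalues)
    ok = (re > 0) & (re < 1)
    out[ok] = -tau_s / np.log(re[ok])
    return out


def spectrum(model: TransitionModel, n_modes: int = 30) -> Spectrum:
    """Leading eigenvalues/relaxation times of P and reversibilized phi."""
    kept = largest_recurrent_component(model)
    pi = stationary_distribution(model)[kept]
    P = model.P[kept][:, kept]
    n = P.shape[0]
    n_modes = min(n_modes, n)
    if n <= DENSE_THRESHOLD:
        vals, vecs = np.linalg.eig(P.toarray())
        order = np.argsort(-np.real(vals))[:n_modes]
        vals, vecs = vals[order], vecs[:, order]
    else:
        try:
            vals, vecs = sparse.linalg.eigs(P.tocsc().astype(float), k=n_modes, which="LR")
        except sparse.linalg.ArpackNoConvergence as err:
            raise RuntimeError("sparse eigensolver failed to converge") from err
        order = np.argsort(-np.real(vals))
        vals, vecs = vals[order], vecs[:, order]
    Pr, pi_sub, _ = reversibilize(model)
    phi_vals, phi = reversible_eigenvectors(Pr, pi_sub, n_modes=n_modes)
    return Spectrum(
        eigenvalues=vals,
        relaxation_times_s=_relaxation_times(vals, model.tau_s),
        right_eigenvectors=vecs,
        phi=phi,
        phi_eigenvalues=phi_vals,
        pi=pi,
        states=kept,
        tau_s=model.tau_s,
    )


# --------------------------------------------------------------------------
# lag validation
# --------------------------------------------------------------------------
def implied_timescale_test(
    labels: np.ndarray | list[np.ndarray],
    tau_grid,
    n_modes: int = 3,
    dt: float = 1.0,
    growth_tolerance: float = 0.2,
):
    """Relaxation times Lambda_i^{-1}(tau) across candidate lags.

    For a genuinely Markov symbolic process the implied timescales are
    independent of tau; systematic growth flags non-Markovianity (e.g.
    heavy-tailed dwell times).  Returns (DataFrame, diagnostics dict) with
    a recommended tau* = the smallest lag inside the plateau.
    """
    import pandas as pd

    tau_grid = sorted(int(t) for t in tau_grid)
    rows = []
    dropped = []
    for tau in tau_grid:
        try:
            model = estimate_transition_matrix(labels, tau, dt=dt)
            spec = spectrum(model, n_modes=n_modes)
        except ValueError:
            dropped.append(tau)
            continue
        for i in range(1, min(n_modes, len(spec.eigenvalues))):
            rows.append(
                {
                    "tau_frames": tau,
                    "tau_s": tau * dt,
                    "mode": i + 1,
                    "relaxation_time_s": spec.relaxation_times_s[i],
                }
            )
    if dropped:
        warnings.warn(f"lags {dropped} dropped: sequences too short")
    table = pd.DataFrame(rows)
    t2 = table[table["mode"] == 2].dropna(subset=["relaxation_time_s"])
    diagnostics: dict = {"dropped_lags": dropped}
    if len(t2) >= 2:
        vals = t2["relaxation_time_s"].to_numpy()
        taus = t2["tau_frames"].to_numpy()
        spread = float((vals.max() - vals.min()) / vals.mean())
        growth = float((vals[-1] - vals[0]) / vals[0])
        diagnostics["relative_spread_mode2"] = spread
        diagnostics["relative_growth_mode2"] = growth
        diagnostics["markovian"] = bool(growth < growth_tolerance)
        # plateau onset: smallest tau whose value is within 10% of the
        # median over the remaining (larger) lags
        tau_star = int(taus[-1])
        for k in range(len(taus)):
            ref = np.median(vals[k:])
            if abs(vals[k] - ref) <= 0.1 * ref:
                tau_star = int(taus[k])
                break
        diagnostics["recommended_tau_frames"] = tau_star
    return table, diagnostics


def shuffled_eigenvalue_floor(
    labels: np.ndarray, tau_frames: int, seed: int = 0, n_shuffles: int = 5, dt: float = 1.0
) -> float:
    """Largest nontrivial |eigenvalue| of matrices from shuffled symbols.

    The shuffle is a random permutation of the symbol sequence, preserving
    marginal occupancy but destroying all temporal structure; modes of the
    real chain below this floor are not significant.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=int)
    floor = 0.0
    for _ in range(n_shuffles):
        perm = rng.permutation(labels)
        model = estimate_transition_matrix(perm, tau_frames, dt=dt)
        spec = spectrum(model, n_modes=2)
        if len(spec.eigenvalues) > 1:
            floor = max(floor, float(np.abs(spec.eigenvalues[1])))
    return floor


# --------------------------------------------------------------------------
# simulation and decoding
# --------------------------------------------------------------------------
def simulate_symbols(
    model: TransitionModel, s0: int, n_steps: int, seed: int = 0
) -> np.ndarray:
    """Sample a symbolic trajectory of ``n_steps`` microstates from P(tau)."""
    P = model.P
    if not (0 <= s0 < model.n_states):
        raise ValueError(f"invalid initial state {s0}")
    indptr, indices, data = P.indptr, P.indices, P.data
    rng = np.random.default_rng(seed)
    u = rng.random(n_steps)
    seq = np.empty(n_steps, dtype=np.int64)
    s = int(s0)
    for t in range(n_steps):
        seq[t] = s
        lo, hi = indptr[s], indptr[s + 1]
        if hi == lo:
            raise ValueError(f"state {s} has no outgoing transitions (dead end)")
        cum = np.cumsum(data[lo:hi])
        k = np.searchsorted(cum, u[t] * cum[-1], side="right")
        s = int(indices[lo + min(k, hi - lo - 1)])
    return seq


def decode_postures(
    symbols: np.ndarray,
    part: MicrostatePartition,
    tau_frames: int,
    seed: int = 0,
    worm_id: str = "decoded",
) -> PostureSeries:
    """Turn a symbolic sequence back into a continuous posture time series.

    For each visited microstate a stored K-frame posture window is drawn
    uniformly from the microstate's members and placed at the symbol step
    (tau frames).  Where consecutive windows overlap (K > tau) they are
    blended with a linear cross-fade; where a gap opens (tau > K) it is
    bridged by linear interpolation.
    """
    symbols = np.asarray(symbols, dtype=int)
    rng = np.random.default_rng(seed)
    K = part.K
    n_modes = part.windows.shape[1] // K
    T_out = (len(symbols) - 1) * tau_frames + K
    acc = np.zeros((T_out, n_modes))
    wacc = np.zeros(T_out)

    overlap = max(0, K - tau_frames)
    w = np.ones(K)
    if overlap > 0:
        ramp = np.arange(1, overlap + 1) / (overlap + 1)
        w[:overlap] = ramp
        w[-overlap:] = ramp[::-1]

    members_cache: dict[int, np.ndarray] = {}
    for i, s in enumerate(symbols):
        rowids = members_cache.get(s)
        if rowids is None:
            rowids = part.members(s)
            if len(rowids) == 0:
                raise ValueError(f"microstate {s} has no stored member windows")
            members_cache[s] = rowids
        row = rowids[rng.integers(len(rowids))]
        snippet = part.windows[row].reshape(K, n_modes)
        t0 = i * tau_frames
        ww = w if i not in (0, len(symbols) - 1) else np.ones(K)  # no fade at the edges
        acc[t0 : t0 + K] += snippet * ww[:, None]
        wacc[t0 : t0 + K] += ww

    filled = wacc > 0
    acc[filled] /= wacc[filled, None]
    if not np.all(filled):  # gaps (tau > K): bridge linearly
        idx = np.arange(T_out)
        for m in range(n_modes):
            acc[~filled, m] = np.interp(idx[~filled], idx[filled], acc[filled, m])
    return PostureSeries(a=acc, dt=part.dt, worm_id=worm_id)
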