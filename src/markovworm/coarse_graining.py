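"""Metastable coarse-graining of the microstate chain.

Long-lived behavioral states are almost invariant sets of the Markov
chain: groups of microstates the dynamics stays within for much longer
than it mixes inside them.  The first nontrivial eigenvector phi_2 of the
reversibilized operator orders microstates along the slowest reaction
coordinate; a single threshold on phi_2 splits them into two sets, chosen
to maximize the smaller of the two set coherences

    chi(S) = sum_{i,j in S} pi_i Pr_ij / sum_{i in S} pi_i,

the probability of staying in S for one step given the chain is in S.
Iterating the split inside the largest-measure state yields a top-down
hierarchy of mesoscopic states, each with dwell-time statistics and
kinetic rates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse

from .markov_model import (
    TransitionModel,
    estimate_transition_matrix,
    largest_recurrent_component,
    reversibilize,
    reversible_eigenvectors,
    stationary_distribution,
)

__all__ = [
    "SplitResult",
    "StateHierarchy",
    "DwellStats",
    "set_coherence",
    "metastable_split",
    "build_hierarchy",
    "project_labels",
    "dwell_statistics",
    "kinetic_rates",
]


# --------------------------------------------------------------------------
# two-set split along phi_2
# --------------------------------------------------------------------------
def set_coherence(Pr, pi: np.ndarray, members: np.ndarray) -> float:
    """chi(S): one-step probability of remaining in S, started from pi|S."""
    members = np.asarray(members)
    if sparse.issparse(Pr):
        sub = Pr[members][:, members]
        stay = float(pi[members] @ np.asarray(sub.sum(axis=1)).ravel())
    else:
        stay = float(pi[members] @ Pr[np.ix_(members, members)].sum(axis=1))
    return stay / pi[members].sum()


@dataclass
class SplitResult:
    labels: np.ndarray  # 0 (low phi_2) / 1 (high phi_2) per microstate
    threshold: float
    score: float  # min of the two set coherences
    phi2: np.ndarray
    coherences: tuple[float, float]
    metastable: bool = True  # False when no better than the stationary baseline


def metastable_split(Pr, pi: np.ndarray, phi2: np.ndarray | None = None) -> SplitResult:
    """Best single-threshold bipartition along phi_2.

    Scans every cut of the phi_2 order (thresholds midway between
    consecutive sorted values, ties broken by microstate index) and keeps
    the one maximizing min(chi(S0), chi(S1)).  By detailed balance the
    pi-weighted cross flow is symmetric, so the scan is computed
    incrementally in O(nnz).
    """
    n = Pr.shape[0]
    if n < 2:
        raise ValueError("need at least two microstates to split")
    if phi2 is None:
        _, phi = reversible_eigenvectors(Pr, pi, n_modes=2)
        phi2 = phi[:, 1]
    if np.ptp(phi2) < 1e-12:
        raise ValueError("no metastable structure: phi_2 is constant")

    order = np.lexsort((np.arange(n), phi2))
    Pr_csr = Pr.tocsr() if sparse.issparse(Pr) else sparse.csr_matrix(Pr)
    in_A = np.zeros(n, dtype=bool)
    mass_A = 0.0  # sum_{i,j in A} pi_i Pr_ij
    pi_A = 0.0
    best = (-np.inf, 0, 0.0, (0.0, 0.0))
    for k in range(n - 1):
        s = order[k]
        row = Pr_csr.getrow(s)
        diag = float(row[0, s])
        into_A = float(row.data[in_A[row.indices]].sum())  # s not yet in A
        # detailed balance: pi_i Pr_is = pi_s Pr_si for i in A, so the
        # incoming mass equals the outgoing mass into A
        mass_A += pi[s] * (diag + 2.0 * into_A)
        in_A[s] = True
        pi_A += pi[s]
        pi_B = 1.0 - pi_A
        chi_A = mass_A / pi_A
        cross = pi_A - mass_A
        chi_B = (pi_B - cross) / pi_B
        score = min(chi_A, chi_B)
        if score > best[0]:
            best = (score, k, 0.0, (chi_A, chi_B))
    score, k_best, _, chis = best
    threshold = 0.5 * (phi2[order[k_best]] + phi2[order[k_best + 1]])
    labels = np.ones(n, dtype=int)
    labels[order[: k_best + 1]] = 0
    # Under no temporal structure chi(S) ~ pi(S) (rows approach pi), so a
    # split is only metastable when both sets beat their stationary mass.
    excess = min(
        chis[0] - pi[labels == 0].sum(),
        chis[1] - pi[labels == 1].sum(),
    )
    return SplitResult(
        labels=labels, threshold=float(threshold), score=float(score),
        phi2=phi2, coherences=(float(chis[0]), float(chis[1])),
        metastable=bool(excess > 1e-9),
    )


# --------------------------------------------------------------------------
# iterative subdivision
# --------------------------------------------------------------------------
@dataclass
class StateHierarchy:
    """Nested micro -> coarse labelings from iterative spectral subdivision.

    ``levels[k]`` has k+1 coarse states; each level refines the previous
    one (exactly one state is split in two).  ``level_info[k]`` records the
    split threshold, metastability score and state measures.
    """

    levels: list[np.ndarray]
    level_info: list[dict]
    pi_micro: np.ndarray
    n_micro: int

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def labels_at(self, n_states: int) -> np.ndarray:
        for lab in self.levels:
            if len(np.unique(lab)) == n_states:
                return lab
        raise ValueError(f"no level with {n_states} coarse states")

    def measures_at(self, n_states: int) -> np.ndarray:
        lab = self.labels_at(n_states)
        return np.array([self.pi_micro[lab == s].sum() for s in range(n_states)])

    def to_json(self, path) -> None:
        payload = {
            "n_micro": self.n_micro,
            "pi_micro": self.pi_micro.tolist(),
            "levels": [lab.tolist() for lab in self.levels],
            "level_info": [
                {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in info.items()}
                for info in self.level_info
            ],
        }
        with open(path, "w") as f:
            json.dump(payload, f)

    @classmethod
    def from_json(cls, path) -> "StateHierarchy":
        with open(path) as f:
            payload = json.load(f)
        return cls(
            levels=[np.asarray(lab, dtype=int) for lab in payload["levels"]],
            level_info=payload["level_info"],
            pi_micro=np.asarray(payload["pi_micro"]),
            n_micro=int(payload["n_micro"]),
        )


def _assign_stragglers(
    labels: np.ndarray, members: np.ndarray, counts: sparse.csr_matrix
) -> None:
    """Give microstates outside the recurrent sub-component the label of
    their most frequent successor (fallback: most frequent predecessor)."""
    unlabeled = [m for m in members if labels[m] < 0]
    for m in unlabeled:
        row = counts.getrow(m).toarray().ravel()
        row[m] = 0
        cand = [j for j in np.argsort(row)[::-1] if row[j] > 0 and labels[j] >= 0]
        if cand:
            labels[m] = labels[cand[0]]
            continue
        col = counts.getcol(m).toarray().ravel()
        cand = [j for j in np.argsort(col)[::-1] if col[j] > 0 and labels[j] >= 0]
        labels[m] = labels[cand[0]] if cand else 0


def _split_subset(
    counts: sparse.csr_matrix, members: np.ndarray, dt: float, tau_frames: int
) -> SplitResult | None:
    """Metastable split of the chain restricted to ``members``."""
    sub_counts = counts[members][:, members]
    if sub_counts.nnz == 0:
        return None
    model = TransitionModel(
        P=_row_normalize(sub_counts), counts=sub_counts.tocsr(),
        tau_frames=tau_frames, dt=dt,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kept = largest_recurrent_component(model)
        if len(kept) < 2:
            return None
        Pr, pi_sub, kept = reversibilize(model)
        try:
            split = metastable_split(Pr, pi_sub)
        except ValueError:
            return None
    # lift to the full member set; unresolved members marked -1
    labels = np.full(len(members), -1, dtype=int)
    labels[kept] = split.labels
    local_counts = sub_counts.tocsr()
    _assign_stragglers(labels, np.arange(len(members)), local_counts)
    return SplitResult(
        labels=labels, threshold=split.threshold, score=split.score,
        phi2=split.phi2, coherences=split.coherences,
    )


def _row_normalize(counts) -> sparse.csr_matrix:
    counts = counts.tocsr().astype(float)
    row_sums = np.asarray(counts.sum(axis=1)).ravel()
    inv = np.divide(1.0, row_sums, out=np.zeros_like(row_sums), where=row_sums > 0)
    return (sparse.diags(inv) @ counts).tocsr()


def build_hierarchy(model: TransitionModel, target_states: int) -> StateHierarchy:
    """Top-down spectral subdivision into ``target_states`` coarse states.

    Level 1 is the phi_2 split of the full reversibilized chain; every
    further level splits the current largest-measure state along the phi_2
    of the chain conditioned on that state's microstates.  States with too
    few microstates (or no internal structure) are skipped with a warning.
    """
    if target_states < 2:
        raise ValueError("target_states must be >= 2")
    n = model.n_states
    pi = stationary_distribution(model)
    levels = [np.zeros(n, dtype=int)]
    level_info: list[dict] = [{"n_states": 1}]

    labels = np.zeros(n, dtype=int)
    while len(np.unique(labels)) < target_states:
        current = np.unique(labels)
        measures = np.array([pi[labels == s].sum() for s in current])
        split_done = False
        for s in current[np.argsort(measures)[::-1]]:
            members = np.flatnonzero(labels == s)
            if len(members) < 2:
                continue
            split = _split_subset(model.counts, members, model.dt, model.tau_frames)
            if split is None:
                warnings.warn(f"coarse state {s} has no splittable structure; skipping")
                continue
            new_label = labels.max() + 1
            new = labels.copy()
            new[members[split.labels == 1]] = new_label
            labels = new
            levels.append(labels.copy())
            level_info.append(
                {
                    "n_states": int(len(np.unique(labels))),
                    "split_state": int(s),
                    "new_state": int(new_label),
                    "threshold": split.threshold,
                    "score": split.score,
                    "measures": np.array(
                        [pi[labels == c].sum() for c in np.unique(labels)]
                    ),
                }
            )
            split_done = True
            break
        if not split_done:
            warnings.warn(
                f"no further metastable structure found at {len(current)} states"
            )
            break
    return StateHierarchy(levels=levels, level_info=level_info, pi_micro=pi, n_micro=n)


def project_labels(coarse_labels: np.ndarray, microstate_sequence: np.ndarray) -> np.ndarray:
    """Map a microstate symbol sequence to coarse-state labels."""
    micro = np.asarray(microstate_sequence, dtype=int)
    coarse = np.asarray(coarse_labels, dtype=int)
    if micro.max() >= len(coarse) or micro.min() < 0:
        raise ValueError("sequence contains microstates not covered by the labeling")
    return coarse[micro]


# --------------------------------------------------------------------------
# dwell-time statistics and kinetics
# --------------------------------------------------------------------------
@dataclass
class DwellStats:
    dwell_times_s: np.ndarray  # pooled over states
    per_state_dwells_s: dict[int, np.ndarray]
    mean_dwell_s: float
    tau1_s: float | None = None
    tau2_s: float | None = None
    weight: float | None = None
    relaxation_time_s: float | None = None  # (1/tau1 + 1/tau2)^-1
    tau1_se: float | None = None  # observed-information standard errors
    tau2_se: float | None = None
    tau1_ci: tuple[float, float] | None = None
    tau2_ci: tuple[float, float] | None = None

    def ccdf(self) -> pd.DataFrame:
        t = np.sort(self.dwell_times_s)
        surv = 1.0 - np.arange(1, len(t) + 1) / len(t)
        return pd.DataFrame({"t_s": t, "ccdf": surv})


def _fit_exp_mixture(
    dwells: np.ndarray, with_se: bool = False
) -> tuple[float, float, float] | tuple[float, float, float, float, float]:
    """Maximum-likelihood fit of w/t1 e^(-t/t1) + (1-w)/t2 e^(-t/t2).

    With ``with_se`` the standard errors of (t1, t2) are computed from the
    observed information (numerical Hessian of the negative log-likelihood
    in log-timescale coordinates, delta method back to seconds); component
    overlap makes these substantially larger than pure-exponential SEs.
    """

    def nll(params):
        lw, lt1, lt2 = params
        w = 1.0 / (1.0 + np.exp(-lw))
        t1, t2 = np.exp(lt1), np.exp(lt2)
        pdf = w / t1 * np.exp(-dwells / t1) + (1 - w) / t2 * np.exp(-dwells / t2)
        return -np.sum(np.log(np.maximum(pdf, 1e-300)))

    m = dwells.mean()
    best = None
    for w0, r1, r2 in [(0.5, 3.0, 0.3), (0.3, 5.0, 0.5), (0.7, 2.0, 0.2)]:
        x0 = [np.log(w0 / (1 - w0)), np.log(m * r1), np.log(m * r2)]
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    lw, lt1, lt2 = best.x
    w = 1.0 / (1.0 + np.exp(-lw))
    t1, t2 = np.exp(lt1), np.exp(lt2)
    flip = t1 < t2
    if flip:  # report the slow timescale first
        t1, t2, w = t2, t1, 1 - w
    if not with_se:
        return w, t1, t2
    eps = 1e-4
    H = np.zeros((3, 3))
    x = best.x
    for i in range(3):
        for j in range(3):
            ei = np.zeros(3); ei[i] = eps
            ej = np.zeros(3); ej[j] = eps
            H[i, j] = (
                nll(x + ei + ej) - nll(x + ei - ej) - nll(x - ei + ej) + nll(x - ei - ej)
            ) / (4 * eps * eps)
    try:
        cov = np.linalg.inv(H)
        se_l1 = np.sqrt(max(cov[1, 1], 0.0))
        se_l2 = np.sqrt(max(cov[2, 2], 0.0))
    except np.linalg.LinAlgError:
        se_l1 = se_l2 = np.nan
    if flip:
        se_l1, se_l2 = se_l2, se_l1
    return w, t1, t2, t1 * se_l1, t2 * se_l2


def dwell_statistics(
    coarse_sequence: np.ndarray,
    dt_symbol: float,
    min_dwells_for_fit: int = 20,
    n_boot: int = 100,
    seed: int = 0,
) -> DwellStats:
    """Dwell-time samples and a censoring-agnostic two-exponential ML fit.

    Dwells are contiguous runs of one coarse label, pooled over states (the
    macrostate dwell distribution mixes both states' exponentials).  With
    fewer than ``min_dwells_for_fit`` complete dwells the fit is refused and
    only raw samples are returned.  The composite relaxation time is
    (tau1^-1 + tau2^-1)^-1, directly comparable to the operator's slowest
    implied timescale.
    """
    seq = np.asarray(coarse_sequence, dtype=int)
    if len(seq) < 2:
        raise ValueError("need at least two symbols")
    edges = np.flatnonzero(np.diff(seq) != 0) + 1
    if len(edges) < 2:
        raise ValueError("need at least two transitions for dwell statistics")
    bounds = np.concatenate([[0], edges, [len(seq)]])
    starts, ends = bounds[:-1], bounds[1:]
    # first and last dwells are censored (we did not see them start/end)
    interior = slice(1, len(starts) - 1) if len(starts) > 2 else slice(0, len(starts))
    dwell_frames = (ends - starts)[interior]
    states = seq[starts[interior]]
    dwells_s = dwell_frames * dt_symbol
    per_state = {int(s): dwells_s[states == s] for s in np.unique(states)}
    stats = DwellStats(
        dwell_times_s=dwells_s,
        per_state_dwells_s=per_state,
        mean_dwell_s=float(dwells_s.mean()),
    )
    if len(dwells_s) < min_dwells_for_fit:
        warnings.warn(f"only {len(dwells_s)} dwells; refusing exponential-mixture fit")
        return stats
    # dwells measured on the symbol lattice overestimate the underlying
    # continuous dwell by half a step on average; shift before fitting
    w, t1, t2, se1, se2 = _fit_exp_mixture(dwells_s - 0.5 * dt_symbol, with_se=True)
    stats.weight, stats.tau1_s, stats.tau2_s = float(w), float(t1), float(t2)
    stats.tau1_se, stats.tau2_se = float(se1), float(se2)
    stats.relaxation_time_s = float(1.0 / (1.0 / t1 + 1.0 / t2))
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        b1, b2 = [], []
        for _ in range(n_boot):
            sample = rng.choice(dwells_s, size=len(dwells_s), replace=True)
            _, bt1, bt2 = _fit_exp_mixture(sample)
            b1.append(bt1)
            b2.append(bt2)
        stats.tau1_ci = tuple(np.percentile(b1, [2.5, 97.5]))
        stats.tau2_ci = tuple(np.percentile(b2, [2.5, 97.5]))
    return stats


def kinetic_rates(coarse_sequence: np.ndarray, dt_symbol: float) -> pd.DataFrame:
    """kappa_{A->B} = (# A->B transitions) / (total time in A), per pair."""
    seq = np.asarray(coarse_sequence, dtype=int)
    states = np.unique(seq)
    time_in = {int(s): float((seq == s).sum() * dt_symbol) for s in states}
    trans = {}
    for a, b in zip(seq[:-1], seq[1:]):
        if a != b:
            trans[(int(a), int(b))] = trans.get((int(a), int(b)), 0) + 1
    rows = [
        {
            "from": a,
            "to": b,
            "n_transitions": n,
            "time_in_from_s": time_in[a],
            "rate_per_s": n / time_in[a],
        }
        for (a, b), n in sorted(trans.items())
    ]
    return pd.DataFrame(rows)
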