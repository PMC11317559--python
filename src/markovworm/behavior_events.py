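"""Interpretive behavioral signals and discrete event detection.

Two scalar signals summarize a posture frame:

* body-wave phase velocity ``omega = -(1/2pi) d/dt atan2(a2, a1)``
  (cycles/s): positive during forward crawling, negative during reversals;
* overall body curvature ``gamma = sum_i theta_i`` (radians): large |gamma|
  during deep turns, with the sign separating ventral from dorsal bends.

Events (reversals, ventral/dorsal turns) are contiguous threshold
crossings with a minimum duration and hysteresis on exit.  The default
thresholds are package choices exposed in :class:`EventThresholds`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .posture import PostureSeries

__all__ = [
    "BehaviorSignals",
    "EventThresholds",
    "EventTable",
    "phase_velocity",
    "curvature",
    "compute_signals",
    "detect_events",
    "event_rates",
]


@dataclass
class BehaviorSignals:
    omega: np.ndarray  # cycles/s
    gamma: np.ndarray | None  # radians (summed tangent angles)
    dt: float
    omega_defined: np.ndarray | None = field(default=None, repr=False)


def phase_velocity(series: PostureSeries, radius_floor: float = 1e-6) -> np.ndarray:
    """Body-wave phase velocity from the (a1, a2) quadrature pair.

    The phase atan2(a2, a1) is unwrapped, differentiated by central
    differences, negated and divided by 2*pi (units: cycles/s).  Frames
    where (a1, a2) is at the origin have undefined phase; omega there is
    linearly interpolated from the surrounding frames.
    """
    a1, a2 = series.a[:, 0], series.a[:, 1]
    phase = np.unwrap(np.arctan2(a2, a1))
    omega = -np.gradient(phase) / (2 * np.pi * series.dt)
    radius = np.hypot(a1, a2)
    bad = radius < radius_floor
    if np.any(bad):
        idx = np.arange(len(omega))
        if np.all(bad):
            raise ValueError("phase undefined on every frame: (a1, a2) = (0, 0)")
        omega[bad] = np.interp(idx[bad], idx[~bad], omega[~bad])
    return omega


def curvature(theta: np.ndarray) -> np.ndarray:
    """Overall body curvature: per-frame sum of tangent angles."""
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    return theta.sum(axis=1)


def compute_signals(series: PostureSeries) -> BehaviorSignals:
    a1, a2 = series.a[:, 0], series.a[:, 1]
    radius = np.hypot(a1, a2)
    return BehaviorSignals(
        omega=phase_velocity(series),
        gamma=curvature(series.theta) if series.theta is not None else None,
        dt=series.dt,
        omega_defined=radius >= 1e-6,
    )


@dataclass
class EventThresholds:
    """Detection thresholds (package defaults; tune per dataset).

    ``omega_reversal``: omega below this marks a reversal (0 cycles/s: the
    wave runs backward).  ``gamma_turn``: |gamma| above this marks a turn;
    None uses 3 SD of gamma, which clears the noise floor of a turn-free
    signal while sitting far below genuine turn excursions.
    ``min_duration_s``: shortest accepted event — half a second, roughly a
    quarter body-wave period; briefer phase dips are wave jitter, not
    behavior.  ``hysteresis``: exit-threshold band as a fraction of the
    signal's interquartile range (omega) or of gamma_turn (turns).
    ``ventral_positive``: sign convention mapping gamma > 0 to ventral.
    """

    omega_reversal: float = 0.0
    gamma_turn: float | None = None
    min_duration_s: float = 0.5
    hysteresis: float = 0.1
    ventral_positive: bool = True


@dataclass
class EventTable:
    events: pd.DataFrame  # columns: type, start_frame, end_frame, start_s, end_s
    duration_s: float

    def count(self, kind: str | None = None) -> int:
        if kind is None:
            return len(self.events)
        return int((self.events["type"] == kind).sum())

    def to_csv(self, path) -> None:
        self.events.to_csv(path, index=False)


def _hysteresis_intervals(
    above: np.ndarray, stay_above: np.ndarray, min_frames: int
) -> list[tuple[int, int]]:
    """Contiguous [start, end) runs: enter on ``above``, exit when
    ``stay_above`` turns false; drop runs shorter than ``min_frames``."""
    intervals = []
    t, n = 0, len(above)
    while t < n:
        if above[t]:
            start = t
            while t < n and stay_above[t]:
                t += 1
            if t - start >= min_frames:
                intervals.append((start, t))
        else:
            t += 1
    return intervals


def detect_events(
    signals: BehaviorSignals, thresholds: EventThresholds | None = None
) -> EventTable:
    """Threshold the behavior signals into reversal and turn events.

    Reversal: omega stays below ``omega_reversal`` (hysteresis band above
    it on exit) for at least ``min_duration_s``.  Turn: |gamma| exceeds
    ``gamma_turn``; the sign of gamma during the event assigns ventral vs
    dorsal.  Requires tangent angles for turns.
    """
    thr = thresholds or EventThresholds()
    dt = signals.dt
    min_frames = max(1, int(round(thr.min_duration_s / dt)))
    rows = []

    omega = signals.omega
    band = thr.hysteresis * (np.percentile(omega, 75) - np.percentile(omega, 25))
    below = omega < thr.omega_reversal
    stay_below = omega < thr.omega_reversal + band
    for start, end in _hysteresis_intervals(below, stay_below, min_frames):
        rows.append(("reversal", start, end))

    if signals.gamma is None:
        if thr.gamma_turn is not None:
            raise ValueError("turn detection requested but no tangent angles available")
    else:
        gamma = signals.gamma
        g_thr = thr.gamma_turn if thr.gamma_turn is not None else 3.0 * np.std(gamma)
        above = np.abs(gamma) > g_thr
        stay_above = np.abs(gamma) > g_thr * (1 - thr.hysteresis)
        for start, end in _hysteresis_intervals(above, stay_above, min_frames):
            mean_g = float(np.mean(gamma[start:end]))
            ventral = (mean_g > 0) == thr.ventral_positive
            rows.append(("ventral_turn" if ventral else "dorsal_turn", start, end))

    df = pd.DataFrame(rows, columns=["type", "start_frame", "end_frame"])
    if len(df):
        df["start_s"] = df["start_frame"] * dt
        df["end_s"] = df["end_frame"] * dt
        df = df.sort_values(["start_frame", "type"]).reset_index(drop=True)
    else:
        df["start_s"] = pd.Series(dtype=float)
        df["end_s"] = pd.Series(dtype=float)
    return EventTable(events=df, duration_s=len(signals.omega) * dt)


def event_rates(
    table: EventTable,
    duration_s: float | None = None,
    n_boot: int = 500,
    seed: int = 0,
    kinds: tuple[str, ...] = ("reversal", "ventral_turn", "dorsal_turn"),
) -> pd.DataFrame:
    """Events per second per type, with bootstrap CIs across events.

    The CI resamples event counts (Poisson-style bootstrap over the
    observed events); with zero events the rate and CI are 0.
    """
    duration = duration_s if duration_s is not None else table.duration_s
    if not (duration > 0):
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for kind in kinds:
        n = table.count(kind)
        rate = n / duration
        if n > 0:
            boot = rng.poisson(n, size=n_boot) / duration
            lo, hi = np.percentile(boot, [2.5, 97.5])
        else:
            lo = hi = 0.0
        rows.append({"type": kind, "rate_per_s": rate, "ci_lo": lo, "ci_hi": hi, "n": n})
    return pd.DataFrame(rows)
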