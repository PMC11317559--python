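"""2D centroid trajectories: container, mean squared displacement, diffusion.

The mean squared displacement is the time-averaged
``MSD(tau) = <|x(t+tau) - x(t)|^2>_t`` over all lag pairs; in the diffusive
regime ``MSD(tau) = 4 D tau`` and the effective diffusion coefficient is
estimated from the slope of a least-squares line over a stated lag range
(default 60-100 s, chosen inside the diffusive regime of worm foraging
tracks, which turn over from ballistic to diffusive between ~10 and 100 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class Trajectory:
    """A 2D centroid path sampled at fixed interval ``dt`` (seconds)."""

    xy: np.ndarray
    dt: float
    heading: np.ndarray | None = field(default=None, repr=False)
    label: str = "trajectory"

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError(f"trajectory must be (T, 2), got {self.xy.shape}")
        if not (self.dt > 0):
            raise ValueError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.dt

    def displacement(self) -> float:
        """Net start-to-end displacement (length units)."""
        return float(np.linalg.norm(self.xy[-1] - self.xy[0]))

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.xy, columns=["x", "y"])
        df.insert(0, "t", np.arange(self.n_frames) * self.dt)
        if self.heading is not None:
            df["heading"] = self.heading
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label: str = "trajectory") -> "Trajectory":
        df = pd.read_csv(path)
        t = df["t"].to_numpy()
        dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
        heading = df["heading"].to_numpy() if "heading" in df.columns else None
        return cls(xy=df[["x", "y"]].to_numpy(), dt=dt, heading=heading, label=label)


def msd(trajectory: Trajectory, max_lag_s: float | None = None) -> pd.DataFrame:
    """Time-averaged mean squared displacement over all lag pairs.

    Returns a DataFrame with columns ``lag_s`` and ``msd`` for lags
    1..max_lag frames.  MSD(0) = 0 is omitted.
    """
    xy = trajectory.xy
    n = xy.shape[0]
    max_lag = n - 1 if max_lag_s is None else min(n - 1, int(round(max_lag_s / trajectory.dt)))
    if max_lag < 1:
        raise ValueError("trajectory too short for the requested lag range")
    lags = np.arange(1, max_lag + 1)
    vals = np.empty(max_lag)
    for k, lag in enumerate(lags):
        d = xy[lag:] - xy[:-lag]
        vals[k] = np.mean(np.sum(d * d, axis=1))
    return pd.DataFrame({"lag_s": lags * trajectory.dt, "msd": vals})


@dataclass
class DiffusionFit:
    D: float
    slope: float
    intercept: float
    scaling_exponent: float  # log-log slope of MSD(tau) on the fit range
    fit_range_s: tuple[float, float]
    linear: bool  # False when the MSD scales visibly non-linearly in tau

    @property
    def is_linear(self) -> bool:
        return self.linear


def fit_diffusion(
    msd_curve: pd.DataFrame,
    fit_range_s: tuple[float, float] = (60.0, 100.0),
    exponent_tolerance: float = 0.3,
) -> DiffusionFit:
    """Estimate D from the slope of MSD(tau) = 4 D tau on ``fit_range_s``.

    The scaling exponent (slope of log MSD vs log tau on the fit range)
    diagnoses the regime: ~1 for diffusive, ~2 for ballistic.  A curve whose
    exponent deviates from 1 by more than ``exponent_tolerance`` is flagged
    non-linear and its D estimate should not be trusted.
    """
    lo, hi = fit_range_s
    sel = (msd_curve["lag_s"] >= lo) & (msd_curve["lag_s"] <= hi)
    if sel.sum() < 3:
        raise ValueError(f"fit range [{lo}, {hi}] s covers fewer than 3 MSD points")
    x = msd_curve.loc[sel, "lag_s"].to_numpy()
    y = msd_curve.loc[sel, "msd"].to_numpy()
    res = stats.linregress(x, y)
    pos = y > 0
    if pos.sum() >= 3:
        exponent = float(stats.linregress(np.log(x[pos]), np.log(y[pos])).slope)
    else:  # degenerate (e.g. stationary track): no scaling to speak of
        exponent = 0.0
    return DiffusionFit(
        D=float(res.slope / 4.0),
        slope=float(res.slope),
        intercept=float(res.intercept),
        scaling_exponent=exponent,
        fit_range_s=(lo, hi),
        linear=bool(abs(exponent - 1.0) <= exponent_tolerance),
    )


def msd_and_diffusion(
    trajectory: Trajectory,
    fit_range_s: tuple[float, float] = (60.0, 100.0),
) -> tuple[pd.DataFrame, DiffusionFit]:
    """Convenience wrapper: MSD curve plus diffusion-coefficient fit."""
    if trajectory.duration_s <= fit_range_s[1]:
        raise ValueError(
            f"trajectory of {trajectory.duration_s:.1f} s is shorter than the "
            f"fit range upper edge {fit_range_s[1]:.1f} s"
        )
    curve = msd(trajectory, max_lag_s=fit_range_s[1] * 1.2)
    return curve, fit_diffusion(curve, fit_range_s)
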