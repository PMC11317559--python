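"""Posture time series container and file I/O.

The raw observable is a multivariate posture time series: per frame, five
eigenworm coefficients ``a = (a1..a5)`` sampled at a fixed interval ``dt``
(1/16 s for the reference recordings).  Optionally a per-segment tangent
angle profile accompanies the modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

N_MODES = 5


@dataclass
class PostureSeries:
    """Time-indexed eigenworm coefficient matrix.

    Parameters
    ----------
    a : (T, 5) array
        Eigenworm coefficients per frame (dimensionless).
    dt : float
        Sampling interval in seconds per frame.
    worm_id : str
        Label for the recording (or simulation) this series came from.
    theta : (T, M) array, optional
        Tangent angles per body segment, when available.
    """

    a: np.ndarray
    dt: float
    worm_id: str = "worm"
    theta: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        if self.a.ndim != 2 or self.a.shape[1] != N_MODES:
            raise ValueError(f"posture array must be (T, {N_MODES}), got {self.a.shape}")
        if self.a.shape[0] < 2:
            raise ValueError("posture series needs at least 2 frames")
        if not np.all(np.isfinite(self.a)):
            raise ValueError("posture series contains non-finite entries")
        if not (self.dt > 0):
            raise ValueError("dt must be positive")
        if self.theta is not None:
            self.theta = np.asarray(self.theta, dtype=float)
            if self.theta.shape[0] != self.a.shape[0]:
                raise ValueError("theta and a must have the same number of frames")

    @property
    def n_frames(self) -> int:
        return self.a.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.dt

    def time(self) -> np.ndarray:
        """Frame times in seconds."""
        return np.arange(self.n_frames) * self.dt

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.a, columns=[f"a{i}" for i in range(1, N_MODES + 1)])
        df.insert(0, "t", self.time())
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, worm_id: str = "worm") -> "PostureSeries":
        df = pd.read_csv(path)
        cols = [f"a{i}" for i in range(1, N_MODES + 1)]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"posture CSV missing columns {missing}")
        t = df["t"].to_numpy()
        dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
        return cls(a=df[cols].to_numpy(), dt=dt, worm_id=worm_id)

    def to_hdf5(self, path, labels: np.ndarray | None = None) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("a", data=self.a)
            f.create_dataset("dt", data=self.dt)
            f.attrs["worm_id"] = self.worm_id
            if self.theta is not None:
                f.create_dataset("theta", data=self.theta)
            if labels is not None:
                f.create_dataset("labels", data=np.asarray(labels))

    @classmethod
    def from_hdf5(cls, path) -> "PostureSeries":
        with h5py.File(path, "r") as f:
            a = f["a"][:]
            dt = float(f["dt"][()])
            worm_id = f.attrs.get("worm_id", "worm")
            theta = f["theta"][:] if "theta" in f else None
        return cls(a=a, dt=dt, worm_id=str(worm_id), theta=theta)
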