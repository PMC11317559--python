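"""Posture-to-path: resistive force theory (RFT) propulsion in 2D.

Each body segment experiences an independent anisotropic drag force

    F_i = alpha_t (v~_i . t^) t^ + alpha_n (v~_i . n^) n^,

linear in its lab-frame velocity v~_i, with tangential and normal drag
coefficients whose ratio alpha = alpha_n / alpha_t is the model's single
free parameter (alpha_t = 1 without loss of generality: the force scale
cancels in the balance equations; crawling propulsion requires alpha > 1).
Writing v~_i = v_i + V + Omega x dx_i — worm-centric shape velocity plus
unknown rigid translation and rotation — and imposing zero net force and
zero net torque about the center of mass yields a 3x3 linear system for
(V, Omega).  Integrating (V, Omega) frame by frame turns a posture time
series into a centroid trajectory.

``rft_solve`` additionally recovers any rigid motion already present
between the two input skeletons (by least-squares rigid registration) and
reports total kinematics = observed rigid motion + force-balance solution
of the residual shape change; for a pure rigid motion the balance
correction vanishes for every alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import eigenworm_basis, modes_to_angles
from .posture import PostureSeries
from .trajectory import DiffusionFit, Trajectory, fit_diffusion, msd, msd_and_diffusion

__all__ = [
    "Skeleton",
    "RFTParams",
    "FrameKinematics",
    "angles_to_skeleton",
    "skeleton_to_angles",
    "solve_force_balance",
    "rft_solve",
    "integrate_path",
    "posture_to_trajectory",
    "calibrate_alpha",
    "msd",
    "fit_diffusion",
    "msd_and_diffusion",
    "Trajectory",
    "DiffusionFit",
]


@dataclass
class RFTParams:
    """Drag ratio alpha = alpha_n / alpha_t and the frame interval."""

    alpha: float = 30.0
    dt: float = 1.0 / 16.0

    def __post_init__(self) -> None:
        if not (self.alpha > 0):
            raise ValueError("alpha must be positive")
        if not (self.dt > 0):
            raise ValueError("dt must be positive")


@dataclass
class Skeleton:
    """Discrete centerline: joint points, segment midpoints, tangent angles."""

    points: np.ndarray  # (..., M+1, 2) joint coordinates
    theta: np.ndarray  # (..., M) tangent angles
    segment_length: float

    @property
    def x(self) -> np.ndarray:
        """Segment midpoints (..., M, 2)."""
        return 0.5 * (self.points[..., :-1, :] + self.points[..., 1:, :])

    @property
    def centroid(self) -> np.ndarray:
        return self.x.mean(axis=-2)


def angles_to_skeleton(theta: np.ndarray, segment_length: float = None,
                       body_length: float = 1.0) -> Skeleton:
    """Chain tangent angles into a skeleton, recentred to zero mean.

    point_{i+1} = point_i + L (cos theta_i, sin theta_i), with L the
    segment length (body_length / M unless given explicitly); midpoints are
    recentred so the per-frame centroid sits at the origin.
    """
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("tangent angles must be finite")
    M = theta.shape[-1]
    L = body_length / M if segment_length is None else segment_length
    steps = L * np.stack([np.cos(theta), np.sin(theta)], axis=-1)
    zero = np.zeros(steps.shape[:-2] + (1, 2))
    points = np.concatenate([zero, np.cumsum(steps, axis=-2)], axis=-2)
    mid = 0.5 * (points[..., :-1, :] + points[..., 1:, :])
    points = points - mid.mean(axis=-2, keepdims=True)[..., :, :]
    return Skeleton(points=points, theta=theta, segment_length=L)


def skeleton_to_angles(skel: Skeleton) -> np.ndarray:
    """Tangent angles from consecutive joint points (inverse of chaining)."""
    d = np.diff(skel.points, axis=-2)
    return np.arctan2(d[..., 1], d[..., 0])


# --------------------------------------------------------------------------
# force balance
# --------------------------------------------------------------------------
def _perp(v: np.ndarray) -> np.ndarray:
    """90-degree counterclockwise rotation: (x, y) -> (-y, x)."""
    return np.stack([-v[..., 1], v[..., 0]], axis=-1)


def _drag_tensors(theta: np.ndarray, alpha: float) -> np.ndarray:
    """Per-segment drag matrices C_i = t t^T + alpha n n^T, shape (...,M,2,2)."""
    t_hat = np.stack([np.cos(theta), np.sin(theta)], axis=-1)
    n_hat = _perp(t_hat)
    return (
        t_hat[..., :, None] * t_hat[..., None, :]
        + alpha * n_hat[..., :, None] * n_hat[..., None, :]
    )


def solve_force_balance(
    v: np.ndarray, dx: np.ndarray, theta: np.ndarray, alpha: float
):
    """Solve zero net force / net torque for rigid (V, Omega).

    Batched over leading axes: ``v`` (worm-centric segment velocities),
    ``dx`` (midpoint offsets from the centroid) and ``theta`` all have
    shape (..., M, *).  Returns (V (...,2), Omega (...), v_lab, forces).
    A singular system (degenerate posture with isotropic drag) falls back
    to a least-squares solve with a warning.
    """
    v = np.asarray(v, dtype=float)
    dx = np.asarray(dx, dtype=float)
    C = _drag_tensors(np.asarray(theta, dtype=float), alpha)
    p = _perp(dx)

    Cv = np.einsum("...mab,...mb->...ma", C, v)
    A = np.zeros(v.shape[:-2] + (3, 3))
    A[..., :2, :2] = C.sum(axis=-3)
    A[..., :2, 2] = np.einsum("...mab,...mb->...a", C, p)
    A[..., 2, :2] = np.einsum("...ma,...mab->...b", p, C)
    A[..., 2, 2] = np.einsum("...ma,...mab,...mb->...", p, C, p)
    b = np.concatenate(
        [-Cv.sum(axis=-2), -np.einsum("...ma,...ma->...", p, Cv)[..., None]], axis=-1
    )
    try:
        z = np.linalg.solve(A, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        warnings.warn("degenerate posture: force/torque system singular, using lstsq")
        z = np.stack(
            [np.linalg.lstsq(Ai, bi, rcond=None)[0] for Ai, bi in
             zip(A.reshape(-1, 3, 3), b.reshape(-1, 3))]
        ).reshape(b.shape)
    V = z[..., :2]
    Omega = z[..., 2]
    v_lab = v + V[..., None, :] + Omega[..., None, None] * p
    forces = np.einsum("...mab,...mb->...ma", C, v_lab)
    return V, Omega, v_lab, forces


@dataclass
class FrameKinematics:
    """Kinematics of one frame step: total rigid motion and RFT internals."""

    V: np.ndarray  # lab-frame translational velocity (2,) or (T,2)
    Omega: np.ndarray  # angular velocity (rad/s)
    v: np.ndarray = field(repr=False)  # worm-centric residual segment velocities
    v_lab: np.ndarray = field(repr=False)
    forces: np.ndarray = field(repr=False)
    force_residual: np.ndarray = field(repr=False, default=None)
    torque_residual: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.force_residual is None:
            # net force relative to the summed force magnitude
            net = np.linalg.norm(self.forces.sum(axis=-2), axis=-1)
            scale = np.linalg.norm(self.forces, axis=-1).sum(axis=-1) + 1e-300
            self.force_residual = net / scale


def _rigid_registration(X: np.ndarray, X1: np.ndarray):
    """Best-fit rotation angle of recentred point sets X -> X1 (batched)."""
    num = np.sum(X[..., 0] * X1[..., 1] - X[..., 1] * X1[..., 0], axis=-1)
    den = np.sum(np.sum(X * X1, axis=-1), axis=-1)
    return np.arctan2(num, den)


def _rot(phi: np.ndarray) -> np.ndarray:
    c, s = np.cos(phi), np.sin(phi)
    R = np.empty(np.shape(phi) + (2, 2))
    R[..., 0, 0], R[..., 0, 1] = c, -s
    R[..., 1, 0], R[..., 1, 1] = s, c
    return R


def rft_solve(skel_t: Skeleton, skel_t1: Skeleton, params: RFTParams) -> FrameKinematics:
    """Kinematics between two consecutive skeleton frames.

    The observed rigid motion (centroid displacement and best-fit rotation)
    is recovered exactly; the residual shape change is fed through the RFT
    force balance, whose (V, Omega) correction is the propulsion the shape
    change generates.  Works batched when the skeletons hold T frames.
    """
    x0, x1 = skel_t.x, skel_t1.x
    c0 = x0.mean(axis=-2, keepdims=True)
    c1 = x1.mean(axis=-2, keepdims=True)
    V_data = (c1 - c0)[..., 0, :] / params.dt
    X0, X1 = x0 - c0, x1 - c1
    phi = _rigid_registration(X0, X1)
    Omega_data = phi / params.dt
    X1_back = np.einsum("...ab,...mb->...ma", _rot(-phi), X1)
    v_res = (X1_back - X0) / params.dt
    V_b, Omega_b, v_lab, forces = solve_force_balance(v_res, X0, skel_t.theta, params.alpha)
    kin = FrameKinematics(
        V=V_data + V_b, Omega=Omega_data + Omega_b, v=v_res, v_lab=v_lab, forces=forces
    )
    # torque residual about the centroid, relative to the torque scale
    torque = np.einsum("...ma,...ma->...", _perp(X0), forces)
    scale = np.sum(np.linalg.norm(X0, axis=-1) * np.linalg.norm(forces, axis=-1), axis=-1)
    kin.torque_residual = np.abs(torque) / (scale + 1e-300)
    return kin


def integrate_path(
    V: np.ndarray,
    Omega: np.ndarray,
    dt: float,
    x0=(0.0, 0.0),
    heading0: float = 0.0,
) -> Trajectory:
    """Compose per-frame kinematics into a centroid path (explicit Euler).

    heading(t+1) = heading(t) + Omega(t) dt;
    x(t+1) = x(t) + R(heading(t)) V(t) dt.
    """
    V = np.atleast_2d(np.asarray(V, dtype=float))
    Omega = np.atleast_1d(np.asarray(Omega, dtype=float))
    T = V.shape[0]
    heading = heading0 + np.concatenate([[0.0], np.cumsum(Omega * dt)])
    c, s = np.cos(heading[:-1]), np.sin(heading[:-1])
    steps = np.stack([c * V[:, 0] - s * V[:, 1], s * V[:, 0] + c * V[:, 1]], axis=1) * dt
    xy = np.asarray(x0, dtype=float) + np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return Trajectory(xy=xy, dt=dt, heading=heading)


def posture_to_trajectory(
    series: PostureSeries,
    params: RFTParams | None = None,
    basis: np.ndarray | None = None,
    body_length: float = 1.0,
    x0=(0.0, 0.0),
    heading0: float = 0.0,
) -> Trajectory:
    """Full pipeline: posture modes -> tangent angles -> RFT -> centroid path.

    Uses the series' attached tangent angles when present, otherwise maps
    the mode coefficients through the synthetic eigenworm basis.  Lengths
    are in body lengths.
    """
    params = params or RFTParams(dt=series.dt)
    theta = series.theta
    if theta is None:
        theta = modes_to_angles(series.a, basis if basis is not None else eigenworm_basis())
    skels = angles_to_skeleton(theta, body_length=body_length)
    # The inputs are worm-centric shapes, so the full frame-to-frame
    # coordinate change is shape change and feeds the force balance whole;
    # the balance (V, Omega) is the body-frame propulsion to integrate.
    # (rft_solve's rigid-registration split is for measured skeleton pairs
    # that may carry real lab-frame rigid motion.)
    X = skels.x
    v = (X[1:] - X[:-1]) / params.dt
    V, Omega, _, _ = solve_force_balance(v, X[:-1], skels.theta[:-1], params.alpha)
    return integrate_path(V, Omega, params.dt, x0=x0, heading0=heading0)


# --------------------------------------------------------------------------
# drag-ratio calibration
# --------------------------------------------------------------------------
def _window_discrepancy(
    series: PostureSeries,
    measured: Trajectory,
    alpha: float,
    window_s: float,
    body_length: float,
) -> np.ndarray:
    """Per-window RMS distance between reconstructed and measured paths.

    Each non-overlapping window is re-anchored at the measured window
    start; the reconstruction's initial heading is aligned to the measured
    initial displacement direction, so only the subsequent path shape is
    scored (drift does not accumulate across windows).
    """
    params = RFTParams(alpha=alpha, dt=series.dt)
    rec = posture_to_trajectory(series, params, body_length=body_length)
    w = max(4, int(round(window_s / series.dt)))
    n_win = min(rec.n_frames, measured.n_frames) // w
    if n_win < 1:
        raise ValueError("trajectories shorter than one calibration window")
    out = np.empty(n_win)
    align = max(2, int(round(1.0 / series.dt)))  # ~1 s of initial motion
    for k in range(n_win):
        sl = slice(k * w, (k + 1) * w)
        r = rec.xy[sl] - rec.xy[sl.start]
        m = measured.xy[sl] - measured.xy[sl.start]
        dr = r[min(align, w - 1)]
        dm = m[min(align, w - 1)]
        if np.linalg.norm(dr) > 1e-12 and np.linalg.norm(dm) > 1e-12:
            dphi = np.arctan2(dm[1], dm[0]) - np.arctan2(dr[1], dr[0])
            r = r @ _rot(dphi).T
        out[k] = np.sqrt(np.mean(np.sum((r - m) ** 2, axis=1)))
    return out


def calibrate_alpha(
    series: PostureSeries,
    measured: Trajectory,
    alpha_grid,
    window_s: float = 60.0,
    body_length: float = 1.0,
    n_boot: int = 200,
    seed: int = 0,
) -> tuple[float, pd.DataFrame, tuple[float, float]]:
    """Infer the drag ratio by matching reconstructed to measured paths.

    Returns (alpha_star, score table, bootstrap CI over windows).
    """
    alpha_grid = sorted(float(a) for a in alpha_grid)
    if not alpha_grid:
        raise ValueError("alpha grid is empty")
    per_alpha = np.array(
        [_window_discrepancy(series, measured, a, window_s, body_length) for a in alpha_grid]
    )  # (n_alpha, n_windows)
    means = per_alpha.mean(axis=1)
    table = pd.DataFrame({"alpha": alpha_grid, "mean_discrepancy": means})
    alpha_star = float(alpha_grid[int(np.argmin(means))])
    rng = np.random.default_rng(seed)
    n_win = per_alpha.shape[1]
    picks = [
        alpha_grid[int(np.argmin(per_alpha[:, rng.integers(n_win, size=n_win)].mean(axis=1)))]
        for _ in range(n_boot)
    ]
    ci = tuple(np.percentile(picks, [2.5, 97.5]))
    return alpha_star, table, ci
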