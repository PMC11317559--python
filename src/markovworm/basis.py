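"""Synthetic eigenworm basis mapping mode coefficients to tangent angles.

A worm's centerline shape is summarized by the tangent angle profile
``theta_i`` along the body; the field convention expands this profile in a
small orthonormal basis of "eigenworm" shapes, so that a posture is a
5-vector of mode coefficients ``a = (a1..a5)``.

The empirical eigenworms of crawling *C. elegans* come from a PCA of real
tracking data and are not shipped here.  This module provides a *synthetic*
stand-in basis with the same qualitative structure:

* modes 1-2: a quadrature pair of body waves (two wavelengths), so that the
  locomotory wave appears as a rotation in the (a1, a2) plane;
* mode 3: a C-shaped bend (half-period sine in the tangent angle), so that
  deep turns appear as large ``a3`` and dominate the summed tangent angle
  (overall curvature); unlike the wave modes it genuinely curves the body,
  so turn pulses reorient the heading under the drag model;
* modes 4-5: a higher-harmonic quadrature pair.

The raw profiles are Gram-Schmidt orthonormalized (bend mode kept exact),
so ``angles_to_modes`` inverts ``modes_to_angles`` on the basis span.  The
wave modes have (near-)zero angle sum, leaving curvature carried almost
entirely by ``a3``.
"""

from __future__ import annotations

import numpy as np

DEFAULT_N_SEGMENTS = 32


def eigenworm_basis(n_segments: int = DEFAULT_N_SEGMENTS) -> np.ndarray:
    """Return an (n_segments, 5) orthonormal synthetic eigenworm basis.

    Column order is (wave-cos, wave-sin, C-bend, harmonic-cos,
    harmonic-sin).  Columns have unit Euclidean norm and are mutually
    orthogonal to machine precision.
    """
    if n_segments < 5:
        raise ValueError("need at least 5 segments for a 5-mode basis")
    s = (np.arange(n_segments) + 0.5) / n_segments
    raw = np.column_stack(
        [
            np.cos(4 * np.pi * s),
            np.sin(4 * np.pi * s),
            1.0 - np.cos(np.pi * s),
            np.cos(6 * np.pi * s),
            np.sin(6 * np.pi * s),
        ]
    )
    # Orthonormalize, keeping the bend mode exactly sinusoidal: process the
    # bend column first, then the wave modes in order, and restore the
    # (wave, wave, bend, harmonic, harmonic) column layout.
    order = [2, 0, 1, 3, 4]
    q = np.zeros_like(raw)
    cols = []
    for k, j in enumerate(order):
        v = raw[:, j].copy()
        for u in cols:
            v -= (u @ v) * u
        v /= np.linalg.norm(v)
        cols.append(v)
        q[:, j] = v
    return q


def modes_to_angles(a: np.ndarray, basis: np.ndarray | None = None) -> np.ndarray:
    """Map mode coefficients (T, 5) to tangent angle profiles (T, M)."""
    if basis is None:
        basis = eigenworm_basis()
    a = np.atleast_2d(np.asarray(a, dtype=float))
    if a.shape[1] != basis.shape[1]:
        raise ValueError(f"expected {basis.shape[1]} mode coefficients, got {a.shape[1]}")
    return a @ basis.T


def angles_to_modes(theta: np.ndarray, basis: np.ndarray | None = None) -> np.ndarray:
    """Project tangent angle profiles (T, M) onto the mode basis -> (T, 5)."""
    if basis is None:
        basis = eigenworm_basis()
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    return theta @ basis
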