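"""Unit-sphere point sets and direction utilities.

The package works with antipodally symmetric functions, so point sets come
in +/- pairs: :func:`symmetric_sphere` returns a golden-spiral hemisphere
together with its antipodes.  These grids serve as quadrature / projection
grids, non-negativity constraint sets and peak-search probes.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidArgumentError

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def symmetric_sphere(n: int = 724) -> np.ndarray:
    """Return ``n`` unit vectors closed under negation (``n`` must be even).

    The upper hemisphere carries ``n/2`` golden-spiral (Fibonacci) points,
    which are close to equal-area; the lower hemisphere is their mirror.
    """
    if n % 2 != 0 or n < 2:
        raise InvalidArgumentError(f"n must be a positive even integer, got {n}")
    half = n // 2
    i = np.arange(half)
    z = (i + 0.5) / half          # z in (0, 1): strictly upper hemisphere
    r = np.sqrt(1.0 - z * z)
    phi = i * _GOLDEN_ANGLE
    upper = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    return np.concatenate([upper, -upper], axis=0)


def check_unit(directions: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Validate an (n, 3) array of unit vectors; returns it as float64."""
    d = np.asarray(directions, dtype=np.float64)
    if d.ndim != 2 or d.shape[1] != 3:
        raise InvalidArgumentError(f"expected (n, 3) directions, got shape {d.shape}")
    norms = np.linalg.norm(d, axis=1)
    if not np.all(np.abs(norms - 1.0) <= tol):
        worst = float(np.max(np.abs(norms - 1.0)))
        raise InvalidArgumentError(f"directions must be unit-norm (worst deviation {worst:.2e})")
    return d


def to_spherical(directions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Convert unit vectors to (theta, phi): polar angle from +z, azimuth from +x."""
    d = np.asarray(directions, dtype=np.float64)
    theta = np.arccos(np.clip(d[..., 2], -1.0, 1.0))
    phi = np.arctan2(d[..., 1], d[..., 0])
    return theta, phi


def angle_between(u: np.ndarray, v: np.ndarray, antipodal: bool = True) -> np.ndarray:
    """Angle in degrees between direction sets, identifying d with -d by default."""
    dots = np.clip(np.tensordot(np.asarray(u), np.asarray(v), axes=([-1], [-1])), -1.0, 1.0)
    if antipodal:
        dots = np.abs(dots)
    return np.degrees(np.arccos(dots))


def rotation_aligning(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix R with R @ a = b for unit vectors a, b (Rodrigues)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    c = float(np.dot(a, b))
    if c < -1.0 + 1e-12:
        # 180 degrees: rotate about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    v = np.cross(a, b)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about a unit axis by an angle in degrees."""
    axis = np.asarray(axis, dtype=np.float64)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    vx = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(t) * vx + (1.0 - np.cos(t)) * (vx @ vx)
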