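"""Rotation helpers and the Cardan z-x-y decomposition.

All public angles are in degrees. Rotation matrices are world-from-local
(columns are the local basis expressed in the parent frame). The Cardan
sequence used throughout is intrinsic z-x-y: ``R = Rz(gamma) @ Rx(alpha) @
Ry(beta)``, i.e. first a rotation about the local z axis (ab-adduction),
then about the once-rotated x axis (axial / mediolateral), then about the
twice-rotated y axis (flexion-extension).
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "rot_x",
    "rot_y",
    "rot_z",
    "compose_zxy",
    "cardan_zxy",
    "unit",
    "angle_between_deg",
    "GimbalLockWarning",
]


class GimbalLockWarning(UserWarning):
    """Raised when the middle Cardan angle approaches +/-90 degrees."""


def rot_x(deg: float | np.ndarray) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    out = np.zeros(np.shape(a) + (3, 3))
    out[..., 0, 0] = 1.0
    out[..., 1, 1] = c
    out[..., 1, 2] = -s
    out[..., 2, 1] = s
    out[..., 2, 2] = c
    return out


def rot_y(deg: float | np.ndarray) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    out = np.zeros(np.shape(a) + (3, 3))
    out[..., 1, 1] = 1.0
    out[..., 0, 0] = c
    out[..., 0, 2] = s
    out[..., 2, 0] = -s
    out[..., 2, 2] = c
    return out


def rot_z(deg: float | np.ndarray) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    out = np.zeros(np.shape(a) + (3, 3))
    out[..., 2, 2] = 1.0
    out[..., 0, 0] = c
    out[..., 0, 1] = -s
    out[..., 1, 0] = s
    out[..., 1, 1] = c
    return out


def compose_zxy(gamma: float | np.ndarray, alpha: float | np.ndarray,
                beta: float | np.ndarray) -> np.ndarray:
    """Compose ``Rz(gamma) @ Rx(alpha) @ Ry(beta)`` (degrees), broadcastable."""
    return rot_z(gamma) @ rot_x(alpha) @ rot_y(beta)


def cardan_zxy(R: np.ndarray, *, lock_tol_deg: float = 0.5) -> tuple:
    """Decompose a rotation into intrinsic z-x-y Cardan angles (degrees).

    Returns ``(gamma, alpha, beta)`` with ``gamma, beta`` on the principal
    branch (-180, 180] and ``alpha`` in [-90, 90]. For batched input
    (``R.shape == (..., 3, 3)``) arrays are returned.

    Within ``lock_tol_deg`` of gimbal lock (|alpha| -> 90) the split between
    gamma and beta is indeterminate; a :class:`GimbalLockWarning` is emitted
    and gamma absorbs the indeterminacy (beta is set from the remaining
    off-axis terms, never silently wrapped).
    """
    R = np.asarray(R, dtype=float)
    if R.shape[-2:] != (3, 3):
        raise ValueError("expected (..., 3, 3) rotation matrices")
    err = np.abs(R @ np.swapaxes(R, -1, -2) - np.eye(3)).max()
    if err > 1e-6:
        raise ValueError(f"matrix is not orthonormal (|R R^T - I| = {err:.2e})")
    if np.any(np.linalg.det(R) < 0):
        raise ValueError("matrix is a reflection (det < 0), not a rotation")

    s_alpha = np.clip(R[..., 2, 1], -1.0, 1.0)
    alpha = np.arcsin(s_alpha)
    near_lock = np.abs(np.abs(s_alpha) - 1.0) < np.sin(np.deg2rad(lock_tol_deg)) ** 2 / 2 + (
        1 - np.cos(np.deg2rad(lock_tol_deg)))
    if np.any(near_lock):
        warnings.warn(
            "Cardan z-x-y decomposition near gimbal lock (|alpha| ~ 90 deg); "
            "gamma absorbs the z/y indeterminacy",
            GimbalLockWarning,
            stacklevel=2,
        )
    beta = np.arctan2(-R[..., 2, 0], R[..., 2, 2])
    gamma = np.arctan2(-R[..., 0, 1], R[..., 1, 1])
    if np.any(near_lock):
        # at lock the z and y rotations act about the same axis; put the whole
        # rotation into gamma and zero beta where degenerate
        beta = np.where(near_lock, 0.0, beta)
        gamma = np.where(
            near_lock, np.arctan2(R[..., 1, 0], R[..., 0, 0]), gamma)
    out = (np.rad2deg(gamma), np.rad2deg(alpha), np.rad2deg(beta))
    if R.ndim == 2:
        return tuple(float(v) for v in out)
    return out


def unit(v: np.ndarray, axis: int = -1) -> np.ndarray:
    """Normalize vectors along ``axis``; raises on (near-)zero length."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    if np.any(n < 1e-12):
        raise ValueError("cannot normalize zero-length vector")
    return v / n


def angle_between_deg(a: np.ndarray, b: np.ndarray, axis: int = -1) -> np.ndarray:
    """Included 3D angle between two vectors in degrees, in [0, 180]."""
    ua, ub = unit(a, axis=axis), unit(b, axis=axis)
    dot = np.clip(np.sum(ua * ub, axis=axis), -1.0, 1.0)
    return np.rad2deg(np.arccos(dot))
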