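"""DLT calibration from cube correspondences and two-view triangulation.

Calibration solves the linearized projection equations (two equations per
sphere, 11 unknowns) by least squares after centroid/scale normalization of
both the 3D and pixel coordinates for conditioning; at least seven
non-coplanar spheres are required. Triangulation solves, per landmark and
frame, the four linear ray equations for (X, Y, Z) and records per-view
reprojection errors. Landmarks missing in either view stay missing — this
module never interpolates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cameras import CameraDLT, Observations2D

MIN_SPHERES = 7


@dataclass
class Trajectory3D:
    """Reconstructed landmark positions plus per-view reprojection errors."""

    landmark_names: tuple
    xyz: np.ndarray                    # (T, N, 3), NaN where missing
    err_px: dict                       # view -> (T, N) pixel error
    condition_number: np.ndarray | None = None   # (T, N) triangulation cond.

    def as_dict(self) -> dict:
        return {n: self.xyz[:, i, :] for i, n in enumerate(self.landmark_names)}

    def to_frame(self) -> pd.DataFrame:
        T, N, _ = self.xyz.shape
        views = list(self.err_px)
        rows = {
            "frame": np.repeat(np.arange(T), N),
            "landmark": np.tile(self.landmark_names, T),
            "X": self.xyz[..., 0].ravel(),
            "Y": self.xyz[..., 1].ravel(),
            "Z": self.xyz[..., 2].ravel(),
        }
        for v in views:
            rows[f"err_{v}"] = self.err_px[v].ravel()
        return pd.DataFrame(rows)


def _normalization(points: np.ndarray) -> np.ndarray:
    """Similarity transform (homogeneous) sending points to zero centroid,
    RMS radius sqrt(dim)."""
    pts = np.asarray(points, dtype=float)
    dim = pts.shape[1]
    centroid = pts.mean(axis=0)
    rms = np.sqrt(np.mean(np.sum((pts - centroid) ** 2, axis=1)))
    scale = np.sqrt(dim) / max(rms, 1e-12)
    T = np.eye(dim + 1)
    T[:dim, :dim] *= scale
    T[:dim, dim] = -scale * centroid
    return T


def calibrate_dlt(xyz: np.ndarray, uv: np.ndarray, view: str = "",
                  *, normalize: bool = True) -> CameraDLT:
    """Fit the 11 DLT coefficients of one view from sphere correspondences.

    Parameters
    ----------
    xyz : (S, 3) sphere positions in meters.
    uv : (S, 2) annotated pixel positions of the same spheres in this view.
    """
    xyz = np.asarray(xyz, dtype=float)
    uv = np.asarray(uv, dtype=float)
    if xyz.shape[0] != uv.shape[0]:
        raise ValueError("3D and 2D correspondence counts differ")
    S = xyz.shape[0]
    if S < MIN_SPHERES:
        raise ValueError(
            f"at least seven corresponding spheres are required (got {S})")
    centered = xyz - xyz.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[-1] < 1e-6 * sv[0]:
        raise ValueError("degenerate sphere configuration (coplanar or collinear)")

    if normalize:
        T3, T2 = _normalization(xyz), _normalization(uv)
    else:
        T3, T2 = np.eye(4), np.eye(3)
    Xh = np.hstack([xyz, np.ones((S, 1))]) @ T3.T
    Uh = np.hstack([uv, np.ones((S, 1))]) @ T2.T
    Xn, Un = Xh[:, :3], Uh[:, :2]

    # rows: [X Y Z 1 0 0 0 0 -uX -uY -uZ] p = u  (and the v analogue)
    A = np.zeros((2 * S, 11))
    b = np.zeros(2 * S)
    A[0::2, 0:3] = Xn
    A[0::2, 3] = 1.0
    A[0::2, 8:11] = -Un[:, 0:1] * Xn
    b[0::2] = Un[:, 0]
    A[1::2, 4:7] = Xn
    A[1::2, 7] = 1.0
    A[1::2, 8:11] = -Un[:, 1:2] * Xn
    b[1::2] = Un[:, 1]
    coeffs, *_ = np.linalg.lstsq(A, b, rcond=None)
    Pn = np.vstack([coeffs[0:4], coeffs[4:8], np.append(coeffs[8:11], 1.0)])
    P = np.linalg.inv(T2) @ Pn @ T3
    cam = CameraDLT.from_matrix(P, view=view)
    resid = cam.project(xyz) - uv
    cam.rms_reprojection_px = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    return cam


def triangulate(camera_d: CameraDLT, camera_l: CameraDLT,
                obs_d: Observations2D, obs_l: Observations2D,
                *, cond_warn: float = 1e6) -> Trajectory3D:
    """Reconstruct 3D landmark trajectories from two calibrated views.

    Solves the stacked ray equations ``(a - u c) . X = u - a4`` (two rows
    per view) in the least-squares sense. A landmark missing in either view
    is left missing; near-parallel ray geometry is flagged through the
    recorded condition number rather than rejected.
    """
    if obs_d.landmark_names != obs_l.landmark_names:
        raise ValueError("views disagree on the landmark catalog")
    if obs_d.n_frames != obs_l.n_frames:
        raise ValueError("views disagree on the number of frames")
    T, N = obs_d.uv.shape[:2]
    xyz = np.full((T, N, 3), np.nan)
    cond = np.full((T, N), np.nan)
    rows = []
    for cam, obs in ((camera_d, obs_d), (camera_l, obs_l)):
        P = cam.P
        rows.append((P[:2, :3], P[:2, 3], P[2, :3]))
    for i in range(T):
        for j in range(N):
            uv1, uv2 = obs_d.uv[i, j], obs_l.uv[i, j]
            if not (np.all(np.isfinite(uv1)) and np.all(np.isfinite(uv2))):
                continue
            A = np.empty((4, 3))
            b = np.empty(4)
            for k, (ab, ab4, c) in enumerate(rows):
                uv = (uv1, uv2)[k]
                A[2 * k:2 * k + 2] = ab - uv[:, None] * c
                b[2 * k:2 * k + 2] = uv - ab4
            sol, _, _, sv = np.linalg.lstsq(A, b, rcond=None)
            xyz[i, j] = sol
            cond[i, j] = sv[0] / sv[-1] if sv[-1] > 0 else np.inf
    err = {}
    for cam, obs in ((camera_d, obs_d), (camera_l, obs_l)):
        reproj = np.full((T, N), np.nan)
        ok = np.all(np.isfinite(xyz), axis=-1)
        if ok.any():
            proj = cam.project(np.where(ok[..., None], xyz, 0.0))
            d = np.linalg.norm(proj - obs.uv, axis=-1)
            reproj[ok] = d[ok]
        err[cam.view or f"view{len(err)}"] = reproj
    return Trajectory3D(obs_d.landmark_names, xyz, err, cond)


def reprojection_report(traj: Trajectory3D) -> pd.DataFrame:
    """Mean/median/max pixel reprojection error per landmark per view."""
    rows = []
    for view, e in traj.err_px.items():
        for j, name in enumerate(traj.landmark_names):
            col = e[:, j]
            col = col[np.isfinite(col)]
            rows.append({
                "view": view, "landmark": name,
                "n": len(col),
                "mean_px": float(np.mean(col)) if len(col) else np.nan,
                "median_px": float(np.median(col)) if len(col) else np.nan,
                "max_px": float(np.max(col)) if len(col) else np.nan,
            })
    return pd.DataFrame(rows)
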