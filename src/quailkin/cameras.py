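"""Biplanar projection rig: 11-coefficient DLT cameras and a calibration cube.

Each view is a direct linear transformation (DLT) camera,

    u = (a1 X + a2 Y + a3 Z + a4) / (c1 X + c2 Y + c3 Z + 1)
    v = (b1 X + b2 Y + b3 Z + b4) / (c1 X + c2 Y + c3 Z + 1),

the classic 11-parameter linear-fractional model used for biplanar X-ray
reconstruction. The default rig emulates the study's laterolateral and
ventrodorsal beams: two perspective cameras with orthogonal optical axes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

VIEW_LATERAL = "lateral"
VIEW_VENTRAL = "ventrodorsal"


@dataclass
class CameraDLT:
    """One calibrated view. ``coeffs`` = (a1..a4, b1..b4, c1..c3)."""

    coeffs: np.ndarray
    view: str = ""
    rms_reprojection_px: float = float("nan")

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float).reshape(11)
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("DLT coefficients must be finite")

    @property
    def P(self) -> np.ndarray:
        """3x4 homogeneous projection matrix with P[2, 3] = 1."""
        a, b, c = self.coeffs[0:4], self.coeffs[4:8], self.coeffs[8:11]
        return np.vstack([a, b, np.append(c, 1.0)])

    @classmethod
    def from_matrix(cls, P: np.ndarray, view: str = "", **kw) -> "CameraDLT":
        P = np.asarray(P, dtype=float)
        if abs(P[2, 3]) < 1e-12:
            raise ValueError("projection matrix cannot be normalized (P[2,3] = 0)")
        P = P / P[2, 3]
        return cls(np.concatenate([P[0], P[1], P[2, :3]]), view=view, **kw)

    def project(self, points: np.ndarray, *, den_tol: float = 1e-9) -> np.ndarray:
        """Project 3D points (..., 3) to pixel coordinates (..., 2)."""
        pts = np.asarray(points, dtype=float)
        h = np.concatenate([pts, np.ones(pts.shape[:-1] + (1,))], axis=-1)
        proj = h @ self.P.T
        den = proj[..., 2]
        if np.any(np.abs(den) < den_tol):
            raise ValueError("point on the camera plane (projection denominator ~ 0)")
        return proj[..., :2] / den[..., None]

    def to_json(self) -> str:
        return json.dumps({"view": self.view, "coeffs": self.coeffs.tolist(),
                           "rms_reprojection_px": self.rms_reprojection_px})

    @classmethod
    def from_json(cls, text: str) -> "CameraDLT":
        d = json.loads(text)
        return cls(np.array(d["coeffs"]), view=d["view"],
                   rms_reprojection_px=d.get("rms_reprojection_px", float("nan")))


@dataclass
class Observations2D:
    """Per-view pixel observations for a whole sequence (NaN = missing)."""

    view: str
    landmark_names: tuple
    uv: np.ndarray                     # (T, N, 2)

    def __post_init__(self) -> None:
        self.landmark_names = tuple(self.landmark_names)
        self.uv = np.asarray(self.uv, dtype=float)
        if self.uv.ndim != 3 or self.uv.shape[1] != len(self.landmark_names) \
                or self.uv.shape[2] != 2:
            raise ValueError("uv must have shape (frames, landmarks, 2)")

    @property
    def n_frames(self) -> int:
        return self.uv.shape[0]


def _pinhole_dlt(position, rows, focal_px, principal, view) -> CameraDLT:
    R = np.asarray(rows, dtype=float)
    K = np.array([[focal_px, 0.0, principal[0]],
                  [0.0, focal_px, principal[1]],
                  [0.0, 0.0, 1.0]])
    C = np.asarray(position, dtype=float)
    P = K @ np.hstack([R, (-R @ C)[:, None]])
    return CameraDLT.from_matrix(P, view=view)


def make_two_view_rig(
    scene_center=(0.3, 0.0, 0.1),
    distance: float = 1.5,
    focal_px: float = 4500.0,
    principal=(600.0, 600.0),
    lateral_tilt_deg: float = 0.0,
) -> tuple:
    """Build the (lateral, ventrodorsal) camera pair.

    The lateral beam views the scene from the animal's right along +y (u
    grows cranially, v grows downward); the ventrodorsal beam views from
    below along +z (u cranial, v toward the animal's left). Optical axes
    are orthogonal up to ``lateral_tilt_deg`` (elevation of the lateral
    beam out of the horizontal plane).
    """
    c = np.asarray(scene_center, dtype=float)
    if distance <= max(0.3, np.abs(c).max()):
        raise ValueError("camera distance must exceed the scene extent")
    tilt = np.deg2rad(lateral_tilt_deg)
    axis_lat = np.array([0.0, np.cos(tilt), np.sin(tilt)])   # viewing dir
    axis_ven = np.array([0.0, 0.0, 1.0])
    cosang = abs(float(axis_lat @ axis_ven))
    if cosang > np.cos(np.deg2rad(25.0)):
        raise ValueError("degenerate rig geometry: optical axes near-parallel")
    x_lat = np.array([1.0, 0.0, 0.0])
    rows_lat = np.vstack([x_lat, np.cross(axis_lat, x_lat), axis_lat])
    lateral = _pinhole_dlt(c - distance * axis_lat, rows_lat,
                           focal_px, principal, VIEW_LATERAL)
    rows_ven = np.array([[1.0, 0.0, 0.0],
                         [0.0, 1.0, 0.0],
                         [0.0, 0.0, 1.0]])
    ventral = _pinhole_dlt(c - distance * axis_ven, rows_ven,
                           focal_px, principal, VIEW_VENTRAL)
    return lateral, ventral


def optical_axis(camera: CameraDLT) -> np.ndarray:
    """Unit viewing direction of a DLT camera (third row of the rotation)."""
    M = camera.P[:, :3]
    axis = M[2] / np.linalg.norm(M[2])
    # the DLT scale can flip the row; orient toward positive depth of the
    # principal plane by convention
    return axis


def project_sequence(camera: CameraDLT, landmarks: dict,
                     names=None) -> Observations2D:
    """Project a landmark trajectory dict (name -> (T, 3)) into one view."""
    names = tuple(names) if names is not None else tuple(landmarks)
    pts = np.stack([landmarks[n] for n in names], axis=1)
    return Observations2D(camera.view, names, camera.project(pts))


def add_pixel_noise(obs: Observations2D, sigma: float, seed: int) -> Observations2D:
    """Add i.i.d. Gaussian pixel noise; ``sigma = 0`` returns the input unchanged."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return obs
    rng = np.random.default_rng(seed)
    noisy = obs.uv + rng.normal(0.0, sigma, size=obs.uv.shape)
    return Observations2D(obs.view, obs.landmark_names, noisy)


@dataclass
class CalibrationCube:
    """Regular grid of X-ray-opaque metal spheres with known 3D positions."""

    positions: np.ndarray              # (S, 3) meters
    spacing: float
    sphere_ids: tuple = field(default=())

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if not self.sphere_ids:
            self.sphere_ids = tuple(range(len(self.positions)))
        if len(self.positions) < 8:
            raise ValueError("calibration cube needs at least 8 spheres")
        if len(np.unique(self.positions.round(12), axis=0)) != len(self.positions):
            raise ValueError("duplicate sphere positions")
        centered = self.positions - self.positions.mean(axis=0)
        if np.linalg.svd(centered, compute_uv=False)[-1] < 1e-9:
            raise ValueError("calibration spheres are coplanar")


def make_calibration_cube(n_per_axis: int = 3, spacing: float = 0.05,
                          center=(0.3, 0.0, 0.1)) -> CalibrationCube:
    """Cube of ``n_per_axis**3`` equidistant spheres centred on the scene."""
    if n_per_axis < 2:
        raise ValueError("need at least 2 spheres per axis")
    g = (np.arange(n_per_axis) - (n_per_axis - 1) / 2.0) * spacing
    pts = np.stack(np.meshgrid(g, g, g, indexing="ij"), axis=-1).reshape(-1, 3)
    return CalibrationCube(pts + np.asarray(center, float), spacing)
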