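"""Anatomical frames, Cardan joint/pelvis angles and effective-leg variables.

Conventions (left leg is the reference):

* Pelvis frame: origin at the centroid of the two hips and the pelvis
  cranial marker; e_y from right hip to left hip, e_z = (p_c - h_r) x e_y,
  e_x = e_y x e_z (all normalized).
* Whole-leg frame: origin at the femur midpoint; e_z from knee to hip,
  e_y = e_z x (k - tmp_dist) — the normal of the hip/knee/TMP-distal plane,
  pointing to the animal's left — and e_x = e_y x e_z.
* Hip angles: Cardan z-x-y decomposition of the leg frame relative to the
  pelvis frame. gamma (about z) is ab-adduction, alpha (about x) the
  axial/mediolateral rotation, beta (about y) flexion-extension. Right-leg
  alpha and gamma are negated so both sides share the left convention, and
  flexion-extension is reported as beta + 90 because in the zero pose the
  femur and pelvis are orthogonal in the sagittal plane.
* Effective leg: the hip -> toe-tip (Mto) segment; its sagittal-plane angle
  against the forward horizontal is < 90 deg when the toe is cranial to
  the hip; the aperture angle is the 3D angle between the two legs'
  hip -> Mto vectors.

All operations accept (T, 3) trajectories or single points, propagate NaNs
(missing landmarks stay missing) and are invariant under global rigid
translation; relative angles are invariant under global rotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .geometry import cardan_zxy, unit

_COLLINEAR_TOL = 1e-8


@dataclass
class BodyFrame:
    """Time series of an orthonormal right-handed anatomical frame."""

    origin: np.ndarray                 # (T, 3)
    basis: np.ndarray                  # (T, 3, 3), columns e_x, e_y, e_z
    label: str = ""

    def __post_init__(self) -> None:
        self.origin = np.atleast_2d(np.asarray(self.origin, dtype=float))
        self.basis = np.asarray(self.basis, dtype=float)
        if self.basis.ndim == 2:
            self.basis = self.basis[None]
        ok = np.all(np.isfinite(self.basis), axis=(-2, -1))
        if ok.any():
            B = self.basis[ok]
            err = np.abs(B @ np.swapaxes(B, -1, -2) - np.eye(3)).max()
            if err > 1e-9:
                raise ValueError(f"basis not orthonormal (err {err:.1e})")
            if np.any(np.linalg.det(B) < 0.99):
                raise ValueError("basis must be right-handed (det = +1)")


def _frame_from(ey_raw, interim_x, origin, label, order="zxy") -> BodyFrame:
    """Shared Gram-Schmidt-by-cross-products construction."""
    norm_cross = np.linalg.norm(np.cross(interim_x, ey_raw), axis=-1)
    scale = (np.linalg.norm(interim_x, axis=-1)
             * np.linalg.norm(ey_raw, axis=-1))
    bad = norm_cross < _COLLINEAR_TOL * np.maximum(scale, 1e-30)
    finite = np.all(np.isfinite(ey_raw), axis=-1) & np.all(
        np.isfinite(interim_x), axis=-1)
    if np.any(bad & finite):
        raise ValueError(f"{label}: defining points are collinear "
                         "(degenerate frame)")
    e_y = unit(ey_raw)
    e_z = unit(np.cross(interim_x, e_y))
    e_x = np.cross(e_y, e_z)
    return BodyFrame(origin=origin, basis=np.stack([e_x, e_y, e_z], axis=-1),
                     label=label)


def pelvis_frame(p_c: np.ndarray, h_r: np.ndarray, h_l: np.ndarray) -> BodyFrame:
    """Pelvis anatomical frame from the cranial marker and both hips."""
    p_c, h_r, h_l = (np.atleast_2d(np.asarray(x, float)) for x in (p_c, h_r, h_l))
    origin = (p_c + h_r + h_l) / 3.0
    return _frame_from(h_l - h_r, p_c - h_r, origin, "pelvis")


def whole_leg_frame(h_i: np.ndarray, k_i: np.ndarray, tmp_dist_i: np.ndarray,
                    side: str) -> BodyFrame:
    """Whole-leg frame (hip/knee/TMP-distal plane) for one side."""
    if side not in ("l", "r"):
        raise ValueError(f"side must be 'l' or 'r', got {side!r}")
    h_i, k_i, tmp = (np.atleast_2d(np.asarray(x, float))
                     for x in (h_i, k_i, tmp_dist_i))
    ez_raw = h_i - k_i
    interim_x = k_i - tmp
    norm_cross = np.linalg.norm(np.cross(ez_raw, interim_x), axis=-1)
    scale = np.linalg.norm(ez_raw, axis=-1) * np.linalg.norm(interim_x, axis=-1)
    finite = np.all(np.isfinite(ez_raw) & np.isfinite(interim_x), axis=-1)
    if np.any((norm_cross < _COLLINEAR_TOL * np.maximum(scale, 1e-30)) & finite):
        raise ValueError("whole-leg frame: hip, knee and TMP-distal are "
                         "collinear (fully extended degenerate leg)")
    e_z = unit(ez_raw)
    e_y = unit(np.cross(e_z, interim_x))
    e_x = np.cross(e_y, e_z)
    return BodyFrame(origin=(h_i + k_i) / 2.0,
                     basis=np.stack([e_x, e_y, e_z], axis=-1),
                     label=f"whole-leg-{side}")


@dataclass
class CardanAngles:
    """z-x-y Cardan angle series (degrees)."""

    gamma: np.ndarray    # about z: ab-adduction / yaw
    alpha: np.ndarray    # about x: mediolateral (axial) rotation / roll
    beta: np.ndarray     # about y: flexion-extension / pitch
    side: str = ""
    reference: str = ""

    @property
    def flexion_extension(self) -> np.ndarray:
        """Hip flexion-extension in the beta + 90 reporting convention."""
        return self.beta + 90.0


def hip_angles(pelvis: BodyFrame, leg: BodyFrame, side: str,
               *, left_reference: bool = True) -> CardanAngles:
    """3D hip angles: leg frame decomposed against the pelvis frame.

    With ``left_reference`` (default, the study's reporting convention) the
    right leg's alpha and gamma are negated so both sides share the left
    leg's sign semantics; pass ``False`` to keep raw per-side values (the
    stride pipeline's ``mirror_to_left`` then handles the flip).
    """
    if side not in ("l", "r"):
        raise ValueError(f"side must be 'l' or 'r', got {side!r}")
    if pelvis.basis.shape[0] != leg.basis.shape[0]:
        raise ValueError("pelvis and leg frames cover different frame counts")
    R_rel = np.swapaxes(pelvis.basis, -1, -2) @ leg.basis
    gamma, alpha, beta = cardan_zxy(R_rel)
    gamma, alpha, beta = (np.atleast_1d(v) for v in (gamma, alpha, beta))
    if side == "r" and left_reference:
        alpha, gamma = -alpha, -gamma
    return CardanAngles(gamma=gamma, alpha=alpha, beta=beta, side=side,
                        reference="pelvis")


def pelvis_global_angles(pelvis: BodyFrame) -> CardanAngles:
    """Pelvis orientation against the global frame (yaw, roll, pitch).

    Same z-x-y sequence as the hip. Negative pitch is retroversion (trunk
    more vertically oriented); positive roll tilts toward the right is
    encoded by the sign of alpha under the left-reference convention;
    positive yaw turns the body toward the left.
    """
    gamma, alpha, beta = cardan_zxy(pelvis.basis)
    return CardanAngles(gamma=np.atleast_1d(gamma), alpha=np.atleast_1d(alpha),
                        beta=np.atleast_1d(beta), reference="global")


def joint_angle(proximal: np.ndarray, joint: np.ndarray,
                distal: np.ndarray) -> np.ndarray:
    """Included 3D angle at a joint, degrees in (0, 180); flexion decreases it."""
    proximal, joint, distal = (np.atleast_2d(np.asarray(x, float))
                               for x in (proximal, joint, distal))
    a = proximal - joint
    b = distal - joint
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    finite = np.isfinite(na) & np.isfinite(nb)
    if np.any((na < 1e-12) & finite) or np.any((nb < 1e-12) & finite):
        raise ValueError("zero-length segment at joint")
    cos = np.clip(np.sum(a * b, axis=-1) / (na * nb), -1.0, 1.0)
    return np.rad2deg(np.arccos(cos))


def effective_leg(hip: np.ndarray, mto: np.ndarray,
                  forward_axis=(1.0, 0.0, 0.0)) -> tuple:
    """Effective-leg length (m) and sagittal angle of attack (deg).

    The angle is measured in the plane spanned by the forward axis and the
    vertical, from the forward horizontal: a vertical leg reads 90 deg,
    toe cranial to the hip < 90 deg, toe caudal > 90 deg.
    """
    hip, mto = np.atleast_2d(np.asarray(hip, float)), np.atleast_2d(
        np.asarray(mto, float))
    v = mto - hip
    length = np.linalg.norm(v, axis=-1)
    if np.any(length[np.isfinite(length)] < 1e-12):
        raise ValueError("hip and toe tip coincide (zero-length effective leg)")
    fwd = unit(np.asarray(forward_axis, float))
    up = np.array([0.0, 0.0, 1.0])
    alpha = np.rad2deg(np.arctan2(-(v @ up), v @ fwd))
    return length, alpha


def aperture_angle(hip_l, mto_l, hip_r, mto_r) -> np.ndarray:
    """3D angle (deg) between the two effective-leg vectors, in [0, 180]."""
    vl = np.atleast_2d(np.asarray(mto_l, float)) - np.atleast_2d(
        np.asarray(hip_l, float))
    vr = np.atleast_2d(np.asarray(mto_r, float)) - np.atleast_2d(
        np.asarray(hip_r, float))
    nl = np.linalg.norm(vl, axis=-1)
    nr = np.linalg.norm(vr, axis=-1)
    if np.any(nl[np.isfinite(nl)] < 1e-12) or np.any(nr[np.isfinite(nr)] < 1e-12):
        raise ValueError("zero-length effective leg")
    cos = np.clip(np.sum(vl * vr, axis=-1) / (nl * nr), -1.0, 1.0)
    return np.rad2deg(np.arccos(cos))


def differentiate(series: np.ndarray, fps: float, *,
                  lowpass_hz: float | None = 25.0, order: int = 4) -> np.ndarray:
    """Velocity by 2nd-order central differences (one-sided at the ends).

    An optional zero-phase Butterworth low-pass (default 4th order, 25 Hz)
    is applied before differencing; pass ``lowpass_hz=None`` to disable.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or len(y) < 3:
        raise ValueError("series must be 1-D with at least 3 samples")
    if lowpass_hz is not None and lowpass_hz < fps / 2:
        padlen = 3 * order
        if len(y) > padlen * 3:
            b, a = butter(order, lowpass_hz / (fps / 2))
            y = filtfilt(b, a, y)
    return np.gradient(y) * fps


# ---------------------------------------------------------------------------
# convenience: full angle table from a reconstructed trajectory

def compute_angle_table(positions: dict, fps: float,
                        *, left_reference: bool = True) -> pd.DataFrame:
    """All angular variables from a landmark-trajectory dict (name -> (T, 3)).

    Produces the same long-format table as the simulator's ground truth:
    columns frame, time, variable, side, value_deg.
    """
    T = len(next(iter(positions.values())))
    t = np.arange(T) / fps
    frames = np.arange(T)
    pel = pelvis_frame(positions["p_c"], positions["h_r"], positions["h_l"])
    pg = pelvis_global_angles(pel)
    rows = []

    def add(variable, side, values):
        rows.append(pd.DataFrame({
            "frame": frames, "time": t, "variable": variable, "side": side,
            "value_deg": np.asarray(values)}))

    add("pelvis_pitch", "", pg.beta)
    add("pelvis_roll", "", pg.alpha)
    add("pelvis_yaw", "", pg.gamma)
    for s in ("l", "r"):
        leg = whole_leg_frame(positions[f"h_{s}"], positions[f"k_{s}"],
                              positions[f"tmp_dist_{s}"], s)
        hip = hip_angles(pel, leg, s, left_reference=left_reference)
        add("hip_flexion", s, hip.flexion_extension)
        add("hip_mediolateral", s, hip.alpha)
        add("hip_abduction", s, hip.gamma)
        add("knee", s, joint_angle(positions[f"h_{s}"], positions[f"k_{s}"],
                                   positions[f"int_prox_{s}"]))
        add("int", s, joint_angle(positions[f"k_{s}"], positions[f"int_prox_{s}"],
                                  positions[f"tmp_dist_{s}"]))
        add("tmp", s, joint_angle(positions[f"int_prox_{s}"],
                                  positions[f"tmp_dist_{s}"],
                                  positions[f"mto_{s}"]))
        length, alpha = effective_leg(positions[f"h_{s}"], positions[f"mto_{s}"])
        add("eff_leg_length", s, length)
        add("eff_leg_angle", s, alpha)
    add("aperture", "", aperture_angle(
        positions["h_l"], positions["mto_l"],
        positions["h_r"], positions["mto_r"]))
    return pd.concat(rows, ignore_index=True)
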