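"""Forward-kinematic gait simulator for the bilateral quail hindlimb.

Builds full 3D landmark trajectories for one trial of a gait condition:
the pelvis advances at the template speed while its orientation follows the
pelvis harmonics; each whole-leg frame is rotated against the pelvis by the
template's Cardan z-x-y hip angles; the planar knee-INT-TMP chain is posed
inside the leg plane from the included joint angles. Pelvis height is
solved frame-by-frame so that the stance toe tracks the terrain (with both
legs reconciled by a smooth stance weighting during double support), which
makes touchdown/toe-off detectable from the toe trajectory alone.

Global frame: x cranial (direction of travel), y toward the animal's left,
z vertical up. All ground truth (angle tables, events, terrain) is retained
for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gait import GaitTemplate, PELVIS_VARIABLES, SPLINE_VARIABLES
from .geometry import compose_zxy
from .skeleton import SkeletonModel
from .strides import StrideEvents

LEGS = ("l", "r")
#: stride-phase offset of each leg (left is the reference/trailing leg)
LEG_OFFSET = {"l": 0.0, "r": 0.5}

@dataclass
class Trial:
    """One simulated trial: landmark trajectories plus retained ground truth."""

    skeleton: SkeletonModel
    template: GaitTemplate
    fps: float
    seed: int
    time: np.ndarray                       # (T,)
    landmarks: dict                        # name -> (T, 3) meters
    pelvis_origin: np.ndarray              # (T, 3)
    pelvis_basis: np.ndarray               # (T, 3, 3), columns e_x, e_y, e_z
    leg_basis: dict                        # side -> (T, 3, 3)
    angles: pd.DataFrame                   # frame, time, variable, side, value_deg
    events: StrideEvents
    ground: dict = field(default_factory=dict)   # side -> (T,) terrain height

    @property
    def n_frames(self) -> int:
        return len(self.time)

    def landmark_array(self, names=None) -> np.ndarray:
        names = list(names) if names is not None else list(self.landmarks)
        return np.stack([self.landmarks[n] for n in names], axis=1)

    def angle_series(self, variable: str, side: str = "") -> np.ndarray:
        df = self.angles
        sel = df[(df.variable == variable) & (df.side == side)]
        return sel.sort_values("frame").value_deg.to_numpy()


def _polar_xz(theta_deg: np.ndarray, radius: float) -> np.ndarray:
    """Vector of length ``radius`` at ``theta_deg`` from +x in the x-z plane."""
    r = np.deg2rad(theta_deg)
    return radius * np.stack(
        [np.cos(r), np.zeros_like(r), np.sin(r)], axis=-1)


def leg_chain_local(skel: SkeletonModel, knee_deg, int_deg, tmp_deg) -> dict:
    """Pose the planar leg chain in leg-frame coordinates (hip at origin).

    The chain lives in the leg frame's x-z plane (x cranial, z proximal
    along the femur); segment directions are tracked as absolute planar
    angles so each included joint angle is honoured exactly: flexion
    decreases the included angle, and the physiological zig-zag (knee
    cranial, INT caudal, TMP cranial) fixes the branch choices.
    """
    knee_deg = np.asarray(knee_deg, dtype=float)
    th_tib = 90.0 + knee_deg                      # tibiotarsus, down-caudal
    th_tmt = th_tib + 180.0 - np.asarray(int_deg, float)   # tarsometatarsus
    th_toe = th_tmt + 180.0 - np.asarray(tmp_deg, float)   # toe, down-cranial
    knee = np.zeros(knee_deg.shape + (3,))
    knee[..., 2] = -skel.femur
    ankle = knee + _polar_xz(th_tib, skel.tibiotarsus)
    tmt_dir = _polar_xz(th_tmt, 1.0)
    tmp_dist = ankle + skel.tarsometatarsus * tmt_dir
    mto = tmp_dist + _polar_xz(th_toe, skel.toe)
    return {
        "h": np.zeros_like(knee),
        "k": knee,
        "int_prox": ankle,
        "int_dist": ankle + skel.int_dist_offset * tmt_dir,
        "tmt_prox": ankle + skel.tmt_prox_offset * tmt_dir,
        "tmp_dist": tmp_dist,
        "mto": mto,
        "fem_mid": 0.5 * knee,
        "toe_mid": 0.5 * (tmp_dist + mto),
    }


def _pelvis_local(skel: SkeletonModel) -> dict:
    """Pelvis landmark coordinates with the origin at the hip/p_c centroid."""
    o = skel.pelvis_cranial_offset / 3.0
    w = skel.pelvis_half_width
    return {
        "p_c": np.array([skel.pelvis_cranial_offset - o, 0.0, 0.0]),
        "h_l": np.array([-o, w, 0.0]),
        "h_r": np.array([-o, -w, 0.0]),
        "p_caud": np.array([-skel.pelvis_caudal_offset, 0.0, 0.008]),
        "p_left": np.array([0.0, w + 0.005, 0.008]),
        "p_right": np.array([0.0, -w - 0.005, 0.008]),
    }


def _smoothstep(s: np.ndarray) -> np.ndarray:
    # quintic smootherstep: C2, so the blended pelvis height stays free of
    # curvature kinks (which would leak into high stride harmonics of every
    # landmark signal)
    s = np.clip(s, 0.0, 1.0)
    return s * s * s * (10.0 + s * (-15.0 + 6.0 * s))


def _toe_height_profile(phase: np.ndarray, stance_fraction: float,
                        apex: float) -> np.ndarray:
    """Target toe height over the stride: a band-limited swing bump.

    Product of four antiperiodic sine factors squared — a degree-4
    trigonometric polynomial with double zeros at TO (= stance fraction),
    TD (phase 1) and two interior stance phases. The toe therefore lands
    and lifts on quadratic flanks exactly at the nominal events, stays
    within a fraction of the apex during stance, and contributes no
    stride harmonic above 4 to any landmark signal.
    """
    zeros = (0.32 * stance_fraction, 0.72 * stance_fraction,
             stance_fraction, 1.0)

    def raw(p):
        out = np.ones_like(p)
        for z in zeros:
            out = out * np.sin(np.pi * (p - z))
        return out ** 2

    dense = np.linspace(stance_fraction, 1.0, 200)
    return raw(np.asarray(phase)) * (apex / raw(dense).max())


#: swing toe-clearance apex of the bump profile (m)
SWING_CLEARANCE = 0.009

#: modulation depth of the single-harmonic stance weight used to blend the
#: two legs' pelvis-height demands
STANCE_WEIGHT_DEPTH = 0.97


def simulate_trial(
    skeleton: SkeletonModel,
    template: GaitTemplate,
    fps: float = 500.0,
    n_strides: int = 2,
    seed: int = 0,
    duration: float | None = None,
    shift_stride: int | None = None,
) -> Trial:
    """Simulate a trial of ``n_strides`` strides sampled at ``fps``.

    For step conditions the terrain shift falls between stride
    ``shift_stride - 1`` and ``shift_stride`` (default: the middle stride):
    the leading (right) leg is the first to contact the shifted plate.
    Identical inputs produce bit-identical output.
    """
    if fps <= 0:
        raise ValueError("fps must be > 0")
    if n_strides < 1:
        raise ValueError("n_strides must be >= 1")
    if skeleton.max_reach < 0.15:
        raise ValueError("skeleton reach is too short for the gait template")
    T = template.stride_duration
    total = duration if duration is not None else n_strides * T
    n = int(round(total * fps))
    t = np.arange(n) / fps
    sf = template.stance_fraction("trailing")
    if shift_stride is None:
        shift_stride = max(1, n_strides // 2)
    step = template.step_height
    t_shift = (shift_stride - 0.5) * T   # leading-leg TD on the shifted plate

    # -- per-leg phase and template evaluation ------------------------------
    phase = {s: (t / T + LEG_OFFSET[s]) % 1.0 for s in LEGS}
    ang = {s: {v: np.asarray(template.evaluate(v, phase[s]))
               for v in SPLINE_VARIABLES} for s in LEGS}
    pel = {v: np.asarray(template.evaluate(v, phase["l"]))
           for v in PELVIS_VARIABLES}

    # -- pelvis orientation and leg frames ----------------------------------
    R_p = compose_zxy(pel["pelvis_yaw"], pel["pelvis_roll"], pel["pelvis_pitch"])
    sign = {"l": 1.0, "r": -1.0}
    R_leg = {}
    for s in LEGS:
        beta = ang[s]["hip_flexion"] - 90.0
        R_leg[s] = R_p @ compose_zxy(sign[s] * ang[s]["hip_abduction"],
                                     sign[s] * ang[s]["hip_mediolateral"],
                                     beta)

    # -- chain positions relative to the pelvis origin ----------------------
    pel_local = _pelvis_local(skeleton)
    rel = {name: np.einsum("tij,j->ti", R_p, loc)
           for name, loc in pel_local.items()}
    for s in LEGS:
        local = leg_chain_local(
            skeleton, ang[s]["knee"], ang[s]["int"], ang[s]["tmp"])
        hip = rel[f"h_{s}"]
        for name, loc in local.items():
            if name == "h":
                continue
            rel[f"{name}_{s}"] = hip + np.einsum("tij,tj->ti", R_leg[s], loc)

    # -- terrain and pelvis height ------------------------------------------
    # each leg demands pelvis_z = ground + bump - (toe height rel. pelvis);
    # the pelvis blends the two demands with a single-harmonic stance
    # weight (the pair sums to exactly 2), which suppresses the swing
    # leg's pull mid-stance while keeping the pelvis height band-limited.
    # The leg demands agree near the touchdown/toe-off events by
    # calibration, so each stance toe tracks its terrain to a fraction of
    # a millimetre.
    ground = {}
    z_req = {}
    weight = {}
    for s in LEGS:
        tau = t / T + LEG_OFFSET[s]
        k = np.floor(tau).astype(int)
        td_time = (k - LEG_OFFSET[s]) * T   # TD of contact k in global time
        g_now = np.where(td_time >= t_shift - 1e-9, step, 0.0) if step else np.zeros(n)
        g_next = (np.where(td_time + T >= t_shift - 1e-9, step, 0.0)
                  if step else np.zeros(n))
        ph = tau % 1.0
        swing = ph >= sf
        sprog = np.where(swing, (ph - sf) / (1.0 - sf), 0.0)
        g = np.where(swing, g_now + (g_next - g_now) * _smoothstep(sprog), g_now)
        c = _toe_height_profile(ph, sf, SWING_CLEARANCE)
        ground[s] = g
        z_req[s] = g + c - rel[f"mto_{s}"][:, 2]
        weight[s] = 1.0 + STANCE_WEIGHT_DEPTH * np.cos(
            2 * np.pi * (ph - 0.5 * sf))
    pelvis_z = (weight["l"] * z_req["l"] + weight["r"] * z_req["r"]) / (
        weight["l"] + weight["r"])

    origin = np.stack([template.speed * t, np.zeros(n), pelvis_z], axis=-1)
    landmarks = {name: origin + xyz for name, xyz in rel.items()}

    # -- ground-truth angle table -------------------------------------------
    rows = []
    frames = np.arange(n)
    for s in LEGS:
        for v in SPLINE_VARIABLES:
            rows.append(pd.DataFrame({
                "frame": frames, "time": t, "variable": v, "side": s,
                "value_deg": ang[s][v]}))
    for v in PELVIS_VARIABLES:
        rows.append(pd.DataFrame({
            "frame": frames, "time": t, "variable": v, "side": "",
            "value_deg": pel[v]}))
    eff = {}
    for s in LEGS:
        vec = landmarks[f"mto_{s}"] - landmarks[f"h_{s}"]
        length = np.linalg.norm(vec, axis=-1)
        alpha = np.rad2deg(np.arctan2(-vec[:, 2], vec[:, 0]))
        eff[s] = vec
        rows.append(pd.DataFrame({
            "frame": frames, "time": t, "variable": "eff_leg_length",
            "side": s, "value_deg": length}))
        rows.append(pd.DataFrame({
            "frame": frames, "time": t, "variable": "eff_leg_angle",
            "side": s, "value_deg": alpha}))
    cosphi = np.sum(eff["l"] * eff["r"], axis=-1) / (
        np.linalg.norm(eff["l"], axis=-1) * np.linalg.norm(eff["r"], axis=-1))
    rows.append(pd.DataFrame({
        "frame": frames, "time": t, "variable": "aperture", "side": "",
        "value_deg": np.rad2deg(np.arccos(np.clip(cosphi, -1, 1)))}))
    angles = pd.concat(rows, ignore_index=True)

    # -- ground-truth events -------------------------------------------------
    tds, tos = {}, {}
    for s in LEGS:
        k0 = 0 if s == "l" else -1   # right leg's cycle -1 TD is before t=0
        leg_tds, leg_tos = [], []
        for k in range(k0, n_strides + 2):
            td_t = (k + (0.5 if s == "r" else 0.0)) * T
            to_t = td_t + sf * T
            fi_td = int(round(td_t * fps))
            fi_to = int(round(to_t * fps))
            if 0 <= fi_td < n:
                leg_tds.append(fi_td)
            if 0 <= fi_to < n:
                leg_tos.append(fi_to)
        tds[s], tos[s] = leg_tds, leg_tos
    events = StrideEvents(
        touchdowns=tds, toeoffs=tos,
        terrain_shift_frame=int(round(t_shift * fps)) if step else None,
        roles={"l": "trailing", "r": "leading"} if step else None)

    return Trial(skeleton=skeleton, template=template, fps=fps, seed=seed,
                 time=t, landmarks=landmarks, pelvis_origin=origin,
                 pelvis_basis=R_p, leg_basis=R_leg, angles=angles,
                 events=events, ground=ground)
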