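"""Per-condition gait templates: spatiotemporal parameters and angle controls.

A :class:`GaitTemplate` holds, for one experimental condition (level walking
or a vertical step of 1/2.5/5 cm up or down), the forward speed, contact and
swing durations per leg role, and the angular trajectory controls:

* six leg/joint variables (hip flexion-extension in the beta+90 reporting
  convention, whole-leg mediolateral rotation alpha, ab-adduction gamma,
  and the knee, INT and TMP included angles) as control points at the five
  stride phases TD, 15%, mid-stride, TO and 85%, interpolated by a periodic
  (level) or clamped (step) cubic spline;
* three pelvis orientation variables (pitch, roll, yaw against the global
  frame) as mean + cosine harmonics, because pelvic pitch oscillates at
  twice the step frequency (4 cycles per stride) which a 5-point spline
  cannot represent.

Values at the printed stride events come from the study's level and step
condition results; mid-stride and swing values, which are not printed, were
calibrated once so that the emergent effective-leg variables (length, angle
of attack, aperture angle) reproduce the printed level values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

CONDITIONS = (
    "level",
    "up_1cm", "up_2.5cm", "up_5cm",
    "down_1cm", "down_2.5cm", "down_5cm",
)

SPLINE_VARIABLES = (
    "hip_flexion", "hip_mediolateral", "hip_abduction", "knee", "int", "tmp")
PELVIS_VARIABLES = ("pelvis_pitch", "pelvis_roll", "pelvis_yaw")

ROLES = ("trailing", "leading")


class _TrigInterpolant:
    """Periodic trigonometric interpolant through points on [0, 1)."""

    def __init__(self, x: np.ndarray, y: np.ndarray):
        if len(x) % 2 == 0:
            raise ValueError("trig interpolation needs an odd point count")
        self.degree = (len(x) - 1) // 2
        M = self._design(np.asarray(x, float))
        self.coef = np.linalg.solve(M, np.asarray(y, float))

    def _design(self, x: np.ndarray) -> np.ndarray:
        cols = [np.ones_like(x)]
        for k in range(1, self.degree + 1):
            cols.append(np.cos(2 * np.pi * k * x))
            cols.append(np.sin(2 * np.pi * k * x))
        return np.stack(cols, axis=-1)

    def __call__(self, x) -> np.ndarray:
        return self._design(np.asarray(x, dtype=float)) @ self.coef

# ---------------------------------------------------------------------------
# Spatiotemporal parameters (seconds, m/s) per condition.
_SPEED = {
    "level": 0.65,
    "up_1cm": 0.55, "up_2.5cm": 0.56, "up_5cm": 0.86,
    "down_1cm": 0.51, "down_2.5cm": 0.44, "down_5cm": 0.6,
}
_CONTACT = {
    "level": {"trailing": 0.23, "leading": 0.22},
    "up_1cm": {"trailing": 0.24, "leading": 0.24},
    "up_2.5cm": {"trailing": 0.30, "leading": 0.33},
    "up_5cm": {"trailing": 0.22, "leading": 0.28},
    "down_1cm": {"trailing": 0.22, "leading": 0.17},
    "down_2.5cm": {"trailing": 0.29, "leading": 0.21},
    "down_5cm": {"trailing": 0.33, "leading": 0.21},
}
_SWING = {
    "level": {"trailing": 0.14, "leading": 0.17},
    "up_1cm": {"trailing": 0.17, "leading": 0.22},
    "up_2.5cm": {"trailing": 0.23, "leading": 0.17},
    "up_5cm": {"trailing": 0.20, "leading": 0.17},
    "down_1cm": {"trailing": 0.19, "leading": 0.17},
    "down_2.5cm": {"trailing": 0.14, "leading": 0.20},
    "down_5cm": {"trailing": 0.14, "leading": 0.20},
}
_STEP_HEIGHT = {
    "level": 0.0,
    "up_1cm": 0.01, "up_2.5cm": 0.025, "up_5cm": 0.05,
    "down_1cm": -0.01, "down_2.5cm": -0.025, "down_5cm": -0.05,
}

# ---------------------------------------------------------------------------
# Angle control values (degrees) at the named stride events.
# Event semantics follow the study's analysis windows: "td" and "e85" carry
# the leading-limb values, "e15" and "to" the trailing-limb values, so one
# table serves both roles of a step trial. "mid" values are calibrated or
# interpolated (not printed).
_EVENTS = ("td", "e15", "mid", "to", "e85")

_LEVEL_CONTROLS = {
    # TD 42, post-TD minimum 41 at 15%, +17 deg extension to TO; mid/swing
    # values calibrated (see module docstring)
    "hip_flexion": {"td": 42.0, "e15": 41.0, "mid": 54.09, "to": 58.0, "e85": 46.5},
    # medial at TD (-14), lateral at TO (+11)
    "hip_mediolateral": {"td": -14.0, "e15": -6.0, "mid": -1.33, "to": 11.0, "e85": 7.58},
    # abducted 36 at TD, reduced to 18 at TO
    "hip_abduction": {"td": 36.0, "e15": 29.0, "mid": 18.9, "to": 18.0, "e85": 26.37},
    "knee": {"td": 120.0, "e15": 98.0, "mid": 56.97, "to": 60.0, "e85": 100.4},
    "int": {"td": 125.0, "e15": 112.0, "mid": 112.46, "to": 112.0, "e85": 109.06},
    "tmp": {"td": 158.0, "e15": 143.0, "mid": 145.45, "to": 142.0, "e85": 156.2},
}

# Step-condition event values from the printed results; unprinted entries
# carry the level value (or the average of the printed neighbours for "mid").
_STEP_CONTROLS = {
    "up_1cm": {
        "hip_flexion": {"td": 37, "e15": 46, "to": 58, "e85": 62},
        "hip_mediolateral": {"td": -7, "e15": -4, "to": 5, "e85": 5},
        "hip_abduction": {"td": 25, "e15": 27, "to": 22, "e85": 25},
        "knee": {"td": 106, "e15": 85, "to": 64, "e85": 112},
        "int": {"td": 112, "e15": 99, "to": 81, "e85": 120},
        "tmp": {"td": 158, "e15": 143, "to": 142, "e85": 150},
    },
    "up_2.5cm": {
        "hip_flexion": {"td": 42, "e15": 49, "to": 58, "e85": 68},
        "hip_mediolateral": {"td": -8, "e15": -2, "to": 5, "e85": 5},
        "hip_abduction": {"td": 30, "e15": 21, "to": 14, "e85": 28},
        "knee": {"td": 112, "e15": 91, "to": 73, "e85": 112},
        "int": {"td": 114, "e15": 112, "to": 112, "e85": 120},
        "tmp": {"td": 158, "e15": 135, "to": 142, "e85": 150},
    },
    "up_5cm": {
        "hip_flexion": {"td": 38, "e15": 62, "to": 58, "e85": 66},
        "hip_mediolateral": {"td": -9, "e15": 6, "to": 9, "e85": 3},
        "hip_abduction": {"td": 25, "e15": 20, "to": 10, "e85": 22},
        "knee": {"td": 110, "e15": 113, "to": 103, "e85": 112},
        "int": {"td": 121, "e15": 139, "to": 143, "e85": 120},
        "tmp": {"td": 158, "e15": 135, "to": 142, "e85": 150},
    },
    "down_1cm": {
        "hip_flexion": {"td": 44, "e15": 41, "to": 58, "e85": 56},
        "hip_mediolateral": {"td": -15, "e15": -6, "to": 11, "e85": 8},
        "hip_abduction": {"td": 23, "e15": 16, "to": 14, "e85": 30},
        "knee": {"td": 120, "e15": 98, "to": 60, "e85": 112},
        "int": {"td": 125, "e15": 112, "to": 112, "e85": 120},
        "tmp": {"td": 158, "e15": 143, "to": 142, "e85": 150},
    },
    "down_2.5cm": {
        "hip_flexion": {"td": 52, "e15": 41, "to": 58, "e85": 56},
        "hip_mediolateral": {"td": 3, "e15": -6, "to": 11, "e85": 8},
        "hip_abduction": {"td": 34, "e15": 28, "to": 17, "e85": 30},
        "knee": {"td": 128, "e15": 98, "to": 60, "e85": 112},
        "int": {"td": 146, "e15": 112, "to": 112, "e85": 120},
        "tmp": {"td": 133, "e15": 143, "to": 142, "e85": 150},
    },
    "down_5cm": {
        "hip_flexion": {"td": 47, "e15": 36, "to": 52, "e85": 56},
        "hip_mediolateral": {"td": -1, "e15": -11, "to": 11, "e85": 8},
        "hip_abduction": {"td": 34, "e15": 34, "to": 16, "e85": 30},
        "knee": {"td": 131, "e15": 90, "to": 48, "e85": 112},
        "int": {"td": 148, "e15": 76, "to": 81, "e85": 120},
        "tmp": {"td": 134, "e15": 143, "to": 142, "e85": 150},
    },
}

# Pelvis harmonics: (mean, amplitude, cycles per stride, phase offset deg).
# Pitch mean -10 deg = the ~10 deg retroversion of level locomotion; pitch
# runs at twice the step frequency. Roll/yaw amplitudes are small, one
# left/right alternation per stride.
_LEVEL_PELVIS = {
    "pelvis_pitch": (-10.0, 1.5, 4, 0.0),
    "pelvis_roll": (0.0, 13.85, 1, 41.09),
    "pelvis_yaw": (0.0, 0.5, 1, 180.0),
}
_STEP_PELVIS_PITCH_MEAN = {
    "up_1cm": -18.0, "up_2.5cm": -22.0, "up_5cm": -28.0,
    "down_1cm": -12.0, "down_2.5cm": -20.0, "down_5cm": -7.0,
}


@dataclass(frozen=True)
class GaitTemplate:
    """Parameterized joint/pelvis trajectory controls for one condition."""

    condition: str
    speed: float
    contact_time: dict
    swing_time: dict
    step_height: float
    control_points: dict          # var -> {phase: value_deg}
    pelvis_harmonics: dict        # var -> (mean, amp, cycles, phase0_deg)
    periodic: bool = True
    _splines: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValueError("speeds and times must be > 0")
        for d in (self.contact_time, self.swing_time):
            for role in ROLES:
                if d.get(role, 0.0) <= 0:
                    raise ValueError("speeds and times must be > 0")
        for var, pts in self.control_points.items():
            phases = np.array(sorted(pts))
            if phases[0] < 0 or phases[-1] >= 1 or np.any(np.diff(phases) <= 0):
                raise ValueError(
                    f"{var}: control phases must be strictly increasing in [0, 1)")

    # -- timing ------------------------------------------------------------
    @property
    def stride_duration(self) -> float:
        """Stride period (s); the trailing/reference leg defines it."""
        return self.contact_time["trailing"] + self.swing_time["trailing"]

    def stance_fraction(self, role: str = "trailing") -> float:
        return self.contact_time[role] / (
            self.contact_time[role] + self.swing_time[role])

    # -- trajectory evaluation ----------------------------------------------
    def _spline(self, var: str):
        if var not in self._splines:
            pts = self.control_points[var]
            x = np.array(sorted(pts))
            y = np.array([pts[p] for p in x])
            if self.periodic:
                # trigonometric interpolation: with n control points the
                # unique trig polynomial of degree (n-1)/2 through them.
                # Band-limited by construction, so the harmonic content of
                # every angle trajectory is controlled explicitly (a cubic
                # spline through the same points leaks energy into high
                # stride harmonics at its knots).
                self._splines[var] = _TrigInterpolant(x, y)
            else:
                self._splines[var] = CubicSpline(x, y, bc_type="clamped")
        return self._splines[var]

    def evaluate(self, var: str, phase) -> np.ndarray:
        """Angle value(s) in degrees at stride phase(s) in [0, 1)."""
        phase = np.asarray(phase, dtype=float) % 1.0
        if var in self.pelvis_harmonics:
            mean, amp, cycles, phase0 = self.pelvis_harmonics[var]
            return mean + amp * np.cos(
                2 * np.pi * cycles * phase + np.deg2rad(phase0))
        if var not in self.control_points:
            raise KeyError(f"unknown angular variable {var!r}")
        return self._spline(var)(phase)

    @property
    def variables(self) -> tuple:
        return tuple(self.control_points) + tuple(self.pelvis_harmonics)

    def to_json(self) -> str:
        return json.dumps({
            "condition": self.condition,
            "speed": self.speed,
            "contact_time": self.contact_time,
            "swing_time": self.swing_time,
            "step_height": self.step_height,
            "control_points": {
                v: {str(p): val for p, val in pts.items()}
                for v, pts in self.control_points.items()},
            "pelvis_harmonics": {
                v: list(h) for v, h in self.pelvis_harmonics.items()},
            "periodic": self.periodic,
        }, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GaitTemplate":
        d = json.loads(text)
        d["control_points"] = {
            v: {float(p): val for p, val in pts.items()}
            for v, pts in d["control_points"].items()}
        d["pelvis_harmonics"] = {
            v: tuple(h) for v, h in d["pelvis_harmonics"].items()}
        return cls(**d)


def _event_phases(contact: float, swing: float) -> dict:
    to_phase = contact / (contact + swing)
    return {"td": 0.0, "e15": 0.15, "mid": 0.5, "to": to_phase, "e85": 0.85}


def make_gait_template(condition: str, **overrides) -> GaitTemplate:
    """Build the template for one of the seven study conditions.

    Keyword overrides replace top-level fields; ``control_points`` overrides
    are merged per variable.
    """
    if condition not in CONDITIONS:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    contact = dict(_CONTACT[condition])
    swing = dict(_SWING[condition])
    phases = _event_phases(contact["trailing"], swing["trailing"])

    if condition == "level":
        raw = {v: dict(d) for v, d in _LEVEL_CONTROLS.items()}
    else:
        raw = {}
        for var in SPLINE_VARIABLES:
            base = dict(_LEVEL_CONTROLS[var])
            base.update(_STEP_CONTROLS[condition][var])
            if "mid" not in _STEP_CONTROLS[condition][var]:
                base["mid"] = 0.5 * (base["e15"] + base["to"])
            raw[var] = base
    control_points = {
        var: {phases[ev]: float(val) for ev, val in pts.items()}
        for var, pts in raw.items()}

    pelvis = dict(_LEVEL_PELVIS)
    if condition != "level":
        mean = _STEP_PELVIS_PITCH_MEAN[condition]
        pelvis["pelvis_pitch"] = (mean,) + _LEVEL_PELVIS["pelvis_pitch"][1:]

    fields = {
        "condition": condition,
        "speed": _SPEED[condition],
        "contact_time": contact,
        "swing_time": swing,
        "step_height": _STEP_HEIGHT[condition],
        "control_points": control_points,
        "pelvis_harmonics": pelvis,
        "periodic": condition == "level",
    }
    cp_override = overrides.pop("control_points", None)
    fields.update(overrides)
    if cp_override:
        merged = {v: dict(d) for v, d in fields["control_points"].items()}
        for var, pts in cp_override.items():
            merged.setdefault(var, {}).update(pts)
        fields["control_points"] = merged
    return GaitTemplate(**fields)
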