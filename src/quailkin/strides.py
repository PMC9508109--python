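"""Stride segmentation, 100-point normalization, mirroring and event windows.

Stride definitions follow the study: for a level trial a stride runs from
one touchdown (TD) of a leg to its next TD; for a step trial the trailing
limb's stride runs from its TD on the level plate to its TD on the shifted
plate, and the leading limb's from its toe-off (TO) on the level plate to
its TO on the shifted plate. Normalized strides carry exactly 100 samples;
phase indexing is 0-based over [0, 99] so the "15%" analysis event is index
15. Event windows are the event sample plus the four preceding and four
following samples (event +/- 4% of the stride), truncated with a flag at
curve boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

N_PHASE = 100

#: variables that flip sign when a right-side trial is mirrored to the
#: left-reference convention (x- and z-rotations)
MIRROR_NEGATE = (
    "hip_mediolateral", "hip_abduction", "pelvis_roll", "pelvis_yaw")


@dataclass
class StrideEvents:
    """Touchdown/toe-off frame indices per leg plus step-trial bookkeeping."""

    touchdowns: dict                  # leg name -> sorted list of frames
    toeoffs: dict                     # leg name -> sorted list of frames
    terrain_shift_frame: int | None = None
    roles: dict | None = None         # leg name -> "trailing" | "leading"

    def __post_init__(self) -> None:
        for leg in self.touchdowns:
            tds = list(self.touchdowns[leg])
            tos = list(self.toeoffs.get(leg, []))
            if sorted(tds) != tds or sorted(tos) != tos:
                raise ValueError("event frames must be sorted")
            for td in tds:
                later = [t for t in tos if t > td]
                nxt_td = [t for t in tds if t > td]
                if later and nxt_td and later[0] > nxt_td[0]:
                    raise ValueError(
                        f"leg {leg!r}: TD/TO events do not alternate")
        if self.roles is not None:
            if sorted(self.roles.values()) != ["leading", "trailing"]:
                raise ValueError("roles must assign one trailing and one leading leg")

    @property
    def legs(self) -> tuple:
        return tuple(self.touchdowns)


@dataclass
class NormalizedStride:
    """100-sample curve of one variable over one stride."""

    variable: str
    side: str                          # "l" | "r" | "" (pelvis/aperture)
    role: str                          # "trailing" | "leading" | "level"
    values: np.ndarray                 # (100,), NaN where missing
    event_phases: dict                 # e.g. {"td": 0.0, "to": 62.2} in [0, 100]
    condition: str = ""
    individual: str = ""
    mirrored: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_PHASE,):
            raise ValueError(f"normalized strides carry exactly {N_PHASE} samples")
        for name, ph in self.event_phases.items():
            if not 0.0 <= ph <= 100.0:
                raise ValueError(f"event {name!r} phase {ph} outside [0, 100]")


@dataclass
class EventWindowSample:
    """Event +/- 4 samples of one normalized stride."""

    variable: str
    event: str                         # "td" | "e15" | "to" | "e85"
    values: np.ndarray                 # length 9 away from boundaries
    individual: str = ""
    condition: str = ""
    truncated: bool = False


# ---------------------------------------------------------------------------
# event detection

def detect_events(
    toe_xyz: np.ndarray,
    fps: float,
    *,
    body_speed: float,
    ground: np.ndarray | float = 0.0,
    height_threshold: float = 0.0008,
    speed_fraction: float | None = None,
    hysteresis: int = 5,
    events: "StrideEvents | None" = None,
    leg: str = "leg",
) -> dict:
    """Detect TD/TO frames of one leg from its toe trajectory.

    Contact is entered when the toe drops below ``ground + height_threshold``
    and left when it rises above three times that level, with ``hysteresis``
    frames of debouncing. If ``speed_fraction`` is given, entering contact
    additionally requires the toe's forward speed to be below
    ``speed_fraction * body_speed`` (off by default: prescribed-angle
    kinematics leave a residual stance skate). Each boundary is refined by
    linearly extrapolating the local toe-height slope to the ground
    crossing and rounding to the nearest frame. If an ``events`` table is
    provided it is returned unchanged (manual/digitized events take
    precedence).
    """
    if events is not None:
        return {"touchdowns": list(events.touchdowns[leg]),
                "toeoffs": list(events.toeoffs[leg])}
    toe_xyz = np.asarray(toe_xyz, dtype=float)
    z = toe_xyz[:, 2] - np.asarray(ground, dtype=float)
    if speed_fraction is not None:
        vx = np.gradient(toe_xyz[:, 0]) * fps
        slow = np.abs(vx) < speed_fraction * abs(body_speed)
    else:
        slow = np.ones(len(z), dtype=bool)
    # two-level hysteresis: enter contact below the threshold (while slow),
    # leave it only above 3x the threshold
    enter = (z < height_threshold) & slow
    leave = z > 3.0 * height_threshold
    contact = np.zeros(len(z), dtype=bool)
    state = bool(enter[0])
    for i in range(len(z)):
        if state and leave[i]:
            state = False
        elif not state and enter[i]:
            state = True
        contact[i] = state
    # debounce: drop contact/flight runs shorter than the hysteresis
    contact = _debounce(contact, hysteresis)
    if not contact.any():
        raise ValueError("no contacts found in toe trajectory")

    tds, tos = [], []
    prev = contact[0]
    for i in range(1, len(contact)):
        if contact[i] and not prev:
            tds.append(_refine_crossing(z, i, fps, falling=True))
        elif prev and not contact[i]:
            # walk back to the low-threshold crossing on the rising flank
            # (the exit index sits at the higher hysteresis level)
            j = i
            while j > 1 and z[j - 1] > height_threshold:
                j -= 1
            tos.append(_refine_crossing(z, j, fps, falling=False))
        prev = contact[i]
    n = len(z)
    tds = sorted({int(np.clip(t, 0, n - 1)) for t in tds})
    tos = sorted({int(np.clip(t, 0, n - 1)) for t in tos})
    return {"touchdowns": tds, "toeoffs": tos}


def _debounce(mask: np.ndarray, min_run: int) -> np.ndarray:
    out = mask.copy()
    edges = np.flatnonzero(np.diff(out.astype(int))) + 1
    bounds = np.concatenate([[0], edges, [len(out)]])
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < min_run and a > 0 and b < len(out):
            out[a:b] = out[a - 1]
    return out


def _refine_crossing(z: np.ndarray, idx: int, fps: float, falling: bool) -> int:
    """Locate the ground touch from the flank around a threshold crossing.

    The toe approaches/leaves the ground with a quadratic flank (it lands
    decelerating), so a parabola is fitted to the local flank and its root
    (or vertex, if it does not quite reach zero) is taken as the event.
    """
    lo = max(0, idx - 4)
    hi = min(len(z), idx + 5)
    t = np.arange(lo, hi, dtype=float)
    seg = z[lo:hi]
    if len(seg) < 3 or np.ptp(seg) < 1e-12:
        return idx
    a, b, c = np.polyfit(t, seg, 2)
    disc = b * b - 4 * a * c
    if abs(a) < 1e-15:
        if abs(b) < 1e-15:
            return idx
        roots = [-c / b]
    elif disc >= 0:
        roots = [(-b + np.sqrt(disc)) / (2 * a), (-b - np.sqrt(disc)) / (2 * a)]
    else:
        roots = [-b / (2 * a)]   # vertex: flank bottoms out above zero
    best = min(roots, key=lambda r: abs(r - idx))
    if abs(best - idx) > 10:
        return idx
    return int(round(best))


# ---------------------------------------------------------------------------
# segmentation

def segment_strides(events: StrideEvents, role: str, leg: str | None = None) -> list:
    """Stride windows ``(start_frame, end_frame, leg)`` for a leg role.

    ``role="level"``: consecutive same-leg TD->TD windows. ``role=
    "trailing"``: the TD->TD window spanning the terrain shift. ``role=
    "leading"``: the TO->TO window spanning the shift.
    """
    if role == "level":
        legs = [leg] if leg else list(events.legs)
        out = []
        for lg in legs:
            tds = events.touchdowns[lg]
            out.extend((a, b, lg) for a, b in zip(tds[:-1], tds[1:]))
        return out
    if events.terrain_shift_frame is None or events.roles is None:
        raise ValueError(f"role {role!r} requires a step trial with a terrain shift")
    if role not in ("trailing", "leading"):
        raise ValueError(f"unknown leg role {role!r}")
    lg = leg or next(k for k, v in events.roles.items() if v == role)
    shift = events.terrain_shift_frame
    marks = events.touchdowns[lg] if role == "trailing" else events.toeoffs[lg]
    before = [f for f in marks if f <= shift]
    after = [f for f in marks if f > shift]
    if not before or not after:
        raise ValueError(f"cannot bracket the terrain shift with {role} events")
    return [(before[-1], after[0], lg)]


# ---------------------------------------------------------------------------
# normalization

def normalize_stride(
    series: np.ndarray,
    variable: str = "",
    *,
    side: str = "",
    role: str = "level",
    events_in_window: dict | None = None,
    condition: str = "",
    individual: str = "",
) -> NormalizedStride:
    """Linearly interpolate one stride window onto 100 phase points.

    Endpoints are preserved exactly; output points bracketed by a missing
    input sample stay missing. ``events_in_window`` maps event names to
    frame offsets within the window; they are converted to [0, 100] phases.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or len(y) < 2:
        raise ValueError("stride window must be a 1-D series of length >= 2")
    good = np.isfinite(y)
    if not good.any():
        raise ValueError("stride window is entirely missing")
    n = len(y)
    x = np.arange(n, dtype=float) / (n - 1)
    grid = np.linspace(0.0, 1.0, N_PHASE)
    vals = np.interp(grid, x[good], y[good])
    if not good.all():
        # mask out grid points whose bracketing source samples include a gap
        bad_idx = np.flatnonzero(~good)
        for b in bad_idx:
            lo = x[b - 1] if b > 0 else x[b]
            hi = x[b + 1] if b < n - 1 else x[b]
            vals[(grid > lo) & (grid < hi)] = np.nan
        vals[np.isin(grid, x[bad_idx])] = np.nan
    phases = {}
    for name, f in (events_in_window or {}).items():
        phases[name] = 100.0 * float(f) / (n - 1)
    return NormalizedStride(variable=variable, side=side, role=role,
                            values=vals, event_phases=phases,
                            condition=condition, individual=individual)


def mirror_to_left(stride: NormalizedStride, side: str | None = None) -> NormalizedStride:
    """Express a right-side trial in the left-reference convention.

    Negates the x/z rotation variables (hip mediolateral/ab-adduction,
    pelvic roll/yaw) for ``side == "r"``; flexion, joint and effective-leg
    variables are side-symmetric and pass through. Mirroring twice is the
    identity. Applies to curves in the raw per-side convention (i.e. hip
    angles computed with ``left_reference=False``).
    """
    s = side if side is not None else stride.side
    if s not in ("l", "r", ""):
        raise ValueError(f"unknown side {s!r}")
    if s != "r":
        return stride
    vals = stride.values
    if stride.variable in MIRROR_NEGATE:
        vals = -vals
    return replace(stride, values=vals, mirrored=not stride.mirrored)


def aggregate_mean_curves(strides: list) -> pd.DataFrame:
    """Pointwise mean/SD/n per (variable, side, role, condition) group.

    Missing samples are ignored pointwise and the per-point n is reported,
    so sparsely observed phases (e.g. hip landmarks dropping out near the
    stride edges) are visible to the caller.
    """
    if not strides:
        raise ValueError("no strides to aggregate")
    rows = []
    keys = {}
    for st in strides:
        keys.setdefault((st.variable, st.side, st.role, st.condition), []).append(st)
    for (var, side, role, cond), group in keys.items():
        mat = np.vstack([g.values for g in group])
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(mat, axis=0)
            sd = np.nanstd(mat, axis=0, ddof=1) if len(group) > 1 else np.zeros(N_PHASE)
        n = np.isfinite(mat).sum(axis=0)
        sd = np.where(n > 1, sd, 0.0)
        for ph in range(N_PHASE):
            rows.append({"variable": var, "side": side, "role": role,
                         "condition": cond, "phase": ph,
                         "mean": mean[ph], "sd": sd[ph], "n": int(n[ph])})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# event windows

ROLE_EVENTS = {"trailing": ("e15", "to"), "leading": ("td", "e85"),
               "level": ("td", "e15", "to", "e85")}
_FIXED_EVENT_PHASE = {"td": 0.0, "e15": 15.0, "e85": 85.0}


def extract_event_windows(stride: NormalizedStride, half_width: int = 4) -> list:
    """Event +/- ``half_width`` samples for the stride role's analysis events.

    Trailing strides contribute the early-stance (15%) and TO events;
    leading strides TD and late stance (85%); level strides all four.
    Windows are truncated (and flagged) at curve boundaries.
    """
    out = []
    for ev in ROLE_EVENTS[stride.role]:
        if ev in _FIXED_EVENT_PHASE:
            phase = _FIXED_EVENT_PHASE[ev]
        elif ev in stride.event_phases:
            phase = stride.event_phases[ev]
        else:
            continue
        if not 0.0 <= phase <= 100.0:
            raise ValueError(f"event {ev!r} phase {phase} outside [0, 100]")
        center = int(round(phase))
        center = min(center, N_PHASE - 1)
        lo = center - half_width
        hi = center + half_width + 1
        truncated = lo < 0 or hi > N_PHASE
        vals = stride.values[max(lo, 0):min(hi, N_PHASE)]
        out.append(EventWindowSample(
            variable=stride.variable, event=ev, values=vals.copy(),
            individual=stride.individual, condition=stride.condition,
            truncated=truncated))
    return out
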