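"""Articulated quail hindlimb skeleton: landmark catalog and segment lengths.

The model is a bilateral chain pelvis -> hip -> knee -> intertarsal joint
(INT, the avian "ankle") -> tarsometatarsal-phalangeal joint (TMP) -> middle
toe tip (Mto). Twenty-two named landmarks are carried: the 15 kinematically
meaningful points (pelvis cranial marker plus 7 per side) and 7 filler
markers rigidly attached to existing segments, matching the N = 22 landmark
pairs annotated per frame pair in the tracking stage.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

SIDES = ("l", "r")

#: landmarks on each body side, proximal to distal
_SIDE_LANDMARKS = (
    "h",          # hip joint
    "k",          # knee joint
    "int_prox",   # proximal intertarsal marker (distal tibiotarsus)
    "int_dist",   # distal intertarsal marker (proximal tarsometatarsus)
    "tmt_prox",   # proximal tarsometatarsus marker
    "tmp_dist",   # distal tarsometatarsus marker = TMP joint
    "mto",        # tip of the middle toe
)

#: markers rigidly attached to reach the full 22-landmark catalog
_FILLERS = ("p_caud", "p_left", "p_right", "fem_mid_l", "fem_mid_r",
            "toe_mid_l", "toe_mid_r")


def _catalog() -> tuple:
    names = ["p_c"]
    for base in _SIDE_LANDMARKS:
        for side in SIDES:
            names.append(f"{base}_{side}")
    names.extend(_FILLERS)
    return tuple(names)


@dataclass(frozen=True)
class SkeletonModel:
    """Segment lengths (meters) and the landmark catalog of one animal.

    Left and right segment lengths are equal by construction (the fields are
    shared); the symmetry invariant is therefore structural.
    """

    pelvis_half_width: float = 0.015
    pelvis_cranial_offset: float = 0.035
    pelvis_caudal_offset: float = 0.04
    femur: float = 0.032981
    tibiotarsus: float = 0.056539
    tarsometatarsus: float = 0.032981
    toe: float = 0.029840
    #: distance of the distal intertarsal / proximal tarsometatarsus markers
    #: from the INT joint, along the tarsometatarsus
    int_dist_offset: float = 0.008
    tmt_prox_offset: float = 0.015
    landmarks: tuple = field(default=_catalog(), init=False)

    def __post_init__(self) -> None:
        for name in ("pelvis_half_width", "pelvis_cranial_offset",
                     "pelvis_caudal_offset", "femur", "tibiotarsus",
                     "tarsometatarsus", "toe", "int_dist_offset",
                     "tmt_prox_offset"):
            if getattr(self, name) <= 0:
                raise ValueError(f"segment length {name!r} must be > 0")
        if self.tmt_prox_offset >= self.tarsometatarsus:
            raise ValueError("tarsometatarsus markers overrun the segment")
        if len(set(self.landmarks)) != len(self.landmarks):
            raise ValueError("landmark catalog names must be unique")

    @property
    def max_reach(self) -> float:
        """Straight-leg hip-to-Mto distance (m)."""
        return self.femur + self.tibiotarsus + self.tarsometatarsus + self.toe

    def femur_length(self, side: str) -> float:
        if side not in SIDES:
            raise ValueError(f"unknown side {side!r}")
        return self.femur

    @property
    def chain(self) -> tuple:
        """Kinematic chain connectivity per side, hip to toe tip."""
        return tuple(
            tuple(f"{b}_{s}" for b in ("h", "k", "int_prox", "tmp_dist", "mto"))
            for s in SIDES
        )

    @property
    def segments(self) -> dict:
        """Landmarks grouped by the rigid segment carrying them."""
        seg = {"pelvis": ["p_c", "h_l", "h_r", "p_caud", "p_left", "p_right"]}
        for s in SIDES:
            seg[f"femur_{s}"] = [f"h_{s}", f"k_{s}", f"fem_mid_{s}"]
            seg[f"tibiotarsus_{s}"] = [f"k_{s}", f"int_prox_{s}"]
            seg[f"tarsometatarsus_{s}"] = [
                f"int_prox_{s}", f"int_dist_{s}", f"tmt_prox_{s}", f"tmp_dist_{s}"]
            seg[f"toe_{s}"] = [f"tmp_dist_{s}", f"toe_mid_{s}", f"mto_{s}"]
        return seg

    def to_json(self) -> str:
        d = asdict(self)
        d.pop("landmarks")
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SkeletonModel":
        return cls(**json.loads(text))


def build_default_quail_skeleton(**overrides) -> SkeletonModel:
    """Default adult common-quail hindlimb skeleton.

    Dimensions give a straight-leg reach of ~0.2 m, so the full range of
    stance effective-leg lengths observed in the study (~0.08-0.15 m) is
    reachable with physiologically flexed joints.
    """
    return SkeletonModel(**overrides)
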