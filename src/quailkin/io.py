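"""Delimited-text readers/writers for every pipeline artifact.

All tabular artifacts are CSV with a one-line header; structured metadata
(rig, skeleton, template, seeds, manifest) is JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cameras import CameraDLT, Observations2D
from .strides import StrideEvents


def write_landmarks_csv(path, landmarks: dict, fps: float) -> None:
    names = list(landmarks)
    T = len(landmarks[names[0]])
    df = pd.DataFrame({
        "frame": np.repeat(np.arange(T), len(names)),
        "time": np.repeat(np.arange(T) / fps, len(names)),
        "landmark": np.tile(names, T),
    })
    arr = np.stack([landmarks[n] for n in names], axis=1).reshape(-1, 3)
    df[["X", "Y", "Z"]] = arr
    df.to_csv(path, index=False)


def read_landmarks_csv(path) -> dict:
    df = pd.read_csv(path)
    out = {}
    for name, sub in df.groupby("landmark", sort=False):
        out[name] = sub.sort_values("frame")[["X", "Y", "Z"]].to_numpy(float)
    return out


def write_observations_csv(path, obs: Observations2D) -> None:
    T, N, _ = obs.uv.shape
    df = pd.DataFrame({
        "frame": np.repeat(np.arange(T), N),
        "landmark": np.tile(obs.landmark_names, T),
        "view": obs.view,
        "u": obs.uv[..., 0].ravel(),
        "v": obs.uv[..., 1].ravel(),
    })
    df.to_csv(path, index=False)


def read_observations_csv(path) -> Observations2D:
    df = pd.read_csv(path)
    names = tuple(df.landmark.drop_duplicates())
    T = df.frame.nunique()
    uv = (df.sort_values(["frame", "landmark"],
                         key=lambda c: c if c.name == "frame"
                         else c.map({n: i for i, n in enumerate(names)}))
          [["u", "v"]].to_numpy(float).reshape(T, len(names), 2))
    return Observations2D(str(df.view.iloc[0]), names, uv)


def write_features_csv(path, X: np.ndarray) -> None:
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
    df.insert(0, "frame", np.arange(len(X)))
    df.to_csv(path, index=False)


def read_features_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    return df.drop(columns=["frame"]).to_numpy(float)


def write_calibration_csv(path, cube_positions: np.ndarray,
                          pixels: dict) -> None:
    """``pixels``: view -> (S, 2) annotated sphere pixels."""
    rows = []
    for view, uv in pixels.items():
        for i, (xyz, p) in enumerate(zip(cube_positions, uv)):
            rows.append({"sphere_id": i, "X": xyz[0], "Y": xyz[1], "Z": xyz[2],
                         "view": view, "u": p[0], "v": p[1]})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_calibration_csv(path) -> dict:
    """Returns view -> (xyz (S,3), uv (S,2)) correspondence arrays."""
    df = pd.read_csv(path)
    out = {}
    for view, sub in df.groupby("view", sort=False):
        sub = sub.sort_values("sphere_id")
        out[str(view)] = (sub[["X", "Y", "Z"]].to_numpy(float),
                          sub[["u", "v"]].to_numpy(float))
    return out


def write_events(path_csv, events: StrideEvents) -> None:
    rows = []
    for leg, frames in events.touchdowns.items():
        rows += [{"leg": leg, "event": "td", "frame": f} for f in frames]
    for leg, frames in events.toeoffs.items():
        rows += [{"leg": leg, "event": "to", "frame": f} for f in frames]
    pd.DataFrame(rows).to_csv(path_csv, index=False)
    side = Path(path_csv).with_suffix(".json")
    side.write_text(json.dumps({
        "terrain_shift_frame": events.terrain_shift_frame,
        "roles": events.roles}))


def read_events(path_csv) -> StrideEvents:
    df = pd.read_csv(path_csv)
    side = Path(path_csv).with_suffix(".json")
    meta = json.loads(side.read_text()) if side.exists() else {}
    tds, tos = {}, {}
    for leg, sub in df.groupby("leg", sort=False):
        tds[leg] = sorted(sub[sub.event == "td"].frame.astype(int))
        tos[leg] = sorted(sub[sub.event == "to"].frame.astype(int))
    return StrideEvents(touchdowns=tds, toeoffs=tos,
                        terrain_shift_frame=meta.get("terrain_shift_frame"),
                        roles=meta.get("roles"))


def write_rig_json(path, lateral: CameraDLT, ventral: CameraDLT) -> None:
    Path(path).write_text(json.dumps({
        "lateral": json.loads(lateral.to_json()),
        "ventrodorsal": json.loads(ventral.to_json())}, indent=2))


def read_rig_json(path) -> tuple:
    d = json.loads(Path(path).read_text())
    return (CameraDLT.from_json(json.dumps(d["lateral"])),
            CameraDLT.from_json(json.dumps(d["ventrodorsal"])))
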