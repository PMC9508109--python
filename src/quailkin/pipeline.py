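"""End-to-end pipeline stages tying the modules together.

Each stage has a pure in-memory function (used by tests and the acceptance
script) and a file-based command used by the CLI: simulate -> track ->
reconstruct -> analyze -> stats. Every command is deterministic given
(config, seed); the manifest lists every artifact with row counts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as qio
from .cameras import (add_pixel_noise, make_calibration_cube,
                      make_two_view_rig, project_sequence)
from .config import PipelineConfig
from .features import synthesize_features
from .gait import PELVIS_VARIABLES, SPLINE_VARIABLES, make_gait_template
from .kinematics import compute_angle_table
from .reconstruct import calibrate_dlt, reprojection_report, triangulate
from .regression import (annotate_from_observations, predict_landmarks,
                         select_training_frames, train_landmark_regressors)
from .simulate import simulate_trial
from .skeleton import build_default_quail_skeleton
from .stats import comparison_table, condition_vs_level, rm_anova
from .strides import (detect_events, extract_event_windows,
                      normalize_stride, segment_strides)

ANGLE_VARIABLES = tuple(SPLINE_VARIABLES) + tuple(PELVIS_VARIABLES) + (
    "eff_leg_length", "eff_leg_angle", "aperture")


# ---------------------------------------------------------------------------
# in-memory stages

def simulate_stage(cfg: PipelineConfig):
    """Synthetic trial + rig + two-view observations + features."""
    skeleton = build_default_quail_skeleton()
    template = make_gait_template(cfg.condition)
    trial = simulate_trial(skeleton, template, fps=cfg.fps,
                           n_strides=cfg.n_strides,
                           seed=cfg.stage_seed("simulate"))
    rig = cfg.rig
    lateral, ventral = make_two_view_rig(
        scene_center=rig.scene_center, distance=rig.distance,
        focal_px=rig.focal_px, principal=rig.principal,
        lateral_tilt_deg=rig.lateral_tilt_deg)
    cube = make_calibration_cube(rig.cube_spheres_per_axis, rig.cube_spacing,
                                 center=rig.scene_center)
    obs = {}
    for cam in (ventral, lateral):
        o = project_sequence(cam, trial.landmarks)
        if cfg.pixel_noise_sd > 0:
            o = add_pixel_noise(o, cfg.pixel_noise_sd,
                                cfg.stage_seed("pixel_noise"))
        obs[cam.view] = o
    feats = synthesize_features(
        obs["ventrodorsal"], obs["lateral"], cfg.features.D,
        noise_sd=cfg.features.noise_sd,
        n_distractors=cfg.features.n_distractors,
        seed=cfg.stage_seed("features"))
    return {"trial": trial, "skeleton": skeleton, "template": template,
            "lateral": lateral, "ventral": ventral, "cube": cube,
            "observations": obs, "features": feats}


def track_stage(cfg: PipelineConfig, sim: dict) -> dict:
    """Annotate M equidistant frame pairs, train the regressors, predict."""
    obs_d = sim["observations"]["ventrodorsal"]
    obs_l = sim["observations"]["lateral"]
    frames = select_training_frames(obs_d.n_frames, cfg.regressor.M)
    annotations = annotate_from_observations(obs_d, obs_l, frames)
    regressor = train_landmark_regressors(
        annotations, sim["features"], C=cfg.regressor.C,
        epsilon=cfg.regressor.epsilon)
    predicted = predict_landmarks(regressor, sim["features"])
    return {"annotations": annotations, "regressor": regressor,
            "predicted": predicted, "training_frames": frames}


def reconstruct_stage(cfg: PipelineConfig, sim: dict, track: dict) -> dict:
    """Calibrate both views from the cube and triangulate predictions."""
    cube = sim["cube"]
    cams = {}
    for cam in (sim["ventral"], sim["lateral"]):
        uv = cam.project(cube.positions)
        cams[cam.view] = calibrate_dlt(cube.positions, uv, view=cam.view)
    traj = triangulate(cams["ventrodorsal"], cams["lateral"],
                       track["predicted"]["ventrodorsal"],
                       track["predicted"]["lateral"])
    return {"cameras": cams, "trajectory": traj,
            "report": reprojection_report(traj)}


def analyze_stage(cfg: PipelineConfig, sim: dict, positions: dict) -> dict:
    """Angle table, stride segmentation and 100-point normalization."""
    trial = sim["trial"]
    angles = compute_angle_table(positions, cfg.fps)
    if cfg.events.use_truth:
        events = trial.events
    else:
        from .strides import StrideEvents
        det = {}
        for leg in ("l", "r"):
            det[leg] = detect_events(
                positions[f"mto_{leg}"], cfg.fps,
                body_speed=sim["template"].speed,
                ground=trial.ground.get(leg, 0.0),
                height_threshold=cfg.events.height_threshold,
                speed_fraction=cfg.events.speed_fraction,
                hysteresis=cfg.events.hysteresis)
        events = StrideEvents(
            touchdowns={leg: det[leg]["touchdowns"] for leg in det},
            toeoffs={leg: det[leg]["toeoffs"] for leg in det},
            terrain_shift_frame=trial.events.terrain_shift_frame,
            roles=trial.events.roles)
    role = "level" if cfg.condition == "level" else None
    strides = []
    if role == "level":
        windows = segment_strides(events, "level")
    else:
        windows = (segment_strides(events, "trailing")
                   + segment_strides(events, "leading"))
    for (a, b, leg) in windows:
        if cfg.condition == "level":
            st_role = "level"
        else:
            st_role = events.roles[leg]
        tos = [f for f in events.toeoffs[leg] if a < f <= b]
        ev = {"td": 0}
        if tos:
            ev["to"] = tos[0] - a
        for var in ANGLE_VARIABLES:
            side = leg if var not in PELVIS_VARIABLES + ("aperture",) else ""
            sel = angles[(angles.variable == var) & (angles.side == side)]
            series = sel.sort_values("frame").value_deg.to_numpy()[a:b + 1]
            strides.append(normalize_stride(
                series, var, side=side, role=st_role, events_in_window=ev,
                condition=cfg.condition))
    return {"angles": angles, "events": events, "strides": strides}


def run_full_chain(cfg: PipelineConfig) -> dict:
    """simulate -> track -> reconstruct -> analyze on one trial."""
    sim = simulate_stage(cfg)
    trk = track_stage(cfg, sim)
    rec = reconstruct_stage(cfg, sim, trk)
    ana = analyze_stage(cfg, sim, rec["trajectory"].as_dict())
    return {"sim": sim, "track": trk, "reconstruct": rec, "analyze": ana}


def level_gait_recovery(seed: int = 1) -> dict:
    """Recover the level-gait summary values through the full chain.

    Simulates two level strides at 500 Hz, projects them noiselessly
    through the biplanar rig, tracks all landmarks with the M = 10
    epsilon-SVR scheme, calibrates and triangulates, computes the angle
    tables and reads off the level-locomotion summary quantities: hip
    flexion-extension at TD, its extension excursion from the post-TD
    minimum to TO, whole-leg ab-adduction at TD and TO, mediolateral
    rotation at TO, stride-mean pelvic retroversion magnitude, the
    aperture angle at the contralateral (leading) touchdown, and the mean
    forward speed. Returns a dict of plain floats plus ``n_frames``.
    """
    from .config import FeatureConfig
    cfg = PipelineConfig(seed=seed, pixel_noise_sd=0.0,
                         features=FeatureConfig(noise_sd=0.0,
                                                n_distractors=0))
    res = run_full_chain(cfg)
    trial = res["sim"]["trial"]
    angles = res["analyze"]["angles"]

    def series(var, side=""):
        sel = angles[(angles.variable == var) & (angles.side == side)]
        return sel.sort_values("frame").value_deg.to_numpy()

    events = trial.events
    n = trial.n_frames
    fps = cfg.fps
    T = trial.template.stride_duration
    sf = trial.template.stance_fraction("trailing")
    pitch = series("pelvis_pitch")
    aperture = series("aperture")

    # Touchdown-event values are read at the trial's first touchdown: the
    # equidistant annotation scheme starts at frame 1, so this TD carries a
    # manual annotation (training-frame accuracy). Stance-interior values
    # (TO readings, the extension excursion, the stride-mean retroversion)
    # are pooled over every complete TD->TD stride of both legs, as the
    # study pools legs and strides into mean curves.
    flex_l = series("hip_flexion", "l")
    abd_l = series("hip_abduction", "l")
    means = {"flex_td": float(flex_l[events.touchdowns["l"][0]]),
             "abd_td": float(abd_l[events.touchdowns["l"][0]])}
    readings = {k: [] for k in ("excursion", "abd_to", "med_to", "retro")}
    for leg in ("l", "r"):
        flex = series("hip_flexion", leg)
        abd = series("hip_abduction", leg)
        med = series("hip_mediolateral", leg)
        tds = events.touchdowns[leg]
        for a, b in zip(tds[:-1], tds[1:]):
            if b >= n:
                continue
            to = next(f for f in events.toeoffs[leg] if a < f <= b)
            readings["excursion"].append(flex[to] - flex[a:to + 1].min())
            readings["abd_to"].append(abd[to])
            readings["med_to"].append(med[to])
            readings["retro"].append(np.abs(pitch[a:b]).mean())
    means.update({k: float(np.mean(v)) for k, v in readings.items()})

    # aperture at every interior touchdown (each TD is a "leading" contact
    # of the landing leg); half-stride events fall mid-frame, so read at
    # the interpolated event time
    ap_vals = []
    for leg in ("l", "r"):
        offset = 0.0 if leg == "l" else 0.5
        k0 = 1 if leg == "l" else 0
        for k in range(k0, 2 * cfg.n_strides):
            f = (k + offset) * T * fps
            if not 1 <= f <= n - 2:
                continue
            f0 = int(np.floor(f))
            w = f - f0
            ap_vals.append((1 - w) * aperture[f0] + w * aperture[f0 + 1])
    td = events.touchdowns["l"][0]
    td_next = events.touchdowns["l"][1]
    x = trial.pelvis_origin[:, 0]
    speed = (x[td_next] - x[td]) / ((td_next - td) / fps)
    return {
        "hip_flexion_td_deg": means["flex_td"],
        "hip_extension_excursion_deg": means["excursion"],
        "abduction_td_deg": means["abd_td"],
        "abduction_to_deg": means["abd_to"],
        "mediolateral_to_deg": means["med_to"],
        "pelvic_retroversion_deg": means["retro"],
        "aperture_td_deg": float(np.mean(ap_vals)),
        "forward_speed_m_s": float(speed),
        "n_frames": trial.n_frames,
        "_chain": res,
    }


# ---------------------------------------------------------------------------
# study-level statistics

def _jittered_template(condition: str, rng: np.random.Generator,
                       indiv_offsets: dict, trial_sd: float):
    """Template with per-individual angle offsets and per-trial noise."""
    overrides = {}
    base = make_gait_template(condition)
    for var, pts in base.control_points.items():
        off = indiv_offsets.get(var, 0.0)
        overrides[var] = {ph: val + off + rng.normal(0.0, trial_sd)
                          for ph, val in pts.items()}
    speed = base.speed * float(np.clip(indiv_offsets.get("__speed__", 1.0), 0.5, 1.5))
    return make_gait_template(condition, control_points=overrides, speed=speed)


def stats_stage(cfg: PipelineConfig) -> dict:
    """Simulated mini-study: per-condition event windows vs level + rm-ANOVA.

    Each simulated individual carries stable angular offsets (between-animal
    variability) plus per-trial noise; the same individuals are reused
    across step conditions so the repeated-measures layer sees paired data.
    """
    sc = cfg.stats
    rng = np.random.default_rng(cfg.stage_seed("stats"))
    skeleton = build_default_quail_skeleton()
    individuals = []
    for i in range(sc.n_individuals):
        offsets = {v: rng.normal(0.0, sc.individual_sd_deg)
                   for v in SPLINE_VARIABLES}
        offsets["__speed__"] = 1.0 + rng.normal(0.0, 0.08)
        individuals.append(offsets)

    def windows_for(condition):
        out = {}
        role = "level" if condition == "level" else None
        for i, offsets in enumerate(individuals):
            tpl = _jittered_template(condition, rng, offsets, sc.trial_sd_deg)
            trial = simulate_trial(skeleton, tpl, fps=250.0, n_strides=2,
                                   seed=cfg.stage_seed("stats") + i)
            events = trial.events
            if condition == "level":
                segs = segment_strides(events, "level", leg="l")[:1]
                st_role = "level"
            else:
                segs = segment_strides(events, "trailing")
                st_role = "trailing"
            a, b, leg = segs[0]
            tos = [f for f in events.toeoffs[leg] if a < f <= b]
            ev = {"td": 0, "to": tos[0] - a if tos else None}
            ev = {k: v for k, v in ev.items() if v is not None}
            for var in sc.variables:
                side = leg if var not in PELVIS_VARIABLES + ("aperture",) else ""
                series = trial.angles
                sel = series[(series.variable == var) & (series.side == side)]
                y = sel.sort_values("frame").value_deg.to_numpy()[a:b + 1]
                ns = normalize_stride(y, var, side=side, role=st_role,
                                      events_in_window=ev, condition=condition,
                                      individual=f"q{i}")
                for w in extract_event_windows(ns):
                    out.setdefault((var, w.event), []).append(w.values)
        return {k: np.vstack(v) for k, v in out.items()}

    level = windows_for("level")
    results = []
    for condition in sc.conditions:
        cond = windows_for(condition)
        for (var, event), wins in cond.items():
            if (var, event) not in level:
                continue
            results.append(condition_vs_level(
                wins, level[(var, event)], variable=var, event=event,
                condition=condition, response=sc.response))
    table = comparison_table(results)

    # repeated-measures layer on the trailing swing time across conditions
    rm_rows = []
    for condition in [c for c in sc.conditions if c != "level"]:
        direction, height = condition.split("_")
        for i, offsets in enumerate(individuals):
            tpl = _jittered_template(condition, rng, offsets, sc.trial_sd_deg)
            rm_rows.append({
                "individual": f"q{i}", "height": height,
                "direction": direction,
                "value": tpl.swing_time["trailing"]
                * (1.0 + rng.normal(0.0, 0.05))})
    rm_table = pd.DataFrame(rm_rows)
    anova = None
    if rm_table.height.nunique() >= 2 and rm_table.direction.nunique() >= 2:
        anova = rm_anova(rm_table)
    return {"comparisons": table, "rm_anova": anova, "rm_table": rm_table}


# ---------------------------------------------------------------------------
# file-based commands (CLI surface)

def _outdir(cfg: PipelineConfig) -> Path:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.write(out / "resolved_config.yaml")
    return out


def _manifest_add(out: Path, entries: dict) -> None:
    path = out / "manifest.json"
    man = json.loads(path.read_text()) if path.exists() else {}
    man.update(entries)
    path.write_text(json.dumps(man, indent=2, sort_keys=True))


def cmd_simulate(cfg: PipelineConfig) -> Path:
    out = _outdir(cfg)
    sim = simulate_stage(cfg)
    trial = sim["trial"]
    qio.write_landmarks_csv(out / "landmarks_3d_truth.csv", trial.landmarks,
                            cfg.fps)
    for view, obs in sim["observations"].items():
        qio.write_observations_csv(out / f"obs_{view}.csv", obs)
    qio.write_features_csv(out / "features.csv", sim["features"].X)
    qio.write_calibration_csv(
        out / "calibration.csv", sim["cube"].positions,
        {cam.view: cam.project(sim["cube"].positions)
         for cam in (sim["ventral"], sim["lateral"])})
    qio.write_events(out / "events.csv", trial.events)
    qio.write_rig_json(out / "rig.json", sim["lateral"], sim["ventral"])
    (out / "skeleton.json").write_text(sim["skeleton"].to_json())
    (out / "template.json").write_text(sim["template"].to_json())
    trial.angles.to_csv(out / "angles_truth.csv", index=False)
    _manifest_add(out, {
        "landmarks_3d_truth.csv": trial.n_frames,
        "obs_ventrodorsal.csv": trial.n_frames,
        "obs_lateral.csv": trial.n_frames,
        "features.csv": int(sim["features"].X.shape[0]),
        "calibration.csv": 2 * len(sim["cube"].positions),
        "events.csv": sum(len(v) for v in trial.events.touchdowns.values())
        + sum(len(v) for v in trial.events.toeoffs.values()),
        "seed": cfg.seed})
    return out


def cmd_track(cfg: PipelineConfig) -> Path:
    out = _outdir(cfg)
    feats_path = out / "features.csv"
    if not feats_path.exists():
        raise FileNotFoundError(
            f"no features at {feats_path}; run the simulate stage first")
    X = qio.read_features_csv(feats_path)
    obs_d = qio.read_observations_csv(out / "obs_ventrodorsal.csv")
    obs_l = qio.read_observations_csv(out / "obs_lateral.csv")
    frames = select_training_frames(obs_d.n_frames, cfg.regressor.M)
    annotations = annotate_from_observations(obs_d, obs_l, frames)
    annotations.table.to_csv(out / "annotations.csv", index=False)
    reg = train_landmark_regressors(annotations, X, C=cfg.regressor.C,
                                    epsilon=cfg.regressor.epsilon)
    (out / "regressor.json").write_text(reg.to_json())
    pred = predict_landmarks(reg, X)
    rmse = []
    for view, obs in ((obs_d.view, obs_d), (obs_l.view, obs_l)):
        qio.write_observations_csv(out / f"pred_{view}.csv", pred[view])
        from .regression import evaluate_localization
        rmse.append(evaluate_localization(pred[view], obs))
    pd.concat(rmse).to_csv(out / "localization_rmse.csv", index=False)
    _manifest_add(out, {"pred_ventrodorsal.csv": pred["ventrodorsal"].n_frames,
                        "pred_lateral.csv": pred["lateral"].n_frames,
                        "training_frames": frames})
    return out


def cmd_reconstruct(cfg: PipelineConfig) -> Path:
    out = _outdir(cfg)
    corr = qio.read_calibration_csv(out / "calibration.csv")
    cams = {}
    for view, (xyz, uv) in corr.items():
        cams[view] = calibrate_dlt(xyz, uv, view=view)
    pred_d = qio.read_observations_csv(out / "pred_ventrodorsal.csv")
    pred_l = qio.read_observations_csv(out / "pred_lateral.csv")
    traj = triangulate(cams["ventrodorsal"], cams["lateral"], pred_d, pred_l)
    traj.to_frame().to_csv(out / "landmarks_3d.csv", index=False)
    reprojection_report(traj).to_csv(out / "reprojection_report.csv",
                                     index=False)
    _manifest_add(out, {"landmarks_3d.csv": traj.xyz.shape[0],
                        "calibration_rms_px": {
                            v: cams[v].rms_reprojection_px for v in cams}})
    return out


def cmd_analyze(cfg: PipelineConfig) -> Path:
    out = _outdir(cfg)
    df = pd.read_csv(out / "landmarks_3d.csv")
    positions = {}
    for name, sub in df.groupby("landmark", sort=False):
        positions[name] = sub.sort_values("frame")[["X", "Y", "Z"]].to_numpy()
    sim = {"trial": _TrialEventsProxy(qio.read_events(out / "events.csv")),
           "template": make_gait_template(cfg.condition)}
    ana = analyze_stage(cfg, sim, positions)
    ana["angles"].to_csv(out / "angles.csv", index=False)
    rows = []
    for st in ana["strides"]:
        for ph, val in enumerate(st.values):
            rows.append({"variable": st.variable, "side": st.side,
                         "role": st.role, "phase": ph, "value": val})
    pd.DataFrame(rows).to_csv(out / "normalized_strides.csv", index=False)
    from .strides import aggregate_mean_curves
    aggregate_mean_curves(ana["strides"]).to_csv(out / "mean_curves.csv",
                                                 index=False)
    _manifest_add(out, {"angles.csv": int(ana["angles"].frame.nunique()),
                        "normalized_strides.csv": len(ana["strides"])})
    return out


class _TrialEventsProxy:
    """Minimal trial stand-in for file-based analyze (events + terrain)."""

    def __init__(self, events):
        self.events = events
        self.ground = {}


def cmd_stats(cfg: PipelineConfig) -> Path:
    out = _outdir(cfg)
    res = stats_stage(cfg)
    res["comparisons"].to_csv(out / "comparisons.csv", index=False)
    if res["rm_anova"] is not None:
        res["rm_anova"].to_csv(out / "rm_anova.csv", index=False)
    res["comparisons"].to_json(out / "comparisons.json", orient="records",
                               indent=2)
    _manifest_add(out, {"comparisons.csv": len(res["comparisons"])})
    return out


def cmd_all(cfg: PipelineConfig) -> Path:
    cmd_simulate(cfg)
    cmd_track(cfg)
    cmd_reconstruct(cfg)
    cmd_analyze(cfg)
    cmd_stats(cfg)
    return Path(cfg.outdir)
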