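"""Plain-text trial and result files.

A trial directory holds one delimited table per rate group plus metadata:

``forces.tsv``
    time_s, fz_L, fz_R, cop_ml_L, cop_ap_L, cop_ml_R, cop_ap_R,
    cop_ml, cop_ap (combined)  — 200 Hz
``kinematics.tsv``
    time_s, com_ml, foot_ml_L, foot_ml_R  — 50 Hz
``emg.tsv``
    time_s, gm_L, gm_R, al_L, al_R  — 2 kHz (optional)
``meta.yaml``
    condition, speed, rates, body mass, leg length, seed
``truth.json``
    simulation ground truth (optional; synthetic trials only)

All units SI.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import SimTruth, TrialTimeSeries

__all__ = ["write_trial", "read_trial", "write_events", "read_events"]


def write_trial(trial: TrialTimeSeries, out_dir, truth: SimTruth | None = None,
                float_format: str = "%.6f") -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    forces = pd.DataFrame({
        "time_s": trial.force_time,
        "fz_L": trial.fz["L"], "fz_R": trial.fz["R"],
        "cop_ml_L": trial.cop_ml["L"], "cop_ap_L": trial.cop_ap["L"],
        "cop_ml_R": trial.cop_ml["R"], "cop_ap_R": trial.cop_ap["R"],
        "cop_ml": trial.combined_cop_ml, "cop_ap": trial.combined_cop_ap,
    })
    forces.to_csv(out / "forces.tsv", sep="\t", index=False,
                  float_format=float_format)
    kin = pd.DataFrame({
        "time_s": trial.kin_time, "com_ml": trial.com_ml,
        "foot_ml_L": trial.foot_ml["L"], "foot_ml_R": trial.foot_ml["R"],
    })
    kin.to_csv(out / "kinematics.tsv", sep="\t", index=False,
               float_format=float_format)
    if trial.emg is not None:
        emg = pd.DataFrame({"time_s": trial.emg_time, **trial.emg})
        emg.to_csv(out / "emg.tsv", sep="\t", index=False,
                   float_format=float_format)
    meta = {
        "condition": trial.condition, "speed_mode": trial.speed_mode,
        "rate_force": trial.rate_force, "rate_kin": trial.rate_kin,
        "rate_emg": trial.rate_emg, "body_mass": trial.body_mass,
        "leg_length": trial.leg_length, **trial.meta,
    }
    (out / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    if truth is not None:
        (out / "truth.json").write_text(json.dumps(_truth_to_dict(truth)))
    return out


def _truth_to_dict(t: SimTruth) -> dict:
    as_list = lambda d: {k: np.asarray(v).tolist() for k, v in d.items()}
    return {
        "true_k_pos": t.true_k_pos, "true_k_vel": t.true_k_vel,
        "effective_k_pos": t.effective_k_pos, "effective_k_vel": t.effective_k_vel,
        "nominal_step_width": t.nominal_step_width,
        "heel_strike_times": as_list(t.heel_strike_times),
        "toe_off_times": as_list(t.toe_off_times),
        "placements": as_list(t.placements),
        "fp_lateral": as_list(t.fp_lateral),
        "com_series": np.asarray(t.com_series).tolist(),
        "emg_burst_gm": as_list(t.emg_burst_gm) if t.emg_burst_gm else None,
        "emg_burst_al": as_list(t.emg_burst_al) if t.emg_burst_al else None,
        "seed": t.seed,
    }


def _truth_from_dict(d: dict) -> SimTruth:
    as_arr = lambda x: {k: np.asarray(v) for k, v in x.items()} if x else None
    return SimTruth(
        true_k_pos=d["true_k_pos"], true_k_vel=d["true_k_vel"],
        effective_k_pos=d["effective_k_pos"], effective_k_vel=d["effective_k_vel"],
        nominal_step_width=d["nominal_step_width"],
        heel_strike_times=as_arr(d["heel_strike_times"]),
        toe_off_times=as_arr(d["toe_off_times"]),
        placements=as_arr(d["placements"]),
        fp_lateral=as_arr(d["fp_lateral"]),
        com_series=np.asarray(d["com_series"]),
        emg_burst_gm=as_arr(d["emg_burst_gm"]),
        emg_burst_al=as_arr(d["emg_burst_al"]),
        seed=d["seed"],
    )


def read_trial(trial_dir):
    """Read a trial directory; returns ``(TrialTimeSeries, SimTruth | None)``."""
    d = Path(trial_dir)
    if not d.is_dir():
        raise FileNotFoundError(f"trial directory not found: {d}")
    meta = yaml.safe_load((d / "meta.yaml").read_text())
    forces = pd.read_csv(d / "forces.tsv", sep="\t")
    kin = pd.read_csv(d / "kinematics.tsv", sep="\t")
    emg_path = d / "emg.tsv"
    emg_time = emg = None
    if emg_path.exists():
        emg_df = pd.read_csv(emg_path, sep="\t")
        emg_time = emg_df["time_s"].to_numpy()
        emg = {c: emg_df[c].to_numpy() for c in emg_df.columns if c != "time_s"}
    trial = TrialTimeSeries(
        force_time=forces["time_s"].to_numpy(),
        fz={"L": forces["fz_L"].to_numpy(), "R": forces["fz_R"].to_numpy()},
        cop_ml={"L": forces["cop_ml_L"].to_numpy(), "R": forces["cop_ml_R"].to_numpy()},
        cop_ap={"L": forces["cop_ap_L"].to_numpy(), "R": forces["cop_ap_R"].to_numpy()},
        combined_cop_ml=forces["cop_ml"].to_numpy(),
        combined_cop_ap=forces["cop_ap"].to_numpy(),
        kin_time=kin["time_s"].to_numpy(), com_ml=kin["com_ml"].to_numpy(),
        foot_ml={"L": kin["foot_ml_L"].to_numpy(), "R": kin["foot_ml_R"].to_numpy()},
        emg_time=emg_time, emg=emg,
        condition=meta.get("condition", "steady"),
        speed_mode=meta.get("speed_mode", "normal"),
        rate_force=meta.get("rate_force", 200.0),
        rate_kin=meta.get("rate_kin", 50.0),
        rate_emg=meta.get("rate_emg", 2000.0),
        body_mass=meta.get("body_mass", 70.0),
        leg_length=meta.get("leg_length", 0.9),
        meta=meta,
    )
    truth = None
    truth_path = d / "truth.json"
    if truth_path.exists():
        truth = _truth_from_dict(json.loads(truth_path.read_text()))
    return trial, truth


def write_events(events, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    events.to_frame().to_csv(path, sep="\t", index=False)
    return path


def read_events(path, rate: float = 200.0):
    from .events import GaitEvents
    return GaitEvents.from_frame(pd.read_csv(path, sep="\t"), rate=rate)
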