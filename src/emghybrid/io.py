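"""Readers and writers for the package's delimited-text and JSON formats.

CSV layouts:
  EMG:         ``time, ch1..chL`` (header required)
  features:    ``time, x1..xL, F, gate``
  trajectory:  ``time, angle_x, angle_y`` (deg; X flexion-extension,
               Y radial-ulnar deviation)
  calibration: ``current_mA, angle_deg``

JSON layouts: per-channel EMG calibration ``{channel: {rest, max}}``,
FES parameters ``{muscle: {b, c, d, residual}}``, network weights
(shape metadata plus a flat coefficient array), metric reports.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import NetworkWeights
from .fes import FesParams
from .metrics import TrialTrajectory
from .preprocess import FeatureSequence, RawEMGRecord
from .trajectory import SampledTrajectory


def read_emg_csv(path: str | Path) -> RawEMGRecord:
    df = pd.read_csv(path)
    if df.columns[0] != "time":
        raise ValueError("first column of an EMG CSV must be 'time'")
    return RawEMGRecord(t=df["time"].to_numpy(),
                        signals=df.iloc[:, 1:].to_numpy())


def write_emg_csv(record: RawEMGRecord, path: str | Path) -> None:
    cols = {"time": record.t}
    for i in range(record.n_channels):
        cols[f"ch{i + 1}"] = record.signals[:, i]
    pd.DataFrame(cols).to_csv(path, index=False)


def write_features_csv(features: FeatureSequence, path: str | Path) -> None:
    cols = {"time": features.t}
    for i in range(features.x.shape[1]):
        cols[f"x{i + 1}"] = features.x[:, i]
    cols["F"] = features.activation
    cols["gate"] = features.gate.astype(int)
    pd.DataFrame(cols).to_csv(path, index=False)


def write_emg_calibration_json(
    rest_baseline: np.ndarray, max_level: np.ndarray, path: str | Path
) -> None:
    data = {
        f"ch{i + 1}": {"rest": float(r), "max": float(m)}
        for i, (r, m) in enumerate(zip(rest_baseline, max_level))
    }
    Path(path).write_text(json.dumps(data, indent=2))


def read_emg_calibration_json(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    data = json.loads(Path(path).read_text())
    keys = sorted(data, key=lambda k: int(k.lstrip("ch")))
    rest = np.array([data[k]["rest"] for k in keys])
    mx = np.array([data[k]["max"] for k in keys])
    return rest, mx


def read_trajectory_csv(path: str | Path) -> SampledTrajectory:
    df = pd.read_csv(path)
    return SampledTrajectory(
        t=df["time"].to_numpy(),
        P=df[["angle_x", "angle_y"]].to_numpy(),
    )


def write_trajectory_csv(traj: SampledTrajectory | TrialTrajectory,
                         path: str | Path) -> None:
    pd.DataFrame({
        "time": traj.t, "angle_x": traj.P[:, 0], "angle_y": traj.P[:, 1]
    }).to_csv(path, index=False)


def read_calibration_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["current_mA"].to_numpy(), df["angle_deg"].to_numpy()


def write_calibration_csv(currents, angles, path: str | Path) -> None:
    pd.DataFrame({"current_mA": currents, "angle_deg": angles}).to_csv(
        path, index=False
    )


def save_weights(weights: NetworkWeights, path: str | Path,
                 report: dict | None = None) -> None:
    data = {
        "shape": list(weights.w.shape),
        "coefficients": weights.w.ravel().tolist(),
    }
    if report is not None:
        data["training_report"] = report
    Path(path).write_text(json.dumps(data))


def load_weights(path: str | Path) -> NetworkWeights:
    data = json.loads(Path(path).read_text())
    w = np.array(data["coefficients"]).reshape(data["shape"])
    return NetworkWeights(w)


def save_fes_params(params_by_muscle: dict, path: str | Path) -> None:
    data = {
        muscle: {"b": p.b, "c": p.c, "d": p.d, "residual": p.residual}
        for muscle, p in params_by_muscle.items()
    }
    Path(path).write_text(json.dumps(data, indent=2))


def load_fes_params(path: str | Path) -> dict:
    data = json.loads(Path(path).read_text())
    return {muscle: FesParams(**vals) for muscle, vals in data.items()}


def read_trial_manifest(path: str | Path) -> list[TrialTrajectory]:
    """Trial-set manifest: JSON with shared start/target and CSV paths.

    ``{"start": [x, y], "target": [x, y], "trials": ["a.csv", ...]}``;
    relative paths resolve against the manifest's directory.
    """
    path = Path(path)
    data = json.loads(path.read_text())
    start = np.asarray(data["start"], dtype=float)
    target = np.asarray(data["target"], dtype=float)
    trials = []
    for rel in data["trials"]:
        traj = read_trajectory_csv((path.parent / rel))
        trials.append(
            TrialTrajectory(t=traj.t, P=traj.P, start=start, target=target)
        )
    return trials
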