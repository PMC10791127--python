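"""Delimited-text file formats for trajectories, trial tables and fit reports.

All formats are plain UTF-8 text so every intermediate of a run can be
inspected and versioned.  Trajectory files are one CSV per trial with columns
``frame, hue_a_deg, hue_b_deg``; trial tables are one CSV row per trial with
the TrialRecord columns (missing responses empty); fit reports are YAML plus
a per-sample responsibility CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .stimulus import HueTrajectory, TrajectoryPair
from .vmmixture import PrecisionPair, VonMisesMixtureFit

__all__ = [
    "write_trajectory_pair",
    "read_trajectory_pair",
    "write_trials",
    "read_trials",
    "write_fit_report",
    "read_fit_report",
    "load_config",
    "save_config",
]

TRIAL_COLUMNS = [
    "subject",
    "trial_id",
    "experiment",
    "soa",
    "cue_present",
    "cued_stream",
    "probed_stream",
    "target_a",
    "target_b",
    "response_1",
    "response_2",
    "favored_stream",
]


def write_trajectory_pair(pair: TrajectoryPair, path) -> None:
    n = min(len(pair.stream_a), len(pair.stream_b))
    df = pd.DataFrame(
        {
            "frame": np.arange(n),
            "hue_a_deg": pair.stream_a.angles[:n],
            "hue_b_deg": pair.stream_b.angles[:n],
        }
    )
    # %.17g round-trips float64 exactly, so read(write(x)) == x bitwise
    df.to_csv(path, index=False, float_format="%.17g")


def _reversals_from_angles(angles: np.ndarray) -> list[int]:
    """Recover reversal frames as sign changes of the wrapped per-frame step."""
    d = np.mod(np.diff(angles) + 180.0, 360.0) - 180.0
    signs = np.sign(d)
    return [int(i) for i in np.flatnonzero(signs[1:] != signs[:-1]) + 1]


def read_trajectory_pair(path, frame_rate: float = 60.0) -> TrajectoryPair:
    df = pd.read_csv(path, float_precision="round_trip")
    streams = []
    for col in ("hue_a_deg", "hue_b_deg"):
        angles = df[col].to_numpy(dtype=float)
        if np.any((angles < 0) | (angles >= 360)):
            bad = int(np.argwhere((angles < 0) | (angles >= 360))[0])
            raise ValueError(f"{path}: hue out of [0, 360) at frame {bad} ({col})")
        step = np.abs(np.mod(np.diff(angles) + 180.0, 360.0) - 180.0)
        speed = float(step[0]) if len(step) else 1.0
        streams.append(
            HueTrajectory(
                angles=angles,
                frame_rate=frame_rate,
                speed=speed,
                reversal_frames=_reversals_from_angles(angles),
            )
        )
    return TrajectoryPair(stream_a=streams[0], stream_b=streams[1])


def write_trials(records: pd.DataFrame, path) -> None:
    cols = [c for c in TRIAL_COLUMNS if c in records.columns] + [
        c for c in records.columns if c not in TRIAL_COLUMNS
    ]
    records.loc[:, cols].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read a trial table and validate hue and error ranges row by row."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("target_a", "target_b", "response_1", "response_2"):
        if col in df.columns:
            v = df[col].to_numpy(dtype=float)
            bad = np.flatnonzero(~np.isnan(v) & ((v < 0) | (v >= 360)))
            if bad.size:
                raise ValueError(f"{path}: {col} out of [0, 360) at row {int(bad[0])}")
    for col in df.columns:
        if col.startswith("error"):
            v = df[col].to_numpy(dtype=float)
            bad = np.flatnonzero(~np.isnan(v) & (np.abs(v) > 180))
            if bad.size:
                raise ValueError(f"{path}: |{col}| > 180 at row {int(bad[0])}")
    return df


def write_fit_report(
    fit: VonMisesMixtureFit,
    pair: PrecisionPair,
    path,
    seed: int | None = None,
    responsibilities_path=None,
) -> None:
    report = {
        "components": [
            {"mu_deg": c.mu, "kappa": c.kappa, "weight": c.weight} for c in fit.components
        ],
        "loglik_nats": fit.loglik,
        "n_samples": fit.n,
        "converged": bool(fit.converged),
        "n_iter": fit.n_iter,
        "sd_precise_deg": pair.sd_precise,
        "sd_imprecise_deg": pair.sd_imprecise,
        "ratio": pair.ratio,
        "seed": seed,
    }
    Path(path).write_text(yaml.safe_dump(report, sort_keys=False), encoding="utf-8")
    if responsibilities_path is not None:
        pd.DataFrame(
            fit.responsibilities, columns=["resp_component_1", "resp_component_2"]
        ).to_csv(responsibilities_path, index=False)


def read_fit_report(path) -> dict:
    return yaml.safe_load(Path(path).read_text(encoding="utf-8"))


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False), encoding="utf-8")
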