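"""Synthetic two-resource observer.

Emulates the statistical structure of continuous-report tracking data for two
simultaneously attended color streams: on every trial one stream is tracked
with high precision (report error ~ von Mises with SD ``sd_high``) and the
other with low precision (``sd_low``).  Which stream is favored is either
fixed per trial (coin flip) or alternates deterministically in time at
``alternation_freq`` Hz, optionally phase-reset by an exogenous luminance cue
— the generative regime the stimulus-onset-asynchrony (SOA) analyses are
designed to detect.

The observer stands in for real behavioral data; it implements exactly the
assumptions of the downstream analyses (no uniform guessing, no swap errors
by default) so that parameter-recovery and null-calibration results isolate
the behavior of the estimators themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .stimulus import TrajectoryPair, circular_difference, probe_targets

__all__ = [
    "ObserverModel",
    "ExperimentDesign",
    "InsufficientDataError",
    "EXP3_SOA_GRIDS",
    "design_for",
    "favored_is_reference",
    "simulate_experiment",
    "simulate_cohort",
    "single_report_errors",
    "targets_uniformity_check",
]

#: Probe times (s after hue onset) for the three SOA variants; the luminance
#: cue appears 0.2 s after onset, so probes start 2.8 s after the cue.
EXP3_SOA_GRIDS = {
    "exp3a": np.arange(3.0, 4.01, 0.2),  # 200 ms steps
    "exp3b": np.arange(3.0, 3.51, 0.1),  # 100 ms steps
    "exp3c": np.arange(3.00, 3.201, 0.04),  # 40 ms steps
}
CUE_TIME_S = 0.2


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class ObserverModel:
    """Parameters of the synthetic observer.

    sd_high / sd_low are report-error SDs in degrees for the favored and
    unfavored stream.  ``allocation`` is "fixed" (favored stream drawn once
    per trial) or "alternating" (favor follows the sign of a cosine at
    ``alternation_freq`` Hz).  ``swap_rate`` optionally swaps the reported
    targets to stress-test the pairing rule; ``first_confidence`` is the
    probability that the favored stream is reported first when both streams
    are reported.
    """

    sd_high: float = 8.0
    sd_low: float = 16.0
    allocation: str = "fixed"
    alternation_freq: float = 1.0  # Hz
    alternation_phase: float = 0.0  # degrees
    cue_resets_phase: bool = True
    swap_rate: float = 0.0
    first_confidence: float = 0.9

    def __post_init__(self) -> None:
        if not (0 < self.sd_high <= self.sd_low):
            raise ValueError("require 0 < sd_high <= sd_low")
        if self.allocation not in ("fixed", "alternating"):
            raise ValueError(f"unknown allocation {self.allocation!r}")
        if self.allocation == "alternating" and not self.alternation_freq > 0:
            raise ValueError("alternation_freq must be > 0 when alternating")


@dataclass(frozen=True)
class ExperimentDesign:
    """Trial-count structure of one experiment variant."""

    experiment: str  # exp1 | exp2 | exp3
    n_trials: int = 150
    soa_grid: tuple[float, ...] = ()
    cued_trials_per_cell: int = 36  # per SOA and probed stream (cue present)
    absent_trials_per_cell: int = 72  # per SOA (cue absent)
    cue_time: float = CUE_TIME_S


def design_for(name: str) -> ExperimentDesign:
    """Standard designs: exp1/exp2 (150 trials), exp3a/b/c (864 trials each)."""
    if name in ("exp1", "exp2"):
        return ExperimentDesign(experiment=name, n_trials=150)
    if name in EXP3_SOA_GRIDS:
        return ExperimentDesign(
            experiment="exp3", soa_grid=tuple(EXP3_SOA_GRIDS[name])
        )
    raise ValueError(f"unknown design {name!r}")


def favored_is_reference(
    model: ObserverModel, t: float | np.ndarray, t_cue: float | np.ndarray
) -> np.ndarray:
    """True where the phase-reference stream is favored at probe time ``t``.

    Favor follows cos(2*pi*f*(t - t_cue) + phase) > 0; at the cue the phase
    function starts at ``alternation_phase`` so the cued stream holds the
    resource first when the phase offset is 0.
    """
    ph = 2.0 * np.pi * model.alternation_freq * (np.asarray(t) - np.asarray(t_cue))
    return np.cos(ph + np.deg2rad(model.alternation_phase)) > 0


def simulate_experiment(
    model: ObserverModel,
    design: ExperimentDesign,
    trajectories: list[TrajectoryPair],
    rng: np.random.Generator | int | None = None,
    subject: int = 0,
) -> pd.DataFrame:
    """Simulate one subject's session; returns one row per trial.

    Targets are the probe-time hues of the supplied trajectory pairs (reused
    cyclically in shuffled order when the design needs more trials than pairs,
    mirroring the reuse of one pre-computed stimulus set across a session).
    The ``favored_stream`` column records the generative ground truth and is
    never consumed by any analysis.
    """
    if not trajectories:
        raise ValueError("trajectories must be non-empty")
    rng = np.random.default_rng(rng)

    if design.experiment in ("exp1", "exp2"):
        n = design.n_trials
        soa = np.full(n, np.nan)
        cue_present = np.zeros(n, dtype=bool)
        cued = np.array(["none"] * n, dtype=object)
        probed = (
            np.array(["both"] * n, dtype=object)
            if design.experiment == "exp1"
            else rng.choice(["a", "b"], size=n)
        )
    elif design.experiment == "exp3":
        if not design.soa_grid:
            raise ValueError("exp3 design requires an soa_grid")
        soas, cues, probes = [], [], []
        for t in design.soa_grid:
            for probe_cued in (True, False):  # cue-present: probed = cued / uncued
                soas += [t] * design.cued_trials_per_cell
                cues += [True] * design.cued_trials_per_cell
                probes += ["cued" if probe_cued else "uncued"] * design.cued_trials_per_cell
            soas += [t] * design.absent_trials_per_cell
            cues += [False] * design.absent_trials_per_cell
            probes += ["either"] * design.absent_trials_per_cell
        n = len(soas)
        order = rng.permutation(n)
        soa = np.asarray(soas)[order]
        cue_present = np.asarray(cues)[order]
        probe_role = np.asarray(probes, dtype=object)[order]
        cued = np.where(cue_present, rng.choice(["a", "b"], size=n), "none").astype(object)
        probed = np.empty(n, dtype=object)
        for i in range(n):
            if not cue_present[i]:
                probed[i] = rng.choice(["a", "b"])
            elif probe_role[i] == "cued":
                probed[i] = cued[i]
            else:
                probed[i] = "b" if cued[i] == "a" else "a"
    else:
        raise ValueError(f"unknown experiment {design.experiment!r}")

    pair_idx = np.resize(rng.permutation(len(trajectories)), n)
    target_a = np.empty(n)
    target_b = np.empty(n)
    for i in range(n):
        target_a[i], target_b[i], _ = probe_targets(trajectories[pair_idx[i]], rng=rng)

    # which stream holds the high-precision resource at probe time
    if model.allocation == "fixed":
        favored = np.where(rng.random(n) < 0.5, "a", "b").astype(object)
    else:
        # phase reference: the cued stream when a cue resets the phase,
        # otherwise a per-trial random-phase process (favor ~ Bernoulli(1/2))
        ref = np.where(cue_present, cued, rng.choice(["a", "b"], size=n)).astype(object)
        other = np.where(ref == "a", "b", "a").astype(object)
        t = np.where(np.isnan(soa), 0.0, soa)
        reset = cue_present & model.cue_resets_phase
        ref_favored = np.where(
            reset,
            favored_is_reference(model, t, design.cue_time),
            rng.random(n) < 0.5,
        )
        favored = np.where(ref_favored, ref, other).astype(object)

    sd_a = np.where(favored == "a", model.sd_high, model.sd_low)
    sd_b = np.where(favored == "b", model.sd_high, model.sd_low)
    err_a = np.rad2deg(rng.vonmises(0.0, 1.0 / np.deg2rad(sd_a) ** 2))
    err_b = np.rad2deg(rng.vonmises(0.0, 1.0 / np.deg2rad(sd_b) ** 2))

    report_a = np.mod(target_a + err_a, 360.0)
    report_b = np.mod(target_b + err_b, 360.0)

    response_1 = np.full(n, np.nan)
    response_2 = np.full(n, np.nan)
    if design.experiment == "exp1":
        fav_first = rng.random(n) < model.first_confidence
        first_is_a = np.where(fav_first, favored == "a", favored == "b")
        response_1 = np.where(first_is_a, report_a, report_b)
        response_2 = np.where(first_is_a, report_b, report_a)
        if model.swap_rate > 0:
            swap = rng.random(n) < model.swap_rate
            response_1, response_2 = (
                np.where(swap, response_2, response_1),
                np.where(swap, response_1, response_2),
            )
    else:
        response_1 = np.where(probed == "a", report_a, report_b)
        if model.swap_rate > 0:
            swap = rng.random(n) < model.swap_rate
            response_1 = np.where(swap, np.where(probed == "a", report_b, report_a), response_1)

    return pd.DataFrame(
        {
            "subject": subject,
            "trial_id": np.arange(n),
            "experiment": design.experiment,
            "soa": soa,
            "cue_present": cue_present,
            "cued_stream": cued,
            "probed_stream": probed,
            "target_a": target_a,
            "target_b": target_b,
            "response_1": response_1,
            "response_2": response_2 if design.experiment == "exp1" else np.nan,
            "favored_stream": favored,
        }
    )


def simulate_cohort(
    model: ObserverModel,
    design: ExperimentDesign,
    trajectories: list[TrajectoryPair],
    n_subjects: int,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Simulate ``n_subjects`` independent sessions with one shared stimulus set."""
    rng = np.random.default_rng(rng)
    frames = [
        simulate_experiment(model, design, trajectories, rng=rng, subject=s)
        for s in range(n_subjects)
    ]
    return pd.concat(frames, ignore_index=True)


def single_report_errors(records: pd.DataFrame) -> pd.Series:
    """Signed response-minus-target error of the probed stream (single report)."""
    probed_target = np.where(
        records["probed_stream"] == "a", records["target_a"], records["target_b"]
    )
    return pd.Series(
        circular_difference(records["response_1"].to_numpy(), probed_target),
        index=records.index,
        name="error",
    )


def targets_uniformity_check(records: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Kolmogorov-Smirnov uniformity checks on the probe-time targets.

    Tests each stream's target hues against circular uniform on [0, 360) and
    the inter-target distance against uniform on [60, 180] (the admissible
    range under the pairing constraint).  Returns {name: (D, p)}.
    """
    if len(records) < 20:
        raise InsufficientDataError("need at least 20 records for uniformity checks")
    out: dict[str, tuple[float, float]] = {}
    for col in ("target_a", "target_b"):
        u = np.mod(records[col].to_numpy(), 360.0) / 360.0
        res = stats.kstest(u, "uniform")
        out[col] = (float(res.statistic), float(res.pvalue))
    d = np.abs(
        circular_difference(records["target_a"].to_numpy(), records["target_b"].to_numpy())
    )
    res = stats.kstest((d - 60.0) / 120.0, "uniform")
    out["inter_target_distance"] = (float(res.statistic), float(res.pvalue))
    return out
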