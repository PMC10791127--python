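"""Target-response pairing for dual-report trials.

When a subject reports both streams, the two dial settings are not labeled:
each response must be assigned to one of the two target hues before errors
can be computed.  Two deterministic strategies are implemented:

* ``first_min`` — the first response goes to the target at minimum angular
  distance (assuming the first report is made with higher confidence), the
  second response to the remaining target.
* ``global_min`` — the smallest of the four target-response distances fixes
  the first assignment irrespective of report order.

Both strategies are bijective; ties (possible only on rounded data) break
toward target *a*, and for ``global_min`` toward the earlier response slot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stimulus import circular_difference

__all__ = ["ErrorSample", "assign_first_min", "assign_global_min", "pair_trials"]


@dataclass(frozen=True)
class ErrorSample:
    """One signed response-minus-target error with its assignment provenance."""

    error: float  # degrees in (-180, 180]
    trial_id: int = 0
    response_slot: str = "single"  # "1" | "2" | "single"
    assigned_target: str = "a"  # "a" | "b"


def _require_finite(targets, responses) -> None:
    vals = [*targets, *responses]
    if any(v is None or not np.isfinite(v) for v in vals):
        raise ValueError("pairing requires two targets and two finite responses")


def assign_first_min(
    targets: tuple[float, float],
    responses: tuple[float, float],
    trial_id: int = 0,
) -> tuple[ErrorSample, ErrorSample]:
    """Pair the first response with its nearest target, the second with the rest."""
    _require_finite(targets, responses)
    t_a, t_b = targets
    r1, r2 = responses
    if abs(circular_difference(r1, t_a)) <= abs(circular_difference(r1, t_b)):
        first_tgt, second_tgt = ("a", t_a), ("b", t_b)
    else:
        first_tgt, second_tgt = ("b", t_b), ("a", t_a)
    return (
        ErrorSample(circular_difference(r1, first_tgt[1]), trial_id, "1", first_tgt[0]),
        ErrorSample(circular_difference(r2, second_tgt[1]), trial_id, "2", second_tgt[0]),
    )


def assign_global_min(
    targets: tuple[float, float],
    responses: tuple[float, float],
    trial_id: int = 0,
) -> tuple[ErrorSample, ErrorSample]:
    """Pair by the overall minimum of the four target-response distances."""
    _require_finite(targets, responses)
    t = {"a": targets[0], "b": targets[1]}
    r = {"1": responses[0], "2": responses[1]}
    # lexicographic candidate order implements the deterministic tie-break
    candidates = [("1", "a"), ("1", "b"), ("2", "a"), ("2", "b")]
    dists = [abs(circular_difference(r[slot], t[tgt])) for slot, tgt in candidates]
    slot0, tgt0 = candidates[int(np.argmin(dists))]
    slot1 = "2" if slot0 == "1" else "1"
    tgt1 = "b" if tgt0 == "a" else "a"
    samples = sorted(
        [
            ErrorSample(circular_difference(r[slot0], t[tgt0]), trial_id, slot0, tgt0),
            ErrorSample(circular_difference(r[slot1], t[tgt1]), trial_id, slot1, tgt1),
        ],
        key=lambda s: s.response_slot,
    )
    return samples[0], samples[1]


def pair_trials(records: pd.DataFrame, strategy: str = "first_min") -> pd.DataFrame:
    """Apply a pairing strategy to every dual-report trial of a trial table.

    Returns a long-format frame with one row per (trial, response), columns
    ``subject, trial_id, response_slot, assigned_target, error``.
    """
    assign = {"first_min": assign_first_min, "global_min": assign_global_min}.get(strategy)
    if assign is None:
        raise ValueError(f"unknown pairing strategy {strategy!r}")
    rows = []
    for rec in records.itertuples(index=False):
        pair = assign(
            (rec.target_a, rec.target_b),
            (rec.response_1, rec.response_2),
            trial_id=int(rec.trial_id),
        )
        for s in pair:
            rows.append(
                {
                    "subject": getattr(rec, "subject", 0),
                    "trial_id": s.trial_id,
                    "response_slot": s.response_slot,
                    "assigned_target": s.assigned_target,
                    "error": s.error,
                }
            )
    return pd.DataFrame(rows)
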