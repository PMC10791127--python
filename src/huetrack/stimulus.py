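"""Paired hue-circle trajectory generation and stimulus statistics.

Two superimposed color streams each follow a constrained random walk through
a circular, iso-luminant hue space: 1 degree per frame at 60 frames/s for
480 frames (8 s), with the walk direction reverting at random intervals of
30-100 frames.  Trajectories are paired under the constraint that the two
streams keep a circular distance of at least 60 degrees at every frame, so
the two colors can never be perceptually confused while their histories
remain mutually unpredictable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ColorCircle",
    "HueTrajectory",
    "TrajectoryPair",
    "StimulusStats",
    "NoAdmissiblePairError",
    "circular_difference",
    "circular_distance",
    "generate_trajectory",
    "generate_trajectory_pool",
    "pair_trajectories",
    "make_trial_pairs",
    "hue_to_color",
    "probe_targets",
    "stimulus_statistics",
]

DEFAULT_N_FRAMES = 480
DEFAULT_FRAME_RATE = 60.0
DEFAULT_SPEED = 1.0
DEFAULT_INTERVAL_RANGE = (30, 100)
DEFAULT_MIN_DIST = 60.0
#: Trial length is truncated uniformly in this frame range (6-8 s at 60 Hz),
#: so the probe-time target hue differs across repetitions of one trajectory.
TRIAL_LENGTH_RANGE = (360, 480)


class NoAdmissiblePairError(RuntimeError):
    """Raised when no trajectory pair satisfies the separation constraint."""


@dataclass(frozen=True)
class ColorCircle:
    """Iso-luminant hue circle in CIE u'v' chromaticity space.

    The circle is centered on the white point and parameterized by hue angle;
    0 degrees lies on the +u' axis, counter-clockwise positive.
    """

    white_u: float = 0.1978
    white_v: float = 0.4683
    luminance: float = 14.5  # cd/m^2
    radius: float = 0.0576  # chromaticity units

    def __post_init__(self) -> None:
        if not (self.radius > 0 and self.luminance > 0):
            raise ValueError("ColorCircle requires radius > 0 and luminance > 0")


@dataclass
class HueTrajectory:
    """One stream's hue angle per frame, with its direction-reversal frames."""

    angles: np.ndarray  # degrees in [0, 360)
    frame_rate: float = DEFAULT_FRAME_RATE
    speed: float = DEFAULT_SPEED
    reversal_frames: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.angles)

    @property
    def duration_s(self) -> float:
        return len(self.angles) / self.frame_rate


@dataclass
class TrajectoryPair:
    """Two trajectories jointly admissible under the minimum-distance rule."""

    stream_a: HueTrajectory
    stream_b: HueTrajectory

    def min_distance(self) -> float:
        n = min(len(self.stream_a), len(self.stream_b))
        return float(
            np.min(circular_distance(self.stream_a.angles[:n], self.stream_b.angles[:n]))
        )


@dataclass
class StimulusStats:
    combined_reversals_mean: float
    combined_reversals_sd: float
    inter_reversal_mean_s: float
    inter_reversal_sd_s: float
    distance_bin_edges: np.ndarray  # degrees
    distance_histogram: np.ndarray  # density over [min_dist, 180]
    intersection_fraction: float  # mean over trials
    intersection_fraction_sd: float


def circular_difference(a, b):
    """Signed shortest arc from ``b`` to ``a`` in degrees, in (-180, +180].

    This is the canonical convention for every angular difference in the
    pipeline, including response-minus-target report errors.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("circular_difference requires finite inputs")
    d = np.mod(a - b, 360.0)
    out = np.where(d > 180.0, d - 360.0, d)
    if out.ndim == 0:
        return float(out)
    return out


def circular_distance(a, b):
    """Unsigned circular distance in degrees, in [0, 180]."""
    return np.abs(circular_difference(a, b))


def generate_trajectory(
    n_frames: int = DEFAULT_N_FRAMES,
    speed: float = DEFAULT_SPEED,
    interval_range: tuple[int, int] = DEFAULT_INTERVAL_RANGE,
    reversal_prob: float = 1.0,
    rng: np.random.Generator | int | None = None,
    frame_rate: float = DEFAULT_FRAME_RATE,
) -> HueTrajectory:
    """Generate one constrained random-walk hue trajectory.

    The walk starts at a uniformly random hue and moves ``speed`` degrees per
    frame.  Candidate reversal frames are spaced by independent uniform integer
    draws from ``interval_range``; at each candidate the direction reverts with
    probability ``reversal_prob``.  Deterministic given the generator state.
    """
    lo, hi = interval_range
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid interval_range {interval_range!r}: need 1 <= lo <= hi")
    if not (0.0 <= reversal_prob <= 1.0):
        raise ValueError("reversal_prob must lie in [0, 1]")
    rng = np.random.default_rng(rng)

    start = rng.uniform(0.0, 360.0)
    direction = 1.0 if rng.random() < 0.5 else -1.0

    candidates: list[int] = []
    f = 0
    while True:
        f += int(rng.integers(lo, hi + 1))
        if f >= n_frames:
            break
        candidates.append(f)
    reversal_frames = [c for c in candidates if rng.random() < reversal_prob]

    # sign of the step leaving frame s flips at every reversal frame <= s
    flips = np.zeros(n_frames - 1, dtype=int)
    for r in reversal_frames:
        flips[r:] += 1
    signs = direction * (-1.0) ** flips
    angles = np.empty(n_frames)
    angles[0] = start
    angles[1:] = np.mod(start + speed * np.cumsum(signs), 360.0)
    return HueTrajectory(
        angles=angles,
        frame_rate=frame_rate,
        speed=speed,
        reversal_frames=reversal_frames,
    )


def generate_trajectory_pool(
    n: int,
    rng: np.random.Generator | int | None = None,
    **kwargs,
) -> list[HueTrajectory]:
    """Generate ``n`` independent trajectories (the offline pre-computed set)."""
    rng = np.random.default_rng(rng)
    return [generate_trajectory(rng=rng, **kwargs) for _ in range(n)]


def pair_trajectories(
    pool: list[HueTrajectory],
    min_dist: float = DEFAULT_MIN_DIST,
    rng: np.random.Generator | int | None = None,
) -> TrajectoryPair:
    """Pick an admissible pair from ``pool`` by greedy scan in random order.

    The only criterion is the per-frame minimum-distance constraint, so pairing
    never couples the histories of the two streams beyond their separation.
    """
    if not pool:
        raise ValueError("pool must be non-empty")
    if not (0.0 < min_dist <= 180.0):
        raise ValueError("min_dist must lie in (0, 180]")
    rng = np.random.default_rng(rng)
    order = rng.permutation(len(pool))
    for i, j in itertools.combinations(order, 2):
        a, b = pool[i], pool[j]
        n = min(len(a), len(b))
        if np.all(circular_distance(a.angles[:n], b.angles[:n]) >= min_dist):
            return TrajectoryPair(stream_a=a, stream_b=b)
    raise NoAdmissiblePairError(
        f"no pair in pool of {len(pool)} maintains {min_dist} deg at every frame"
    )


def make_trial_pairs(
    n_trials: int,
    min_dist: float = DEFAULT_MIN_DIST,
    rng: np.random.Generator | int | None = None,
    max_attempts_per_pair: int = 2000,
    **trajectory_kwargs,
) -> list[TrajectoryPair]:
    """Build ``n_trials`` admissible pairs from freshly generated trajectories.

    Rejection sampling: draw two independent trajectories and keep them iff
    they satisfy the constraint, which preserves independence of the surviving
    histories conditional on admissibility.
    """
    rng = np.random.default_rng(rng)
    pairs: list[TrajectoryPair] = []
    for _ in range(n_trials):
        for _attempt in range(max_attempts_per_pair):
            a = generate_trajectory(rng=rng, **trajectory_kwargs)
            b = generate_trajectory(rng=rng, **trajectory_kwargs)
            n = min(len(a), len(b))
            if np.all(circular_distance(a.angles[:n], b.angles[:n]) >= min_dist):
                pairs.append(TrajectoryPair(stream_a=a, stream_b=b))
                break
        else:
            raise NoAdmissiblePairError(
                f"failed to draw an admissible pair in {max_attempts_per_pair} attempts"
            )
    return pairs


def hue_to_color(angle, circle: ColorCircle = ColorCircle()):
    """Map hue angle to (u', v', luminance) on the iso-luminant color circle."""
    rad = np.deg2rad(np.asarray(angle, dtype=float))
    u = circle.white_u + circle.radius * np.cos(rad)
    v = circle.white_v + circle.radius * np.sin(rad)
    lum = np.broadcast_to(circle.luminance, u.shape).copy()
    if u.ndim == 0:
        return float(u), float(v), float(lum)
    return u, v, lum


def probe_targets(
    pair: TrajectoryPair,
    rng: np.random.Generator | int | None = None,
    length_range: tuple[int, int] = TRIAL_LENGTH_RANGE,
) -> tuple[float, float, int]:
    """Truncate a pair at a random trial length and return probe-time hues.

    Returns ``(target_a, target_b, n_frames_used)``; the targets are the last
    hue of each stream before the probe.
    """
    rng = np.random.default_rng(rng)
    lo, hi = length_range
    hi = min(hi, len(pair.stream_a), len(pair.stream_b))
    n_used = int(rng.integers(lo, hi + 1))
    return (
        float(pair.stream_a.angles[n_used - 1]),
        float(pair.stream_b.angles[n_used - 1]),
        n_used,
    )


def stimulus_statistics(
    pairs: list[TrajectoryPair],
    min_dist: float = DEFAULT_MIN_DIST,
    bin_width: float = 1.0,
) -> StimulusStats:
    """Descriptive statistics of a set of trial pairs.

    Combined reversal counts (both streams per trial), pooled inter-reversal
    intervals in seconds, the per-frame inter-stream distance histogram over
    [min_dist, 180], and the per-trial intersection of visited integer hues.
    """
    if not pairs:
        raise ValueError("pairs must be non-empty")
    counts = []
    intervals_s = []
    distances = []
    intersections = []
    for p in pairs:
        rev = sorted(p.stream_a.reversal_frames) + sorted(p.stream_b.reversal_frames)
        counts.append(len(rev))
        combined = np.sort(np.asarray(rev, dtype=float))
        if len(combined) >= 2:
            intervals_s.extend(np.diff(combined) / p.stream_a.frame_rate)
        n = min(len(p.stream_a), len(p.stream_b))
        distances.append(circular_distance(p.stream_a.angles[:n], p.stream_b.angles[:n]))
        hues_a = set(np.mod(np.rint(p.stream_a.angles[:n]), 360).astype(int))
        hues_b = set(np.mod(np.rint(p.stream_b.angles[:n]), 360).astype(int))
        shared = len(hues_a & hues_b)
        intersections.append(0.5 * (shared / len(hues_a) + shared / len(hues_b)))

    counts = np.asarray(counts, dtype=float)
    intervals_s = np.asarray(intervals_s, dtype=float)
    distances = np.concatenate(distances)
    edges = np.arange(min_dist, 180.0 + bin_width, bin_width)
    bin_counts, edges = np.histogram(distances, bins=edges)
    total = bin_counts.sum()
    hist = bin_counts / (total * np.diff(edges)) if total else bin_counts.astype(float)
    ddof = 1 if len(counts) > 1 else 0
    return StimulusStats(
        combined_reversals_mean=float(np.mean(counts)),
        combined_reversals_sd=float(np.std(counts, ddof=ddof)),
        inter_reversal_mean_s=float(np.mean(intervals_s)) if len(intervals_s) else float("nan"),
        inter_reversal_sd_s=(
            float(np.std(intervals_s, ddof=1)) if len(intervals_s) > 1 else float("nan")
        ),
        distance_bin_edges=edges,
        distance_histogram=hist,
        intersection_fraction=float(np.mean(intersections)),
        intersection_fraction_sd=(
            float(np.std(intersections, ddof=1)) if len(intersections) > 1 else 0.0
        ),
    )
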