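"""SOA time-courses of report precision and their spectral phase analysis.

In the cued experiment the luminance cue identifies the two streams, so no
mixture is needed: per subject, condition (cue-absent trials, cued stream of
cue-present trials, uncued stream of cue-present trials) and probe time
(six SOAs), precision is the scale of a half-normal fit to absolute report
errors.  The per-subject matrices are z-normalized, the cued/uncued
time-courses Fourier-transformed (mean-removed, zero-padded), and the
cued-minus-uncued phase differences tested across subjects for phase locking
(PLV) and for concentration at 0 deg (in-phase) or 180 deg (anti-phase) with
v-tests at the peak phase-lock frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .observer import single_report_errors

__all__ = [
    "TimecourseMatrix",
    "SpectralResult",
    "CohortSpectral",
    "MissingCellError",
    "DegenerateSubjectError",
    "CONDITIONS",
    "fit_halfnormal_sd",
    "znormalize_subject",
    "spectral_phase",
    "plv_across_subjects",
    "v_test",
    "build_timecourses",
    "analyze_alternation",
]

CONDITIONS = ("cue_absent", "cued_stream", "uncued_stream")


class MissingCellError(ValueError):
    pass


class DegenerateSubjectError(ValueError):
    pass


@dataclass
class TimecourseMatrix:
    """Per-subject precision estimates: (n_subjects, n_conditions, n_soa)."""

    values: np.ndarray
    soa_grid: np.ndarray  # seconds, strictly increasing, equally spaced
    subjects: list
    conditions: tuple[str, ...] = CONDITIONS
    normalized: bool = False
    cell_counts: np.ndarray | None = None

    @property
    def dt(self) -> float:
        return float(self.soa_grid[1] - self.soa_grid[0])


@dataclass
class SpectralResult:
    """Single-subject spectrum of one pair of time-courses."""

    freqs: np.ndarray  # Hz per rFFT bin
    phase_diff: np.ndarray  # degrees in (-180, 180], per bin
    amplitude_a: np.ndarray
    amplitude_b: np.ndarray


@dataclass
class CohortSpectral:
    """Across-subject phase statistics of the cued/uncued time-courses."""

    freqs: np.ndarray
    phase_diffs: np.ndarray  # (n_subjects, n_bins) degrees
    plv: np.ndarray  # per bin, in [0, 1]
    peak_bin: int
    peak_freq: float
    v_test_0: tuple[float, float, float, float]  # (V, u, p, mean_angle)
    v_test_180: tuple[float, float, float, float]


def fit_halfnormal_sd(abs_errors) -> float:
    """Maximum-likelihood scale of a zero-location half-normal.

    For absolute errors x (degrees in [0, 180]) the MLE is
    sqrt(mean(x^2)); using absolute differences disregards negligible
    clockwise/counter-clockwise hue biases.
    """
    x = np.asarray(abs_errors, dtype=float)
    if x.size == 0:
        raise ValueError("abs_errors must be non-empty")
    if np.any((x < 0) | (x > 180)):
        raise ValueError("absolute errors must lie in [0, 180] degrees")
    return float(np.sqrt(np.mean(x**2)))


def znormalize_subject(matrix: TimecourseMatrix) -> TimecourseMatrix:
    """Z-score every subject's cells against that subject's own mean and SD.

    Removes large between-subject differences in overall performance;
    location and positive scaling of one subject's raw cells leave the
    normalized cells unchanged.
    """
    if matrix.normalized:
        raise ValueError("matrix is already normalized")
    vals = matrix.values.astype(float).copy()
    for s in range(vals.shape[0]):
        cells = vals[s]
        sd = np.nanstd(cells, ddof=1)
        if not sd > 0:
            raise DegenerateSubjectError(
                f"subject {matrix.subjects[s]!r} has zero within-subject SD"
            )
        vals[s] = (cells - np.nanmean(cells)) / sd
    return replace(matrix, values=vals, normalized=True)


def _wrap_deg(x):
    d = np.mod(np.asarray(x, dtype=float), 360.0)
    return np.where(d > 180.0, d - 360.0, d)


def spectral_phase(
    timecourse_a,
    timecourse_b,
    dt: float,
    pad_to: int = 16,
) -> SpectralResult:
    """Discrete Fourier spectra of two short time-courses and their phase lag.

    Both series are mean-removed and zero-padded to ``pad_to`` points, so bin
    k sits at k/(pad_to*dt) Hz; the phase difference is phase(a) - phase(b)
    wrapped to (-180, 180].
    """
    a = np.asarray(timecourse_a, dtype=float)
    b = np.asarray(timecourse_b, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("time-courses must be 1-D with matching length")
    if len(a) > pad_to:
        raise ValueError("pad_to must be >= series length")
    fa = np.fft.rfft(a - a.mean(), n=pad_to)
    fb = np.fft.rfft(b - b.mean(), n=pad_to)
    freqs = np.arange(pad_to // 2 + 1) / (pad_to * dt)
    phase_diff = _wrap_deg(np.rad2deg(np.angle(fa) - np.angle(fb)))
    return SpectralResult(
        freqs=freqs,
        phase_diff=phase_diff,
        amplitude_a=np.abs(fa),
        amplitude_b=np.abs(fb),
    )


def plv_across_subjects(phase_diffs_deg) -> float:
    """Phase-locking value: modulus of the mean unit phasor across subjects."""
    ph = np.deg2rad(np.asarray(phase_diffs_deg, dtype=float))
    if ph.size < 2:
        raise ValueError("need at least 2 phases")
    return float(np.abs(np.mean(np.exp(1j * ph))))


def v_test(angles_deg, theta0_deg: float) -> tuple[float, float, float, float]:
    """Modified Rayleigh (v-) test for concentration at a specified direction.

    V = n * Rbar * cos(mean - theta0); u = V * sqrt(2/n) is referred to the
    upper tail of the standard normal.  Returns (V, u, p, mean_angle_deg).
    """
    ang = np.deg2rad(np.asarray(angles_deg, dtype=float))
    n = ang.size
    if n < 5:
        raise ValueError("need at least 5 angles")
    z = np.mean(np.exp(1j * ang))
    rbar = np.abs(z)
    mean_angle = np.angle(z)
    v = n * rbar * np.cos(mean_angle - np.deg2rad(theta0_deg))
    u = v * np.sqrt(2.0 / n)
    p = float(stats.norm.sf(u))
    return float(v), float(u), p, float(_wrap_deg(np.rad2deg(mean_angle)))


def build_timecourses(
    records: pd.DataFrame,
    normalize: bool = True,
) -> TimecourseMatrix:
    """Per-SOA half-normal precision estimates from cued-experiment records.

    Groups absolute single-report errors by subject x condition x SOA
    (conditions: cue-absent trials; cued and uncued stream of cue-present
    trials), fits the half-normal scale per cell, and z-normalizes each
    subject unless ``normalize=False``.  An empty cell raises
    :class:`MissingCellError` naming the cell.
    """
    records = records.copy()
    records["abs_error"] = np.abs(single_report_errors(records))
    probed_cued = records["probed_stream"] == records["cued_stream"]
    cond = np.where(
        ~records["cue_present"],
        "cue_absent",
        np.where(probed_cued, "cued_stream", "uncued_stream"),
    )
    records["condition"] = cond

    subjects = sorted(records["subject"].unique())
    soa_grid = np.sort(records["soa"].unique())
    vals = np.full((len(subjects), len(CONDITIONS), len(soa_grid)), np.nan)
    counts = np.zeros_like(vals, dtype=int)
    grouped = records.groupby(["subject", "condition", "soa"])["abs_error"]
    cells = grouped.apply(lambda g: (fit_halfnormal_sd(g.to_numpy()), len(g)))
    for (subj, c, t), (sd, cnt) in cells.items():
        i = subjects.index(subj)
        j = CONDITIONS.index(c)
        k = int(np.argmin(np.abs(soa_grid - t)))
        vals[i, j, k] = sd
        counts[i, j, k] = cnt
    if np.isnan(vals).any():
        i, j, k = map(int, np.argwhere(np.isnan(vals))[0])
        raise MissingCellError(
            f"no trials for subject={subjects[i]!r}, condition={CONDITIONS[j]!r}, "
            f"soa={soa_grid[k]:g}"
        )
    matrix = TimecourseMatrix(
        values=vals,
        soa_grid=soa_grid,
        subjects=subjects,
        normalized=False,
        cell_counts=counts,
    )
    return znormalize_subject(matrix) if normalize else matrix


def analyze_alternation(
    matrix: TimecourseMatrix,
    pad_to: int = 16,
    band: tuple[float, float] | None = None,
) -> CohortSpectral:
    """Across-subject phase analysis of the cued vs uncued precision series.

    Computes each subject's cued-minus-uncued phase difference per frequency
    bin, the across-subject PLV per bin, selects the peak-PLV bin within the
    resolvable band (default: one cycle per observation window, 1/(n*dt), up
    to the Nyquist frequency 1/(2*dt)), and runs v-tests of the phase
    differences at that bin against 0 and 180 degrees.
    """
    i_cued = matrix.conditions.index("cued_stream")
    i_uncued = matrix.conditions.index("uncued_stream")
    n_subj = matrix.values.shape[0]
    specs = [
        spectral_phase(
            matrix.values[s, i_cued], matrix.values[s, i_uncued], matrix.dt, pad_to
        )
        for s in range(n_subj)
    ]
    freqs = specs[0].freqs
    phase_diffs = np.stack([sp.phase_diff for sp in specs])
    plv = np.array([plv_across_subjects(phase_diffs[:, k]) for k in range(len(freqs))])

    if band is None:
        n_soa = matrix.values.shape[2]
        band = (1.0 / (n_soa * matrix.dt), 1.0 / (2.0 * matrix.dt))
    candidate = (freqs > 0) & (freqs >= band[0]) & (freqs <= band[1])
    # the Nyquist bin of a real signal carries only a 0/180-deg phase, which
    # makes its PLV trivially high; never select it as the peak
    candidate &= freqs < 0.5 / matrix.dt - 1e-12
    if not candidate.any():
        raise ValueError("no frequency bins inside the requested band")
    masked = np.where(candidate, plv, -np.inf)
    peak = int(np.argmax(masked))
    return CohortSpectral(
        freqs=freqs,
        phase_diffs=phase_diffs,
        plv=plv,
        peak_bin=peak,
        peak_freq=float(freqs[peak]),
        v_test_0=v_test(phase_diffs[:, peak], 0.0),
        v_test_180=v_test(phase_diffs[:, peak], 180.0),
    )
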