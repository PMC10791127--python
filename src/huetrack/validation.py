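"""Monte-Carlo, permutation and regression validation of the precision fits.

Four estimator-level checks:

* :func:`monte_carlo_null` — does a subject's fitted precision pair look like
  pairs refit from data simulated at those very precisions?  Simulated
  responses are built on the subject's actual targets, routed through the
  same pairing rule, refit with the constrained mixture, and the resulting
  cloud summarized by a 4-parameter (no-covariance) 2D Gaussian.
* :func:`equal_deviation_ratio_null` — the upward bias of the fitted
  high/low SD ratio when the two mixture halves truly share one deviation;
  quantifies how large an observed ratio must be before it means anything.
* :func:`permutation_consistency` — are per-subject precision pairs in two
  conditions closer than chance, measured by the sum of per-subject Euclidean
  distances against random re-assignments of subjects?
* :func:`regression_through_origin` — the zero-intercept regression
  p_low = a * p_high used to summarize the precision ratio across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from warnings import warn

import numpy as np
from scipy import stats

from .pairing import assign_first_min
from .stimulus import circular_difference
from .vmmixture import PrecisionPair, fit_constrained_mixture, kappa_from_vm_sd

__all__ = [
    "NullDistribution2D",
    "RatioNullResult",
    "InsufficientSimulationWarning",
    "monte_carlo_null",
    "null_p_value",
    "empirical_tail_p",
    "equal_deviation_ratio_null",
    "permutation_consistency",
    "regression_through_origin",
    "ks_uniform_circular",
]


class InsufficientSimulationWarning(UserWarning):
    pass


@dataclass
class NullDistribution2D:
    """4-parameter Gaussian summary of simulated precision-pair clouds."""

    mean_precise: float
    mean_imprecise: float
    sd_precise_axis: float
    sd_imprecise_axis: float
    n_sim: int
    samples: np.ndarray  # (n_sim, 2): (sd_precise, sd_imprecise)


@dataclass
class RatioNullResult:
    ratios: np.ndarray
    median_ratio: float
    reference_ratio: float
    frac_exceeding: float


def _fit_ratio_dataset(errors, n_restarts, rng):
    _, pair = fit_constrained_mixture(errors, n_restarts=n_restarts, rng=rng)
    return pair


def monte_carlo_null(
    targets,
    sd_pair: PrecisionPair,
    n_sim: int = 1000,
    design: str = "exp1",
    rng: np.random.Generator | int | None = None,
    n_restarts: int = 5,
    repair: bool = True,
) -> NullDistribution2D:
    """Null distribution of refitted precision pairs at the observed precisions.

    ``targets`` is an (n_trials, 2) array of the subject's probe-time target
    hues for ``design="exp1"`` (two responses per trial, re-passed through the
    pairing rule when ``repair``), or a length-n array for ``design="exp2"``
    (one response per trial, stream membership random).
    """
    if n_sim < 100:
        warn("n_sim < 100 gives an unstable 2D-Gaussian null", InsufficientSimulationWarning)
    rng = np.random.default_rng(rng)
    targets = np.asarray(targets, dtype=float)
    sds = np.array([sd_pair.sd_precise, sd_pair.sd_imprecise])
    kappas = kappa_from_vm_sd(sds)

    samples = np.empty((n_sim, 2))
    for s in range(n_sim):
        if design == "exp1":
            n_tr = targets.shape[0]
            precise_is_a = rng.random(n_tr) < 0.5
            k_a = np.where(precise_is_a, kappas[0], kappas[1])
            k_b = np.where(precise_is_a, kappas[1], kappas[0])
            resp_a = np.mod(targets[:, 0] + np.rad2deg(rng.vonmises(0.0, k_a)), 360.0)
            resp_b = np.mod(targets[:, 1] + np.rad2deg(rng.vonmises(0.0, k_b)), 360.0)
            if repair:
                a_first = rng.random(n_tr) < 0.5
                errors = []
                for i in range(n_tr):
                    r1, r2 = (
                        (resp_a[i], resp_b[i]) if a_first[i] else (resp_b[i], resp_a[i])
                    )
                    e1, e2 = assign_first_min(
                        (targets[i, 0], targets[i, 1]), (r1, r2), trial_id=i
                    )
                    errors += [e1.error, e2.error]
                errors = np.asarray(errors)
            else:
                errors = np.concatenate(
                    [
                        circular_difference(resp_a, targets[:, 0]),
                        circular_difference(resp_b, targets[:, 1]),
                    ]
                )
        elif design == "exp2":
            n_tr = targets.shape[0]
            precise = rng.random(n_tr) < 0.5
            k = np.where(precise, kappas[0], kappas[1])
            errors = np.rad2deg(rng.vonmises(0.0, k))
        else:
            raise ValueError(f"unknown design {design!r}")
        pair = _fit_ratio_dataset(errors, n_restarts, rng)
        samples[s] = (pair.sd_precise, pair.sd_imprecise)

    return NullDistribution2D(
        mean_precise=float(samples[:, 0].mean()),
        mean_imprecise=float(samples[:, 1].mean()),
        sd_precise_axis=float(samples[:, 0].std(ddof=1)),
        sd_imprecise_axis=float(samples[:, 1].std(ddof=1)),
        n_sim=n_sim,
        samples=samples,
    )


def _standardized_r2(observed: PrecisionPair, null: NullDistribution2D) -> float:
    if null.sd_precise_axis <= 0 or null.sd_imprecise_axis <= 0:
        raise ValueError("degenerate null: zero axis SD")
    return float(
        ((observed.sd_precise - null.mean_precise) / null.sd_precise_axis) ** 2
        + ((observed.sd_imprecise - null.mean_imprecise) / null.sd_imprecise_axis) ** 2
    )


def null_p_value(observed: PrecisionPair, null: NullDistribution2D) -> float:
    """Position of the observed pair within the Gaussian null.

    The squared axis-standardized radius is referred to its 2-df chi-square
    distribution; p = 1 means the observed pair sits at the null mean.
    """
    return float(stats.chi2.sf(_standardized_r2(observed, null), df=2))


def empirical_tail_p(observed: PrecisionPair, null: NullDistribution2D) -> float:
    """Tail proportion of the simulated cloud itself (add-one rule)."""
    r2_obs = _standardized_r2(observed, null)
    r2_sim = (
        (null.samples[:, 0] - null.mean_precise) / null.sd_precise_axis
    ) ** 2 + ((null.samples[:, 1] - null.mean_imprecise) / null.sd_imprecise_axis) ** 2
    return float((1 + np.sum(r2_sim >= r2_obs)) / (null.n_sim + 1))


def equal_deviation_ratio_null(
    sd: float = 15.0,
    n_errors: int = 300,
    n_sim: int = 1000,
    rng: np.random.Generator | int | None = None,
    reference_ratio: float = 1.928,
    n_restarts: int = 5,
) -> RatioNullResult:
    """Ratio bias of the constrained mixture when both halves share one SD.

    Each simulated dataset draws ``n_errors`` signed errors from a single
    von Mises centered at 0 with deviation ``sd`` degrees, fits the
    constrained mixture, and records the high/low SD ratio.  Returns the
    ratio distribution, its median, and the fraction strictly exceeding
    ``reference_ratio``.
    """
    if not sd > 0:
        raise ValueError("sd must be > 0")
    rng = np.random.default_rng(rng)
    kappa = kappa_from_vm_sd(sd)
    ratios = np.empty(n_sim)
    for s in range(n_sim):
        errors = np.rad2deg(rng.vonmises(0.0, kappa, size=n_errors))
        ratios[s] = _fit_ratio_dataset(errors, n_restarts, rng).ratio
    return RatioNullResult(
        ratios=ratios,
        median_ratio=float(np.median(ratios)),
        reference_ratio=reference_ratio,
        frac_exceeding=float(np.mean(ratios > reference_ratio)),
    )


def permutation_consistency(
    pairs_x,
    pairs_y,
    n_perm: int = 10000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Consistency of per-subject precision pairs across two conditions.

    Statistic: sum over subjects of the Euclidean distance between subject
    s's (sd_precise, sd_imprecise) point in x and in y.  The null permutes
    which subject of y each subject of x is compared with; p is the
    proportion of permuted sums <= the observed sum, counting the identity
    permutation (add-one rule), so small p = more consistent than chance.
    """
    x = np.asarray(pairs_x, dtype=float)
    y = np.asarray(pairs_y, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("pairs_x and pairs_y must both be (n_subjects, 2)")
    n = x.shape[0]
    if n < 5:
        raise ValueError("need at least 5 subjects")
    rng = np.random.default_rng(rng)
    dmat = np.linalg.norm(x[:, None, :] - y[None, :, :], axis=2)  # (n, n)
    observed = float(np.trace(dmat))
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    perm_sums = dmat[np.arange(n)[None, :], perms].sum(axis=1)
    p = float((1 + np.sum(perm_sums <= observed)) / (n_perm + 1))
    return observed, p


def regression_through_origin(x, y) -> tuple[float, float, float, tuple[int, int]]:
    """Zero-intercept regression y = a*x with its F-test.

    Returns ``(a, F, p, (1, n-1))`` where a = sum(xy)/sum(x^2) and F compares
    the regression sum of squares against the residual on n-1 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need matched x, y with at least 3 subjects")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("x must not be all zero")
    a = float(np.sum(x * y) / sxx)
    fitted = a * x
    ss_reg = float(np.sum(fitted**2))
    ss_res = float(np.sum((y - fitted) ** 2))
    n = len(x)
    df = (1, n - 1)
    if ss_res == 0:
        return a, float("inf"), 0.0, df
    f = ss_reg / (ss_res / (n - 1))
    p = float(stats.f.sf(f, *df))
    return a, float(f), p, df


def ks_uniform_circular(angles) -> tuple[float, float]:
    """Kolmogorov-Smirnov test of hue angles against uniform on [0, 360)."""
    angles = np.asarray(angles, dtype=float)
    if len(angles) < 10:
        raise ValueError("need at least 10 angles")
    res = stats.kstest(np.mod(angles, 360.0) / 360.0, "uniform")
    return float(res.statistic), float(res.pvalue)
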