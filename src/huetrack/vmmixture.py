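"""Constrained two-component von Mises mixture of report errors.

The pooled signed errors of a session mix responses governed by two latent
precision resources.  Because exactly one of the two resources underlies each
report and stream identity is unknowable from a single trial, the mixture is
constrained: both component weights are fixed at 0.5 and both means are
boxed to 0 +/- 10 degrees (absorbing small clockwise/counter-clockwise hue
biases).  Precision is reported as the von Mises dispersion sd = sqrt(1/kappa)
(in radians, converted to degrees), so the pair of fitted kappas yields a
high-precision and a low-precision SD and their ratio.

Fitting is expectation-maximization with the M-step kappa update obtained by
inverting the mean-resultant-length relation A(kappa) = I1(kappa)/I0(kappa)
(Best-Fisher starting value plus Newton refinement).  Restarts run as one
vectorized EM over jittered initializations; the best final log-likelihood
wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import i0e, i1e

__all__ = [
    "VonMisesComponent",
    "VonMisesMixtureFit",
    "PrecisionPair",
    "DegenerateFitWarning",
    "vm_sd_from_kappa",
    "kappa_from_vm_sd",
    "mixture_loglik",
    "fit_constrained_mixture",
]

KAPPA_MIN = 1e-3
KAPPA_MAX = 1e4


class DegenerateFitWarning(UserWarning):
    """Emitted when the data are so concentrated that kappa hits its cap."""


@dataclass(frozen=True)
class VonMisesComponent:
    mu: float  # degrees, |mu| <= mu_bound
    kappa: float  # concentration, dimensionless
    weight: float = 0.5


@dataclass
class VonMisesMixtureFit:
    components: tuple[VonMisesComponent, VonMisesComponent]
    loglik: float  # nats, density on the radian scale
    n: int
    responsibilities: np.ndarray  # (n, 2), rows sum to 1
    converged: bool
    n_iter: int


@dataclass(frozen=True)
class PrecisionPair:
    """Ordered precision SDs of the two components and their ratio."""

    sd_precise: float  # degrees, smaller SD = higher precision
    sd_imprecise: float
    ratio: float  # sd_imprecise / sd_precise, >= 1

    @classmethod
    def from_sds(cls, sd1: float, sd2: float) -> "PrecisionPair":
        lo, hi = sorted((float(sd1), float(sd2)))
        return cls(sd_precise=lo, sd_imprecise=hi, ratio=hi / lo)


def vm_sd_from_kappa(kappa):
    """Map concentration to precision SD: sqrt(1/kappa) radians, in degrees."""
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa <= 0):
        raise ValueError("kappa must be > 0")
    out = np.rad2deg(np.sqrt(1.0 / kappa))
    return float(out) if out.ndim == 0 else out


def kappa_from_vm_sd(sd_deg):
    """Inverse of :func:`vm_sd_from_kappa`."""
    sd_deg = np.asarray(sd_deg, dtype=float)
    if np.any(sd_deg <= 0):
        raise ValueError("sd must be > 0")
    out = 1.0 / np.deg2rad(sd_deg) ** 2
    return float(out) if out.ndim == 0 else out


def _log_i0(kappa):
    return np.log(i0e(kappa)) + kappa


def _a_kappa(kappa):
    """Mean resultant length A(kappa) = I1/I0."""
    return i1e(kappa) / i0e(kappa)


def _a_inv(rbar):
    """Invert A(kappa) = rbar: Best-Fisher approximation + Newton steps."""
    r = np.clip(np.asarray(rbar, dtype=float), 1e-12, 1.0 - 1e-12)
    k = np.where(
        r < 0.53,
        2.0 * r + r**3 + 5.0 * r**5 / 6.0,
        np.where(r < 0.85, -0.4 + 1.39 * r + 0.43 / (1.0 - r), 1.0 / (r**3 - 4.0 * r**2 + 3.0 * r)),
    )
    k = np.clip(k, KAPPA_MIN, KAPPA_MAX)
    for _ in range(4):
        a = _a_kappa(k)
        da = 1.0 - a / k - a * a
        step = np.where(np.abs(da) > 1e-14, (a - r) / np.where(da == 0, 1.0, da), 0.0)
        k = np.clip(k - step, KAPPA_MIN, KAPPA_MAX)
    return k


def _vm_logpdf(x_rad, mu_rad, kappa):
    return kappa * np.cos(x_rad - mu_rad) - np.log(2.0 * np.pi) - _log_i0(kappa)


def mixture_loglik(errors_deg, components) -> float:
    """Log-likelihood (nats) of signed errors under an equal-weight pair.

    Density is on the radian scale; in the kappa -> 0 limit each component
    tends to the circular uniform density 1/(2*pi).
    """
    x = np.deg2rad(np.asarray(errors_deg, dtype=float))
    logf = np.stack(
        [_vm_logpdf(x, np.deg2rad(c.mu), c.kappa) + np.log(c.weight) for c in components],
        axis=-1,
    )
    m = logf.max(axis=-1)
    return float(np.sum(m + np.log(np.sum(np.exp(logf - m[..., None]), axis=-1))))


def _moment_init(x_rad: np.ndarray) -> tuple[float, float]:
    """Initial kappas from moment fits to the inner/outer halves of |error|."""
    order = np.argsort(np.abs(x_rad))
    half = len(x_rad) // 2
    kappas = []
    for part in (order[:half], order[half:]):
        rbar = np.abs(np.mean(np.exp(1j * x_rad[part])))
        kappas.append(float(_a_inv(rbar)))
    return kappas[0], kappas[1]  # concentrated half first


def fit_constrained_mixture(
    errors_deg,
    mu_bound: float = 10.0,
    n_restarts: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
    rng: np.random.Generator | int | None = None,
) -> tuple[VonMisesMixtureFit, PrecisionPair]:
    """Fit the constrained mixture by EM and derive the precision pair.

    Requires at least 20 samples with |error| <= 180.  Restarts jitter the
    moment-based initialization; all restarts are iterated simultaneously and
    the best final log-likelihood is kept.  Near-degenerate data (all angles
    essentially identical) emit :class:`DegenerateFitWarning` with kappa
    capped at its upper bound.
    """
    x_deg = np.asarray(errors_deg, dtype=float)
    if len(x_deg) < 20:
        raise ValueError("need at least 20 error samples")
    if np.any(np.abs(x_deg) > 180.0 + 1e-9):
        raise ValueError("errors must lie in [-180, 180] degrees")
    rng = np.random.default_rng(rng)
    x = np.deg2rad(x_deg)  # (n,)
    n = len(x)
    m = int(n_restarts)
    mu_cap = np.deg2rad(mu_bound)

    k_hi, k_lo = _moment_init(x)
    kappas = np.empty((m, 2))
    mus = np.zeros((m, 2))
    kappas[0] = (k_hi, k_lo)
    if m > 1:
        jitter = np.exp(rng.normal(0.0, 0.35, size=(m - 1, 2)))
        kappas[1:] = np.clip(np.array([k_hi, k_lo]) * jitter, KAPPA_MIN, KAPPA_MAX)
        mus[1:] = rng.uniform(-mu_cap / 2, mu_cap / 2, size=(m - 1, 2))

    cosx = np.cos(x)[:, None, None]
    sinx = np.sin(x)[:, None, None]
    xcol = x[:, None, None]
    log_half = np.log(0.5)

    loglik = np.full(m, -np.inf)
    active = np.ones(m, dtype=bool)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E-step (vectorized over restarts and components)
        logf = (
            kappas[None] * np.cos(xcol - mus[None])
            - np.log(2.0 * np.pi)
            - _log_i0(kappas[None])
            + log_half
        )  # (n, m, 2)
        mx = logf.max(axis=2, keepdims=True)
        lse = mx[..., 0] + np.log(np.exp(logf - mx).sum(axis=2))  # (n, m)
        new_loglik = lse.sum(axis=0)
        r = np.exp(logf - lse[..., None])  # responsibilities

        # M-step
        w = r.sum(axis=0)  # (m, 2)
        s = (r * sinx).sum(axis=0)
        c = (r * cosx).sum(axis=0)
        mus = np.clip(np.arctan2(s, c), -mu_cap, mu_cap)
        rbar = (r * np.cos(xcol - mus[None])).sum(axis=0) / np.maximum(w, 1e-12)
        kappas = _a_inv(np.clip(rbar, 0.0, 1.0))

        done = np.abs(new_loglik - loglik) < tol
        loglik = new_loglik
        active &= ~done
        if not active.any():
            break
    converged = not active.any()

    best = int(np.argmax(loglik))
    mu_best = mus[best]
    kap_best = kappas[best]
    if np.any(kap_best >= KAPPA_MAX * (1 - 1e-9)):
        warnings.warn(
            "near-degenerate error distribution: kappa capped at its upper bound",
            DegenerateFitWarning,
        )

    comps = tuple(
        VonMisesComponent(mu=float(np.rad2deg(mu_best[j])), kappa=float(kap_best[j]))
        for j in range(2)
    )
    final_ll = mixture_loglik(x_deg, comps)
    logf = np.stack(
        [_vm_logpdf(x, np.deg2rad(cc.mu), cc.kappa) + log_half for cc in comps], axis=1
    )
    mx = logf.max(axis=1, keepdims=True)
    resp = np.exp(logf - mx - np.log(np.exp(logf - mx).sum(axis=1, keepdims=True)))

    fit = VonMisesMixtureFit(
        components=comps,
        loglik=final_ll,
        n=n,
        responsibilities=resp,
        converged=converged,
        n_iter=n_iter,
    )
    pair = PrecisionPair.from_sds(
        vm_sd_from_kappa(comps[0].kappa), vm_sd_from_kappa(comps[1].kappa)
    )
    return fit, pair
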