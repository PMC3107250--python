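"""First-passage-time statistics.

The first-passage time of drifted Brownian motion to an absorbing wall
follows the inverse Gaussian law

    f(t; mu, lam) = sqrt(lam / (2 pi t^3)) exp(-lam (t - mu)^2 / (2 mu^2 t)),

with mean mu and scale parameter lam.  Transport simulations produce FPT
samples that are fitted by the closed-form maximum-likelihood estimates;
the implied positive drift is v = L/mu over the transport span L, and
the matching zero-interaction baseline is the 1D free-diffusion passage
time L^2/(2D).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


class DegenerateSampleError(ValueError):
    """All sample values identical: the scale MLE diverges."""


@dataclass
class FPTSample:
    """A set of first-passage times in ms with its mean and SEM."""

    times: np.ndarray
    n: int
    mean: float
    sem: float | None  # None for n < 2

    @classmethod
    def from_times(cls, times) -> "FPTSample":
        times = np.asarray(times, float)
        if times.ndim != 1 or len(times) == 0:
            raise ValueError("need a nonempty 1D sample")
        if np.any(times <= 0):
            raise ValueError("first-passage times must be positive")
        n = len(times)
        sem = float(times.std(ddof=1) / math.sqrt(n)) if n > 1 else None
        return cls(times=times, n=n, mean=float(times.mean()), sem=sem)


@dataclass
class IGFit:
    """Fitted inverse-Gaussian parameters and goodness-of-fit summary."""

    mu: float  # ms
    lam: float  # ms
    log_likelihood: float
    max_cdf_discrepancy: float  # sup |empirical cdf - fitted cdf|


def invgauss_pdf(t, mu: float, lam: float):
    """Inverse-Gaussian density f(t; mu, lam); vectorized over t."""
    t = np.asarray(t, float)
    if np.any(t <= 0) or mu <= 0 or lam <= 0:
        raise ValueError("t, mu and lam must be positive")
    out = np.sqrt(lam / (2.0 * np.pi * t ** 3)) * np.exp(
        -lam * (t - mu) ** 2 / (2.0 * mu ** 2 * t))
    return out if out.ndim else float(out)


def invgauss_cdf(t, mu: float, lam: float):
    """Inverse-Gaussian cumulative distribution function."""
    t = np.asarray(t, float)
    if np.any(t <= 0) or mu <= 0 or lam <= 0:
        raise ValueError("t, mu and lam must be positive")
    out = stats.invgauss.cdf(t, mu / lam, scale=lam)
    return out if np.ndim(out) else float(out)


def fit_invgauss(sample: FPTSample | np.ndarray) -> IGFit:
    """Closed-form maximum-likelihood inverse-Gaussian fit.

    mu_hat is the sample mean; lam_hat = n / sum(1/t_i - 1/mu_hat).
    Also reports the maximum discrepancy between the empirical and
    fitted cdfs.
    """
    if not isinstance(sample, FPTSample):
        sample = FPTSample.from_times(sample)
    t = sample.times
    n = sample.n
    if n < 3:
        raise ValueError("need at least 3 first-passage times")
    mu = sample.mean
    denom = float(np.sum(1.0 / t - 1.0 / mu))
    if denom <= 0 or n / denom > 1e12 * mu:
        raise DegenerateSampleError(
            "sample has (near-)identical values; scale MLE diverges")
    lam = n / denom
    loglik = float(np.sum(np.log(invgauss_pdf(t, mu, lam))))
    ts = np.sort(t)
    fitted = invgauss_cdf(ts, mu, lam)
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    disc = float(max(np.abs(ecdf_hi - fitted).max(),
                     np.abs(ecdf_lo - fitted).max()))
    return IGFit(mu=mu, lam=lam, log_likelihood=loglik,
                 max_cdf_discrepancy=disc)


def drift_estimate(L_nm: float, mu_ms: float) -> float:
    """Implied positive drift v = L/mu in um/s for a span L (nm) and mean
    first-passage time mu (ms)."""
    if L_nm <= 0 or mu_ms <= 0:
        raise ValueError("span and mean FPT must be positive")
    return L_nm / mu_ms  # nm/ms == um/s


def free_diffusion_fpt(L_nm: float, D_um2_s: float) -> float:
    """1D free-diffusion first-passage baseline t = L^2/(2D), in ms."""
    if L_nm <= 0 or D_um2_s <= 0:
        raise ValueError("span and diffusion coefficient must be positive")
    return L_nm ** 2 / (2.0 * D_um2_s) * 1e-3  # nm^2 / (um^2/s) -> ms
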