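"""Independent numerical oracles used by the test suite.

Everything here is deliberately written against scipy / plain quadrature,
not against the package's own weight or kernel machinery, so that a test
comparing the two is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import gammaln


def brute_force_fhat(i: int, h_on_grid: np.ndarray, delay_pdf, dt: float = 1e-3) -> float:
    """Interval-integrated interpolated completion propensity, by brute force.

    Double quadrature of the unit-interval interpolation of the propensity
    history ``h_on_grid`` (values at t = 0..T) against the delay density
    ``delay_pdf`` (a callable), respecting that the delay measure has no
    mass below zero (the inner integration runs over s in [max(t-1, 0), t]).
    """
    total = 0.0
    nx = 1000
    xs = np.linspace(0.0, 1.0, nx + 1)
    for m in range(i):
        tg = np.arange(m, m + 1 + 1e-12, dt)
        lo = np.maximum(tg - 1.0, 0.0)
        width = tg - lo
        S = lo[:, None] + xs[None, :] * width[:, None]
        pdf = delay_pdf(S)
        pdf = np.where(np.isfinite(pdf), pdf, 0.0)
        h0 = h_on_grid[i - 1 - m]
        h1 = h_on_grid[i - m]
        integrand = ((S + 1.0 - tg[:, None]) * h0 + (tg[:, None] - S) * h1) * pdf
        inner = np.trapezoid(integrand, axis=1) * width / nx
        total += np.trapezoid(inner, dx=dt)
    return float(total)


def poisson_loglik_termwise(r: np.ndarray, F: np.ndarray) -> float:
    """Sum of independent Poisson log-pmfs, term by term via scipy."""
    total = 0.0
    for k in range(r.shape[0]):
        for i in range(r.shape[1]):
            f = F[k, i]
            n = r[k, i]
            if f <= 0:
                if n > 0:
                    return -np.inf
                continue
            total += float(stats.poisson.logpmf(n, f))
    return total


def gaussian_obs_loglik(y: np.ndarray, yobs: np.ndarray, sigma_e: float) -> float:
    """Observation factor via scipy.stats.norm."""
    sd = np.sqrt(np.asarray(y, dtype=float) + sigma_e)
    return float(stats.norm.logpdf(np.asarray(yobs), loc=y, scale=sd).sum())


def exact_event_loglik_delayed_birth(
    t_complete: np.ndarray, A: float, delay_cdf, T: float, n_grid: int = 20000
) -> float:
    """Exact event-history log-likelihood of a delayed pure-birth process.

    For production at constant initiation rate A with delay distribution
    eta, the completion propensity is f(t) = A * F_eta(t) and the exact
    likelihood of the completion times in (0, T] is
    prod_j f(t_j) * exp(-Lambda(T)) with Lambda(T) = A * int_0^T F_eta.
    """
    t = np.asarray(t_complete, dtype=float)
    grid = np.linspace(0.0, T, n_grid + 1)
    Lam = A * np.trapezoid(delay_cdf(grid), grid)
    f = A * np.maximum(delay_cdf(t), 1e-300)
    return float(np.sum(np.log(f)) - Lam)


def grid_posterior_gamma_rate(
    counts: float,
    exposure: float,
    prior_shape: float,
    prior_rate: float,
    theta_max: float = 5.0,
    step: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray]:
    """Brute-force grid posterior of a rate with Poisson(theta * exposure).

    Returns (theta grid, normalised posterior density on the grid).
    """
    theta = np.arange(step, theta_max + step / 2, step)
    logpost = (
        counts * np.log(theta)
        - theta * exposure
        + (prior_shape - 1.0) * np.log(theta)
        - prior_rate * theta
    )
    logpost -= logpost.max()
    dens = np.exp(logpost)
    dens /= np.trapezoid(dens, theta)
    return theta, dens
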