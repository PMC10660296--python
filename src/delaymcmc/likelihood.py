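"""Approximate likelihood of a delayed network observed on a unit grid.

Three factors are exposed:

* the interpolated completion propensity fhat_k(i) — the expected number of
  completions of reaction k in interval (i-1, i] given the grid trajectory,
  obtained by linearly interpolating the initiation propensity between grid
  points and averaging over the delay distribution;

* the count likelihood — a product over intervals and reactions of Poisson
  factors fhat^r e^{-fhat} / r!, valid only when the trajectory is exactly
  the stoichiometric reconstruction of the counts (the indicator chi).
  The exponential normaliser is sum_{i,k} fhat_k(i) because fhat_k(i) is
  itself the integral of the interpolated completion propensity over its
  interval, so no separate time integral is needed;

* the Gaussian observation likelihood of noisy measurements of the observed
  species, with state-dependent variance y(t) + sigma_e.

Their product (Poisson count factor times observation factor, with the
unobserved species integrated out trivially through chi) is the joint
likelihood used by the sampler.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _core
from .network import DELAY_GRID_STEP, DelayedNetwork, ParameterSet

__all__ = [
    "ObservationModel",
    "Observations",
    "completion_weights",
    "approx_completion_propensity",
    "completion_propensity_matrix",
    "approx_log_likelihood",
    "observation_log_likelihood",
    "joint_log_likelihood",
]

completion_weights = _core.completion_weights

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ObservationModel:
    """Gaussian observation noise with variance y + sigma_e.

    ``sigma_e`` is the additive variance floor (squared-count units); the
    state-dependent part models shot-like noise growing with the signal.
    """

    sigma_e: float

    def __post_init__(self) -> None:
        if self.sigma_e < 0:
            raise ValueError("sigma_e must be nonnegative")

    def var(self, y) -> np.ndarray:
        return np.asarray(y, dtype=float) + self.sigma_e


@dataclass
class Observations:
    """Noisy measurements of the observed species on the grid 0..T.

    ``values`` has shape (n_observed_species, T+1); entries may be negative
    because Gaussian noise on small counts can undershoot zero.
    """

    values: np.ndarray
    species: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != len(self.species):
            raise ValueError("row count does not match species list")

    @property
    def T(self) -> int:
        return self.values.shape[1] - 1


def approx_completion_propensity(
    i: int,
    z: np.ndarray,
    net: DelayedNetwork,
    params: ParameterSet,
    k: int,
    step: float = DELAY_GRID_STEP,
) -> float:
    """fhat_k(i): expected completions of reaction k in interval (i-1, i].

    ``z`` is the full (u, T+1) grid trajectory.  With a zero delay this
    reduces exactly to the trapezoid 0.5 * (h_k(z(i-1)) + h_k(z(i))).
    """
    z = np.atleast_2d(np.asarray(z))
    T = z.shape[1] - 1
    if not 1 <= i <= T:
        raise ValueError(f"interval index i={i} outside 1..{T}")
    F = completion_propensity_matrix(net, params, z, step=step)
    return float(F[k, i - 1])


def completion_propensity_matrix(
    net: DelayedNetwork,
    params: ParameterSet,
    z: np.ndarray,
    step: float = DELAY_GRID_STEP,
    compiled: _core.CompiledNetwork | None = None,
) -> np.ndarray:
    """All fhat_k(i) as a (v, T) matrix for a given grid trajectory."""
    z = np.atleast_2d(np.asarray(z))
    T = z.shape[1] - 1
    comp = compiled if compiled is not None else _core.compile_network(net, params, T, step)
    H = _core.hist_matrix(comp, z)
    return _core.fhat_kernel(H, comp.W0, comp.W1)


def approx_log_likelihood(
    r: np.ndarray,
    z: np.ndarray,
    net: DelayedNetwork,
    params: ParameterSet,
    step: float = DELAY_GRID_STEP,
    compiled: _core.CompiledNetwork | None = None,
) -> float:
    """Log of the approximate count likelihood.

    Returns -inf when chi(z | r) = 0, i.e. when the trajectory is not the
    nonnegative stoichiometric reconstruction of the counts, or when a
    positive count sits on a zero completion propensity.
    """
    r = np.asarray(r, dtype=np.int64)
    z = np.atleast_2d(np.asarray(z, dtype=np.int64))
    _, netc = net.stoichiometry()
    if not _core.chi_consistent(net.z0(), netc, r, z):
        return -np.inf
    F = completion_propensity_matrix(net, params, z, step=step, compiled=compiled)
    return float(_core.poisson_loglik_kernel(r, F))


def observation_log_likelihood(
    y: np.ndarray,
    yobs: np.ndarray | Observations,
    om: ObservationModel,
) -> float:
    """Gaussian log-likelihood of noisy observations given the true counts.

    Sums over observed species and every grid time 0..T with per-point
    variance y(t) + sigma_e.
    """
    if isinstance(yobs, Observations):
        yobs = yobs.values
    y = np.atleast_2d(np.asarray(y, dtype=float))
    yobs = np.atleast_2d(np.asarray(yobs, dtype=float))
    if y.shape != yobs.shape:
        raise ValueError(f"shape mismatch: y {y.shape} vs yobs {yobs.shape}")
    var = om.var(y)
    if (var <= 0).any():
        raise ValueError("degenerate observation variance (y = 0 and sigma_e = 0)")
    resid = yobs - y
    return float(-0.5 * np.sum(_LOG_2PI + np.log(var) + resid**2 / var))


def joint_log_likelihood(
    r: np.ndarray,
    net: DelayedNetwork,
    params: ParameterSet,
    yobs: np.ndarray | Observations,
    om: ObservationModel,
    step: float = DELAY_GRID_STEP,
) -> float:
    """Observation factor plus count factor for counts r.

    The trajectory of all species is reconstructed from r; the observation
    factor touches only the observed rows.  Returns -inf if the
    reconstruction goes negative.
    """
    r = np.asarray(r, dtype=np.int64)
    _, netc = net.stoichiometry()
    z = _core.reconstruct(net.z0(), netc, r)
    if (z < 0).any():
        return -np.inf
    obs_rows = np.flatnonzero(net.observed_mask())
    ll_obs = observation_log_likelihood(z[obs_rows], yobs, om)
    ll_counts = approx_log_likelihood(r, z, net, params, step=step)
    return ll_obs + ll_counts
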