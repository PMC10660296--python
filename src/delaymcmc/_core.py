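"""Shared numerical core.

Holds the array ("compiled") form of a delayed network, the unit-interval
completion-propensity weights, the numba kernels used by the tau-leaping
simulator and the count likelihood, and stoichiometric reconstruction.

The central identity: the integral over interval (i-1, i] of the linearly
interpolated completion propensity can be written

    fhat_k(i) = sum_m  W0_k[m] * h_k(z(i-1-m)) + W1_k[m] * h_k(z(i-m))

with weights that depend only on the delay distribution eta_k:

    W0[m] = int phi0_m(s) d eta(s),   W1[m] = int phi1_m(s) d eta(s),

    phi0_m(s) = (s+1-m)^2 / 2           on [m-1, m]
                (1 - (s-m)^2) / 2       on [m, m+1]
    phi1_m(s) = (1 - (m-s)^2) / 2       on [m-1, m]
                (m+1-s)^2 / 2           on [m, m+1]

and phi0_m + phi1_m is the unit tent at m, so the weights of a constant
propensity sum to the delay mass reachable within the horizon.  For the
zero-delay (Dirac) case W0[0] = W1[0] = 1/2, the trapezoid rule.
Delay mass at lags beyond the current interval index is excluded
automatically because only terms m < i enter fhat(i): an initiation cannot
predate time zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .network import (
    DELAY_GRID_STEP,
    DelayDistribution,
    DelayedNetwork,
    ParameterSet,
)

FORM_CONSTANT = 0
FORM_LINEAR = 1
FORM_MM = 2

_FORM_CODES = {
    "constant": FORM_CONSTANT,
    "mass_action_linear": FORM_LINEAR,
    "michaelis_menten": FORM_MM,
}


# ---------------------------------------------------------------------------
# completion-propensity weights
# ---------------------------------------------------------------------------


def completion_weights(
    delay: DelayDistribution, T: int, step: float = DELAY_GRID_STEP
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-interval interpolation weights (W0, W1), each of length T.

    Quadrature: the delay density on a uniform grid of ``step`` minutes
    (trapezoidal convolution for sums of Gammas), truncated at the smaller
    of the horizon T and the 1 - 1e-8 tail quantile; truncated tail mass is
    renormalised into the covered support unless the cut is the horizon
    itself, in which case the lost mass is genuinely unreachable.
    """
    W0 = np.zeros(T)
    W1 = np.zeros(T)
    if delay.family == "dirac_zero":
        W0[0] = 0.5
        W1[0] = 0.5
        return W0, W1

    n_per = round(1.0 / step)
    if abs(n_per * step - 1.0) > 1e-12:
        raise ValueError("delay grid step must divide one time unit")
    q = delay.tail_quantile()
    n_units = max(1, min(T, int(math.ceil(q))))
    n = n_units * n_per
    _, cdf = delay.grid_cdf(float(n_units), step)
    mass = np.diff(cdf[: n + 1])  # per-cell delay mass
    total = float(cdf[n])
    if n_units >= q and total > 0:
        mass = mass / total  # fold the 1e-8 tail back in

    x = (np.arange(n_per) + 0.5) / n_per  # cell midpoints within a unit
    b_right0 = 0.5 * (1.0 - x**2)
    b_left0 = 0.5 * x**2
    b_right1 = 0.5 * (1.0 - x) ** 2
    b_left1 = 0.5 * (1.0 - (1.0 - x) ** 2)

    for unit in range(n_units):
        seg = mass[unit * n_per : (unit + 1) * n_per]
        W0[unit] += seg @ b_right0
        W1[unit] += seg @ b_right1
        if unit + 1 < T:
            W0[unit + 1] += seg @ b_left0
            W1[unit + 1] += seg @ b_left1
    return W0, W1


# ---------------------------------------------------------------------------
# compiled network
# ---------------------------------------------------------------------------


@dataclass
class CompiledNetwork:
    """Array form of a network bound to numeric parameter values."""

    net: DelayedNetwork
    T: int
    step: float
    z0: np.ndarray  # (u,) int64
    reactants: np.ndarray  # (v, u) int64
    net_change: np.ndarray  # (v, u) int64
    form: np.ndarray  # (v,) int64
    rate: np.ndarray  # (v,) float64
    km: np.ndarray  # (v,) float64
    sp: np.ndarray  # (v,) int64
    W0: np.ndarray  # (v, T) float64
    W1: np.ndarray  # (v, T) float64
    delays: list[DelayDistribution]
    values: dict[str, float]
    rate_slots: dict[str, list[int]] = field(default_factory=dict)
    km_slots: dict[str, list[int]] = field(default_factory=dict)
    delay_shape_slots: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    delay_rate_slots: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def u(self) -> int:
        return self.z0.size

    @property
    def v(self) -> int:
        return self.form.size

    def observed_rows(self) -> np.ndarray:
        return np.flatnonzero(self.net.observed_mask())

    # -- parameter updates -------------------------------------------------
    def set_kinetic(self, name: str, value: float) -> None:
        if name not in self.rate_slots:
            raise KeyError(f"{name} is not a multiplicative rate slot")
        self.values[name] = float(value)
        for k in self.rate_slots[name]:
            self.rate[k] = value

    def set_delay_rate(self, name: str, value: float) -> None:
        if name not in self.delay_rate_slots:
            raise KeyError(f"{name} is not a delay rate slot")
        self.values[name] = float(value)
        for k, _j in self.delay_rate_slots[name]:
            self.delays[k] = self.net.reactions[k].delay.resolve(self.values)
            self.W0[k], self.W1[k] = completion_weights(
                self.delays[k], self.T, self.step
            )

    def delay_weights_for(
        self, k: int, overrides: dict[str, float]
    ) -> tuple[np.ndarray, np.ndarray]:
        """Weights of reaction ``k`` under hypothetical parameter values."""
        vals = dict(self.values)
        vals.update(overrides)
        d = self.net.reactions[k].delay.resolve(vals)
        return completion_weights(d, self.T, self.step)


def compile_network(
    net: DelayedNetwork,
    params: ParameterSet,
    T: int,
    step: float = DELAY_GRID_STEP,
) -> CompiledNetwork:
    """Bind a network to numeric parameters over a horizon of T unit steps."""
    if T <= 0 or int(T) != T:
        raise ValueError("T must be a positive integer number of unit steps")
    T = int(T)
    idx = net.species_index()
    reac, netc = net.stoichiometry()
    v = net.v
    form = np.zeros(v, dtype=np.int64)
    rate = np.zeros(v)
    km = np.zeros(v)
    sp = np.full(v, -1, dtype=np.int64)
    W0 = np.zeros((v, T))
    W1 = np.zeros((v, T))
    delays: list[DelayDistribution] = []
    values = dict(params.values)
    comp = CompiledNetwork(
        net=net,
        T=T,
        step=step,
        z0=net.z0(),
        reactants=reac,
        net_change=netc,
        form=form,
        rate=rate,
        km=km,
        sp=sp,
        W0=W0,
        W1=W1,
        delays=delays,
        values=values,
    )
    for k, rxn in enumerate(net.reactions):
        p = rxn.propensity
        form[k] = _FORM_CODES[p.form]
        if isinstance(p.rate, str):
            rate[k] = values[p.rate]
            comp.rate_slots.setdefault(p.rate, []).append(k)
        else:
            rate[k] = p.rate
        if p.km is not None:
            if isinstance(p.km, str):
                km[k] = values[p.km]
                comp.km_slots.setdefault(p.km, []).append(k)
            else:
                km[k] = p.km
        if p.species is not None:
            sp[k] = idx[p.species]
        for j, (s_par, r_par) in enumerate(rxn.delay.components):
            if isinstance(s_par, str):
                comp.delay_shape_slots.setdefault(s_par, []).append((k, j))
            if isinstance(r_par, str):
                comp.delay_rate_slots.setdefault(r_par, []).append((k, j))
        d = rxn.delay.resolve(values)
        delays.append(d)
        W0[k], W1[k] = completion_weights(d, T, step)
    return comp


# ---------------------------------------------------------------------------
# propensity histories and reconstruction
# ---------------------------------------------------------------------------


def hist_matrix(comp: CompiledNetwork, z: np.ndarray) -> np.ndarray:
    """Initiation propensities h_k(z(t)) as a (v, T+1) matrix.

    ``z`` is the (u, T+1) species-by-time trajectory.
    """
    ntime = z.shape[1]
    H = np.empty((comp.v, ntime))
    for k in range(comp.v):
        if comp.form[k] == FORM_CONSTANT:
            H[k] = comp.rate[k]
        elif comp.form[k] == FORM_LINEAR:
            H[k] = comp.rate[k] * z[comp.sp[k]]
        else:
            zs = z[comp.sp[k]].astype(float)
            with np.errstate(divide="ignore", invalid="ignore"):
                H[k] = np.where(
                    zs > 0, comp.rate[k] * zs / (comp.km[k] + zs), 0.0
                )
    return H


def reconstruct(z0: np.ndarray, net_change: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Trajectory implied by per-interval completion counts.

    z(i) = z(0) + sum_k (q_k - p_k) * cumulative counts of k through i.
    """
    cum = np.cumsum(r, axis=1)  # (v, T)
    z = np.empty((z0.size, r.shape[1] + 1), dtype=np.int64)
    z[:, 0] = z0
    z[:, 1:] = z0[:, None] + net_change.T @ cum
    return z


def chi_consistent(z0: np.ndarray, net_change: np.ndarray, r: np.ndarray, z: np.ndarray) -> bool:
    """Indicator chi(z | r): trajectory matches counts and stays nonnegative."""
    zr = reconstruct(z0, net_change, r)
    return bool(np.array_equal(zr, z) and (zr >= 0).all())


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _h_eval(form, rate, km, sp, zrow, k):
    if form[k] == 0:
        return rate[k]
    zs = zrow[sp[k]]
    if form[k] == 1:
        return rate[k] * zs
    if zs <= 0:
        return 0.0
    return rate[k] * zs / (km[k] + zs)


@njit(cache=True)
def fhat_kernel(H, W0, W1):
    """Interpolated completion propensities fhat_k(i) for i = 1..T.

    H is the (v, T+1) matrix of initiation propensities on the grid.
    """
    v = H.shape[0]
    T = H.shape[1] - 1
    F = np.zeros((v, T))
    for k in range(v):
        for i in range(1, T + 1):
            acc = 0.0
            for m in range(i):
                acc += W0[k, m] * H[k, i - 1 - m] + W1[k, m] * H[k, i - m]
            F[k, i - 1] = acc
    return F


@njit(cache=True)
def _trunc_poisson(rng, lam, bound):
    """Poisson(lam) conditioned on being <= bound."""
    if bound <= 0 or lam <= 0.0:
        return 0
    for _ in range(64):
        x = rng.poisson(lam)
        if x <= bound:
            return int(x)
    # rejection keeps failing: invert the CDF on 0..bound
    p = math.exp(-lam)
    if p == 0.0:
        # P(X <= bound) has underflowed; the conditional law is a point
        # mass at the bound to working precision
        return int(bound)
    total = 0.0
    q = p
    for x in range(bound + 1):
        total += q
        q = q * lam / (x + 1)
    u = rng.random() * total
    cum = 0.0
    q = p
    for x in range(bound + 1):
        cum += q
        if u <= cum:
            return x
        q = q * lam / (x + 1)
    return int(bound)


@njit(cache=True)
def fhat_transform_kernel(W0, W1):
    """(T+1, T) matrix A with fhat(i) = sum_t H(t) * A[t, i-1]."""
    T = W0.size
    A = np.zeros((T + 1, T))
    for m in range(T):
        for c in range(m, T):
            A[c - m, c] += W0[m]
            A[c + 1 - m, c] += W1[m]
    return A


@njit(cache=True)
def _log_pois(r, lam):
    if lam <= 0.0:
        return 0.0 if r == 0 else -np.inf
    return r * math.log(lam) - lam - math.lgamma(r + 1.0)


@njit(cache=True)
def _log_trunc_norm(lam, bound):
    """log P(Poisson(lam) <= bound), the truncated-draw normaliser."""
    if bound < 0:
        return -np.inf
    if lam <= 0.0:
        return 0.0
    if bound >= lam + 10.0 * math.sqrt(lam) + 20.0:
        return 0.0  # upper tail below ~1e-20
    x0 = int(min(bound, math.floor(lam)))
    t_max = x0 * math.log(lam) - lam - math.lgamma(x0 + 1.0)
    s = 0.0
    for x in range(bound + 1):
        s += math.exp(x * math.log(lam) - lam - math.lgamma(x + 1.0) - t_max)
    return t_max + math.log(s)


@njit(cache=True)
def tau_leap_window_kernel(
    z0, reactants, net_change, form, rate, km, sp, W0, W1, T, rng,
    start, resample, r_given, z_head, do_sample, lam_floor,
):
    """Delayed tau-leaping over a window, with exact proposal density.

    Intervals 1..start are copied from ``r_given``/``z_head``; from interval
    start+1 on, counts of reactions with ``resample[k]`` true are drawn —
    or, when ``do_sample`` is false, read from ``r_given`` and their density
    accumulated — while the rest keep their given counts.  ``start = 0``
    with every reaction resampled is the plain simulator.

    Counts are Poisson with mean fhat_k(i) evaluated from the trajectory so
    far; the not-yet-known endpoint state z(i) in the m = 0 interpolation
    term is replaced by z(i-1) (zero-order hold).  Within each interval,
    production-only reactions are drawn first; reactions with reactants are
    then drawn from a Poisson truncated to the range that keeps every
    consumed species nonnegative, so chi = 1 holds by construction.  The
    returned log-density covers exactly the resampled block and makes the
    proposal usable in an exact Metropolis--Hastings ratio.

    Returns (z, r, logq, ok); ok is false when the fixed counts are
    infeasible for the proposed trajectory, or (in evaluation mode) when
    the given counts are unreachable under this draw order.
    """
    u = z0.size
    v = form.size
    z = np.zeros((u, T + 1), dtype=np.int64)
    z[:, 0] = z0
    H = np.zeros((v, T + 1))
    r = np.zeros((v, T), dtype=np.int64)
    for i in range(1, start + 1):
        for s in range(u):
            z[s, i] = z_head[s, i]
        for k in range(v):
            r[k, i - 1] = r_given[k, i - 1]
    for i in range(start + 1):
        for k in range(v):
            H[k, i] = _h_eval(form, rate, km, sp, z[:, i], k)
    has_reac = np.zeros(v, dtype=np.bool_)
    for k in range(v):
        for s in range(u):
            if reactants[k, s] > 0:
                has_reac[k] = True
    ri = np.zeros(v, dtype=np.int64)
    lam = np.zeros(v)
    avail = np.zeros(u, dtype=np.int64)
    logq = 0.0
    for i in range(start + 1, T + 1):
        for k in range(v):
            if resample[k]:
                acc = (W0[k, 0] + W1[k, 0]) * H[k, i - 1]
                for m in range(1, i):
                    acc += W0[k, m] * H[k, i - 1 - m] + W1[k, m] * H[k, i - m]
                # the floor keeps the proposal's support full: without
                # it, counts in intervals where the hold propensity is
                # exactly zero but the interpolated one is positive could
                # never be proposed
                lam[k] = acc if acc > lam_floor else lam_floor
            else:
                lam[k] = 0.0
        for s in range(u):
            avail[s] = z[s, i - 1]
        # pass 1: reactions without reactants (pure production)
        for k in range(v):
            if has_reac[k]:
                continue
            if resample[k]:
                if do_sample:
                    ri[k] = rng.poisson(lam[k]) if lam[k] > 0.0 else 0
                else:
                    ri[k] = r_given[k, i - 1]
                logq += _log_pois(ri[k], lam[k])
                if logq == -np.inf:
                    return z, r, logq, False
            else:
                ri[k] = r_given[k, i - 1]
            for s in range(u):
                avail[s] += net_change[k, s] * ri[k]
        # pass 2: consuming reactions, truncated to the feasible range
        for k in range(v):
            if not has_reac[k]:
                continue
            bound = np.int64(2**62)
            for s in range(u):
                if reactants[k, s] > 0:
                    b = avail[s] // reactants[k, s]
                    if b < bound:
                        bound = b
            if resample[k]:
                if bound < 0:
                    return z, r, -np.inf, False
                if do_sample:
                    ri[k] = _trunc_poisson(rng, lam[k], bound)
                else:
                    ri[k] = r_given[k, i - 1]
                    if ri[k] > bound:
                        return z, r, -np.inf, False
                logq += _log_pois(ri[k], lam[k]) - _log_trunc_norm(lam[k], bound)
                if logq == -np.inf:
                    return z, r, logq, False
            else:
                ri[k] = r_given[k, i - 1]
            for s in range(u):
                avail[s] += net_change[k, s] * ri[k]
        for s in range(u):
            if avail[s] < 0:
                return z, r, logq, False  # fixed counts are infeasible here
            z[s, i] = avail[s]
        for k in range(v):
            r[k, i - 1] = ri[k]
            H[k, i] = _h_eval(form, rate, km, sp, z[:, i], k)
    return z, r, logq, True


def tau_leap_kernel(z0, reactants, net_change, form, rate, km, sp, W0, W1, T, rng):
    """Unconditional delayed tau-leaping (all reactions, full horizon)."""
    v = form.size
    resample = np.ones(v, dtype=np.bool_)
    r_given = np.zeros((v, T), dtype=np.int64)
    z_head = np.zeros((z0.size, T + 1), dtype=np.int64)
    z, r, _logq, _ok = tau_leap_window_kernel(
        z0, reactants, net_change, form, rate, km, sp, W0, W1, T, rng,
        0, resample, r_given, z_head, True, 0.0,
    )
    return z, r


@njit(cache=True)
def poisson_loglik_kernel(r, F):
    """sum_{i,k} [ r log fhat - fhat - log r! ]; -inf if fhat = 0 with r > 0."""
    v, T = F.shape
    total = 0.0
    for k in range(v):
        for i in range(T):
            f = F[k, i]
            n = r[k, i]
            if f <= 0.0:
                if n > 0:
                    return -np.inf
                continue
            total += n * math.log(f) - f - math.lgamma(n + 1.0)
    return total
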