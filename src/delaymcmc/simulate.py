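"""Stochastic simulation of delayed reaction networks.

Two simulators share one convention: trajectories are sampled on the
integer grid t = 0, 1, ..., T and reaction counts are completions binned
into the half-open intervals (i-1, i].

* :func:`simulate_delayed_ssa` is the exact event-driven algorithm with a
  pending-completion queue: initiations fire at exponential times from the
  current total initiation propensity; a delayed reaction schedules its
  completion after a random lag drawn from its delay distribution.
  Reactants are consumed at initiation, products delivered at completion
  (for undelayed reactions the two coincide).

* :func:`simulate_tau_leaping` draws per-interval completion counts from a
  Poisson with mean equal to the interpolated completion propensity built
  from the trajectory simulated so far; it is the generative twin of the
  approximate count likelihood and is what the MCMC uses to propose latent
  counts.

Both are deterministic given (network, parameters, T, seed).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from . import _core
from .network import DelayedNetwork, ParameterSet

__all__ = [
    "EventLog",
    "SSAResult",
    "simulate_delayed_ssa",
    "simulate_tau_leaping",
    "reconstruct_trajectory",
    "chi_consistent",
]


@dataclass
class EventLog:
    """Completion-ordered reaction events of one realisation.

    Events whose completion falls beyond the horizon T are retained (they
    are in-flight at the end of the observation window) but flagged and
    excluded from the binned reaction counts.
    """

    t_init: np.ndarray
    t_complete: np.ndarray
    reaction: np.ndarray  # 0-based reaction index
    T: float

    def __len__(self) -> int:
        return int(self.t_complete.size)

    @property
    def completed(self) -> np.ndarray:
        return self.t_complete <= self.T

    def counts(self, v: int) -> np.ndarray:
        """Per-reaction, per-unit-interval completion counts (v, T)."""
        T = int(self.T)
        r = np.zeros((v, T), dtype=np.int64)
        sel = self.completed & (self.t_complete > 0)
        bins = np.ceil(self.t_complete[sel]).astype(int)
        np.add.at(r, (self.reaction[sel], bins - 1), 1)
        return r


@dataclass
class SSAResult:
    trajectory: np.ndarray  # (u, T+1) int64
    events: EventLog
    counts: np.ndarray  # (v, T) int64


def _rng_from(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_delayed_ssa(
    net: DelayedNetwork,
    params: ParameterSet,
    T: int,
    seed=None,
) -> SSAResult:
    """Exact stochastic simulation with a pending-completion queue."""
    if T <= 0 or int(T) != T:
        raise ValueError("T must be a positive integer")
    T = int(T)
    rng = _rng_from(seed)
    comp = _compile_no_weights(net, params)
    z = comp.z0.copy()
    traj = np.zeros((net.u, T + 1), dtype=np.int64)
    traj[:, 0] = z
    next_grid = 1

    heap: list[tuple[float, int, int]] = []  # (t_complete, seq, reaction)
    seq = 0
    ev_init: list[float] = []
    ev_comp: list[float] = []
    ev_kind: list[int] = []

    t = 0.0
    products = comp.net_change + comp.reactants  # (v, u)
    while True:
        h = _propensities(comp, z)
        if (h < 0).any():
            raise ValueError("negative propensity encountered")
        total = float(h.sum())
        t_init = t + rng.exponential(1.0 / total) if total > 0 else np.inf
        t_comp = heap[0][0] if heap else np.inf
        t_next = min(t_init, t_comp)
        if t_next > T and not (heap and t_comp <= T):
            break
        # state is constant on (t, t_next); fill crossed grid points
        while next_grid <= T and next_grid < t_next:
            traj[:, next_grid] = z
            next_grid += 1
        if t_comp <= t_init:
            t_c, _, k = heapq.heappop(heap)
            t = t_c
            z = z + products[k]
            # completion time was recorded when the event was scheduled
        else:
            t = t_init
            u01 = rng.random() * total
            k = min(
                int(np.searchsorted(np.cumsum(h), u01, side="right")),
                comp.form.size - 1,
            )
            z = z - comp.reactants[k]
            if (z < 0).any():
                raise ValueError("reactant consumed below zero")
            delay = comp.delays[k]
            if delay.family == "dirac_zero":
                z = z + products[k]
                ev_init.append(t)
                ev_comp.append(t)
                ev_kind.append(k)
            else:
                d = float(delay.sample(rng))
                ev_init.append(t)
                ev_comp.append(t + d)
                ev_kind.append(k)
                if t + d <= T:
                    heapq.heappush(heap, (t + d, seq, k))
                    seq += 1
    while next_grid <= T:
        traj[:, next_grid] = z
        next_grid += 1

    order = np.argsort(np.array(ev_comp), kind="stable")
    events = EventLog(
        t_init=np.array(ev_init)[order],
        t_complete=np.array(ev_comp)[order],
        reaction=np.array(ev_kind, dtype=np.int64)[order],
        T=float(T),
    )
    return SSAResult(traj, events, events.counts(net.v))


def simulate_tau_leaping(
    net: DelayedNetwork,
    params: ParameterSet,
    T: int,
    seed=None,
    compiled: _core.CompiledNetwork | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Delayed tau-leaping on the unit grid.

    Returns ``(trajectory, counts)`` with shapes (u, T+1) and (v, T).  A
    pre-compiled network may be supplied to skip recompilation in loops.
    """
    rng = _rng_from(seed)
    comp = compiled if compiled is not None else _core.compile_network(net, params, int(T))
    z, r = _core.tau_leap_kernel(
        comp.z0,
        comp.reactants,
        comp.net_change,
        comp.form,
        comp.rate,
        comp.km,
        comp.sp,
        comp.W0,
        comp.W1,
        comp.T,
        rng,
    )
    return z, r


def reconstruct_trajectory(net: DelayedNetwork, counts: np.ndarray) -> np.ndarray:
    """Trajectory implied by completion counts via the stoichiometry."""
    _, netc = net.stoichiometry()
    return _core.reconstruct(net.z0(), netc, np.asarray(counts, dtype=np.int64))


def chi_consistent(net: DelayedNetwork, counts: np.ndarray, trajectory: np.ndarray) -> bool:
    """chi(z | r): does the trajectory match the counts and stay >= 0?"""
    _, netc = net.stoichiometry()
    return _core.chi_consistent(
        net.z0(), netc, np.asarray(counts, dtype=np.int64), np.asarray(trajectory)
    )


# -- internals --------------------------------------------------------------


def _compile_no_weights(net: DelayedNetwork, params: ParameterSet):
    """Array form without completion weights (the SSA does not need them)."""
    import types

    idx = net.species_index()
    reac, netc = net.stoichiometry()
    v = net.v
    form = np.zeros(v, dtype=np.int64)
    rate = np.zeros(v)
    km = np.zeros(v)
    sp = np.full(v, -1, dtype=np.int64)
    values = params.values
    delays = []
    for k, rxn in enumerate(net.reactions):
        p = rxn.propensity
        form[k] = _core._FORM_CODES[p.form]
        rate[k] = values[p.rate] if isinstance(p.rate, str) else p.rate
        if p.km is not None:
            km[k] = values[p.km] if isinstance(p.km, str) else p.km
        if p.species is not None:
            sp[k] = idx[p.species]
        delays.append(rxn.delay.resolve(values))
    return types.SimpleNamespace(
        z0=net.z0(), reactants=reac, net_change=netc, form=form, rate=rate,
        km=km, sp=sp, delays=delays,
    )


def _propensities(comp, z: np.ndarray) -> np.ndarray:
    v = comp.form.size
    h = np.zeros(v)
    for k in range(v):
        h[k] = _core._h_eval.py_func(comp.form, comp.rate, comp.km, comp.sp, z, k)
    return h
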