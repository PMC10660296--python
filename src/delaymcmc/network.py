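"""Delayed biochemical reaction networks.

A network couples species, reactions with one of three propensity forms
(constant, linear mass action, Michaelis--Menten) and a per-reaction delay
distribution describing the random lag between reaction initiation and
completion.  Delays stand in for unmodelled sequential steps (transcription,
translation, folding, target search) and are either degenerate at zero,
Gamma, or a sum of independent Gamma variables.

The built-in two-step activation model has an unobserved activator X
produced at constant rate ``AX`` and diluted at rate ``B``; X drives the
production of an observed reporter Y through a Michaelis--Menten propensity
``AY * X / (KM + X)`` whose completions are delayed by the convolution of a
regulation delay (tauX) and a maturation delay (tauY); Y is diluted at the
same rate ``B``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats


@lru_cache(maxsize=256)
def _gamma_edge_cdf(shape: float, rate: float, n: int, step: float):
    """Gamma CDF at the grid edges 0, step, ..., n*step (read-only, cached)."""
    c = stats.gamma.cdf(np.arange(n + 1) * step, shape, scale=1.0 / rate)
    c.setflags(write=False)
    return c


@lru_cache(maxsize=256)
def _gamma_mid_cdf(shape: float, rate: float, n: int, step: float):
    """Gamma CDF at the cell midpoints (k + 1/2)*step, k = 0..n-1 (cached)."""
    c = stats.gamma.cdf(
        (np.arange(n) + 0.5) * step, shape, scale=1.0 / rate
    )
    c.setflags(write=False)
    return c


@lru_cache(maxsize=256)
def _gamma_tail_quantile(shape: float, rate: float, prob: float) -> float:
    return float(stats.gamma.ppf(prob, shape, scale=1.0 / rate))

__all__ = [
    "DelayDistribution",
    "Propensity",
    "Reaction",
    "DelayedNetwork",
    "ParameterSet",
    "build_two_step_model",
    "delay_mean",
    "delay_cdf",
]

#: default quadrature step (minutes) for numerical delay convolutions
DELAY_GRID_STEP = 0.0025
#: delay mass beyond this quantile is truncated and renormalised
DELAY_TAIL_MASS = 1e-8

_FAMILIES = ("dirac_zero", "gamma", "sum_of_gammas")

ParamValue = float | str  # a number, or the name of a ParameterSet entry


def _is_name(v: ParamValue) -> bool:
    return isinstance(v, str)


@dataclass(frozen=True)
class DelayDistribution:
    """Distribution of the initiation-to-completion lag of one reaction.

    ``components`` is a tuple of (shape, rate) pairs of independent Gamma
    variables whose sum is the delay; it is empty for ``dirac_zero`` and has
    a single entry for ``gamma``.  Entries may be parameter names (strings)
    to be resolved against a :class:`ParameterSet` before numerical use.
    """

    family: str
    components: tuple[tuple[ParamValue, ParamValue], ...] = ()

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown delay family {self.family!r}")
        n = len(self.components)
        if self.family == "dirac_zero" and n != 0:
            raise ValueError("dirac_zero takes no parameters")
        if self.family == "gamma" and n != 1:
            raise ValueError("gamma takes exactly one (shape, rate) pair")
        if self.family == "sum_of_gammas" and n < 1:
            raise ValueError("sum_of_gammas needs at least one component")
        for shape, rate in self.components:
            for v in (shape, rate):
                if not _is_name(v) and (not math.isfinite(v) or v <= 0):
                    raise ValueError(
                        f"Gamma shape/rate must be positive, got {v!r}"
                    )

    # -- constructors -----------------------------------------------------
    @classmethod
    def dirac_zero(cls) -> "DelayDistribution":
        return cls("dirac_zero")

    @classmethod
    def gamma(cls, shape: ParamValue, rate: ParamValue) -> "DelayDistribution":
        return cls("gamma", ((shape, rate),))

    @classmethod
    def sum_of_gammas(
        cls, components: Iterable[tuple[ParamValue, ParamValue]]
    ) -> "DelayDistribution":
        return cls("sum_of_gammas", tuple(components))

    # -- parameter plumbing ----------------------------------------------
    @property
    def is_resolved(self) -> bool:
        return all(
            not _is_name(v) for comp in self.components for v in comp
        )

    def parameter_names(self) -> list[str]:
        return [v for comp in self.components for v in comp if _is_name(v)]

    def resolve(self, values: Mapping[str, float]) -> "DelayDistribution":
        """Substitute named shape/rate entries with numbers from ``values``."""
        comps = tuple(
            (
                values[s] if _is_name(s) else s,
                values[r] if _is_name(r) else r,
            )
            for s, r in self.components
        )
        return replace(self, components=comps)

    def _require_resolved(self) -> None:
        if not self.is_resolved:
            raise ValueError(
                "delay distribution has unresolved named parameters: "
                f"{self.parameter_names()}"
            )

    # -- numerics ---------------------------------------------------------
    def mean(self) -> float:
        """Mean delay, the sum of component means shape/rate (0 for dirac)."""
        self._require_resolved()
        return float(sum(s / r for s, r in self.components))

    def tail_quantile(self, tail: float = DELAY_TAIL_MASS) -> float:
        """An upper bound on the (1 - tail) quantile of the delay."""
        self._require_resolved()
        if self.family == "dirac_zero":
            return 0.0
        n = len(self.components)
        return float(
            sum(
                _gamma_tail_quantile(float(s), float(r), 1.0 - tail / n)
                for s, r in self.components
            )
        )

    def grid_cdf(
        self, t_max: float, step: float = DELAY_GRID_STEP
    ) -> tuple[np.ndarray, np.ndarray]:
        """CDF of the delay on the uniform grid 0, step, ..., >= t_max.

        A single Gamma is evaluated exactly.  A sum is reduced by
        convolving the exact cell masses of the first component with the
        CDF of the sum of the rest evaluated at cell midpoints — a
        mass-times-CDF quadrature whose accuracy is second order in the
        step regardless of density singularities at the origin (Gamma
        shapes below two have singular density derivatives there, which
        defeats a plain density-level trapezoid convolution).
        """
        self._require_resolved()
        if self.family == "dirac_zero":
            raise ValueError("dirac_zero has no grid CDF")
        n = int(math.ceil(t_max / step + 0.5))
        s = np.arange(n + 1) * step
        if len(self.components) == 1:
            shape, rate = self.components[0]
            return s, np.array(
                _gamma_edge_cdf(float(shape), float(rate), n, float(step))
            )
        shape0, rate0 = self.components[0]
        edge = _gamma_edge_cdf(float(shape0), float(rate0), n, float(step))
        mass = np.diff(edge)  # exact mass of each cell of the first component
        rest = DelayDistribution("sum_of_gammas", self.components[1:])
        if len(rest.components) == 1:
            sh, ra = rest.components[0]
            cr = np.array(_gamma_mid_cdf(float(sh), float(ra), n, float(step)))
        else:
            s_r, c_r = rest.grid_cdf(t_max, step)
            cr = np.interp((np.arange(n) + 0.5) * step, s_r, c_r)
        from scipy.signal import fftconvolve

        conv = fftconvolve(mass, cr)[:n]
        cdf = np.concatenate(([0.0], np.minimum(np.maximum(conv, 0.0), 1.0)))
        cdf = np.maximum.accumulate(cdf)
        return s, cdf

    def cdf(self, t):
        """CDF at ``t`` (scalar or array); 0 for t < 0 by convention.

        Exact (regularised lower incomplete gamma) for a single Gamma;
        numerical convolution on the quadrature grid for a sum of Gammas.
        """
        self._require_resolved()
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        if self.family == "dirac_zero":
            out = np.where(t >= 0.0, 1.0, 0.0)
        elif self.family == "gamma":
            shape, rate = self.components[0]
            out = stats.gamma.cdf(np.maximum(t, 0.0), shape, scale=1.0 / rate)
            out = np.where(t < 0.0, 0.0, out)
        else:
            s_max = max(self.tail_quantile(), float(np.max(t, initial=0.0)))
            s_max = max(s_max, DELAY_GRID_STEP)
            s, cdf = self.grid_cdf(s_max)
            out = np.interp(t, s, cdf, left=0.0, right=1.0)
            out = np.where(t < 0.0, 0.0, out)
        return float(out[0]) if scalar else out

    def sample(self, rng: np.random.Generator, size=None):
        """Draw delay(s): the sum of independent Gamma component draws."""
        self._require_resolved()
        if self.family == "dirac_zero":
            return 0.0 if size is None else np.zeros(size)
        total = None
        for shape, rate in self.components:
            d = rng.gamma(shape, 1.0 / rate, size=size)
            total = d if total is None else total + d
        return total


def delay_mean(d: DelayDistribution) -> float:
    """Mean of a delay distribution in minutes."""
    return d.mean()


def delay_cdf(d: DelayDistribution, t):
    """CDF of a delay distribution at time(s) ``t``."""
    return d.cdf(t)


# ---------------------------------------------------------------------------
# propensities and reactions
# ---------------------------------------------------------------------------

_PROP_FORMS = ("constant", "mass_action_linear", "michaelis_menten")


@dataclass(frozen=True)
class Propensity:
    """Initiation propensity h_k(z) of a reaction.

    constant:            h = rate
    mass_action_linear:  h = rate * z[species]
    michaelis_menten:    h = rate * z[species] / (km + z[species])

    The ``rate`` slot multiplies the whole form in every case, which is what
    makes it conjugate under the Poisson count likelihood.
    """

    form: str
    rate: ParamValue
    species: str | None = None
    km: ParamValue | None = None

    def __post_init__(self) -> None:
        if self.form not in _PROP_FORMS:
            raise ValueError(f"unknown propensity form {self.form!r}")
        if self.form != "constant" and self.species is None:
            raise ValueError(f"{self.form} needs a substrate species")
        if self.form == "michaelis_menten" and self.km is None:
            raise ValueError("michaelis_menten needs a km slot")

    def parameter_names(self) -> list[str]:
        return [v for v in (self.rate, self.km) if v is not None and _is_name(v)]

    def evaluate(self, z: Mapping[str, float], values: Mapping[str, float]) -> float:
        rate = values[self.rate] if _is_name(self.rate) else self.rate
        if self.form == "constant":
            return float(rate)
        zs = float(z[self.species])
        if self.form == "mass_action_linear":
            return float(rate * zs)
        km = values[self.km] if _is_name(self.km) else self.km
        return float(rate * zs / (km + zs)) if zs > 0 else 0.0


@dataclass(frozen=True)
class Reaction:
    """One reaction: stoichiometry, initiation propensity and delay."""

    name: str
    reactants: Mapping[str, int] = field(default_factory=dict)
    products: Mapping[str, int] = field(default_factory=dict)
    propensity: Propensity = None  # type: ignore[assignment]
    delay: DelayDistribution = field(default_factory=DelayDistribution.dirac_zero)

    def __post_init__(self) -> None:
        if self.propensity is None:
            raise ValueError("reaction needs a propensity")
        for stoich in (self.reactants, self.products):
            for sp, coef in stoich.items():
                if not isinstance(coef, (int, np.integer)) or coef < 0:
                    raise ValueError(
                        f"stoichiometric coefficient of {sp} must be a "
                        f"nonnegative integer, got {coef!r}"
                    )

    @property
    def is_delayed(self) -> bool:
        return self.delay.family != "dirac_zero"

    def parameter_names(self) -> list[str]:
        return self.propensity.parameter_names() + self.delay.parameter_names()


@dataclass(frozen=True)
class DelayedNetwork:
    """Species, reactions and initial state of a delayed reaction network."""

    species: tuple[str, ...]
    observed: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    init_state: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.observed:
            raise ValueError("at least one species must be observed")
        unknown = set(self.observed) - set(self.species)
        if unknown:
            raise ValueError(f"observed species not in network: {unknown}")
        for rxn in self.reactions:
            for sp in (*rxn.reactants, *rxn.products):
                if sp not in self.species:
                    raise ValueError(
                        f"reaction {rxn.name}: unknown species {sp!r}"
                    )
            if rxn.propensity.species is not None and (
                rxn.propensity.species not in self.species
            ):
                raise ValueError(
                    f"reaction {rxn.name}: unknown substrate "
                    f"{rxn.propensity.species!r}"
                )
        for sp in self.species:
            z0 = self.init_state.get(sp, 0)
            if not isinstance(z0, (int, np.integer)) or z0 < 0:
                raise ValueError(f"init state of {sp} must be a nonnegative int")

    @property
    def u(self) -> int:
        return len(self.species)

    @property
    def v(self) -> int:
        return len(self.reactions)

    def species_index(self) -> dict[str, int]:
        return {sp: j for j, sp in enumerate(self.species)}

    def observed_mask(self) -> np.ndarray:
        obs = set(self.observed)
        return np.array([sp in obs for sp in self.species])

    def z0(self) -> np.ndarray:
        return np.array(
            [self.init_state.get(sp, 0) for sp in self.species], dtype=np.int64
        )

    def stoichiometry(self) -> tuple[np.ndarray, np.ndarray]:
        """(reactant matrix, net-change matrix), each of shape (v, u)."""
        idx = self.species_index()
        reac = np.zeros((self.v, self.u), dtype=np.int64)
        net = np.zeros((self.v, self.u), dtype=np.int64)
        for k, rxn in enumerate(self.reactions):
            for sp, c in rxn.reactants.items():
                reac[k, idx[sp]] += c
                net[k, idx[sp]] -= c
            for sp, c in rxn.products.items():
                net[k, idx[sp]] += c
        return reac, net

    def parameter_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for rxn in self.reactions:
            for name in rxn.parameter_names():
                seen.setdefault(name)
        return list(seen)


# ---------------------------------------------------------------------------
# parameter sets
# ---------------------------------------------------------------------------


@dataclass
class ParameterSet:
    """Named kinetic and delay parameters with a free/fixed mask.

    Rates and delay shapes/rates must be nonnegative (zero is permitted so
    that degenerate networks can be simulated); entries not listed in
    ``free`` are treated as known constants during inference.
    """

    values: dict[str, float]
    free: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.values = {k: float(v) for k, v in self.values.items()}
        self.free = frozenset(self.free)
        for k, v in self.values.items():
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"parameter {k} must be finite and >= 0, got {v}")
        missing = self.free - set(self.values)
        if missing:
            raise ValueError(f"free parameters without values: {missing}")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    @property
    def fixed(self) -> frozenset[str]:
        return frozenset(self.values) - self.free

    def copy(self) -> "ParameterSet":
        return ParameterSet(dict(self.values), self.free)

    def with_free(self, *names: str) -> "ParameterSet":
        return ParameterSet(dict(self.values), frozenset(names))

    def updated(self, **changes: float) -> "ParameterSet":
        vals = dict(self.values)
        vals.update(changes)
        return ParameterSet(vals, self.free)


# ---------------------------------------------------------------------------
# the two-step activation model
# ---------------------------------------------------------------------------


def _named_delay_components(
    delay: DelayDistribution, base: str, values: dict[str, float]
) -> list[tuple[str, str]]:
    """Register a numeric delay's components as named parameters."""
    if not delay.is_resolved:
        raise ValueError(f"{base}: delay must have numeric parameters")
    comps: list[tuple[str, str]] = []
    multi = len(delay.components) > 1
    for j, (shape, rate) in enumerate(delay.components):
        tag = f"{base}{j}" if multi else base
        values[f"{tag}_shape"] = float(shape)
        values[f"{tag}_rate"] = float(rate)
        comps.append((f"{tag}_shape", f"{tag}_rate"))
    return comps


def build_two_step_model(
    AX: float,
    AY: float,
    KM: float,
    B: float,
    delayX: DelayDistribution,
    delayY: DelayDistribution,
    x0: int = 0,
    y0: int = 0,
) -> tuple[DelayedNetwork, ParameterSet]:
    """Two-step activation model: unobserved X activates observed Y.

    Reactions:
        R1  0 -> X      constant AX, no delay
        R2  X -> 0      linear B*X, no delay
        R3  0 -> Y      Michaelis-Menten AY*X/(KM+X), delayed by the sum of
                        the regulation delay (delayX) and the maturation
                        delay (delayY)
        R4  Y -> 0      linear B*Y, no delay

    The regulation and maturation delays are composed into one delayed
    reaction whose delay is the convolution of the two: only the delay sum
    is identifiable from Y, and a single delayed production reproduces the
    same observable process without an intermediate species.

    Returns the network together with a :class:`ParameterSet` holding the
    generative values (all fixed; callers choose the free mask).
    """
    for name, val in (("AX", AX), ("AY", AY), ("KM", KM), ("B", B)):
        if not math.isfinite(val) or val <= 0:
            raise ValueError(f"{name} must be a positive finite rate, got {val}")
    if x0 < 0 or y0 < 0:
        raise ValueError("initial copy numbers must be nonnegative")

    values: dict[str, float] = {"AX": AX, "AY": AY, "KM": KM, "B": B}
    comps: list[tuple[str, str]] = []
    comps += _named_delay_components(delayX, "tauX", values)
    comps += _named_delay_components(delayY, "tauY", values)
    if comps:
        delay3 = DelayDistribution.sum_of_gammas(comps)
    else:
        delay3 = DelayDistribution.dirac_zero()

    net = DelayedNetwork(
        species=("X", "Y"),
        observed=("Y",),
        reactions=(
            Reaction("R1", {}, {"X": 1}, Propensity("constant", "AX")),
            Reaction(
                "R2", {"X": 1}, {}, Propensity("mass_action_linear", "B", "X")
            ),
            Reaction(
                "R3",
                {},
                {"Y": 1},
                Propensity("michaelis_menten", "AY", "X", "KM"),
                delay=delay3,
            ),
            Reaction(
                "R4", {"Y": 1}, {}, Propensity("mass_action_linear", "B", "Y")
            ),
        ),
        init_state={"X": int(x0), "Y": int(y0)},
    )
    return net, ParameterSet(values)
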