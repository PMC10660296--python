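"""Completion propensities and the approximate joint likelihood."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from delaymcmc import _core
from delaymcmc.likelihood import (
    ObservationModel,
    approx_completion_propensity,
    approx_log_likelihood,
    completion_propensity_matrix,
    joint_log_likelihood,
    observation_log_likelihood,
)
from delaymcmc.network import (
    DelayDistribution,
    DelayedNetwork,
    ParameterSet,
    Propensity,
    Reaction,
)
from delaymcmc.simulate import reconstruct_trajectory, simulate_tau_leaping

from _oracles import (
    brute_force_fhat,
    gaussian_obs_loglik,
    poisson_loglik_termwise,
)


def _single_reaction_net(propensity, delay, species=("Z",), observed=("Z",)):
    return DelayedNetwork(
        species=species,
        observed=observed,
        reactions=(Reaction("R1", {}, {"Z": 1}, propensity, delay=delay),),
        init_state={},
    )


def test_zero_delay_reduces_to_trapezoid():
    """With a Dirac delay the completion propensity is the trapezoid rule."""
    net = DelayedNetwork(
        species=("Z",),
        observed=("Z",),
        reactions=(
            Reaction(
                "deg",
                {"Z": 1},
                {},
                Propensity("mass_action_linear", 0.5, "Z"),
            ),
        ),
        init_state={"Z": 4},
    )
    z = np.array([[4, 8]])
    params = ParameterSet({})
    val = approx_completion_propensity(1, z, net, params, k=0)
    assert val == pytest.approx(0.5 * (0.5 * 4 + 0.5 * 8), abs=1e-12)  # = 3


def test_constant_propensity_integrates_to_rate():
    """Once the delay mass is fully reachable, fhat of a constant rate is the rate."""
    net = _single_reaction_net(
        Propensity("constant", 2.5), DelayDistribution.gamma(3.6, 0.6)
    )
    T = 60
    z = np.zeros((1, T + 1), dtype=np.int64)
    F = completion_propensity_matrix(net, ParameterSet({}), z)
    assert F[0, -1] == pytest.approx(2.5, rel=1e-6)
    # early intervals see only part of the delay mass
    assert F[0, 0] < 0.1 * 2.5


def test_fhat_matches_brute_force_quadrature():
    """Gamma(2,1) delay, ramp trajectory, linear propensity h = z."""
    T = 10
    z = np.arange(T + 1, dtype=np.int64)[None, :]
    net = _single_reaction_net(
        Propensity("mass_action_linear", 1.0, "Z"),
        DelayDistribution.gamma(2.0, 1.0),
    )
    F = completion_propensity_matrix(net, ParameterSet({}), z)
    pdf = stats.gamma(2.0, scale=1.0).pdf
    h = z[0].astype(float)
    for i in range(1, T + 1):
        assert F[0, i - 1] == pytest.approx(
            brute_force_fhat(i, h, pdf), abs=1e-5
        )


@given(
    shape=st.floats(1.5, 6.0),
    rate=st.floats(0.4, 2.0),
    zvals=st.lists(st.integers(0, 9), min_size=6, max_size=6),
)
@settings(max_examples=5, deadline=None)
def test_fhat_brute_force_property(shape, rate, zvals):
    z = np.array(zvals, dtype=np.int64)[None, :]
    net = _single_reaction_net(
        Propensity("mass_action_linear", 0.7, "Z"),
        DelayDistribution.gamma(shape, rate),
    )
    F = completion_propensity_matrix(net, ParameterSet({}), z)
    pdf = stats.gamma(shape, scale=1.0 / rate).pdf
    h = 0.7 * z[0].astype(float)
    i = 5
    # tolerance scales with the propensity magnitude (both sides are
    # quadratures whose absolute error is proportional to it)
    tol = 1e-5 * max(1.0, h.max())
    assert F[0, i - 1] == pytest.approx(brute_force_fhat(i, h, pdf), abs=tol)


def test_count_loglik_single_cell_poisson():
    # one reaction, one interval, fhat = 2, r = 3
    r = np.array([[3]], dtype=np.int64)
    F = np.array([[2.0]])
    val = float(_core.poisson_loglik_kernel(r, F))
    assert val == pytest.approx(3 * math.log(2) - 2 - math.log(6), abs=1e-12)
    # impossible count on a zero propensity
    assert float(_core.poisson_loglik_kernel(np.array([[1]]), np.array([[0.0]]))) == -np.inf


def test_count_loglik_inconsistent_counts_is_minus_inf(two_step):
    net, params = two_step
    z, r = simulate_tau_leaping(net, params, 10, seed=3)
    bad = r.copy()
    bad[0, 0] += 1  # breaks the reconstruction identity
    assert approx_log_likelihood(bad, z, net, params) == -np.inf


def test_count_loglik_matches_termwise_oracle():
    """Small no-delay instance: equals the sum of scipy Poisson log-pmfs."""
    net = DelayedNetwork(
        species=("Z",),
        observed=("Z",),
        reactions=(
            Reaction("birth", {}, {"Z": 1}, Propensity("constant", 1.3)),
            Reaction(
                "death", {"Z": 1}, {}, Propensity("mass_action_linear", 0.4, "Z")
            ),
        ),
        init_state={"Z": 2},
    )
    params = ParameterSet({})
    z, r = simulate_tau_leaping(net, params, 5, seed=11)
    F = completion_propensity_matrix(net, params, z)
    ours = approx_log_likelihood(r, z, net, params)
    assert ours == pytest.approx(poisson_loglik_termwise(r, F), abs=1e-10)


def test_per_cell_poisson_mass_normalises():
    """The per-cell factors are a proper Poisson pmf (mass sums to one)."""
    F = np.array([[2.7]])
    total = sum(
        math.exp(float(_core.poisson_loglik_kernel(np.array([[n]]), F)))
        for n in range(60)
    )
    assert total == pytest.approx(1.0, abs=1e-10)


def test_observation_loglik_zero_residuals():
    om = ObservationModel(10.0)
    y = np.zeros((1, 101))
    val = observation_log_likelihood(y, y, om)
    assert val == pytest.approx(-101 * 0.5 * math.log(2 * math.pi * 10), abs=1e-10)


def test_observation_loglik_quadratic_scaling():
    om = ObservationModel(4.0)
    y = np.array([[3.0, 5.0, 2.0]])
    res = np.array([[1.0, -2.0, 0.5]])
    base = observation_log_likelihood(y, y, om)
    l1 = observation_log_likelihood(y, y + res, om)
    l2 = observation_log_likelihood(y, y + 2 * res, om)
    # doubling every residual quadruples the quadratic penalty
    assert (l2 - base) == pytest.approx(4 * (l1 - base), rel=1e-10)


def test_observation_loglik_matches_scipy(rng):
    om = ObservationModel(10.0)
    y = rng.integers(0, 50, size=(1, 30)).astype(float)
    yobs = y + rng.normal(0, 3, size=y.shape)
    assert observation_log_likelihood(y, yobs, om) == pytest.approx(
        gaussian_obs_loglik(y, yobs, 10.0), abs=1e-9
    )


def test_noise_floor_flattens_likelihood():
    """A larger noise floor makes the likelihood less sensitive to the data."""
    y = np.array([[20.0]])
    yobs = np.array([[26.0]])
    eps = 1e-4
    grads = []
    for sigma_e in (1.0, 10.0, 100.0):
        om = ObservationModel(sigma_e)
        g = (
            observation_log_likelihood(y, yobs + eps, om)
            - observation_log_likelihood(y, yobs - eps, om)
        ) / (2 * eps)
        grads.append(abs(g))
    assert grads[0] > grads[1] > grads[2]


def test_degenerate_variance_raises():
    om = ObservationModel(0.0)
    with pytest.raises(ValueError):
        observation_log_likelihood(np.zeros((1, 3)), np.zeros((1, 3)), om)


def test_joint_decomposes_and_rejects_invalid(two_step):
    net, params = two_step
    om = ObservationModel(10.0)
    z, r = simulate_tau_leaping(net, params, 8, seed=5)
    yobs = z[1:2].astype(float) + 0.5
    joint = joint_log_likelihood(r, net, params, yobs, om)
    expected = observation_log_likelihood(
        z[1:2], yobs, om
    ) + approx_log_likelihood(r, z, net, params)
    assert joint == pytest.approx(expected, abs=1e-9)
    # counts whose reconstruction goes negative
    bad = np.zeros_like(r)
    bad[1, 0] = 5  # five X deaths from an empty state
    assert joint_log_likelihood(bad, net, params, yobs, om) == -np.inf


def test_joint_matches_independent_reimplementation(two_step):
    """Full recomputation from first principles on a small instance.

    The delay of the production reaction is the sum of two equal-rate
    Gammas, which is available in closed form, so the oracle needs none of
    the package's convolution machinery.
    """
    net, params = two_step
    om = ObservationModel(10.0)
    T = 5
    z, r = simulate_tau_leaping(net, params, T, seed=9)
    rng = np.random.default_rng(1)
    yobs = z[1:2] + rng.normal(0, 1, size=(1, T + 1))

    X, Y = z[0].astype(float), z[1].astype(float)
    H = np.vstack(
        [
            np.full(T + 1, 10.0),
            0.05 * X,
            np.where(X > 0, 60.0 * X / (100.0 + X), 0.0),
            0.05 * Y,
        ]
    )
    pdfs = [None, None, stats.gamma(7.2, scale=1.0 / 0.6).pdf, None]
    F = np.zeros((4, T))
    for k in range(4):
        for i in range(1, T + 1):
            if pdfs[k] is None:  # no delay: trapezoid
                F[k, i - 1] = 0.5 * (H[k, i - 1] + H[k, i])
            else:
                F[k, i - 1] = brute_force_fhat(i, H[k], pdfs[k])
    oracle = poisson_loglik_termwise(r, F) + gaussian_obs_loglik(
        z[1:2], yobs, 10.0
    )
    ours = joint_log_likelihood(r, net, params, yobs, om)
    assert ours == pytest.approx(oracle, abs=2e-4)


def test_no_delay_reduction_equals_trapezoid_tau_leap_likelihood():
    """With every delay Dirac, the likelihood is the trapezoid tau-leap one."""
    net = DelayedNetwork(
        species=("Z",),
        observed=("Z",),
        reactions=(
            Reaction("birth", {}, {"Z": 1}, Propensity("constant", 2.0)),
            Reaction(
                "death", {"Z": 1}, {}, Propensity("mass_action_linear", 0.3, "Z")
            ),
        ),
        init_state={"Z": 1},
    )
    params = ParameterSet({})
    z, r = simulate_tau_leaping(net, params, 6, seed=2)
    Z = z[0].astype(float)
    F = np.vstack(
        [
            np.full(6, 2.0),
            0.3 * 0.5 * (Z[:-1] + Z[1:]),
        ]
    )
    assert approx_log_likelihood(r, z, net, params) == pytest.approx(
        poisson_loglik_termwise(r, F), abs=1e-9
    )


def test_reconstruction_round_trip(two_step):
    net, params = two_step
    z, r = simulate_tau_leaping(net, params, 20, seed=8)
    assert np.array_equal(reconstruct_trajectory(net, r), z)
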