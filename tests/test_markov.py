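"""Transition matrices, projections, stationary and rotation equilibria."""

import numpy as np
import pytest

import weeddyn as wd
from weeddyn.markov import (
    CovariateProfile,
    _power_iteration,
    build_transition_matrix,
    convergence_time,
    project_trajectory,
    rotation_equilibrium,
    stationary_distribution,
)


def _random_stochastic(rng):
    M = rng.random((4, 4)) + 0.05
    return M / M.sum(axis=0)


def test_matrix_columns_are_conditional_probability_vectors(toy_model):
    for use in wd.LAND_USES:
        tm = build_transition_matrix(toy_model, CovariateProfile(land_use=use))
        assert np.max(np.abs(tm.P.sum(axis=0) - 1.0)) < 1e-12
        for i in range(4):
            expected = wd.conditional_transition_probs(
                toy_model, i, {f"land_use[{use}]": 1.0} if use != "wheat" else {})
            assert np.allclose(tm.P[:, i], expected, atol=1e-12)


def test_columns_shift_mass_upward_with_previous_level(toy_model):
    """Stochastic ordering across columns: higher previous level, higher state."""
    tm = build_transition_matrix(toy_model, CovariateProfile())
    cumulative = np.cumsum(tm.P, axis=0)
    for i in range(3):
        assert np.all(cumulative[:3, i + 1] < cumulative[:3, i])


def test_saturating_land_use_drives_columns_to_absent(toy_model):
    strong = wd.make_true_model(
        toy_model.thresholds, toy_model.alpha,
        dict(toy_model.coefs, **{"land_use[paddy_rice]": -25.0}), 0.0,
        spec=toy_model.spec)
    tm = build_transition_matrix(strong, CovariateProfile(land_use="paddy_rice"))
    assert np.allclose(tm.P[0], 1.0, atol=1e-6)


def test_nonconverged_model_requires_force(toy_model):
    bad = wd.make_true_model(toy_model.thresholds, toy_model.alpha,
                             toy_model.coefs, 1.0, spec=toy_model.spec)
    bad.converged = False
    with pytest.raises(ValueError):
        build_transition_matrix(bad, CovariateProfile())
    build_transition_matrix(bad, CovariateProfile(), force=True)


def test_identity_matrix_gives_constant_trajectory():
    q0 = np.array([0.1, 0.2, 0.3, 0.4])
    tr = project_trajectory([np.eye(4)], q0, horizon=5)
    assert np.allclose(tr.states, q0)


def test_rank_one_matrix_converges_in_one_step():
    c = np.array([0.4, 0.3, 0.2, 0.1])
    P = np.tile(c[:, None], 4)
    tr = project_trajectory([P], np.array([0.0, 0.0, 0.0, 1.0]), horizon=3)
    assert np.allclose(tr.states[1:], c)


def test_projection_conserves_probability(projection_fit):
    tm = build_transition_matrix(projection_fit, CovariateProfile())
    tr = project_trajectory([tm], wd.delta_state(3), horizon=20)
    assert tr.horizon == 20
    assert np.allclose(tr.states.sum(axis=1), 1.0, atol=1e-12)


def test_projection_is_linear_in_the_initial_state(toy_model):
    tm = build_transition_matrix(toy_model, CovariateProfile(land_use="barley"))
    a, b, w = wd.delta_state(0), wd.delta_state(3), 0.3
    mix = project_trajectory([tm], w * a + (1 - w) * b, horizon=10).states
    parts = (w * project_trajectory([tm], a, horizon=10).states
             + (1 - w) * project_trajectory([tm], b, horizon=10).states)
    assert np.allclose(mix, parts, atol=1e-12)


def test_stationary_of_rank_one_and_doubly_stochastic_matrices():
    c = np.array([0.4, 0.3, 0.2, 0.1])
    res = stationary_distribution(np.tile(c[:, None], 4))
    assert np.allclose(res.phases[0], c, atol=1e-12)
    # symmetric doubly stochastic -> uniform
    P = np.full((4, 4), 0.1) + np.eye(4) * 0.6
    res = stationary_distribution(P)
    assert np.allclose(res.phases[0], 0.25, atol=1e-12)


def test_stationary_agrees_with_power_iteration_oracle_on_random_matrices():
    rng = np.random.default_rng(42)
    for _ in range(50):
        P = _random_stochastic(rng)
        res = stationary_distribution(P)
        oracle = _power_iteration(P, iters=500)
        assert np.max(np.abs(res.phases[0] - oracle)) < 1e-10
        assert abs(res.dominant_eigenvalue - 1.0) < 1e-10
        assert res.residual < 1e-10


def test_rotation_equilibrium_fixed_point_identities():
    rng = np.random.default_rng(7)
    for _ in range(20):
        P1, P2 = _random_stochastic(rng), _random_stochastic(rng)
        res = rotation_equilibrium(P1, P2)
        q1, q2 = res.phases
        assert np.max(np.abs(P2 @ q1 - q2)) < 1e-10
        assert np.max(np.abs(P1 @ q2 - q1)) < 1e-10


def test_identical_phases_reduce_to_single_stationary_distribution():
    rng = np.random.default_rng(3)
    P = _random_stochastic(rng)
    rot = rotation_equilibrium(P, P)
    single = stationary_distribution(P)
    for q in rot.phases:
        assert np.allclose(q, single.phases[0], atol=1e-10)


def test_reducible_chain_falls_back_with_warning():
    P = np.eye(4)  # every state absorbing: stationary vector not unique
    res = stationary_distribution(P)
    assert res.warnings
    assert abs(res.phases[0].sum() - 1.0) < 1e-12


def test_convergence_time_basics():
    tr = wd.Trajectory(states=np.tile(np.array([0.25, 0.25, 0.25, 0.25]), (5, 1)))
    assert convergence_time(tr, np.full(4, 0.25)) == 0
    target = np.array([1.0, 0.0, 0.0, 0.0])
    assert convergence_time(tr, target) == "not reached"
    with pytest.raises(ValueError):
        convergence_time(tr, target, tol=0.0)


def test_larger_tolerance_never_converges_later(projection_fit):
    tm = build_transition_matrix(projection_fit, CovariateProfile())
    target = stationary_distribution(tm).phases[0]
    tr = project_trajectory([tm], wd.delta_state(3), horizon=200)
    times = [convergence_time(tr, target, tol) for tol in (0.001, 0.01, 0.1)]
    assert all(isinstance(t, int) for t in times)
    assert times[0] >= times[1] >= times[2]
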