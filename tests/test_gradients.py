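"""The three gradient engines against analytic oracles and each other."""

import numpy as np
import pytest

from adjfit import (
    ExperimentData,
    FdScheme,
    OdeModel,
    SolverSettings,
    compile_model,
    fim,
    forward_sensitivities,
    generate_data,
    grad_adjoint,
    grad_fd,
    grad_forward,
    gradient,
    negloglik,
    simulate,
    solve_adjoint,
)
from adjfit.fixtures import NetworkSpec, make_random_network

LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# analytic oracles
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("method, tol", [("fd", 1e-6), ("forward", 1e-8), ("adjoint", 1e-8)])
def test_const_gradient_is_minus_two(const_cm, const_data, method, tol):
    """J(theta) = 1/2((1-theta)^2 + (3-theta)^2); J'(1) = -2 exactly."""
    res = gradient(const_cm, [1.0], const_data, method=method)
    assert res.J == pytest.approx(2.0, abs=1e-10)
    assert res.grad == pytest.approx([-2.0], abs=tol)


def test_decay_gradient_closed_form_forward(decay_cm, decay_datum):
    res = grad_forward(decay_cm, [1.0, 2.0], decay_datum)
    assert res.grad == pytest.approx([-LN2 / 2, 0.25], abs=1e-8)


def test_decay_gradient_closed_form_adjoint(decay_cm, decay_datum):
    res = grad_adjoint(decay_cm, [1.0, 2.0], decay_datum)
    assert res.grad == pytest.approx([-LN2 / 2, 0.25], abs=1e-6)


def test_decay_gradient_central_fd(decay_cm, decay_datum):
    res = grad_fd(decay_cm, [1.0, 2.0], decay_datum, FdScheme.central(1e-4))
    assert res.grad == pytest.approx([-0.3466, 0.2500], abs=1e-4)


def test_forward_sensitivities_decay_closed_form(decay_cm):
    """s^y = (dy/dk, dy/dx0) = (-t x0 e^{-kt}, e^{-kt}) = (-ln 2, 1/2) at t=ln 2."""
    _, fs = forward_sensitivities(decay_cm, [1.0, 2.0], [LN2])
    assert fs.output_sens[0, 0] == pytest.approx([-LN2, 0.5], abs=1e-6)


def test_initial_state_sensitivity_equals_x0_jacobian(transfection_cm):
    theta = np.array([0.8, 1.2, 0.4, 2.0])
    t0 = transfection_cm.t0
    _, fs = forward_sensitivities(transfection_cm, theta, [t0, 1.0])
    assert fs.state_sens[0] == pytest.approx(transfection_cm.X0_theta(theta))


def test_forward_output_sens_consistent_with_chain_rule(decay_cm):
    """s^y = H_x s^x + H_theta at every stored time."""
    theta = np.array([0.6, 1.4])
    times = np.linspace(0.3, 2.7, 5)
    traj, fs = forward_sensitivities(decay_cm, theta, times)
    for j in range(times.size):
        expected = (
            decay_cm.H_x(traj.states[j], theta) @ fs.state_sens[j]
            + decay_cm.H_theta(traj.states[j], theta)
        )
        assert fs.output_sens[j] == pytest.approx(expected, rel=1e-10)


# ---------------------------------------------------------------------------
# adjoint walk (hand-solved backward problem on the decay fixture)
# ---------------------------------------------------------------------------

def test_adjoint_walk_const(const_cm, const_data):
    """With df/dx = 0 the adjoint is piecewise constant: p(t2)=2, p(t0)=2."""
    traj = simulate(const_cm, [1.0], const_data.times)
    adj = solve_adjoint(const_cm, [1.0], const_data, traj)
    p_plus, p_post = adj.checkpoints[2.0]
    assert p_plus == pytest.approx([0.0])      # p = 0 beyond the last measurement
    assert p_post == pytest.approx([2.0])
    p_plus1, p_post1 = adj.checkpoints[1.0]
    assert p_plus1 == pytest.approx([2.0])
    assert p_post1 == pytest.approx([2.0])     # zero-residual jump adds nothing
    assert adj.p_t0 == pytest.approx([2.0])


def test_adjoint_walk_decay(decay_cm, decay_datum):
    """Closed form: p(t1) = -1/2, p(t) = -e^{t - ln2}/2, p(0) = -1/4,
    and q_k1 = \\int_0^{ln2} p (-x) dt = ln2 / 2."""
    theta = [1.0, 2.0]
    traj = simulate(decay_cm, theta, decay_datum.times)
    adj = solve_adjoint(decay_cm, theta, decay_datum, traj)
    _, p_post = adj.checkpoints[decay_datum.times[0]]
    assert p_post == pytest.approx([-0.5], abs=1e-6)
    assert adj.p_t0 == pytest.approx([-0.25], abs=1e-6)
    assert adj.quadratures == pytest.approx([LN2 / 2, 0.0], abs=1e-6)


def test_adjoint_const_gradient_assembles_from_initial_condition_term(
    const_cm, const_data
):
    """dJ/dtheta = -p(t0) dx0/dtheta = -2 with no quadrature contribution."""
    res = grad_adjoint(const_cm, [1.0], const_data)
    assert res.grad == pytest.approx([-2.0], abs=1e-10)


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

def test_event_gradient_matches_fd_across_the_jump(
    transfection_cm, transfection_theta, transfection_noisy
):
    """Adjoint gradient w.r.t. all four parameters (including the jump
    amount m0, which only enters through the event) matches central FD."""
    st = SolverSettings(rtol=1e-11, atol=1e-18)
    ga = grad_adjoint(transfection_cm, transfection_theta, transfection_noisy, st)
    gd = grad_fd(
        transfection_cm, transfection_theta, transfection_noisy,
        FdScheme.central(1e-6), settings=st,
    )
    assert ga.grad == pytest.approx(gd.grad, rel=1e-4)


def test_forward_and_adjoint_agree_across_events(
    transfection_cm, transfection_theta, transfection_noisy
):
    gf = grad_forward(transfection_cm, transfection_theta, transfection_noisy)
    ga = grad_adjoint(transfection_cm, transfection_theta, transfection_noisy)
    assert ga.grad == pytest.approx(gf.grad, rel=1e-5)


def test_jump_only_parameter_gradient_sign():
    """Toy model: dx/dt=0, x0=0, jump x += theta at t=1, datum at t=2.
    Then y(2) = theta and dJ/dtheta = -(ybar - theta)."""
    cm = compile_model(
        OdeModel(
            state_names=("x",),
            parameter_names=("amount",),
            observable_names=("y",),
            rhs=("0",),
            initial=("0",),
            outputs=("x",),
            events=(__import__("adjfit").EventSpec(1.0, ("x + amount",)),),
        )
    )
    data = ExperimentData(times=[2.0], values=[[3.0]], sigmas=1.0)
    for method in ("fd", "forward", "adjoint"):
        res = gradient(cm, [1.0], data, method=method)
        assert res.grad == pytest.approx([-2.0], abs=1e-6), method


# ---------------------------------------------------------------------------
# cross-method equivalence and stationarity
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", [3, 11])
def test_adjoint_equals_forward_on_random_networks(seed):
    model, theta = make_random_network(NetworkSpec(n_x=6, n_r=12, seed=seed))
    cm = compile_model(model)
    data = generate_data(cm, theta, np.linspace(0.5, 10.0, 8), sigma=0.1,
                         seed=seed + 500)
    gf = grad_forward(cm, theta, data)
    ga = grad_adjoint(cm, theta, data)
    rel = np.max(np.abs(ga.grad - gf.grad) / (np.abs(gf.grad) + 1e-8))
    assert rel <= 1e-5


@pytest.mark.parametrize("method", ["fd", "forward", "adjoint"])
def test_gradient_vanishes_at_data_generating_parameters(
    decay_cm, method
):
    """Noise-free data generated at theta makes theta a stationary point."""
    theta = [1.0, 2.0]
    data = generate_data(decay_cm, theta, np.linspace(0.2, 2.0, 6), sigma=0.0)
    scheme = FdScheme.central(1e-4) if method == "fd" else None
    res = gradient(decay_cm, theta, data, method=method, scheme=scheme)
    assert np.max(np.abs(res.grad)) <= 1e-6


# ---------------------------------------------------------------------------
# FIM
# ---------------------------------------------------------------------------

def test_fim_const_two_points(const_cm, const_data):
    """s^y = 1 at both times with sigma = 1 gives FIM = [[2]]."""
    _, fs = forward_sensitivities(const_cm, [1.0], const_data.times)
    assert fim(fs, const_data) == pytest.approx(np.array([[2.0]]))


def test_fim_symmetric_psd(transfection_cm, transfection_theta, transfection_noisy):
    _, fs = forward_sensitivities(
        transfection_cm, transfection_theta, transfection_noisy.times
    )
    F = fim(fs, transfection_noisy)
    assert F == pytest.approx(F.T)
    assert np.min(np.linalg.eigvalsh(F)) >= -1e-10


def test_fim_all_masked_is_zero(const_cm):
    data = ExperimentData(
        times=[1.0, 2.0], values=[[1.0, 3.0]], sigmas=1.0,
        mask=[[False, False]],
    )
    _, fs = forward_sensitivities(const_cm, [1.0], data.times)
    assert fim(fs, data) == pytest.approx(np.zeros((1, 1)))


# ---------------------------------------------------------------------------
# dispatcher, structural counts, subsets, failure flags
# ---------------------------------------------------------------------------

def test_unknown_method_rejected(const_cm, const_data):
    with pytest.raises(ValueError, match="unknown gradient method"):
        gradient(const_cm, [1.0], const_data, method="magic")


def test_adjoint_backward_solve_count_is_one_for_any_subset():
    model, theta = make_random_network(NetworkSpec(n_x=6, n_r=12, seed=1))
    cm = compile_model(model)
    data = generate_data(cm, theta, np.linspace(0.5, 5.0, 5), sigma=0.1, seed=7)
    for k in (1, 4, 12):
        res = gradient(cm, theta, data, method="adjoint", subset=list(range(k)))
        assert res.diagnostics["n_backward_solves"] == 1
        assert res.diagnostics["n_forward_solves"] == 1
        assert res.grad.size == k


def test_central_fd_simulation_count_is_2k():
    model, theta = make_random_network(NetworkSpec(n_x=6, n_r=12, seed=1))
    cm = compile_model(model)
    data = generate_data(cm, theta, np.linspace(0.5, 5.0, 5), sigma=0.1, seed=7)
    for k in (1, 3, 8):
        res = gradient(cm, theta, data, method="fd", subset=list(range(k)))
        assert res.diagnostics["n_simulations"] == 2 * k


def test_one_sided_fd_simulation_count_is_k_plus_1(const_cm, const_data):
    res = grad_fd(const_cm, [1.0], const_data, FdScheme.forward(1e-4))
    assert res.diagnostics["n_simulations"] == 1 + 1


def test_forward_augmented_dimension_scales_with_subset():
    model, theta = make_random_network(NetworkSpec(n_x=6, n_r=12, seed=1))
    cm = compile_model(model)
    data = generate_data(cm, theta, np.linspace(0.5, 5.0, 5), sigma=0.1, seed=7)
    for k in (1, 5):
        res = gradient(cm, theta, data, method="forward", subset=list(range(k)))
        assert res.diagnostics["augmented_dim"] == cm.n_x * (1 + k)


def test_subset_gradient_matches_full_components(decay_cm, decay_datum):
    full = grad_adjoint(decay_cm, [1.0, 2.0], decay_datum).grad
    only_x0 = grad_adjoint(decay_cm, [1.0, 2.0], decay_datum, subset=[1]).grad
    assert only_x0 == pytest.approx([full[1]], rel=1e-6)


def test_fd_failure_is_flagged_not_silent():
    """A perturbed simulation that blows up flags the component as NaN."""
    cm = compile_model(
        OdeModel(
            state_names=("x",),
            parameter_names=("k",),
            observable_names=("y",),
            rhs=("k*x^2",),
            initial=("1",),
            outputs=("x",),
        )
    )
    data = ExperimentData(times=[1.0], values=[[2.0]], sigmas=1.0)
    # base k=0.5 integrates to t=1 (blow-up at t=2); k+0.6=1.1 blows before t=1
    res = grad_fd(cm, [0.5], data, FdScheme(a=0.6, b=0.0))
    assert np.isnan(res.grad[0])
    assert res.diagnostics["failed_components"] == [0]


def test_adjoint_robust_to_tolerance_tightening(decay_cm, decay_datum):
    g1 = grad_adjoint(decay_cm, [1.0, 2.0], decay_datum,
                      SolverSettings(rtol=1e-8, atol=1e-16)).grad
    g2 = grad_adjoint(decay_cm, [1.0, 2.0], decay_datum,
                      SolverSettings(rtol=1e-13, atol=1e-20)).grad
    assert np.max(np.abs(g1 - g2) / (np.abs(g2) + 1e-8)) <= 1e-4


def test_gradient_with_missing_values(decay_cm):
    """Masked entries drop out of every engine identically."""
    times = np.linspace(0.2, 2.0, 6)
    theta = [1.0, 2.0]
    full = generate_data(decay_cm, theta, times, sigma=0.1, seed=3)
    masked_vals = full.values.copy()
    mask = full.mask.copy()
    mask[0, ::2] = False
    part = ExperimentData(times=times, values=masked_vals, sigmas=full.sigmas,
                          mask=mask)
    grads = [gradient(decay_cm, theta, part, method=m).grad
             for m in ("forward", "adjoint")]
    assert grads[0] == pytest.approx(grads[1], rel=1e-6)
    # and they differ from the full-data gradient
    assert not np.allclose(grads[0], gradient(decay_cm, theta, full,
                                              method="forward").grad)
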