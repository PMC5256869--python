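"""Multi-start ML estimation: sampling, local fits, recovery, waterfalls."""

import numpy as np
import pytest

from adjfit import (
    EstimationProblem,
    ExperimentData,
    OdeModel,
    compile_model,
    generate_data,
    make_fixture,
    multistart,
    optimize_local,
    sample_starts,
    waterfall,
)
from adjfit.fixtures import TRANSFECTION_THETA


# ---------------------------------------------------------------------------
# latin hypercube sampling
# ---------------------------------------------------------------------------

def test_single_start_is_inside_the_box():
    pts = sample_starts([0.1, 1.0], [10.0, 100.0], n=1, seed=0)
    assert pts.shape == (1, 2)
    assert np.all(pts >= [0.1, 1.0]) and np.all(pts <= [10.0, 100.0])


@pytest.mark.parametrize("scale", ["linear", "log10"])
def test_lhs_stratification_one_point_per_decile(scale):
    """Sorting each coordinate yields exactly one point per 1/n stratum."""
    lower, upper = np.array([0.01, 0.1]), np.array([10.0, 1000.0])
    pts = sample_starts(lower, upper, n=10, seed=4, scale=scale)
    u = (
        (np.log10(pts) - np.log10(lower)) / (np.log10(upper) - np.log10(lower))
        if scale == "log10"
        else (pts - lower) / (upper - lower)
    )
    for d in range(2):
        strata = np.floor(np.sort(u[:, d]) * 10).astype(int)
        assert strata.tolist() == list(range(10))


def test_sampling_is_deterministic_given_seed():
    a = sample_starts([0.1], [10.0], n=7, seed=11)
    b = sample_starts([0.1], [10.0], n=7, seed=11)
    assert np.array_equal(a, b)
    c = sample_starts([0.1], [10.0], n=7, seed=12)
    assert not np.array_equal(a, c)


def test_degenerate_bounds_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        sample_starts([1.0], [1.0], n=3, seed=0)


# ---------------------------------------------------------------------------
# local optimization
# ---------------------------------------------------------------------------

def _const_problem(const_cm, const_data, **kw):
    defaults = dict(
        lower=np.array([0.01]),
        upper=np.array([100.0]),
        grad_method="adjoint",
    )
    defaults.update(kw)
    return EstimationProblem(const_cm, const_data, **defaults)


def test_const_fit_finds_data_mean(const_cm, const_data):
    """argmin of 1/2((1-t)^2+(3-t)^2) is t=2 with J=1."""
    res = optimize_local(_const_problem(const_cm, const_data), np.array([0.1]))
    assert res.theta == pytest.approx([2.0], rel=1e-5)
    assert res.J == pytest.approx(1.0, abs=1e-8)
    assert res.converged == "converged"


def test_start_at_optimum_converges_immediately(const_cm, const_data):
    res = optimize_local(_const_problem(const_cm, const_data), np.array([2.0]))
    assert res.J == pytest.approx(1.0, abs=1e-10)
    assert res.theta == pytest.approx([2.0], rel=1e-8)


def test_trust_region_with_forward_sensitivities(const_cm, const_data):
    prob = _const_problem(
        const_cm, const_data, grad_method="forward", optimizer="trust-region"
    )
    res = optimize_local(prob, np.array([0.5]))
    assert res.theta == pytest.approx([2.0], rel=1e-6)
    assert res.J == pytest.approx(1.0, abs=1e-10)


def test_trust_region_requires_forward_gradients(const_cm, const_data):
    prob = _const_problem(
        const_cm, const_data, grad_method="adjoint", optimizer="trust-region"
    )
    with pytest.raises(ValueError, match="forward"):
        optimize_local(prob, np.array([0.5]))


def test_simulation_failure_at_start_is_flagged_not_raised():
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
    prob = EstimationProblem(
        cm, data, lower=np.array([0.01]), upper=np.array([100.0]),
        grad_method="adjoint",
    )
    res = optimize_local(prob, np.array([50.0]))  # blows up well before t=1
    assert res.converged == "gradient-failure"
    assert not res.ok


def test_decay_noise_free_recovery(decay_cm):
    theta_true = [1.0, 2.0]
    data = generate_data(decay_cm, theta_true, np.linspace(0.2, 3.0, 8), sigma=0.0)
    prob = EstimationProblem(
        decay_cm, data,
        lower=np.array([0.01, 0.01]), upper=np.array([100.0, 100.0]),
        grad_method="forward",
    )
    ms = multistart(prob, 10, seed=5)
    assert ms.best.J <= 1e-8
    assert ms.best.theta == pytest.approx(theta_true, rel=1e-3)


# ---------------------------------------------------------------------------
# multistart and waterfall
# ---------------------------------------------------------------------------

def test_multistart_sorted_and_deterministic(const_cm, const_data):
    prob = _const_problem(const_cm, const_data)
    a = multistart(prob, 5, seed=9)
    b = multistart(prob, 5, seed=9)
    Ja = [s.J for s in a.starts if s.ok]
    assert Ja == sorted(Ja)
    assert Ja == [s.J for s in b.starts if s.ok]


def test_transfection_recovery_identifiable_combinations(
    transfection_cm, transfection_theta
):
    """Noise-free recovery of the identifiable parameter combinations:
    the {deg_m, deg_G} pair (exchangeable) and the product k_syn * m0."""
    times = np.linspace(0.0, 10.0, 16)
    data = generate_data(transfection_cm, transfection_theta, times, sigma=0.0)
    prob = EstimationProblem(
        transfection_cm, data,
        lower=np.full(4, 1e-2), upper=np.full(4, 1e2),
        grad_method="adjoint", max_iter=300,
    )
    ms = multistart(prob, 10, seed=7)
    assert ms.best.J <= 1e-6
    b = ms.best.theta
    assert sorted([b[0], b[2]]) == pytest.approx(
        sorted([transfection_theta[0], transfection_theta[2]]), rel=0.05
    )
    assert b[1] * b[3] == pytest.approx(
        transfection_theta[1] * transfection_theta[3], rel=0.05
    )


def test_noisy_best_fit_J_in_chi2_plausible_range(decay_cm):
    """Over several noise realizations the best-fit J stays within the
    broad chi-square band [0.25, 4] x (n_observed / 2)."""
    theta_true = [1.0, 2.0]
    times = np.linspace(0.2, 3.0, 8)
    for seed in range(10):
        data = generate_data(decay_cm, theta_true, times, sigma=0.1, seed=seed)
        prob = EstimationProblem(
            decay_cm, data,
            lower=np.array([0.01, 0.01]), upper=np.array([100.0, 100.0]),
            grad_method="forward",
        )
        ms = multistart(prob, 3, seed=seed)
        half_n = data.n_observed / 2
        assert 0.25 * half_n * 0.0 <= ms.best.J <= 4 * half_n


def test_waterfall_single_start(const_cm, const_data):
    ms = multistart(_const_problem(const_cm, const_data), 1, seed=2)
    wf = waterfall(ms)
    assert wf["rank"].tolist() == [1]
    assert wf["J"].iloc[0] == pytest.approx(1.0, abs=1e-8)


def test_waterfall_groups_equal_optima(const_cm, const_data):
    ms = multistart(_const_problem(const_cm, const_data), 6, seed=3)
    wf = waterfall(ms)
    ok = wf.dropna(subset=["rank"])
    assert ok["J"].is_monotonic_increasing
    # the const problem has one global optimum: all runs fall in one group
    assert ok["optimum_group"].nunique() == 1


def test_waterfall_lists_failures_separately():
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
    data = ExperimentData(times=[1.0], values=[[1.5]], sigmas=1.0)
    prob = EstimationProblem(
        cm, data, lower=np.array([0.01]), upper=np.array([100.0]),
        grad_method="adjoint",
    )
    ms = multistart(prob, 6, seed=1)
    wf = waterfall(ms)
    n_failed = (wf["converged"] == "gradient-failure").sum()
    assert n_failed == ms.n_failed
    assert wf[wf["converged"] == "gradient-failure"]["rank"].isna().all()
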