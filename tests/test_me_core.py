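"""Core reparameterization, entropy, and solver behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mescore import (
    MEProblem,
    SolverOptions,
    SupportGrid,
    WeightMatrix,
    build_support,
    check_solution,
    entropy,
    logistic_model,
    normal_model,
    reparameterize,
    solve_me_normal_closed,
    solve_me_score,
)
from mescore.me_core import DimensionError

from .conftest import make_separated_design

Z_NORMAL = np.array([1.59, 2.10, 2.61, 3.13, 3.64, 4.15, 4.66])
P_NORMAL = np.array([0.087, 0.101, 0.117, 0.136, 0.159, 0.185, 0.215])
Z_POISSON = np.array([0.0, 3.75, 7.5, 11.25, 15.0])
P_POISSON = np.array([0.184, 0.256, 0.283, 0.247, 0.034])


# ---------------------------------------------------------------------------
# reparameterize / entropy
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "z, p, expected, atol",
    [
        (Z_NORMAL, P_NORMAL, 3.432, 5e-3),
        # reference weights are printed to 3 dp and sum to 1.004; after
        # renormalization the expectation moves by ~0.03
        (Z_POISSON, P_POISSON, 6.375, 5e-2),
        (np.linspace(-3, 3, 9), np.full(9, 1 / 9), 0.0, 1e-12),
    ],
)
def test_reparameterize_examples(z, p, expected, atol):
    grid = SupportGrid((z,))
    weights = WeightMatrix((p / p.sum(),))
    assert reparameterize(grid, weights)[0] == pytest.approx(expected, abs=atol)


def test_reparameterize_dimension_mismatch_names_parameter():
    grid = SupportGrid((np.array([0.0, 1.0, 2.0]),), ("lambda",))
    weights = WeightMatrix((np.array([0.5, 0.5]),))
    with pytest.raises(DimensionError, match="lambda"):
        reparameterize(grid, weights)


def test_entropy_uniform_point_mass_and_additivity():
    assert entropy(WeightMatrix.uniform([7])) == pytest.approx(np.log(7))
    assert entropy(WeightMatrix((np.array([1.0, 0, 0, 0]),))) == 0.0
    assert entropy(WeightMatrix.uniform([5, 5])) == pytest.approx(2 * np.log(5))


def test_weight_matrix_rejects_invalid_rows():
    with pytest.raises(ValueError):
        WeightMatrix((np.array([0.6, 0.6]),))  # sums to 1.2
    with pytest.raises(ValueError):
        WeightMatrix((np.array([1.2, -0.2]),))  # negative entry


def test_support_grid_rejects_degenerate_and_unsorted():
    with pytest.raises(ValueError):
        SupportGrid((np.array([1.0]),))  # point mass
    with pytest.raises(ValueError):
        SupportGrid((np.array([1.0, 0.5, 2.0]),))


@given(
    st.lists(st.floats(-50, 50), min_size=3, max_size=8, unique=True),
    st.lists(st.floats(0.01, 1.0), min_size=3, max_size=8),
)
@settings(max_examples=30, deadline=None, derandomize=True)
def test_reparameterize_stays_inside_support_box(points, raw_weights):
    k = min(len(points), len(raw_weights))
    z = np.sort(np.asarray(points[:k]))
    if np.any(np.diff(z) <= 0):
        return
    p = np.asarray(raw_weights[:k])
    p = p / p.sum()
    theta = reparameterize(SupportGrid((z,)), WeightMatrix((p,)))[0]
    assert z[0] - 1e-9 <= theta <= z[-1] + 1e-9


# ---------------------------------------------------------------------------
# closed-form normal path
# ---------------------------------------------------------------------------


def test_normal_closed_form_worked_example(normal_sample):
    """Known n=12 sample, sigma2=1, K=7: multiplier, mean and weights."""
    fit = solve_me_normal_closed(normal_sample, 1.0, Z_NORMAL)
    assert fit.theta_hat[0] == pytest.approx(3.432, abs=1e-3)
    assert abs(fit.multipliers["lambda1"]) == pytest.approx(0.024, abs=2e-3)
    np.testing.assert_allclose(fit.weights_hat.rows[0], P_NORMAL, atol=2e-3)
    assert fit.feasible and fit.converged


def test_normal_closed_uniform_weights_at_symmetric_midpoint():
    z = np.linspace(-2.0, 2.0, 5)
    y = np.array([-1.0, 1.0])  # mean at the midpoint of a symmetric grid
    fit = solve_me_normal_closed(y, 1.0, z)
    assert fit.multipliers["lambda1"] == pytest.approx(0.0, abs=1e-10)
    np.testing.assert_allclose(fit.weights_hat.rows[0], 0.2, atol=1e-10)


def test_normal_closed_mean_outside_support_raises():
    with pytest.raises(ValueError, match="widen"):
        solve_me_normal_closed(np.array([10.0, 12.0]), 1.0, np.linspace(0, 5, 5))


@given(st.integers(0, 10_000))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_normal_closed_root_residual(seed):
    rng = np.random.default_rng(seed)
    y = rng.normal(rng.uniform(-5, 5), 1.0, size=rng.integers(3, 40))
    z = np.linspace(y.min() - 1, y.max() + 1, 7)
    fit = solve_me_normal_closed(y, 1.0, z)
    assert abs(fit.theta_hat[0] - y.mean()) < 1e-10


def test_gibbs_mean_is_monotone_in_multiplier(normal_sample):
    """z'p(l1) strictly decreasing in l1 implies a unique 1-D root."""
    n = normal_sample.size
    lams = np.linspace(-0.5, 0.5, 41)
    means = []
    for lam in lams:
        e = -Z_NORMAL * lam * n
        e -= e.max()
        p = np.exp(e)
        means.append(Z_NORMAL @ (p / p.sum()))
    assert np.all(np.diff(means) < 0)


# ---------------------------------------------------------------------------
# general solver vs oracle
# ---------------------------------------------------------------------------


def test_general_solver_matches_closed_form_oracle(rng):
    """On random normal samples the two solution paths agree to 1e-6."""
    model = normal_model(1.0)
    for _ in range(50):
        y = rng.normal(rng.uniform(-4, 4), 1.0, size=rng.integers(5, 30))
        grid = build_support("normal", y, 7)
        closed = solve_me_normal_closed(y, 1.0, grid.points_per_param[0])
        fit = solve_me_score(MEProblem(model, grid), y)
        assert fit.feasible
        assert abs(fit.theta_hat[0] - closed.theta_hat[0]) < 1e-6
        assert abs(fit.theta_hat[0] - y.mean()) < 1e-6


def test_general_solver_multiplier_matches_closed_form(normal_sample):
    grid = SupportGrid((Z_NORMAL,))
    fit = solve_me_score(MEProblem(normal_model(1.0), grid), normal_sample)
    closed = solve_me_normal_closed(normal_sample, 1.0, Z_NORMAL)
    assert fit.multipliers is not None
    assert fit.multipliers["score"][0] == pytest.approx(
        closed.multipliers["lambda1"], abs=1e-6
    )


def test_translation_equivariance_normal(rng):
    y = rng.normal(1.0, 1.0, 15)
    c = 3.7
    fit = solve_me_score(
        MEProblem(normal_model(1.0), build_support("normal", y, 7)), y
    )
    fit_shift = solve_me_score(
        MEProblem(normal_model(1.0), build_support("normal", y + c, 7)), y + c
    )
    assert fit_shift.theta_hat[0] - fit.theta_hat[0] == pytest.approx(c, abs=1e-8)


def test_entropy_bound_and_uniform_start():
    grid = SupportGrid((np.linspace(0, 1, 5), np.linspace(0, 2, 7)))
    bound = np.log(5) + np.log(7)
    assert entropy(WeightMatrix.uniform(grid.sizes)) == pytest.approx(bound)
    # any fit entropy stays below the product-simplex maximum
    y = np.array([0.4, 0.6, 0.5])
    fit = solve_me_score(
        MEProblem(normal_model(1.0), build_support("normal", y, 7)), y
    )
    assert fit.entropy_value <= np.log(7) + 1e-9


def test_solver_reports_infeasible_without_raising(rng):
    """Complete separation: score has no root in the box; fit is flagged."""
    design = make_separated_design(rng, n=24, p=1)
    problem = MEProblem(
        logistic_model(2), build_support("logistic", design, 7, bound=10.0)
    )
    fit = solve_me_score(problem, design)
    assert not fit.feasible
    assert np.all(np.isfinite(fit.theta_hat))
    for theta, (lo, hi) in zip(fit.theta_hat, problem.supports.box()):
        assert lo - 1e-9 <= theta <= hi + 1e-9


def test_solver_options_validation_and_roundtrip():
    with pytest.raises(ValueError):
        SolverOptions(constraint_tolerance=-1.0)
    with pytest.raises(ValueError):
        SolverOptions(probability_floor=0.9)
    opts = SolverOptions(max_iterations=77)
    assert SolverOptions.from_dict(opts.to_dict()) == opts


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def test_check_solution_passes_on_clean_fit(normal_sample):
    problem = MEProblem(normal_model(1.0), SupportGrid((Z_NORMAL,)))
    fit = solve_me_score(problem, normal_sample)
    report = check_solution(fit, problem, normal_sample)
    assert report.ok, report.failures()


def test_check_solution_flags_bad_row_sum(normal_sample):
    import dataclasses

    problem = MEProblem(normal_model(1.0), SupportGrid((Z_NORMAL,)))
    fit = solve_me_score(problem, normal_sample)
    bad_row = fit.weights_hat.rows[0] * 0.9
    tampered = dataclasses.replace(
        fit, weights_hat=object.__new__(WeightMatrix.__mro__[0])
    )
    # bypass WeightMatrix validation to emulate a corrupted result
    object.__setattr__(tampered.weights_hat, "rows", (bad_row,))
    report = check_solution(tampered, problem, normal_sample)
    assert not report.ok
    assert "row_normalization" in report.failures()


def test_check_solution_flags_score_residual_under_separation(rng):
    design = make_separated_design(rng, n=24, p=1)
    problem = MEProblem(
        logistic_model(2), build_support("logistic", design, 7, bound=10.0)
    )
    fit = solve_me_score(problem, design)
    report = check_solution(fit, problem, design)
    assert report.failures() == ["score_residual"]
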