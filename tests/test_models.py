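"""Dose-toxicity surfaces: closed-form limits, constraints, gradients,
partial-order conformity and the uniform-monotonicity checker."""

import numpy as np
import pytest
from scipy.special import expit

from combocrm.grid import DoseGrid
from combocrm.models import (
    ConfigurationError,
    ConstraintViolationError,
    EPS_CONSTRAINT,
    ModelSpec,
    check_constraints,
    check_partial_order_matrix,
    check_uniform_monotonicity,
    evaluate_toxicity,
    family_names,
    grad_toxicity,
    toxicity_at,
    toxicity_matrix,
    toxicity_table,
)
from combocrm.priors import default_prior

GRID_SK = DoseGrid(
    (0.1, 0.2), (0.1, 0.2), skeleton_p=(1e-18, 0.5), skeleton_q=(0.2, 0.4)
)


class TestClosedFormLimits:
    """Boundary identities of the printed formulas, to 1e-12."""

    def test_logistic_at_zero_theta(self):
        spec = ModelSpec("logistic4", (0, 0, 0, 0))
        grid = DoseGrid((1.0, 2.0), (0.5, 1.5))
        for j, k in grid.levels():
            assert evaluate_toxicity(spec, grid, j, k, check=False) == 0.5

    def test_logistic_hand_value(self):
        # logit^-1(-1 + 0.5 + 0.5 + 0.1) at (u, v) = (1, 1)
        grid = DoseGrid((1.0, 2.0), (1.0, 2.0))
        f = toxicity_at("logistic4", np.array([-1, 0.5, 0.5, 0.1]), grid, (1, 1))
        assert abs(f - expit(0.1)) < 1e-12
        assert abs(f - 0.52497918747894) < 1e-11

    def test_clayton_marginal_collapse(self):
        # p_j -> 0 kills the (1 - p^alpha)^(-gamma) factor: F = q_k^beta
        f = toxicity_at("clayton", np.array([1.2, 0.8, 1.5]), GRID_SK, (1, 2))
        assert abs(f - 0.4**0.8) < 1e-12

    def test_gumbel_independence_limit(self):
        # gamma = 0 makes the association bracket equal one
        f = toxicity_at("gumbel", np.array([1.2, 0.8, 0.0]), GRID_SK, (2, 2))
        expected = 1 - (1 - 0.5**1.2) * (1 - 0.4**0.8)
        assert abs(f - expected) < 1e-12

    def test_log_linear_no_interaction(self):
        grid = DoseGrid((0.1, 0.3), (0.2, 0.4))
        f = toxicity_at("log_linear", np.array([1.1, 0.7, 0.0]), grid, (2, 1))
        assert abs(f - (1 - (1 - 0.3) ** 1.1 * (1 - 0.2) ** 0.7)) < 1e-12

    def test_six_param_zero_dose(self):
        grid = DoseGrid((0.0, 0.5), (0.0, 0.5))
        f = toxicity_at("six_param", np.ones(6), grid, (1, 1))
        assert f == 0.0

    def test_change_point_plateau(self):
        # alpha + beta*u + gamma*v = w + 10 -> the cap expit(w)
        w = 0.8
        grid = DoseGrid((10.0, 11.0), (0.3, 0.5))
        theta = np.array([w + 10 - 10.0 - 0.3, 1.0, 1.0, w])
        f = toxicity_at("change_point", theta, grid, (1, 1))
        assert abs(f - expit(w)) < 1e-12


class TestConstraints:
    def test_logistic_admissible(self, bank):
        rep = check_constraints(ModelSpec("logistic4", (0, 1, 1, 0)), bank["grid_4x4_raw"])
        assert rep.admissible and not rep.violations

    def test_logistic_interaction_violation_named(self):
        grid = DoseGrid((0.2, 0.6), (0.5, 1.0))
        rep = check_constraints(ModelSpec("logistic4", (0, 1, 1, -2)), grid)
        assert not rep.admissible
        assert any("theta2 + theta4*v_2" in v for v in rep.violations)

    def test_log_linear_gamma_sign(self):
        grid = DoseGrid((0.1, 0.3), (0.2, 0.4))
        rep = check_constraints(ModelSpec("log_linear", (1, 1, +0.5)), grid)
        assert not rep.admissible and "gamma < 0" in rep.violations

    def test_boundary_theta_inadmissible(self):
        grid = DoseGrid((0.5, 1.0), (0.5, 1.0))
        rep = check_constraints(ModelSpec("logistic4", (0, 0.0, 1, 0)), grid)
        assert not rep.admissible  # theta2 = 0 sits on the open boundary

    def test_evaluate_raises_on_inadmissible(self):
        grid = DoseGrid((0.5, 1.0), (0.5, 1.0))
        with pytest.raises(ConstraintViolationError, match="theta2"):
            evaluate_toxicity(ModelSpec("logistic4", (0, -1, 1, 0)), grid, 1, 1)

    def test_copula_needs_skeleton(self):
        grid = DoseGrid((0.5, 1.0), (0.5, 1.0))
        with pytest.raises(ConfigurationError, match="skeleton"):
            evaluate_toxicity(ModelSpec("clayton", (1, 1, 1)), grid, 1, 1, check=False)

    def test_wrong_dimension(self):
        grid = DoseGrid((0.5, 1.0), (0.5, 1.0))
        with pytest.raises(ConfigurationError, match="parameters"):
            check_constraints(ModelSpec("logistic4", (1, 1, 1)), grid)


@pytest.mark.parametrize("family", family_names())
def test_partial_order_conformity(family, bank):
    """F strictly increases along rows and columns for sampled admissible
    thetas (change-point: nondecreasing, ties only at the plateau cap)."""
    grid = bank[bank["canonical_grid"][family]]
    prior = default_prior(family, grid)
    thetas = prior.sample_admissible(np.random.default_rng(42), 500, grid)
    table = toxicity_table(family, thetas, grid)
    if family == "change_point":
        for th, m in zip(thetas, table):
            assert check_partial_order_matrix(m, family, cap=expit(th[3]))
    else:
        assert (np.diff(table, axis=1) > 0).all()
        assert (np.diff(table, axis=2) > 0).all()


def test_toxicity_matrix_consistency(bank):
    grid = bank["grid_4x4_unit"]
    spec = ModelSpec("six_param", (0.5, 0.4, 0.3, 1.0, 1.2, 0.8))
    m = toxicity_matrix(spec, grid)
    for j, k in grid.levels():
        assert m[j - 1, k - 1] == evaluate_toxicity(spec, grid, j, k, check=False)


def test_scaled_logistic_plateau(bank):
    grid = bank["grid_4x4_std"]
    prior = default_prior("scaled_logistic", grid)
    thetas = prior.sample_admissible(np.random.default_rng(7), 200, grid)
    table = toxicity_table("scaled_logistic", thetas, grid)
    assert (table < thetas[:, 0][:, None, None]).all()


def test_change_point_cap(bank):
    grid = bank["grid_4x4_raw"]
    prior = default_prior("change_point", grid)
    thetas = prior.sample_admissible(np.random.default_rng(8), 200, grid)
    table = toxicity_table("change_point", thetas, grid)
    caps = expit(thetas[:, 3])[:, None, None]
    assert (table <= caps + 1e-15).all()


class TestGradients:
    def test_logistic_gradient_closed_form(self):
        grid = DoseGrid((1.0, 2.0), (1.0, 2.0))
        g = grad_toxicity(ModelSpec("logistic4", (0, 0, 0, 0)), grid, 1, 1)
        assert not g.kink
        np.testing.assert_allclose(g.grad, 0.25 * np.ones(4), rtol=1e-8)

    @pytest.mark.parametrize("family", ["clayton", "gumbel"])
    def test_copula_nonincreasing_in_alpha(self, family, bank):
        grid = bank["grid_4x4_std"]
        prior = default_prior(family, grid)
        thetas = prior.sample_admissible(np.random.default_rng(3), 100, grid)
        for th in thetas[:20]:
            g = grad_toxicity(ModelSpec(family, tuple(th)), grid, 2, 3)
            assert (g.grad <= 1e-12).all()  # uniformly nonincreasing family

    def test_six_param_alpha1_analytic(self, bank):
        grid = bank["grid_4x4_unit"]
        prior = default_prior("six_param", grid)
        thetas = prior.sample_admissible(np.random.default_rng(4), 100, grid)
        u, v = grid.dose((3, 2))
        for th in thetas:
            a1, a2, a3, b1, b2, b3 = th
            G = a1 * u**b1 + a2 * v**b2 + a3 * (u**b1 * v**b2) ** b3
            analytic = u**b1 / (1 + G) ** 2
            g = grad_toxicity(ModelSpec("six_param", tuple(th)), grid, 3, 2)
            assert g.grad[0] >= 0
            np.testing.assert_allclose(g.grad[0], analytic, rtol=1e-6)

    def test_change_point_kink_flagged(self, bank):
        fx = bank["kink_change_point"]
        g = grad_toxicity(
            ModelSpec("change_point", fx["theta"]), fx["grid"], *fx["level"]
        )
        assert g.kink and g.one_sided
        # off the kink surface no flag
        g2 = grad_toxicity(
            ModelSpec("change_point", (0.0, 1.0, 1.0, 5.0)), fx["grid"], *fx["level"]
        )
        assert not g2.kink


class TestUniformMonotonicity:
    def test_raw_dose_logistic_nondecreasing(self, bank):
        grid = bank["grid_4x4_raw"]
        prior = default_prior("logistic4", grid)
        rep = check_uniform_monotonicity(
            "logistic4", grid, prior.sampler(grid, 0), n_thetas=40, seed=0
        )
        assert rep.uniformly_monotone and rep.direction == "nondecreasing"
        assert all(q.direction == "nondecreasing" for q in rep.params)

    def test_mixed_sign_doses_falsified_with_witness(self, bank):
        grid = bank["grid_4x4_std"]  # contains u_j of both signs
        prior = default_prior("logistic4", grid)
        rep = check_uniform_monotonicity(
            "logistic4", grid, prior.sampler(grid, 0), n_thetas=40, seed=0
        )
        assert not rep.uniformly_monotone
        assert rep.witness is not None
        flagged = {q.name for q in rep.params if q.direction == "not_uniformly_monotone"}
        assert flagged & {"theta2", "theta3", "theta4"}

    def test_all_negative_doses_direction_conflict(self):
        # every dose negative: each parameter is one-directional on the grid
        # but theta1 rises while theta2/theta3 fall -> no common direction
        grid = DoseGrid((-2.0, -1.5), (-1.8, -1.2))
        prior = default_prior("logistic4", grid)
        rep = check_uniform_monotonicity(
            "logistic4", grid, prior.sampler(grid, 1), n_thetas=30, seed=1
        )
        assert not rep.uniformly_monotone and rep.witness is not None

    def test_clayton_uniformly_nonincreasing(self, bank):
        grid = bank["grid_4x4_std"]
        prior = default_prior("clayton", grid)
        rep = check_uniform_monotonicity(
            "clayton", grid, prior.sampler(grid, 2), n_thetas=40, seed=2
        )
        assert rep.uniformly_monotone and rep.direction == "nonincreasing"

    def test_deterministic_given_seed(self, bank):
        grid = bank["grid_4x4_std"]
        prior = default_prior("logistic4", grid)
        reps = [
            check_uniform_monotonicity(
                "logistic4", grid, prior.sampler(grid, 5), n_thetas=10, seed=9
            ).to_dict()
            for _ in range(2)
        ]
        assert reps[0] == reps[1]
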