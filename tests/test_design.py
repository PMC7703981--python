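"""Candidate-set geometry, the target-closest selection rule, titration and
trial simulation invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from combocrm.design import (
    SWITCH,
    TwoStageConfig,
    candidate_sets_d,
    candidate_sets_nd,
    check_theorem6_condition,
    run_trial,
    select_next_dose,
    titration_next,
)
from combocrm.grid import DoseGrid
from combocrm.models import ConfigurationError
from combocrm.posterior import PosteriorEngine
from combocrm.priors import default_prior
from combocrm.scenarios import ToxScenario, gen_scenario
from conftest import make_trace


def _grid(J, K):
    return DoseGrid(tuple(0.5 * np.arange(1, J + 1)), tuple(0.4 * np.arange(1, K + 1)))


def _monotone_matrix(J, K, seed=0):
    rng = np.random.default_rng(seed)
    return np.cumsum(rng.random((J, K)) + 0.05, axis=0).cumsum(axis=1) / (J * K + 4)


class TestCandidateSetsND:
    def test_interior(self):
        s = candidate_sets_nd((2, 2), _grid(3, 3))
        assert s.escalation == {(3, 2), (2, 3)}
        assert s.deescalation == {(1, 2), (2, 1)}
        assert s.admissible == {(2, 2), (3, 2), (2, 3), (1, 2), (2, 1)}

    def test_corner_clipping(self):
        s = candidate_sets_nd((1, 1), _grid(3, 3))
        assert s.escalation == {(2, 1), (1, 2)} and not s.deescalation

    def test_degenerate_grid(self):
        s = candidate_sets_nd((1, 1), _grid(1, 1))
        assert s.admissible == {(1, 1)}


class TestCandidateSetsD:
    def test_diagonal_classification(self):
        grid = _grid(3, 3)
        est = _monotone_matrix(3, 3)
        est[2, 0] = est[1, 1] + 0.1  # F(3,1) above current (2,2)
        est[0, 2] = est[1, 1] - 0.1  # F(1,3) below
        s = candidate_sets_d((2, 2), grid, est)
        assert (3, 1) in s.escalation and (1, 3) in s.deescalation

    def test_exact_tie_excluded(self):
        grid = _grid(3, 3)
        est = _monotone_matrix(3, 3)
        est[2, 0] = est[1, 1]
        s = candidate_sets_d((2, 2), grid, est)
        assert (3, 1) not in s.admissible

    def test_strong_vs_weak_source(self):
        grid = _grid(3, 3)
        est = _monotone_matrix(3, 3)
        est[2, 0] = est[1, 1] + 0.2
        truth = _monotone_matrix(3, 3, seed=1)
        truth[2, 0] = truth[1, 1] - 0.2
        weak = candidate_sets_d((2, 2), grid, est, "weak")
        strong = candidate_sets_d((2, 2), grid, truth, "strong")
        assert (3, 1) in weak.escalation and (3, 1) in strong.deescalation


@pytest.mark.parametrize("J,K", [(1, 1), (1, 4), (4, 1), (3, 3), (5, 5), (5, 4)])
def test_candidate_set_invariants_exhaustive(J, K):
    grid = _grid(J, K)
    ordering = _monotone_matrix(J, K)
    for current in grid.levels():
        for s in (
            candidate_sets_nd(current, grid),
            candidate_sets_d(current, grid, ordering),
        ):
            assert s.admissible == s.escalation | s.deescalation | {current}
            assert not s.escalation & s.deescalation
            j, k = current
            for lvl in s.escalation | s.deescalation:
                assert grid.contains(lvl)
                dj, dk = lvl[0] - j, lvl[1] - k
                assert abs(dj) + abs(dk) == 1 or (
                    s.design_kind == "d" and (dj, dk) in ((1, -1), (-1, 1))
                )
                assert (dj, dk) not in ((1, 1), (-1, -1))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    J=st.integers(1, 5), K=st.integers(1, 5),
    j=st.integers(1, 5), k=st.integers(1, 5), seed=st.integers(0, 10),
)
def test_candidate_set_invariants_property(J, K, j, k, seed):
    if j > J or k > K:
        return
    grid = _grid(J, K)
    s = candidate_sets_d((j, k), grid, _monotone_matrix(J, K, seed))
    assert s.admissible == s.escalation | s.deescalation | {(j, k)}
    assert (j + 1, k + 1) not in s.admissible - {(j, k)}


class TestSelectNextDose:
    def test_unique_argmin(self):
        est = np.array([[0.10, 0.45], [0.28, 0.6]])
        grid = _grid(2, 2)
        s = candidate_sets_nd((1, 1), grid)
        assert select_next_dose(est, s, 0.30) == (2, 1)

    def test_exact_tie_prefers_current(self, bank):
        fx = bank["tie_eq2"]
        s = candidate_sets_nd(fx["current"], _grid(3, 3))
        assert select_next_dose(fx["estimates"], s, fx["p_T"]) == fx["current"]

    def test_tie_without_current_prefers_lower_partial_order(self, bank):
        fx = bank["tie_eq2"]
        # current estimate pushed away from the tie: (3,2) and (2,3) remain
        # exactly tied; both are partial-order minimal -> lexicographic (2,3)
        est = fx["estimates"].copy()
        est[1, 1] = 0.9
        s = candidate_sets_nd(fx["current"], _grid(3, 3))
        assert select_next_dose(est, s, fx["p_T"]) == (2, 3)

    def test_singleton_admissible(self):
        est = np.array([[0.5]])
        s = candidate_sets_nd((1, 1), _grid(1, 1))
        assert select_next_dose(est, s, 0.3) == (1, 1)

    def test_presentation_order_invariance(self):
        est = _monotone_matrix(4, 4)
        grid = _grid(4, 4)
        s = candidate_sets_d((2, 3), grid, est)
        picks = {select_next_dose(est, s, 0.30) for _ in range(5)}
        assert len(picks) == 1


class TestTitration:
    PATH = ((1, 1), (2, 1), (2, 2))

    def test_advance_on_no_tox(self):
        cfg = TwoStageConfig(self.PATH)
        assert titration_next(cfg, 0, 0) == (2, 1)

    def test_switch_on_first_toxicity(self):
        cfg = TwoStageConfig(self.PATH)
        assert titration_next(cfg, 0, 1) == SWITCH

    def test_exhaustion_switches_by_default(self):
        cfg = TwoStageConfig(self.PATH)
        assert titration_next(cfg, 2, 0) == SWITCH

    def test_pure_first_toxicity_rule_holds_top(self):
        cfg = TwoStageConfig(self.PATH, switch_rule="first_toxicity")
        assert titration_next(cfg, 2, 0) == (2, 2)

    @pytest.mark.parametrize(
        "path", [((2, 1),), ((1, 1), (3, 1)), ((1, 1), (2, 2)), ((1, 1), (1, 1))]
    )
    def test_invalid_paths_rejected(self, path):
        with pytest.raises(ConfigurationError):
            TwoStageConfig(path)

    def test_staircase_is_valid_and_monotone(self, bank):
        TwoStageConfig(bank["path_staircase_4x4"]).validate(bank["grid_4x4_raw"])
        TwoStageConfig(bank["path_agent1_first_4x4"]).validate(bank["grid_4x4_raw"])


@pytest.fixture(scope="module")
def sim_parts(bank):
    grid = bank["grid_4x4_std"]
    prior = bank["prior_logistic4"]
    engine = PosteriorEngine("logistic4", grid, prior, seed=0)
    scenario = gen_scenario(4, 4, 0.3, seed=5, grid=grid)
    return grid, prior, engine, scenario


class TestRunTrial:
    def test_single_patient(self, sim_parts):
        grid, prior, engine, scenario = sim_parts
        tr = run_trial(
            "one_stage_nd", "logistic4", prior, grid, scenario, 0.3, 1,
            seed=0, start=(2, 2), engine=engine,
        )
        assert tr.N == 1 and tr.records[0].level == (2, 2)
        assert tr.records[0].next_level is None

    def test_default_start_is_prior_mtd(self, sim_parts):
        grid, prior, engine, scenario = sim_parts
        tr = run_trial(
            "one_stage_nd", "logistic4", prior, grid, scenario, 0.3, 1,
            seed=0, engine=engine,
        )
        d = np.abs(tr.f_hat_prior - 0.3)
        assert d[tr.start_level[0] - 1, tr.start_level[1] - 1] == d.min()

    def test_no_toxicity_two_stage_titrates_then_escalates(self, sim_parts):
        grid, prior, engine, _ = sim_parts
        safe = ToxScenario(grid, np.clip(gen_scenario(4, 4, 0.3, seed=1).p * 1e-5, 1e-9, 1))
        tr = run_trial(
            "two_stage_nd", "logistic4", prior, grid, safe, 0.3, 12,
            seed=3, engine=engine,
        )
        path = tr.titration_path
        doses = tr.doses()
        m = tr.switch_index
        assert m == len(path) + 1  # path exhausted, no toxicity seen
        assert tuple(doses[: len(path)]) == path
        for rec in tr.records[:-1]:  # never a de-escalation move
            dj = rec.next_level[0] - rec.level[0]
            dk = rec.next_level[1] - rec.level[1]
            assert dj >= 0 and dk >= 0

    def test_seeded_determinism(self, sim_parts):
        grid, prior, engine, scenario = sim_parts
        a = run_trial("one_stage_d", "logistic4", prior, grid, scenario, 0.3, 30,
                      seed=11, engine=engine)
        b = run_trial("one_stage_d", "logistic4", prior, grid, scenario, 0.3, 30,
                      seed=11, engine=engine)
        assert a.doses() == b.doses()
        for ra, rb in zip(a.records, b.records):
            np.testing.assert_array_equal(ra.theta_hat, rb.theta_hat)
            np.testing.assert_array_equal(ra.f_hat, rb.f_hat)

    @pytest.mark.parametrize("design", ["one_stage_nd", "one_stage_d", "two_stage_nd"])
    def test_no_dose_skipping(self, design, sim_parts):
        grid, prior, engine, scenario = sim_parts
        for seed in range(4):
            tr = run_trial(design, "logistic4", prior, grid, scenario, 0.3, 25,
                           seed=seed, engine=engine)
            for rec in tr.records[:-1]:
                dj = rec.next_level[0] - rec.level[0]
                dk = rec.next_level[1] - rec.level[1]
                assert (abs(dj) + abs(dk) <= 1) or (
                    design.endswith("_d") and (dj, dk) in ((1, -1), (-1, 1))
                )

    def test_two_stage_bookkeeping(self, sim_parts):
        grid, prior, engine, scenario = sim_parts
        for seed in range(6):
            tr = run_trial("two_stage_nd", "logistic4", prior, grid, scenario,
                           0.3, 20, seed=seed, engine=engine)
            m = tr.switch_index
            if m is None:
                continue
            for rec in tr.records:
                assert rec.stage == ("titration" if rec.n < m else "model")
            assert all(
                d == p for d, p in zip(tr.doses()[: m - 1], tr.titration_path)
            )

    def test_outcome_override(self, sim_parts):
        grid, prior, engine, scenario = sim_parts
        tr = run_trial("two_stage_nd", "logistic4", prior, grid, scenario, 0.3, 4,
                       seed=0, outcomes=[0, 0, 1, 0], engine=engine)
        assert [r.y for r in tr.records] == [0, 0, 1, 0]
        assert tr.switch_index == 4  # toxicity at patient 3 fires the rule


class TestTheorem6:
    def test_not_applicable_without_switch(self, bank):
        grid = bank["grid_3x3_raw"]
        tr = make_trace(grid, [((1, 1), 0), ((2, 1), 0)])
        rep = check_theorem6_condition(tr, default_prior("logistic4", grid))
        assert not rep.applicable

    def test_holds_for_partial_order_descent(self, bank):
        # Y_M = 1 and X_{M+1} below X_M in the known partial order: the
        # difference is negative for every admissible theta
        grid = bank["grid_4x4_std"]
        tr = make_trace(
            grid,
            [((1, 1), 0), ((2, 1), 1), ((2, 2), 1), ((2, 1), 0)],
            design="two_stage_nd",
            switch_index=3,
        )
        rep = check_theorem6_condition(tr, default_prior("logistic4", grid), seed=4)
        assert rep.applicable and rep.holds

    def test_violation_detected_on_antidiagonal_move(self, bank):
        # Y_M = 1 followed by an anti-diagonal move whose model difference
        # changes sign over the prior support -> witness found
        grid = bank["grid_4x4_std"]
        tr = make_trace(
            grid,
            [((2, 1), 0), ((2, 2), 1), ((2, 2), 1), ((3, 1), 0)],
            design="two_stage_d",
            switch_index=3,
        )
        rep = check_theorem6_condition(
            tr, default_prior("logistic4", grid), n_thetas=400, seed=4
        )
        assert rep.applicable and rep.holds is False
        assert rep.witness is not None and rep.witness["product"] > 0
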