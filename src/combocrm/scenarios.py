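"""True-toxicity scenarios and the named fixtures used by the audit suites.

A :class:`ToxScenario` holds the true DLT probabilities p_jk of a simulated
trial.  Every scenario respects the known partial order — toxicity strictly
increases along each row and column — while anti-diagonal cells remain
unconstrained relative to each other, which is exactly the structure that
makes combination-trial coherence subtle.

:func:`gen_misspecified_pair` constructs the canonical counterexample: a
model whose estimated ordering ranks an anti-diagonal neighbour *above* the
current dose while the truth ranks it *below*, so a D-design transition into
it after a non-toxicity is weakly coherent but strongly incoherent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.special import expit, logit

from .grid import DoseGrid, Level
from .models import ConfigurationError, ModelSpec, toxicity_matrix
from .priors import Prior, prior_from_spec

__all__ = [
    "ToxScenario",
    "gen_scenario",
    "gen_misspecified_pair",
    "fixture_bank",
]


@dataclass(frozen=True)
class ToxScenario:
    """True DLT probabilities on a dose grid, conforming the partial order."""

    grid: DoseGrid
    p: np.ndarray
    mtd_target: Optional[Level] = None

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        if p.shape != self.grid.shape:
            raise ConfigurationError(
                f"scenario shape {p.shape} does not match grid {self.grid.shape}"
            )
        if not ((p > 0.0) & (p < 1.0)).all():
            raise ConfigurationError("scenario probabilities must lie in (0,1)")
        if p.shape[0] > 1 and not (np.diff(p, axis=0) > 0).all():
            raise ConfigurationError("scenario must strictly increase along rows")
        if p.shape[1] > 1 and not (np.diff(p, axis=1) > 0).all():
            raise ConfigurationError("scenario must strictly increase along columns")
        if self.mtd_target is not None:
            self.grid.require(self.mtd_target)

    def prob(self, level: Level) -> float:
        j, k = self.grid.require(level)
        return float(self.p[j - 1, k - 1])

    def mtd(self, p_T: float) -> Level:
        """The combination whose true DLT probability is closest to p_T."""
        j, k = np.unravel_index(np.argmin(np.abs(self.p - p_T)), self.p.shape)
        return (int(j) + 1, int(k) + 1)

    # -- serialization (CSV matrix + JSON sidecar) ---------------------------
    def save(self, csv_path: str | Path) -> None:
        csv_path = Path(csv_path)
        np.savetxt(csv_path, self.p, delimiter=",", fmt="%.17g")
        sidecar = {
            "grid": self.grid.to_dict(),
            "mtd_target": list(self.mtd_target) if self.mtd_target else None,
        }
        csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, csv_path: str | Path) -> "ToxScenario":
        csv_path = Path(csv_path)
        p = np.atleast_2d(np.loadtxt(csv_path, delimiter=","))
        side = json.loads(csv_path.with_suffix(".json").read_text())
        mtd = tuple(side["mtd_target"]) if side.get("mtd_target") else None
        return cls(DoseGrid.from_dict(side["grid"]), p, mtd)


def _default_grid(J: int, K: int) -> DoseGrid:
    """A standardized-dose grid with evenly spread single-agent skeletons."""
    sk_p = 0.08 + 0.5 * np.arange(1, J + 1) / (J + 1)
    sk_q = 0.06 + 0.5 * np.arange(1, K + 1) / (K + 1)
    return DoseGrid.from_skeletons(tuple(sk_p), tuple(sk_q))


def gen_scenario(
    J: int,
    K: int,
    p_T: float,
    mtd_location: Optional[Level] = None,
    spread: float = 1.0,
    seed: int = 0,
    grid: Optional[DoseGrid] = None,
) -> ToxScenario:
    """Seeded partial-order-consistent scenario anchored at an MTD cell.

    Toxicity is built additively on the logit scale from positive seeded
    row/column increments (Exponential, scale proportional to ``spread``),
    then shifted so the probability at ``mtd_location`` lands within
    ``spread/10`` of the target ``p_T``.  Strict row/column monotonicity
    holds by construction.
    """
    if J < 1 or K < 1:
        raise ConfigurationError("J, K must be >= 1")
    if not 0.0 < p_T < 1.0:
        raise ConfigurationError("p_T must lie in (0,1)")
    rng = np.random.default_rng(seed)
    mtd = mtd_location or ((J + 1) // 2, (K + 1) // 2)
    if not (1 <= mtd[0] <= J and 1 <= mtd[1] <= K):
        raise ConfigurationError(f"mtd_location {mtd} outside the {J}x{K} grid")
    row_inc = rng.exponential(0.7 * spread, J) + 0.08 * spread
    col_inc = rng.exponential(0.7 * spread, K) + 0.08 * spread
    a = np.cumsum(row_inc)
    b = np.cumsum(col_inc)
    anchor = p_T + rng.uniform(-1.0, 1.0) * spread / 10.0
    anchor = min(max(anchor, 0.02), 0.98)
    c = logit(anchor) - a[mtd[0] - 1] - b[mtd[1] - 1]
    p = expit(c + a[:, None] + b[None, :])
    if not ((p > 0) & (p < 1)).all() or (
        J > 1 and not (np.diff(p, axis=0) > 0).all()
    ) or (K > 1 and not (np.diff(p, axis=1) > 0).all()):
        raise ConfigurationError(
            "scenario construction saturated; reduce spread or grid size"
        )
    return ToxScenario(grid or _default_grid(J, K), p, mtd)


# ---------------------------------------------------------------------------
# misspecification fixture
# ---------------------------------------------------------------------------

# Core 3x3 construction (logistic model with a tight prior around theta0):
# the model ranks (3,1) above (2,2), closest to p_T = 0.30, while the truth
# ranks (3,1) below (2,2).  A D-design trial started at (1,1) then walks
# (1,1) -> (1,2) -> (2,2) -> (3,1) whenever the first three outcomes are
# non-toxic; the last transition is weakly coherent (escalation per the
# model) but strongly incoherent (a true de-escalation after Y = 0).
_MISSPEC_U = (-0.469, 0.0, 1.642)
_MISSPEC_V = (-2.442, -1.266, 0.064)
_MISSPEC_P = np.array(
    [
        [0.02, 0.06, 0.35],
        [0.05, 0.30, 0.45],
        [0.15, 0.50, 0.60],
    ]
)


def misspec_prior(family: str = "logistic4") -> Prior:
    """The tight prior used by the misspecification fixture."""
    return prior_from_spec(
        family,
        [
            ("normal", 0.0, 0.05),
            ("uniform", 0.9, 1.1),
            ("uniform", 0.9, 1.1),
            ("normal", 0.0, 0.05),
        ],
        label="misspec_tight",
    )


def gen_misspecified_pair(
    J: int = 3, K: int = 3, p_T: float = 0.30, seed: int = 0
) -> tuple[ToxScenario, ModelSpec, Level]:
    """Scenario + model whose diagonal orderings disagree at a target cell.

    Returns ``(scenario, spec, cell)`` where ``cell = (3, 1)`` satisfies both
    inequalities of the weak-but-not-strong construction relative to the
    current dose (2, 2): the model (at the prior center theta0, to which the
    tight fixture prior keeps every interim estimate close) gives
    ``F(cell) > F(2,2)`` while the truth gives ``p(cell) < p(2,2)``.  Both
    inequalities are asserted, not assumed.  ``spec.prior`` carries the
    fixture prior.  Deterministic in (args, seed).
    """
    if J < 3 or K < 3:
        raise ConfigurationError("misspecification fixture needs J, K >= 3")
    shift = float(logit(p_T) - logit(0.30))
    u = list(_MISSPEC_U) + [_MISSPEC_U[-1] + 0.8 * i for i in range(1, J - 2)]
    v = list(_MISSPEC_V) + [_MISSPEC_V[-1] + 0.5 * i for i in range(1, K - 2)]
    grid = DoseGrid(tuple(u), tuple(v))
    p = expit(logit(_MISSPEC_P) + shift)
    p_full = np.empty((J, K))
    p_full[:3, :3] = p
    for j in range(3, J):
        p_full[j, :3] = p_full[j - 1, :3] + 0.3 * (0.98 - p_full[j - 1, :3])
    for k in range(3, K):
        p_full[:, k] = p_full[:, k - 1] + 0.3 * (0.98 - p_full[:, k - 1])
    theta0 = (shift, 1.0, 1.0, 0.0)
    spec = ModelSpec("logistic4", theta0, prior=misspec_prior())
    scenario = ToxScenario(grid, p_full, mtd_target=(2, 2))
    cell, current = (3, 1), (2, 2)
    f = toxicity_matrix(spec, grid, check=False)
    if not (
        f[cell[0] - 1, cell[1] - 1] > f[current[0] - 1, current[1] - 1]
        and scenario.prob(cell) < scenario.prob(current)
    ):
        raise ConfigurationError(
            "misspecification construction failed its own contract"
        )
    return scenario, spec, cell


# ---------------------------------------------------------------------------
# fixture bank
# ---------------------------------------------------------------------------


def _staircase_path(J: int, K: int) -> tuple[Level, ...]:
    """(1,1) -> (2,1) -> (2,2) -> (3,2) -> ... clipped to the grid."""
    path = [(1, 1)]
    j, k = 1, 1
    bump_j = True
    while (j, k) != (J, K):
        if bump_j and j < J:
            j += 1
        elif k < K:
            k += 1
        else:
            j += 1
        bump_j = not bump_j
        path.append((j, k))
    return tuple(path)


def strong_coherence_config() -> dict:
    """A D-design configuration whose diagonal ordering is theta-invariant.

    The uniform box prior keeps theta2 - theta3 >= 0.75 while |theta4| is
    small, so on the half-step raw-dose grid the agent-1 direction dominates
    every anti-diagonal comparison for every theta in the support; the
    scenario is the model surface at a theta* inside the box.  Conditions B1
    and B2 therefore hold over the whole support and the strong-coherence
    guarantee applies.
    """
    grid = DoseGrid((0.5, 1.0, 1.5, 2.0), (0.5, 1.0, 1.5, 2.0))
    prior = prior_from_spec(
        "logistic4",
        [
            ("uniform", -4.0, -2.0),
            ("uniform", 1.5, 2.5),
            ("uniform", 0.25, 0.75),
            ("uniform", 0.05, 0.15),
        ],
        label="strong_coherence_box",
    )
    theta_star = (-3.0, 2.0, 0.5, 0.1)
    p = toxicity_matrix(ModelSpec("logistic4", theta_star), grid)
    scenario = ToxScenario(grid, p)
    return {
        "family": "logistic4",
        "grid": grid,
        "prior": prior,
        "theta_star": theta_star,
        "scenario": scenario,
        "p_T": 0.30,
    }


def fixture_bank() -> dict:
    """Named grids, titration paths, priors and tie/kink cases.

    Stable across calls; addressable from configs, tests and the CLI.
    """
    sk4_p = (0.10, 0.20, 0.30, 0.40)
    sk4_q = (0.08, 0.16, 0.24, 0.32)
    grid_4x4_raw = DoseGrid(
        (0.5, 1.0, 1.5, 2.0), (0.5, 1.0, 1.5, 2.0),
        skeleton_p=sk4_p, skeleton_q=sk4_q,
    )
    grid_4x4_std = DoseGrid.from_skeletons((0.2, 0.35, 0.5, 0.65), (0.15, 0.30, 0.45, 0.60))
    grid_4x4_unit = DoseGrid(
        (0.1, 0.3, 0.5, 0.7), (0.1, 0.3, 0.5, 0.7),
        skeleton_p=sk4_p, skeleton_q=sk4_q,
    )
    grid_3x3_raw = DoseGrid(
        (0.5, 1.0, 1.5), (0.5, 1.0, 1.5),
        skeleton_p=(0.1, 0.2, 0.3), skeleton_q=(0.08, 0.18, 0.28),
    )
    grid_5x4 = DoseGrid(
        (0.4, 0.8, 1.2, 1.6, 2.0), (0.5, 1.0, 1.5, 2.0),
        skeleton_p=(0.06, 0.12, 0.2, 0.3, 0.4), skeleton_q=sk4_q,
    )
    grid_4x1 = DoseGrid((0.5, 1.0, 1.5, 2.0), (1.0,),
                        skeleton_p=sk4_p, skeleton_q=(0.2,))
    bank: dict = {
        "grid_3x3_raw": grid_3x3_raw,
        "grid_4x4_raw": grid_4x4_raw,
        "grid_4x4_std": grid_4x4_std,
        "grid_4x4_unit": grid_4x4_unit,
        "grid_5x4": grid_5x4,
        "grid_4x1": grid_4x1,
        "path_staircase_4x4": _staircase_path(4, 4),
        "path_staircase_3x3": _staircase_path(3, 3),
        "path_agent1_first_4x4": tuple(
            [(j, 1) for j in range(1, 5)] + [(4, k) for k in range(2, 5)]
        ),
        # exact |F - p_T| tie between the current dose and an escalation
        # candidate: all values are dyadic, so both distances are 0.0625
        # exactly in binary floating point.
        "tie_eq2": {
            "estimates": np.array(
                [
                    [0.0625, 0.125, 0.1875],
                    [0.125, 0.25, 0.375],
                    [0.1875, 0.375, 0.5],
                ]
            ),
            "p_T": 0.3125,
            "current": (2, 2),
            "tied": ((2, 2), (3, 2), (2, 3)),
        },
        # change-point theta sitting exactly on the kink surface at level
        # (2, 4) of grid_4x4_unit: alpha + beta*u + gamma*v = 0.3 + 0.7 = w
        "kink_change_point": {
            "grid": grid_4x4_unit,
            "theta": (0.0, 1.0, 1.0, 1.0),
            "level": (2, 4),
        },
        "strong_coherence_demo": strong_coherence_config(),
    }
    # canonical grid per family + default prior on it
    canonical = {
        "logistic4": "grid_4x4_std",
        "generalized_crm": "grid_4x4_raw",
        "scaled_logistic": "grid_4x4_std",
        "change_point": "grid_4x4_raw",
        "clayton": "grid_4x4_std",
        "gumbel": "grid_4x4_std",
        "log_linear": "grid_4x4_unit",
        "six_param": "grid_4x4_unit",
    }
    bank["canonical_grid"] = canonical
    from .priors import default_prior

    for fam, gname in canonical.items():
        bank[f"prior_{fam}"] = default_prior(fam, bank[gname])
    return bank
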