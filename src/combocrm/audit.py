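"""Coherence audits for simulated combination-trial traces.

A design is *coherent* when it never escalates after an observed toxicity
and never de-escalates after a non-toxicity.  For combination trials the
classification of a move as escalation or de-escalation depends on how the
anti-diagonal neighbours are ordered relative to the current dose:

* **weak semantics** — ordered by the interim model estimates F_hat (what
  the design itself believes);
* **strong semantics** — ordered by the true scenario probabilities (what a
  regulator cares about under model misspecification).

ND traces contain no diagonal moves, so the two semantics coincide there.
The module also provides empirical checkers for the sufficient conditions
behind the coherence guarantees: the sign condition linking outcome
residual, posterior-mean shift and model gradient (condition A), and the
dose-monotonicity / diagonal-order-agreement pair (conditions B1 and B2).
All checkers are falsifiers over sampled thetas or realized traces — they
can exhibit witnesses, never prove theorems.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional

import numpy as np
import pandas as pd

from .design import TrialTrace, candidate_sets_for
from .grid import DoseGrid, Level
from .models import (
    ConfigurationError,
    ModelSpec,
    grad_toxicity,
    toxicity_table,
)
from .scenarios import ToxScenario

__all__ = [
    "Violation",
    "CoherenceReport",
    "audit_trace",
    "ConditionAReport",
    "check_condition_A",
    "ConditionBReport",
    "check_condition_B",
    "summarize_batch",
]


@dataclass(frozen=True)
class Violation:
    n: int  #: transition index (patient whose outcome preceded the move)
    type: str  #: "escalate_after_tox" | "deescalate_after_no_tox"
    details: dict


@dataclass(frozen=True)
class CoherenceReport:
    semantics: str
    n_transitions: int
    n_excluded: int  #: transitions skipped for unconverged posteriors
    violations: tuple[Violation, ...]
    verdict: bool

    def to_dict(self) -> dict:
        return {
            "semantics": self.semantics,
            "n_transitions": self.n_transitions,
            "n_excluded": self.n_excluded,
            "violations": [
                {"n": v.n, "type": v.type, "details": v.details}
                for v in self.violations
            ],
            "verdict": self.verdict,
        }


def audit_trace(
    trace: TrialTrace,
    semantics: str = "weak",
    scenario: Optional[ToxScenario] = None,
) -> CoherenceReport:
    """Classify every transition of a trace against the coherence definition.

    A violation is recorded at transition n when Y_n = 1 and X_{n+1} lies in
    the escalation set, or Y_n = 0 and X_{n+1} lies in the de-escalation set,
    with the sets rebuilt from the trace under the requested semantics.
    Transitions whose interim posterior is flagged unconverged are excluded
    from the verdict and counted separately.
    """
    if semantics not in ("weak", "strong"):
        raise ConfigurationError("semantics must be 'weak' or 'strong'")
    ordering_true: Optional[np.ndarray] = None
    if semantics == "strong":
        if scenario is not None:
            ordering_true = scenario.p
        elif trace.scenario_p is not None:
            ordering_true = trace.scenario_p
        else:
            raise ConfigurationError(
                "strong semantics needs the true scenario probabilities"
            )
    violations: list[Violation] = []
    n_trans = 0
    n_excluded = 0
    for rec in trace.records:
        if rec.next_level is None:
            continue
        n_trans += 1
        if not rec.converged:
            n_excluded += 1
            continue
        if rec.next_level == rec.level:
            continue
        ordering = rec.f_hat if semantics == "weak" else ordering_true
        sets = candidate_sets_for(
            trace.design_kind, rec.level, trace.grid,
            ordering=ordering, semantics=semantics,
        )
        if rec.y == 1 and rec.next_level in sets.escalation:
            violations.append(
                Violation(
                    rec.n,
                    "escalate_after_tox",
                    {"from": list(rec.level), "to": list(rec.next_level)},
                )
            )
        elif rec.y == 0 and rec.next_level in sets.deescalation:
            violations.append(
                Violation(
                    rec.n,
                    "deescalate_after_no_tox",
                    {"from": list(rec.level), "to": list(rec.next_level)},
                )
            )
    return CoherenceReport(
        semantics, n_trans, n_excluded, tuple(violations), not violations
    )


# ---------------------------------------------------------------------------
# condition A: (Y_n - p_T)(theta_hat_{n,t} - theta_hat_{n-1,t}) dF/dtheta_t >= 0
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConditionAReport:
    verdict: bool
    min_product: float
    n_updates: int
    n_kink_skipped: int
    n_excluded: int
    worst: Optional[dict]
    eps: float


def check_condition_A(
    trace: TrialTrace,
    eps: float = 1e-6,
) -> ConditionAReport:
    """Evaluate the sign condition at every posterior update of a trace.

    The gradient dF/dtheta_t at the treated dose is taken at theta_hat_{n-1},
    the estimate in force when patient n was dosed.  Updates flagged by the
    change-point kink detector are skipped and counted; updates with
    unconverged posteriors are excluded and reported.  The verdict requires
    every product >= -eps.
    """
    thetas = trace.theta_path()
    min_prod = np.inf
    worst = None
    n_upd = n_kink = n_excl = 0
    for rec in trace.records:
        prev, cur = thetas[rec.n - 1], thetas[rec.n]
        if not rec.converged:
            n_excl += 1
            continue
        g = grad_toxicity(
            ModelSpec(trace.family, tuple(prev)), trace.grid, *rec.level
        )
        if g.kink:
            n_kink += 1
            continue
        n_upd += 1
        prods = (rec.y - trace.p_T) * (cur - prev) * g.grad
        t = int(np.argmin(prods))
        if prods[t] < min_prod:
            min_prod = float(prods[t])
            worst = {
                "n": rec.n,
                "t": t,
                "product": float(prods[t]),
                "level": list(rec.level),
                "y": rec.y,
            }
    if n_upd == 0:
        return ConditionAReport(True, np.inf, 0, n_kink, n_excl, None, eps)
    return ConditionAReport(
        bool(min_prod >= -eps), min_prod, n_upd, n_kink, n_excl, worst, eps
    )


# ---------------------------------------------------------------------------
# conditions B1 / B2
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConditionBReport:
    b1: bool
    b2: bool
    b2_vacuous: bool
    n_thetas: int
    pairs: tuple[tuple[Level, Level], ...]
    witness_b1: Optional[dict]
    witness_b2: Optional[dict]


def _sgn(x: np.ndarray, tol: float) -> np.ndarray:
    return np.where(x > tol, 1, np.where(x < -tol, -1, 0))


def check_condition_B(
    family: str,
    grid: DoseGrid,
    scenario: ToxScenario,
    theta_sampler: Callable[[int], np.ndarray],
    n_thetas: int = 200,
    tol: float = 1e-12,
) -> ConditionBReport:
    """Probe conditions B1 and B2 over a sampled set of admissible thetas.

    B1: F strictly increases along each coordinate of the grid for every
    sampled theta.  B2: for every interior anti-diagonal pair, the sign of
    the model difference agrees with the sign of the true difference for
    every sampled theta.  Any mismatch falsifies with a witness.  B2 is
    vacuously true when the grid has no anti-diagonal pairs.
    """
    if scenario.p.shape != grid.shape:
        raise ConfigurationError("scenario does not match the grid")
    thetas = np.atleast_2d(np.asarray(theta_sampler(n_thetas), dtype=float))
    table = toxicity_table(family, thetas, grid)  # (S, J, K)

    witness_b1 = None
    b1 = True
    for axis in (1, 2):
        d = np.diff(table, axis=axis)
        if d.size and not (d > tol).all():
            b1 = False
            i = np.unravel_index(np.argmin(d), d.shape)
            witness_b1 = {
                "theta": thetas[i[0]].tolist(),
                "axis": "u" if axis == 1 else "v",
                "at": [int(i[1]) + 1, int(i[2]) + 1],
                "delta_F": float(d[i]),
            }
            break

    pairs: list[tuple[Level, Level]] = [
        ((j, k), (j + 1, k - 1))
        for j in range(1, grid.J)
        for k in range(2, grid.K + 1)
    ]
    b2 = True
    witness_b2 = None
    for (j, k), (j2, k2) in pairs:
        model_diff = table[:, j2 - 1, k2 - 1] - table[:, j - 1, k - 1]
        true_sgn = int(_sgn(
            np.array(scenario.p[j2 - 1, k2 - 1] - scenario.p[j - 1, k - 1]), tol
        ))
        model_sgn = _sgn(model_diff, tol)
        bad = np.nonzero(model_sgn != true_sgn)[0]
        if bad.size:
            b2 = False
            i = int(bad[0])
            witness_b2 = {
                "pair": [list((j, k)), list((j2, k2))],
                "theta": thetas[i].tolist(),
                "model_sign": int(model_sgn[i]),
                "true_sign": true_sgn,
            }
            break
    return ConditionBReport(
        b1, b2, not pairs, thetas.shape[0], tuple(pairs), witness_b1, witness_b2
    )


# ---------------------------------------------------------------------------
# batch summaries
# ---------------------------------------------------------------------------


def summarize_batch(
    entries: Iterable[tuple[dict, CoherenceReport]]
) -> pd.DataFrame:
    """Aggregate violation counts by (design, family, semantics).

    ``entries`` pairs a metadata dict (at least design/family/semantics keys)
    with the per-trace report.  Zero-violation rows for theorem-covered
    combinations are the acceptance surface of the audit batches.
    """
    rows = []
    for meta, report in entries:
        rows.append(
            {
                "design": meta.get("design", ""),
                "family": meta.get("family", ""),
                "semantics": report.semantics,
                "n_transitions": report.n_transitions,
                "n_excluded": report.n_excluded,
                "n_violations": len(report.violations),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "design", "family", "semantics", "n_traces",
                "n_transitions", "n_excluded", "n_violations",
                "violation_rate", "all_coherent",
            ]
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["design", "family", "semantics"], as_index=False)
        .agg(
            n_traces=("n_violations", "size"),
            n_transitions=("n_transitions", "sum"),
            n_excluded=("n_excluded", "sum"),
            n_violations=("n_violations", "sum"),
        )
        .assign(
            violation_rate=lambda d: np.where(
                d.n_transitions > 0, d.n_violations / d.n_transitions, 0.0
            ),
            all_coherent=lambda d: d.n_violations == 0,
        )
    )
    return out
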