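"""Dose-assignment engines for combination phase I designs.

Two geometries are implemented for the candidate escalation set E_n and
de-escalation set D_n around the current dose (j, k):

* **ND-design** — no diagonal movement: E = {(j+1,k), (j,k+1)},
  D = {(j-1,k), (j,k-1)}, clipped to the grid.
* **D-design** — additionally the anti-diagonal neighbours (j+1,k-1) and
  (j-1,k+1), whose toxicity order relative to the current dose is unknown a
  priori; each is classified into E or D by an ordering surface — the model
  estimates F_hat (the basis of *weak* coherence) or the true probabilities
  (the basis of *strong* coherence).  Exact ordering ties are excluded from
  both sets.

Given candidate sets, the next dose is the admissible dose whose estimated
toxicity is closest to the target p_T.  The two-stage design first titrates
along a pre-selected monotone path from (1,1) and hands over to the
model-based rule at the first observed toxicity (or when the path is
exhausted, under the default switch rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .grid import DoseGrid, Level
from .models import ConfigurationError, ModelSpec, toxicity_at, toxicity_matrix
from .posterior import PosteriorEngine
from .priors import Prior
from .scenarios import ToxScenario, _staircase_path

__all__ = [
    "SWITCH",
    "CandidateSets",
    "candidate_sets_nd",
    "candidate_sets_d",
    "candidate_sets_for",
    "select_next_dose",
    "closest_to_target",
    "TwoStageConfig",
    "titration_next",
    "PatientRecord",
    "TrialTrace",
    "run_trial",
    "Theorem6Report",
    "check_theorem6_condition",
    "DESIGNS",
]

#: sentinel returned by titration_next when the switch rule R fires
SWITCH = "SWITCH"

DESIGNS = ("one_stage_nd", "one_stage_d", "two_stage_nd", "two_stage_d")


@dataclass(frozen=True)
class CandidateSets:
    """The admissible moves A = {current} | E | D for one transition."""

    current: Level
    escalation: frozenset[Level]
    deescalation: frozenset[Level]
    design_kind: str  #: "nd" | "d"
    diagonal_semantics: str  #: "none" | "weak" | "strong"

    def __post_init__(self) -> None:
        if self.escalation & self.deescalation:
            raise ConfigurationError("E and D overlap")
        j, k = self.current
        for lvl in self.escalation | self.deescalation:
            dj, dk = lvl[0] - j, lvl[1] - k
            ok = abs(dj) + abs(dk) == 1 or (
                self.design_kind == "d" and abs(dj) == 1 and abs(dk) == 1 and dj == -dk
            )
            if not ok:
                raise ConfigurationError(
                    f"{lvl} is not an admissible neighbour of {self.current}"
                )

    @property
    def admissible(self) -> frozenset[Level]:
        return self.escalation | self.deescalation | {self.current}


def _nd_neighbours(current: Level, grid: DoseGrid) -> tuple[set[Level], set[Level]]:
    j, k = grid.require(current)
    esc = {(j + 1, k), (j, k + 1)}
    dee = {(j - 1, k), (j, k - 1)}
    return (
        {x for x in esc if grid.contains(x)},
        {x for x in dee if grid.contains(x)},
    )


def candidate_sets_nd(current: Level, grid: DoseGrid) -> CandidateSets:
    """ND-design sets: one-step coordinate moves only."""
    esc, dee = _nd_neighbours(current, grid)
    return CandidateSets(current, frozenset(esc), frozenset(dee), "nd", "none")


def candidate_sets_d(
    current: Level,
    grid: DoseGrid,
    ordering: np.ndarray,
    semantics: str = "weak",
) -> CandidateSets:
    """D-design sets: coordinate moves plus classified anti-diagonal moves.

    ``ordering`` is a J x K surface (model estimates for weak semantics, true
    probabilities for strong semantics).  An in-grid anti-diagonal neighbour
    goes to E when its ordering value exceeds the current dose's, to D when
    below, and is excluded from both on an exact tie.
    """
    ordering = np.asarray(ordering, dtype=float)
    if ordering.shape != grid.shape:
        raise ConfigurationError("ordering surface does not match the grid")
    esc, dee = _nd_neighbours(current, grid)
    j, k = current
    o_cur = ordering[j - 1, k - 1]
    if not np.isfinite(o_cur):
        raise ConfigurationError("ordering value missing at the current dose")
    for lvl in ((j + 1, k - 1), (j - 1, k + 1)):
        if not grid.contains(lvl):
            continue
        o = ordering[lvl[0] - 1, lvl[1] - 1]
        if not np.isfinite(o):
            raise ConfigurationError(f"ordering value missing at {lvl}")
        if o > o_cur:
            esc.add(lvl)
        elif o < o_cur:
            dee.add(lvl)
        # exact tie: excluded from both E and D
    return CandidateSets(current, frozenset(esc), frozenset(dee), "d", semantics)


def candidate_sets_for(
    design_kind: str,
    current: Level,
    grid: DoseGrid,
    ordering: Optional[np.ndarray] = None,
    semantics: str = "weak",
) -> CandidateSets:
    if design_kind == "nd":
        return candidate_sets_nd(current, grid)
    if design_kind == "d":
        if ordering is None:
            raise ConfigurationError("the D-design needs an ordering surface")
        return candidate_sets_d(current, grid, ordering, semantics)
    raise ConfigurationError(f"unknown design kind '{design_kind}'")


def _minimal_levels(levels: Sequence[Level]) -> list[Level]:
    """Minimal elements under the componentwise partial order."""
    out = []
    for a in levels:
        if not any(
            b != a and b[0] <= a[0] and b[1] <= a[1] for b in levels
        ):
            out.append(a)
    return out


def closest_to_target(
    estimates: np.ndarray,
    levels: Sequence[Level],
    p_T: float,
    current: Optional[Level] = None,
    tie_rule: str = "prefer_current",
) -> Level:
    """argmin over ``levels`` of |estimate - p_T| with deterministic ties.

    Exact ties are resolved by: the current dose if tied (under the default
    rule); otherwise the doses minimal in the known partial order; then
    lexicographic (j, k).  ``tie_rule="lexicographic"`` skips the first two
    steps.
    """
    if not 0.0 < p_T < 1.0:
        raise ConfigurationError("p_T must lie in (0,1)")
    if not levels:
        raise ConfigurationError("empty candidate set")
    estimates = np.asarray(estimates, dtype=float)
    dist = {lvl: abs(estimates[lvl[0] - 1, lvl[1] - 1] - p_T) for lvl in levels}
    best = min(dist.values())
    ties = sorted(lvl for lvl, d in dist.items() if d == best)
    if len(ties) == 1 or tie_rule == "lexicographic":
        return ties[0]
    if tie_rule != "prefer_current":
        raise ConfigurationError(f"unknown tie rule '{tie_rule}'")
    if current is not None and current in ties:
        return current
    return sorted(_minimal_levels(ties))[0]


def select_next_dose(
    estimates: np.ndarray,
    sets: CandidateSets,
    p_T: float,
    tie_rule: str = "prefer_current",
) -> Level:
    """The dose in A_n with model toxicity estimate closest to p_T."""
    return closest_to_target(
        estimates, sorted(sets.admissible), p_T, sets.current, tie_rule
    )


# ---------------------------------------------------------------------------
# two-stage titration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TwoStageConfig:
    """Stage-1 titration: a monotone path from (1,1) plus the switch rule."""

    path: tuple[Level, ...]
    switch_rule: str = "path_exhausted_or_first_toxicity"

    def __post_init__(self) -> None:
        path = tuple((int(j), int(k)) for j, k in self.path)
        object.__setattr__(self, "path", path)
        if not path or path[0] != (1, 1):
            raise ConfigurationError("titration path must start at (1,1)")
        for a, b in zip(path, path[1:]):
            dj, dk = b[0] - a[0], b[1] - a[1]
            if sorted((dj, dk)) != [0, 1]:
                raise ConfigurationError(
                    f"titration step {a} -> {b} must raise exactly one agent "
                    "by one level"
                )
        if self.switch_rule not in (
            "first_toxicity",
            "path_exhausted_or_first_toxicity",
        ):
            raise ConfigurationError(f"unknown switch rule '{self.switch_rule}'")

    @classmethod
    def staircase(cls, grid: DoseGrid, **kw) -> "TwoStageConfig":
        return cls(_staircase_path(grid.J, grid.K), **kw)

    def validate(self, grid: DoseGrid) -> "TwoStageConfig":
        for lvl in self.path:
            grid.require(lvl)
        return self


def titration_next(config: TwoStageConfig, position: int, y: int):
    """Stage-1 transition: next path element, or SWITCH when rule R fires.

    ``position`` is the 0-based index of the current dose on the path.  The
    first toxicity always fires R; an exhausted path fires R under the
    default rule, and holds the last dose under the pure
    ``"first_toxicity"`` rule.
    """
    if not 0 <= position < len(config.path):
        raise ConfigurationError("position must index the titration path")
    if y:
        return SWITCH
    if position == len(config.path) - 1:
        if config.switch_rule == "path_exhausted_or_first_toxicity":
            return SWITCH
        return config.path[position]  # hold the top of the path
    return config.path[position + 1]


# ---------------------------------------------------------------------------
# trial simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatientRecord:
    """Everything recorded for one patient: dose, outcome, interim estimates
    and the decision that produced the next dose."""

    n: int  #: 1-based patient index
    level: Level  #: X_n
    y: int  #: Y_n
    stage: str  #: "titration" | "model" — how X_n itself was assigned
    theta_hat: np.ndarray  #: posterior mean after observing Y_n
    f_hat: np.ndarray  #: J x K plug-in toxicity surface at theta_hat
    mc_error: np.ndarray
    converged: bool
    decision_rule: Optional[str]  #: "titration" | "titration_hold" | "model"
    sets: Optional[CandidateSets]  #: candidate sets behind a model decision
    next_level: Optional[Level]  #: X_{n+1} (None for the last patient)


@dataclass(frozen=True)
class TrialTrace:
    """One simulated trial: per-patient assignments, outcomes and estimates."""

    design: str
    family: str
    grid: DoseGrid
    p_T: float
    N: int
    seed: Optional[int]
    prior_label: str
    engine_method: str
    scenario_p: Optional[np.ndarray]
    start_level: Level
    titration_path: Optional[tuple[Level, ...]]
    theta_hat_prior: np.ndarray
    f_hat_prior: np.ndarray
    switch_index: Optional[int]  #: M, the first model-dosed patient (two-stage)
    records: tuple[PatientRecord, ...]

    @property
    def design_kind(self) -> str:
        return "d" if self.design.endswith("_d") else "nd"

    @property
    def two_stage(self) -> bool:
        return self.design.startswith("two_stage")

    def doses(self) -> list[Level]:
        return [r.level for r in self.records]

    def theta_path(self) -> list[np.ndarray]:
        """theta_hat_0 (prior), theta_hat_1, ..., theta_hat_N."""
        return [self.theta_hat_prior] + [r.theta_hat for r in self.records]


def _normalize_design(design: str) -> str:
    d = design.lower().replace("-", "_")
    aliases = {"nd": "one_stage_nd", "d": "one_stage_d"}
    d = aliases.get(d, d)
    if d not in DESIGNS:
        raise ConfigurationError(f"unknown design '{design}'; choose from {DESIGNS}")
    return d


def run_trial(
    design: str,
    family: str,
    prior: Prior,
    grid: DoseGrid,
    scenario: ToxScenario,
    p_T: float,
    N: int,
    seed: Optional[int] = 0,
    start: Optional[Level | str] = None,
    titration: Optional[TwoStageConfig] = None,
    outcomes: Optional[Sequence[int]] = None,
    engine: Optional[PosteriorEngine] = None,
    tie_rule: str = "prefer_current",
    mc_tol: float = 0.05,
) -> TrialTrace:
    """Simulate one trial of N sequentially enrolled patients.

    One-stage designs start at the prior estimate of the MTD (the grid dose
    whose prior plug-in toxicity is closest to p_T) unless ``start`` names a
    level or ``"lowest"``.  Two-stage designs start at (1,1) on the titration
    path and hand over to the model-based rule when the switch rule fires;
    from then on doses follow the posterior plug-in rule restricted to the
    no-skipping candidate sets.  Outcomes are Bernoulli draws from the
    scenario using one seeded stream per trial (patient n consumes the n-th
    draw, so design variants are comparable under common random numbers);
    an explicit ``outcomes`` sequence overrides the draws, for constructed
    demonstrations.
    """
    design = _normalize_design(design)
    if N < 1:
        raise ConfigurationError("N must be >= 1")
    if not 0.0 < p_T < 1.0:
        raise ConfigurationError("p_T must lie in (0,1)")
    if scenario.p.shape != grid.shape:
        raise ConfigurationError("scenario does not match the grid shape")
    if outcomes is not None and len(outcomes) < N:
        raise ConfigurationError("outcomes override must cover all N patients")
    engine = engine or PosteriorEngine(family, grid, prior, seed=seed or 0)
    if engine.family != family or engine.grid != grid:
        raise ConfigurationError("engine does not match family/grid")
    rng = np.random.default_rng(seed)
    draws = rng.random(N)

    logw = engine.initial_logw()
    theta_prior = engine.mean(logw)
    f_prior = toxicity_matrix(ModelSpec(family, tuple(theta_prior)), grid, check=False)

    two_stage = design.startswith("two_stage")
    kind = "d" if design.endswith("_d") else "nd"
    path: Optional[tuple[Level, ...]] = None
    if two_stage:
        cfg = (titration or TwoStageConfig.staircase(grid)).validate(grid)
        path = cfg.path
        X: Level = path[0]
        pos = 0
        switched = False
    else:
        if start in (None, "prior_mtd"):
            X = closest_to_target(f_prior, list(grid.levels()), p_T, tie_rule=tie_rule)
        elif start == "lowest":
            X = (1, 1)
        else:
            X = grid.require(tuple(start))  # type: ignore[arg-type]
        switched = True  # model-based from patient 1

    switch_index: Optional[int] = None
    records: list[PatientRecord] = []
    for n in range(1, N + 1):
        y = int(outcomes[n - 1]) if outcomes is not None else int(
            draws[n - 1] < scenario.prob(X)
        )
        logw = engine.update(logw, X, y)
        theta_hat = engine.mean(logw)
        mc = engine.mc_error(logw)
        f_hat = toxicity_matrix(ModelSpec(family, tuple(theta_hat)), grid, check=False)
        stage = "model" if switched else "titration"

        next_level: Optional[Level] = None
        sets: Optional[CandidateSets] = None
        rule: Optional[str] = None
        if n < N:
            if two_stage and not switched:
                nxt = titration_next(cfg, pos, y)
                if nxt == SWITCH:
                    switched = True
                    switch_index = n + 1
                else:
                    rule = "titration" if nxt != X else "titration_hold"
                    next_level = nxt
                    if nxt != X:
                        pos += 1
            if next_level is None:
                sets = candidate_sets_for(kind, X, grid, ordering=f_hat)
                next_level = select_next_dose(f_hat, sets, p_T, tie_rule)
                rule = "model"
        records.append(
            PatientRecord(
                n=n,
                level=X,
                y=y,
                stage=stage,
                theta_hat=theta_hat,
                f_hat=f_hat,
                mc_error=mc,
                converged=bool((mc <= mc_tol).all()),
                decision_rule=rule,
                sets=sets,
                next_level=next_level,
            )
        )
        if next_level is not None:
            X = next_level

    return TrialTrace(
        design=design,
        family=family,
        grid=grid,
        p_T=p_T,
        N=N,
        seed=seed,
        prior_label=prior.label,
        engine_method=engine.method,
        scenario_p=scenario.p.copy(),
        start_level=records[0].level,
        titration_path=path,
        theta_hat_prior=theta_prior,
        f_hat_prior=f_prior,
        switch_index=switch_index,
        records=tuple(records),
    )


# ---------------------------------------------------------------------------
# two-stage switch condition (Theorem-6-style check)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Theorem6Report:
    applicable: bool
    holds: Optional[bool]
    n_thetas: int
    max_product: Optional[float]
    witness: Optional[dict]
    detail: str


def check_theorem6_condition(
    trace: TrialTrace,
    prior: Prior,
    n_thetas: int = 200,
    seed: int = 0,
    tol: float = 1e-12,
) -> Theorem6Report:
    """Empirically probe the switch-transition inequality of a two-stage run.

    For the first model-dosed patient M, the two-stage design inherits
    coherence when (Y_M - p_T) * {F(X_{M+1}, theta) - F(X_M, theta)} <= 0
    almost surely in theta.  "Almost surely" is verified over a seeded sample
    of admissible thetas drawn from the prior support — a falsifier with
    documented coverage, not a proof.  Returns the maximizing witness theta
    when the inequality fails.
    """
    M = trace.switch_index
    if M is None or M >= trace.N:
        return Theorem6Report(
            False, None, 0, None, None,
            "no switch transition in the trace (not applicable)",
        )
    rec = trace.records[M - 1]
    nxt = rec.next_level
    if nxt is None:
        return Theorem6Report(False, None, 0, None, None, "switch patient is last")
    thetas = prior.sample_admissible(np.random.default_rng(seed), n_thetas, trace.grid)
    f_next = toxicity_at(trace.family, thetas, trace.grid, nxt)
    f_cur = toxicity_at(trace.family, thetas, trace.grid, rec.level)
    prods = (rec.y - trace.p_T) * (f_next - f_cur)
    i = int(np.argmax(prods))
    holds = bool(prods[i] <= tol)
    witness = None
    if not holds:
        witness = {
            "theta": thetas[i].tolist(),
            "product": float(prods[i]),
            "X_M": list(rec.level),
            "X_M_plus_1": list(nxt),
            "Y_M": rec.y,
        }
    return Theorem6Report(
        True, holds, n_thetas, float(prods[i]), witness,
        f"switch at patient {M}: {rec.level} -> {nxt} after Y={rec.y}",
    )
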