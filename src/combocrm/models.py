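"""Dose-toxicity surfaces for two-agent combination designs.

Eight parametric families from the combination dose-finding literature are
implemented behind one registry.  Each family maps a parameter vector theta
and a dose combination (u_j, v_k) to a DLT probability F_jk(theta), and
carries the admissibility constraints that make the surface conform the
known partial order (toxicity increases when either agent's dose increases
with the other held fixed).

Families
--------
``logistic4``
    logit F = t1 + t2*u + t3*v + t4*u*v, with t2 > 0, t3 > 0 and
    t2 + t4*v_k > 0, t3 + t4*u_j > 0 on the grid.
``generalized_crm``
    logit F = alpha_k + beta*u_j: agent 2 enters as a categorical dummy
    (one intercept per level), agent 1 as a continuous dose; beta > 0 and
    the intercepts ordered alpha_1 < ... < alpha_K.
``scaled_logistic``
    F = rho * expit(t1 + t2*u + t3*v), 0 < rho < 1: plateaus at rho
    instead of 1 (targeted agents).
``change_point``
    logit F = min(alpha + beta*u + gamma*v, w): increases up to the
    threshold surface and then flattens at the cap expit(w).
``clayton``
    Clayton-copula combination of single-agent skeleton curves p_j^alpha,
    q_k^beta with association gamma; alpha, beta, gamma > 0.
``gumbel``
    Farlie-Gumbel-Morgenstern ("Gumbel") copula of the same marginals,
    F = 1 - (1-p^a)(1-q^b){1 + p^a q^b tanh(g/2)}.
``log_linear``
    log(1-F) = a*log(1-u) + b*log(1-v) + g*log(1-u)log(1-v); a, b > 0,
    g < 0; doses must satisfy u, v < 1.
``six_param``
    F = G/(1+G) with G = a1*u^b1 + a2*v^b2 + a3*(u^b1 v^b2)^b3, all six
    parameters positive, standardized doses in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.special import expit

from .grid import DoseGrid, Level

__all__ = [
    "ModelSpec",
    "ConstraintReport",
    "GradResult",
    "UniformMonotonicityReport",
    "ConstraintViolationError",
    "ConfigurationError",
    "FAMILIES",
    "family_names",
    "n_params",
    "param_names",
    "evaluate_toxicity",
    "toxicity_at",
    "toxicity_matrix",
    "check_constraints",
    "admissible_mask",
    "grad_toxicity",
    "check_uniform_monotonicity",
    "check_partial_order_matrix",
]

#: strict inequalities are enforced with this numerical margin
EPS_CONSTRAINT = 1e-10


class ConstraintViolationError(ValueError):
    """theta violates the family's partial-order admissibility predicate."""


class ConfigurationError(ValueError):
    """Model/grid configuration is inconsistent (missing skeleton, bad dose)."""


# ---------------------------------------------------------------------------
# family definitions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Family:
    """One dose-toxicity family: evaluator + constraint predicates."""

    name: str
    needs_skeleton: bool
    #: param_names(grid) -> tuple of names (length may depend on K)
    _param_names: Callable[[DoseGrid], tuple[str, ...]]
    #: f(theta (...,p), u, v, p_skel, q_skel) -> F, vectorized over theta
    _f: Callable
    #: margins(theta (S,p), grid) -> list of (label, (S,) margin arrays);
    #: admissible iff every margin > EPS_CONSTRAINT
    _margins: Callable
    #: optional grid validation (dose domain)
    _check_grid: Optional[Callable[[DoseGrid], None]] = None
    #: default prior spec: list of (kind, *params) per component;
    #: kinds: normal(mu, sd), expon(rate), negexpon(rate), uniform(a, b)
    _default_prior: Optional[Callable[[DoseGrid], list[tuple]]] = None

    def param_names(self, grid: DoseGrid) -> tuple[str, ...]:
        return self._param_names(grid)

    def n_params(self, grid: DoseGrid) -> int:
        return len(self.param_names(grid))

    def check_grid(self, grid: DoseGrid) -> None:
        if self.needs_skeleton and (
            grid.skeleton_p is None or grid.skeleton_q is None
        ):
            raise ConfigurationError(
                f"family '{self.name}' requires a grid with single-agent "
                "toxicity skeletons (skeleton_p / skeleton_q)"
            )
        if self._check_grid is not None:
            self._check_grid(grid)

    def f(self, theta: np.ndarray, u: float, v: float, grid: DoseGrid,
          level: Optional[Level] = None) -> np.ndarray:
        """F(u, v, theta) vectorized over the leading axes of theta."""
        theta = np.asarray(theta, dtype=float)
        pj = qk = None
        if self.needs_skeleton:
            if level is None:
                raise ConfigurationError(
                    f"family '{self.name}' is defined on grid levels through "
                    "its skeleton; pass the level pair"
                )
            pj, qk = grid.skeleton(level)
        return self._f(theta, u, v, pj, qk)

    def margins(self, theta: np.ndarray, grid: DoseGrid) -> list[tuple[str, np.ndarray]]:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        return self._margins(theta, grid)

    def default_prior_spec(self, grid: DoseGrid) -> list[tuple]:
        if self._default_prior is None:
            raise ConfigurationError(f"no default prior for '{self.name}'")
        return self._default_prior(grid)


def _logistic4_f(t, u, v, pj, qk):
    return expit(t[..., 0] + t[..., 1] * u + t[..., 2] * v + t[..., 3] * u * v)


def _logistic4_margins(t, grid):
    out = [("theta2 > 0", t[:, 1]), ("theta3 > 0", t[:, 2])]
    for k, vk in enumerate(grid.v, start=1):
        out.append((f"theta2 + theta4*v_{k} > 0", t[:, 1] + t[:, 3] * vk))
    for j, uj in enumerate(grid.u, start=1):
        out.append((f"theta3 + theta4*u_{j} > 0", t[:, 2] + t[:, 3] * uj))
    return out


def _gencrm_names(grid):
    return tuple(f"alpha_{k}" for k in range(1, grid.K + 1)) + ("beta",)


def _gencrm_f(t, u, v, pj, qk):
    # caller passes v = (k-1) as the categorical index (see toxicity_at)
    k = int(v)
    return expit(t[..., k] + t[..., -1] * u)


def _gencrm_margins(t, grid):
    out = [("beta > 0", t[:, -1])]
    for k in range(grid.K - 1):
        out.append((f"alpha_{k + 2} - alpha_{k + 1} > 0", t[:, k + 1] - t[:, k]))
    return out


def _scaled_logistic_f(t, u, v, pj, qk):
    return t[..., 0] * expit(t[..., 1] + t[..., 2] * u + t[..., 3] * v)


def _scaled_logistic_margins(t, grid):
    return [
        ("rho > 0", t[:, 0]),
        ("rho < 1", 1.0 - t[:, 0]),
        ("theta2 > 0", t[:, 2]),
        ("theta3 > 0", t[:, 3]),
    ]


def _change_point_f(t, u, v, pj, qk):
    lin = t[..., 0] + t[..., 1] * u + t[..., 2] * v
    return expit(np.minimum(lin, t[..., 3]))


def _change_point_margins(t, grid):
    return [("beta > 0", t[:, 1]), ("gamma > 0", t[:, 2])]


def _clayton_f(t, u, v, pj, qk):
    a, b, g = t[..., 0], t[..., 1], t[..., 2]
    with np.errstate(over="ignore"):
        s = (
            np.exp(-g * np.log1p(-(pj ** a)))
            + np.exp(-g * np.log1p(-(qk ** b)))
            - 1.0
        )
        return -np.expm1(-np.log(s) / g)


def _positive_margins(names):
    def margins(t, grid):
        return [(f"{nm} > 0", t[:, i]) for i, nm in enumerate(names)]

    return margins


def _gumbel_f(t, u, v, pj, qk):
    a = pj ** t[..., 0]
    b = qk ** t[..., 1]
    c = np.tanh(t[..., 2] / 2.0)
    return 1.0 - (1.0 - a) * (1.0 - b) * (1.0 + a * b * c)


def _log_linear_f(t, u, v, pj, qk):
    lu, lv = np.log1p(-u), np.log1p(-v)
    g = t[..., 0] * lu + t[..., 1] * lv + t[..., 2] * lu * lv
    return -np.expm1(g)


def _log_linear_margins(t, grid):
    return [("alpha > 0", t[:, 0]), ("beta > 0", t[:, 1]), ("gamma < 0", -t[:, 2])]


def _log_linear_grid(grid):
    if max(grid.u) >= 1.0 or max(grid.v) >= 1.0:
        raise ConfigurationError(
            "log_linear requires standardized doses u_j, v_k < 1 "
            "(log(1-dose) must exist)"
        )


def _six_param_f(t, u, v, pj, qk):
    a1, a2, a3 = t[..., 0], t[..., 1], t[..., 2]
    b1, b2, b3 = t[..., 3], t[..., 4], t[..., 5]
    ub = u ** b1 if u > 0 else np.zeros_like(b1)
    vb = v ** b2 if v > 0 else np.zeros_like(b2)
    inter = ub * vb
    g = a1 * ub + a2 * vb + a3 * np.where(inter > 0, inter, 1.0) ** b3 * (inter > 0)
    return g / (1.0 + g)


def _six_param_grid(grid):
    if min(grid.u) < 0 or min(grid.v) < 0 or max(grid.u) > 1 or max(grid.v) > 1:
        raise ConfigurationError("six_param requires standardized doses in [0, 1]")


def _std_logistic_prior(grid):
    return [("normal", 0.0, 2.0), ("expon", 1.0), ("expon", 1.0), ("normal", 0.0, 2.0)]


FAMILIES: dict[str, Family] = {
    "logistic4": Family(
        "logistic4",
        False,
        lambda g: ("theta1", "theta2", "theta3", "theta4"),
        _logistic4_f,
        _logistic4_margins,
        _default_prior=_std_logistic_prior,
    ),
    "generalized_crm": Family(
        "generalized_crm",
        False,
        _gencrm_names,
        _gencrm_f,
        _gencrm_margins,
        _default_prior=lambda g: [("normal", 0.0, 2.0)] * g.K + [("expon", 1.0)],
    ),
    "scaled_logistic": Family(
        "scaled_logistic",
        False,
        lambda g: ("rho", "theta1", "theta2", "theta3"),
        _scaled_logistic_f,
        _scaled_logistic_margins,
        _default_prior=lambda g: [
            ("uniform", 0.0, 1.0),
            ("normal", 0.0, 2.0),
            ("expon", 1.0),
            ("expon", 1.0),
        ],
    ),
    "change_point": Family(
        "change_point",
        False,
        lambda g: ("alpha", "beta", "gamma", "w"),
        _change_point_f,
        _change_point_margins,
        _default_prior=lambda g: [
            ("normal", 0.0, 2.0),
            ("expon", 1.0),
            ("expon", 1.0),
            ("normal", 0.0, 2.0),
        ],
    ),
    "clayton": Family(
        "clayton",
        True,
        lambda g: ("alpha", "beta", "gamma"),
        _clayton_f,
        _positive_margins(("alpha", "beta", "gamma")),
        _default_prior=lambda g: [("expon", 1.0)] * 3,
    ),
    "gumbel": Family(
        "gumbel",
        True,
        lambda g: ("alpha", "beta", "gamma"),
        _gumbel_f,
        _positive_margins(("alpha", "beta", "gamma")),
        _default_prior=lambda g: [("expon", 1.0)] * 3,
    ),
    "log_linear": Family(
        "log_linear",
        False,
        lambda g: ("alpha", "beta", "gamma"),
        _log_linear_f,
        _log_linear_margins,
        _check_grid=_log_linear_grid,
        _default_prior=lambda g: [("expon", 1.0), ("expon", 1.0), ("negexpon", 1.0)],
    ),
    "six_param": Family(
        "six_param",
        False,
        lambda g: ("alpha1", "alpha2", "alpha3", "beta1", "beta2", "beta3"),
        _six_param_f,
        _positive_margins(("alpha1", "alpha2", "alpha3", "beta1", "beta2", "beta3")),
        _check_grid=_six_param_grid,
        _default_prior=lambda g: [("expon", 1.0)] * 6,
    ),
}


def family_names() -> tuple[str, ...]:
    return tuple(FAMILIES)


def get_family(name: str) -> Family:
    try:
        return FAMILIES[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown model family '{name}'; choose from {sorted(FAMILIES)}"
        ) from None


def n_params(family: str, grid: DoseGrid) -> int:
    return get_family(family).n_params(grid)


def param_names(family: str, grid: DoseGrid) -> tuple[str, ...]:
    return get_family(family).param_names(grid)


# ---------------------------------------------------------------------------
# ModelSpec and scalar/matrix evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """A family plus a concrete parameter vector theta."""

    family: str
    theta: tuple[float, ...]
    prior: object = None  # optional attached Prior (see combocrm.priors)

    def __post_init__(self) -> None:
        get_family(self.family)
        object.__setattr__(self, "theta", tuple(float(x) for x in self.theta))

    @property
    def constraint_tag(self) -> str:
        return f"{self.family}_partial_order"

    def validated(self, grid: DoseGrid) -> "ModelSpec":
        report = check_constraints(self, grid)
        if not report.admissible:
            raise ConstraintViolationError(
                f"theta inadmissible for '{self.family}': "
                + "; ".join(report.violations)
            )
        return self


@dataclass(frozen=True)
class ConstraintReport:
    admissible: bool
    violations: tuple[str, ...]


def check_constraints(spec: ModelSpec, grid: DoseGrid) -> ConstraintReport:
    """Evaluate every printed admissibility inequality for the family.

    Strict inequalities are enforced with margin ``EPS_CONSTRAINT``; boundary
    thetas are inadmissible.
    """
    fam = get_family(spec.family)
    theta = np.asarray(spec.theta, dtype=float)
    if theta.shape != (fam.n_params(grid),):
        raise ConfigurationError(
            f"'{spec.family}' needs {fam.n_params(grid)} parameters, "
            f"got {theta.shape}"
        )
    violations = [
        label
        for label, margin in fam.margins(theta, grid)
        if not margin[0] > EPS_CONSTRAINT
    ]
    return ConstraintReport(not violations, tuple(violations))


def admissible_mask(family: str, thetas: np.ndarray, grid: DoseGrid) -> np.ndarray:
    """Vectorized admissibility over an (S, p) array of parameter vectors."""
    fam = get_family(family)
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    ok = np.ones(thetas.shape[0], dtype=bool)
    for _, margin in fam.margins(thetas, grid):
        ok &= margin > EPS_CONSTRAINT
    return ok


def toxicity_at(
    family: str,
    thetas: np.ndarray,
    grid: DoseGrid,
    level: Level,
) -> np.ndarray:
    """F at one dose combination for many theta vectors (no admissibility
    gate; total function used by posterior engines and gradient probes)."""
    fam = get_family(family)
    fam.check_grid(grid)
    j, k = grid.require(level)
    u, v = grid.dose(level)
    if family == "generalized_crm":
        # agent 2 is categorical: the evaluator needs the level index
        return fam.f(np.asarray(thetas, float), u, float(k - 1), grid, level)
    return fam.f(np.asarray(thetas, float), u, v, grid, level)


def evaluate_toxicity(
    spec: ModelSpec, grid: DoseGrid, j: int, k: int, check: bool = True
) -> float:
    """F_jk(theta) for a single dose combination.

    With ``check=True`` (default) an inadmissible theta raises
    :class:`ConstraintViolationError` naming the violated predicates.
    """
    if check:
        spec.validated(grid)
    val = float(toxicity_at(spec.family, np.asarray(spec.theta), grid, (j, k)))
    return val


def toxicity_matrix(spec: ModelSpec, grid: DoseGrid, check: bool = True) -> np.ndarray:
    """The J x K matrix of model toxicity probabilities F_jk(theta)."""
    if check:
        spec.validated(grid)
    theta = np.asarray(spec.theta, dtype=float)
    out = np.empty(grid.shape)
    for j, k in grid.levels():
        out[j - 1, k - 1] = toxicity_at(spec.family, theta, grid, (j, k))
    return out


def toxicity_table(family: str, thetas: np.ndarray, grid: DoseGrid) -> np.ndarray:
    """(S, J, K) table of F over S theta vectors; posterior-engine workhorse."""
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    out = np.empty((thetas.shape[0],) + grid.shape)
    for j, k in grid.levels():
        out[:, j - 1, k - 1] = toxicity_at(family, thetas, grid, (j, k))
    return out


def check_partial_order_matrix(
    matrix: np.ndarray, family: str = "", cap: Optional[float] = None,
    tol: float = 0.0,
) -> bool:
    """Is the matrix increasing along each row and column?

    Strict for every family except ``change_point``, whose plateau makes the
    surface only nondecreasing: there ties are accepted exactly where both
    cells sit at the cap ``expit(w)``.
    """
    m = np.asarray(matrix, dtype=float)
    drow = np.diff(m, axis=0)
    dcol = np.diff(m, axis=1)
    if family != "change_point":
        return bool((drow > tol).all() and (dcol > tol).all())
    if (drow < -1e-15).any() or (dcol < -1e-15).any():
        return False
    if cap is None:
        return True
    # ties only allowed on the plateau
    at_cap = np.isclose(m, cap, rtol=0, atol=1e-12)
    row_tie = np.isclose(drow, 0, atol=1e-15)
    col_tie = np.isclose(dcol, 0, atol=1e-15)
    ok_r = (~row_tie) | (at_cap[1:, :] & at_cap[:-1, :])
    ok_c = (~col_tie) | (at_cap[:, 1:] & at_cap[:, :-1])
    return bool(ok_r.all() and ok_c.all())


# ---------------------------------------------------------------------------
# gradients
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GradResult:
    grad: np.ndarray  #: central-difference dF/dtheta_t, length p
    kink: bool  #: change_point: the +/-h probes straddle the kink surface
    one_sided: dict = field(default_factory=dict)  #: t -> (backward, forward)


def grad_toxicity(spec: ModelSpec, grid: DoseGrid, j: int, k: int) -> GradResult:
    """Central-difference gradient of F_jk with respect to theta.

    Step ``h_t = 1e-5 * max(1, |theta_t|)``.  For the change-point family,
    components whose probes straddle the threshold surface are flagged and
    reported with one-sided derivatives as well (the central value is kept
    in ``grad`` for completeness).
    """
    theta = np.asarray(spec.theta, dtype=float)
    p = theta.size
    h = 1e-5 * np.maximum(1.0, np.abs(theta))
    grad = np.empty(p)
    kink = False
    one_sided: dict[int, tuple[float, float]] = {}

    def f_at(th):
        return float(toxicity_at(spec.family, th, grid, (j, k)))

    f0 = f_at(theta)
    for t in range(p):
        tp, tm = theta.copy(), theta.copy()
        tp[t] += h[t]
        tm[t] -= h[t]
        fp, fm = f_at(tp), f_at(tm)
        grad[t] = (fp - fm) / (2 * h[t])
        if spec.family == "change_point":
            u, v = grid.dose((j, k))
            side = lambda th: (th[0] + th[1] * u + th[2] * v) - th[3]  # noqa: E731
            if np.sign(side(tp)) != np.sign(side(tm)):
                kink = True
                one_sided[t] = ((f0 - fm) / h[t], (fp - f0) / h[t])
    return GradResult(grad, kink, one_sided)


# ---------------------------------------------------------------------------
# uniform monotonicity (Definition-2-style checker; a falsifier, not a proof)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParamDirection:
    name: str
    direction: str  #: nondecreasing | nonincreasing | not_uniformly_monotone
    flat: bool  #: no perturbation moved F beyond tolerance
    witness: Optional[dict] = None


@dataclass(frozen=True)
class UniformMonotonicityReport:
    family: str
    params: tuple[ParamDirection, ...]
    uniformly_monotone: bool
    direction: Optional[str]  #: the shared direction when the verdict holds
    witness: Optional[dict]
    n_thetas: int
    n_perturbations: int

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "uniformly_monotone": self.uniformly_monotone,
            "direction": self.direction,
            "params": [
                {"name": q.name, "direction": q.direction, "flat": q.flat,
                 "witness": q.witness}
                for q in self.params
            ],
            "witness": self.witness,
            "n_thetas": self.n_thetas,
            "n_perturbations": self.n_perturbations,
        }


def check_uniform_monotonicity(
    family: str,
    grid: DoseGrid,
    theta_sampler: Callable[[int], np.ndarray],
    n_thetas: int = 50,
    n_perturbations: int = 8,
    seed: int = 0,
    tol: float = 1e-9,
) -> UniformMonotonicityReport:
    """Search for violations of uniform monotonicity by paired perturbation.

    For each parameter, admissible thetas from ``theta_sampler`` are nudged
    upward and the change in F is recorded at every grid point.  A single
    direction is certified only over the sampled set: the check can falsify
    uniform monotonicity (with a witness) but never prove it.  The overall
    verdict requires one direction shared by all parameters, matching the
    "uniformly nondecreasing (or nonincreasing)" reading in which the whole
    surface moves one way.
    """
    if n_thetas < 1 or n_perturbations < 1:
        raise ConfigurationError("n_thetas and n_perturbations must be >= 1")
    fam = get_family(family)
    fam.check_grid(grid)
    rng = np.random.default_rng(seed)
    thetas = np.atleast_2d(np.asarray(theta_sampler(n_thetas), dtype=float))
    if thetas.shape[0] == 0:
        raise ConfigurationError("theta_sampler returned no admissible thetas")
    if not admissible_mask(family, thetas, grid).all():
        raise ConfigurationError("theta_sampler yielded inadmissible thetas")
    p = fam.n_params(grid)
    levels = list(grid.levels())
    f_base = toxicity_table(family, thetas, grid)  # (S, J, K)

    params: list[ParamDirection] = []
    for t in range(p):
        has_pos = has_neg = False
        pos_wit = neg_wit = None
        for _ in range(n_perturbations):
            delta = np.abs(rng.normal(0.0, 0.25, size=thetas.shape[0])) * np.maximum(
                1.0, np.abs(thetas[:, t])
            ) + 1e-8
            pert = thetas.copy()
            pert[:, t] += delta
            keep = admissible_mask(family, pert, grid)
            if not keep.any():
                continue
            df = toxicity_table(family, pert[keep], grid) - f_base[keep]
            if (df > tol).any() and not has_pos:
                has_pos = True
                i, jj, kk = np.unravel_index(np.argmax(df), df.shape)
                pos_wit = {
                    "theta": thetas[keep][i].tolist(),
                    "theta_perturbed": pert[keep][i].tolist(),
                    "level": list(levels[jj * grid.K + kk]),
                    "delta_F": float(df[i, jj, kk]),
                }
            if (df < -tol).any() and not has_neg:
                has_neg = True
                i, jj, kk = np.unravel_index(np.argmin(df), df.shape)
                neg_wit = {
                    "theta": thetas[keep][i].tolist(),
                    "theta_perturbed": pert[keep][i].tolist(),
                    "level": list(levels[jj * grid.K + kk]),
                    "delta_F": float(df[i, jj, kk]),
                }
            if has_pos and has_neg:
                break
        name = fam.param_names(grid)[t]
        if has_pos and has_neg:
            params.append(
                ParamDirection(
                    name, "not_uniformly_monotone", False,
                    {"increase": pos_wit, "decrease": neg_wit},
                )
            )
        elif has_neg:
            params.append(ParamDirection(name, "nonincreasing", False, neg_wit))
        else:
            # nondecreasing covers the flat case as well
            params.append(ParamDirection(name, "nondecreasing", not has_pos, pos_wit))

    mixed = [q for q in params if q.direction == "not_uniformly_monotone"]
    ups = [q for q in params if q.direction == "nondecreasing" and not q.flat]
    downs = [q for q in params if q.direction == "nonincreasing"]
    if mixed:
        verdict, direction, witness = False, None, mixed[0].witness
    elif ups and downs:
        verdict, direction = False, None
        witness = {
            "conflict": [
                {"param": ups[0].name, "direction": "nondecreasing",
                 "witness": ups[0].witness},
                {"param": downs[0].name, "direction": "nonincreasing",
                 "witness": downs[0].witness},
            ]
        }
    else:
        verdict = True
        direction = "nonincreasing" if downs else "nondecreasing"
        witness = None
    return UniformMonotonicityReport(
        family, tuple(params), verdict, direction, witness, n_thetas, n_perturbations
    )
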