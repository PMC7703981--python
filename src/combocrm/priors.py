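"""Prior specifications for the dose-toxicity model parameters.

A prior is a product of independent one-dimensional components multiplied by
the family's joint admissibility indicator on the attached grid.  Component
kinds:

``("normal", mu, sd)``      unconstrained components
``("expon", rate)``         components constrained positive
``("negexpon", rate)``      components constrained negative (log-linear gamma)
``("uniform", a, b)``       bounded components (e.g. the scaled-logistic rho)

Each kind carries its natural Gauss rule (Hermite, Laguerre, Legendre), so a
tensor-product node set integrates the prior exactly and the likelihood to
spectral accuracy.  The same objects provide seeded sampling (for importance
sampling and for the admissible-theta samplers used by the audit checkers)
and truncation boxes with prior mass < 1e-8 outside (for the brute-force
test oracle).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from numpy.polynomial.hermite import hermgauss
from numpy.polynomial.laguerre import laggauss
from numpy.polynomial.legendre import leggauss

from .grid import DoseGrid
from .models import ConfigurationError, admissible_mask, get_family

__all__ = ["ComponentPrior", "Prior", "default_prior", "prior_from_spec"]

#: one-sided tail mass kept outside truncation boxes (< 1e-8 total by design)
_TAIL_Z = 6.0  # normal: 6 sigma, two-sided mass ~2e-9
_TAIL_EXP = 19.0  # exponential: e^-19 ~ 5.6e-9


@dataclass(frozen=True)
class ComponentPrior:
    kind: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "params", tuple(float(x) for x in self.params))
        if self.kind == "normal":
            if len(self.params) != 2 or self.params[1] <= 0:
                raise ConfigurationError("normal prior needs (mu, sd>0)")
        elif self.kind in ("expon", "negexpon"):
            if len(self.params) != 1 or self.params[0] <= 0:
                raise ConfigurationError(f"{self.kind} prior needs (rate>0,)")
        elif self.kind == "uniform":
            if len(self.params) != 2 or self.params[0] >= self.params[1]:
                raise ConfigurationError("uniform prior needs (a, b) with a < b")
        else:
            raise ConfigurationError(f"unknown prior kind '{self.kind}'")

    # -- quadrature ---------------------------------------------------------
    def quad_nodes(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        """Nodes x and log-weights such that sum(exp(logw) f(x)) ~ E_prior[f]."""
        if self.kind == "normal":
            mu, sd = self.params
            x, w = hermgauss(n)
            return mu + np.sqrt(2.0) * sd * x, np.log(w / np.sqrt(np.pi))
        if self.kind == "expon":
            (rate,) = self.params
            x, w = laggauss(n)
            with np.errstate(divide="ignore"):
                return x / rate, np.log(w)
        if self.kind == "negexpon":
            (rate,) = self.params
            x, w = laggauss(n)
            with np.errstate(divide="ignore"):
                return -x / rate, np.log(w)
        a, b = self.params
        x, w = leggauss(n)
        return (a + b) / 2.0 + (b - a) / 2.0 * x, np.log(w / 2.0)

    # -- sampling -----------------------------------------------------------
    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "normal":
            return rng.normal(self.params[0], self.params[1], size)
        if self.kind == "expon":
            return rng.exponential(1.0 / self.params[0], size)
        if self.kind == "negexpon":
            return -rng.exponential(1.0 / self.params[0], size)
        return rng.uniform(self.params[0], self.params[1], size)

    # -- density ------------------------------------------------------------
    def logpdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "normal":
            mu, sd = self.params
            return -0.5 * ((x - mu) / sd) ** 2 - np.log(sd * np.sqrt(2 * np.pi))
        if self.kind == "expon":
            (rate,) = self.params
            return np.where(x >= 0, np.log(rate) - rate * x, -np.inf)
        if self.kind == "negexpon":
            (rate,) = self.params
            return np.where(x <= 0, np.log(rate) + rate * x, -np.inf)
        a, b = self.params
        inside = (x >= a) & (x <= b)
        return np.where(inside, -np.log(b - a), -np.inf)

    def box(self) -> tuple[float, float]:
        """Truncation interval containing all but < 1e-8 of the mass."""
        if self.kind == "normal":
            mu, sd = self.params
            return mu - _TAIL_Z * sd, mu + _TAIL_Z * sd
        if self.kind == "expon":
            return 0.0, _TAIL_EXP / self.params[0]
        if self.kind == "negexpon":
            return -_TAIL_EXP / self.params[0], 0.0
        return self.params[0], self.params[1]

    def mean(self) -> float:
        if self.kind == "normal":
            return self.params[0]
        if self.kind == "expon":
            return 1.0 / self.params[0]
        if self.kind == "negexpon":
            return -1.0 / self.params[0]
        return (self.params[0] + self.params[1]) / 2.0

    def to_tuple(self) -> tuple:
        return (self.kind, *self.params)


@dataclass(frozen=True)
class Prior:
    """Independent component priors x the family admissibility indicator."""

    family: str
    components: tuple[ComponentPrior, ...]
    label: str = "default"

    def __post_init__(self) -> None:
        get_family(self.family)

    @property
    def p(self) -> int:
        return len(self.components)

    def _check_dim(self, grid: DoseGrid) -> None:
        need = get_family(self.family).n_params(grid)
        if self.p != need:
            raise ConfigurationError(
                f"prior has {self.p} components but '{self.family}' needs "
                f"{need} on this grid"
            )

    def quad_nodes(
        self, grid: DoseGrid, nodes_per_axis: int | Sequence[int]
    ) -> tuple[np.ndarray, np.ndarray]:
        """Tensor-product prior-weighted nodes.

        Returns ``(nodes (S, p), logw (S,))`` with ``logw = -inf`` on nodes
        outside the admissible set, so that ``sum(exp(logw) f(nodes))``
        approximates the integral of f against the constrained prior
        (normalisation happens downstream).
        """
        self._check_dim(grid)
        if isinstance(nodes_per_axis, int):
            counts = [nodes_per_axis] * self.p
        else:
            counts = list(nodes_per_axis)
            if len(counts) != self.p:
                raise ConfigurationError("one node count per component required")
        axes = [c.quad_nodes(n) for c, n in zip(self.components, counts)]
        grids = np.meshgrid(*[a[0] for a in axes], indexing="ij")
        nodes = np.stack([g.ravel() for g in grids], axis=-1)
        logw = np.zeros(nodes.shape[0])
        for t, (_, lw) in enumerate(axes):
            shape = [1] * self.p
            shape[t] = -1
            logw += np.broadcast_to(
                lw.reshape(shape), [len(a[0]) for a in axes]
            ).ravel()
        ok = admissible_mask(self.family, nodes, grid)
        if not ok.any():
            raise ConfigurationError(
                "no quadrature node is admissible; prior support and the "
                "family constraints are incompatible on this grid"
            )
        logw = np.where(ok, logw, -np.inf)
        return nodes, logw

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draws from the unconstrained product prior, shape (size, p)."""
        return np.stack([c.sample(rng, size) for c in self.components], axis=-1)

    def sample_admissible(
        self,
        rng: np.random.Generator,
        size: int,
        grid: DoseGrid,
        max_tries: int = 200,
    ) -> np.ndarray:
        """Rejection sampling of admissible thetas; raises if acceptance ~ 0."""
        self._check_dim(grid)
        out: list[np.ndarray] = []
        have = 0
        for _ in range(max_tries):
            cand = self.sample(rng, max(size, 256))
            keep = cand[admissible_mask(self.family, cand, grid)]
            if keep.size:
                out.append(keep)
                have += keep.shape[0]
            if have >= size:
                break
        if have < size:
            raise ConfigurationError(
                f"could not draw {size} admissible thetas for "
                f"'{self.family}' (acceptance rate too low)"
            )
        return np.concatenate(out, axis=0)[:size]

    def sampler(
        self, grid: DoseGrid, seed: int
    ) -> Callable[[int], np.ndarray]:
        """A seeded admissible-theta sampler, as the checkers expect."""
        rng = np.random.default_rng(seed)
        return lambda n: self.sample_admissible(rng, n, grid)

    def logpdf(self, thetas: np.ndarray) -> np.ndarray:
        """Product-prior log density (without the admissibility indicator)."""
        thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
        return sum(
            c.logpdf(thetas[:, t]) for t, c in enumerate(self.components)
        )

    def box(self) -> list[tuple[float, float]]:
        return [c.box() for c in self.components]

    def mean(self) -> np.ndarray:
        """Unconstrained product-prior mean (not the constrained one)."""
        return np.array([c.mean() for c in self.components])

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "label": self.label,
            "components": [list(c.to_tuple()) for c in self.components],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Prior":
        comps = tuple(
            ComponentPrior(c[0], tuple(c[1:])) for c in d["components"]
        )
        return cls(d["family"], comps, d.get("label", "custom"))


def prior_from_spec(family: str, spec: Sequence[tuple], label: str = "custom") -> Prior:
    comps = tuple(ComponentPrior(s[0], tuple(s[1:])) for s in spec)
    return Prior(family, comps, label)


def default_prior(family: str, grid: DoseGrid) -> Prior:
    """The package default prior for a family on a grid.

    Normal(0, 2^2) on unconstrained components, Exponential(1) on positive
    components (mirrored for negative ones), Uniform(0,1) on rho, times the
    family's admissibility indicator.
    """
    fam = get_family(family)
    return prior_from_spec(family, fam.default_prior_spec(grid), label="default")
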