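"""Dose grids for two-agent combination trials.

A trial combines J ordered dose levels of agent 1 (standardized or raw doses
``u_1 < ... < u_J``) with K ordered levels of agent 2 (``v_1 < ... < v_K``).
Dose combinations are addressed by 1-based level pairs ``(j, k)``.  Copula
models additionally need *skeletons*: prior single-agent toxicity estimates
``p_j`` / ``q_k`` in (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = ["DoseGrid", "Level"]

Level = tuple[int, int]


def _strictly_increasing(x: Sequence[float]) -> bool:
    return all(a < b for a, b in zip(x, x[1:]))


@dataclass(frozen=True)
class DoseGrid:
    """The J x K lattice of dose values for the two agents.

    Parameters
    ----------
    u, v
        Strictly increasing dose values for agents 1 and 2.
    skeleton_p, skeleton_q
        Optional strictly increasing prior single-agent DLT probability
        estimates in (0, 1), required by the copula families.
    """

    u: tuple[float, ...]
    v: tuple[float, ...]
    skeleton_p: Optional[tuple[float, ...]] = None
    skeleton_q: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "u", tuple(float(x) for x in self.u))
        object.__setattr__(self, "v", tuple(float(x) for x in self.v))
        if len(self.u) < 1 or len(self.v) < 1:
            raise ValueError("grid needs at least one dose level per agent")
        if not _strictly_increasing(self.u):
            raise ValueError("agent-1 doses u must be strictly increasing")
        if not _strictly_increasing(self.v):
            raise ValueError("agent-2 doses v must be strictly increasing")
        for name in ("skeleton_p", "skeleton_q"):
            s = getattr(self, name)
            if s is None:
                continue
            s = tuple(float(x) for x in s)
            object.__setattr__(self, name, s)
            expected = len(self.u) if name == "skeleton_p" else len(self.v)
            if len(s) != expected:
                raise ValueError(f"{name} must have length {expected}")
            if not _strictly_increasing(s):
                raise ValueError(f"{name} must be strictly increasing")
            if not all(0.0 < x < 1.0 for x in s):
                raise ValueError(f"{name} values must lie in the open (0,1)")

    @property
    def J(self) -> int:
        return len(self.u)

    @property
    def K(self) -> int:
        return len(self.v)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.J, self.K)

    def levels(self) -> Iterator[Level]:
        """All level pairs (j, k), 1-based, row-major."""
        for j in range(1, self.J + 1):
            for k in range(1, self.K + 1):
                yield (j, k)

    def contains(self, level: Level) -> bool:
        j, k = level
        return 1 <= j <= self.J and 1 <= k <= self.K

    def require(self, level: Level) -> Level:
        if not self.contains(level):
            raise ValueError(f"level {level} outside the {self.J}x{self.K} grid")
        return level

    def dose(self, level: Level) -> tuple[float, float]:
        """The (u_j, v_k) dose values for a 1-based level pair."""
        j, k = self.require(level)
        return self.u[j - 1], self.v[k - 1]

    def skeleton(self, level: Level) -> tuple[float, float]:
        """The (p_j, q_k) skeleton values; error if skeletons absent."""
        j, k = self.require(level)
        if self.skeleton_p is None or self.skeleton_q is None:
            raise ValueError(
                "this grid carries no single-agent toxicity skeleton "
                "(skeleton_p/skeleton_q); copula families require one"
            )
        return self.skeleton_p[j - 1], self.skeleton_q[k - 1]

    def to_dict(self) -> dict:
        d = {"u": list(self.u), "v": list(self.v)}
        if self.skeleton_p is not None:
            d["skeleton_p"] = list(self.skeleton_p)
        if self.skeleton_q is not None:
            d["skeleton_q"] = list(self.skeleton_q)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DoseGrid":
        return cls(
            u=tuple(d["u"]),
            v=tuple(d["v"]),
            skeleton_p=tuple(d["skeleton_p"]) if d.get("skeleton_p") else None,
            skeleton_q=tuple(d["skeleton_q"]) if d.get("skeleton_q") else None,
        )

    @classmethod
    def from_skeletons(
        cls, skeleton_p: Sequence[float], skeleton_q: Sequence[float]
    ) -> "DoseGrid":
        """Standardized-dose grid u_j = logit(p_j), v_k = logit(q_k)."""
        p = np.asarray(skeleton_p, dtype=float)
        q = np.asarray(skeleton_q, dtype=float)
        logit = lambda x: np.log(x / (1.0 - x))  # noqa: E731
        return cls(
            u=tuple(logit(p)),
            v=tuple(logit(q)),
            skeleton_p=tuple(p),
            skeleton_q=tuple(q),
        )
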