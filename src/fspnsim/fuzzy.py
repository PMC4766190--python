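"""Triangular fuzzy numbers and alpha-cut machinery.

A fuzzy number represents an uncertain quantity by a membership function
``mu : R -> [0, 1]``: the degree to which each value is considered possible.
The triangular shape ``(a, b, c)`` is the workhorse in practice — an expert
states a pessimistic value ``a``, a most-possible value ``b`` and an
optimistic value ``c``, and membership rises linearly from ``a`` to ``b``
and falls linearly from ``b`` to ``c``.

Level-wise (alpha-cut) decomposition is what makes fuzzy numbers computable:
the alpha-cut of a fuzzy number is the crisp interval of values with
membership at least alpha, and a fuzzy number is fully recovered from the
family of its cuts.  Uncertainty propagation in this package works on cuts:
decompose the inputs, push crisp samples of each cut through the stochastic
model, and compose the output intervals back into a membership function
(Zadeh's extension principle, realized level by level).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "TriangularFuzzyNumber",
    "AlphaCut",
    "AlphaCutSet",
    "PiecewiseLinearMembership",
    "NestednessError",
    "discretize_cut",
    "compose_cuts",
]


class NestednessError(ValueError):
    """Alpha-cuts are not nested and strict policy is in force."""


@dataclass(frozen=True)
class TriangularFuzzyNumber:
    """Triangular fuzzy number ``(a, b, c)`` with ``a <= b <= c``.

    ``a`` and ``c`` bound the support, ``b`` is the core (the unique value
    with membership 1).  The degenerate case ``a == b == c`` embeds a crisp
    number.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (self.a <= self.b <= self.c):
            raise ValueError(
                f"triangular fuzzy number requires a <= b <= c, "
                f"got ({self.a}, {self.b}, {self.c})"
            )

    @property
    def is_crisp(self) -> bool:
        return self.a == self.c

    def membership(self, x: float) -> float:
        """Degree to which ``x`` belongs to the fuzzy number.

        Piecewise linear: 0 outside ``[a, c]``, 1 at ``b``, linear flanks.
        Degenerate flanks (``a == b`` or ``b == c``) take the limit value 1
        at the shared point.
        """
        a, b, c = self.a, self.b, self.c
        if x < a or x > c:
            return 0.0
        if x == b:
            return 1.0
        if x < b:  # a < x < b, so a < b
            return (x - a) / (b - a)
        return (c - x) / (c - b)  # b < x < c, so b < c

    def alpha_cut(self, alpha: float) -> "AlphaCut":
        """Closed interval ``[a + alpha(b-a), c - alpha(c-b)]``.

        At alpha = 0 this is the closed support ``[a, c]``; at alpha = 1 the
        degenerate core ``[b, b]``.
        """
        if not 0.0 <= alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {alpha}")
        lower = self.a + alpha * (self.b - self.a)
        upper = self.c - alpha * (self.c - self.b)
        if lower > upper:  # round-off crossing near alpha = 1
            lower = upper = 0.5 * (lower + upper)
        return AlphaCut(alpha=alpha, lower=lower, upper=upper)

    def support(self) -> tuple[float, float]:
        """Closure of the set of values with non-zero membership."""
        return (self.a, self.c)

    def core(self) -> tuple[float, float]:
        """Set of values with membership exactly 1 (a point, as interval)."""
        return (self.b, self.b)

    def decompose(self, alphas: Iterable[float]) -> "AlphaCutSet":
        """Alpha-cut decomposition at the given levels."""
        return AlphaCutSet(sorted(self.alpha_cut(al) for al in alphas))


@dataclass(frozen=True, order=True)
class AlphaCut:
    """One level of a fuzzy number: the interval of values with mu >= alpha."""

    alpha: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.lower > self.upper:
            raise ValueError(
                f"alpha-cut interval requires lower <= upper, "
                f"got [{self.lower}, {self.upper}] at alpha={self.alpha}"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)


@dataclass
class AlphaCutSet:
    """Cuts of one quantity, sorted by ascending alpha.

    Cuts of a genuine fuzzy number are nested: raising alpha can only shrink
    the interval.  Monte-Carlo estimated cuts may violate this by noise; see
    :meth:`repaired`.
    """

    cuts: list[AlphaCut] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cuts = sorted(self.cuts, key=lambda c: c.alpha)

    def __iter__(self):
        return iter(self.cuts)

    def __len__(self) -> int:
        return len(self.cuts)

    @property
    def alphas(self) -> list[float]:
        return [c.alpha for c in self.cuts]

    def is_nested(self) -> bool:
        """True iff lower endpoints are non-decreasing and uppers non-increasing in alpha."""
        for lo_cut, hi_cut in zip(self.cuts, self.cuts[1:]):
            if hi_cut.lower < lo_cut.lower or hi_cut.upper > lo_cut.upper:
                return False
        return True

    def repaired(self) -> "AlphaCutSet":
        """Monotone-envelope repair of nestedness violations.

        Lower endpoints are replaced by their running maximum in ascending
        alpha, upper endpoints by their running minimum, which is the
        smallest perturbation making the family nested.  If a repaired cut
        would cross (lower > upper) both endpoints collapse to the midpoint
        of the crossing pair.
        """
        repaired: list[AlphaCut] = []
        lo, up = -math.inf, math.inf
        for cut in self.cuts:
            new_lo = max(lo, cut.lower)
            new_up = min(up, cut.upper)
            if new_lo > new_up:
                # disjoint with the running envelope: collapse to the point
                # of the envelope band closest to the cut's midpoint
                v = min(max(cut.midpoint, lo), up)
                new_lo = new_up = v
            lo, up = new_lo, new_up
            repaired.append(AlphaCut(cut.alpha, lo, up))
        return AlphaCutSet(repaired)

    def to_rows(self) -> list[dict]:
        return [
            {"alpha": c.alpha, "lower": c.lower, "upper": c.upper} for c in self.cuts
        ]


@dataclass
class PiecewiseLinearMembership:
    """Membership function given by linear interpolation between knots.

    ``knots`` is a list of ``(x, mu)`` pairs with x non-decreasing, mu
    unimodal (rises to 1, then falls).  Outside the knot range membership
    is 0.
    """

    knots: list[tuple[float, float]]

    def __post_init__(self) -> None:
        xs = [x for x, _ in self.knots]
        if any(x1 > x2 for x1, x2 in zip(xs, xs[1:])):
            raise ValueError("membership knots must have non-decreasing x")
        mus = [mu for _, mu in self.knots]
        if not mus or max(mus) < 1.0 - 1e-12:
            raise ValueError("membership function must attain 1 (normalized)")
        if any(mu < -1e-12 or mu > 1 + 1e-12 for mu in mus):
            raise ValueError("membership values must lie in [0, 1]")

    def __call__(self, x: float) -> float:
        xs = [k[0] for k in self.knots]
        if x < xs[0] or x > xs[-1]:
            return 0.0
        if len(self.knots) == 1:
            return self.knots[0][1]
        # max over segments so vertical segments (degenerate cores) are exact
        best = 0.0
        for (x1, m1), (x2, m2) in zip(self.knots, self.knots[1:]):
            if x1 <= x <= x2:
                if x2 == x1:
                    best = max(best, m1, m2)
                else:
                    best = max(best, m1 + (m2 - m1) * (x - x1) / (x2 - x1))
        return best

    @property
    def support(self) -> tuple[float, float]:
        return (self.knots[0][0], self.knots[-1][0])

    @property
    def core_values(self) -> list[float]:
        return [x for x, mu in self.knots if mu >= 1.0 - 1e-12]

    def to_rows(self) -> list[dict]:
        return [{"x": x, "mu": mu} for x, mu in self.knots]


def discretize_cut(
    cut: AlphaCut,
    k: int,
    method: Literal["grid", "lhs"] = "grid",
    seed: int | None = None,
) -> list[float]:
    """Crisp sample points covering the interval of an alpha-cut.

    grid
        ``k`` equally spaced points including both endpoints (``k = 1``
        gives the midpoint).
    lhs
        Latin-hypercube style stratified sampling: one uniform draw per
        equal-width stratum, reproducible from ``seed``.

    A degenerate interval collapses to a single value regardless of ``k``.
    """
    if k < 1:
        raise ValueError(f"number of points per cut must be >= 1, got {k}")
    lo, up = cut.lower, cut.upper
    if lo == up:
        return [lo]
    if method == "grid":
        if k == 1:
            return [cut.midpoint]
        return list(np.linspace(lo, up, k))
    if method == "lhs":
        rng = np.random.default_rng(seed)
        edges = np.linspace(lo, up, k + 1)
        draws = edges[:-1] + rng.random(k) * (edges[1:] - edges[:-1])
        return list(np.sort(draws))
    raise ValueError(f"unknown discretization method: {method!r}")


def compose_cuts(
    cuts: AlphaCutSet,
    policy: Literal["repair", "strict"] = "repair",
) -> PiecewiseLinearMembership:
    """Compose alpha-cuts into a piecewise-linear membership function.

    The lower endpoints, in ascending alpha, form the ascending branch of
    the membership function; the upper endpoints, in descending alpha, the
    descending branch.  The result's alpha-cuts at the input levels equal
    the input intervals, with linear interpolation in between.

    Requires a cut at alpha = 1 (normalization).  Non-nested input is
    repaired by monotone envelope under ``policy='repair'`` (with a
    warning); ``'strict'`` raises :class:`NestednessError` instead.
    """
    if len(cuts) == 0:
        raise ValueError("cannot compose an empty alpha-cut set")
    if not any(abs(c.alpha - 1.0) < 1e-12 for c in cuts):
        raise ValueError("alpha-cut set must include the alpha = 1 cut")
    if not cuts.is_nested():
        if policy == "strict":
            raise NestednessError("alpha-cuts are not nested")
        warnings.warn(
            "alpha-cuts are not nested (Monte-Carlo noise?); "
            "applying monotone-envelope repair",
            stacklevel=2,
        )
        cuts = cuts.repaired()
    ascending = [(c.lower, c.alpha) for c in cuts.cuts]
    descending = [(c.upper, c.alpha) for c in reversed(cuts.cuts)]
    knots = ascending + descending
    # drop consecutive duplicate points (degenerate core interval)
    deduped: list[tuple[float, float]] = []
    for knot in knots:
        if not deduped or abs(knot[0] - deduped[-1][0]) > 0 or knot[1] != deduped[-1][1]:
            deduped.append(knot)
    return PiecewiseLinearMembership(deduped)
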