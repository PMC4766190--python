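"""Qualitative structural analysis of Petri nets.

Structure alone — before any kinetics — already constrains the dynamics:

* a *P-invariant* (semi-positive left kernel vector of the incidence
  matrix) is a weighted token sum conserved by every firing, e.g. a
  conservation of protein mass across its complexes;
* a *T-invariant* (right kernel vector) is a firing-count vector that
  reproduces a marking — coverage of all transitions by T-invariants is a
  necessary condition for every reaction to contribute to steady-state
  cycling;
* places not covered by any P-invariant are candidates for structurally
  unbounded token growth, which rules out explicit CTMC construction and
  motivates simulation-based analysis;
* the siphon-trap property (every minimal siphon contains an initially
  marked trap) guarantees liveness for extended-simple nets.

Invariants are computed with the Farkas (Fourier–Motzkin) elimination over
exact Python integers, so the kernel conditions hold exactly.  Siphons and
traps are enumerated exhaustively over place subsets, which is adequate for
the small biochemical nets in scope (guarded at 20 places).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .net_model import FSPNModel
from .ssa import Trajectory

__all__ = [
    "Invariant",
    "Coverage",
    "SiphonOrTrap",
    "StructuralReport",
    "minimal_p_invariants",
    "minimal_t_invariants",
    "coverage",
    "minimal_siphons",
    "minimal_traps",
    "maximal_trap_within",
    "stp_holds",
    "is_extended_simple",
    "check_conservation",
    "structural_report",
]

MAX_PLACES_FOR_ENUMERATION = 20


@dataclass(frozen=True)
class Invariant:
    """Semi-positive kernel vector of the incidence matrix.

    ``weights`` maps node id (place for P-invariants, transition for
    T-invariants) to a non-negative integer; zero entries are omitted.
    """

    weights: tuple[tuple[str, int], ...]

    @property
    def support(self) -> frozenset[str]:
        return frozenset(n for n, w in self.weights if w != 0)

    def weight(self, node: str) -> int:
        return dict(self.weights).get(node, 0)

    def as_dict(self) -> dict[str, int]:
        return dict(self.weights)

    def __str__(self) -> str:
        terms = [
            (f"{w}*{n}" if w != 1 else n)
            for n, w in sorted(self.weights)
            if w != 0
        ]
        return " + ".join(terms)


def _farkas_minimal(C: np.ndarray, labels: list[str]) -> list[Invariant]:
    """All minimal semi-positive integer vectors x with x^T C = 0.

    Fourier–Motzkin elimination of each constraint column, carrying the
    generating combination alongside; exact Python-int arithmetic
    throughout, gcd normalization, then support-minimality filtering.
    """
    n, m = C.shape
    rows: list[tuple[list[int], list[int]]] = []
    for i in range(n):
        unit = [0] * n
        unit[i] = 1
        rows.append(([int(v) for v in C[i, :]], unit))
    for j in range(m):
        zero = [r for r in rows if r[0][j] == 0]
        pos = [r for r in rows if r[0][j] > 0]
        neg = [r for r in rows if r[0][j] < 0]
        new = list(zero)
        for cp, xp in pos:
            for cn, xn in neg:
                a, b = cp[j], -cn[j]
                g = math.gcd(a, b)
                fa, fb = b // g, a // g
                cc = [fa * u + fb * v for u, v in zip(cp, cn)]
                xx = [fa * u + fb * v for u, v in zip(xp, xn)]
                g2 = 0
                for v in xx:
                    g2 = math.gcd(g2, v)
                if g2 > 1 and all(c % g2 == 0 for c in cc):
                    cc = [c // g2 for c in cc]
                    xx = [v // g2 for v in xx]
                new.append((cc, xx))
        # prune duplicates to keep the row set small
        seen: set[tuple[int, ...]] = set()
        rows = []
        for cc, xx in new:
            key = tuple(xx)
            if key not in seen:
                seen.add(key)
                rows.append((cc, xx))
    candidates = []
    for cc, xx in rows:
        if any(c != 0 for c in cc) or all(v == 0 for v in xx):
            continue
        g = 0
        for v in xx:
            g = math.gcd(g, v)
        candidates.append(tuple(v // g for v in xx))
    candidates = sorted(set(candidates))
    supports = [frozenset(i for i, v in enumerate(x) if v) for x in candidates]
    minimal = [
        x
        for x, s in zip(candidates, supports)
        if not any(o < s for o in supports)
    ]
    invs = [
        Invariant(tuple((labels[i], v) for i, v in enumerate(x) if v))
        for x in minimal
    ]
    return sorted(invs, key=lambda inv: sorted(inv.support))


def minimal_p_invariants(model: FSPNModel) -> list[Invariant]:
    """Complete set of minimal semi-positive P-invariants (conserved sums)."""
    return _farkas_minimal(model.incidence_matrix(), model.place_ids)


def minimal_t_invariants(model: FSPNModel) -> list[Invariant]:
    """Complete set of minimal semi-positive T-invariants (reproducing
    firing-count vectors)."""
    return _farkas_minimal(model.incidence_matrix().T, model.transition_ids)


@dataclass(frozen=True)
class Coverage:
    """Which nodes carry positive weight in at least one minimal invariant."""

    covered: frozenset[str]
    uncovered: frozenset[str]

    @property
    def is_covered(self) -> bool:
        return not self.uncovered


def coverage(
    model: FSPNModel, invariants: list[Invariant], kind: str = "place"
) -> Coverage:
    """Invariant coverage of places (kind='place') or transitions.

    Uncovered places are the candidates for structurally unbounded token
    growth; full transition coverage means every reaction can take part in
    steady-state cycling.
    """
    nodes = set(model.place_ids if kind == "place" else model.transition_ids)
    covered = set().union(*(inv.support for inv in invariants)) if invariants else set()
    covered &= nodes
    return Coverage(frozenset(covered), frozenset(nodes - covered))


# -- siphons and traps ---------------------------------------------------


def _place_adjacency(model: FSPNModel):
    pre_t: dict[str, set[str]] = {p: set() for p in model.place_ids}  # transitions feeding p
    post_t: dict[str, set[str]] = {p: set() for p in model.place_ids}  # transitions consuming p
    for t in model.transition_ids:
        for p, _ in model.pre_arcs(t):
            post_t[p].add(t)
        for p, _ in model.post_arcs(t):
            pre_t[p].add(t)
    return pre_t, post_t


@dataclass(frozen=True)
class SiphonOrTrap:
    places: frozenset[str]
    kind: str  # "siphon" | "trap"


def _is_siphon(S: set[str], pre_t, post_t) -> bool:
    # every transition with an output into S also takes an input from S;
    # fully isolated place sets are excluded as degenerate
    preset = set().union(*(pre_t[p] for p in S))
    postset = set().union(*(post_t[p] for p in S))
    return bool(preset | postset) and preset <= postset


def _is_trap(S: set[str], pre_t, post_t) -> bool:
    preset = set().union(*(pre_t[p] for p in S))
    postset = set().union(*(post_t[p] for p in S))
    return bool(preset | postset) and postset <= preset


def _minimal_subsets(model: FSPNModel, predicate) -> list[frozenset[str]]:
    places = model.place_ids
    if len(places) > MAX_PLACES_FOR_ENUMERATION:
        raise ValueError(
            f"exhaustive siphon/trap enumeration is limited to "
            f"{MAX_PLACES_FOR_ENUMERATION} places (net has {len(places)})"
        )
    pre_t, post_t = _place_adjacency(model)
    found: list[frozenset[str]] = []
    for size in range(1, len(places) + 1):
        for combo in itertools.combinations(places, size):
            S = frozenset(combo)
            if any(f < S for f in found):
                continue
            if predicate(set(S), pre_t, post_t):
                found.append(S)
    return sorted(found, key=sorted)


def minimal_siphons(model: FSPNModel) -> list[SiphonOrTrap]:
    """Minimal non-empty place sets that, once empty, stay empty forever."""
    return [SiphonOrTrap(S, "siphon") for S in _minimal_subsets(model, _is_siphon)]


def minimal_traps(model: FSPNModel) -> list[SiphonOrTrap]:
    """Minimal non-empty place sets that, once marked, stay marked forever."""
    return [SiphonOrTrap(S, "trap") for S in _minimal_subsets(model, _is_trap)]


def maximal_trap_within(model: FSPNModel, places: frozenset[str]) -> frozenset[str]:
    """Largest trap contained in a place set (possibly empty).

    Iteratively removes any place with a consuming transition that does not
    feed back into the remaining set; the fixpoint is the maximal trap.
    """
    pre_t, post_t = _place_adjacency(model)
    post_places: dict[str, set[str]] = {t: set() for t in model.transition_ids}
    for p in model.place_ids:
        for t in pre_t[p]:
            post_places[t].add(p)
    Q = set(places)
    changed = True
    while changed and Q:
        changed = False
        for p in list(Q):
            for t in post_t[p]:
                if not (post_places[t] & Q):
                    Q.discard(p)
                    changed = True
                    break
    return frozenset(Q)


def stp_holds(model: FSPNModel) -> bool:
    """Siphon-trap property: every minimal siphon contains a trap that is
    marked at the initial marking.  For extended-simple nets this implies
    liveness."""
    m0 = model.initial_marking
    for siphon in minimal_siphons(model):
        trap = maximal_trap_within(model, siphon.places)
        if not trap or sum(m0[p] for p in trap) == 0:
            return False
    return True


def is_extended_simple(model: FSPNModel) -> bool:
    """Extended-simple (ES) structural class: any two places sharing a
    consuming transition have nested post-sets."""
    _, post_t = _place_adjacency(model)
    for p, q in itertools.combinations(model.place_ids, 2):
        sp, sq = post_t[p], post_t[q]
        if sp & sq and not (sp <= sq or sq <= sp):
            return False
    return True


def check_conservation(traj: Trajectory, inv: Invariant) -> bool:
    """True iff the invariant-weighted token sum is constant along the
    sampled trajectory (dynamic confirmation of a structural P-invariant)."""
    w = np.zeros(len(traj.place_ids))
    for pid, weight in inv.weights:
        w[traj.place_ids.index(pid)] = weight
    sums = traj.states @ w
    return bool(np.all(sums == sums[0]))


@dataclass
class StructuralReport:
    """Bundle of all structural diagnostics for one net."""

    p_invariants: list[Invariant]
    t_invariants: list[Invariant]
    place_coverage: Coverage
    transition_coverage: Coverage
    siphons: list[SiphonOrTrap]
    traps: list[SiphonOrTrap]
    stp: bool
    extended_simple: bool

    @property
    def implied_live(self) -> bool | None:
        """Liveness implied by STP + ES; None when the conditions do not
        apply (liveness itself is not decided here)."""
        return True if (self.stp and self.extended_simple) else None

    def to_dict(self) -> dict:
        return {
            "p_invariants": [inv.as_dict() for inv in self.p_invariants],
            "t_invariants": [inv.as_dict() for inv in self.t_invariants],
            "covered_places": sorted(self.place_coverage.covered),
            "unbounded_place_candidates": sorted(self.place_coverage.uncovered),
            "covered_transitions": sorted(self.transition_coverage.covered),
            "uncovered_transitions": sorted(self.transition_coverage.uncovered),
            "minimal_siphons": [sorted(s.places) for s in self.siphons],
            "minimal_traps": [sorted(s.places) for s in self.traps],
            "siphon_trap_property": self.stp,
            "extended_simple": self.extended_simple,
            "implied_live": self.implied_live,
        }


def structural_report(model: FSPNModel) -> StructuralReport:
    p_invs = minimal_p_invariants(model)
    t_invs = minimal_t_invariants(model)
    return StructuralReport(
        p_invariants=p_invs,
        t_invariants=t_invs,
        place_coverage=coverage(model, p_invs, "place"),
        transition_coverage=coverage(model, t_invs, "transition"),
        siphons=minimal_siphons(model),
        traps=minimal_traps(model),
        stp=stp_holds(model),
        extended_simple=is_extended_simple(model),
    )
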