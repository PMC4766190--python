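"""Petri-net / SPN / FSPN data model, hazards, and model-file I/O.

A stochastic Petri net (SPN) is a bipartite graph of *places* (chemical
species) and *transitions* (reactions) joined by weighted arcs
(stoichiometry), together with an initial token *marking* (molecule counts)
and a kinetic rate constant per transition.  Each enabled transition fires
after an exponentially distributed delay whose rate is a marking-dependent
hazard; the default hazard is the Gillespie propensity
``theta * #{reactant combinations}``.

A *fuzzy* stochastic Petri net (FSPN) is an SPN in which any rate constant
may be a :class:`~fspnsim.fuzzy.TriangularFuzzyNumber` instead of a crisp
positive real, expressing fuzzy uncertainty about the parameter.  Replacing
every fuzzy parameter by a crisp value (for instance its core) turns the
FSPN back into a plain SPN.

Models are stored as small JSON files; the three in-repo fixtures (a virus
infection toy model in crisp and fuzzy variants, and the 8-reaction yeast
pheromone-induced G-protein cycle) are available through :func:`fixture`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Literal, Mapping

import numpy as np

from .fuzzy import TriangularFuzzyNumber

__all__ = [
    "ModelValidationError",
    "Place",
    "Arc",
    "Transition",
    "FSPNModel",
    "Marking",
    "enabled_transitions",
    "fire",
    "hazard",
    "incidence_matrix",
    "read_model",
    "write_model",
    "fixture",
    "FIXTURE_NAMES",
]

#: A marking assigns a non-negative molecule count to every place id.
Marking = dict[str, int]

RateLaw = Literal["mass_action", "constant", "explicit_product"]
_RATE_LAWS = ("mass_action", "constant", "explicit_product")

#: Token counts beyond this raise instead of silently growing (in-scope
#: models stay far below; this guards runaway explosive nets).
MAX_TOKENS = 10**9

FIXTURE_NAMES = ("virus_crisp", "virus_fuzzy", "yeast_polarization")


class ModelValidationError(ValueError):
    """A model file or model object violates a structural invariant."""


@dataclass(frozen=True)
class Place:
    id: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("place id must be non-empty")


@dataclass(frozen=True)
class Arc:
    """Directed weighted arc between a place and a transition (either way)."""

    source: str
    target: str
    weight: int = 1

    def __post_init__(self) -> None:
        if self.weight < 1:
            raise ModelValidationError(
                f"arc {self.source}->{self.target}: weight must be >= 1, "
                f"got {self.weight}"
            )


@dataclass(frozen=True)
class Transition:
    """A reaction with its kinetic parameter and rate-law convention.

    ``parameter`` is a crisp positive rate constant or a triangular fuzzy
    number whose support lies strictly above 0.  ``rate_law`` selects the
    hazard: ``mass_action`` (Gillespie combination counts, the default),
    ``constant`` (marking-independent, e.g. zeroth-order input), or
    ``explicit_product`` (plain product of counts raised to arc weights).
    """

    id: str
    parameter: float | TriangularFuzzyNumber
    rate_law: RateLaw = "mass_action"

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("transition id must be non-empty")
        if self.rate_law not in _RATE_LAWS:
            raise ModelValidationError(
                f"transition {self.id}: unknown rate law {self.rate_law!r}"
            )
        p = self.parameter
        if isinstance(p, TriangularFuzzyNumber):
            if p.a <= 0:
                raise ModelValidationError(
                    f"transition {self.id}: fuzzy parameter support must be "
                    f"strictly positive, got lower bound {p.a}"
                )
        elif not (isinstance(p, (int, float)) and p > 0 and math.isfinite(p)):
            raise ModelValidationError(
                f"transition {self.id}: crisp parameter must be a positive "
                f"finite real, got {p!r}"
            )

    @property
    def is_fuzzy(self) -> bool:
        return isinstance(self.parameter, TriangularFuzzyNumber)


@dataclass
class FSPNModel:
    """Fuzzy stochastic Petri net: places, transitions, arcs, initial marking.

    When every parameter is crisp the model is a plain SPN and can be
    simulated directly; fuzzy parameters require the alpha-cut propagation
    pipeline (:mod:`fspnsim.fuzzy_analysis`).
    """

    name: str
    places: list[Place]
    transitions: list[Transition]
    arcs: list[Arc]
    initial_marking: Marking

    # derived lookups, built on validation
    _pre: dict[str, list[tuple[str, int]]] = field(repr=False, default_factory=dict)
    _post: dict[str, list[tuple[str, int]]] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------

    def validate(self) -> None:
        place_ids = [p.id for p in self.places]
        trans_ids = [t.id for t in self.transitions]
        if len(set(place_ids)) != len(place_ids):
            raise ModelValidationError("duplicate place ids")
        if len(set(trans_ids)) != len(trans_ids):
            raise ModelValidationError("duplicate transition ids")
        if set(place_ids) & set(trans_ids):
            raise ModelValidationError("place and transition ids must be disjoint")
        pset, tset = set(place_ids), set(trans_ids)
        pre: dict[str, list[tuple[str, int]]] = {t: [] for t in trans_ids}
        post: dict[str, list[tuple[str, int]]] = {t: [] for t in trans_ids}
        for arc in self.arcs:
            if arc.source in pset and arc.target in tset:
                pre[arc.target].append((arc.source, arc.weight))
            elif arc.source in tset and arc.target in pset:
                post[arc.source].append((arc.target, arc.weight))
            else:
                raise ModelValidationError(
                    f"arc {arc.source}->{arc.target} must connect a place "
                    "and a transition (both ids must exist)"
                )
        self._pre = pre
        self._post = post
        self.validate_marking(self.initial_marking)

    def validate_marking(self, m: Mapping[str, int]) -> None:
        pset = {p.id for p in self.places}
        unknown = set(m) - pset
        if unknown:
            raise ModelValidationError(f"marking refers to unknown places: {sorted(unknown)}")
        missing = pset - set(m)
        if missing:
            raise ModelValidationError(f"marking misses places: {sorted(missing)}")
        for pid, count in m.items():
            if not isinstance(count, (int, np.integer)) or count < 0:
                raise ModelValidationError(
                    f"marking of {pid} must be a non-negative integer, got {count!r}"
                )
            if count > MAX_TOKENS:
                raise ModelValidationError(
                    f"marking of {pid} exceeds the token-count guard ({MAX_TOKENS})"
                )

    # -- accessors ------------------------------------------------------

    @property
    def place_ids(self) -> list[str]:
        return [p.id for p in self.places]

    @property
    def transition_ids(self) -> list[str]:
        return [t.id for t in self.transitions]

    def transition(self, tid: str) -> Transition:
        for t in self.transitions:
            if t.id == tid:
                return t
        raise KeyError(f"unknown transition: {tid}")

    def pre_arcs(self, tid: str) -> list[tuple[str, int]]:
        """(place, weight) pairs of the input arcs of a transition."""
        if tid not in self._pre:
            raise KeyError(f"unknown transition: {tid}")
        return list(self._pre[tid])

    def post_arcs(self, tid: str) -> list[tuple[str, int]]:
        if tid not in self._post:
            raise KeyError(f"unknown transition: {tid}")
        return list(self._post[tid])

    @property
    def is_crisp(self) -> bool:
        """True iff no parameter is fuzzy (the model is a plain SPN)."""
        return not any(t.is_fuzzy for t in self.transitions)

    def fuzzy_parameters(self) -> dict[str, TriangularFuzzyNumber]:
        """Fuzzy parameters keyed by transition id, in transition order."""
        return {
            t.id: t.parameter for t in self.transitions if t.is_fuzzy  # type: ignore[misc]
        }

    # -- dynamics -------------------------------------------------------

    def enabled_transitions(self, m: Mapping[str, int]) -> set[str]:
        """Transitions whose every preplace holds at least the arc weight.

        Transitions with no preplaces (source reactions) are always enabled.
        """
        self.validate_marking(m)
        return {
            t.id
            for t in self.transitions
            if all(m[p] >= w for p, w in self._pre[t.id])
        }

    def fire(self, m: Mapping[str, int], tid: str) -> Marking:
        """Fire a transition, returning the successor marking.

        The argument marking is not mutated.  Firing a disabled transition
        raises ``ValueError``.
        """
        self.validate_marking(m)
        if tid not in self._pre:
            raise KeyError(f"unknown transition: {tid}")
        if any(m[p] < w for p, w in self._pre[tid]):
            raise ValueError(f"transition {tid} is not enabled in the given marking")
        out = dict(m)
        for p, w in self._pre[tid]:
            out[p] -= w
        for p, w in self._post[tid]:
            out[p] += w
            if out[p] > MAX_TOKENS:
                raise OverflowError(
                    f"token count on {p} exceeds the guard ({MAX_TOKENS})"
                )
        return out

    def hazard(self, m: Mapping[str, int], tid: str, theta: float) -> float:
        """Marking-dependent firing rate for a crisp parameter sample.

        ``mass_action``: ``theta * prod_p C(m[p], w(p, t))`` over preplaces
        (the Gillespie reactant-combination count), hence exactly 0 when the
        transition is disabled.  ``constant``: ``theta``.
        ``explicit_product``: ``theta * prod_p m[p] ** w(p, t)``.
        """
        if theta <= 0:
            raise ValueError(f"theta must be positive, got {theta}")
        if any(c < 0 for c in m.values()):
            raise ValueError("marking contains negative counts")
        t = self.transition(tid)
        if t.rate_law == "constant":
            return theta
        h = theta
        for p, w in self._pre[tid]:
            if t.rate_law == "mass_action":
                h *= math.comb(m[p], w) if m[p] >= w else 0
            else:  # explicit_product
                h *= m[p] ** w
        return h

    def incidence_matrix(self) -> np.ndarray:
        """Integer matrix C with C[p, t] = out-weight(t, p) - in-weight(p, t).

        Rows follow ``place_ids``, columns ``transition_ids``; firing t maps
        a marking m to m + C[:, t].
        """
        pidx = {p: i for i, p in enumerate(self.place_ids)}
        C = np.zeros((len(self.places), len(self.transitions)), dtype=np.int64)
        for j, t in enumerate(self.transitions):
            for p, w in self._pre[t.id]:
                C[pidx[p], j] -= w
            for p, w in self._post[t.id]:
                C[pidx[p], j] += w
        return C

    # -- parameter substitution -----------------------------------------

    def with_parameters(self, assignment: Mapping[str, float]) -> "FSPNModel":
        """Copy of the model with the given transitions' parameters replaced
        by crisp values (used to instantiate one fuzzy-parameter combination)."""
        unknown = set(assignment) - set(self.transition_ids)
        if unknown:
            raise KeyError(f"unknown transitions in assignment: {sorted(unknown)}")
        new_transitions = [
            replace(t, parameter=float(assignment[t.id])) if t.id in assignment else t
            for t in self.transitions
        ]
        return FSPNModel(
            name=self.name,
            places=self.places,
            transitions=new_transitions,
            arcs=self.arcs,
            initial_marking=dict(self.initial_marking),
        )

    def defuzzify_core(self) -> "FSPNModel":
        """SPN obtained by replacing every fuzzy parameter with its core."""
        cores = {tid: fn.b for tid, fn in self.fuzzy_parameters().items()}
        return self.with_parameters(cores) if cores else self


# -- module-level functional aliases (thin wrappers over the methods) ----


def enabled_transitions(model: FSPNModel, m: Mapping[str, int]) -> set[str]:
    return model.enabled_transitions(m)


def fire(model: FSPNModel, m: Mapping[str, int], tid: str) -> Marking:
    return model.fire(m, tid)


def hazard(model: FSPNModel, m: Mapping[str, int], tid: str, theta: float) -> float:
    return model.hazard(m, tid, theta)


def incidence_matrix(model: FSPNModel) -> np.ndarray:
    return model.incidence_matrix()


# -- JSON model files ----------------------------------------------------


def _parse_parameter(raw, tid: str) -> float | TriangularFuzzyNumber:
    if isinstance(raw, dict):
        if set(raw) != {"triangular"}:
            raise ModelValidationError(
                f"transition {tid}: parameter object must have the single "
                f"key 'triangular', got {sorted(raw)}"
            )
        triple = raw["triangular"]
        if not isinstance(triple, (list, tuple)) or len(triple) != 3:
            raise ModelValidationError(
                f"transition {tid}: 'triangular' must be a 3-element list"
            )
        try:
            a, b, c = (float(v) for v in triple)
        except (TypeError, ValueError) as exc:
            raise ModelValidationError(
                f"transition {tid}: non-numeric triangular parameter {triple!r}"
            ) from exc
        try:
            return TriangularFuzzyNumber(a, b, c)
        except ValueError as exc:
            raise ModelValidationError(f"transition {tid}: {exc}") from exc
    try:
        return float(raw)
    except (TypeError, ValueError) as exc:
        raise ModelValidationError(
            f"transition {tid}: parameter must be a number, a decimal string "
            f"or a triangular object, got {raw!r}"
        ) from exc


def model_from_dict(data: dict) -> FSPNModel:
    """Build and validate a model from the JSON schema dictionary."""
    for key in ("places", "transitions", "arcs", "initial_marking"):
        if key not in data:
            raise ModelValidationError(f"model file misses required key {key!r}")
    places = [
        Place(id=p["id"], description=p.get("description", ""))
        for p in data["places"]
    ]
    transitions = [
        Transition(
            id=t["id"],
            parameter=_parse_parameter(t["parameter"], t["id"]),
            rate_law=t.get("rate_law", "mass_action"),
        )
        for t in data["transitions"]
    ]
    arcs = [
        Arc(source=a["from"], target=a["to"], weight=int(a.get("weight", 1)))
        for a in data["arcs"]
    ]
    marking = {pid: int(c) for pid, c in data["initial_marking"].items()}
    return FSPNModel(
        name=data.get("name", ""),
        places=places,
        transitions=transitions,
        arcs=arcs,
        initial_marking=marking,
    )


def model_to_dict(model: FSPNModel) -> dict:
    def param_out(p):
        if isinstance(p, TriangularFuzzyNumber):
            return {"triangular": [p.a, p.b, p.c]}
        return p

    return {
        "name": model.name,
        "places": [
            {"id": p.id, **({"description": p.description} if p.description else {})}
            for p in model.places
        ],
        "transitions": [
            {"id": t.id, "rate_law": t.rate_law, "parameter": param_out(t.parameter)}
            for t in model.transitions
        ],
        "arcs": [
            {"from": a.source, "to": a.target, "weight": a.weight} for a in model.arcs
        ],
        "initial_marking": dict(model.initial_marking),
    }


def read_model(path) -> FSPNModel:
    """Read a model from a JSON file (see the schema in the README)."""
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelValidationError(f"{path}: not valid JSON: {exc}") from exc
    return model_from_dict(data)


def write_model(model: FSPNModel, path) -> None:
    """Write a model to a JSON file; read ∘ write is the identity."""
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=2)
        fh.write("\n")


def fixture(name: str) -> FSPNModel:
    """One of the bundled example models.

    ``virus_crisp`` / ``virus_fuzzy``
        Virus infection toy model (cell growth, infection, virus release
        with burst size 10, deaths, degradation) with crisp respectively
        triangular-fuzzy rate constants.  The initial marking (10 healthy
        cells, 5 virions) is a documented modelling assumption.
    ``yeast_polarization``
        The 8-reaction pheromone-induced G-protein cycle in budding yeast;
        unbounded (two source reactions), all parameters crisp.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    ref = resources.files("fspnsim") / "fixtures" / f"{name}.json"
    return model_from_dict(json.loads(ref.read_text()))
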