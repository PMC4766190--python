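import pytest
from hypothesis import settings

from fspnsim.net_model import Arc, FSPNModel, Place, Transition, fixture

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def yeast():
    return fixture("yeast_polarization")


@pytest.fixture(scope="session")
def virus_crisp():
    return fixture("virus_crisp")


@pytest.fixture(scope="session")
def virus_fuzzy():
    return fixture("virus_fuzzy")


def make_net(places, transitions, arcs, marking, name="test_net"):
    """Terse net constructor: transitions as (id, theta[, rate_law]),
    arcs as (src, tgt[, weight])."""
    return FSPNModel(
        name=name,
        places=[Place(p) for p in places],
        transitions=[Transition(*t) for t in transitions],
        arcs=[Arc(*a) for a in arcs],
        initial_marking=dict(marking),
    )


def source_net(theta=1.0, x0=0):
    """Pure birth: one source transition feeding X at constant rate."""
    return make_net(
        ["X"], [("birth", theta, "constant")], [("birth", "X")], {"X": x0},
        name="source",
    )


def birth_death_net(lam=5.0, mu=1.0, x0=0, fuzzy_lam=None):
    """M/M/infinity queue: constant arrivals, per-token death; the
    stationary mean of X is lam/mu (analytic oracle)."""
    lam_param = fuzzy_lam if fuzzy_lam is not None else lam
    return make_net(
        ["X"],
        [("birth", lam_param, "constant"), ("death", mu)],
        [("birth", "X"), ("X", "death")],
        {"X": x0},
        name="birth_death",
    )


def ring_net(theta_ab=2.0, theta_ba=3.0, tokens=5):
    """Closed two-place ring; bounded (tokens conserved), small CTMC."""
    return make_net(
        ["A", "B"],
        [("tab", theta_ab), ("tba", theta_ba)],
        [("A", "tab"), ("tab", "B"), ("B", "tba"), ("tba", "A")],
        {"A": tokens, "B": 0},
        name="ring",
    )
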