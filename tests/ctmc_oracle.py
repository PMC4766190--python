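"""Independent CTMC oracle for bounded nets.

Builds the reachability graph by breadth-first search, assembles the
generator matrix from the crisp hazards, and solves the stationary
equations pi Q = 0, sum(pi) = 1 with a dense linear solve.  Used as the
exact reference for SSA long-run means on small bounded nets; it shares
only the elementary net semantics (enabling, firing, hazards) with the
package, not the simulation path under test.
"""

from __future__ import annotations

import numpy as np

from fspnsim.net_model import FSPNModel


def stationary_means(model: FSPNModel, max_states: int = 200) -> dict[str, float]:
    """Stationary mean token count per place of an ergodic bounded net."""
    order = model.place_ids
    thetas = {t.id: float(t.parameter) for t in model.transitions}

    def key(m):
        return tuple(m[p] for p in order)

    index: dict[tuple, int] = {}
    markings: list[dict] = []
    frontier = [dict(model.initial_marking)]
    index[key(frontier[0])] = 0
    markings.append(frontier[0])
    edges: list[tuple[int, int, float]] = []
    while frontier:
        m = frontier.pop()
        i = index[key(m)]
        for tid in model.enabled_transitions(m):
            rate = model.hazard(m, tid, thetas[tid])
            if rate <= 0:
                continue
            m2 = model.fire(m, tid)
            k2 = key(m2)
            if k2 not in index:
                if len(index) >= max_states:
                    raise ValueError(f"state space exceeds {max_states} states")
                index[k2] = len(markings)
                markings.append(m2)
                frontier.append(m2)
            edges.append((i, index[k2], rate))

    n = len(markings)
    Q = np.zeros((n, n))
    for i, j, rate in edges:
        Q[i, j] += rate
        Q[i, i] -= rate
    # solve pi Q = 0 with normalization replacing one equation
    A = Q.T.copy()
    A[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    pi = np.linalg.solve(A, b)
    assert np.all(pi > -1e-9)
    counts = np.array([[m[p] for p in order] for m in markings], dtype=float)
    means = pi @ counts
    return dict(zip(order, means))
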