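"""Gillespie direct-method simulation of an SPN and output estimators.

The semantics of a stochastic Petri net is a continuous-time Markov chain
on the (possibly infinite) set of reachable markings: each enabled
transition carries an exponential firing delay with marking-dependent rate.
The direct method draws the waiting time to the next event from
``Exp(sum of hazards)`` and picks the firing transition with probability
proportional to its hazard.  Trajectories are recorded on a regular
sampling grid (default spacing 1.0 time unit).

Two estimators turn trajectories into output measures:

* transient mean — the sample mean of a measure at a fixed time point over
  N independent replications, with a normal-approximation confidence
  interval;
* steady-state mean — the time average of a single long run after
  truncating the warmup prefix that is still biased by the initial
  marking (MSER-5 by default, or a fixed fraction / fixed index).

Reproducibility: a master seed fully determines every trajectory.
Replication ``n`` of an ensemble uses the stream
``SeedSequence(master, spawn_key=(n,))``, so any single replication can be
re-run in isolation.
"""

from __future__ import annotations

import math
import random
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .net_model import FSPNModel, MAX_TOKENS

__all__ = [
    "SimulationConfig",
    "MeasureDefinition",
    "Trajectory",
    "MeasureEstimate",
    "EnsembleSummary",
    "simulate",
    "simulate_ensemble",
    "transient_mean",
    "ensemble_summary",
    "steady_state_mean",
    "warmup_index",
    "mser5_index",
    "replications_for",
    "derive_seed",
]

#: Warmup policy: "mser5", a float in (0, 1) (fixed fraction of the run) or
#: a non-negative int (fixed truncation index, in sampling-grid steps).
WarmupPolicy = Literal["mser5"] | float | int


def derive_seed(master: int | None, *key: int) -> int:
    """Deterministic per-stream integer seed derived from a master seed.

    Streams are identified by an integer spawn key, e.g. the replication
    index; distinct keys yield statistically independent streams.
    """
    ss = np.random.SeedSequence(master, spawn_key=tuple(key))
    s = ss.generate_state(2, dtype=np.uint64)
    return int(s[0] ^ (s[1] << 1)) & (2**63 - 1)


@dataclass
class SimulationConfig:
    """Simulation protocol: horizon, sampling grid, seeding, estimator mode."""

    end_time: float
    sampling_interval: float = 1.0
    seed: int | None = None
    mode: Literal["transient", "steady_state"] = "transient"
    replications: int = 1
    warmup: WarmupPolicy = "mser5"
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if self.end_time <= 0:
            raise ValueError("end_time must be positive")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        if self.mode not in ("transient", "steady_state"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class MeasureDefinition:
    """An output measure: a (weighted sum of) place count(s) and a statistic.

    ``statistic`` is ``mean_at_time`` (transient mean at ``time``) or
    ``steady_state_mean`` (warmup-truncated time average of one long run).
    """

    name: str
    weights: Mapping[str, float]
    statistic: Literal["mean_at_time", "steady_state_mean"] = "steady_state_mean"
    time: float | None = None

    @classmethod
    def place(
        cls,
        place_id: str,
        statistic: str = "steady_state_mean",
        time: float | None = None,
    ) -> "MeasureDefinition":
        return cls(place_id, {place_id: 1.0}, statistic, time)  # type: ignore[arg-type]

    @classmethod
    def parse(cls, text: str) -> "MeasureDefinition":
        """Parse compact measure syntax: ``G:steady`` or ``G+Gbg:mean@100``."""
        expr, _, stat = text.partition(":")
        weights = {p.strip(): 1.0 for p in expr.split("+")}
        stat = stat or "steady"
        if stat.startswith("mean@"):
            return cls(expr, weights, "mean_at_time", float(stat[5:]))
        if stat in ("steady", "steady_state", "steady_state_mean"):
            return cls(expr, weights, "steady_state_mean", None)
        raise ValueError(f"cannot parse measure statistic {stat!r} in {text!r}")

    def validate_against(self, model: FSPNModel) -> None:
        unknown = set(self.weights) - set(model.place_ids)
        if unknown:
            raise ValueError(f"measure {self.name!r} refers to unknown places {sorted(unknown)}")


@dataclass
class Trajectory:
    """One SSA run sampled on a regular time grid.

    ``states[i, j]`` is the count of place ``place_ids[j]`` just after the
    last event at or before ``times[i]`` (piecewise-constant sampling).
    """

    times: np.ndarray
    states: np.ndarray
    place_ids: list[str]
    seed: int | None = None
    n_events: int = 0
    event_times: np.ndarray | None = None

    def series(self, measure: MeasureDefinition | str) -> np.ndarray:
        """Grid series of a measure (or a bare place id)."""
        if isinstance(measure, str):
            measure = MeasureDefinition.place(measure)
        out = np.zeros(len(self.times))
        for pid, w in measure.weights.items():
            out += w * self.states[:, self.place_ids.index(pid)]
        return out

    def final_marking(self) -> dict[str, int]:
        return dict(zip(self.place_ids, (int(x) for x in self.states[-1])))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=self.place_ids)
        df.insert(0, "time", self.times)
        return df


def _compile(model: FSPNModel):
    """Flatten the net into index-based tables for the inner loop."""
    pidx = {p: i for i, p in enumerate(model.place_ids)}
    pre: list[list[tuple[int, int, bool]]] = []  # (place, weight, use_comb)
    delta: list[list[tuple[int, int]]] = []
    thetas: list[float] = []
    for t in model.transitions:
        if not isinstance(t.parameter, (int, float)):
            raise ValueError(
                f"transition {t.id} has a fuzzy parameter; simulate() needs a "
                "crisp SPN (defuzzify or use the fuzzy analysis pipeline)"
            )
        thetas.append(float(t.parameter))
        if t.rate_law == "constant":
            pre.append([])
        else:
            use_comb = t.rate_law == "mass_action"
            pre.append([(pidx[p], w, use_comb) for p, w in model.pre_arcs(t.id)])
        change: dict[int, int] = {}
        for p, w in model.pre_arcs(t.id):
            change[pidx[p]] = change.get(pidx[p], 0) - w
        for p, w in model.post_arcs(t.id):
            change[pidx[p]] = change.get(pidx[p], 0) + w
        delta.append([(i, d) for i, d in change.items() if d != 0])
    return pre, delta, thetas


def simulate(
    model: FSPNModel,
    config: SimulationConfig,
    record_events: bool = False,
) -> Trajectory:
    """Run one Gillespie direct-method trajectory of a crisp-parameter model.

    The trajectory is a deterministic function of (model, config.seed):
    identical inputs give identical output.  A dead marking (total hazard
    zero) freezes the state for the rest of the grid.
    """
    pre, delta, thetas = _compile(model)
    n_t = len(thetas)
    dt = config.sampling_interval
    n_grid = int(math.floor(config.end_time / dt + 1e-9)) + 1
    times = np.arange(n_grid) * dt
    states = np.empty((n_grid, len(model.places)), dtype=np.int64)
    state = [int(model.initial_marking[p]) for p in model.place_ids]

    seed = derive_seed(config.seed) if config.seed is not None else None
    rng = random.Random(seed)
    comb = math.comb
    expovariate, uniform = rng.expovariate, rng.random

    ev_times: list[float] = []
    n_events = 0
    t = 0.0
    gi = 0
    hz = [0.0] * n_t
    while True:
        total = 0.0
        for j in range(n_t):
            h = thetas[j]
            for pi, w, use_comb in pre[j]:
                x = state[pi]
                if w == 1:
                    h *= x
                elif use_comb:
                    h *= comb(x, w) if x >= w else 0
                else:
                    h *= x**w
            hz[j] = h
            total += h
        if total <= 0.0:
            if n_events == 0:
                warnings.warn(
                    "no transition is enabled at the initial marking; "
                    "the trajectory is constant",
                    stacklevel=2,
                )
            states[gi:] = state
            break
        t += expovariate(total)
        while gi < n_grid and times[gi] < t:
            states[gi] = state
            gi += 1
        if gi == n_grid:
            break
        r = uniform() * total
        acc = 0.0
        j = n_t - 1  # fallback against float round-off
        for k in range(n_t):
            acc += hz[k]
            if r < acc:
                j = k
                break
        for pi, d in delta[j]:
            state[pi] += d
            if state[pi] > MAX_TOKENS:
                raise OverflowError(
                    f"token count on {model.place_ids[pi]} exceeds the guard"
                )
        n_events += 1
        if record_events:
            ev_times.append(t)
    return Trajectory(
        times=times,
        states=states,
        place_ids=model.place_ids,
        seed=config.seed,
        n_events=n_events,
        event_times=np.asarray(ev_times) if record_events else None,
    )


def simulate_ensemble(model: FSPNModel, config: SimulationConfig) -> list[Trajectory]:
    """N independent replications; replication n runs on sub-seed stream n."""
    out = []
    for n in range(config.replications):
        sub = SimulationConfig(
            end_time=config.end_time,
            sampling_interval=config.sampling_interval,
            seed=derive_seed(config.seed, n) if config.seed is not None else None,
            mode=config.mode,
            replications=1,
            warmup=config.warmup,
            confidence=config.confidence,
        )
        out.append(simulate(model, sub))
    return out


@dataclass(frozen=True)
class MeasureEstimate:
    """Point estimate of one measure with spread across replications."""

    mean: float
    variance: float
    ci_low: float
    ci_high: float
    n: int

    @property
    def half_width(self) -> float:
        return 0.5 * (self.ci_high - self.ci_low)


@dataclass
class EnsembleSummary:
    """Per-grid-time ensemble mean, variance and confidence band of a measure."""

    measure: MeasureDefinition
    times: np.ndarray
    mean: np.ndarray
    variance: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n: int
    confidence: float

    def at(self, t: float) -> MeasureEstimate:
        idx = int(round(t / (self.times[1] - self.times[0]))) if len(self.times) > 1 else 0
        if t > self.times[-1] + 1e-9 or idx >= len(self.times):
            raise ValueError(f"time {t} is beyond the simulated horizon {self.times[-1]}")
        return MeasureEstimate(
            mean=float(self.mean[idx]),
            variance=float(self.variance[idx]),
            ci_low=float(self.ci_low[idx]),
            ci_high=float(self.ci_high[idx]),
            n=self.n,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "mean": self.mean,
                "variance": self.variance,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def ensemble_summary(
    trajectories: Sequence[Trajectory],
    measure: MeasureDefinition,
    confidence: float = 0.95,
) -> EnsembleSummary:
    """Sample mean over replications at every grid time, with a
    normal-approximation confidence band (undefined width for N = 1)."""
    if not trajectories:
        raise ValueError("need at least one trajectory")
    t0 = trajectories[0].times
    for traj in trajectories[1:]:
        if len(traj.times) != len(t0) or not np.allclose(traj.times, t0):
            raise ValueError("all trajectories must share the sampling grid")
    ys = np.stack([traj.series(measure) for traj in trajectories])
    n = ys.shape[0]
    mean = ys.mean(axis=0)
    if n >= 2:
        var = ys.var(axis=0, ddof=1)
        z = stats.norm.ppf(0.5 + confidence / 2)
        hw = z * np.sqrt(var / n)
    else:
        var = np.full_like(mean, np.nan)
        hw = np.full_like(mean, np.nan)
    return EnsembleSummary(
        measure=measure,
        times=t0,
        mean=mean,
        variance=var,
        ci_low=mean - hw,
        ci_high=mean + hw,
        n=n,
        confidence=confidence,
    )


def transient_mean(
    trajectories: Sequence[Trajectory],
    measure: MeasureDefinition,
    t: float | None = None,
    confidence: float = 0.95,
) -> MeasureEstimate:
    """Transient sample mean of a measure at grid time ``t`` (default: the
    measure's own time) across independent replications."""
    if t is None:
        t = measure.time
    if t is None:
        raise ValueError("no time point given for the transient mean")
    return ensemble_summary(trajectories, measure, confidence).at(t)


def mser5_index(y: np.ndarray, batch: int = 5) -> int:
    """MSER truncation point on batch means (batch size 5 by default).

    Groups the series into batches, then picks the truncation ``d`` (over
    the first half of the batches) minimizing the MSER statistic — the
    squared standard error of the mean of the remaining batches,
    ``sum((x_j - xbar_d)^2) / (B - d)^2``.  Returns the truncation index in
    original-observation units.
    """
    y = np.asarray(y, dtype=float)
    n_batches = len(y) // batch
    if n_batches < 2:
        return 0
    bm = y[: n_batches * batch].reshape(n_batches, batch).mean(axis=1)
    d_max = n_batches // 2
    # suffix sums from each candidate truncation point
    csum = np.concatenate([[0.0], np.cumsum(bm)])
    csq = np.concatenate([[0.0], np.cumsum(bm**2)])
    d = np.arange(d_max + 1)
    m = n_batches - d
    s = csum[-1] - csum[d]
    sq = csq[-1] - csq[d]
    mser = (sq - s**2 / m) / m**2
    return int(d[np.argmin(mser)]) * batch


def warmup_index(y: np.ndarray, warmup: WarmupPolicy) -> int:
    """Resolve a warmup policy into a truncation index for a series."""
    n = len(y)
    if warmup == "mser5":
        return mser5_index(y)
    if isinstance(warmup, bool):
        raise ValueError("warmup must be 'mser5', a fraction or an index")
    if isinstance(warmup, float):
        if not 0.0 <= warmup < 1.0:
            raise ValueError(f"warmup fraction must be in [0, 1), got {warmup}")
        return int(math.floor(warmup * n))
    if isinstance(warmup, int):
        if warmup < 0:
            raise ValueError("warmup index must be non-negative")
        return warmup
    raise ValueError(f"unknown warmup policy {warmup!r}")


def steady_state_mean(
    traj: Trajectory,
    measure: MeasureDefinition | str,
    warmup: WarmupPolicy = "mser5",
) -> float:
    """Warmup-truncated time average of a measure along one long run.

    With observations ``y_1..y_L`` on the sampling grid and truncation
    index ``l``, returns ``sum(y_{l+1}..y_L) / (L - l)``.
    """
    y = traj.series(measure) if not isinstance(traj, np.ndarray) else traj
    l = warmup_index(y, warmup)
    if l >= len(y):
        raise ValueError(
            f"warmup index {l} leaves no observations (series length {len(y)})"
        )
    return float(np.mean(y[l:]))


def replications_for(confidence: float, accuracy: float) -> int:
    """Replication count for a target confidence level and absolute accuracy.

    Hoeffding-style bound ``ceil(ln(2 / (1 - confidence)) / (2 accuracy^2))``
    for a [0, 1]-scaled measure: distribution-free, hence conservative.
    Monotone — tighter accuracy or higher confidence never lowers the count.
    """
    if not 0.0 < confidence < 1.0:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    if accuracy <= 0:
        raise ValueError(f"accuracy must be positive, got {accuracy}")
    return math.ceil(math.log(2.0 / (1.0 - confidence)) / (2.0 * accuracy**2))
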