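"""Propagation of fuzzy parameter uncertainty through an SPN.

The pipeline realizes Zadeh's extension principle level by level:

1. decompose every fuzzy rate constant into its alpha-cuts at a common
   grid of levels (default 0.0, 0.1, ..., 1.0);
2. discretize each cut into K crisp values (default 11, equally spaced)
   and form the Cartesian product over the fuzzy parameters;
3. for every parameter combination, instantiate the crisp SPN and estimate
   each output measure by stochastic simulation (transient ensemble mean
   or warmup-truncated steady-state time average);
4. the alpha-cut of an output at level alpha is the [min, max] envelope of
   the estimates over the combinations at that level — the alpha-cut image
   of a scalar function under the extension principle;
5. compose the cuts back into a piecewise-linear membership function.

Monte-Carlo noise can make estimated cuts slightly non-nested; the default
policy repairs them by monotone envelope (strict mode raises instead).

Every (parameter combination) is simulated under a sub-seed derived
deterministically from the master seed and the combination's crisp values,
so a combination shared between alpha levels (e.g. the core) is simulated
once and reproduces identically whether or not the cache is enabled.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .fuzzy import (
    AlphaCut,
    AlphaCutSet,
    NestednessError,
    PiecewiseLinearMembership,
    compose_cuts,
    discretize_cut,
)
from .net_model import FSPNModel
from .ssa import (
    MeasureDefinition,
    SimulationConfig,
    simulate,
    simulate_ensemble,
    steady_state_mean,
    transient_mean,
)

__all__ = [
    "FuzzyAnalysisConfig",
    "ParameterCombination",
    "FuzzyMeasureResult",
    "FuzzyResult",
    "combination_seed",
    "parameter_grid",
    "run_alpha_level",
    "analyze",
]

DEFAULT_ALPHA_LEVELS = tuple(round(0.1 * j, 1) for j in range(11))


@dataclass
class FuzzyAnalysisConfig:
    """Configuration of the alpha-cut propagation pipeline."""

    simulation: SimulationConfig
    measures: Sequence[MeasureDefinition]
    alpha_levels: Sequence[float] = DEFAULT_ALPHA_LEVELS
    points_per_cut: int = 11
    method: Literal["grid", "lhs"] = "grid"
    seed: int | None = None
    nestedness: Literal["repair", "strict"] = "repair"
    cache: bool = True
    combination_budget: int = 100_000

    def __post_init__(self) -> None:
        levels = sorted(float(a) for a in self.alpha_levels)
        if not levels:
            raise ValueError("need at least one alpha level")
        if any(a < 0 or a > 1 for a in levels):
            raise ValueError("alpha levels must lie in [0, 1]")
        if abs(levels[-1] - 1.0) > 1e-12:
            raise ValueError("alpha levels must include 1.0 (normalization)")
        self.alpha_levels = levels
        if self.points_per_cut < 1:
            raise ValueError("points_per_cut must be >= 1")
        if self.seed is None:
            self.seed = self.simulation.seed


@dataclass(frozen=True)
class ParameterCombination:
    """One crisp assignment to the fuzzy parameters, with provenance."""

    values: tuple[tuple[str, float], ...]  # (transition id, crisp theta)
    alpha: float
    indices: tuple[int, ...]  # per-parameter sample index within its cut

    def as_dict(self) -> dict[str, float]:
        return dict(self.values)


def combination_seed(master: int | None, values: Mapping[str, float]) -> int:
    """Deterministic sub-seed for one parameter combination.

    Hashes the crisp values (keyed by transition id, rounded to 12
    significant decimals) together with the master seed, so the same
    combination gets the same stream at every alpha level.
    """
    payload = json.dumps(
        {k: float(f"{v:.12g}") for k, v in sorted(values.items())},
        sort_keys=True,
    ).encode()
    digest = hashlib.sha256(payload).digest()
    entropy = int.from_bytes(digest[:8], "big")
    ss = np.random.SeedSequence([entropy] if master is None else [master, entropy])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def parameter_grid(
    model: FSPNModel,
    alpha: float,
    k: int,
    method: Literal["grid", "lhs"] = "grid",
    seed: int | None = None,
) -> list[ParameterCombination]:
    """Cartesian product of the discretized alpha-cuts of all fuzzy
    parameters.  A model with no fuzzy parameter yields one (empty)
    combination; degenerate cuts collapse to a single point."""
    fuzzy = model.fuzzy_parameters()
    axes: list[list[float]] = []
    for i, (tid, fn) in enumerate(fuzzy.items()):
        cut = fn.alpha_cut(alpha)
        axis_seed = None
        if method == "lhs":
            axis_seed = int(
                np.random.SeedSequence(
                    [0 if seed is None else seed, i, int(round(alpha * 10**6))]
                ).generate_state(1, dtype=np.uint32)[0]
            )
        axes.append(discretize_cut(cut, k, method=method, seed=axis_seed))
    tids = list(fuzzy)
    combos = []
    for indices in itertools.product(*(range(len(ax)) for ax in axes)):
        values = tuple((tid, axes[i][idx]) for i, (tid, idx) in enumerate(zip(tids, indices)))
        combos.append(ParameterCombination(values=values, alpha=alpha, indices=indices))
    return combos


def _estimate_measures(
    model: FSPNModel,
    combo: ParameterCombination,
    config: FuzzyAnalysisConfig,
) -> dict[str, float]:
    """Simulate one crisp instance and evaluate every measure on it."""
    crisp = model.with_parameters(combo.as_dict()) if combo.values else model
    sub_seed = combination_seed(config.seed, combo.as_dict())
    sim = replace(config.simulation, seed=sub_seed)
    out: dict[str, float] = {}
    if sim.mode == "steady_state":
        traj = simulate(crisp, sim)
        for m in config.measures:
            out[m.name] = steady_state_mean(traj, m, warmup=sim.warmup)
    else:
        trajs = simulate_ensemble(crisp, sim)
        for m in config.measures:
            t = m.time if m.time is not None else sim.end_time
            out[m.name] = transient_mean(trajs, m, t, sim.confidence).mean
    return out


def run_alpha_level(
    model: FSPNModel,
    alpha: float,
    config: FuzzyAnalysisConfig,
    cache: dict | None = None,
    audit_rows: list | None = None,
) -> dict[str, AlphaCut]:
    """Estimate each measure's alpha-cut at one level.

    The cut is the [min, max] of the per-combination estimates over the
    discretized parameter grid at this level.
    """
    combos = parameter_grid(
        model, alpha, config.points_per_cut, config.method, config.seed
    )
    if len(combos) > config.combination_budget:
        warnings.warn(
            f"{len(combos)} parameter combinations at alpha={alpha} exceed "
            f"the budget ({config.combination_budget}); consider fewer "
            "points per cut",
            stacklevel=2,
        )
    per_measure: dict[str, list[float]] = {m.name: [] for m in config.measures}
    for combo in combos:
        key = tuple(sorted((tid, float(f"{v:.12g}")) for tid, v in combo.values))
        if cache is not None and key in cache:
            estimates = cache[key]
        else:
            estimates = _estimate_measures(model, combo, config)
            if cache is not None:
                cache[key] = estimates
        for name, value in estimates.items():
            per_measure[name].append(value)
        if audit_rows is not None:
            for name, value in estimates.items():
                audit_rows.append(
                    {
                        "measure": name,
                        "alpha": alpha,
                        "combination": json.dumps(combo.as_dict(), sort_keys=True),
                        "estimate": value,
                        "seed": combination_seed(config.seed, combo.as_dict()),
                    }
                )
    return {
        name: AlphaCut(alpha=alpha, lower=min(vals), upper=max(vals))
        for name, vals in per_measure.items()
    }


@dataclass
class FuzzyMeasureResult:
    """Fuzzy output for one measure: cuts and composed membership."""

    name: str
    raw_cuts: AlphaCutSet
    cuts: AlphaCutSet  # after nestedness policy
    membership: PiecewiseLinearMembership


@dataclass
class FuzzyResult:
    """Headline output of the pipeline: one fuzzy number per measure plus
    the full (alpha, combination, estimate) audit table."""

    measures: dict[str, FuzzyMeasureResult]
    audit: pd.DataFrame
    master_seed: int | None

    def __getitem__(self, name: str) -> FuzzyMeasureResult:
        return self.measures[name]


def analyze(model: FSPNModel, config: FuzzyAnalysisConfig) -> FuzzyResult:
    """Full uncertainty propagation: all alpha levels, all measures.

    With no fuzzy parameters this reduces to a single crisp estimate per
    measure (a degenerate membership function), after a warning.
    """
    if not config.measures:
        raise ValueError("at least one output measure is required")
    for m in config.measures:
        m.validate_against(model)
    if model.is_crisp:
        warnings.warn(
            "model has no fuzzy parameters; the result is a crisp point",
            stacklevel=2,
        )
    cache: dict | None = {} if config.cache else None
    audit_rows: list[dict] = []
    cuts_by_measure: dict[str, list[AlphaCut]] = {m.name: [] for m in config.measures}
    for alpha in config.alpha_levels:
        level_cuts = run_alpha_level(model, alpha, config, cache, audit_rows)
        for name, cut in level_cuts.items():
            cuts_by_measure[name].append(cut)
    measures: dict[str, FuzzyMeasureResult] = {}
    for name, cuts in cuts_by_measure.items():
        raw = AlphaCutSet(cuts)
        if raw.is_nested():
            fixed = raw
        elif config.nestedness == "strict":
            raise NestednessError(
                f"estimated alpha-cuts of measure {name!r} are not nested"
            )
        else:
            warnings.warn(
                f"alpha-cuts of measure {name!r} are not nested "
                "(Monte-Carlo noise); applying monotone-envelope repair",
                stacklevel=2,
            )
            fixed = raw.repaired()
        measures[name] = FuzzyMeasureResult(
            name=name,
            raw_cuts=raw,
            cuts=fixed,
            membership=compose_cuts(fixed, policy="repair"),
        )
    return FuzzyResult(
        measures=measures,
        audit=pd.DataFrame(audit_rows),
        master_seed=config.seed,
    )
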