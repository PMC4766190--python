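# fspnsim — fuzzy stochastic Petri nets

Stochastic Petri nets (SPNs) model biochemical reaction networks whose
dynamics are intrinsically random: places hold molecule counts, transitions
are reactions firing after exponential delays with mass-action hazards
`h(t, θ) = θ · #{reactant combinations}`, and the semantics is a
continuous-time Markov chain.  In practice many kinetic parameters θ are
not known as crisp numbers — data are incomplete, vague, or vary between
conditions.  A **fuzzy stochastic Petri net (FSPN)** keeps the stochastic
dynamics but lets any rate constant be a triangular fuzzy number
`(a, b, c)`: a pessimistic value, a most-possible value and an optimistic
value elicited from expert knowledge.

`fspnsim` is for modellers who want to know how that parameter uncertainty
shows up in the outputs.  It computes, for any output measure `Y` (the
transient or steady-state mean of a species), the *membership function*
`μ_Y` quantifying the possibility of each output value, by level-wise
application of Zadeh's extension principle:

1. decompose each fuzzy parameter `θ̃` into its α-cuts
   `θ̃_α = [a + α(b−a), c − α(c−b)]` at levels α = 0, 0.1, …, 1;
2. discretize each cut into K crisp values and form all parameter
   combinations;
3. for each combination, estimate `Y` by Gillespie simulation — transient
   sample mean `Ȳ = (1/N) Σ_n Y_n` over N replications, or the steady-state
   time average `Ȳ_l = (1/(L−l)) Σ_{i>l} Y_i` of one long run after warmup
   truncation at index `l` (MSER-5 by default);
4. the α-cut of `Y` is the [min, max] envelope of the estimates at that
   level; composing the cuts yields `μ_Y`.

Because the analysis is purely simulation-based it works equally for
bounded and **unbounded** nets, where the CTMC is infinite and numerical
solvers are out of reach.  A structural-analysis module (exact integer
P/T-invariants, invariant coverage, siphons/traps, the siphon-trap
property) diagnoses conservation laws and unbounded places beforehand.

## Worked example: the yeast pheromone-induced G-protein cycle

The bundled `yeast_polarization` model has 7 places
(L, R, RL, G, Gbg, Ga, Gd), 8 reactions, initial marking
(4, 500, 110, 300, 20, 2, 90) and rate constants
k = (0.38, 0.04, 0.082, 0.12, 0.021, 0.1, 0.005, 13.21).

```sh
fspnsim fixtures yeast_polarization yeast.json
fspnsim structure yeast.json
```

```
net: yeast_polarization (7 places, 8 transitions)
P-invariants (3):
  G + Ga + Gd
  G + Gbg
  L
...
structurally unbounded place candidates: ['R', 'RL']
transitions covered by T-invariants
siphon-trap property: True
extended simple: True
implied liveness: yes (STP holds on an extended-simple net)
```

Three conserved sums (the ligand count L, the two G-protein subunit pools),
with R and RL structurally unbounded — so this net has an infinite state
space and can only be analyzed by simulation.  Now declare the
dephosphorylation constant k6 fuzzy and propagate:

```sh
fspnsim analyze yeast.json --fuzzy "r6=0.05,0.1,0.15" \
    --alpha-levels 3 --points 3 --mode steady \
    --end-time 5000 --warmup 500 --seed 1 \
    --measure G:steady --out out_g
```

```
G: core ~ 227.417 at alpha=1; [110.26, 258.682] at alpha=0
```

Reading `out_g/G_cuts.csv`: at full possibility (α = 1, k6 at its core
0.1) the steady-state mean of G is about 227 molecules; across the whole
support of k6 (α = 0) it can be as low as ~110 and as high as ~259.  The
composed membership function is in `G_membership.csv`, and `audit.csv`
records every (α, parameter combination, estimate, sub-seed) so any number
is reproducible from the manifest.

The same pipeline is available as a library:

```python
from fspnsim import (fixture, TriangularFuzzyNumber, FuzzyAnalysisConfig,
                     SimulationConfig, MeasureDefinition, analyze)

model = fixture("yeast_polarization")
# ... set r6 fuzzy, configure, analyze(model, config) ...
```

## Model files

Models are JSON:

```json
{
  "name": "...",
  "places": [{"id": "X"}],
  "transitions": [
    {"id": "t1", "rate_law": "mass_action", "parameter": 0.1},
    {"id": "t2", "rate_law": "constant", "parameter": {"triangular": [0.05, 0.1, 0.15]}}
  ],
  "arcs": [{"from": "X", "to": "t1", "weight": 1}],
  "initial_marking": {"X": 10}
}
```

Weights default to 1; parameters accept numbers, decimal strings, or
`{"triangular": [a, b, c]}` with `0 < a ≤ b ≤ c`.

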