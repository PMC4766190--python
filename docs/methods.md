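# Methods

## Model class

A fuzzy stochastic Petri net is a six-tuple `<P, T, F, f, v, M0>`: places
`P`, transitions `T`, weighted arcs `(F, f)`, an initial marking `M0`, and
a hazard assignment `v` giving each transition a rate function with a
kinetic parameter θ that is either a crisp positive real or a triangular
fuzzy number with strictly positive support.  Replacing every fuzzy
parameter by a crisp value (sampling a point of an α-cut, or taking the
core) yields a plain SPN whose semantics is a continuous-time Markov chain
on the reachable markings.

Three rate laws are supported, selected per transition:

* `mass_action` (default): `θ · Π_p C(m[p], w(p,t))` over the preplaces —
  the Gillespie reactant-combination count.  It is exactly zero iff the
  transition is disabled.  For all in-scope models every input arc has
  weight 1, where this coincides with the plain product `θ·A·B` written in
  rate-function tables.
* `constant`: `θ`, marking-independent (zeroth-order input reactions).
* `explicit_product`: `θ · Π_p m[p]^w`, for compatibility with tools that
  use concentrations-style products at weights ≥ 2.

Catalysts (species appearing on both sides of a reaction, like the ligand
L in the receptor-binding reaction) are modelled as a symmetric input +
output arc pair; the hazard counts the catalyst's tokens and firing leaves
it unchanged, which also makes the catalyst a one-place P-invariant.

Token counts are unbounded non-negative integers with a guard at 10^9;
in-scope models stay far below.

## Simulation

The direct Gillespie method: at each step the waiting time is drawn from
`Exp(Σ_j h_j)` and the firing transition with probability `h_j / Σ h`.
Trajectories are recorded on a regular grid (default spacing 1.0 time
unit, matching the case study's sampling of one observation per time
unit); the value at a grid point is the marking just after the last event
at or before it.  Dead markings (total hazard 0) freeze the remaining
grid.  A warning (not an error) is issued when nothing is enabled at the
start.

Randomness is fully seed-determined.  The master seed is expanded through
`numpy.random.SeedSequence` spawn keys: replication *n* of an ensemble
uses `SeedSequence(master, spawn_key=(n,))`, so any replication can be
reproduced in isolation.  The inner loop consumes a `random.Random` stream
seeded from that sequence.

## Estimators

*Transient mean.*  `Ȳ = (1/N) Σ_n Y_n` across N independent replications
at a grid time, with a normal-approximation confidence interval (undefined
at N = 1, flagged as NaN).  The companion `replications_for(confidence,
accuracy)` uses the distribution-free Hoeffding bound
`⌈ln(2/(1−confidence)) / (2·accuracy²)⌉` for a [0, 1]-scaled measure —
185 replications at 95%/0.1, 18,445 at 95%/0.01.  It is a conservative
planning device, not a stopping rule.

*Steady-state mean.*  The time average `(1/(L−l)) Σ_{i>l} Y_i` of a single
long run, truncating the warmup prefix still biased by the initial
marking.  The truncation index `l` comes from one of three policies:
MSER-5 (default — batch means of size 5, truncation minimizing the
squared standard error of the remaining batches, searched over the first
half), a fixed fraction of the run, or a fixed index.  All three are
config-selectable so results can bracket the choice; for the case-study
runs the choice moves the estimate by well under the Monte-Carlo noise
because the initial marking is close to the stationary regime.

## Uncertainty propagation

Per α level: each fuzzy parameter's cut `[a+α(b−a), c−α(c−b)]` is
discretized into K points (default 11; equally spaced including both
endpoints, or Latin-hypercube stratified draws), the Cartesian product
over fuzzy parameters forms the combinations, each combination is
simulated as a crisp SPN, and the output α-cut is the [min, max] envelope
of the estimates — the α-cut image of a scalar output under the extension
principle, which matches an "at least / at most" reading of the support
cut.  The α = 0 cut is taken as the closed support `[a, c]` (the closed-form
cut formula's value), not the whole real line.

Each combination gets a sub-seed derived by hashing its crisp values
(rounded to 12 significant digits) with the master seed.  Consequences:
a combination shared between levels (e.g. the core at every odd grid) is
simulated once and cached, and enabling or disabling the cache cannot
change any number.  Common random numbers across combinations are *not*
used; estimates at different grid points are independent.

Monte-Carlo noise can make estimated cuts non-nested by a small margin.
The default policy repairs them to the monotone envelope (running max of
lower endpoints, running min of uppers, collapsing to the nearest feasible
point if a cut is disjoint from the running band) with a warning; strict
mode raises instead.  Composition connects the lower endpoints (ascending
α) and upper endpoints (descending α) into a piecewise-linear membership
function that reproduces the input cuts exactly at their levels and is 0
outside the widest cut.

Only triangular fuzzy numbers are implemented; the α-cut interface is the
extension point for other shapes.  Fuzzy arithmetic, defuzzification
operators beyond taking the core, and sensitivity indices are out of
scope.

## Structural analysis

Minimal semi-positive P- and T-invariants are computed by Farkas
(Fourier–Motzkin) elimination over exact Python integers, with gcd
normalization and support-inclusion minimality filtering; the kernel
conditions `xᵀC = 0` / `Cy = 0` therefore hold exactly.  Places not
covered by any P-invariant are reported as structurally-unbounded
candidates.  Siphons and traps are enumerated exhaustively over place
subsets (guarded at 20 places; the bundled nets have ≤ 7), and the
siphon-trap property checks that the maximal trap inside every minimal
siphon is initially marked.  Liveness itself is not decided: the report
states STP and the extended-simple class check, and flags the implied
liveness only when both hold.  Fully isolated place sets are excluded
from the siphon/trap listings as degenerate.

## Case-study protocol and problem sizes

The yeast polarization runs use horizon 38,000 time units with sampling
interval 1 (≈2×10⁶ reaction events per run, ~10 s each) in
`scripts/acceptance.py`, and a scaled-down protocol (horizon 5,000,
fixed warmup 500) in the test suite; at these lengths the Monte-Carlo
standard error of the steady-state mean of G is a few molecules, small
against the reference tolerances.  Because the steady-state mean of G is
monotone in k6 over its support, the α = 0 cut endpoints are attained at
the cut endpoints k6 = 0.05 and 0.15, so endpoint runs suffice for the
support cut.

The virus-infection fixtures carry the published rate functions; their
initial marking (10 uninfected cells, 0 infected, 5 virions) is a
documented modelling assumption, editable in the JSON file.

The printed initial marking of the yeast model, "(4,500, 110, 300, 20, 2,
90)", is read as seven values (4, 500, 110, 300, 20, 2, 90) aligned with
(L, R, RL, G, Gbg, Ga, Gd) — six values cannot cover seven places, and the
resulting conserved sums (L = 4, G+Gbg = 320, G+Ga+Gd = 392) are
consistent with the reported steady-state range of G.

## What the tests do and do not show

The distributional tests (Poisson event counts, exponential waiting
times), the CTMC-oracle equivalence on small bounded nets, and the
closed-form M/M/∞ surrogate with fuzzy arrival rate validate the
simulator and the propagation pipeline against independent references.
They exercise small, well-mixed mass-action networks; they do not probe
stiff dynamics, extreme token counts, or non-exponential delays
(non-Markovian firing is out of scope).  Steady-state estimates assume
the measure's time average converges; for unbounded places with net
drift (R, RL transients notwithstanding) a steady-state measure is only
meaningful if the structure admits stationarity, which the T-invariant
coverage check supports but does not prove.
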