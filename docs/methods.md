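# Methods

## Problem

A chronogram is a rooted binary phylogeny whose node dates are measured
backward from the tips (leaves at 0 by default, dates in units such as
mya). Bayesian molecular dating produces posterior samples of chronograms
calibrated with absolute (fossil) constraints only. Horizontal gene
transfers add *relative* information: a transfer from donor edge `(a, b)`
to recipient edge `(c, d)` can only happen between coexisting lineages,
so `a` must be older than `d`. Posterior chronograms frequently violate
such relative constraints. This package takes chronogram samples plus a
set of relative constraints `R` and adjusts node dates as little as
possible so every constraint holds, then aggregates corrected samples
into one representative chronogram.

## Constraint system

With input dates `t_i`, corrected dates `t'_i`, parent map `p(i)`, and
`n` leaves (internal nodes `1..n-1`, root 1, leaves `n..2n-1`):

- topology: `t'_p(i) − t'_i ≥ ε_topo` for every non-root `i`;
- relative: `t'_i ≥ t'_j` for each constraint "`i` at least as old as `j`";
- leaves fixed: `t'_i = t_i` for every leaf;
- optional per-node absolute bounds (off by default — they can make the
  relative constraints unsatisfiable, and the input samples were already
  calibrated with absolute information).

Strict parent-over-child ordering is imposed through the positive margin
`ε_topo` (default `1e-6 ×` root age), which also keeps corrected branch
lengths inside the log's domain for the SLRB objective. Constraint
satisfiability is decided before solving: the directed graph with an edge
per tree branch (parent→child) and per constraint (older→younger) admits
a valid dating iff it is acyclic; one witnessing cycle is reported
otherwise. Cycles composed purely of constraint edges would only force
date equalities, but are rejected as well (flagged separately in the
report). Constraints whose endpoints are ancestrally related are excluded
up front with a warning — ancestor-older-than-descendant is implied by
the topology and the reverse is impossible.

## Objectives

Three deviation measures define "as little as possible", with
`b_i = t_p(i) − t_i` and `b'_i` the corrected analogue:

- **SBD** — squared branch-length deviation,
  `Σ_i (1/b_i)(b_i − b'_i)²` over the `2n−2` edges. Convex quadratic.
  The inverse-length weight penalizes deviation on short branches more.
- **SLRB** — squared log ratio of branch lengths,
  `Σ_i √b_i · ln²(b'_i/b_i)`. Non-convex; symmetric under multiplying or
  dividing a branch by the same factor. Natural log; any other base
  rescales the objective uniformly and cannot move the argmin.
- **SDD** — squared date deviation, `Σ_i (1/t_i)(t_i − t'_i)²` over the
  `n−1` internal nodes. Convex quadratic; older nodes move more cheaply.

All three are nonnegative and vanish exactly at the input, so an input
with zero violations is returned unchanged. Degenerate inputs
(zero-length branches, internal nodes dated 0, as occur in real posterior
samples) are handled by flooring the branch lengths and dates entering
*weights and ratios* at `ε_len` (default `1e-8 ×` root age); deviation
terms use the raw values.

## Solving

Decision variables are the `n−1` internal dates; leaf dates are folded in
as constants (equivalent to, and smaller than, optimizing all `2n−1`
dates with equality constraints). The program is rescaled internally to
unit root age — this conditions the weights uniformly, makes all solver
tolerances scale-free, and makes scale equivariance (scaling input dates
by `c` scales the optimum by `c`) hold to machine precision because the
scaled program is literally identical. SBD and SDD are solved as convex
QPs with exact gradient and Hessian via SciPy's `trust-constr`
interior-point method, so the reported optimum is the global optimum.
SLRB is solved by the same method with analytic gradient/Hessian,
warm-started from the SBD optimum (a feasible convex surrogate), plus a
configurable number of seeded multistarts (default 1 extra) built by
lognormally jittering the warm start's parent–child date increments
bottom-up (which preserves branch-length positivity); the best feasible
local solve is returned. Because interior-point iterates can transiently
leave the `b' > 0` region, the SLRB log is replaced below `ε_topo/2` by
its second-order Taylor expansion there — finite value, restoring
gradient — which does not affect the reported solution (always feasible,
hence in the exact-log region). Default solver tolerances `gtol 1e-8`,
`xtol 1e-10` (on the unit-root-age scale) keep objective error around
`1e-5` relative, two orders below the grid-oracle test tolerance;
feasibility is accepted at residual `1e-8` on the unit scale. Reported
objective values are recomputed from the final dates in the input units.

A brute-force reference (`gridsearch.grid_minimize`) enumerates internal
dates exhaustively on a `0.01 ×` root-age grid (upper bound `4/3 ×` root
age) and is used to cross-check solver optima on 4–5-leaf instances. It
shares no code path with the solver beyond the tree structure.

## Aggregation

Topology-identical samples are matched node-by-node via clade leaf-name
sets (robust to child ordering in Newick sources); discordant topologies
are an error, not silently intersected. The aggregate assigns each node a
monotone summary (average by default; median/min/max available) of its
matched dates. Monotonicity gives two guarantees used as test invariants:
the aggregate of valid chronograms is a valid chronogram, and if every
member satisfies `R` the aggregate satisfies `R`. Per-node date
distributions report the mean and the *sample* standard deviation
(`ddof=1`, configurable); `m = 1` reports sd 0 with a degenerate flag.
The rejection-sampling baseline keeps members satisfying at least a
cutoff number of constraints (e.g. ≥21 of 24), preserving order, and
warns when nothing survives.

## Metrics

Between topology-matched trees: mean absolute internal-node date
difference (over `n−1` nodes), mean absolute branch-length difference
(over `2n−2` edges), and per-edge percent branch-length change
`|b' − b| / b × 100` with the *input* tree in the denominator (hence
asymmetric; argument order is fixed). Percent changes are binned
left-closed/right-open into `[0,1), [1,5), [5,10), [10,20), [20,40),
[40,∞)` by default. The "average date gap" statistic is computed over the
constraints violated in the input aggregate and re-evaluated on the
corrected aggregate over that same subset, measuring how far formerly
violated node pairs moved into the satisfied region. The model-selection
report compares candidate dating models by how much correction their
chronograms need (violations, deviations, percent change); the ranking is
descriptive, with no significance testing.

## Synthetic data

The generator emulates the pipeline that misdates real trees:

1. **Species tree** — birth–death process (birth 1.0, death 0.2 per unit
   time) conditioned on the leaf count by rejection; the process stops at
   the n-th birth, every extant tip is extended by the exponential
   waiting time to the next event (so no zero-length cherry), and the
   tree is rescaled to height 1. Study sizes: 100 leaves.
2. **Rate relaxation** — autocorrelated lognormal: branch rate
   `log r_child ~ Normal(log r_parent − v/2, v)` with
   `v = σ² × branch duration`, root at start rate 1, so the expected
   child rate equals the parent rate (anchored by a Monte-Carlo moment
   test). σ² ∈ {0.25, 0.5} in the two study arms.
3. **Transfers** — a time point uniform on the tree's total branch
   length (edge ∝ duration, uniform along it), recipient uniform among
   edges alive at that time outside the donor parent's subtree. The
   derived constraint (donor's parent older than recipient's child)
   holds in the truth by construction; degenerate picks are re-drawn.
4. **Perturbation** — stands in for a dating method's imperfect output:
   branch durations are multiplied by freshly drawn relaxed rates, nodes
   re-dated bottom-up by longest root path (a naive strict-clock reading
   of the relaxed tree), and dates rescaled so the root recovers the true
   height. Draws repeat until at least the requested number of
   constraints (3 in the recovery study) is violated; when a transfer set
   cannot reach that within 100 draws, a fresh set is drawn — the
   analogue of simulating another random gene tree. At σ² = 0.25 this
   yields mean absolute node-date errors near 0.08–0.10 on height-1
   trees, the error scale of real relaxed-clock dating.

The default of 25 transfers per 100-leaf tree was chosen so that accepted
perturbations typically violate 3–4 constraints, the count the recovery
study conditions on. What the generator does **not** emulate: posterior
correlation structure across samples from one analysis, systematic model
misspecification bias, topology error, or non-contemporaneous tips (the
data model supports dated tips, the generator does not produce them).
Passing tests therefore demonstrate correctness and recovery behavior of
the optimization machinery under realistic error magnitudes, not
end-to-end accuracy of any particular dating package.

## Problem sizes used in tests

The test suite runs feasibility on 200 instances (leaf counts 5–100,
1–10 constraints each, at least one violated), grid-oracle equivalence on
30 instances of 4–5 leaves at grid step 0.01 × root age, constraint
preservation on 100 random 3-member ensembles under all four
summarizers, and the recovery study on 20 replicates of 100-leaf trees
(10 per σ² arm). `scripts/acceptance.py` recomputes the same families of
quantities at moderately smaller counts (60 feasibility instances, 9
oracle instances, 50 ensembles, the full 20-replicate recovery study)
from a single command-line seed.

## Known limitations

- SLRB is non-convex; the returned solution is the best of a warm start
  plus seeded multistarts, not a certified global optimum. In practice it
  agrees with the exhaustive grid on every small instance tested.
- Interior-point solutions satisfy constraints to tolerance, not exactly;
  violation counting accepts a configurable tolerance (default 0 for
  exact comparison, `1e-6 ×` root age where solver output is checked).
- Aggregation requires a single shared topology; there is no consensus
  machinery for discordant posteriors.
- Constraints are hard: no probabilistic/soft constraint support, and no
  inference of transfers from gene trees (reconciliation is upstream).
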