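# Methods

## Model and update rule

The network is a directed, weighted graph on `N` nodes whose state is a
vector `x ∈ {−1, +1}^N` (−1 quiescent, +1 active).  Entry `W[i, j]` of
the weight matrix is the strength of the link from node `j` *into* node
`i`; 0 means no link.  Dynamics are synchronous: every node thresholds
its summed input at zero simultaneously,

    x_i[n+1] = sgn⁺( Σ_j W[i, j] x_j[n] ),     sgn⁺(u) = +1 if u ≥ 0 else −1.

A zero input sum — including the case of a node with no surviving
incoming links — resolves to +1.  Synchronous updating is essential to
the study: once pruning destroys the symmetry of the initial weight
matrix, trajectories can fall into limit cycles, which only exist under
wholesale updates.  Asynchronous updating is deliberately not
implemented.

A single pattern `s` (each component an independent fair ±1 draw) is
stored by the rank-1 Hebbian outer product `T = s sᵀ`, diagonal included.
`T` is symmetric with single nonzero eigenvalue `N` on eigenvector `s`,
and both `s` and `−s` are fixed points.  A second pattern `r` is required
to be *exactly* orthogonal (`r·s = 0`, only possible for even `N`; odd
`N` raises rather than approximates) and is drawn uniformly over all
exact partners by choosing the `N/2` agreement positions uniformly at
random.

## Trajectory classification

`evolve` iterates the update and, after each step, compares the new state
with the previous `max_period` states (default 4).  The first exact
repeat at lag `p` classifies the run as a fixed point (`p = 1`) or a
limit cycle of period `p`; no repeat within `max_iters` steps (default
500) is nonconvergent.  The reported iteration count is the number of
update steps needed to first *reach* the recurring state, so a start that
is already a fixed point costs 0 and a generic start on the full net
costs 1–2.  State comparisons are exact integer comparisons over a
sliding window — no hashing.  All weight–state products are computed in
float64, which is exact for the integer values that occur here (|sums| ≤
2N).

For `N ≤ 20` an exhaustive oracle computes the full transition map of all
`2^N` states in one vectorised pass and walks the functional graph,
returning every terminal cycle (any period) with its exact basin size.
The Monte-Carlo classifier is tested against this oracle state-by-state
on small nets.

## The retention criterion

A pruned net *retains* its designated attractor when

1. `s` **and** `−s` are both fixed points, and
2. every probe in a fresh panel of uniform random initial states
   converges, within the iteration cap and without entering a limit
   cycle, to `s` or `−s`.

Two design choices here deserve justification.

**The complement is part of the criterion.**  Because input sums are
linear, negating a state negates every node's input, so `−s` can only
fail to be fixed while `s` survives through a node whose input *ties at
exactly zero* on `s` — for example a node that has lost all of its
incoming links and is silently pinned to +1 by the tie rule.  A pattern
"stored" in such a degenerate way is an artifact of the tie convention,
not of the link structure: testing `s` alone would let the pruning loop
strip every input from every node where `s_i = +1` and terminate at
roughly `N/2` links with isolated nodes, which contradicts the behaviour
this pipeline is built to study (minimal nets at slightly more than `N`
links in which every node receives at least one input).  Requiring the
pair is exactly equivalent to requiring that no node's input ties to zero
on the pattern, and restores the intended physics: the minimal skeletons
then keep ≥ 1 incoming link per node, with totals in the low 200s at
`N = 200`.

**Complement identification.**  Probes reaching `−s` count as reaching
the designated attractor (and `±r` as reaching the second one).  Roughly
half of all random starts of the symmetric net provably flow to `−s`, so
global convergence "to the attractor" is only satisfiable up to sign.
Probe reports still record which sign was reached.

Fresh probe states are drawn at every retention test rather than reusing
a fixed panel, so the minimal net is not shaped around any particular
probe set.  Nonconvergent probes and limit-cycle probes both count as
retention failure.

A caveat that the tests make explicit: with 100 probes the criterion is
statistical.  At `N ≥ 50` the accepted nets also pass much larger fresh
panels, but at toy sizes (`N = 12`) a net can pass 100 probes while a
few percent of the `2^12` states genuinely escape — small state spaces
make the Monte-Carlo criterion loose, not the dynamics different.

## Experiment 1: minimal skeleton

Defaults: `N = 200`, bulk prune to 10 links/node (uniformly chosen
survivors, retention re-verified, resampled on failure up to 20 times),
then one-at-a-time pruning with 100 probes per test, 500-iteration cap,
period-4 cycle screen.  One link is drawn uniformly from the eligible
remaining links, zeroed, and tested; acceptance makes the deletion
permanent and resets eligibility (losing a link can change which other
links are removable); rejection reinstates the link and marks it
ineligible until the next acceptance.  Termination — a full round of
rejections — implies every remaining link has a witnessed failing initial
state, which is what makes the one-link-fragility (minimality) property
testable: at `N = 12` it is confirmed exhaustively, at `N = 50` with
fresh 200-probe panels per deleted link.

The full-connectivity net is *not* retention-gated before bulk pruning.
For patterns with exactly zero component sum (probability ≈ 5.6% at
`N = 200`) the fully connected net has a spurious all-ones fixed point
that captures probes orthogonal to `s`; it disappears under mild pruning
and is irrelevant to every measured quantity, so the pipeline verifies
retention after the bulk prune instead of before it.

Snapshots of the matrix are kept every 25 accepted deletions (cadence
configurable) plus the final skeleton.

## Experiment 2: second attractor

Given a completed skeleton `T*`, the dual matrix is

    U[i, j] = T*[i, j]             on the protected set (nonzeros of T*),
    U[i, j] = s_i s_j + r_i r_j    elsewhere,

i.e. the standard two-pattern Hebbian sum wherever the skeleton does not
already own the entry.  All four of `±s, ±r` are provably fixed points of
this construction (the skeleton perturbs the two-pattern input sums by at
most the skeleton's row degree, far below `N`); the build verifies this,
and the full `U` is additionally verified to send 1000 random starts to a
designated attractor before pruning begins.

Added links are then pruned — protected entries are never candidates and
are asserted bit-identical at exit — first in bulk to 15 links/node
total, then one at a time with 200 probes per test.  Phase 1 accepts a
deletion iff both pairs `{±s}` and `{±r}` stay fixed and every probe
reaches one of the four designated states.  When an entire round is
rejected, the run switches to phase 2: the `{±s}` pair must stay fixed
and probes must reach designated *fixed points*, but the second pair is
no longer required to survive.  The trace marks the transition and
records the links-per-node at the first accepted step where `{±r}` is no
longer fixed — the second attractor's fixed-point loss point, the
quantity the acceptance script reports (typically 1.5–2.0 links/node at
`N = 200`).  "Supported as a fixed point" uses the same complement-pair
notion as retention.

## Seeding

Every experiment takes one master seed and derives per-purpose child
generators (`attractor`, `bulk`, `links`, `probes`, ...) via
`numpy.random.SeedSequence.spawn`; spawn keys are recorded in run
metadata so any stage can be re-seeded in isolation.  Fixing the master
seed fixes every output bit-for-bit.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `n_starts` (single) | 100 | probes per retention test in experiment 1 |
| `n_starts` (dual) | 200 | probes per test in experiment 2 |
| `max_iters` | 500 | iteration cap per probe |
| `max_period` | 4 | largest limit-cycle period screened |
| `bulk_target` | 10 / 15 | links per node after the bulk prune (single / dual) |
| `n_verify_starts` | 1000 | probes verifying the full dual construction |
| `resample_budget` | 20 | bulk-prune retries before declaring failure |

Probe counts of 100 (single) and 200 (dual) are the study conditions;
they, not the dynamics, set how strict "global" retention is.

## What the generator emulates, and what it does not

All inputs are synthetic by design: uniform ±1 patterns, exactly
orthogonal partners, uniform ±1 probe states.  Uniform probes model an
environment that perturbs every configuration equally; real biological
perturbation distributions are concentrated around operating points, so
passing these tests says nothing about basins weighted by realistic
perturbations.  Step-function nodes stand in for saturating biochemical
nonlinearities (e.g. Michaelis–Menten kinetics); the minimal-connectivity
numbers are tied to this idealisation and to the zero-tie convention,
and should be read as structural results about threshold networks, not
quantitative predictions for any particular pathway.

## Problem sizes

The test suite runs the science checks at desk scale — one `N = 50` and
ten `N = 100` pruning runs, a full dual run at `N = 50`, the
mass-elimination sweep at `N = 200` (cheap), exhaustive checks at
`N ≤ 12` — and finishes in about two minutes.  `scripts/acceptance.py`
runs the paper-scale `N = 200` single and dual experiments in about one
minute on one CPU.  The ln(N)-collapse check compares pooled binned
curves (bin width 0.25 links/node) between `N = 50` and `N = 100` and
asserts a median relative gap ≤ 15% on the shared grid, against a ~16%
gap for the unnormalized curves.

## Known limitations

- The pruning order is greedy/random; the skeleton found is minimal in
  the one-link-deletion sense, not a globally smallest supporting
  subgraph.
- Retention is Monte-Carlo; "globally attracting" means "no witnessed
  escape among the probe panel" (see the small-`N` caveat above).
- The degree-frequency histogram of minimal nets decays across bins, but
  the first two bins (degree 1 and 2) are statistically indistinguishable
  at ten runs; the monotonicity test allows for sampling error (2 SE).
- Dual grafting at toy sizes (`N ≲ 16`) can fail its global-convergence
  verification because spurious mixture states of the two-pattern matrix
  own a noticeable fraction of a small state space; at `N ≥ 20` this is
  not observed.
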