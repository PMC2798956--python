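# Methods

## Model and scope

The simulator targets well-mixed, constant-volume chemical systems with
integer molecule counts, mass-action kinetics, constant stochastic rate
constants, and at most two reactants and two products per reaction.
Reactions with more slots are rejected by validation rather than
auto-decomposed: splitting a ternary reaction into binary steps changes the
rate semantics, and that choice belongs to the modeler. Zero- and
first-order reactions are expressed by padding slots with the omnipresent
species ∅ (id `"0"`, index 0), whose count is frozen at 1 — this removes
every special case from propensity evaluation, factoring and selection.

Self-reactions A+A use the combinatorial convention a = c·x·(x−1)/2. The
unhalved convention c·x·(x−1) is available through the `self_rate_halved`
flag threaded through `propensity`, `build_structures` and the engines,
because both conventions circulate in the literature and the difference
silently rescales rates by 2.

Out of scope: time-varying rates, non-mass-action kinetics, compartments
and variable volume, dynamic re-clouding during a run, and the
indexed-priority-queue (next-reaction) engine family.

## Two-phase iteration

Phase 1 (read): draw u₁ ∈ [0,1), set r = u₁·a₀, and map r to a reaction —
linear scan of the super-cache; on a miss, subtract P_sc and descend the
main tree to a cloud; inside the cloud divide the residual by x_T, walk the
primary tree if r′ < R, otherwise subtract R and step through sub-trees
(subtracting x_{s_j}·S_j each) and descend the matching sub-tree after a
further division by x_{s_j}. Phase 2 (write): draw u₂ ∈ (0,1], advance
time by τ = ln(1/u₂)/a₀, and execute the reaction's compiled update
program. Two uniforms per step, in that fixed order, from a seeded PCG64
generator — trajectories are bit-reproducible given (network, seed,
configuration).

The rescaling choice in Phase 1 makes the interval width assigned to a
primary leaf x_T·(c_i·x_{o_i}) and to a sub-tree leaf x_T·(x_{s_j}·c_i),
i.e. exactly the reaction's propensity, which is what the
breakpoint-enumeration audit (`diagnostics.selection_intervals`) verifies
against brute force. The engines are compared distributionally, never
path-wise: with different data layouts the same uniform maps to different
reactions.

## Preprocessing

1. **Trial run** — a direct-method simulation whose per-reaction
   propensities are averaged weighted by holding times. Default length
   10⁵ steps; tests and the acceptance script use shorter trial runs (or an
   explicit uniform profile) where the measured quantity does not depend on
   the profile, since the profile only shapes structure layout, never
   correctness. A stalled trial averages over the time simulated before the
   stall; `uniform_profile` is the fallback for degenerate inputs.
2. **Super-cache** — the 16 reactions (configurable) with the largest
   average propensity, descending, ties broken by reaction index.
3. **Greedy cloud assignment** — a candidate cloud per species holds every
   unassigned reaction with that species as a reactant; its score is the
   summed average propensity of its members. Fix the best candidate
   (ties → lowest species index), remove its members everywhere, rescore,
   repeat. Reactions with two ∅ reactants that miss the super-cache fall
   into a dedicated ∅-cloud whose factor count is the frozen 1.
4. **Sub-tree partition** — within a cloud, members sharing a secondary
   reactant form a sub-tree when there are at least three of them;
   ∅-partnered members and factor self-reactions always stay primary.
5. **Graphs and programs** — the bipartite dependency graph (≤ 6M edges;
   a species with zero net stoichiometric change in a reaction is *not* an
   affected species, so catalytic participation costs nothing), and one
   static instruction list per reaction, ordered: count deltas, self-leaf
   refreshes, primary-leaf refreshes, C adjustments, super-cache
   refreshes, then one a_T/main-tree finalize per touched cloud.

A factor-species self-reaction stores leaf value c·(x_T−1)/2; the O(1)
cloud rescale is insufficient for it, so its program includes an explicit
leaf refresh whenever x_T changes.

## Numerical policy

Cached sums are kept equal to their from-scratch values to machine
precision rather than merely drift-bounded:

- **Sum trees** update a leaf by recomputing each ancestor as the sum of
  its k children (O(k·log_k n)), so every internal node is bit-identical to
  a full rebuild at all times.
- **P_sc** is re-summed over the fixed-size super-cache array at each
  refresh — O(1) in system size.
- **C** is maintained as the exact sum of cached per-sub-tree terms
  x_{s_j}·S_j, each refreshed as a single exact product when its species
  changes. A running `C += δ·S_j` accumulator was measured to leave
  ~10⁻¹³-scale residue after cancelling sequences (fatal to a relative
  comparison when the true value returns to zero); the term refresh has the
  same cost and leaves none.
- a₀ is recomputed as P_sc + main-tree root after each program, not
  accumulated.

Measured consequence: worst relative deviation of any cached quantity from
brute-force recomputation is ~10⁻¹⁵ over 10⁵ steps on a 2000-reaction hub
network, and over 200 random systems run 2000 steps each. A full
`recompute_all` still runs every 10⁶ steps and before each recorded sample
as a belt-and-braces default, and the engine falls back to one
recompute-and-retry if a selection walk hits a float-residue dead end near
extinction (cached a₀ a few ulp above a true zero).

`locate` uses half-open intervals, so zero-weight leaves are unselectable
and boundary ties cannot occur; microscopic upper-boundary excess from
summation-order differences is clamped into the last positive-weight child.
Default branching factor k = 4 everywhere (configurable; the suite
exercises k ∈ {2, 4, 8, 16}); trees are capacity-padded with zero leaves
and never rebalanced, since the reaction set is static.

Recording is time-gridded sample-and-hold (state held on [t, t+τ) is
recorded at every grid point in that interval), which matches reporting
state at chosen times; a `max_samples` cap (default 10⁶) bounds memory when
a propensity collapse stretches one holding interval across a huge number
of grid points — the run continues unrecorded past the cap. Counts are
int64; time is float64 seconds.

## Synthetic study systems

`generate_hub_network` emulates the structure of large signalling models: a
few hub species at high copy number (default 1000) appearing as a reactant
in a controllable fraction of reactions (default 90%), log-uniform rates
over [10⁻², 10²], non-hub counts uniform on [0, 100], 10% of non-hub
reactions catalytic. With ≥ 2 hubs, hub reactions convert one hub form
into another (total hub stock conserved — the ATP/ADP cycling idiom), so
long runs cannot exhaust the super-species while every hub firing still
changes two hub counts, which is what makes the reaction-clique dependency
graph quadratic and keeps the valence CDF mass near the fan-out. A lone
hub is simply consumed. The `buffer_non_hubs` option additionally returns
every non-hub reactant as a product (clamped substrate pools), holding the
load stationary for the counted-cost experiments. What the generator does
*not* reproduce: real pathway topology, conservation structure beyond the
hub stock, or literature rate constants — statistical agreement on these
networks shows engine correctness, not biological fidelity of any
particular model.

The canonical models carry their closed forms: immigration–death (λ=10,
γ=1; stationary Poisson, mean = variance = 10), pure decay (x₀=1000, c=1;
E[x(t)] = 1000·e^{−t}), symmetric isomerization (stationary mean 50),
dimerization (parity invariant), and an enzyme-hub toy.

## Verification strategy and problem sizes

Oracles are independent of the paths they check: brute-force propensity
summation against every cached total; breakpoint enumeration against the
selector; full rebuilds against incremental tree updates; a pairwise
dependency scan against the clique graph; closed-form stationary/transient
moments against both engines at 3-standard-error tolerance; chi-square
(α = 0.001, small-expectation bins pooled) against frozen selection
frequencies at 10⁶ draws. Long-run checks use 10⁵ engine steps on the
2000-reaction hub network with consistency audited at ten checkpoints;
counted-complexity comparisons run 2000 steps per fan-out on buffered hub
networks of 10/100/1000 reactions. These sizes were chosen so the whole
suite completes in a couple of minutes on one core while every effect being
tested is orders of magnitude larger than its Monte-Carlo or float noise.

## Known limitations

- Super-cache membership and cloud assignment are fixed at preprocessing;
  if the propensity profile drifts far from the trial run's, selection
  stays exact but the cache-hit rate (a performance property) degrades.
- The greedy clouding has no optimality guarantee; its score counts each
  reaction's average propensity once per candidate cloud.
- Per-step cost is measured by operation counters, not wall-clock time;
  this implementation is written for clarity and auditability, not raw
  speed.
- SBML ingest accepts only kinetic laws that are a plain product of one
  rate parameter and the reactant species; anything else is rejected
  explicitly rather than approximated.
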