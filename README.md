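# lolcat-ssa

Exact stochastic simulation of mass-action reaction networks, built for the
regime where classical Gillespie implementations fall over: large systems in
which a few **super-species** (ATP-like currency metabolites, scaffold
proteins, shared enzymes) appear as reactants in a large fraction of the
reactions. It is a library first — `import lolcat_ssa` — with short
narrative scripts in `examples/` and a thin `lolcat-ssa` command line on
top.

## The problem and the method

The stochastic simulation algorithm (SSA) draws, at each step, a reaction
*j* with probability a_j/a₀ and a holding time τ ~ Exp(a₀), where a_j is
the mass-action propensity (a = c·x_i·x_j for distinct reactants,
c·x·(x−1)/2 for a self-reaction) and a₀ = Σ_j a_j. The expensive parts at
scale are (1) mapping a uniform variate to a reaction and (2) refreshing
the propensities the firing invalidated — when a super-species count
changes, thousands of a_j change with it.

This implementation is the LOLCAT Method: it factors the common reactant
out of each group of reactions sharing one. A **cloud** with factor-species
x_T stores

    a_T = x_T · (R + C),   R = Σ_{i∈T₀} c_i·x_{o_i},   C = Σ_j x_{s_j}·S_j,

where T₀ (the **primary tree**, a balanced k-ary cumulative-sum tree) holds
members keyed by c_i·x_{other}, and each **sub-tree** T_j holds members that
also share a secondary species s_j — its leaves are the constants c_i, so
its root S_j never changes. Consequences:

- a change of x_T rescales the entire cloud in **O(1)**, however many
  thousands of reactions it holds;
- a change of a secondary species s_j adjusts C in **O(1)**;
- only a primary partner change touches a tree path, **O(log_k |T₀|)**.

Selection walks a constant-size **super-cache** of the hottest reactions
(linear scan, running total P_sc), then a k-ary **main tree** over cloud
totals, then into a cloud, rescaling the residual by 1/x_T (and 1/x_{s_j})
on entry. The interval of r ∈ [0, a₀) mapped to each reaction has width
exactly a_j, so the sampled law is identical to the textbook direct method
— the information is only organized differently.

Update propagation uses a **bipartite dependency graph** (reaction →
species it changes; species → reactions it feeds), bounded by 6M edges for
M reactions, instead of the reaction-clique graph that grows towards M² when
a super-species is present. The graph plus the cloud layout is compiled
once into a per-reaction **update program**: a fixed instruction list
(count deltas, cloud rescale, leaf refresh, C adjustment, super-cache
refresh) executed on every firing.

The package also contains the textbook direct method (`run_direct`, the
statistical oracle), an ODM-style sorted-linear-scan baseline with
operation counters (`run_odm_baseline`, clique or bipartite graph), a
synthetic hub-network generator with the super-species structure, canonical
analytically solvable models, and valence/memory diagnostics.

## Worked example

```python
from lolcat_ssa import RunSpec, canonical_model, run_lolcat

system, facts = canonical_model("immigration_death")   # ∅→A at 10/s, A→∅ at 1/s
traj = run_lolcat(system, RunSpec(max_time=300.0, seed=1, record_interval=0.1),
                  trial_steps=2000)
x = traj.counts[traj.times >= 10.0, 0].astype(float)
print(x.mean(), x.var(ddof=1) / x.mean())
```

Running `python examples/01_simulate_birth_death.py` prints:

```
samples kept:      2900 (t in [10, 300], every 0.1 s)
time-averaged mean: 9.912   (stationary law says 10.0)
Fano factor:        1.088   (Poisson says 1.0)
events fired:       5950
```

The stationary law of this immigration–death process is Poisson(10), so
the time-averaged mean sits near 10 and the variance/mean ratio near 1;
both are within Monte-Carlo error here. `examples/03_update_cost_comparison.py`
shows the headline scaling: on hub networks of fan-out 10/100/1000 the
factored engine performs a flat ~10–18 structure updates per step while the
clique-graph ODM baseline's propensity recomputations grow as the fan-out
(10 → 100 → 1000).

Networks are read from a one-reaction-per-line text format
(`R1: A + B -> C + 0 @ 2.0`, `0` meaning the empty slot) or from SBML
Level 3 with constant-rate mass-action kinetics; see
`examples/05_network_file_round_trip.py` and the `lolcat-ssa simulate`,
`preprocess`, `diagnose` and `verify` subcommands.

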