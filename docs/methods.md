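# Methods

## Model

Strain design is posed as a network-interdiction game on a constraint-based
metabolic model. The host cell is the network user: for a fixed knockout
vector `y` it may adopt *any* steady-state flux distribution consistent with
mass balance (`S v = 0`), flux bounds, and a minimum-growth requirement — in
particular the one that minimizes target export. The metabolic engineer is
the interdictor: with at most `K` reaction knockouts from a candidate set
`J̄`, maximize that worst-case (guaranteed minimum) production. No optimality
principle is imposed on the mutant's growth; the only biological assumptions
are steady state, the flux bounds, and that an engineered strain must retain
a minimum growth rate (default 10% of wild-type) to be propagatable.

Reversible reactions keep signed bounds throughout; nothing is split into
irreversible pairs. Flux caps enter the formulation only through
`U_j = max(|lb_j|, |ub_j|)`. Units are mmol/gDW/h for fluxes and 1/h for
growth everywhere; no conversion layer exists.

## Single-level reformulation

The inner problem's knockout disjunction is replaced by a Lagrangian penalty:
`min c_P'v + Σ_{j∈J̄} M_j u_j y_j` with magnitude variables `u_j >= ±v_j`,
`u_j <= U_j`, and multipliers `M_j` drawn once per run from U(90, 110)
(seeded, default seed 2020). The random spread avoids the degenerate ties a
constant penalty can create; ~100 is orders of magnitude above any marginal
production gain per unit flux in the fixtures and in genome-scale models fed
by a bounded substrate uptake.

LP duality applied to the penalized follower yields a single-level MILP whose
continuous block contains, simultaneously:

1. follower primal feasibility (`S v = 0`, bounds, `u >= |v|`, `u <= U`,
   growth floor);
2. follower dual feasibility (`S'λ + α − β + γ − δ − e_bio φ = −c_P`, and the
   dual-capacity rows `α_j + β_j − ε_j <= M_j y_j`, relaxed by the knockout
   choice);
3. one strong-duality row tying `c_P'v` to the dual objective
   `−ub'γ + lb'δ − U'ε + gf·φ`; and
4. coupling rows `u_j + U_j y_j <= U_j` that pin `u_j = 0` (hence `v_j = 0`)
   whenever `y_j = 1`.

With the coupling rows present, the penalty term `Σ M_j u_j y_j` vanishes
identically at every feasible point, so the strong-duality row involves no
bilinear product and the continuous restriction at any fixed binary `y` is an
LP whose optimum equals the exact follower minimum. This construction was
re-derived from first principles and is validated in the test suite against
an exhaustive enumeration oracle rather than trusted as a transcription.
The knockout budget is `Σ y_j <= K` ("at most K knockouts").

The growth floor lives inside the follower (and hence the slave) rather than
as a post-hoc filter: designs that kill required growth make the slave
infeasible and are excluded by feasibility cuts during the search.

## Hybrid Benders algorithm

All `y`-dependence of the single-level MILP sits in the inequality right-hand
side `b − By`, so Benders decomposition applies cleanly: a binary master
(MP) over `(y, z)` accumulates cuts; the continuous slave (SP) at `ȳ` is
solved and its duals converted into

* an optimality cut `z <= (b − By)'π + b_eq'λ` when the SP is feasible (the
  SP value is the design's guaranteed minimum production), or
* a feasibility cut `(b − By)'π + b_eq'λ >= 0` from a Farkas certificate when
  it is not. The backend does not export rays, so the certificate is obtained
  from a normalized ray LP (minimize the certified right-hand side over the
  homogeneous dual cone with `Σπ <= 1`); validity of the resulting cut for
  every feasible design follows directly from Farkas' lemma.

Accelerations:

* **Pareto cuts.** The SP right-hand side is perturbed toward a core point:
  `(b − Bȳ) + μ(b − Bŷ)` with `μ = 1e-8`. The perturbed dual optimum is
  dual-feasible for the unperturbed SP, so the cut remains valid, and it is
  undominated at the core point. `ŷ` starts at the interior constant
  `min(0.5, K/(|J̄|+1))` per component and is averaged (`ŷ ← (ŷ + ȳ)/2`)
  with every new feasible master point, which keeps it strictly interior.
  Pool values are never read off the perturbed SP: each feasible design is
  re-evaluated with the exact follower LP (cheap — one LP — and removes the
  O(μ) perturbation from reported numbers).
* **Local branching.** The MP is restricted to the Hamming ball
  `Δ_H(y, y′) <= r − 1` around the incumbent `y′` (initial radius `r0 = 3`,
  `y′` initialized at the wild type). An empty ball is excluded permanently
  with the reverse inequality `Δ_H >= ρ` — the exclusion radius `ρ` is frozen
  at failure time while `r` keeps growing, since letting both track each
  other keeps the ring `Δ_H <= r−1 ∧ Δ_H >= r+1` empty forever. A ball whose
  master bound falls to the incumbent value is likewise reversed: it provably
  contains nothing better. `y′` re-centres on every incumbent improvement
  (and when an early-terminated master reports a value below the slave's).
* **Early termination.** The master may stop at an absolute optimality gap of
  `1 + 300/(sqrt(iter) + 1)` flux units (monotone to 1). The backend only
  accepts relative gaps, so the absolute gap is divided by the objective cap.
  A master answer seen twice is pinned with an exact (unperturbed) cut; seen
  three times, the master is forced exact; seen more, the point is excluded
  by a no-good inequality (its value is already recorded, so the search loses
  nothing).

`z` is capped above by the theoretical maximum production (TMP) — the FBA
optimum with the target as objective, computed without a growth floor — which
is a valid bound on any interdiction value and replaces an unbounded initial
master.

**Bound accounting and termination.** A master bound obtained inside a
Hamming ball is valid only there, so the global upper bound `z̄` is updated
only from master solves with no active ball: reversed regions were proven
dominated when they were reversed, hence `max(incumbent, bound)` is a true
global bound. The run stops when an *exact, unbranched* master solve closes
the gap to `z̄ − z_ <= 1e-4` (or on the iteration cap, default 10 000, or the
wall-clock budget, default 3600 s). Every feasible design whose guaranteed
production reaches `threshold_fraction × TMP` enters the pool as it is found;
the pool is deduplicated and ordered by guaranteed minimum production, ties
broken lexicographically.

## Preprocessing

* **Dead ends**: reactions whose flux range over the plain feasible region is
  {0} are removed iteratively together with orphaned metabolites; the biomass
  optimum is unchanged by construction.
* **Linear chains**: a metabolite with exactly one producer and one consumer
  forces a fixed flux ratio between them, so the pair is merged with combined
  stoichiometry and ratio-scaled, intersected bounds; objective-carrying
  reactions and explicitly protected ids (pass the target) are never merged,
  and a mapping back to original reaction ids is returned.
* **Candidates**: from all reactions, drop the biomass and target reactions,
  exchanges (keeping oxygen uptake by default — its knockout encodes the
  anaerobic switch), reactions without gene rules (configurable; a knockout
  without a genetic handle is not implementable), reactions essential at the
  growth floor (single-deletion FBA), user excludes, and reactions touching
  any metabolite with more than `n_c` carbons (`n_c = 100` disables the
  filter; the carbon rule applies to all participating metabolites,
  substrates and products alike). Each rule is a switch and per-rule removal
  counts are logged.

## Tolerances and numerical choices

| quantity | value | rationale |
|---|---|---|
| LP feasibility | 1e-9 | HiGHS default scale for these well-conditioned fixtures |
| zero-flux / coupling tolerance | 1e-6 | separates structural zeros from round-off |
| Benders closure | 1e-4 | absolute, in flux units |
| Pareto `μ` | 1e-8 | large enough to steer duals, below reporting precision |
| penalties `M_j` | U(90,110), seed 2020 | see above |
| brute-force guard | 5000 subsets | keeps the oracle a fixture-scale tool |

Production envelopes fix biomass by equality on a grid from 0 to the design's
maximal growth (equality reproduces the classic envelope shape; at grid edges
an equality made infeasible by round-off is retried with a ±1e-9 slack).
Coupling classes: *strong* if the guaranteed minimum is positive at zero
growth, *growth-coupled* if positive at maximal growth only, else *none*.
Alternate LP optima make flux vectors solver-dependent; only objective
values are contract-bearing.

## Synthetic fixtures

`make_toy_network("toy5")` is the minimal interdiction instance: one
substrate uptake capped at 10 mmol/gDW/h, an uncoupled and a product-coupled
route to biomass, a biomass sink and a product export — small enough that
every LP value is checkable by hand. `random_branched` generalizes it to
`n_branches` parallel two-step routes of which a chosen fraction co-produce
the product; stoichiometric coefficients are drawn from {1, 2} (hand-checkable
brute-force values), bounds are 10 for uptake and effectively unbounded
elsewhere, and identical seeds give identical models.

These fixtures exercise every code path of the algorithm (optimality and
feasibility cuts, branching, reversal, pooling) but are deliberately *not*
genome-scale: they have no cofactor cycling, no reversible internal loops, no
oxygen exchange, and candidate sets of at most ten reactions. Passing tests
therefore demonstrate algorithmic correctness (agreement with exhaustive
enumeration, duality identities, cut validity), not biological predictions;
genome-scale behaviour (candidate sets of 150–350 reactions, hour-scale runs)
additionally depends on MILP backend strength. The default run configuration
(10% minimum growth, `n_c = 100`, K = 5, 1 h budget) reflects the regime the
method is intended for.

## Known limitations

* Reaction-level knockouts only; gene-level mapping through GPR logic is out
  of scope (gene rules are carried and used only as a candidate filter).
* Solution quality beyond the pool-and-rank mechanism (diversity extraction,
  scoring systems) is not attempted.
* Constraint-based steady-state modelling throughout: no kinetics, no
  regulation, no metabolic adjustment (MOMA-style) re-ranking.
* The enumeration oracle and the direct MILP baseline are fixture-scale
  verification tools, not genome-scale solvers.
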