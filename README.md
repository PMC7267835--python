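# nihba

Network-interdiction strain design for genome-scale metabolic models, solved
by a hybrid Benders algorithm (HBA) with Pareto-optimal cuts and local
branching.

## The problem

Metabolic engineers remove reactions from a host's metabolic network so that
making the target chemical becomes unavoidable: every flux state the mutant
can settle into while growing must export product. Classical bilevel
strain-design tools (OptKnock and descendants) assume the mutant grows
optimally and solve a big-M MILP that scales poorly and is numerically
fragile at genome scale.

This package instead treats strain design as a *network interdiction* game,
with no growth-optimality assumption. For a stoichiometric matrix `S`, flux
vector `v` with bounds `lb <= v <= ub`, target coefficient vector `c_P` and a
binary knockout vector `y` over a candidate set `J̄` with budget `K`:

```
max_y  min_v  c_P' v
s.t.   S v = 0
       lb_j (1 - y_j) <= v_j <= ub_j (1 - y_j),   j in J̄
       v_biomass >= growth floor,                  sum_j y_j <= K
```

The host (inner player) minimizes target flux; the engineer (outer player)
chooses knockouts to make even that pessimistic minimum large. The knockout
disjunction is folded into the inner objective in Lagrangian form
(`min c_P'v + Σ M_j u_j y_j`, `u_j >= |v_j|`, `M_j ~ U(90, 110)`), LP duality
turns the bilevel program into a single-level MILP, and Benders decomposition
splits that MILP into a binary master over `y` and a continuous slave whose
duals supply optimality cuts (feasible designs) and Farkas feasibility cuts
(designs that kill required growth). Pareto-optimal cuts via a core-point
perturbation (`mu = 1e-8`) and local branching on the Hamming distance around
the incumbent accelerate convergence, and every feasible design whose
guaranteed production passes a user threshold is kept in a solution pool — a
single run returns many growth-coupled designs, each with its production
envelope.

## Worked example

The canonical toy network has substrate A, biomass precursor B and product C,
with an uncoupled route `R1: A -> B` and a coupled route `R3: A -> B + C`:

```python
from nihba import InterdictionDesign, make_toy_network

model = make_toy_network("toy5")
design = InterdictionDesign(model, target="PRD", K=1, require_gene_rule=False)
results = design.fit()          # hybrid Benders search
print(results.summary())
```

```
Network Interdiction Strain Design Results
==========================================================
Model:               toy5 (3 metabolites, 5 reactions)
Target reaction:     PRD
Method:              hba (status: optimal)
Candidates (n_s):    2 (carbon cutoff n_c = 100)
Max knockouts K:     1
Wild-type growth:    10.0000 1/h
Growth floor:        1.0000 1/h
Theoretical max:     10.0000 mmol/gDW/h
Solutions in pool:   2
----------------------------------------------------------
knockouts  n_knockouts  growth  min_production  min_production_at_floor  max_production  pct_tmp       coupling
       R1            1 10.0000         10.0000                   1.0000         10.0000 100.0000 growth_coupled
   (none)            0 10.0000          0.0000                   0.0000         10.0000   0.0000           none
```

Knocking out the uncoupled route `R1` forces all flux through `R3`, so
product export equals biomass flux: the guaranteed minimum production is 1.0
mmol/gDW/h at the growth floor (10% of wild type) and 10.0 at optimal growth
(100% of the theoretical maximum), a growth-coupled design. The wild type
guarantees nothing (`min_production = 0`).

The same search is available from the shell on SBML-FBC or COBRA-JSON models:

```
nihba run --model model.xml --target EX_succ_e --max-ko 5 --out results/
nihba envelope --model model.xml --target EX_succ_e --knockouts PDH,PFL
nihba candidates --model model.xml --target EX_succ_e --carbon-max 22
```

`nihba run` writes a solutions TSV (knockouts, growth, min/max production,
% of theoretical maximum, coupling class), knockout/subsystem frequency
tables and a run-metadata JSON with the bound trace.

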