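"""LP-level analyses: FBA, theoretical maximum production, the follower
(inner-minimization) problem, production envelopes and coupling classes.

Flux balance analysis solves ``max c'v  s.t.  S v = 0, lb <= v <= ub``.  The
*follower* problem is the host cell's response to a knockout design: it
minimizes the target flux over the knocked-out feasible region subject to a
minimum-growth requirement, and is the evaluation oracle for any design.
A *production envelope* reports the attainable min/max target flux as biomass
is swept from zero to the design's maximum growth; its shape determines
whether a design is growth coupled (positive guaranteed production at maximal
growth) or strongly growth coupled (positive even at zero growth).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _solver
from .errors import InfeasibleModelError
from .model import DesignVector, MetabolicModel, apply_knockouts

__all__ = [
    "FluxSolution",
    "EnvelopeCurve",
    "solve_fba",
    "theoretical_max_production",
    "follower_min_production",
    "production_envelope",
    "classify_coupling",
]

FEASIBILITY_TOL = 1e-9
ZERO_FLUX_TOL = 1e-6


@dataclass
class FluxSolution:
    v: np.ndarray | None
    objective_value: float | None
    status: str
    duals: np.ndarray | None = None

    @property
    def optimal(self) -> bool:
        return self.status == _solver.OPTIMAL


@dataclass
class EnvelopeCurve:
    biomass_grid: np.ndarray
    min_production: np.ndarray
    max_production: np.ndarray
    coupling_class: str = "none"
    target: str = ""

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "biomass": self.biomass_grid,
                "min_production": self.min_production,
                "max_production": self.max_production,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def solve_fba(
    model: MetabolicModel,
    objective_index: int | None = None,
    sense: str = "max",
    extra_bounds: dict[int, tuple[float, float]] | None = None,
) -> FluxSolution:
    """Solve an FBA LP.  Infeasible/unbounded outcomes are reported in
    ``status``, never raised."""
    n = model.n_reactions
    if objective_index is None:
        objective_index = model.biomass_index
    if not 0 <= objective_index < n:
        raise IndexError(f"objective index {objective_index} out of range")
    c = np.zeros(n)
    c[objective_index] = 1.0
    lb, ub = model.lb.copy(), model.ub.copy()
    if extra_bounds:
        for j, (lo, hi) in extra_bounds.items():
            lb[j], ub[j] = lo, hi
    res = _solver.solve_lp(
        c,
        A_eq=model.S,
        b_eq=np.zeros(model.n_metabolites),
        bounds=list(zip(lb, ub)),
        sense=sense,
    )
    if not res.status == _solver.OPTIMAL:
        return FluxSolution(None, None, res.status)
    return FluxSolution(res.x, float(res.objective), res.status, res.duals_eq)


def theoretical_max_production(model: MetabolicModel, target: int) -> float:
    """FBA optimum with the objective switched to the target flux (TMP).

    TMP is the denominator of all "% TMP" reporting.  Computed without any
    growth requirement.
    """
    sol = solve_fba(model, objective_index=target, sense="max")
    if not sol.optimal:
        raise InfeasibleModelError(
            f"cannot compute theoretical maximum production: LP {sol.status}"
        )
    return float(sol.objective_value)


def follower_min_production(
    model: MetabolicModel,
    target: int,
    design: DesignVector | None = None,
    growth_floor: float = 0.0,
) -> FluxSolution:
    """Minimum target flux of the knocked-out strain at the growth floor.

    Solves ``min v_target`` over ``S v = 0``, knocked-out reactions fixed to
    zero, and ``v_biomass >= growth_floor``.  This is the exact inner
    (follower) problem of the interdiction game and the evaluation oracle for
    any design.
    """
    if growth_floor < 0:
        raise ValueError("growth_floor must be nonnegative")
    kmodel = apply_knockouts(model, design) if design is not None else model
    bio = kmodel.biomass_index
    extra = {bio: (max(kmodel.lb[bio], growth_floor), kmodel.ub[bio])}
    if extra[bio][0] > extra[bio][1]:
        return FluxSolution(None, None, _solver.INFEASIBLE)
    return solve_fba(kmodel, objective_index=target, sense="min", extra_bounds=extra)


def production_envelope(
    model: MetabolicModel,
    target: int,
    design: DesignVector | None = None,
    n_points: int = 21,
) -> EnvelopeCurve:
    """Min/max target flux while biomass is fixed (equality) on a grid
    spanning [0, maximal growth of the knocked-out model]."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    kmodel = apply_knockouts(model, design) if design is not None else model
    bio = kmodel.biomass_index
    growth = solve_fba(kmodel)
    if not growth.optimal:
        raise InfeasibleModelError("design is infeasible; empty envelope")
    mu_max = max(growth.objective_value, 0.0)
    grid = np.linspace(0.0, mu_max, n_points)
    mins, maxs = np.empty(n_points), np.empty(n_points)
    for i, b in enumerate(grid):
        extra = {bio: (b, b)}
        lo = solve_fba(kmodel, objective_index=target, sense="min", extra_bounds=extra)
        hi = solve_fba(kmodel, objective_index=target, sense="max", extra_bounds=extra)
        if not (lo.optimal and hi.optimal):
            # relax the equality by the feasibility tolerance at grid edges
            extra = {bio: (max(b - 1e-9, 0.0), b + 1e-9)}
            lo = solve_fba(kmodel, target, "min", extra)
            hi = solve_fba(kmodel, target, "max", extra)
        mins[i] = lo.objective_value if lo.optimal else np.nan
        maxs[i] = hi.objective_value if hi.optimal else np.nan
    curve = EnvelopeCurve(grid, mins, maxs, target=model.reaction_ids[target])
    curve.coupling_class = classify_coupling(curve)
    return curve


def classify_coupling(curve: EnvelopeCurve, tol: float = ZERO_FLUX_TOL) -> str:
    """'strong' if guaranteed production is positive at zero growth,
    'growth_coupled' if positive at maximal growth only, else 'none'."""
    min0 = curve.min_production[0]
    minmax = curve.min_production[-1]
    if np.isfinite(min0) and min0 > tol:
        return "strong"
    if np.isfinite(minmax) and minmax > tol:
        return "growth_coupled"
    return "none"

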