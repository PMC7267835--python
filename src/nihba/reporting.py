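"""Solution-pool post-processing: record evaluation, filtering,
knockout/subsystem frequency summaries and TSV export.

A design's headline numbers follow the convention of reporting min and max
production *at the knocked-out strain's optimal growth* (the growth value
printed alongside them); the zero-growth envelope endpoint is used only for
the strong-coupling flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InfeasibleModelError
from .fba import (
    EnvelopeCurve,
    production_envelope,
    solve_fba,
    theoretical_max_production,
    ZERO_FLUX_TOL,
)
from .model import DesignVector, MetabolicModel

__all__ = [
    "SolutionRecord",
    "evaluate_record",
    "filter_pool",
    "knockout_frequency",
    "pool_to_frame",
]


@dataclass
class SolutionRecord:
    design: DesignVector
    knocked_ids: tuple[str, ...]
    growth_at_solution: float
    min_production: float
    max_production: float
    pct_tmp: float
    coupling_class: str
    envelope: EnvelopeCurve | None = None
    min_production_at_floor: float = field(default=np.nan)

    def key(self) -> tuple:
        return tuple(self.design.y)


def evaluate_record(
    model: MetabolicModel,
    design: DesignVector,
    target: int,
    tmp: float | None = None,
) -> SolutionRecord:
    """Evaluate a design: maximal growth of the knocked-out strain, min/max
    target flux at that growth, percent of the wild-type theoretical maximum,
    and the coupling class."""
    if tmp is None:
        tmp = theoretical_max_production(model, target)
    from .model import apply_knockouts

    kmodel = apply_knockouts(model, design)
    bio = kmodel.biomass_index
    growth = solve_fba(kmodel)
    if not growth.optimal:
        raise InfeasibleModelError("design is infeasible; cannot evaluate")
    mu_star = float(growth.objective_value)

    def minmax_at(b: float) -> tuple[float, float]:
        extra = {bio: (b, b)}
        lo = solve_fba(kmodel, target, "min", extra)
        hi = solve_fba(kmodel, target, "max", extra)
        if not (lo.optimal and hi.optimal):
            extra = {bio: (max(b - 1e-9, 0.0), b + 1e-9)}
            lo = solve_fba(kmodel, target, "min", extra)
            hi = solve_fba(kmodel, target, "max", extra)
        return float(lo.objective_value), float(hi.objective_value)

    pmin, pmax = minmax_at(mu_star)
    pmin0, _ = minmax_at(0.0)
    if pmin0 > ZERO_FLUX_TOL:
        coupling = "strong"
    elif pmin > ZERO_FLUX_TOL:
        coupling = "growth_coupled"
    else:
        coupling = "none"
    pct = 100.0 * pmin / tmp if tmp > 0 else 0.0
    return SolutionRecord(
        design=design,
        knocked_ids=design.knocked_ids(model),
        growth_at_solution=mu_star,
        min_production=pmin,
        max_production=pmax,
        pct_tmp=pct,
        coupling_class=coupling,
    )


def attach_envelope(
    model: MetabolicModel, record: SolutionRecord, target: int, n_points: int = 21
) -> SolutionRecord:
    record.envelope = production_envelope(model, target, record.design, n_points)
    return record


def filter_pool(
    pool: list[SolutionRecord], threshold_fraction: float = 0.0
) -> list[SolutionRecord]:
    """Keep records with min production >= threshold_fraction * TMP (via the
    stored pct_tmp), deduplicate identical designs, and stable-sort by min
    production descending then lexicographic design.  Idempotent."""
    if not 0.0 <= threshold_fraction:
        raise ValueError("threshold_fraction must be nonnegative")
    seen: dict[tuple, SolutionRecord] = {}
    for rec in pool:
        if rec.pct_tmp >= 100.0 * threshold_fraction - 1e-9:
            seen.setdefault(rec.key(), rec)
    return sorted(seen.values(), key=lambda r: (-r.min_production, r.key()))


def knockout_frequency(
    pool: list[SolutionRecord], model: MetabolicModel
) -> tuple[pd.Series, pd.Series]:
    """Fraction of pool designs containing each knockout, and fraction with
    at least one knockout in each subsystem (a design with two knockouts in
    one subsystem counts once)."""
    if not pool:
        raise ValueError("empty solution pool")
    n = len(pool)
    per_reaction: dict[str, int] = {}
    per_subsystem: dict[str, int] = {}
    for rec in pool:
        subsystems = set()
        for rid in rec.knocked_ids:
            per_reaction[rid] = per_reaction.get(rid, 0) + 1
            subsystems.add(model.subsystems[model.index(rid)] or "(none)")
        for s in subsystems:
            per_subsystem[s] = per_subsystem.get(s, 0) + 1
    rxn = pd.Series({k: v / n for k, v in per_reaction.items()},
                    name="fraction").sort_values(ascending=False)
    sub = pd.Series({k: v / n for k, v in per_subsystem.items()},
                    name="fraction").sort_values(ascending=False)
    return rxn, sub


def pool_to_frame(pool: list[SolutionRecord]) -> pd.DataFrame:
    rows = [
        {
            "knockouts": ",".join(rec.knocked_ids) or "(none)",
            "n_knockouts": rec.design.n_knockouts,
            "growth": rec.growth_at_solution,
            "min_production": rec.min_production,
            "max_production": rec.max_production,
            "pct_tmp": rec.pct_tmp,
            "coupling": rec.coupling_class,
        }
        for rec in pool
    ]
    return pd.DataFrame(rows)
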