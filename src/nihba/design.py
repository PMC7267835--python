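"""High-level modelling interface.

:class:`InterdictionDesign` is constructed from a metabolic model and a
target exchange reaction; its :meth:`~InterdictionDesign.fit` runs the
strain-design search (hybrid Benders by default) and returns an
:class:`InterdictionResults` carrying the best design, the full solution
pool, the search trace and a ``summary()`` table.

    >>> from nihba import InterdictionDesign, make_toy_network
    >>> des = InterdictionDesign(make_toy_network("toy5"), target="PRD", K=1)
    >>> res = des.fit()
    >>> res.best_value
    1.0
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import pandas as pd

from .benders import HBAConfig, HBAResult, IterState, run_hba
from .errors import ConfigurationError
from .fba import production_envelope, solve_fba, theoretical_max_production
from .milp import (
    brute_force_interdiction,
    build_single_level_milp,
    sample_penalties,
    solve_direct,
)
from .model import MetabolicModel
from .preprocess import CandidateSet, select_candidates
from .reporting import SolutionRecord, evaluate_record, knockout_frequency, pool_to_frame

__all__ = ["InterdictionDesign", "InterdictionResults"]


class InterdictionDesign:
    """Network-interdiction strain-design problem on a metabolic model.

    Parameters
    ----------
    model : MetabolicModel
        The (possibly reduced) metabolic network.
    target : str or int
        Target exchange reaction whose guaranteed minimum flux is maximized.
    K : int
        Maximum allowable number of reaction knockouts.
    candidates : CandidateSet or sequence of reaction positions, optional
        Knockout candidates; selected automatically when omitted.
    n_c : int
        Carbon cutoff for automatic candidate selection (100 = off).
    min_growth_fraction : float
        Minimum growth requirement as a fraction of wild-type growth.
    require_gene_rule : bool
        Whether automatic selection drops reactions without gene rules.
    """

    def __init__(
        self,
        model: MetabolicModel,
        target: str | int,
        K: int = 5,
        candidates: CandidateSet | tuple[int, ...] | None = None,
        n_c: int = 100,
        min_growth_fraction: float = 0.1,
        require_gene_rule: bool = True,
        keep_oxygen: bool = True,
        user_excludes: tuple[str, ...] = (),
        **config,
    ) -> None:
        self.model = model
        self.target = model.index(target) if isinstance(target, str) else int(target)
        if self.target == model.biomass_index:
            raise ConfigurationError("target must differ from the biomass reaction")
        wild = solve_fba(model)
        if not wild.optimal:
            raise ConfigurationError("wild-type FBA is infeasible")
        self.wild_type_growth = float(wild.objective_value)
        self.tmp = theoretical_max_production(model, self.target)
        growth_floor = config.pop("growth_floor", None)
        self.config = HBAConfig(
            K=K,
            min_growth_fraction=min_growth_fraction,
            growth_floor=growth_floor,
            **config,
        )
        self.growth_floor = (
            growth_floor
            if growth_floor is not None
            else min_growth_fraction * self.wild_type_growth
        )
        if candidates is None:
            candidates = select_candidates(
                model,
                target=self.target,
                n_c=n_c,
                growth_floor=self.growth_floor,
                keep_oxygen=keep_oxygen,
                require_gene_rule=require_gene_rule,
                user_excludes=user_excludes,
            )
        self.candidates = (
            candidates
            if isinstance(candidates, CandidateSet)
            else CandidateSet(tuple(int(j) for j in candidates), n_c)
        )

    @classmethod
    def from_file(cls, path, target: str, dialect: str | None = None, **kw):
        from .io import load_model

        return cls(load_model(path, dialect), target, **kw)

    # ------------------------------------------------------------------
    def fit(self, method: str = "hba", time_limit: float | None = None
            ) -> "InterdictionResults":
        """Search for growth-coupled knockout designs.

        method : {"hba", "direct", "brute"}
            "hba" runs the hybrid Benders algorithm (returns the whole
            solution pool); "direct" hands the single-level MILP to the
            backend; "brute" enumerates all designs (guarded, fixtures only).
        """
        cfg = self.config
        if time_limit is not None:
            cfg = dataclasses.replace(cfg, time_limit=time_limit)
        cfg = dataclasses.replace(cfg, growth_floor=self.growth_floor)
        if method == "hba":
            hba = run_hba(self.model, self.candidates, self.target, cfg)
            return InterdictionResults(self, hba, method)
        if method == "direct":
            milp = build_single_level_milp(
                self.model, self.candidates, self.target, cfg.K,
                sample_penalties(self.candidates.n_s, cfg.penalty_seed,
                                 *cfg.m_range),
                self.growth_floor,
            )
            value, design, status = solve_direct(milp, time_limit=cfg.time_limit)
            records = []
            if design is not None:
                rec = evaluate_record(self.model, design, self.target, tmp=self.tmp)
                rec.min_production_at_floor = value
                records = [rec]
            hba = HBAResult(records[0] if records else None, records, [],
                            status, self.tmp, self.growth_floor)
            return InterdictionResults(self, hba, method)
        if method == "brute":
            value, designs = brute_force_interdiction(
                self.model, self.candidates, cfg.K, self.target,
                self.growth_floor,
            )
            records = []
            for design in designs:
                rec = evaluate_record(self.model, design, self.target, tmp=self.tmp)
                rec.min_production_at_floor = value
                records.append(rec)
            hba = HBAResult(records[0] if records else None, records, [],
                            "optimal", self.tmp, self.growth_floor)
            return InterdictionResults(self, hba, method)
        raise ValueError(f"unknown method {method!r}")


@dataclass
class InterdictionResults:
    """Fitted strain-design results: best design, pool, trace, summaries."""

    problem: InterdictionDesign
    raw: HBAResult
    method: str

    # -- accessors ------------------------------------------------------
    @property
    def best(self) -> SolutionRecord | None:
        return self.raw.best

    @property
    def best_value(self) -> float | None:
        return self.raw.best_value

    @property
    def pool(self) -> list[SolutionRecord]:
        return self.raw.pool

    @property
    def trace(self) -> list[IterState]:
        return self.raw.trace

    @property
    def status(self) -> str:
        return self.raw.status

    def to_frame(self) -> pd.DataFrame:
        df = pool_to_frame(self.pool)
        if len(df):
            df.insert(
                4, "min_production_at_floor",
                [r.min_production_at_floor for r in self.pool],
            )
        return df

    def envelope(self, record: SolutionRecord | None = None, n_points: int = 21):
        rec = record or self.best
        design = rec.design if rec is not None else None
        return production_envelope(
            self.problem.model, self.problem.target, design, n_points
        )

    def knockout_frequency(self):
        return knockout_frequency(self.pool, self.problem.model)

    # -- presentation ---------------------------------------------------
    def summary(self, max_rows: int = 10) -> str:
        p = self.problem
        m = p.model
        lines = [
            "Network Interdiction Strain Design Results",
            "=" * 58,
            f"Model:               {m.name} ({m.n_metabolites} metabolites, "
            f"{m.n_reactions} reactions)",
            f"Target reaction:     {m.reaction_ids[p.target]}",
            f"Method:              {self.method} (status: {self.status})",
            f"Candidates (n_s):    {p.candidates.n_s} (carbon cutoff n_c = "
            f"{p.candidates.n_c})",
            f"Max knockouts K:     {p.config.K}",
            f"Wild-type growth:    {p.wild_type_growth:.4f} 1/h",
            f"Growth floor:        {p.growth_floor:.4f} 1/h",
            f"Theoretical max:     {p.tmp:.4f} mmol/gDW/h",
            f"Solutions in pool:   {len(self.pool)}",
            "-" * 58,
        ]
        if self.best is None:
            lines.append("No feasible design found.")
        else:
            df = self.to_frame().head(max_rows)
            lines.append(df.to_string(
                index=False,
                float_format=lambda x: f"{x:.4f}",
            ))
            if len(self.pool) > max_rows:
                lines.append(f"... ({len(self.pool) - max_rows} more)")
        return "\n".join(lines)

    def __repr__(self) -> str:
        best = "none" if self.best is None else ",".join(self.best.knocked_ids)
        return (
            f"<InterdictionResults method={self.method} status={self.status} "
            f"best=[{best}] pool={len(self.pool)}>"
        )
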