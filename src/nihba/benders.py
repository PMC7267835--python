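"""Hybrid Benders algorithm (HBA) for the interdiction MILP.

The single-level MILP is split into a binary master problem (MP) over the
knockout vector ``y`` and a surrogate ``z``, and a continuous slave problem
(SP) — the single-level constraints with ``y`` fixed.  Each slave solve
yields a Benders cut: an *optimality cut* ``z <= (b - By)'pi + b_eq'lam``
from the optimal duals when the slave is feasible (its value is the design's
guaranteed minimum production), or a *feasibility cut*
``(b - By)'pi + b_eq'lam >= 0`` from a Farkas ray when the design cannot
reach the growth floor.

Two accelerations make the loop practical:

* **Pareto-optimal cuts** — the slave is solved once per iteration with the
  right-hand side perturbed toward a core point ``ŷ`` in the relative
  interior of the binary hull, ``(b - Bȳ) + mu (b - Bŷ)`` with
  ``mu = 1e-8``; the resulting dual is dual-feasible for the unperturbed
  slave, so the cut is valid, and it is not dominated at the core point.
  ``ŷ`` is dragged toward each new feasible ``ȳ`` by averaging.
* **Local branching** — the MP is restricted to a Hamming ball
  ``Delta_H(y, y') <= r - 1`` around the incumbent ``y'``.  An empty ball is
  permanently excluded with the reverse inequality ``Delta_H >= rho`` and the
  radius grown; a ball whose MP bound falls to the incumbent value is
  likewise reversed (it cannot contain a better design).  Because reversed
  regions are only ever discarded when they are proven dominated, a master
  solve with no active ball gives a valid global upper bound, and final
  convergence is certified by an exact unbranched master solve.

The MP is allowed to stop early at an absolute gap of ``1 + 300/(sqrt(iter)
+ 1)`` flux units, which shrinks toward 1 as the iteration counter grows;
every feasible design meeting the production threshold is stored in the
solution pool as it is discovered.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import _solver
from .errors import ConfigurationError, InfeasibleModelError
from .fba import follower_min_production, solve_fba, theoretical_max_production
from .milp import SingleLevelMILP, build_single_level_milp, sample_penalties
from .model import DesignVector, MetabolicModel
from .preprocess import CandidateSet

logger = logging.getLogger(__name__)

__all__ = [
    "HBAConfig",
    "BendersCut",
    "CorePoint",
    "BranchState",
    "IterState",
    "HBAResult",
    "hamming_distance",
    "update_core_point",
    "mip_gap",
    "solve_master",
    "solve_slave",
    "run_hba",
]


@dataclass(frozen=True)
class HBAConfig:
    """Run configuration for the hybrid Benders search."""

    K: int = 5
    min_growth_fraction: float = 0.1  # of wild-type growth, if growth_floor unset
    growth_floor: float | None = None  # absolute floor in 1/h
    threshold_fraction: float = 0.0  # pool admission: value >= fraction * TMP
    mu: float = 1e-8  # Pareto perturbation weight
    m_range: tuple[float, float] = (90.0, 110.0)
    penalty_seed: int = 2020
    r0: int = 3  # initial local-branching radius
    time_limit: float = 3600.0  # wall-clock budget, seconds
    max_iter: int = 10000
    closure_tol: float = 1e-4
    use_gap_schedule: bool = True
    recompute_exact: bool = True  # pool values re-evaluated at mu = 0


@dataclass
class BendersCut:
    """Affine cut in (z, y): optimality ``z <= constant - coef.y`` or
    feasibility ``constant - coef.y >= 0``."""

    kind: str  # {"optimality", "feasibility"}
    constant: float
    coef: np.ndarray  # per-candidate coefficients
    pi: np.ndarray | None = None  # dual extreme point / ray (diagnostics)

    def rhs_at(self, y: np.ndarray) -> float:
        return float(self.constant - self.coef @ np.asarray(y, dtype=float))

    def signature(self) -> tuple:
        return (self.kind, round(self.constant, 9),
                tuple(np.round(self.coef, 9)))


@dataclass
class CorePoint:
    """Fractional point in the relative interior of the feasible binary hull."""

    y_hat: np.ndarray
    mu: float = 1e-8

    def __post_init__(self):
        self.y_hat = np.asarray(self.y_hat, dtype=float)
        if np.any(self.y_hat <= 0.0) or np.any(self.y_hat >= 1.0):
            raise ValueError("core point must be strictly interior (0 < y < 1)")


@dataclass
class BranchState:
    """Local-branching state: incumbent reference, radius and the accumulated
    reverse (exclusion) inequalities."""

    y_prime: np.ndarray | None  # None = no active Hamming ball
    r: int
    reverses: list = field(default_factory=list)  # [(y_ref, rho)], Delta >= rho

    def __post_init__(self):
        if self.r < 1:
            raise ValueError("branching radius must be >= 1")


@dataclass
class IterState:
    iteration: int
    z_upper: float
    z_lower: float
    cut_kind: str
    r: int
    pool_size: int
    elapsed: float
    y_bar: tuple = ()


@dataclass
class HBAResult:
    best: "object | None"  # SolutionRecord (import cycle avoided)
    pool: list
    trace: list[IterState]
    status: str
    tmp: float
    growth_floor: float
    cuts: list[BendersCut] = field(default_factory=list)

    @property
    def best_value(self) -> float | None:
        """Guaranteed minimum production of the best design at the growth
        floor (the interdiction objective)."""
        return None if self.best is None else float(self.best.min_production_at_floor)

    def __iter__(self):  # (best, pool, trace) unpacking
        return iter((self.best, self.pool, self.trace))


def hamming_distance(y, y_prime) -> int:
    """Number of differing coordinates between two binary vectors."""
    y = np.asarray(y)
    y_prime = np.asarray(y_prime)
    if y.shape != y_prime.shape:
        raise ValueError("length mismatch in Hamming distance")
    return int(np.sum(y != y_prime))


def update_core_point(current: CorePoint, y_bar) -> CorePoint:
    """Average the core point with a new feasible binary point; interiority
    is preserved from an interior start."""
    y_bar = np.asarray(y_bar, dtype=float)
    return CorePoint(0.5 * (current.y_hat + y_bar), current.mu)


def mip_gap(iteration: int) -> float:
    """Early-termination gap for the MP: 1 + 300/(sqrt(iter) + 1), an
    absolute gap in flux units, decreasing toward 1."""
    if iteration < 0:
        raise ValueError("iteration must be nonnegative")
    return 1.0 + 300.0 / (np.sqrt(iteration) + 1.0)


@dataclass
class MasterSolution:
    status: str
    y_bar: np.ndarray | None
    z_bound: float | None  # proven upper bound on z in the region
    z_value: float | None  # incumbent objective value


def solve_master(
    cuts: list[BendersCut],
    branch: BranchState,
    K: int,
    z_cap: float,
    gap: float = 0.0,
    excluded: list | None = None,
    n_candidates: int | None = None,
) -> MasterSolution:
    """Solve the binary master: max z over the accumulated Benders cuts,
    the knockout budget, the active Hamming ball and reverse inequalities.

    ``gap`` is an absolute objective gap; it is converted to the backend's
    relative gap against ``z_cap``.  Infeasibility (empty branched region) is
    reported in the status for the caller to widen the radius.
    """
    if z_cap < 0:
        raise ValueError("z_cap must be nonnegative")
    if n_candidates is None:
        if branch.y_prime is not None:
            n_candidates = len(branch.y_prime)
        elif cuts:
            n_candidates = len(cuts[0].coef)
        else:
            raise ValueError("cannot infer candidate count")
    nc = n_candidates
    nv = nc + 1  # y ... , z last
    rows, lo_b, up_b = [], [], []

    def add_row(coef_y: np.ndarray, coef_z: float, upper: float):
        rows.append(np.concatenate([coef_y, [coef_z]]))
        up_b.append(upper)

    add_row(np.ones(nc), 0.0, float(K))
    for cut in cuts:
        if cut.kind == "optimality":
            add_row(cut.coef, 1.0, cut.constant)  # z + g.y <= a0
        else:
            add_row(cut.coef, 0.0, cut.constant)  # g.y <= a0
    if branch.y_prime is not None:
        yp = np.asarray(branch.y_prime, dtype=float)
        add_row(1.0 - 2.0 * yp, 0.0, branch.r - 1.0 - yp.sum())
    for y_ref, rho in branch.reverses:
        yr = np.asarray(y_ref, dtype=float)
        add_row(-(1.0 - 2.0 * yr), 0.0, yr.sum() - float(rho))
    for y_ex in excluded or ():
        yx = np.asarray(y_ex, dtype=float)
        add_row(-(1.0 - 2.0 * yx), 0.0, yx.sum() - 1.0)  # Delta >= 1

    A_ub = sp.csr_matrix(np.vstack(rows))
    b_ub = np.asarray(up_b, dtype=float)
    c = np.zeros(nv)
    c[-1] = 1.0
    bounds = [(0.0, 1.0)] * nc + [(0.0, z_cap)]
    integrality = np.concatenate([np.ones(nc), [0.0]])
    rel_gap = None
    if gap > 0:
        rel_gap = min(gap / max(z_cap, 1.0), 100.0)
    res = _solver.solve_milp(
        c, integrality, A_ub=A_ub, b_ub=b_ub, bounds=bounds,
        sense="max", rel_gap=rel_gap,
    )
    if res.x is None:
        return MasterSolution(res.status, None, None, None)
    y_bar = np.round(res.x[:nc]).astype(int)
    bound = min(float(res.bound), z_cap)
    return MasterSolution(res.status, y_bar, bound, float(res.objective))


def solve_slave(
    milp: SingleLevelMILP,
    y_bar: np.ndarray,
    core: CorePoint | None = None,
    recompute_exact: bool = True,
):
    """Solve the (Pareto-perturbed) slave at ``y_bar`` and derive a cut.

    Returns ``(kind, value, cut, x)``: an optimality cut with the design's
    guaranteed minimum production when the slave is feasible, or a
    feasibility cut from a Farkas ray of the unperturbed system otherwise.
    The reported value is always the unperturbed one: by default the design
    is re-evaluated with the exact follower LP.
    """
    y_bar = np.asarray(y_bar, dtype=float)
    rhs = milp.rhs(y_bar)
    if core is not None:
        rhs = rhs + core.mu * milp.rhs(core.y_hat)
    res = _solver.solve_lp(
        milp.c, A_eq=milp.A_eq, b_eq=milp.b_eq, A_ub=milp.A_ub, b_ub=rhs,
        bounds=milp.x_bounds, sense="max",
    )
    if res.status == _solver.OPTIMAL:
        value = float(res.objective)
        if recompute_exact:
            design = DesignVector(
                tuple(int(v) for v in np.round(y_bar)), milp.candidates, milp.K
            )
            exact = follower_min_production(
                milp.model, milp.target, design, milp.growth_floor
            )
            if exact.optimal:
                value = float(exact.objective_value)
        pi = np.maximum(res.duals_ub, 0.0)
        constant = float(milp.b @ pi + milp.b_eq @ res.duals_eq)
        coef = np.asarray((milp.B.T @ pi).ravel())
        cut = BendersCut("optimality", constant, coef, pi)
        return "optimality", value, cut, res.x
    if res.status != _solver.INFEASIBLE:
        raise InfeasibleModelError(
            f"slave dual is infeasible (primal {res.status}); the "
            "interdiction model is mis-specified"
        )
    ray = _solver.farkas_ray(milp.A_eq, milp.b_eq, milp.A_ub, milp.rhs(y_bar))
    if ray is None:
        # perturbation pushed a boundary-feasible system infeasible; retry
        # without the perturbation
        res0 = _solver.solve_lp(
            milp.c, A_eq=milp.A_eq, b_eq=milp.b_eq, A_ub=milp.A_ub,
            b_ub=milp.rhs(y_bar), bounds=milp.x_bounds, sense="max",
        )
        if res0.status == _solver.OPTIMAL:
            pi = np.maximum(res0.duals_ub, 0.0)
            constant = float(milp.b @ pi + milp.b_eq @ res0.duals_eq)
            coef = np.asarray((milp.B.T @ pi).ravel())
            return ("optimality", float(res0.objective),
                    BendersCut("optimality", constant, coef, pi), res0.x)
        raise InfeasibleModelError("no Farkas certificate for infeasible slave")
    lam, pi = ray
    constant = float(milp.b @ pi + milp.b_eq @ lam)
    coef = np.asarray((milp.B.T @ pi).ravel())
    return "feasibility", None, BendersCut("feasibility", constant, coef, pi), None


def run_hba(
    model: MetabolicModel,
    candidates: CandidateSet | tuple[int, ...],
    target: int,
    config: HBAConfig | None = None,
) -> HBAResult:
    """Run the hybrid Benders search and return the best design, the
    in-search solution pool, and the per-iteration trace."""
    from .reporting import evaluate_record  # local import to avoid a cycle

    cfg = config or HBAConfig()
    cand = tuple(candidates.indices if isinstance(candidates, CandidateSet)
                 else candidates)
    if not cand:
        raise ConfigurationError("candidate set is empty")
    nc = len(cand)

    wild = solve_fba(model)
    if not wild.optimal:
        raise InfeasibleModelError("wild-type FBA is infeasible")
    floor = (cfg.growth_floor if cfg.growth_floor is not None
             else cfg.min_growth_fraction * wild.objective_value)
    if wild.objective_value < floor - 1e-9:
        raise InfeasibleModelError("wild-type growth is below the growth floor")
    tmp = theoretical_max_production(model, target)
    penalties = sample_penalties(nc, cfg.penalty_seed, *cfg.m_range)
    slm = build_single_level_milp(model, cand, target, cfg.K, penalties, floor)

    z_cap = max(tmp, 0.0)
    cuts: list[BendersCut] = []
    cut_signatures: set = set()
    y_prime = np.zeros(nc, dtype=int)
    r = cfg.r0
    branch_active = True
    reverses: list[tuple[np.ndarray, int]] = []
    excluded: list[np.ndarray] = []
    core = CorePoint(np.full(nc, min(0.5, cfg.K / (nc + 1.0))), cfg.mu)
    z_lo = -np.inf
    z_up = z_cap
    best_key: tuple | None = None
    pool: dict[tuple, float] = {}
    visited: dict[tuple, int] = {}
    trace: list[IterState] = []
    status = "iteration_limit"
    start = time.monotonic()
    last_exact_unbranched = False

    def add_cut(cut: BendersCut) -> None:
        sig = cut.signature()
        if sig not in cut_signatures:
            cut_signatures.add(sig)
            cuts.append(cut)

    for it in range(cfg.max_iter):
        elapsed = time.monotonic() - start
        if elapsed > cfg.time_limit:
            status = "time_limit"
            break
        force_exact = any(v >= 3 for v in visited.values())
        gap = 0.0
        if cfg.use_gap_schedule and not force_exact and branch_active:
            gap = mip_gap(it)
        branch = BranchState(y_prime if branch_active else None, r, reverses)
        mp = solve_master(cuts, branch, cfg.K, z_cap, gap, excluded, nc)

        if mp.status == _solver.INFEASIBLE:
            if branch_active:
                # empty/exhausted Hamming ball: exclude it (radius frozen at
                # failure time) and widen the search ring
                rho = r + 1
                covered = any(
                    np.array_equal(yr, y_prime) and rr <= rho
                    for yr, rr in reverses
                )
                if not covered:
                    reverses.append((y_prime.copy(), rho))
                r += 1
                if r - 1 >= nc:
                    branch_active = False  # ball covers everything: drop it
                trace.append(IterState(it, _fin(z_up), _fin(z_lo), "none", r,
                                       len(pool), elapsed))
                continue
            # no active ball and still infeasible: every design is excluded
            # by cuts/reverses, i.e. the space is exhausted
            z_up = max(z_lo, 0.0) if np.isfinite(z_lo) else 0.0
            status = "optimal" if np.isfinite(z_lo) else "infeasible"
            trace.append(IterState(it, _fin(z_up), _fin(z_lo), "none", r,
                                   len(pool), elapsed))
            break

        y_bar = mp.y_bar
        key = tuple(int(v) for v in y_bar)
        cut_kind = "cached"

        if not branch_active:
            # reversed regions are dominated, so this bound is global
            z_up = min(z_up, max(mp.z_bound, z_lo if np.isfinite(z_lo) else 0.0))
            last_exact_unbranched = gap == 0.0
        else:
            last_exact_unbranched = False

        if key not in visited:
            visited[key] = 1
            kind, value, cut, _x = solve_slave(
                slm, y_bar, core, recompute_exact=cfg.recompute_exact
            )
            add_cut(cut)
            cut_kind = kind
            if kind == "optimality":
                core = update_core_point(core, y_bar)
                if value >= cfg.threshold_fraction * tmp - 1e-9:
                    pool[key] = value
                improved = value > z_lo + 1e-9
                if improved:
                    z_lo = value
                    best_key = key
                    y_prime = np.array(key, dtype=int)
                    r = cfg.r0
                    branch_active = True
                elif mp.z_value is not None and mp.z_value < value - 1e-9:
                    # MP value at y_bar worse than the slave value: recentre
                    y_prime = np.array(key, dtype=int)
                    r = cfg.r0
                    branch_active = True
        else:
            visited[key] += 1
            if visited[key] == 2:
                # repeat under early termination: pin it with an exact cut
                kind, value, cut, _x = solve_slave(
                    slm, y_bar, core=None, recompute_exact=cfg.recompute_exact
                )
                add_cut(cut)
                cut_kind = f"{kind}(exact)"
            elif visited[key] >= 4:
                excluded.append(np.array(key, dtype=int))  # value already known

        # reverse the branch when its bound cannot beat the incumbent
        if branch_active and np.isfinite(z_lo) and mp.z_bound <= z_lo + cfg.closure_tol:
            reverses.append((y_prime.copy(), r))
            branch_active = False

        trace.append(
            IterState(it, _fin(z_up), _fin(z_lo), cut_kind, r,
                      len(pool), elapsed, key)
        )
        if (
            np.isfinite(z_lo)
            and last_exact_unbranched
            and z_up - z_lo <= cfg.closure_tol
        ):
            status = "optimal"
            break
    else:
        status = "iteration_limit"

    records = []
    for key, value in pool.items():
        design = DesignVector(key, cand, cfg.K)
        rec = evaluate_record(model, design, target, tmp=tmp)
        rec.min_production_at_floor = value
        records.append(rec)
    records.sort(key=lambda rec: (-rec.min_production_at_floor,
                                  rec.design.y))
    best = records[0] if records else None
    return HBAResult(best, records, trace, status, tmp, floor, cuts)


def _fin(x: float) -> float:
    return float(x) if np.isfinite(x) else float("nan")


def default_config(**overrides) -> HBAConfig:
    return HBAConfig(**overrides)
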