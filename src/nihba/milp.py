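"""The network-interdiction MILP machinery.

The strain-design game is a max–min problem: the engineer picks a binary
knockout vector ``y`` (at most ``K`` ones over the candidate set J̄) to
maximize the *minimum* target flux the host can settle on,

    max_y  min_v  c_P' v   s.t.  S v = 0,  bounds,  v_j = 0 where y_j = 1,

with a minimum-growth requirement in the inner problem.  The knockout
restriction is folded into the inner objective in Lagrangian form,
``min c_P'v + sum_j M_j u_j y_j`` with ``u_j >= |v_j|`` and penalties
``M_j ~ U(90, 110)``, which linearizes via auxiliary magnitudes ``u``.
Applying LP duality to the penalized follower then yields a single-level
MILP: follower primal feasibility, follower dual feasibility, a
strong-duality row linking the two objectives, coupling rows
``u_j + U_j y_j <= U_j`` (which pin ``v_j = 0`` when ``y_j = 1``) and
dual-capacity rows relaxed by ``M_j y_j``, where ``U_j = max(|lb_j|,|ub_j|)``.

Continuous variable layout of the single-level problem (in order):

    v (n, free)      flux vector
    u (n, >= 0)      |v| magnitudes, capped by U
    lam (m, free)    follower duals of S v = 0
    alpha (n, >= 0)  duals of  v - u <= 0
    beta  (n, >= 0)  duals of -v - u <= 0
    gamma (n, >= 0)  duals of  v <= ub
    delta (n, >= 0)  duals of -v <= -lb
    eps   (n, >= 0)  duals of  u <= U
    phi   (1, >= 0)  dual of the growth floor -v_bio <= -floor

For a fixed feasible binary ``y`` the continuous restriction is an LP whose
optimum equals the follower's minimum (strong duality) — this is the Benders
slave problem, with all y-dependence confined to the right-hand side
``b - B y``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import _solver
from .errors import CapabilityError
from .fba import FluxSolution, follower_min_production
from .model import DesignVector, MetabolicModel
from .preprocess import CandidateSet

__all__ = [
    "PenaltyVector",
    "FollowerLP",
    "SingleLevelMILP",
    "sample_penalties",
    "build_follower_lp",
    "build_single_level_milp",
    "solve_direct",
    "brute_force_interdiction",
]

DEFAULT_PENALTY_SEED = 2020
BRUTE_FORCE_GUARD = 5000


@dataclass(frozen=True)
class PenaltyVector:
    """Per-candidate Lagrange multipliers M_j (dimensionless, ~100)."""

    M: np.ndarray
    seed: int

    def __post_init__(self):
        object.__setattr__(self, "M", np.asarray(self.M, dtype=float))


def sample_penalties(
    n_candidates: int,
    seed: int = DEFAULT_PENALTY_SEED,
    low: float = 90.0,
    high: float = 110.0,
) -> PenaltyVector:
    """Independent uniform draws in [low, high]; reproducible per seed."""
    if low > high:
        raise ValueError("low must not exceed high")
    rng = np.random.default_rng(seed)
    return PenaltyVector(rng.uniform(low, high, size=n_candidates), seed)


@dataclass
class FollowerLP:
    """The penalized (Lagrangian) follower LP for a fixed design."""

    model: MetabolicModel
    target: int
    c: np.ndarray  # objective over [v; u_cand]
    A_ub: sp.csr_matrix
    b_ub: np.ndarray
    bounds: list
    candidates: tuple[int, ...]

    def solve(self) -> FluxSolution:
        n = self.model.n_reactions
        res = _solver.solve_lp(
            self.c,
            A_eq=sp.hstack(
                [self.model.S, sp.csr_matrix((self.model.n_metabolites,
                                              len(self.candidates)))]
            ),
            b_eq=np.zeros(self.model.n_metabolites),
            A_ub=self.A_ub,
            b_ub=self.b_ub,
            bounds=self.bounds,
            sense="min",
        )
        if res.status != _solver.OPTIMAL:
            return FluxSolution(None, None, res.status)
        return FluxSolution(res.x[:n], float(res.objective), res.status)


def build_follower_lp(
    model: MetabolicModel,
    target: int,
    penalties: PenaltyVector,
    design: DesignVector,
    growth_floor: float = 0.0,
) -> FollowerLP:
    """Build ``min c_P v + sum_j M_j y_j u_j`` over the *unknocked* feasible
    region: the knockouts act only through the penalty.  With sufficiently
    large M its optimum equals the exact follower minimum."""
    if len(penalties.M) < len(design.candidates):
        raise ValueError("penalty vector does not cover all candidates")
    n = model.n_reactions
    cand = design.candidates
    nc = len(cand)
    c = np.zeros(n + nc)
    c[target] = 1.0
    c[n:] = penalties.M[:nc] * np.asarray(design.y, float)
    U = np.maximum(np.abs(model.lb), np.abs(model.ub))
    rows, cols, data = [], [], []
    for k, j in enumerate(cand):
        rows += [2 * k, 2 * k, 2 * k + 1, 2 * k + 1]
        cols += [j, n + k, j, n + k]
        data += [1.0, -1.0, -1.0, -1.0]  # v_j - u_k <= 0 ; -v_j - u_k <= 0
    A_ub = sp.csr_matrix((data, (rows, cols)), shape=(2 * nc, n + nc))
    b_ub = np.zeros(2 * nc)
    bounds = list(zip(model.lb, model.ub))
    bio = model.biomass_index
    bounds[bio] = (max(model.lb[bio], growth_floor), model.ub[bio])
    bounds += [(0.0, U[j]) for j in cand]
    return FollowerLP(model, target, c, A_ub, b_ub, bounds, cand)


@dataclass
class SingleLevelMILP:
    """The LP-duality single-level reformulation in block form.

    All y-dependence sits in the inequality right-hand side ``b - B y``;
    ``A_eq x = b_eq`` and ``A_ub x <= b - B y`` describe the continuous part,
    and the binary part adds ``sum y <= K``.
    """

    model: MetabolicModel
    candidates: tuple[int, ...]
    target: int
    K: int
    penalties: PenaltyVector
    growth_floor: float
    c: np.ndarray  # objective over x (max sense)
    A_eq: sp.csr_matrix
    b_eq: np.ndarray
    A_ub: sp.csr_matrix
    b: np.ndarray
    B: sp.csr_matrix  # shape (rows(A_ub), n_candidates)
    x_bounds: list
    U: np.ndarray
    row_labels: dict = field(default_factory=dict)

    @property
    def n_vars(self) -> int:
        return len(self.c)

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)

    def rhs(self, y: np.ndarray) -> np.ndarray:
        return self.b - self.B @ np.asarray(y, dtype=float)

    def split(self, x: np.ndarray) -> dict[str, np.ndarray]:
        n, m = self.model.n_reactions, self.model.n_metabolites
        parts, off = {}, 0
        for name, size in [
            ("v", n), ("u", n), ("lam", m), ("alpha", n), ("beta", n),
            ("gamma", n), ("delta", n), ("eps", n), ("phi", 1),
        ]:
            parts[name] = x[off: off + size]
            off += size
        return parts

    def duality_residual(self, x: np.ndarray) -> float:
        """|follower primal objective - follower dual objective| at x."""
        p = self.split(x)
        n = self.model.n_reactions
        primal = p["v"][self.target]
        dual = (
            -self.model.ub @ p["gamma"]
            + self.model.lb @ p["delta"]
            - self.U @ p["eps"]
            + self.growth_floor * p["phi"][0]
        )
        return float(abs(primal - dual))

    def write_lp(self, path) -> None:
        """Dump the MILP in CPLEX LP file format for external inspection."""
        n_y = self.n_candidates
        lines = ["Maximize", " obj: " + _lp_expr(self.c, "x", ""), "Subject To"]
        A_eq = self.A_eq.tocsr()
        for i in range(A_eq.shape[0]):
            row = A_eq.getrow(i)
            expr = _lp_terms(row, "x")
            lines.append(f" e{i}: {expr} = {self.b_eq[i]:g}")
        A_ub, B = self.A_ub.tocsr(), self.B.tocsr()
        for i in range(A_ub.shape[0]):
            expr = _lp_terms(A_ub.getrow(i), "x")
            yexpr = _lp_terms(B.getrow(i), "y")
            joined = expr + ((" + " + yexpr) if yexpr else "")
            lines.append(f" c{i}: {joined} <= {self.b[i]:g}")
        lines.append(
            " k: " + " + ".join(f"y{k}" for k in range(n_y)) + f" <= {self.K}"
        )
        lines.append("Bounds")
        for j, (lo, hi) in enumerate(self.x_bounds):
            lo_s = "-inf" if lo is None or lo == -np.inf else f"{lo:g}"
            hi_s = "+inf" if hi is None or hi == np.inf else f"{hi:g}"
            lines.append(f" {lo_s} <= x{j} <= {hi_s}")
        lines.append("Binary")
        lines.append(" " + " ".join(f"y{k}" for k in range(n_y)))
        lines.append("End")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def _lp_terms(row, prefix: str) -> str:
    coo = row.tocoo()
    terms = [f"{v:+g} {prefix}{j}" for j, v in zip(coo.col, coo.data)]
    return " ".join(terms)


def _lp_expr(c, prefix, _unused) -> str:
    return " ".join(f"{v:+g} {prefix}{j}" for j, v in enumerate(c) if v != 0)


def build_single_level_milp(
    model: MetabolicModel,
    candidates: CandidateSet | tuple[int, ...],
    target: int,
    K: int,
    penalties: PenaltyVector | None = None,
    growth_floor: float = 0.0,
) -> SingleLevelMILP:
    """Assemble the single-level MILP blocks (see module docstring)."""
    cand = tuple(candidates.indices if isinstance(candidates, CandidateSet)
                 else candidates)
    if not cand:
        raise ValueError("candidate set is empty")
    if K < 0:
        raise ValueError("K must be nonnegative")
    if penalties is None:
        penalties = sample_penalties(len(cand))
    if len(penalties.M) < len(cand):
        raise ValueError("penalty vector does not cover all candidates")

    n, m = model.n_reactions, model.n_metabolites
    nc = len(cand)
    U = np.maximum(np.abs(model.lb), np.abs(model.ub))
    bio = model.biomass_index
    c_P = np.zeros(n)
    c_P[target] = 1.0

    # column offsets
    o_v, o_u, o_lam = 0, n, 2 * n
    o_a, o_b, o_g = 2 * n + m, 3 * n + m, 4 * n + m
    o_d, o_e, o_phi = 5 * n + m, 6 * n + m, 7 * n + m
    N = 7 * n + m + 1

    def eye(offset, scale=1.0):
        return sp.coo_matrix(
            ([scale] * n, (range(n), [offset + r for r in range(n)])),
            shape=(n, N),
        )

    S = model.S.tocoo()

    # --- equalities ------------------------------------------------------
    # E1: S v = 0
    E1 = sp.coo_matrix((S.data, (S.row, S.col + o_v)), shape=(m, N))
    # E2: S' lam + alpha - beta + gamma - delta - e_bio phi = -c_P
    St = model.S.T.tocoo()
    blocks = [
        sp.coo_matrix((St.data, (St.row, St.col + o_lam)), shape=(n, N)),
        eye(o_a, 1.0),
        eye(o_b, -1.0),
        eye(o_g, 1.0),
        eye(o_d, -1.0),
        sp.coo_matrix(([-1.0], ([bio], [o_phi])), shape=(n, N)),
    ]
    E2 = sum(blocks[1:], blocks[0])
    A_eq = sp.vstack([E1, E2]).tocsr()
    b_eq = np.concatenate([np.zeros(m), -c_P])

    # --- inequalities A x <= b - B y -------------------------------------
    rows_list, b_list, B_rows = [], [], []

    def add(rows, bvals, Bblock, label):
        rows_list.append(rows)
        b_list.append(np.atleast_1d(np.asarray(bvals, dtype=float)))
        B_rows.append(Bblock)

    zeros_B = lambda k: sp.csr_matrix((k, nc))

    # R1: v - u <= 0 ; R2: -v - u <= 0
    add(eye(o_v, 1.0) + eye(o_u, -1.0), np.zeros(n), zeros_B(n), "abs_pos")
    add(eye(o_v, -1.0) + eye(o_u, -1.0), np.zeros(n), zeros_B(n), "abs_neg")
    # R3/R4: flux bounds as rows (their duals gamma/delta are cut-bearing)
    add(eye(o_v, 1.0), model.ub, zeros_B(n), "ub")
    add(eye(o_v, -1.0), -model.lb, zeros_B(n), "lb")
    # R5: u <= U
    add(eye(o_u, 1.0), U, zeros_B(n), "u_cap")
    # R6: -v_bio <= -growth_floor
    add(
        sp.coo_matrix(([-1.0], ([0], [o_v + bio])), shape=(1, N)),
        [-growth_floor],
        zeros_B(1),
        "growth_floor",
    )
    # R7: u_j <= U_j - U_j y_j  (coupling; forces v_j = 0 when y_j = 1)
    R7 = sp.coo_matrix(
        (np.ones(nc), (range(nc), [o_u + j for j in cand])), shape=(nc, N)
    )
    B7 = sp.coo_matrix(
        ([U[j] for j in cand], (range(nc), range(nc))), shape=(nc, nc)
    ).tocsr()
    add(R7, [U[j] for j in cand], B7, "coupling")
    # R8: alpha + beta - eps <= M y (candidates) / <= 0 (non-candidates)
    R8 = eye(o_a, 1.0) + eye(o_b, 1.0) + eye(o_e, -1.0)
    B8 = sp.coo_matrix(
        (-penalties.M[:nc], ([cand[k] for k in range(nc)], range(nc))),
        shape=(n, nc),
    ).tocsr()
    add(R8, np.zeros(n), B8, "dual_capacity")
    # R9: strong duality  c_P v + ub' gamma - lb' delta + U' eps - gf phi <= 0
    r9 = np.zeros(N)
    r9[o_v + target] = 1.0
    r9[o_g: o_g + n] = model.ub
    r9[o_d: o_d + n] = -model.lb
    r9[o_e: o_e + n] = U
    r9[o_phi] = -growth_floor
    add(sp.csr_matrix(r9), [0.0], zeros_B(1), "strong_duality")

    A_ub = sp.vstack(rows_list).tocsr()
    b = np.concatenate(b_list)
    B = sp.vstack(B_rows).tocsr()

    # row-label offsets for diagnostics
    off = 0
    row_labels = {}
    for label, block in zip(
        ["abs_pos", "abs_neg", "ub", "lb", "u_cap", "growth_floor",
         "coupling", "dual_capacity", "strong_duality"],
        rows_list,
    ):
        row_labels[label] = (off, off + block.shape[0])
        off += block.shape[0]

    x_bounds = (
        [(None, None)] * n          # v (bounded by rows)
        + [(0.0, None)] * n         # u
        + [(None, None)] * m        # lam
        + [(0.0, None)] * (5 * n)   # alpha..eps
        + [(0.0, None)]             # phi
    )
    c = np.zeros(N)
    c[o_v + target] = 1.0

    # lam/duals need finite boxes only for pathological models; HiGHS copes.
    return SingleLevelMILP(
        model=model,
        candidates=cand,
        target=target,
        K=K,
        penalties=penalties,
        growth_floor=growth_floor,
        c=c,
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=A_ub,
        b=b,
        B=B,
        x_bounds=x_bounds,
        U=U,
        row_labels=row_labels,
    )


def solve_direct(
    milp: SingleLevelMILP,
    time_limit: float | None = None,
    exact_value: bool = True,
) -> tuple[float | None, DesignVector | None, str]:
    """Solve the single-level MILP directly with the MILP backend (the
    baseline a modern solver would run on the reformulation).

    With ``exact_value`` (default) the returned objective is the incumbent
    design re-evaluated by the exact follower LP, which strips the MILP
    backend's feasibility slack from the reported production value.
    """
    N, nc = milp.n_vars, milp.n_candidates
    c_full = np.concatenate([milp.c, np.zeros(nc)])
    A_eq = sp.hstack([milp.A_eq, sp.csr_matrix((milp.A_eq.shape[0], nc))])
    A_ub = sp.hstack([milp.A_ub, milp.B])
    k_row = sp.hstack(
        [sp.csr_matrix((1, N)), sp.csr_matrix(np.ones((1, nc)))]
    )
    A_ub = sp.vstack([A_ub, k_row]).tocsr()
    b_ub = np.concatenate([milp.b, [float(milp.K)]])
    bounds = milp.x_bounds + [(0.0, 1.0)] * nc
    integrality = np.concatenate([np.zeros(N), np.ones(nc)])
    res = _solver.solve_milp(
        c_full,
        integrality,
        A_eq=A_eq,
        b_eq=milp.b_eq,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=bounds,
        sense="max",
        rel_gap=1e-9,
        time_limit=time_limit,
    )
    if res.x is None:
        return None, None, res.status
    y = np.round(res.x[N:]).astype(int)
    design = DesignVector(tuple(int(v) for v in y), milp.candidates, milp.K)
    value = float(res.objective)
    if exact_value:
        sol = follower_min_production(
            milp.model, milp.target, design, milp.growth_floor
        )
        if sol.optimal:
            value = float(sol.objective_value)
    return value, design, res.status


def brute_force_interdiction(
    model: MetabolicModel,
    candidates: CandidateSet | tuple[int, ...],
    K: int,
    target: int,
    growth_floor: float = 0.0,
    guard: int = BRUTE_FORCE_GUARD,
) -> tuple[float, list[DesignVector]]:
    """Exhaustive oracle: enumerate all designs of size <= K, evaluate the
    follower LP, return the best guaranteed minimum and every argmax design.
    Infeasible designs (growth floor unreachable) are skipped."""
    cand = tuple(candidates.indices if isinstance(candidates, CandidateSet)
                 else candidates)
    total = sum(math.comb(len(cand), k) for k in range(K + 1))
    if total > guard:
        raise CapabilityError(
            f"{total} subsets exceed the enumeration guard ({guard}); "
            "use the hybrid Benders algorithm instead"
        )
    best_value = -np.inf
    best: list[DesignVector] = []
    for k in range(K + 1):
        for combo in itertools.combinations(cand, k):
            design = DesignVector.from_knockouts(set(combo), cand, K)
            sol = follower_min_production(model, target, design, growth_floor)
            if not sol.optimal:
                continue
            val = sol.objective_value
            if val > best_value + 1e-9:
                best_value, best = val, [design]
            elif abs(val - best_value) <= 1e-9:
                best.append(design)
    if not best:
        raise CapabilityError("no feasible design at the growth floor")
    return float(best_value), best
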