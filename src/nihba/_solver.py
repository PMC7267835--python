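"""Thin HiGHS-backed LP/MILP layer.

Implements the backend contract the rest of the package relies on: given an
objective sense, linear constraints, bounds and an integrality mask, return a
status, primal values, LP duals, and (for infeasible LPs) a Farkas ray.
Everything is expressed in the canonical form

    optimize  c'x   s.t.  A_eq x = b_eq,  A_ub x <= b_ub,  lo <= x <= up.

Dual conventions follow the maximization reading: for a *max* problem the
inequality duals ``pi`` are nonnegative and the dual objective is
``b_ub' pi + b_eq' lam``; for a *min* problem signs flip accordingly.
scipy's ``linprog`` marginals are derivatives of the minimized objective, so
``pi = -marginals`` for a max problem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import LinearConstraint, linprog, milp

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"
ITERATION_LIMIT = "iteration_limit"
TIME_LIMIT = "time_limit"

_LP_STATUS = {0: OPTIMAL, 1: ITERATION_LIMIT, 2: INFEASIBLE, 3: UNBOUNDED, 4: "error"}


@dataclass
class LPResult:
    status: str
    x: np.ndarray | None
    objective: float | None
    duals_eq: np.ndarray | None = None
    duals_ub: np.ndarray | None = None


@dataclass
class MILPResult:
    status: str
    x: np.ndarray | None
    objective: float | None
    bound: float | None  # best proven bound on the objective (sense-corrected)


def solve_lp(
    c,
    A_eq=None,
    b_eq=None,
    A_ub=None,
    b_ub=None,
    bounds=None,
    sense: str = "min",
) -> LPResult:
    c = np.asarray(c, dtype=float)
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(
        sign * c,
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=bounds if bounds is not None else [(None, None)] * len(c),
        method="highs",
    )
    status = _LP_STATUS.get(res.status, "error")
    if status != OPTIMAL:
        return LPResult(status, None, None)
    # marginals are d(min obj)/d(rhs); for a max problem the dual values are
    # their negatives, for a min problem the marginals themselves
    duals_eq = sign * res.eqlin.marginals if A_eq is not None else None
    duals_ub = sign * res.ineqlin.marginals if A_ub is not None else None
    return LPResult(OPTIMAL, res.x, sign * res.fun, duals_eq, duals_ub)


def farkas_ray(A_eq, b_eq, A_ub, b_ub) -> tuple[np.ndarray, np.ndarray] | None:
    """Certificate of infeasibility for {A_eq x = b_eq, A_ub x <= b_ub}.

    Returns ``(lam, pi)`` with ``pi >= 0``, ``A_eq' lam + A_ub' pi = 0`` and
    ``b_eq' lam + b_ub' pi < 0``, i.e. an extreme ray of the dual cone proving
    the primal empty; ``None`` if no certificate is found (primal feasible).
    The ray is found by minimizing ``b_eq' lam + b_ub' pi`` over the
    normalized dual cone ``sum(pi) <= 1``.
    """
    A_eq = sp.csr_matrix(A_eq)
    A_ub = sp.csr_matrix(A_ub)
    m_eq, n = A_eq.shape
    m_ub = A_ub.shape[0]
    # variables: lam (free, m_eq), pi (>= 0, m_ub)
    c = np.concatenate([np.asarray(b_eq, float), np.asarray(b_ub, float)])
    A = sp.hstack([A_eq.T, A_ub.T], format="csr")  # n rows: A' [lam; pi] = 0
    norm = sp.hstack(
        [sp.csr_matrix((1, m_eq)), sp.csr_matrix(np.ones((1, m_ub)))], format="csr"
    )
    # lam needs a box for HiGHS to stay bounded; the cone is scale-invariant.
    bounds = [(-1e6, 1e6)] * m_eq + [(0, None)] * m_ub
    res = linprog(
        c,
        A_eq=A,
        b_eq=np.zeros(n),
        A_ub=norm,
        b_ub=[1.0],
        bounds=bounds,
        method="highs",
    )
    if res.status != 0 or res.fun > -1e-9:
        return None
    lam = res.x[:m_eq]
    pi = np.maximum(res.x[m_eq:], 0.0)
    return lam, pi


def solve_milp(
    c,
    integrality,
    A_eq=None,
    b_eq=None,
    A_ub=None,
    b_ub=None,
    bounds=None,
    sense: str = "min",
    rel_gap: float | None = None,
    time_limit: float | None = None,
) -> MILPResult:
    c = np.asarray(c, dtype=float)
    sign = -1.0 if sense == "max" else 1.0
    constraints = []
    if A_eq is not None and sp.csr_matrix(A_eq).shape[0]:
        b_eq = np.asarray(b_eq, float)
        constraints.append(LinearConstraint(A_eq, b_eq, b_eq))
    if A_ub is not None and sp.csr_matrix(A_ub).shape[0]:
        constraints.append(
            LinearConstraint(A_ub, -np.inf, np.asarray(b_ub, float))
        )
    if bounds is None:
        lo, up = np.full(len(c), -np.inf), np.full(len(c), np.inf)
    else:
        lo = np.array([-np.inf if b[0] is None else b[0] for b in bounds])
        up = np.array([np.inf if b[1] is None else b[1] for b in bounds])
    options: dict = {}
    if rel_gap is not None:
        options["mip_rel_gap"] = float(rel_gap)
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    res = milp(
        c=sign * c,
        constraints=constraints,
        integrality=np.asarray(integrality),
        bounds=(lo, up),
        options=options,
    )
    if res.status == 2:
        return MILPResult(INFEASIBLE, None, None, None)
    if res.status == 3:
        return MILPResult(UNBOUNDED, None, None, None)
    if res.x is None:
        return MILPResult("error" if res.status == 4 else TIME_LIMIT, None, None, None)
    status = OPTIMAL if res.status == 0 else TIME_LIMIT
    bound = getattr(res, "mip_dual_bound", None)
    if bound is None:
        bound = res.fun
    return MILPResult(status, res.x, sign * res.fun, sign * bound)
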