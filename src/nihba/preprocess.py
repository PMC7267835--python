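"""Model reduction and candidate-knockout selection.

Genome-scale models are pruned before the interdiction search: blocked
(dead-end) reactions are removed, maximal linear chains are compressed into
single pseudo-reactions, and the knockout candidate set J̄ is assembled by a
sequence of exclusion rules — biomass, target, exchange reactions (optionally
keeping oxygen uptake, whose knockout encodes the anaerobic switch), reactions
without gene association, reactions essential at the growth floor, explicit
user excludes, and the carbon filter: any reaction touching a metabolite with
more than ``n_c`` carbon atoms is dropped (``n_c = 100`` disables the rule).
Every rule is a switch and per-rule removal counts are logged so candidate-set
sizes can be compared across configurations.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .errors import ConfigurationError, FormatError, InfeasibleModelError
from .model import DesignVector, MetabolicModel
from .fba import solve_fba

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateSet",
    "carbon_count",
    "remove_dead_ends",
    "compress_linear_chains",
    "essential_reactions",
    "select_candidates",
]

_ELEMENT_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class CandidateSet:
    """Candidate knockout positions J̄ with the carbon cutoff that produced
    them; ``n_s`` is the candidate-set size."""

    indices: tuple[int, ...]
    n_c: int
    exclusion_counts: dict | None = None

    def __post_init__(self):
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("candidate indices must be distinct")

    @property
    def n_s(self) -> int:
        return len(self.indices)

    def ids(self, model: MetabolicModel) -> list[str]:
        return [model.reaction_ids[j] for j in self.indices]


def carbon_count(formula: str) -> int:
    """Number of carbon atoms in a chemical formula string.

    Empty or missing formulas count as zero (with a logged warning), so
    unannotated metabolites never trigger the carbon filter.
    """
    if not formula:
        logger.warning("empty chemical formula treated as carbon-free")
        return 0
    pos, count = 0, 0
    for match in _ELEMENT_RE.finditer(formula):
        if match.start() != pos:
            raise FormatError(f"malformed formula token in {formula!r} at {pos}")
        element, num = match.groups()
        if element == "C":
            count += int(num) if num else 1
        pos = match.end()
    if pos != len(formula):
        raise FormatError(f"malformed formula token in {formula!r} at {pos}")
    return count


def _flux_ranges(model: MetabolicModel, indices=None) -> np.ndarray:
    """FVA over the plain feasible region (no growth requirement)."""
    if indices is None:
        indices = range(model.n_reactions)
    out = np.zeros((len(list(indices)), 2))
    for k, j in enumerate(indices):
        lo = solve_fba(model, objective_index=j, sense="min")
        hi = solve_fba(model, objective_index=j, sense="max")
        out[k] = (
            lo.objective_value if lo.optimal else np.nan,
            hi.objective_value if hi.optimal else np.nan,
        )
    return out


def remove_dead_ends(
    model: MetabolicModel, tol: float = 1e-9
) -> tuple[MetabolicModel, list[str]]:
    """Iteratively remove blocked reactions (flux range {0}) and the orphan
    metabolites they leave behind, until a fixed point.  The biomass optimum
    is unchanged (removed reactions carried no flux)."""
    current = model.copy()
    removed: list[str] = []
    while True:
        ranges = _flux_ranges(current)
        blocked = [
            j
            for j in range(current.n_reactions)
            if abs(ranges[j, 0]) <= tol and abs(ranges[j, 1]) <= tol
            and j != current.biomass_index
        ]
        if not blocked:
            break
        removed.extend(current.reaction_ids[j] for j in blocked)
        keep = sorted(set(range(current.n_reactions)) - set(blocked))
        current = _subset_reactions(current, keep)
    return current, removed


def _subset_reactions(model: MetabolicModel, keep: list[int]) -> MetabolicModel:
    S = model.S.tocsc()[:, keep]
    used_mets = np.flatnonzero(np.diff(sp.csr_matrix(S).indptr))
    return MetabolicModel(
        metabolite_ids=[model.metabolite_ids[i] for i in used_mets],
        reaction_ids=[model.reaction_ids[j] for j in keep],
        S=sp.csr_matrix(S)[used_mets, :].tocsc(),
        lb=model.lb[keep],
        ub=model.ub[keep],
        objective=model.objective[keep],
        formulas=[model.formulas[i] for i in used_mets],
        subsystems=[model.subsystems[j] for j in keep],
        gene_rules=[model.gene_rules[j] for j in keep],
        name=model.name,
    )


def compress_linear_chains(
    model: MetabolicModel,
    protect: tuple[str, ...] = (),
) -> tuple[MetabolicModel, dict[str, list[str]]]:
    """Merge maximal linear chains into single pseudo-reactions.

    A metabolite with exactly one producing and one consuming reaction forces
    a fixed flux ratio between the two by mass balance, so they are merged
    with combined stoichiometry and intersected (ratio-scaled) bounds.
    Reactions carrying objective weight, plus any id in ``protect`` (pass the
    target export so it survives compression), are never merged.  The
    returned mapping sends each merged pseudo-reaction id to the original
    reaction ids it contains, so knockouts can be reported in original ids.
    """
    current = model.copy()
    mapping: dict[str, list[str]] = {r: [r] for r in current.reaction_ids}
    protected = set(protect)
    while True:
        merge = _find_mergeable_pair(current, protected)
        if merge is None:
            break
        i_met, p, q, s_p, s_q = merge
        ratio = s_p / s_q  # v_q = ratio * v_p
        S = current.S.tolil()
        new_col = (S[:, p] + ratio * S[:, q]).toarray().ravel()
        new_col[i_met] = 0.0
        new_id = f"{current.reaction_ids[p]}&{current.reaction_ids[q]}"
        lbq, ubq = sorted((current.lb[q] / ratio, current.ub[q] / ratio))
        lb_new = max(current.lb[p], lbq)
        ub_new = min(current.ub[p], ubq)
        keep = [j for j in range(current.n_reactions) if j not in (p, q)]
        kept_ids = [current.reaction_ids[j] for j in keep]
        merged_members = mapping.pop(current.reaction_ids[p]) + mapping.pop(
            current.reaction_ids[q]
        )
        mapping[new_id] = merged_members
        S_keep = current.S.tocsc()[:, keep]
        S_new = sp.hstack([S_keep, sp.csc_matrix(new_col[:, None])]).tocsc()
        subsys = [current.subsystems[j] for j in keep] + [
            current.subsystems[p] or current.subsystems[q]
        ]
        rules = [current.gene_rules[j] for j in keep] + [
            " and ".join(
                r for r in (current.gene_rules[p], current.gene_rules[q]) if r
            )
        ]
        current = MetabolicModel(
            metabolite_ids=list(current.metabolite_ids),
            reaction_ids=kept_ids + [new_id],
            S=S_new,
            lb=np.append(current.lb[keep], lb_new),
            ub=np.append(current.ub[keep], ub_new),
            objective=np.append(current.objective[keep], 0.0),
            formulas=list(current.formulas),
            subsystems=subsys,
            gene_rules=rules,
            name=current.name,
        )
    mapping = {k: v for k, v in mapping.items() if len(v) > 1}
    return current, mapping


def _find_mergeable_pair(model: MetabolicModel, protected: set[str]):
    S = model.S.tocsr()
    for i in range(model.n_metabolites):
        row = S.getrow(i).tocoo()
        if row.nnz != 2:
            continue
        (j1, s1), (j2, s2) = zip(row.col, row.data)
        if s1 * s2 >= 0:  # need one producer, one consumer
            continue
        p, s_p, q, s_q = (j1, s1, j2, -s2) if s1 > 0 else (j2, s2, j1, -s1)
        if any(
            model.objective[j] != 0 or model.reaction_ids[j] in protected
            for j in (p, q)
        ):
            continue
        return i, p, q, s_p, s_q
    return None


def essential_reactions(
    model: MetabolicModel, growth_floor: float
) -> set[str]:
    """Reactions whose single knockout drops maximal growth below the floor."""
    wild = solve_fba(model)
    if not wild.optimal:
        raise InfeasibleModelError("wild-type FBA is infeasible")
    if wild.objective_value < growth_floor:
        raise InfeasibleModelError(
            f"wild-type growth {wild.objective_value:.6g} already below the "
            f"floor {growth_floor:.6g}"
        )
    essential = set()
    for j in range(model.n_reactions):
        sol = solve_fba(model, extra_bounds={j: (0.0, 0.0)})
        if (not sol.optimal) or sol.objective_value < growth_floor - 1e-9:
            essential.add(model.reaction_ids[j])
    return essential


def select_candidates(
    model: MetabolicModel,
    target: int,
    n_c: int = 100,
    growth_floor: float = 0.0,
    keep_oxygen: bool = True,
    require_gene_rule: bool = True,
    user_excludes: tuple[str, ...] = (),
) -> CandidateSet:
    """Assemble the knockout candidate set J̄.

    Starting from all reactions, excludes: the biomass and target reactions;
    all exchange reactions (optionally keeping oxygen uptake as a candidate,
    since oxygen-exchange knockouts encode the anaerobic switch); reactions
    with empty gene rules when ``require_gene_rule``; reactions essential at
    ``growth_floor``; ``user_excludes``; and any reaction with a participating
    metabolite of more than ``n_c`` carbons.
    """
    n = model.n_reactions
    keep = np.ones(n, dtype=bool)
    counts: dict[str, int] = {}

    def exclude(mask: np.ndarray, rule: str) -> None:
        mask = np.asarray(mask, dtype=bool)
        counts[rule] = int(np.count_nonzero(mask & keep))
        keep[mask] = False

    exclude(model.objective != 0, "biomass")
    tmask = np.zeros(n, dtype=bool)
    tmask[target] = True
    exclude(tmask, "target")

    exch = model.exchange_flags.copy()
    if keep_oxygen:
        S = model.S.tocsc()
        for j in np.flatnonzero(exch):
            met = S.getcol(j).tocoo().row[0]
            fid = model.formulas[met].upper()
            mid = model.metabolite_ids[met].lower()
            if fid == "O2" or mid.startswith("o2"):
                exch[j] = False
    exclude(exch, "exchange")

    if require_gene_rule:
        exclude([not r for r in model.gene_rules], "no_gene_rule")

    ess = essential_reactions(model, growth_floor)
    exclude([r in ess for r in model.reaction_ids], "essential")

    missing = [r for r in user_excludes if r not in model.reaction_ids]
    for r in missing:
        logger.warning("user exclude %r not in model; ignored", r)
    exclude([r in set(user_excludes) for r in model.reaction_ids], "user")

    met_carbons = np.array([carbon_count(f) for f in model.formulas])
    high_c = met_carbons > n_c
    S = model.S.tocsc()
    touches = np.zeros(n, dtype=bool)
    for j in range(n):
        rows = S.getcol(j).tocoo().row
        touches[j] = bool(np.any(high_c[rows]))
    exclude(touches, "carbon")

    logger.info("candidate selection removal counts: %s", counts)
    indices = tuple(int(j) for j in np.flatnonzero(keep))
    if not indices:
        raise ConfigurationError(
            "candidate set is empty; consider a larger carbon cutoff n_c"
        )
    return CandidateSet(indices=indices, n_c=n_c, exclusion_counts=counts)


def design_from_ids(
    model: MetabolicModel, candidates: CandidateSet, knocked_ids, K: int | None = None
) -> DesignVector:
    """Convenience: build a DesignVector from reaction ids."""
    knocked = {model.index(r) for r in knocked_ids}
    K = K if K is not None else len(knocked)
    return DesignVector.from_knockouts(knocked, candidates.indices, K)
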