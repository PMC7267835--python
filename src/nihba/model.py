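"""Core model representation and synthetic fixture networks.

A :class:`MetabolicModel` is the lightweight in-memory container used
throughout the package: a sparse stoichiometric matrix ``S`` (metabolites x
reactions), signed flux bounds in mmol/gDW/h, an objective weight vector
selecting the biomass reaction, and per-metabolite / per-reaction annotations
(chemical formulas, subsystems, gene rules).  Reversible reactions keep their
signed bounds; the interdiction machinery handles signs directly through
``U_j = max(|lb_j|, |ub_j|)``, so no irreversible splitting is ever done.

A :class:`DesignVector` is a binary knockout vector over a candidate subset
of reactions, with a knockout budget ``K``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .errors import ConfigurationError, FormatError

__all__ = ["MetabolicModel", "DesignVector", "apply_knockouts", "make_toy_network"]

TOY5_REACTIONS = ("UP", "R1", "R3", "BIO", "PRD")


@dataclass
class MetabolicModel:
    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: sp.csc_matrix
    lb: np.ndarray
    ub: np.ndarray
    objective: np.ndarray
    formulas: list[str] = field(default_factory=list)
    subsystems: list[str] = field(default_factory=list)
    gene_rules: list[str] = field(default_factory=list)
    name: str = "model"

    def __post_init__(self) -> None:
        self.S = sp.csc_matrix(self.S)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        self.objective = np.asarray(self.objective, dtype=float)
        if not self.formulas:
            self.formulas = [""] * self.n_metabolites
        if not self.subsystems:
            self.subsystems = [""] * self.n_reactions
        if not self.gene_rules:
            self.gene_rules = [""] * self.n_reactions
        self.validate()

    # -- structural properties -------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def biomass_index(self) -> int:
        nz = np.flatnonzero(self.objective)
        if nz.size == 0:
            raise ConfigurationError("model has no objective (biomass) reaction")
        return int(nz[np.argmax(np.abs(self.objective[nz]))])

    @property
    def exchange_flags(self) -> np.ndarray:
        """True for single-metabolite boundary (exchange/sink) reactions."""
        counts = np.diff(self.S.indptr)
        return counts == 1

    def index(self, reaction_id: str) -> int:
        try:
            return self.reaction_ids.index(reaction_id)
        except ValueError:
            raise KeyError(f"unknown reaction id {reaction_id!r}") from None

    def metabolite_index(self, metabolite_id: str) -> int:
        try:
            return self.metabolite_ids.index(metabolite_id)
        except ValueError:
            raise KeyError(f"unknown metabolite id {metabolite_id!r}") from None

    def validate(self) -> None:
        m, n = self.S.shape
        if m != self.n_metabolites or n != self.n_reactions:
            raise FormatError(
                f"S is {m}x{n} but model declares {self.n_metabolites} metabolites "
                f"and {self.n_reactions} reactions"
            )
        if len(self.lb) != n or len(self.ub) != n or len(self.objective) != n:
            raise FormatError("bounds/objective length does not match reaction count")
        bad = np.flatnonzero(self.lb > self.ub + 1e-12)
        if bad.size:
            raise FormatError(
                f"lower bound exceeds upper bound for reaction "
                f"{self.reaction_ids[bad[0]]!r}"
            )
        if len(self.formulas) != m:
            raise FormatError("formulas length does not match metabolite count")
        if len(self.subsystems) != n or len(self.gene_rules) != n:
            raise FormatError("subsystems/gene_rules length does not match reactions")
        self.biomass_index  # raises ConfigurationError if absent

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            S=self.S.copy(),
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            objective=self.objective.copy(),
            formulas=list(self.formulas),
            subsystems=list(self.subsystems),
            gene_rules=list(self.gene_rules),
            name=self.name,
        )

    def equals(self, other: "MetabolicModel", atol: float = 0.0) -> bool:
        return (
            self.metabolite_ids == other.metabolite_ids
            and self.reaction_ids == other.reaction_ids
            and (abs(self.S - other.S) > atol).nnz == 0
            and np.allclose(self.lb, other.lb, atol=atol)
            and np.allclose(self.ub, other.ub, atol=atol)
            and np.allclose(self.objective, other.objective, atol=atol)
            and self.formulas == other.formulas
            and self.subsystems == other.subsystems
        )


@dataclass(frozen=True)
class DesignVector:
    """Binary knockout vector over the candidate reaction list ``J̄``."""

    y: tuple[int, ...]
    candidates: tuple[int, ...]
    K: int

    def __post_init__(self) -> None:
        if len(self.y) != len(self.candidates):
            raise ValueError("y and candidate list have different lengths")
        if any(v not in (0, 1) for v in self.y):
            raise ValueError("y must be binary")
        if len(set(self.candidates)) != len(self.candidates):
            raise ValueError("candidate indices must be distinct")
        if sum(self.y) > self.K:
            raise ValueError(f"design uses {sum(self.y)} knockouts but K={self.K}")

    @classmethod
    def from_knockouts(
        cls, knocked: "set[int] | list[int]", candidates, K: int
    ) -> "DesignVector":
        candidates = tuple(int(c) for c in candidates)
        knocked = set(int(k) for k in knocked)
        stray = knocked - set(candidates)
        if stray:
            raise IndexError(f"knockout indices {sorted(stray)} not in candidate list")
        return cls(tuple(1 if c in knocked else 0 for c in candidates), candidates, K)

    @property
    def knocked_indices(self) -> tuple[int, ...]:
        return tuple(c for c, v in zip(self.candidates, self.y) if v)

    def knocked_ids(self, model: MetabolicModel) -> tuple[str, ...]:
        return tuple(model.reaction_ids[j] for j in self.knocked_indices)

    @property
    def n_knockouts(self) -> int:
        return int(sum(self.y))


def apply_knockouts(model: MetabolicModel, design: DesignVector) -> MetabolicModel:
    """Return a copy of *model* with knocked-out reaction bounds fixed to zero.

    The input model is never modified.  Idempotent and commutative over
    disjoint designs by construction (bounds assignment).
    """
    n = model.n_reactions
    for j in design.knocked_indices:
        if not 0 <= j < n:
            raise IndexError(f"knockout index {j} outside model with {n} reactions")
    out = model.copy()
    idx = list(design.knocked_indices)
    out.lb[idx] = 0.0
    out.ub[idx] = 0.0
    return out


def _toy5() -> MetabolicModel:
    # UP: -> A (ub 10); R1: A -> B; R3: A -> B + C; BIO: B -> (objective);
    # PRD: C -> (target export).  7 nonzero stoichiometric entries.
    S = sp.csc_matrix(
        np.array(
            [
                #  UP   R1   R3  BIO  PRD
                [1.0, -1.0, -1.0, 0.0, 0.0],  # A
                [0.0, 1.0, 1.0, -1.0, 0.0],  # B
                [0.0, 0.0, 1.0, 0.0, -1.0],  # C
            ]
        )
    )
    return MetabolicModel(
        metabolite_ids=["A", "B", "C"],
        reaction_ids=list(TOY5_REACTIONS),
        S=S,
        lb=np.zeros(5),
        ub=np.array([10.0, 1000.0, 1000.0, 1000.0, 1000.0]),
        objective=np.array([0.0, 0.0, 0.0, 1.0, 0.0]),
        name="toy5",
    )


def make_toy_network(
    kind: str = "toy5",
    n_branches: int = 4,
    coupled_fraction: float = 0.5,
    seed: int = 0,
) -> MetabolicModel:
    """Generate a small mass-balanced network fixture.

    ``toy5`` is the canonical 3-metabolite, 5-reaction network with one
    uncoupled route (R1) and one product-coupled route (R3) from substrate to
    biomass.  ``random_branched`` generalizes it: one substrate uptake
    (ub 10 mmol/gDW/h), ``n_branches`` parallel two-step routes
    A -> X_i -> B from substrate to the biomass precursor, of which a
    ``coupled_fraction`` co-produce the product metabolite C, plus a biomass
    sink (objective) and a product export (target).  Stoichiometric
    coefficients are drawn from {1, 2} so brute-force LP values stay
    hand-checkable.  Identical seeds give identical models.
    """
    if kind == "toy5":
        return _toy5()
    if kind != "random_branched":
        raise ValueError(f"unknown fixture kind {kind!r}")
    if n_branches < 1:
        raise ValueError("n_branches must be >= 1")
    if not 0.0 <= coupled_fraction <= 1.0:
        raise ValueError("coupled_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    n_coupled = int(round(coupled_fraction * n_branches))
    coupled = np.zeros(n_branches, dtype=bool)
    coupled[rng.permutation(n_branches)[:n_coupled]] = True

    metabolite_ids = ["A", "B", "C"] + [f"X{i+1}" for i in range(n_branches)]
    reaction_ids = ["UP"]
    m = len(metabolite_ids)
    cols: list[np.ndarray] = []
    lb: list[float] = []
    ub: list[float] = []

    up = np.zeros(m)
    up[0] = 1.0
    cols.append(up)
    lb.append(0.0)
    ub.append(10.0)

    for i in range(n_branches):
        xi = 3 + i
        a_i = float(rng.integers(1, 3))  # A consumed per X_i made
        col = np.zeros(m)
        col[0] = -a_i
        col[xi] = 1.0
        cols.append(col)
        reaction_ids.append(f"R{i+1}")
        lb.append(0.0)
        ub.append(1000.0)

        b_i = float(rng.integers(1, 3))  # B made per X_i consumed
        col = np.zeros(m)
        col[xi] = -1.0
        col[1] = b_i
        if coupled[i]:
            col[2] = float(rng.integers(1, 3))
        cols.append(col)
        reaction_ids.append(f"E{i+1}")
        lb.append(0.0)
        ub.append(1000.0)

    bio = np.zeros(m)
    bio[1] = -1.0
    cols.append(bio)
    reaction_ids.append("BIO")
    lb.append(0.0)
    ub.append(1000.0)

    prd = np.zeros(m)
    prd[2] = -1.0
    cols.append(prd)
    reaction_ids.append("PRD")
    lb.append(0.0)
    ub.append(1000.0)

    S = sp.csc_matrix(np.column_stack(cols))
    objective = np.zeros(len(reaction_ids))
    objective[reaction_ids.index("BIO")] = 1.0
    # C has no producer when nothing is coupled; give PRD a zero bound then so
    # the model stays consistent (the target is simply blocked).
    model = MetabolicModel(
        metabolite_ids=metabolite_ids,
        reaction_ids=reaction_ids,
        S=S,
        lb=np.array(lb),
        ub=np.array(ub),
        objective=objective,
        name=f"random_branched(n={n_branches},f={coupled_fraction},seed={seed})",
    )
    if not coupled.any():
        model.ub[model.index("PRD")] = 0.0
    return model
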