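"""Readers and writers for SBML Level-3 FBC and COBRA-style JSON.

Parsing and serialization are delegated to cobrapy (which uses python-libsbml
for SBML); this module only converts between :class:`cobra.Model` and the
package's :class:`MetabolicModel`.  Bounds, the objective reaction,
metabolite formulas, subsystems and gene rules are preserved exactly;
reversible reactions keep their signed bounds.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .errors import ConfigurationError, FormatError
from .model import MetabolicModel

logger = logging.getLogger(__name__)

__all__ = ["load_model", "write_model", "from_cobra", "to_cobra"]

_DIALECTS = ("sbml-fbc", "cobra-json")


def _infer_dialect(path: Path) -> str:
    if path.suffix.lower() == ".json":
        return "cobra-json"
    return "sbml-fbc"


def from_cobra(cmodel) -> MetabolicModel:
    """Convert a ``cobra.Model`` into a :class:`MetabolicModel`."""
    met_ids = [m.id for m in cmodel.metabolites]
    rxn_ids = [r.id for r in cmodel.reactions]
    met_pos = {m: i for i, m in enumerate(met_ids)}
    S = sp.dok_matrix((len(met_ids), len(rxn_ids)))
    lb = np.empty(len(rxn_ids))
    ub = np.empty(len(rxn_ids))
    obj = np.zeros(len(rxn_ids))
    subsystems, gene_rules = [], []
    for j, rxn in enumerate(cmodel.reactions):
        for met, coef in rxn.metabolites.items():
            S[met_pos[met.id], j] = float(coef)
        lb[j], ub[j] = float(rxn.lower_bound), float(rxn.upper_bound)
        obj[j] = float(rxn.objective_coefficient)
        subsystems.append(rxn.subsystem or "")
        gene_rules.append(rxn.gene_reaction_rule or "")
    if not np.any(obj):
        raise ConfigurationError(
            f"model {cmodel.id or '<unnamed>'} declares no objective reaction"
        )
    formulas = [m.formula or "" for m in cmodel.metabolites]
    model = MetabolicModel(
        metabolite_ids=met_ids,
        reaction_ids=rxn_ids,
        S=sp.csc_matrix(S),
        lb=lb,
        ub=ub,
        objective=obj,
        formulas=formulas,
        subsystems=subsystems,
        gene_rules=gene_rules,
        name=cmodel.id or "model",
    )
    return model


def to_cobra(model: MetabolicModel):
    """Convert a :class:`MetabolicModel` into a ``cobra.Model``."""
    import cobra

    cmodel = cobra.Model(model.name)
    mets = []
    for i, mid in enumerate(model.metabolite_ids):
        met = cobra.Metabolite(mid, compartment="c")
        if model.formulas[i]:
            met.formula = model.formulas[i]
        mets.append(met)
    cmodel.add_metabolites(mets)
    S = model.S.tocsc()
    reactions = []
    for j, rid in enumerate(model.reaction_ids):
        rxn = cobra.Reaction(rid)
        rxn.lower_bound = float(model.lb[j])
        rxn.upper_bound = float(model.ub[j])
        if model.subsystems[j]:
            rxn.subsystem = model.subsystems[j]
        reactions.append(rxn)
    cmodel.add_reactions(reactions)
    for j, rxn in enumerate(cmodel.reactions):
        col = S.getcol(j).tocoo()
        rxn.add_metabolites(
            {mets[i]: float(v) for i, v in zip(col.row, col.data)}
        )
        if model.gene_rules[j]:
            rxn.gene_reaction_rule = model.gene_rules[j]
    cmodel.objective = {
        cmodel.reactions[int(j)]: float(model.objective[j])
        for j in np.flatnonzero(model.objective)
    }
    return cmodel


def load_model(path, dialect: str | None = None) -> MetabolicModel:
    """Load a model from SBML Level-3 FBC or COBRA-style JSON.

    Unknown JSON fields are ignored with a logged warning (cobrapy
    convention).  A file whose bounds violate lb <= ub, or that lacks an
    objective reaction, raises :class:`FormatError` /
    :class:`ConfigurationError` naming the offending element.
    """
    import cobra.io

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect or _infer_dialect(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"dialect must be one of {_DIALECTS}, got {dialect!r}")
    try:
        if dialect == "cobra-json":
            cmodel = cobra.io.load_json_model(str(path))
        else:
            cmodel = cobra.io.read_sbml_model(str(path))
    except (ConfigurationError, FormatError):
        raise
    except Exception as exc:  # parse errors from libsbml / json
        culprit = _find_bound_violation(path, dialect)
        if culprit is not None:
            raise FormatError(
                f"reaction {culprit!r} in {path.name} has lower bound above "
                "its upper bound"
            ) from exc
        raise FormatError(f"could not parse {path.name} as {dialect}: {exc}") from exc
    return from_cobra(cmodel)


def _find_bound_violation(path: Path, dialect: str) -> str | None:
    """Name the first reaction with lb > ub in a raw model file, if any."""
    try:
        if dialect == "cobra-json":
            import json

            doc = json.loads(path.read_text())
            for rxn in doc.get("reactions", []):
                if rxn.get("lower_bound", 0) > rxn.get("upper_bound", 0):
                    return rxn.get("id")
    except Exception:
        return None
    return None


def write_model(model: MetabolicModel, path, dialect: str | None = None) -> None:
    """Write a model as SBML Level-3 FBC or COBRA-style JSON."""
    import cobra.io

    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"dialect must be one of {_DIALECTS}, got {dialect!r}")
    cmodel = to_cobra(model)
    if dialect == "cobra-json":
        cobra.io.save_json_model(cmodel, str(path))
    else:
        cobra.io.write_sbml_model(cmodel, str(path))
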