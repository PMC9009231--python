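"""Loading, validation, curation and classification of genome-scale models.

The in-memory container is :class:`cobra.Model` (stoichiometry, bounds,
subsystems, EC annotations and GPR strings all live there); this module
adds strict validation, a curation-directive format, and the functional
classification of reactions into uptake / transport / enzymatic /
secretion-and-demand components.

Flux unit convention: mmol/L/min throughout.  Exchange reactions are
written ``metabolite -> (nothing)`` with uptake as negative flux.
Unannotated reactions default to bounds (-1000, 1000) if reversible and
(0, 1000) otherwise — effectively unbounded relative to kinetic caps.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping

import cobra
import pandas as pd

from .gpr import GPRRule, parse_gpr

__all__ = [
    "DEFAULT_BOUND",
    "ModelValidationError",
    "CurationDirective",
    "CurationList",
    "load_model",
    "write_model",
    "validate_model",
    "apply_curation",
    "classify_reactions",
    "reaction_gpr",
    "reaction_ec_numbers",
]

logger = logging.getLogger(__name__)

DEFAULT_BOUND = 1000.0

ReactionComponent = Literal["uptake", "transport", "enzymatic", "secretion_demand"]


class ModelValidationError(ValueError):
    """A structural invariant of the metabolic model is violated."""


def load_model(path: str | Path, flux_scale: float = 1.0) -> cobra.Model:
    """Load an SBML (L3/fbc) or JSON model and validate it.

    Parameters
    ----------
    path:
        ``.xml``/``.sbml`` for SBML, ``.json`` for the JSON dialect.
    flux_scale:
        Multiplies every bound at load time; use it to convert model
        files whose fluxes are not in mmol/L/min.
    """
    path = Path(path)
    if path.suffix in (".xml", ".sbml"):
        model = cobra.io.read_sbml_model(str(path))
    elif path.suffix == ".json":
        model = cobra.io.load_json_model(str(path))
    else:
        raise ValueError(f"unrecognised model format: {path.suffix!r}")
    _apply_default_bounds(model)
    if flux_scale != 1.0:
        for rxn in model.reactions:
            rxn.bounds = (rxn.lower_bound * flux_scale, rxn.upper_bound * flux_scale)
    validate_model(model)
    return model


def write_model(model: cobra.Model, path: str | Path) -> None:
    """Write a model as SBML (``.xml``/``.sbml``) or JSON (``.json``)."""
    path = Path(path)
    if path.suffix in (".xml", ".sbml"):
        cobra.io.write_sbml_model(model, str(path))
    elif path.suffix == ".json":
        cobra.io.save_json_model(model, str(path))
    else:
        raise ValueError(f"unrecognised model format: {path.suffix!r}")


def _apply_default_bounds(model: cobra.Model) -> None:
    """Replace solver-infinite bounds with the documented finite default."""
    n_defaulted = 0
    for rxn in model.reactions:
        lb, ub = rxn.lower_bound, rxn.upper_bound
        if math.isinf(lb) or math.isinf(ub):
            rxn.bounds = (
                max(lb, -DEFAULT_BOUND) if math.isfinite(lb) else -DEFAULT_BOUND,
                min(ub, DEFAULT_BOUND) if math.isfinite(ub) else DEFAULT_BOUND,
            )
            n_defaulted += 1
    if n_defaulted:
        logger.warning(
            "replaced infinite bounds with ±%g on %d reactions",
            DEFAULT_BOUND,
            n_defaulted,
        )


def validate_model(model: cobra.Model) -> None:
    """Check the structural invariants; raise :class:`ModelValidationError`.

    Checked: every stoichiometry references a listed metabolite (cobra
    guarantees this by construction, re-asserted defensively), lb <= ub
    for every reaction, and every gene referenced by a GPR is in the
    gene list.  GPR strings must parse in the and/or dialect.
    """
    met_ids = {m.id for m in model.metabolites}
    gene_ids = {g.id for g in model.genes}
    for rxn in model.reactions:
        for met in rxn.metabolites:
            if met.id not in met_ids:
                raise ModelValidationError(
                    f"reaction {rxn.id}: dangling metabolite {met.id}"
                )
        if rxn.lower_bound > rxn.upper_bound:
            raise ModelValidationError(
                f"reaction {rxn.id}: lower bound {rxn.lower_bound} exceeds "
                f"upper bound {rxn.upper_bound}"
            )
        rule = parse_gpr(rxn.gene_reaction_rule)
        unknown = rule.genes - gene_ids
        if unknown:
            raise ModelValidationError(
                f"reaction {rxn.id}: GPR references unknown genes {sorted(unknown)}"
            )


def reaction_gpr(rxn: cobra.Reaction) -> GPRRule:
    """Parse the reaction's GPR string into an expression tree."""
    return parse_gpr(rxn.gene_reaction_rule)


def reaction_ec_numbers(rxn: cobra.Reaction) -> list[str]:
    """EC numbers from the reaction annotation (possibly empty)."""
    ec = rxn.annotation.get("ec-code", [])
    if isinstance(ec, str):
        ec = [ec]
    return list(ec)


@dataclass(frozen=True)
class CurationDirective:
    reaction_id: str
    directive: Literal["make_irreversible", "set_lower_bound", "set_upper_bound"]
    value: float | None = None


@dataclass
class CurationList:
    """An ordered list of bound/reversibility curation directives.

    TSV format: columns ``reaction_id``, ``directive``, ``value`` (value
    may be blank for ``make_irreversible``).
    """

    directives: list[CurationDirective]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CurationList":
        df = pd.read_csv(path, sep="\t")
        out = []
        for row in df.itertuples(index=False):
            value = getattr(row, "value", None)
            if value is not None and pd.isna(value):
                value = None
            out.append(CurationDirective(row.reaction_id, row.directive, value))
        return cls(out)


def apply_curation(model: cobra.Model, curation: CurationList) -> cobra.Model:
    """Apply curation directives and return a new model.

    ``make_irreversible`` raises the lower bound to at least 0 (so a
    reversible reaction becomes forward-only); ``set_lower_bound`` /
    ``set_upper_bound`` overwrite one bound.  Directives never need to
    widen bounds to be meaningful; ``make_irreversible`` never does.
    """
    unknown = [d.reaction_id for d in curation.directives
               if d.reaction_id not in model.reactions]
    if unknown:
        raise KeyError(f"curation targets absent reactions: {sorted(set(unknown))}")
    model = model.copy()
    for d in curation.directives:
        rxn = model.reactions.get_by_id(d.reaction_id)
        if d.directive == "make_irreversible":
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
        elif d.directive == "set_lower_bound":
            rxn.lower_bound = float(d.value)
        elif d.directive == "set_upper_bound":
            rxn.upper_bound = float(d.value)
        else:
            raise ValueError(f"unknown directive {d.directive!r}")
    return model


def _is_boundary(rxn: cobra.Reaction) -> bool:
    # exchange/demand/sink: single side of the stoichiometry is empty
    return len(rxn.metabolites) > 0 and (
        all(c < 0 for c in rxn.metabolites.values())
        or all(c > 0 for c in rxn.metabolites.values())
    )


def classify_reactions(model: cobra.Model) -> dict[str, ReactionComponent]:
    """Partition reactions into the four functional components.

    Boundary reactions that admit negative flux are nutrient ``uptake``;
    boundary reactions restricted to nonnegative flux are
    ``secretion_demand``.  Interior reactions that move species between
    compartments without an EC annotation are ``transport``; everything
    else is ``enzymatic``.  The labels are exhaustive and exclusive.
    """
    out: dict[str, ReactionComponent] = {}
    for rxn in model.reactions:
        if _is_boundary(rxn):
            out[rxn.id] = "uptake" if rxn.lower_bound < 0 else "secretion_demand"
            continue
        compartments = {m.compartment for m in rxn.metabolites}
        if len(compartments) > 1 and not reaction_ec_numbers(rxn):
            out[rxn.id] = "transport"
        else:
            out[rxn.id] = "enzymatic"
    return out
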