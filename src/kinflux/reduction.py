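"""Context-specific model reduction that favours kinetically covered reactions.

The reduction follows the GIMME scheme: reactions without a turnover
number (or, in the expression-threshold variant, below an expression
cutoff) are penalised, and for each stated objective an LP minimises
the total absolute penalised flux subject to steady state, bounds, and
the objective held at a fraction ``f`` of its unconstrained optimum.
Reactions kept are the union over objectives of (a) every unpenalised
reaction and (b) penalised reactions that still carry flux in the
minimising solution — i.e. those the network cannot do without.

Objectives are enforced one at a time and the retained sets unioned,
which guarantees each objective remains attainable at >= f x optimum
on the reduced model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import reduce
from operator import add

import cobra
import pandas as pd

from .flux import fba
from .kinetics import KcatTable
from .model_io import classify_reactions, reaction_gpr

__all__ = ["ReductionSpec", "gimme_reduce", "reduction_report"]


@dataclass
class ReductionSpec:
    """What to preserve and what to penalise during reduction.

    ``penalties`` maps reaction id -> 1 (penalised: no Kcat record) or 0;
    build it with :meth:`from_kcats` for the kinetic-coverage criterion
    or supply any other indicator (e.g. low expression) directly.
    """

    objectives: list[str]
    fraction: float = 0.9
    penalties: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError("objective fraction must be in (0, 1]")

    @classmethod
    def from_kcats(
        cls,
        model: cobra.Model,
        kcats: KcatTable,
        objectives: list[str],
        fraction: float = 0.9,
    ) -> "ReductionSpec":
        penalties = {r.id: 0 if kcats.covers(r) else 1 for r in model.reactions}
        return cls(objectives=objectives, fraction=fraction, penalties=penalties)


def _minimal_penalty_fluxes(
    model: cobra.Model, spec: ReductionSpec, objective: str
) -> pd.Series:
    """Solve one GIMME LP and return its flux vector."""
    base = fba(model, objective)
    if not base.optimal or base.objective_value <= 0:
        raise ValueError(
            f"objective {objective!r} is infeasible or has optimum <= 0; "
            "cannot anchor the reduction"
        )
    with model:
        prob = model.problem
        obj_rxn = model.reactions.get_by_id(objective)
        keep_obj = prob.Constraint(
            obj_rxn.flux_expression,
            lb=spec.fraction * base.objective_value,
            name="reduction_objective_floor",
        )
        model.add_cons_vars([keep_obj])
        abs_vars = []
        cons = []
        for rxn in model.reactions:
            if spec.penalties.get(rxn.id, 0) != 1:
                continue
            a = prob.Variable(f"absflux_{rxn.id}", lb=0)
            cons.append(prob.Constraint(a - rxn.flux_expression, lb=0))
            cons.append(prob.Constraint(a + rxn.flux_expression, lb=0))
            abs_vars.append(a)
        model.add_cons_vars(abs_vars + cons)
        if abs_vars:
            model.objective = prob.Objective(reduce(add, abs_vars), direction="min")
        else:
            model.objective = prob.Objective(0, direction="min")
        sol = model.optimize()
        if sol.status != "optimal":
            raise ValueError(f"reduction LP for objective {objective!r} failed")
        return sol.fluxes


def gimme_reduce(
    model: cobra.Model, spec: ReductionSpec, flux_tol: float = 1e-6
) -> cobra.Model:
    """Reduce the model, keeping unpenalised reactions and penalised
    reactions that carry |flux| > ``flux_tol`` in some objective's
    penalty-minimising solution."""
    missing = [o for o in spec.objectives if o not in model.reactions]
    if missing:
        raise KeyError(f"objectives absent from model: {missing}")
    keep = {rid for rid, pen in spec.penalties.items() if pen == 0}
    keep |= {r.id for r in model.reactions if r.id not in spec.penalties}
    for objective in spec.objectives:
        fluxes = _minimal_penalty_fluxes(model, spec, objective)
        keep |= {
            rid
            for rid, pen in spec.penalties.items()
            if pen == 1 and rid in fluxes.index and abs(fluxes[rid]) > flux_tol
        }
    reduced = model.copy()
    drop = [r for r in reduced.reactions if r.id not in keep]
    if drop:
        reduced.remove_reactions(drop, remove_orphans=True)
    return reduced


def reduction_report(
    before: cobra.Model, after: cobra.Model, kcats: KcatTable
) -> dict:
    """Retention statistics of a reduction.

    Reports metabolite/reaction/gene retention, the per-component
    breakdown of the reduced model, and the fraction of enzyme-related
    (GPR-bearing) reactions that still lack a Kcat record.
    """
    before_ids = {r.id for r in before.reactions}
    after_ids = {r.id for r in after.reactions}
    if not after_ids <= before_ids:
        raise ValueError("reduced model is not a submodel of the input")

    def genes_in_use(m: cobra.Model) -> set[str]:
        return {g for r in m.reactions for g in reaction_gpr(r).genes}

    components = classify_reactions(after)
    breakdown = pd.Series(components).value_counts().to_dict()
    enzymatic = [r for r in after.reactions if not reaction_gpr(r).is_empty]
    lacking = [r.id for r in enzymatic if not kcats.covers(r)]
    return {
        "metabolites_before": len(before.metabolites),
        "metabolites_after": len(after.metabolites),
        "reactions_before": len(before.reactions),
        "reactions_after": len(after.reactions),
        "genes_before": len(genes_in_use(before)),
        "genes_after": len(genes_in_use(after)),
        "reaction_retention": len(after_ids) / max(len(before_ids), 1),
        "component_breakdown": breakdown,
        "enzymatic_reactions": len(enzymatic),
        "enzymatic_without_kcat": len(lacking),
        "fraction_enzymatic_without_kcat":
            len(lacking) / len(enzymatic) if enzymatic else 0.0,
    }
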