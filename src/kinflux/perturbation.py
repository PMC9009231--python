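"""In silico perturbation screens over kinetic contexts.

A perturbation edits the kinetic state, never the network topology
(except knock-in, which may insert a reaction): gene knockouts zero the
gene's enzyme abundance and re-derive every Vmax through the GPR rules,
so isozyme redundancy and complex stoichiometry are respected; reaction
inhibition scales Vmax by (1 - s); activation/knock-in scales it by a
fold change or sets it outright.  Screens re-solve an FBA readout per
perturbation, which is what a genome-wide scan needs — full
re-sampling is available by running the pipeline on the perturbed
context.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Literal, Sequence

import cobra
import pandas as pd

from .flux import fba
from .gpr import UNLIMITED
from .kinetics import (
    OXPHOS_WHITELIST,
    KcatTable,
    KineticContext,
    UptakeConfig,
    apply_kinetic_bounds,
    reaction_vmax,
)

__all__ = ["PerturbationSpec", "perturb_context", "screen"]

Mode = Literal["knockout", "knockin", "inhibit", "activate"]


@dataclass(frozen=True)
class PerturbationSpec:
    """One perturbation: targets, mode and strength.

    ``knockout`` targets genes; the other modes target reactions.
    ``strength`` in [0, 1] applies to ``inhibit``; ``fold`` >= 0 applies
    to ``activate``; ``knockin`` requires ``vmax`` (the cap given to the
    inserted or re-enabled reaction) and, for reactions absent from the
    model, an ``insert`` reaction object.
    """

    targets: tuple[str, ...]
    mode: Mode
    strength: float | None = None
    fold: float | None = None
    vmax: float | None = None
    insert: tuple[cobra.Reaction, ...] = ()

    def __post_init__(self):
        if not self.targets:
            raise ValueError("perturbation needs at least one target")
        if self.mode == "inhibit":
            if self.strength is None or not (0.0 <= self.strength <= 1.0):
                raise ValueError("inhibition strength must be in [0, 1]")
        if self.mode == "activate":
            if self.fold is None or self.fold < 0:
                raise ValueError("activation fold must be >= 0")
        if self.mode == "knockin" and self.vmax is None:
            raise ValueError("knock-in requires an explicit Vmax")


def perturb_context(
    context: KineticContext,
    model: cobra.Model,
    spec: PerturbationSpec,
    kcats: KcatTable | None = None,
    whitelist: Iterable[str] | None = None,
) -> tuple[KineticContext, cobra.Model]:
    """Apply a perturbation; returns the new context and (possibly
    extended) model.  Whitelisted reactions keep their unlimited caps."""
    wl = set(OXPHOS_WHITELIST if whitelist is None else whitelist)
    if spec.mode == "knockout":
        if kcats is None:
            raise ValueError("gene knockout needs the Kcat table to re-derive Vmax")
        unknown = [g for g in spec.targets if g not in model.genes]
        if unknown:
            raise KeyError(f"unknown gene targets: {unknown}")
        abundance = dict(context.enzyme_abundance)
        for g in spec.targets:
            abundance[g] = 0.0
        new_ctx = reaction_vmax(
            model, abundance, kcats, whitelist=wl, sample_id=context.sample_id
        )
        return new_ctx, model

    vmax = dict(context.vmax)
    model_out = model
    inserted = {r.id: r for r in spec.insert}
    for target in spec.targets:
        if target not in vmax and spec.mode != "knockin":
            raise KeyError(f"unknown reaction target: {target}")
        if target in wl:
            continue
        if spec.mode == "inhibit":
            v = vmax[target]
            vmax[target] = 0.0 if spec.strength == 1.0 else v * (1.0 - spec.strength)
        elif spec.mode == "activate":
            v = vmax[target]
            vmax[target] = v * spec.fold if math.isfinite(v) else v
        elif spec.mode == "knockin":
            if target not in vmax:
                if target not in inserted:
                    raise KeyError(
                        f"knock-in target {target} absent from model and no "
                        "reaction object supplied"
                    )
                if model_out is model:
                    model_out = model.copy()
                model_out.add_reactions([inserted[target]])
            vmax[target] = float(spec.vmax)
    new_ctx = KineticContext(context.sample_id, dict(context.enzyme_abundance), vmax)
    if model_out is not model:
        for rxn in model_out.reactions:
            new_ctx.vmax.setdefault(rxn.id, UNLIMITED)
    return new_ctx, model_out


def screen(
    context: KineticContext,
    model: cobra.Model,
    genes: Sequence[str],
    objective: str,
    kcats: KcatTable,
    mode: Mode = "knockout",
    strength: float | None = None,
    pairs: bool = False,
    uptake_config: UptakeConfig | None = None,
    whitelist: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Single or pairwise perturbation screen with an FBA readout.

    Returns one row per target (or target pair) with the perturbed
    objective value and its absolute and relative change from the
    unperturbed baseline; infeasible perturbed models are reported with
    objective 0 and ``infeasible=True``.  Ordering is deterministic
    (sorted targets).
    """
    unknown = sorted(set(genes) - {g.id for g in model.genes})
    if unknown:
        raise KeyError(f"screen genes absent from model: {unknown}")
    baseline_model = apply_kinetic_bounds(model, context, uptake_config)
    baseline = fba(baseline_model, objective)
    if not baseline.optimal:
        raise ValueError("baseline model is not solvable; cannot screen")
    base_val = baseline.objective_value

    targets: list[tuple[str, ...]]
    ordered = sorted(genes)
    targets = [tuple(p) for p in combinations(ordered, 2)] if pairs else [
        (g,) for g in ordered
    ]

    rows = []
    for tgt in targets:
        spec = PerturbationSpec(targets=tgt, mode=mode, strength=strength)
        ctx, mdl = perturb_context(context, model, spec, kcats, whitelist)
        res = fba(apply_kinetic_bounds(mdl, ctx, uptake_config), objective)
        infeasible = not res.optimal
        value = 0.0 if infeasible else res.objective_value
        rows.append({
            "target": "+".join(tgt),
            "objective_value": value,
            "absolute_change": value - base_val,
            "relative_change": (value - base_val) / base_val if base_val else float("nan"),
            "infeasible": infeasible,
        })
    return pd.DataFrame(rows).set_index("target")
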