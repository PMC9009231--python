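"""End-to-end per-sample modeling: expression in, mean fluxes out.

For each sample the pipeline (i) predicts enzyme abundances from the
transcript profile, (ii) converts them to Vmax caps through the GPR
rules and Kcat table, (iii) applies kinetic and uptake bounds,
(iv) prunes reactions that FVA shows cannot carry flux (the individual
model), (v) samples the flux polytope and (vi) averages the draws.
Cohorts are summarised into a rectangular reactions x samples matrix
with pruned reactions contributing flux 0.
"""

from __future__ import annotations

import cobra
import pandas as pd

from .flux import achr_sample, fva, prune_zero_flux, summarize_samples
from .kinetics import (
    KcatTable,
    ProteinRatioTable,
    UptakeConfig,
    apply_kinetic_bounds,
    estimate_enzyme_abundance,
    reaction_vmax,
)

__all__ = ["run_sample", "run_cohort"]


def run_sample(
    model: cobra.Model,
    expression: pd.Series,
    kcats: KcatTable,
    ratios: ProteinRatioTable,
    uptake_config: UptakeConfig | None = None,
    sample_id: str = "sample",
    n_draws: int = 1000,
    warmup: int = 200,
    thinning: int = 100,
    seed: int | None = None,
    prune_tol: float = 1e-6,
) -> pd.Series:
    """Model one sample; returns mean flux per reaction of the input
    model (0 for reactions pruned from the individual model)."""
    abundance = estimate_enzyme_abundance(expression, ratios)
    context = reaction_vmax(model, abundance, kcats, sample_id=sample_id)
    bounded = apply_kinetic_bounds(model, context, uptake_config)
    ranges = fva(bounded)
    individual = prune_zero_flux(bounded, ranges, tol=prune_tol)
    samples = achr_sample(individual, n_draws=n_draws, warmup=warmup,
                          thinning=thinning, seed=seed)
    mean = samples.mean_flux()
    return mean.reindex([r.id for r in model.reactions], fill_value=0.0)


def run_cohort(
    model: cobra.Model,
    expression: pd.DataFrame,
    kcats: KcatTable,
    ratios: ProteinRatioTable,
    uptake_config: UptakeConfig | None = None,
    n_draws: int = 1000,
    warmup: int = 200,
    thinning: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Model every column of a genes x samples expression matrix.

    Per-sample sampler seeds are derived deterministically from
    ``seed`` so the whole cohort is reproducible.
    """
    columns = {}
    for i, sample_id in enumerate(expression.columns):
        sample_seed = None if seed is None else (seed + 7919 * i) % (2**31)
        columns[sample_id] = run_sample(
            model, expression[sample_id], kcats, ratios, uptake_config,
            sample_id=str(sample_id), n_draws=n_draws, warmup=warmup,
            thinning=thinning, seed=sample_seed,
        )
    return pd.DataFrame(columns)
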