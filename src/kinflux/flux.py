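"""Flux computation: FBA, FVA, per-sample pruning, and polytope sampling.

FBA and FVA are linear programs over the steady-state flux polytope
{v : S v = 0, lb <= v <= ub}; they are delegated to cobrapy.  Blocked
reactions (FVA min and max both ~0) are removed to form the per-sample
"individual model".  Flux distributions are then drawn with an
artificial-centering hit-and-run sampler implemented here: warmup
vertices come from LPs along random directions, chain directions point
from a random warmup vertex through the running centre, and the step
along the chord is uniform — which keeps low-dimensional polytopes
exactly uniform, draws feasible to tight tolerances, and the whole
chain reproducible from a seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import cobra
import numpy as np
import pandas as pd
from cobra.util.array import create_stoichiometric_matrix
from scipy.linalg import null_space
from scipy.optimize import linprog

from .model_io import ModelValidationError

__all__ = [
    "FluxResult",
    "FluxSamples",
    "fba",
    "fva",
    "prune_zero_flux",
    "achr_sample",
    "summarize_samples",
]

logger = logging.getLogger(__name__)

STEADY_STATE_TOL = 1e-6
BOUNDS_TOL = 1e-9


@dataclass
class FluxResult:
    objective_value: float
    fluxes: pd.Series
    status: str

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def _check_bounds(model: cobra.Model) -> None:
    for rxn in model.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            raise ModelValidationError(
                f"reaction {rxn.id}: lower bound exceeds upper bound"
            )


def fba(model: cobra.Model, objective: str | None = None) -> FluxResult:
    """Maximise the objective flux subject to S v = 0 and bounds."""
    _check_bounds(model)
    with model:
        if objective is not None:
            model.objective = model.reactions.get_by_id(objective)
        sol = model.optimize()
    if sol.status != "optimal":
        return FluxResult(float("nan"), pd.Series(dtype=float), sol.status)
    return FluxResult(float(sol.objective_value), sol.fluxes, "optimal")


def fva(
    model: cobra.Model,
    objective_fraction: float | None = None,
    reactions: list[str] | None = None,
) -> pd.DataFrame:
    """Per-reaction (minimum, maximum) flux; optionally holding the
    objective at >= objective_fraction of its optimum.

    Returns a DataFrame indexed by reaction id with columns
    ``minimum``/``maximum``.
    """
    _check_bounds(model)
    frac = 0.0 if objective_fraction is None else float(objective_fraction)
    result = cobra.flux_analysis.flux_variability_analysis(
        model,
        reaction_list=reactions,
        fraction_of_optimum=frac,
        processes=1,
    )
    return result[["minimum", "maximum"]]


def prune_zero_flux(
    model: cobra.Model, fva_result: pd.DataFrame, tol: float = 1e-6
) -> cobra.Model:
    """Remove reactions that cannot carry flux, and orphaned metabolites.

    A reaction is blocked when both its FVA minimum and maximum are
    within ``tol`` of zero.  The result is the per-sample individual
    model; its FBA optimum is unchanged because removed reactions carry
    no flux in any feasible state.
    """
    model = model.copy()
    blocked = [
        rid
        for rid, row in fva_result.iterrows()
        if abs(row["minimum"]) <= tol and abs(row["maximum"]) <= tol
        and rid in model.reactions
    ]
    if blocked:
        model.remove_reactions(
            [model.reactions.get_by_id(r) for r in blocked], remove_orphans=True
        )
    return model


@dataclass
class FluxSamples:
    """Draws from the steady-state flux polytope.

    ``draws`` is a reactions x draws DataFrame (rows = reaction ids).
    """

    draws: pd.DataFrame
    seed: int | None
    warmup: int
    thinning: int
    sample_id: str = "sample"

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.draws.index)

    def mean_flux(self) -> pd.Series:
        return self.draws.mean(axis=1)


def _warmup_points(
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    n_points: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vertices of the flux polytope from LPs along random directions.

    Directions are standard-normal vectors, alternately maximised and
    minimised, which scatters warmup points across the boundary.
    """
    n = S.shape[1]
    bounds = list(zip(lb, ub))
    points = []
    attempts = 0
    while len(points) < n_points and attempts < 4 * n_points:
        attempts += 1
        c = rng.standard_normal(n)
        sign = -1.0 if len(points) % 2 == 0 else 1.0  # -c => maximise
        res = linprog(sign * c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                      bounds=bounds, method="highs")
        if res.status == 0:
            points.append(res.x)
        elif res.status in (2, 3):
            raise ValueError("flux polytope is empty or unbounded; cannot sample")
    if not points:
        raise ValueError("could not generate any warmup point")
    return np.asarray(points)


def achr_sample(
    model: cobra.Model,
    n_draws: int = 1000,
    warmup: int = 200,
    thinning: int = 100,
    seed: int | None = None,
) -> FluxSamples:
    """Artificial-centering hit-and-run sampling of the flux polytope.

    Warmup vertices are produced by maximising/minimising random
    directions; the chain then repeatedly moves from the current point
    along the direction (random warmup vertex - running centre), with
    the step drawn uniformly over the feasible chord.  Every
    ``thinning``-th point is recorded.  Fixed ``seed`` reproduces the
    draw matrix bit for bit.  Points are re-projected onto the
    stoichiometric null space periodically so steady state holds to
    1e-6 and bounds to 1e-9 on every recorded draw.
    """
    _check_bounds(model)
    rng = np.random.default_rng(seed)
    S = create_stoichiometric_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    rxn_ids = [r.id for r in model.reactions]

    N = null_space(S)
    if N.shape[1] == 0:
        point = np.zeros(S.shape[1])
        if np.any(lb > BOUNDS_TOL) or np.any(ub < -BOUNDS_TOL):
            raise ValueError("flux polytope is empty")
        warnings.warn("degenerate flux polytope: only the zero flux is feasible")
        draws = np.tile(point[:, None], (1, n_draws))
        return FluxSamples(pd.DataFrame(draws, index=rxn_ids), seed, 0, thinning)

    W = _warmup_points(S, lb, ub, warmup, rng)
    # clean the LP solutions: project onto the null space, clip to bounds
    W = (N @ (N.T @ W.T)).T
    np.clip(W, lb, ub, out=W)

    center = W.mean(axis=0)
    x = center.copy()
    spread = float(np.max(W.max(axis=0) - W.min(axis=0)))
    if spread < 1e-12:
        warnings.warn("degenerate flux polytope: single feasible point")
        draws = np.tile(x[:, None], (1, n_draws))
        return FluxSamples(pd.DataFrame(draws, index=rxn_ids), seed, len(W), thinning)

    n_accum = W.shape[0]
    draws = np.empty((len(rxn_ids), n_draws))
    recorded = 0
    step = 0
    while recorded < n_draws:
        step += 1
        d = W[rng.integers(W.shape[0])] - center
        nrm = np.linalg.norm(d)
        if nrm < 1e-12:
            continue
        d /= nrm
        with np.errstate(divide="ignore", invalid="ignore"):
            lo = (lb - x) / d
            hi = (ub - x) / d
        active = np.abs(d) > 1e-11
        alpha_low = np.where(d > 0, lo, hi)[active]
        alpha_high = np.where(d > 0, hi, lo)[active]
        amin = alpha_low.max(initial=-np.inf)
        amax = alpha_high.min(initial=np.inf)
        if not np.isfinite(amin) or not np.isfinite(amax) or amax - amin < 1e-12:
            continue
        x = x + rng.uniform(amin, amax) * d
        if step % 500 == 0:
            x = N @ (N.T @ x)
            np.clip(x, lb, ub, out=x)
        n_accum += 1
        center += (x - center) / n_accum
        if step % thinning == 0:
            clean = N @ (N.T @ x)
            np.clip(clean, lb, ub, out=clean)
            draws[:, recorded] = clean
            recorded += 1
    return FluxSamples(pd.DataFrame(draws, index=rxn_ids), seed, W.shape[0], thinning)


def summarize_samples(
    samples: dict[str, FluxSamples], reactions: list[str] | None = None
) -> pd.DataFrame:
    """Average each sample's draws into a reactions x samples matrix.

    Rows are the union of reaction ids across the per-sample models (or
    the explicit ``reactions`` list); a reaction pruned from one
    sample's model contributes flux 0 in that column, keeping the
    cohort matrix rectangular.
    """
    if not samples:
        raise ValueError("no samples to summarise")
    if reactions is None:
        reactions = sorted(set().union(*(s.reaction_ids for s in samples.values())))
    out = pd.DataFrame(0.0, index=reactions, columns=list(samples))
    for sid, s in samples.items():
        means = s.mean_flux()
        out.loc[means.index.intersection(out.index), sid] = means
    return out
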