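"""Group-specific metabolic signatures via dual linear models.

Because cases (centenarians, ~100 y) are necessarily older than their
controls (~60 y), a single case/control regression would conflate the
group signature with ordinary aging.  The engine therefore fits two
ordinary-least-squares models per feature (a flux, or a log2 metabolite
abundance):

* model 1 — ``value ~ case_indicator + sex`` on case + control samples,
  giving the unfiltered group effect (beta1, p1);
* model 2 — ``value ~ age + sex`` on control samples only, giving the
  aging effect (beta2, p2).

A feature is called *up* when it is significantly up in model 1
(p1 < alpha, beta1 > 0) and not significantly up in model 2 (p2 >=
alpha or beta2 < 0); *down* symmetrically; otherwise *none*.  Per
subsystem (or metabolite class) the differential-abundance score is
``DA = (#up - #down) / #features``, in [-1, 1], and its significance
comes from re-running the whole pipeline under label shuffles:
``p = #(shuffled DA > observed)/B`` when DA > 0 (mirrored when DA < 0,
p = 1 when DA = 0), followed by Benjamini-Hochberg FDR across
subsystems.  Shuffles permute the group labels only; age and sex stay
attached to their samples.

The OLS fits are computed in closed form, vectorised across features,
so the B-fold shuffle bootstrap stays fast; correctness is pinned
against statsmodels in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModelFit",
    "SignatureResult",
    "DAResult",
    "fit_model1",
    "fit_model2",
    "call_signature",
    "da_score",
    "da_bootstrap",
    "welch_t_from_summary",
    "fisher_exact_2x2",
    "compare_signatures",
    "benjamini_hochberg",
    "SignatureModel",
    "SignatureResults",
]


# ---------------------------------------------------------------------------
# vectorised OLS core
# ---------------------------------------------------------------------------

def _ols_term(Y: np.ndarray, X: np.ndarray, col: int) -> tuple[np.ndarray, np.ndarray]:
    """OLS of each row of Y (features x n) on X (n x p); returns the
    coefficient and two-sided p-value of column ``col``."""
    n, p = X.shape
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (X.T @ Y.T)          # p x F
    resid = Y.T - X @ beta                # n x F
    dof = n - p
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[col, col], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[col] / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    return beta[col], pvals


@dataclass
class ModelFit:
    """Per-feature coefficient and p-value of the term of interest."""

    table: pd.DataFrame  # index: feature; columns: beta, p
    tag: Literal["model1", "model2"]
    excluded: list[str] = field(default_factory=list)

    @property
    def beta(self) -> pd.Series:
        return self.table["beta"]

    @property
    def p(self) -> pd.Series:
        return self.table["p"]


def _sex_indicator(design: pd.DataFrame) -> np.ndarray:
    return (design["sex"].astype(str).str.lower() == "male").to_numpy(float)


def _drop_constant(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    variance = matrix.var(axis=1, ddof=0)
    constant = list(matrix.index[variance == 0.0])
    return matrix.drop(index=constant), constant


def fit_model1(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    case: str = "CEN",
    control: str = "F1SP",
) -> ModelFit:
    """Unfiltered group signature: value ~ case indicator + sex.

    ``matrix`` is features x samples; ``design`` must carry group and
    sex for every matrix column used.  Zero-variance features are
    excluded and listed on the returned fit.
    """
    sel = design.index[design["group"].isin([case, control])]
    sel = sel.intersection(matrix.columns)
    groups = design.loc[sel, "group"]
    if (groups == case).sum() == 0 or (groups == control).sum() == 0:
        raise ValueError(f"both groups {case!r} and {control!r} must be present")
    sub = matrix[sel]
    sub, excluded = _drop_constant(sub)
    X = np.column_stack([
        np.ones(len(sel)),
        (groups == case).to_numpy(float),
        _sex_indicator(design.loc[sel]),
    ])
    beta, p = _ols_term(sub.to_numpy(float), X, col=1)
    table = pd.DataFrame({"beta": beta, "p": p}, index=sub.index)
    if excluded:
        warnings.warn(f"{len(excluded)} constant features excluded from model 1")
    return ModelFit(table, "model1", excluded)


def fit_model2(
    matrix: pd.DataFrame, design: pd.DataFrame, control: str = "F1SP"
) -> ModelFit:
    """Aging effect within controls: value ~ age + sex."""
    sel = design.index[design["group"] == control].intersection(matrix.columns)
    ages = design.loc[sel, "age"].astype(float)
    if ages.nunique() < 3:
        raise ValueError("control group needs >= 3 distinct ages for the age model")
    sub = matrix[sel]
    sub, excluded = _drop_constant(sub)
    X = np.column_stack([
        np.ones(len(sel)),
        ages.to_numpy(),
        _sex_indicator(design.loc[sel]),
    ])
    beta, p = _ols_term(sub.to_numpy(float), X, col=1)
    table = pd.DataFrame({"beta": beta, "p": p}, index=sub.index)
    if excluded:
        warnings.warn(f"{len(excluded)} constant features excluded from model 2")
    return ModelFit(table, "model2", excluded)


# ---------------------------------------------------------------------------
# signature calls and DA scores
# ---------------------------------------------------------------------------

@dataclass
class SignatureResult:
    """Per-feature {up, down, none} calls with the underlying fits."""

    table: pd.DataFrame  # columns: beta1, p1, beta2, p2, call
    alpha: float = 0.05

    @property
    def call(self) -> pd.Series:
        return self.table["call"]

    def counts(self) -> dict[str, int]:
        c = self.call.value_counts()
        return {k: int(c.get(k, 0)) for k in ("up", "down", "none")}


def _calls(
    beta1: np.ndarray, p1: np.ndarray, beta2: np.ndarray, p2: np.ndarray, alpha: float
) -> np.ndarray:
    """Vectorised call rule shared by the observed and shuffled paths."""
    aging_up = (p2 < alpha) & (beta2 > 0)
    aging_down = (p2 < alpha) & (beta2 < 0)
    up = (p1 < alpha) & (beta1 > 0) & ~aging_up
    down = (p1 < alpha) & (beta1 < 0) & ~aging_down
    out = np.where(up, "up", np.where(down, "down", "none"))
    return out


def call_signature(
    fit1: ModelFit, fit2: ModelFit, alpha: float = 0.05
) -> SignatureResult:
    """Combine the two fits into up/down/none calls.

    Features missing from the aging fit (e.g. constant within controls)
    are treated as showing no aging effect (p2 = 1, beta2 = 0).
    """
    features = fit1.table.index
    t2 = fit2.table.reindex(features)
    beta2 = t2["beta"].fillna(0.0).to_numpy()
    p2 = t2["p"].fillna(1.0).to_numpy()
    beta1 = fit1.beta.to_numpy()
    p1 = fit1.p.to_numpy()
    call = _calls(beta1, p1, beta2, p2, alpha)
    table = pd.DataFrame(
        {"beta1": beta1, "p1": p1, "beta2": beta2, "p2": p2, "call": call},
        index=features,
    )
    return SignatureResult(table, alpha)


def da_score(signature: SignatureResult, grouping: pd.Series) -> pd.Series:
    """Differential-abundance score per subsystem: (#up - #down)/#features.

    ``grouping`` maps feature -> subsystem; features outside the
    signature are ignored, empty subsystems are omitted.
    """
    shared = signature.table.index.intersection(grouping.index)
    call = signature.call.loc[shared]
    sub = grouping.loc[shared]
    up = call.eq("up").groupby(sub).sum()
    down = call.eq("down").groupby(sub).sum()
    total = sub.groupby(sub).size()
    return ((up - down) / total).astype(float)


@dataclass
class DAResult:
    """DA scores with shuffle p-values and BH-adjusted q-values."""

    table: pd.DataFrame  # index: subsystem; columns: da, p, fdr, n_features
    n_shuffles: int = 0
    seed: int | None = None


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def da_bootstrap(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    grouping: pd.Series,
    case: str = "CEN",
    control: str = "F1SP",
    B: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    smoothed: bool = False,
    tie_policy: Literal["count", "strict"] = "count",
) -> DAResult:
    """DA scores with label-shuffle significance.

    The full pipeline (model 1 on shuffled case/control labels, model 2
    on the samples currently labelled control, calls, DA) is recomputed
    under ``B`` permutations of the group labels; ages and sexes stay
    attached to their samples.

    DA scores are ratios of small integer counts, so shuffled scores
    tie with the observed one often; a permutation p that excludes ties
    (``tie_policy='strict'``) is anticonservative for such discrete
    statistics.  The default counts ties (p = #(shuffled at least as
    extreme)/B), which keeps the test valid.  ``smoothed=True`` uses
    (count+1)/(B+1) instead of the raw count/B fraction.
    """
    if B < 100:
        warnings.warn(f"B={B} shuffles is small; p-values will be coarse")
    rng = np.random.default_rng(seed)

    sel = design.index[design["group"].isin([case, control])]
    sel = sel.intersection(matrix.columns)
    sub_design = design.loc[sel]
    Y_df, _ = _drop_constant(matrix[sel])
    features = Y_df.index
    Y = Y_df.to_numpy(float)
    n = len(sel)
    is_case = (sub_design["group"] == case).to_numpy(float)
    age = sub_design["age"].to_numpy(float)
    sex = _sex_indicator(sub_design)

    shared = features.intersection(grouping.index)
    keep_mask = features.isin(shared)
    sub_codes, subsystems = pd.factorize(grouping.loc[features[keep_mask]])
    n_sub = len(subsystems)
    totals = np.bincount(sub_codes, minlength=n_sub).astype(float)

    def pipeline_da(case_ind: np.ndarray) -> np.ndarray:
        X1 = np.column_stack([np.ones(n), case_ind, sex])
        b1, p1 = _ols_term(Y, X1, col=1)
        ctrl = case_ind == 0
        X2 = np.column_stack([np.ones(ctrl.sum()), age[ctrl], sex[ctrl]])
        b2, p2 = _ols_term(Y[:, ctrl], X2, col=1)
        call = _calls(b1, p1, b2, p2, alpha)[keep_mask]
        up = np.bincount(sub_codes, weights=(call == "up"), minlength=n_sub)
        down = np.bincount(sub_codes, weights=(call == "down"), minlength=n_sub)
        return (up - down) / totals

    observed = pipeline_da(is_case)

    exceed = np.zeros(n_sub)
    for _ in range(B):
        shuffled = rng.permutation(is_case)
        da_b = pipeline_da(shuffled)
        if tie_policy == "count":
            exceed += np.where(observed > 0, da_b >= observed,
                               np.where(observed < 0, da_b <= observed, 0.0))
        else:
            exceed += np.where(observed > 0, da_b > observed,
                               np.where(observed < 0, da_b < observed, 0.0))
    if smoothed:
        p = (exceed + 1.0) / (B + 1.0)
    else:
        p = exceed / B
    p = np.where(observed == 0, 1.0, p)
    fdr = benjamini_hochberg(p)
    table = pd.DataFrame(
        {"da": observed, "p": p, "fdr": fdr, "n_features": totals.astype(int)},
        index=pd.Index(subsystems, name="subsystem"),
    )
    return DAResult(table, n_shuffles=B, seed=seed)


# ---------------------------------------------------------------------------
# summary-statistic tests and signature comparison
# ---------------------------------------------------------------------------

def welch_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Welch unequal-variance two-sided t-test from summary statistics.

    Returns (t, Welch-Satterthwaite df, p).
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    A zero margin makes the table uninformative: p = 1 with a warning.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("need a 2x2 table of nonnegative counts")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn("zero margin in 2x2 table; Fisher p set to 1")
        return 1.0
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def compare_signatures(
    fit_a: ModelFit | SignatureResult, fit_b: ModelFit | SignatureResult
) -> tuple[float, float]:
    """Pearson correlation between two signatures' effect sizes.

    Accepts model fits (uses beta) or signature results (uses beta1);
    returns (r, p) over the shared features.
    """
    def betas(obj) -> pd.Series:
        if isinstance(obj, ModelFit):
            return obj.beta
        return obj.table["beta1"]

    a, b = betas(fit_a), betas(fit_b)
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared features to correlate signatures")
    r, p = stats.pearsonr(a.loc[shared], b.loc[shared])
    return float(r), float(p)


# ---------------------------------------------------------------------------
# model/results front end
# ---------------------------------------------------------------------------

class SignatureModel:
    """Dual-linear-model signature analysis of a feature x sample matrix.

    Parameters
    ----------
    matrix:
        features x samples (fluxes enter untransformed; metabolite
        abundances should be log2-transformed via ``log2=True``).
    design:
        sample table with columns group, age, sex.
    grouping:
        optional feature -> subsystem/class mapping enabling DA scores.
    """

    def __init__(
        self,
        matrix: pd.DataFrame,
        design: pd.DataFrame,
        grouping: pd.Series | None = None,
        case: str = "CEN",
        control: str = "F1SP",
        log2: bool = False,
    ):
        if log2:
            if (matrix <= 0).any().any():
                raise ValueError("log2 transform requires strictly positive values")
            matrix = np.log2(matrix)
        self.matrix = matrix
        self.design = design
        self.grouping = grouping
        self.case = case
        self.control = control

    def fit(
        self,
        alpha: float = 0.05,
        B: int | None = None,
        seed: int | None = None,
    ) -> "SignatureResults":
        fit1 = fit_model1(self.matrix, self.design, self.case, self.control)
        fit2 = fit_model2(self.matrix, self.design, self.control)
        signature = call_signature(fit1, fit2, alpha)
        da = None
        if self.grouping is not None:
            if B is not None:
                da = da_bootstrap(
                    self.matrix, self.design, self.grouping,
                    self.case, self.control, B=B, seed=seed, alpha=alpha,
                )
            else:
                scores = da_score(signature, self.grouping)
                da = DAResult(pd.DataFrame({
                    "da": scores,
                    "p": np.nan,
                    "fdr": np.nan,
                    "n_features": self.grouping.loc[
                        self.grouping.index.intersection(signature.table.index)
                    ].groupby(self.grouping).size().reindex(scores.index),
                }))
        return SignatureResults(self, fit1, fit2, signature, da)


@dataclass
class SignatureResults:
    """Fitted signature analysis: per-feature calls and subsystem DA."""

    model: SignatureModel
    fit1: ModelFit
    fit2: ModelFit
    signature: SignatureResult
    da: DAResult | None = None

    def summary(self) -> str:
        counts = self.signature.counts()
        lines = [
            "Signature analysis (dual linear models)",
            "=======================================",
            f"case group:    {self.model.case}",
            f"control group: {self.model.control}",
            f"features:      {len(self.signature.table)}",
            f"alpha:         {self.signature.alpha}",
            f"calls:         up={counts['up']}  down={counts['down']}  "
            f"none={counts['none']}",
        ]
        if self.da is not None:
            lines.append("")
            lines.append("Subsystem differential-abundance scores")
            lines.append(self.da.table.sort_values("da", ascending=False)
                         .to_string(float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)
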