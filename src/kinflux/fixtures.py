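"""Deterministic synthetic inputs: toy networks and synthetic cohorts.

``make_toy_model`` builds an 8-reaction central-carbon toy (glucose and
oxygen uptake, fermentation at 2 ATP/glucose, respiration at 32
ATP/glucose, lactate secretion, ATP demand) whose FBA optima are known
in closed form: with glucose capped at g and oxygen at o, respiration
runs at r = min(g, o/6) and fermentation at g - r, so the maximal ATP
demand flux is ``32 r + 2 (g - r)``.  The default caps (10, 12) give 80
and, with respiration shut off, lactate secretion 20.

``make_synthetic_cohort`` emulates a centenarian-family study: groups
CEN (cases, aged ~98-108), F1SP (controls, ~45-75) and optionally F1,
with per-feature multiplicative group effects planted in one subsystem,
an age slope planted in another, sex offsets, and log-normal noise —
exactly the additive-on-log structure the dual linear models assume.
Ground truth is returned so recovery can be scored without re-deriving
it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import cobra
import numpy as np
import pandas as pd
from cobra import Metabolite, Model, Reaction

from .kinetics import KcatRecord, KcatTable, ProteinRatioTable

__all__ = [
    "ToySpec",
    "CohortSpec",
    "make_toy_model",
    "make_chain_model",
    "make_parallel_path_model",
    "make_synthetic_cohort",
    "toy_ratio_table",
]


def _reaction(
    rid: str,
    stoich: dict[Metabolite, float],
    lb: float,
    ub: float,
    gpr: str = "",
    ec: str | None = None,
    subsystem: str = "",
) -> Reaction:
    rxn = Reaction(rid)
    rxn.add_metabolites(stoich)
    rxn.bounds = (lb, ub)
    if gpr:
        rxn.gene_reaction_rule = gpr
    if ec:
        rxn.annotation["ec-code"] = ec
    rxn.subsystem = subsystem
    return rxn


@dataclass(frozen=True)
class ToySpec:
    """Parameters of the toy central-carbon network."""

    seed: int = 0
    glucose_cap: float = 10.0
    o2_cap: float = 12.0
    fermentation_atp: float = 2.0
    respiration_atp: float = 32.0
    o2_per_glucose: float = 6.0
    #: reactions that receive a Kcat record
    kcat_coverage: tuple[str, ...] = ("FERM", "RESP")

    def __post_init__(self):
        if self.fermentation_atp <= 0 or self.respiration_atp <= 0:
            raise ValueError("ATP yields must be positive")
        if self.glucose_cap < 0 or self.o2_cap < 0:
            raise ValueError("uptake caps must be nonnegative")

    def analytic_atp_optimum(self) -> float:
        """Closed-form maximal ATP demand flux."""
        r = min(self.glucose_cap, self.o2_cap / self.o2_per_glucose)
        return self.respiration_atp * r + self.fermentation_atp * (self.glucose_cap - r)


def make_toy_model(spec: ToySpec = ToySpec()) -> tuple[Model, KcatTable, pd.Series]:
    """Build the toy model plus a matching Kcat table and expression profile."""
    model = Model("toy_core")
    glc_e = Metabolite("glc_e", name="glucose", compartment="e")
    glc_c = Metabolite("glc_c", name="glucose", compartment="c")
    o2_e = Metabolite("o2_e", name="oxygen", compartment="e")
    lac_c = Metabolite("lac_c", name="lactate", compartment="c")
    lac_e = Metabolite("lac_e", name="lactate", compartment="e")
    atp_c = Metabolite("atp_c", name="ATP", compartment="c")
    model.add_reactions([
        _reaction("EX_glc", {glc_e: -1}, -spec.glucose_cap, 1000.0,
                  subsystem="Exchange"),
        _reaction("EX_o2", {o2_e: -1}, -spec.o2_cap, 1000.0, subsystem="Exchange"),
        _reaction("EX_lac", {lac_e: -1}, 0.0, 1000.0, subsystem="Exchange"),
        _reaction("GLCt", {glc_e: -1, glc_c: 1}, 0.0, 1000.0,
                  subsystem="Transport"),
        _reaction("LACt", {lac_c: -1, lac_e: 1}, 0.0, 1000.0,
                  subsystem="Transport"),
        _reaction("FERM", {glc_c: -1, lac_c: 2, atp_c: spec.fermentation_atp},
                  0.0, 1000.0, gpr="g_ferm1 or g_ferm2", ec="1.1.1.27",
                  subsystem="Glycolysis"),
        _reaction("RESP", {glc_c: -1, o2_e: -spec.o2_per_glucose,
                           atp_c: spec.respiration_atp},
                  0.0, 1000.0, gpr="g_resp1", ec="1.9.3.1",
                  subsystem="OxidativePhosphorylation"),
        _reaction("ATPM", {atp_c: -1}, 0.0, 1000.0, subsystem="Demand"),
    ])
    model.objective = "ATPM"

    kcats = KcatTable()
    if "FERM" in spec.kcat_coverage:
        # keyed by EC to exercise the EC lookup path
        kcats.add("1.1.1.27", KcatRecord(200.0, "human", "measured-human"))
        kcats.add("1.1.1.27", KcatRecord(400.0, "rat", "other-species"))
    if "RESP" in spec.kcat_coverage:
        # keyed by reaction id to exercise the id-precedence path
        kcats.add("RESP", KcatRecord(150.0, "human", "measured-human"))

    rng = np.random.default_rng(spec.seed)
    expression = pd.Series(
        np.round(rng.uniform(50.0, 150.0, 3), 6),
        index=["g_ferm1", "g_ferm2", "g_resp1"],
        name="FPKM",
    )
    return model, kcats, expression


def toy_ratio_table(ratio: float = 1.0) -> ProteinRatioTable:
    """alpha/gamma table for the toy genes.

    The default ratio of 1.0 puts enzyme abundances in the 50-150
    nmol/L range, where the toy Vmax caps (Kcat 300/s fermentation,
    150/s respiration) fall below the stoichiometric limits — the
    regime in which kinetic constraints actually shape the flux
    distribution.
    """
    genes = ["g_ferm1", "g_ferm2", "g_resp1"]
    return ProteinRatioTable({g: ratio for g in genes}, ratio)


def make_chain_model(bound: float = 1.0) -> Model:
    """A ⇌ B chain with every |bound| <= ``bound``: a 1-D flux polytope.

    All three reactions must carry the same flux v in [-bound, bound],
    so samples of any reaction should be uniform on that interval.
    """
    model = Model("chain")
    a_e = Metabolite("A_e", compartment="e")
    b_e = Metabolite("B_e", compartment="e")
    model.add_reactions([
        _reaction("EX_A", {a_e: -1}, -bound, bound),
        _reaction("AB", {a_e: -1, b_e: 1}, -bound, bound),
        _reaction("EX_B", {b_e: -1}, -bound, bound),
    ])
    return model


def make_parallel_path_model(sole_route: bool = False) -> tuple[Model, KcatTable]:
    """Fixture for context-specific reduction.

    Substrate S feeds product P through two parallel routes: R1 carries
    a Kcat record, R2 does not.  With both routes present a reduction
    that penalises Kcat-less flux should drop R2 without losing any
    objective value; with ``sole_route=True`` R1 is absent and R2, now
    the only way to the objective, must be retained.
    """
    model = Model("parallel_paths")
    s_e = Metabolite("S_e", compartment="e")
    s_c = Metabolite("S_c", compartment="c")
    p_c = Metabolite("P_c", compartment="c")
    reactions = [
        _reaction("EX_S", {s_e: -1}, -10.0, 0.0, subsystem="Exchange"),
        _reaction("St", {s_e: -1, s_c: 1}, 0.0, 1000.0, subsystem="Transport"),
        _reaction("R2", {s_c: -1, p_c: 1}, 0.0, 1000.0, gpr="g2",
                  subsystem="PathB"),
        _reaction("OBJ", {p_c: -1}, 0.0, 1000.0, subsystem="Demand"),
    ]
    if not sole_route:
        reactions.insert(2, _reaction("R1", {s_c: -1, p_c: 1}, 0.0, 1000.0,
                                      gpr="g1", ec="2.7.1.1",
                                      subsystem="PathA"))
    model.add_reactions(reactions)
    model.objective = "OBJ"
    kcats = KcatTable()
    kcats.add("R1", KcatRecord(100.0))
    return model, kcats


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort generator."""

    seed: int = 0
    n_case: int = 40
    n_control: int = 40
    n_f1: int = 0
    case_age_range: tuple[float, float] = (98.0, 108.0)
    control_age_range: tuple[float, float] = (45.0, 75.0)
    sex_ratio: float = 0.5  # fraction female
    n_subsystems: int = 20
    features_per_subsystem: int = 10
    planted_subsystem: str = "SS01"
    aging_subsystem: str = "SS02"
    effect: float = 1.5          # multiplicative case-group shift
    f1_effect_exponent: float = 0.5
    age_slope: float = 0.02      # per year, on the log scale
    sex_offset_sd: float = 0.05  # log scale
    noise_sd: float = 0.2        # log scale

    def __post_init__(self):
        if min(self.n_case, self.n_control) < 3:
            raise ValueError("group sizes must be >= 3")
        if self.effect <= 0:
            raise ValueError("effect size must be positive")


def make_synthetic_cohort(
    spec: CohortSpec = CohortSpec(),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, dict]:
    """Generate (matrix, design, grouping, truth).

    ``matrix`` is features x samples (flux-like, positive); ``design``
    has columns group/age/sex indexed by sample id; ``grouping`` maps
    feature -> subsystem; ``truth`` lists the planted and aging feature
    ids and the spec itself.
    """
    rng = np.random.default_rng(spec.seed)
    n_feat = spec.n_subsystems * spec.features_per_subsystem
    features = [f"feat_{i:04d}" for i in range(n_feat)]
    subsystems = [f"SS{(i // spec.features_per_subsystem) + 1:02d}" for i in range(n_feat)]
    grouping = pd.Series(subsystems, index=features, name="subsystem")

    rows = []
    for group, n, age_rng in [
        ("CEN", spec.n_case, spec.case_age_range),
        ("F1", spec.n_f1, spec.control_age_range),
        ("F1SP", spec.n_control, spec.control_age_range),
    ]:
        for i in range(n):
            rows.append({
                "sample": f"{group}_{i:03d}",
                "group": group,
                "age": float(np.round(rng.uniform(*age_rng), 1)),
                "sex": "female" if rng.random() < spec.sex_ratio else "male",
            })
    design = pd.DataFrame(rows).set_index("sample")

    planted = grouping.index[grouping == spec.planted_subsystem]
    aging = grouping.index[grouping == spec.aging_subsystem]

    base = rng.normal(0.0, 0.5, n_feat)          # log baseline per feature
    sex_off = rng.normal(0.0, spec.sex_offset_sd, n_feat)
    is_planted = grouping.isin([spec.planted_subsystem]).to_numpy()
    is_aging = grouping.isin([spec.aging_subsystem]).to_numpy()

    age = design["age"].to_numpy()
    age_ref = float(np.mean(spec.control_age_range))
    male = (design["sex"] == "male").to_numpy().astype(float)
    group_exp = np.select(
        [design["group"] == "CEN", design["group"] == "F1"],
        [1.0, spec.f1_effect_exponent],
        default=0.0,
    )

    log_m = (
        base[:, None]
        + np.log(spec.effect) * np.outer(is_planted, group_exp)
        + spec.age_slope * np.outer(is_aging, age - age_ref)
        + np.outer(sex_off, male)
        + rng.normal(0.0, spec.noise_sd, (n_feat, len(design)))
    )
    matrix = pd.DataFrame(np.exp(log_m), index=features, columns=design.index)

    truth = {
        "planted_features": list(planted),
        "aging_features": list(aging),
        "spec": spec,
    }
    return matrix, design, grouping, truth
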