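"""Enzyme-kinetic flux bounds: from transcripts to Vmax caps.

The chain is:

1. steady-state enzyme abundance  E = (alpha/gamma) * M, where M is the
   transcript level (FPKM) and alpha/gamma the per-gene ratio of protein
   synthesis to degradation rates, estimated as the median protein/mRNA
   ratio across tissues (protein concentrations in nmol/L);
2. the reaction-level effective abundance through the GPR rule
   (OR -> sum of isozymes, AND -> min over complex subunits);
3. the Michaelis-Menten cap  V <= Vmax = Kcat * [E].

Units: with Kcat in 1/s and E in nmol/L,
``Vmax[mmol/L/min] = Kcat * 60 * E * 1e-6``; both conversion factors are
explicit below and configurable.

Eight oxidative-phosphorylation reactions are whitelisted to "unlimited"
by default: each needs >20 gene products, so any missing abundance would
spuriously shut down ATP production.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from statistics import median
from typing import Iterable, Mapping

import cobra
import numpy as np
import pandas as pd

from .gpr import UNLIMITED, GPRRule
from .model_io import reaction_ec_numbers, reaction_gpr

__all__ = [
    "SECONDS_PER_MINUTE",
    "NMOL_TO_MMOL",
    "OXPHOS_WHITELIST",
    "KcatRecord",
    "KcatTable",
    "ProteinRatioTable",
    "KineticContext",
    "UptakeConfig",
    "estimate_alpha_gamma",
    "estimate_enzyme_abundance",
    "effective_enzyme",
    "reaction_vmax",
    "apply_kinetic_bounds",
]

logger = logging.getLogger(__name__)

SECONDS_PER_MINUTE = 60.0
NMOL_TO_MMOL = 1e-6

#: essential oxidative-phosphorylation reactions left kinetically unlimited
OXPHOS_WHITELIST = frozenset(
    ["ATPS4mi", "CYOOm2i", "CYOR_u10mi", "NADH2_u10mi",
     "r0205", "CYOOm3i", "FADH2ETC", "GLYC3PFADm"]
)


@dataclass(frozen=True)
class KcatRecord:
    value: float  # 1/s
    species: str = "human"
    provenance: str = "measured-human"  # or "other-species"

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError(f"Kcat must be positive, got {self.value}")


@dataclass
class KcatTable:
    """Turnover numbers keyed by EC number or reaction id.

    Multiple records per key are summarised by their median.  Lookup for
    a reaction prefers a record under the reaction id; otherwise all
    records under any of the reaction's EC numbers are pooled and their
    median is used.
    """

    records: dict[str, list[KcatRecord]] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KcatTable":
        """TSV columns: key, kcat_per_s, species, source."""
        df = pd.read_csv(path, sep="\t")
        table = cls()
        for row in df.itertuples(index=False):
            table.add(row.key, KcatRecord(float(row.kcat_per_s),
                                          getattr(row, "species", "human"),
                                          getattr(row, "source", "measured-human")))
        return table

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"key": k, "kcat_per_s": r.value, "species": r.species, "source": r.provenance}
            for k, recs in sorted(self.records.items())
            for r in recs
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def add(self, key: str, record: KcatRecord) -> None:
        self.records.setdefault(key, []).append(record)

    def lookup(self, key: str) -> float | None:
        recs = self.records.get(key)
        if not recs:
            return None
        return median(r.value for r in recs)

    def for_reaction(self, rxn: cobra.Reaction) -> float | None:
        """Kcat for a reaction: reaction-id record wins over EC records;
        multiple matching EC numbers pool into one median."""
        by_id = self.records.get(rxn.id)
        if by_id:
            return median(r.value for r in by_id)
        pooled = [r.value for ec in reaction_ec_numbers(rxn)
                  for r in self.records.get(ec, [])]
        if not pooled:
            return None
        return median(pooled)

    def covers(self, rxn: cobra.Reaction) -> bool:
        return self.for_reaction(rxn) is not None


@dataclass
class ProteinRatioTable:
    """Per-gene alpha/gamma ratios with a global fallback.

    The ratio is dimensionless scale from FPKM to nmol/L; genes without
    a usable tissue observation fall back to the cohort-wide median
    ratio and are listed in ``fallback_genes``.
    """

    ratios: dict[str, float]
    fallback: float
    fallback_genes: frozenset[str] = frozenset()

    def __post_init__(self):
        bad = [g for g, r in self.ratios.items() if r <= 0]
        if bad or self.fallback <= 0:
            raise ValueError("alpha/gamma ratios must be positive")

    def get(self, gene: str) -> float:
        return self.ratios.get(gene, self.fallback)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProteinRatioTable":
        df = pd.read_csv(path, sep="\t")
        ratios = dict(zip(df["gene"], df["ratio"].astype(float)))
        fallback = float(np.median(list(ratios.values())))
        return cls(ratios, fallback)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"gene": list(self.ratios), "ratio": list(self.ratios.values())}
        ).to_csv(path, sep="\t", index=False)


def estimate_alpha_gamma(
    mrna: pd.DataFrame, protein: pd.DataFrame
) -> ProteinRatioTable:
    """Estimate per-gene alpha/gamma as the median protein/mRNA ratio.

    ``mrna`` and ``protein`` are gene x tissue matrices on shared gene
    ids (FPKM and nmol/L).  Tissues where a gene's mRNA is missing or
    zero are skipped for that gene; genes with no usable tissue get the
    global fallback (median of all per-gene ratios) and are flagged.
    """
    genes = mrna.index.intersection(protein.index)
    tissues = mrna.columns.intersection(protein.columns)
    if len(genes) == 0 or len(tissues) == 0:
        raise ValueError("mRNA and protein matrices share no genes/tissues")
    ratios: dict[str, float] = {}
    no_data: list[str] = []
    for g in genes:
        m = mrna.loc[g, tissues].astype(float)
        p = protein.loc[g, tissues].astype(float)
        usable = (m > 0) & m.notna() & p.notna()
        if usable.any():
            ratios[g] = float((p[usable] / m[usable]).median())
        else:
            no_data.append(g)
    if not ratios:
        raise ValueError("no gene has a usable protein/mRNA tissue pair")
    fallback = float(np.median(list(ratios.values())))
    for g in no_data:
        ratios[g] = fallback
    return ProteinRatioTable(ratios, fallback, frozenset(no_data))


def estimate_enzyme_abundance(
    expression: Mapping[str, float] | pd.Series, ratios: ProteinRatioTable
) -> dict[str, float]:
    """Steady-state enzyme abundance E = (alpha/gamma) * M, in nmol/L."""
    if isinstance(expression, pd.Series):
        expression = expression.to_dict()
    return {g: ratios.get(g) * float(m) for g, m in expression.items()}


def effective_enzyme(rule: GPRRule, abundance: Mapping[str, float]) -> float:
    """Reaction-level effective abundance under the GPR rule.

    OR -> sum of children, AND -> min of children, empty rule ->
    ``UNLIMITED``.  Genes missing from ``abundance`` count as 0.
    """
    missing = rule.genes - set(abundance)
    if missing:
        logger.debug("GPR genes without abundance treated as 0: %s", sorted(missing))
    return rule.effective_abundance(abundance, missing=0.0)


@dataclass
class KineticContext:
    """Per-sample kinetic state: enzyme abundances and reaction Vmax caps.

    ``vmax`` maps every reaction id of the model to a cap in mmol/L/min,
    with ``math.inf`` meaning "unlimited" (no Kcat record, empty GPR, or
    whitelisted reaction).
    """

    sample_id: str
    enzyme_abundance: dict[str, float]
    vmax: dict[str, float]

    def __post_init__(self):
        bad = [g for g, e in self.enzyme_abundance.items() if e < 0]
        if bad:
            raise ValueError(f"negative enzyme abundance for {bad[:5]}")
        bad = [r for r, v in self.vmax.items() if not math.isinf(v) and v < 0]
        if bad:
            raise ValueError(f"negative Vmax for {bad[:5]}")

    def capped_fraction(self) -> float:
        finite = sum(1 for v in self.vmax.values() if math.isfinite(v))
        return finite / len(self.vmax) if self.vmax else 0.0


def reaction_vmax(
    model: cobra.Model,
    enzyme_abundance: Mapping[str, float],
    kcats: KcatTable,
    whitelist: Iterable[str] | None = None,
    sample_id: str = "sample",
    kcat_time_factor: float = SECONDS_PER_MINUTE,
    abundance_unit_factor: float = NMOL_TO_MMOL,
) -> KineticContext:
    """Compute the per-reaction Vmax caps for one sample.

    Vmax = Kcat[1/s] * 60 * E[nmol/L] * 1e-6  (mmol/L/min) for reactions
    with both a Kcat record and a nonempty GPR; all other reactions, and
    whitelisted ones, are unlimited.
    """
    if whitelist is None:
        whitelist = OXPHOS_WHITELIST
    whitelist = set(whitelist)
    vmax: dict[str, float] = {}
    n_capped = n_enzymatic = 0
    for rxn in model.reactions:
        rule = reaction_gpr(rxn)
        kcat = kcats.for_reaction(rxn)
        if not rule.is_empty:
            n_enzymatic += 1
        if rxn.id in whitelist or rule.is_empty or kcat is None:
            vmax[rxn.id] = UNLIMITED
            continue
        e_eff = effective_enzyme(rule, enzyme_abundance)
        if math.isinf(e_eff):
            vmax[rxn.id] = UNLIMITED
            continue
        vmax[rxn.id] = kcat * kcat_time_factor * e_eff * abundance_unit_factor
        n_capped += 1
    if n_enzymatic:
        logger.info(
            "sample %s: kinetic caps on %d/%d GPR-bearing reactions (%.1f%%)",
            sample_id, n_capped, n_enzymatic, 100.0 * n_capped / n_enzymatic,
        )
    return KineticContext(sample_id, dict(enzyme_abundance), vmax)


@dataclass(frozen=True)
class UptakeEntry:
    exchange_id: str
    category: str  # nutrient | essential_amino_acid | cofactor | iron_oxygen
    uptake_bound: float | None = None     # magnitude of allowed uptake
    secretion_bound: float | None = None  # cap on secretion, if any


@dataclass
class UptakeConfig:
    """Uptake/secretion policy for exchange reactions.

    Categories: ``nutrient`` uses the configured literature uptake rate;
    ``essential_amino_acid`` uses a small default (0.01 mmol/L/min,
    configurable); ``cofactor`` and ``iron_oxygen`` are unlimited.
    Uptake is negative flux, so an uptake bound u sets lower_bound = -u.
    """

    entries: dict[str, UptakeEntry] = field(default_factory=dict)
    essential_aa_rate: float = 0.01

    @classmethod
    def from_tsv(cls, path: str | Path, essential_aa_rate: float = 0.01) -> "UptakeConfig":
        df = pd.read_csv(path, sep="\t")
        entries = {}
        for row in df.itertuples(index=False):
            up = getattr(row, "uptake_bound", None)
            sec = getattr(row, "secretion_bound", None)
            entries[row.exchange_id] = UptakeEntry(
                row.exchange_id,
                row.category,
                None if up is None or pd.isna(up) else float(up),
                None if sec is None or pd.isna(sec) else float(sec),
            )
        return cls(entries, essential_aa_rate)

    def uptake_rate(self, entry: UptakeEntry) -> float:
        if entry.category == "nutrient":
            if entry.uptake_bound is None:
                raise ValueError(f"nutrient {entry.exchange_id} lacks an uptake bound")
            return entry.uptake_bound
        if entry.category == "essential_amino_acid":
            return entry.uptake_bound if entry.uptake_bound is not None else self.essential_aa_rate
        # cofactor / iron_oxygen: unlimited
        return math.inf


def apply_kinetic_bounds(
    model: cobra.Model,
    context: KineticContext,
    uptake_config: UptakeConfig | None = None,
    default_bound: float = 1000.0,
) -> cobra.Model:
    """Return a copy of the model with kinetic and uptake bounds applied.

    Irreversible reactions get ``ub <- min(ub, Vmax)``; reversible
    reactions are additionally capped symmetrically at ``lb <- max(lb,
    -Vmax)``.  Exchange reactions listed in the uptake config get their
    category's uptake rate as ``lb = -rate`` (unlimited categories get
    ``-default_bound``) and, when configured, a secretion cap as ``ub``.
    """
    model = model.copy()
    for rxn in model.reactions:
        v = context.vmax.get(rxn.id, UNLIMITED)
        if math.isfinite(v):
            new_ub = min(rxn.upper_bound, v)
            new_lb = max(rxn.lower_bound, -v) if rxn.lower_bound < 0 else rxn.lower_bound
            rxn.bounds = (new_lb, new_ub)
    if uptake_config is not None:
        for exch_id, entry in uptake_config.entries.items():
            if exch_id not in model.reactions:
                logger.warning("uptake config names absent exchange %s; skipped", exch_id)
                continue
            rxn = model.reactions.get_by_id(exch_id)
            rate = uptake_config.uptake_rate(entry)
            lb = -default_bound if math.isinf(rate) else -rate
            ub = rxn.upper_bound
            if entry.secretion_bound is not None:
                ub = entry.secretion_bound
            rxn.bounds = (lb, ub)
    return model
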