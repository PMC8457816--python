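"""First-course regimen costing.

Costs are computed for a fixed reference patient (body surface area 1.8 m²,
weight 75 kg, creatinine clearance 75 mL/min) with exact-milligram pricing
by default (an optional switch rounds each administration up to whole
units, i.e. vial wastage).  Adjuvant regimens run for a fixed number of
cycles or a mean duration; metastatic regimens run for the median
progression-free survival / time to progression of the pivotal trial,
converted to fractional cycles.  GnRH agonists are always costed over a
5-year course.  All amounts are Australian dollars (AUD); drug delivery,
hospitalization and toxicity costs are excluded.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .trees import Modality, TreeSpec, expected_utilization

DAYS_PER_MONTH = 365.25 / 12.0

#: components recognised as GnRH agonists, pinned to a 5-year course
GNRH_DURATION_MONTHS = 60.0


class CostError(ValueError):
    """Raised for costing-configuration problems (unpriced drugs, bad rules)."""


@dataclass(frozen=True)
class ReferencePatient:
    """The standardized patient used for all dose calculations."""

    bsa_m2: float = 1.8
    weight_kg: float = 75.0
    crcl_ml_min: float = 75.0

    def __post_init__(self):
        if min(self.bsa_m2, self.weight_kg, self.crcl_ml_min) <= 0:
            raise CostError("reference-patient parameters must be positive")


class DoseKind(enum.Enum):
    PER_M2 = "per_m2"
    PER_KG = "per_kg"
    AUC_CALVERT = "auc_calvert"
    FLAT = "flat"


@dataclass(frozen=True)
class DosingRule:
    """Dose coefficient: mg/m², mg/kg, Calvert AUC target, or flat mg/units."""

    kind: DoseKind
    amount: float

    def __post_init__(self):
        if self.amount <= 0:
            raise CostError("dose amount must be positive")


def dose_mg(rule: DosingRule, patient: ReferencePatient) -> float:
    """Administered dose in mg (or flat units) for the reference patient.

    Carboplatin uses the Calvert formula: dose = AUC x (CrCl + 25).
    """
    if rule.kind is DoseKind.PER_M2:
        return rule.amount * patient.bsa_m2
    if rule.kind is DoseKind.PER_KG:
        return rule.amount * patient.weight_kg
    if rule.kind is DoseKind.AUC_CALVERT:
        return rule.amount * (patient.crcl_ml_min + 25.0)
    if rule.kind is DoseKind.FLAT:
        return rule.amount
    raise CostError(f"unknown dosing rule kind: {rule.kind!r}")


@dataclass(frozen=True)
class Component:
    """One drug (or priced service) within a regimen."""

    drug: str
    rule: DosingRule
    doses_per_cycle: float = 1.0
    cycle_days: float = 21.0
    #: optional duration override in months (e.g. 60 for GnRH agonists),
    #: taking precedence over the regimen-level duration
    duration_months: float | None = None
    is_gnrh: bool = False


@dataclass(frozen=True)
class Regimen:
    """A recommended regimen with a defined course length.

    Exactly one of ``n_cycles`` (fixed course, typical adjuvant) or
    ``duration_months`` (mean adjuvant duration, or median PFS/TTP in the
    metastatic setting) must be given.  ``add_ons`` are one-time flat-priced
    items (e.g. PD-L1 testing) expressed as (item, quantity).
    """

    id: str
    setting: str
    components: tuple[Component, ...]
    n_cycles: float | None = None
    duration_months: float | None = None
    add_ons: tuple[tuple[str, float], ...] = ()

    def __post_init__(self):
        if (self.n_cycles is None) == (self.duration_months is None):
            raise CostError(
                f"regimen {self.id!r}: exactly one of n_cycles/duration_months "
                "must be set"
            )
        dur = self.n_cycles if self.n_cycles is not None else self.duration_months
        if dur is None or dur <= 0:
            raise CostError(f"regimen {self.id!r}: duration must be positive")


@dataclass
class RegimenCatalog:
    """All regimens plus the leaf-referenced equiprobable regimen sets."""

    regimens: dict[str, Regimen]
    regimen_sets: dict[str, tuple[str, ...]]

    def set_regimens(self, set_id: str) -> list[Regimen]:
        if set_id not in self.regimen_sets:
            raise CostError(f"unknown regimen set: {set_id!r}")
        ids = self.regimen_sets[set_id]
        if not ids:
            raise CostError(f"regimen set {set_id!r} is empty")
        return [self.regimens[r] for r in ids]


class PriceTable:
    """Unit prices per drug and tier, with exact-mg (linear) pricing.

    Backed by a DataFrame with columns ``drug, unit_size, price_aud, tier``;
    ``tier`` is ``lowest`` or ``highest`` listed price.
    """

    TIERS = ("lowest", "highest")

    def __init__(self, frame: pd.DataFrame):
        required = {"drug", "unit_size", "price_aud", "tier"}
        missing = required - set(frame.columns)
        if missing:
            raise CostError(f"price table missing columns: {sorted(missing)}")
        bad_tier = set(frame["tier"]) - set(self.TIERS)
        if bad_tier:
            raise CostError(f"unknown price tiers: {sorted(bad_tier)}")
        if (frame["price_aud"] < 0).any():
            raise CostError("prices must be non-negative")
        if frame.duplicated(["drug", "tier"]).any():
            dups = frame[frame.duplicated(["drug", "tier"])]["drug"].tolist()
            raise CostError(f"duplicate (drug, tier) rows: {dups}")
        self.frame = frame.reset_index(drop=True)
        self._index = {
            (r.drug, r.tier): (float(r.unit_size), float(r.price_aud))
            for r in frame.itertuples()
        }

    def unit(self, drug: str, tier: str) -> tuple[float, float]:
        try:
            return self._index[(drug, tier)]
        except KeyError:
            raise CostError(f"drug {drug!r} is not priced at tier {tier!r}") from None

    def per_mg(self, drug: str, tier: str) -> float:
        unit_size, price = self.unit(drug, tier)
        return price / unit_size

    def item_cost(self, drug: str, mg: float, tier: str, vial_rounding: bool) -> float:
        unit_size, price = self.unit(drug, tier)
        if vial_rounding:
            return math.ceil(mg / unit_size - 1e-12) * price
        return mg * price / unit_size


def course_cost(
    regimen: Regimen,
    prices: PriceTable,
    patient: ReferencePatient | None = None,
    tier: str = "lowest",
    vial_rounding: bool = False,
) -> float:
    """Total AUD cost of one full course of ``regimen`` for the reference patient."""
    patient = patient or ReferencePatient()
    total = 0.0
    for comp in regimen.components:
        if comp.is_gnrh:
            months = GNRH_DURATION_MONTHS
            n_doses = comp.doses_per_cycle * months * DAYS_PER_MONTH / comp.cycle_days
        elif comp.duration_months is not None:
            n_doses = (
                comp.doses_per_cycle
                * comp.duration_months
                * DAYS_PER_MONTH
                / comp.cycle_days
            )
        elif regimen.n_cycles is not None:
            n_doses = comp.doses_per_cycle * regimen.n_cycles
        else:
            n_doses = (
                comp.doses_per_cycle
                * regimen.duration_months
                * DAYS_PER_MONTH
                / comp.cycle_days
            )
        mg = dose_mg(comp.rule, patient)
        if vial_rounding:
            # wastage accrues per administration
            per_dose = prices.item_cost(comp.drug, mg, tier, True)
            total += per_dose * n_doses
        else:
            total += prices.item_cost(comp.drug, mg * n_doses, tier, False)
    for item, qty in regimen.add_ons:
        unit_size, price = prices.unit(item, tier)
        total += qty * price
    return total


# ---------------------------------------------------------------------------
# Modality groups (the reporting aggregation used throughout)
# ---------------------------------------------------------------------------

#: reporting groups: members accrue cost; the denominator modality defines
#: "per person needing treatment" for the group
MODALITY_GROUPS: dict[str, dict] = {
    "chemo_her2_io": {
        "members": {
            Modality.CHEMOTHERAPY,
            Modality.HER2,
            Modality.IMMUNOTHERAPY,
            Modality.GCSF,
            Modality.MULTIGENE_ASSAY,
        },
        "denominator": Modality.CHEMOTHERAPY,
    },
    "endocrine_cdk46": {
        "members": {Modality.ENDOCRINE, Modality.CDK46, Modality.OOPHORECTOMY},
        "denominator": Modality.ENDOCRINE,
    },
}


def _leaf_group_cost(
    leaf_indications,
    members,
    catalog: RegimenCatalog,
    prices: PriceTable,
    patient: ReferencePatient,
    tier: str,
    vial_rounding: bool,
    regimen_pick: str = "mean",
) -> float:
    """Expected cost of all group-member indications on one leaf.

    ``regimen_pick`` selects within each equiprobable regimen set:
    ``mean`` (base case), ``min`` or ``max`` (price sensitivity).
    """
    cost = 0.0
    for ind in leaf_indications:
        if ind.modality not in members:
            continue
        regimens = catalog.set_regimens(ind.regimen_set)
        costs = [
            course_cost(r, prices, patient, tier, vial_rounding) for r in regimens
        ]
        if regimen_pick == "mean":
            cost += float(np.mean(costs))
        elif regimen_pick == "min":
            cost += float(np.min(costs))
        elif regimen_pick == "max":
            cost += float(np.max(costs))
        else:
            raise CostError(f"unknown regimen_pick: {regimen_pick!r}")
    return cost


def level_cost_per_person(
    tree: TreeSpec,
    catalog: RegimenCatalog,
    prices: PriceTable,
    patient: ReferencePatient | None = None,
    tier: str = "lowest",
    vial_rounding: bool = False,
    regimen_pick: str = "mean",
) -> dict[str, float]:
    """AUD per person *needing treatment*, by modality group, for one level.

    The expected cost over tree paths (each indicated leaf contributes path
    probability times the equiprobable-regimen mean) is divided by the
    group's denominator-modality utilization proportion.  A level where the
    denominator proportion is zero (e.g. chemotherapy at Basic) reports 0.
    """
    patient = patient or ReferencePatient()
    util = expected_utilization(tree)
    expected = {g: 0.0 for g in MODALITY_GROUPS}
    for leaf, prob, _ in tree.leaf_paths():
        if not leaf.indications:
            continue
        for gname, g in MODALITY_GROUPS.items():
            expected[gname] += prob * _leaf_group_cost(
                leaf.indications,
                g["members"],
                catalog,
                prices,
                patient,
                tier,
                vial_rounding,
                regimen_pick,
            )
    out = {}
    for gname, g in MODALITY_GROUPS.items():
        denom = util[g["denominator"]]
        out[gname] = expected[gname] / denom if denom > 0 else 0.0
    return out


@dataclass
class CostResult:
    """Per-person costs by (level, group) and total costs by (income group, year)."""

    per_person: pd.DataFrame  # columns: level, modality_group, aud_per_person
    totals: pd.DataFrame | None = None  # income_group, modality_group, year, cost_aud


def per_person_costs(
    trees: Mapping, catalog: RegimenCatalog, prices: PriceTable, **kwargs
) -> pd.DataFrame:
    """Per-person group costs for every resource level in ``trees``."""
    rows = []
    for level, tree in trees.items():
        pp = level_cost_per_person(tree, catalog, prices, **kwargs)
        for gname, value in pp.items():
            rows.append(
                {
                    "level": getattr(level, "label", str(level)),
                    "modality_group": gname,
                    "aud_per_person": value,
                }
            )
    return pd.DataFrame(rows)


def total_cost(need: pd.DataFrame, per_person: pd.DataFrame) -> pd.DataFrame:
    """Total AUD by income group / modality group / year: need x per-person cost.

    ``need`` must carry columns ``income_group, level, modality_group, year,
    persons`` where ``modality_group`` names the group whose denominator
    modality the ``persons`` column counts; ``per_person`` is the frame from
    :func:`per_person_costs`.
    """
    required = {"income_group", "level", "modality_group", "year", "persons"}
    missing = required - set(need.columns)
    if missing:
        raise CostError(f"need table missing columns: {sorted(missing)}")
    merged = need.merge(per_person, on=["level", "modality_group"], how="left")
    if merged["aud_per_person"].isna().any():
        bad = merged[merged["aud_per_person"].isna()][
            ["level", "modality_group"]
        ].drop_duplicates()
        raise CostError(
            "no per-person cost for: "
            + ", ".join(f"{r.level}/{r.modality_group}" for r in bad.itertuples())
        )
    merged["cost_aud"] = merged["persons"] * merged["aud_per_person"]
    return merged[
        ["income_group", "level", "modality_group", "year", "persons", "cost_aud"]
    ]
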