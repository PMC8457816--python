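"""Incidence-weighted treatment need.

Each country carries a World Bank income group (L, LM, UM, H); each income
group is assigned an NCCN resource level (base case: L-Basic, LM-Core,
UM-Enhanced, H-Maximal).  Need for a modality is country incidence times
the level's utilization proportion, pooled to income-group and global
totals.  Needs are carried as reals end to end; integer and percent
rounding happens only in the reporting layer.
"""

from __future__ import annotations

import enum
import warnings
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import pandas as pd

from .trees import Modality, ResourceLevel, UtilizationResult


class DemandError(ValueError):
    """Raised for inconsistent demand-model inputs."""


class IncomeGroup(enum.Enum):
    """World Bank income classification."""

    L = "L"
    LM = "LM"
    UM = "UM"
    H = "H"

    @classmethod
    def from_label(cls, label: str) -> "IncomeGroup":
        try:
            return cls(str(label))
        except ValueError:
            raise DemandError(f"unknown income group: {label!r}") from None


#: base-case income-to-resource-level assignment
DEFAULT_ASSIGNMENT: dict[IncomeGroup, ResourceLevel] = {
    IncomeGroup.L: ResourceLevel.BASIC,
    IncomeGroup.LM: ResourceLevel.CORE,
    IncomeGroup.UM: ResourceLevel.ENHANCED,
    IncomeGroup.H: ResourceLevel.MAXIMAL,
}

ResourceAssignment = Mapping[IncomeGroup, ResourceLevel]

INCIDENCE_COLUMNS = ["country", "income_group", "year", "cases"]


def validate_incidence(table: pd.DataFrame) -> pd.DataFrame:
    """Check the incidence-table schema and invariants; return the table."""
    missing = set(INCIDENCE_COLUMNS) - set(table.columns)
    if missing:
        raise DemandError(f"incidence table missing columns: {sorted(missing)}")
    if table.empty:
        raise DemandError("incidence table is empty")
    if (table["cases"] < 0).any():
        raise DemandError("incidence table contains negative case counts")
    dup = table.duplicated(["country", "year"])
    if dup.any():
        pairs = table.loc[dup, ["country", "year"]].values.tolist()
        raise DemandError(f"duplicate (country, year) rows: {pairs}")
    for g in table["income_group"]:
        IncomeGroup.from_label(g)
    return table


def _check_assignment(assignment: ResourceAssignment) -> None:
    missing = [g.value for g in IncomeGroup if g not in assignment]
    if missing:
        raise DemandError(f"resource assignment missing income groups: {missing}")


def compute_need(
    incidence: pd.DataFrame,
    assignment: ResourceAssignment,
    utilizations: Mapping[ResourceLevel, UtilizationResult],
    year: int,
    modalities: tuple[Modality, ...] = tuple(Modality),
) -> pd.DataFrame:
    """Persons needing treatment per (income group, modality) in ``year``.

    need(g, m) = (sum of incidence over countries in g) x proportion(level(g), m).
    Returns columns ``income_group, level, modality, year, persons, share``
    where ``share`` is the group's fraction of global need for that modality.
    """
    validate_incidence(incidence)
    _check_assignment(assignment)
    sub = incidence[incidence["year"] == year]
    if sub.empty:
        raise DemandError(f"incidence table has no rows for year {year}")
    group_cases = sub.groupby("income_group")["cases"].sum()

    rows = []
    for group in IncomeGroup:
        level = assignment[group]
        if level not in utilizations:
            raise DemandError(f"no utilization result for level {level.label!r}")
        util = utilizations[level]
        cases = float(group_cases.get(group.value, 0.0))
        for m in modalities:
            rows.append(
                {
                    "income_group": group.value,
                    "level": level.label,
                    "modality": m.value,
                    "year": year,
                    "persons": cases * util[m],
                }
            )
    need = pd.DataFrame(rows)
    totals = need.groupby("modality")["persons"].transform("sum")
    with pd.option_context("mode.chained_assignment", None):
        need["share"] = (need["persons"] / totals).where(totals > 0, 0.0)
    return need


def need_shares(need: pd.DataFrame, modality: Modality, year: int) -> pd.Series:
    """Per-income-group fraction of global need for one modality and year."""
    sub = need[(need["modality"] == modality.value) & (need["year"] == year)]
    if sub.empty:
        raise DemandError(f"no need rows for {modality.value} in {year}")
    total = sub["persons"].sum()
    if total <= 0:
        warnings.warn(
            f"global need for {modality.value} in {year} is zero; shares set to 0",
            stacklevel=2,
        )
        return pd.Series(0.0, index=sub["income_group"].values)
    return pd.Series(
        (sub["persons"] / total).values, index=sub["income_group"].values
    )


def incidence_shares(incidence: pd.DataFrame, year: int) -> pd.Series:
    """Per-income-group fraction of global incident cases in ``year``."""
    validate_incidence(incidence)
    sub = incidence[incidence["year"] == year]
    if sub.empty:
        raise DemandError(f"incidence table has no rows for year {year}")
    group = sub.groupby("income_group")["cases"].sum()
    total = group.sum()
    if total <= 0:
        raise DemandError(f"total incidence in {year} is zero")
    return group / total


# ---------------------------------------------------------------------------
# Reporting helpers
# ---------------------------------------------------------------------------


def percent(fraction: float, decimals: int = 0) -> float:
    """Report a fraction as a percentage, rounding half-up.

    Integer percents match headline reporting ("3%", "27%"); one decimal is
    used for sub-1% quantities ("0.2%").
    """
    quantum = Decimal(1).scaleb(-decimals)
    return float(
        Decimal(repr(float(fraction) * 100)).quantize(quantum, rounding=ROUND_HALF_UP)
    )


def round_half_up(value: float, decimals: int = 0) -> float:
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))
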