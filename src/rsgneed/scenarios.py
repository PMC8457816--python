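"""Upscaling scenarios, price sensitivity bounds, and fold-change reporting.

Seven scenarios progressively reassign income groups to higher resource
levels, from the base mapping (L-Basic, LM-Core, UM-Enhanced, H-Maximal) to
all-Maximal.  Each transition raises exactly one income group by one rank;
the group with the lowest current rank moves first (ties broken toward the
lower income group).  The total rank deficit of the base mapping is six, so
the ladder reaches all-Maximal in exactly seven scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .costs import MODALITY_GROUPS, CostError, total_cost
from .demand import (
    DEFAULT_ASSIGNMENT,
    DemandError,
    IncomeGroup,
    ResourceAssignment,
    compute_need,
    round_half_up,
)
from .trees import Modality, ResourceLevel, UtilizationResult


@dataclass(frozen=True)
class Scenario:
    """One rung of the upscaling ladder."""

    id: int
    assignment: tuple[tuple[IncomeGroup, ResourceLevel], ...]

    @property
    def mapping(self) -> dict[IncomeGroup, ResourceLevel]:
        return dict(self.assignment)


def default_scenario_ladder() -> list[Scenario]:
    """The seven-scenario upscaling ladder (base mapping to all-Maximal)."""
    levels_by_rank = {lv.rank: lv for lv in ResourceLevel}
    current = dict(DEFAULT_ASSIGNMENT)
    ladder = [Scenario(1, tuple(current.items()))]
    for sid in range(2, 8):
        # raise the group with the lowest rank; ties go to the lower income
        candidates = [g for g in IncomeGroup if current[g] is not ResourceLevel.MAXIMAL]
        target = min(candidates, key=lambda g: (current[g].rank, g.value))
        current[target] = levels_by_rank[current[target].rank + 1]
        ladder.append(Scenario(sid, tuple(current.items())))
    return ladder


def validate_ladder(ladder: Sequence[Scenario]) -> None:
    if not ladder:
        raise DemandError("scenario ladder is empty")
    if dict(ladder[0].assignment) != dict(DEFAULT_ASSIGNMENT):
        raise DemandError("scenario 1 must be the default income-level mapping")
    if any(lv is not ResourceLevel.MAXIMAL for _, lv in ladder[-1].assignment):
        raise DemandError("final scenario must assign Maximal to every group")
    for prev, cur in zip(ladder, ladder[1:]):
        p, c = dict(prev.assignment), dict(cur.assignment)
        diffs = [(g, p[g].rank, c[g].rank) for g in IncomeGroup if p[g] is not c[g]]
        if any(new < old for _, old, new in diffs):
            raise DemandError(
                f"scenario {cur.id} lowers a group's resource level"
            )


def run_scenarios(
    ladder: Sequence[Scenario],
    incidence: pd.DataFrame,
    utilizations: Mapping[ResourceLevel, UtilizationResult],
    per_person: pd.DataFrame,
    year: int,
) -> pd.DataFrame:
    """Global need and cost per scenario and modality group.

    Returns columns ``scenario, modality_group, need, cost_aud`` where
    ``need`` counts persons needing the group's denominator modality and
    ``cost_aud`` is the global group cost under that scenario's assignment.
    """
    validate_ladder(ladder)
    rows = []
    for sc in ladder:
        need = compute_need(incidence, sc.mapping, utilizations, year)
        for gname, g in MODALITY_GROUPS.items():
            denom = g["denominator"].value
            sub = need[need["modality"] == denom][
                ["income_group", "level", "year", "persons"]
            ].assign(modality_group=gname)
            totals = total_cost(sub, per_person)
            rows.append(
                {
                    "scenario": sc.id,
                    "modality_group": gname,
                    "need": sub["persons"].sum(),
                    "cost_aud": totals["cost_aud"].sum(),
                }
            )
    return pd.DataFrame(rows)


def price_sensitivity(
    trees: Mapping[ResourceLevel, "object"],
    catalog,
    prices,
    mode: str,
    patient=None,
) -> pd.DataFrame:
    """Per-person costs under the price-sensitivity bounds.

    ``lowest``/``highest`` select the cheapest/most expensive recommended
    regimen per indication (at the lowest/highest listed unit price tier);
    ``half_lowest``/``double_highest`` scale those bounds by 0.5/2.0.
    """
    from .costs import per_person_costs

    modes = {
        "lowest": ("min", "lowest", 1.0),
        "highest": ("max", "highest", 1.0),
        "half_lowest": ("min", "lowest", 0.5),
        "double_highest": ("max", "highest", 2.0),
    }
    if mode not in modes:
        raise CostError(f"unknown price-sensitivity mode: {mode!r}")
    pick, tier, factor = modes[mode]
    frame = per_person_costs(
        trees, catalog, prices, patient=patient, tier=tier, regimen_pick=pick
    )
    frame["aud_per_person"] = frame["aud_per_person"] * factor
    frame["mode"] = mode
    return frame


def fold_change(before: float, after: float) -> tuple[float, float]:
    """Ratio ``after/before`` with its reported rounding.

    Returns ``(raw, reported)``: the report rounds half-up to an integer
    when the ratio is at least 2, else to one decimal.
    """
    if before <= 0:
        raise ValueError("fold_change requires before > 0")
    ratio = after / before
    if ratio >= 2:
        return ratio, round_half_up(ratio, 0)
    return ratio, round_half_up(ratio, 1)


def basic_counterfactual(
    incidence: pd.DataFrame,
    utilizations: Mapping[ResourceLevel, UtilizationResult],
    per_person: pd.DataFrame,
    year: int,
) -> dict[str, float]:
    """Extra chemotherapy need and cost if low-income countries had Core services.

    Difference between the L-to-Core and base (L-to-Basic) runs for the
    chemo/HER2/IO group.
    """
    alt = dict(DEFAULT_ASSIGNMENT)
    alt[IncomeGroup.L] = ResourceLevel.CORE

    out = {}
    for label, assignment in (("base", DEFAULT_ASSIGNMENT), ("core_l", alt)):
        need = compute_need(incidence, assignment, utilizations, year)
        chemo = need[need["modality"] == Modality.CHEMOTHERAPY.value][
            ["income_group", "level", "year", "persons"]
        ].assign(modality_group="chemo_her2_io")
        totals = total_cost(chemo, per_person)
        out[label] = (chemo["persons"].sum(), totals["cost_aud"].sum())
    return {
        "extra_need": out["core_l"][0] - out["base"][0],
        "extra_cost_aud": out["core_l"][1] - out["base"][1],
    }
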