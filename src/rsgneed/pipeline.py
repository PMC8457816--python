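"""End-to-end pipeline: inputs -> utilization -> need -> cost -> scenarios.

This is the programmatic equivalent of the model's tailorable interface:
every input (incidence, trees, regimens, prices, assignment, category
policy) can be replaced through the documented file schemas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .costs import MODALITY_GROUPS, per_person_costs, total_cost
from .demand import (
    DEFAULT_ASSIGNMENT,
    IncomeGroup,
    compute_need,
    incidence_shares,
    percent,
)
from .io import RunConfig, load_catalog, log_run_header, read_incidence_csv, read_prices_csv
from .scenarios import (
    basic_counterfactual,
    default_scenario_ladder,
    fold_change,
    price_sensitivity,
    run_scenarios,
)
from .trees import (
    Modality,
    ResourceLevel,
    apply_category_policy,
    default_category_policy,
    expected_utilization,
    load_tree,
)

log = logging.getLogger("rsgneed")


@dataclass
class PipelineResult:
    utilization: pd.DataFrame  # level x modality proportions
    need: pd.DataFrame  # income_group x modality x year
    per_person: pd.DataFrame  # level x modality_group
    totals: pd.DataFrame  # income_group x modality_group x year
    scenarios: pd.DataFrame  # scenario x modality_group
    summary: str = ""
    extras: dict = field(default_factory=dict)


def load_inputs(config: RunConfig):
    incidence = read_incidence_csv(config.incidence_csv)
    trees = {
        level: load_tree(Path(path).read_text())
        for level, path in config.tree_paths().items()
    }
    catalog = load_catalog(Path(config.regimens_yaml).read_text())
    prices = read_prices_csv(config.prices_csv)
    return incidence, trees, catalog, prices


def utilization_frame(utils) -> pd.DataFrame:
    rows = []
    for level, u in utils.items():
        for m in Modality:
            rows.append(
                {"level": level.label, "modality": m.value, "proportion": u[m]}
            )
    return pd.DataFrame(rows)


def group_need_frame(need: pd.DataFrame) -> pd.DataFrame:
    """Need rows restricted to each modality group's denominator modality."""
    frames = []
    for gname, g in MODALITY_GROUPS.items():
        denom = g["denominator"].value
        sub = need[need["modality"] == denom][
            ["income_group", "level", "year", "persons"]
        ].assign(modality_group=gname)
        frames.append(sub)
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: RunConfig, write: bool = True) -> PipelineResult:
    """Execute the full base-case analysis described by ``config``."""
    log_run_header(config)
    incidence, raw_trees, catalog, prices = load_inputs(config)
    policy = default_category_policy()
    trees = {lv: apply_category_policy(t, policy) for lv, t in raw_trees.items()}
    utils = {lv: expected_utilization(t) for lv, t in trees.items()}
    log.info("utilization computed for %d levels", len(utils))

    needs = []
    for year in config.years:
        needs.append(compute_need(incidence, DEFAULT_ASSIGNMENT, utils, year))
    need = pd.concat(needs, ignore_index=True)
    log.info("need table: %d rows over years %s", len(need), config.years)

    per_person = per_person_costs(
        trees, catalog, prices, tier=config.tier, vial_rounding=config.vial_rounding
    )
    totals = total_cost(group_need_frame(need), per_person)
    log.info("cost totals: %d rows", len(totals))

    ladder = default_scenario_ladder()
    scen = run_scenarios(ladder, incidence, utils, per_person, config.years[0])
    log.info("scenario table: %d rows", len(scen))

    counterfactual = basic_counterfactual(incidence, utils, per_person, config.years[0])

    result = PipelineResult(
        utilization=utilization_frame(utils),
        need=need,
        per_person=per_person,
        totals=totals,
        scenarios=scen,
        extras={"basic_counterfactual": counterfactual, "incidence": incidence},
    )
    result.summary = summarize(result, config)
    if write:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        result.utilization.to_csv(outdir / "utilization.csv", index=False)
        result.need.to_csv(outdir / "need.csv", index=False)
        result.per_person.to_csv(outdir / "cost_per_person.csv", index=False)
        result.totals.to_csv(outdir / "cost_totals.csv", index=False)
        result.scenarios.to_csv(outdir / "scenarios.csv", index=False)
        (outdir / "summary.txt").write_text(result.summary)
    return result


def _need_total(need: pd.DataFrame, modality: Modality, year: int) -> float:
    sub = need[(need["modality"] == modality.value) & (need["year"] == year)]
    return float(sub["persons"].sum())


def summarize(result: PipelineResult, config: RunConfig) -> str:
    """Human-readable analogue of the need-and-cost tables."""
    lines = ["Resource-stratified need and cost of first-course systemic therapy", ""]
    incidence = result.extras["incidence"]
    for year in config.years:
        total_cases = incidence[incidence["year"] == year]["cases"].sum()
        lines.append(f"=== {year} (incident cases: {total_cases:,.0f}) ===")
        shares = incidence_shares(incidence, year)
        lines.append(
            "incidence by income group: "
            + ", ".join(
                f"{g.value} {percent(shares.get(g.value, 0.0)):.0f}%"
                for g in IncomeGroup
            )
        )
        for m in (Modality.CHEMOTHERAPY, Modality.HER2, Modality.ENDOCRINE,
                  Modality.IMMUNOTHERAPY):
            tot = _need_total(result.need, m, year)
            lines.append(
                f"need, {m.value}: {tot:,.0f} persons "
                f"({percent(tot / total_cases):.0f}% of incident cases)"
            )
        for gname in MODALITY_GROUPS:
            sub = result.totals[
                (result.totals["modality_group"] == gname)
                & (result.totals["year"] == year)
            ]
            lines.append(
                f"global cost, {gname}: ${sub['cost_aud'].sum() / 1e9:,.2f} billion AUD"
            )
        lines.append("")
    lines.append("per-person cost (AUD per person needing treatment):")
    for row in result.per_person.itertuples():
        lines.append(
            f"  {row.level:9s} {row.modality_group:16s} {row.aud_per_person:>12,.0f}"
        )
    lines.append("")
    year0 = config.years[0]
    scen = result.scenarios
    s1 = scen[scen["scenario"] == 1].set_index("modality_group")
    s7 = scen[scen["scenario"] == scen["scenario"].max()].set_index("modality_group")
    chemo_decline = 1 - s7.loc["chemo_her2_io", "need"] / s1.loc["chemo_her2_io", "need"]
    _, total_fold = fold_change(
        s1["cost_aud"].sum(), s7["cost_aud"].sum()
    )
    lines.append(
        f"upscaling to all-Maximal in {year0}: chemotherapy need "
        f"{'declines' if chemo_decline > 0 else 'rises'} by "
        f"{percent(abs(chemo_decline)):.0f}%, total cost rises "
        f"{total_fold}-fold (${s1['cost_aud'].sum() / 1e9:.0f}B to "
        f"${s7['cost_aud'].sum() / 1e9:.0f}B AUD)"
    )
    cf = result.extras["basic_counterfactual"]
    lines.append(
        f"Core services in low-income countries would add "
        f"{cf['extra_need']:,.0f} chemotherapy courses "
        f"(${cf['extra_cost_aud'] / 1e6:,.0f} million AUD)"
    )
    lines.append("")
    return "\n".join(lines)


def run_price_sensitivity(config: RunConfig, write: bool = True) -> pd.DataFrame:
    """Four price bounds (per person and global totals) for every group."""
    incidence, raw_trees, catalog, prices = load_inputs(config)
    policy = default_category_policy()
    trees = {lv: apply_category_policy(t, policy) for lv, t in raw_trees.items()}
    utils = {lv: expected_utilization(t) for lv, t in trees.items()}
    frames = []
    for mode in ("half_lowest", "lowest", "highest", "double_highest"):
        pp = price_sensitivity(trees, catalog, prices, mode)
        for year in config.years:
            need = compute_need(incidence, DEFAULT_ASSIGNMENT, utils, year)
            totals = total_cost(
                group_need_frame(need),
                pp[["level", "modality_group", "aud_per_person"]],
            )
            agg = (
                totals.groupby("modality_group")["cost_aud"].sum().reset_index()
            )
            agg["mode"] = mode
            agg["year"] = year
            frames.append(agg)
    out = pd.concat(frames, ignore_index=True)
    if write:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        out.to_csv(outdir / "price_sensitivity.csv", index=False)
    return out


def run_deescalation(config: RunConfig, write: bool = True) -> pd.DataFrame:
    """Chemotherapy de-escalation sensitivity for Core and Enhanced."""
    from .synthesis import DEESCALATED_NODE_NEG_CHEMO
    from .trees import deescalation_adjust

    _, raw_trees, _, _ = load_inputs(config)
    policy = default_category_policy()
    rows = []
    for level, subgroup_rate in DEESCALATED_NODE_NEG_CHEMO.items():
        tree = apply_category_policy(raw_trees[level], policy)
        before = expected_utilization(tree)[Modality.CHEMOTHERAPY]
        adjusted = deescalation_adjust(tree, subgroup_rate)
        after = expected_utilization(adjusted)[Modality.CHEMOTHERAPY]
        rows.append(
            {
                "level": level.label,
                "chemo_proportion": before,
                "deescalated_proportion": after,
            }
        )
    out = pd.DataFrame(rows)
    if write:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        out.to_csv(outdir / "deescalation.csv", index=False)
    return out


def run_upscaling(config: RunConfig, write: bool = True) -> pd.DataFrame:
    """The seven-scenario upscaling table (needs it computes match run_pipeline)."""
    result = run_pipeline(config, write=False)
    out = result.scenarios
    if write:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        out.to_csv(outdir / "upscaling.csv", index=False)
    return out
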