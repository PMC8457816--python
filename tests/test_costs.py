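"""Regimen costing: dosing rules, course costs, per-person and total costs."""

import numpy as np
import pandas as pd
import pytest

from rsgneed import (
    Category,
    Component,
    CostError,
    DoseKind,
    DosingRule,
    Indication,
    Modality,
    PriceTable,
    ReferencePatient,
    Regimen,
    RegimenCatalog,
    ResourceLevel,
    course_cost,
    dose_mg,
    level_cost_per_person,
    per_person_costs,
    total_cost,
)
from rsgneed.trees import TreeNode, TreeSpec

PATIENT = ReferencePatient()


def price_frame(rows):
    return PriceTable(pd.DataFrame(rows, columns=["drug", "unit_size", "price_aud", "tier"]))


class TestDoseMg:
    @pytest.mark.parametrize(
        "kind,amount,expected",
        [
            (DoseKind.PER_M2, 100.0, 180.0),  # 100 x 1.8 m2
            (DoseKind.PER_KG, 2.0, 150.0),  # 2 x 75 kg
            (DoseKind.AUC_CALVERT, 6.0, 600.0),  # 6 x (75 + 25)
            (DoseKind.FLAT, 500.0, 500.0),
        ],
    )
    def test_reference_patient_doses(self, kind, amount, expected):
        assert dose_mg(DosingRule(kind, amount), PATIENT) == expected

    def test_nonpositive_amount_rejected(self):
        with pytest.raises(CostError):
            DosingRule(DoseKind.FLAT, 0.0)

    def test_nonpositive_patient_rejected(self):
        with pytest.raises(CostError):
            ReferencePatient(bsa_m2=0.0)


class TestCourseCost:
    def test_fixed_cycle_course(self):
        # 100 mg/m2 -> 180 mg/dose, 1 dose/cycle, 4 cycles, 2 AUD/mg
        reg = Regimen(
            "r", "adjuvant",
            (Component("d", DosingRule(DoseKind.PER_M2, 100.0)),),
            n_cycles=4,
        )
        prices = price_frame([("d", 1.0, 2.0, "lowest")])
        assert course_cost(reg, prices, PATIENT) == pytest.approx(1440.0)

    def test_metastatic_course_from_median_pfs(self):
        # 1,000 AUD per monthly administration over 7.4 months
        reg = Regimen(
            "r", "metastatic",
            (Component("d", DosingRule(DoseKind.FLAT, 1.0),
                       cycle_days=365.25 / 12),),
            duration_months=7.4,
        )
        prices = price_frame([("d", 1.0, 1000.0, "lowest")])
        assert course_cost(reg, prices, PATIENT) == pytest.approx(7400.0)

    def test_zero_prices_zero_cost(self, catalog, prices):
        zero = PriceTable(prices.frame.assign(price_aud=0.0))
        for reg in catalog.regimens.values():
            assert course_cost(reg, zero, PATIENT) == 0.0

    def test_unpriced_drug_named_in_error(self):
        reg = Regimen(
            "r", "adjuvant",
            (Component("obscuredrug", DosingRule(DoseKind.FLAT, 1.0)),),
            n_cycles=1,
        )
        prices = price_frame([("other", 1.0, 1.0, "lowest")])
        with pytest.raises(CostError, match="obscuredrug"):
            course_cost(reg, prices, PATIENT)

    def test_gnrh_always_costed_over_five_years(self):
        short = Regimen(
            "r", "adjuvant",
            (Component("gnrh", DosingRule(DoseKind.FLAT, 3.6), cycle_days=28.0,
                       is_gnrh=True),),
            duration_months=24.0,  # regimen duration shorter than 5 years
        )
        prices = price_frame([("gnrh", 3.6, 100.0, "lowest")])
        expected_doses = 60 * (365.25 / 12) / 28.0
        assert course_cost(short, prices, PATIENT) == pytest.approx(
            expected_doses * 100.0
        )

    def test_add_ons_are_one_time(self):
        reg = Regimen(
            "r", "metastatic",
            (Component("d", DosingRule(DoseKind.FLAT, 1.0), cycle_days=14.0),),
            duration_months=6.0,
            add_ons=(("test_item", 1.0),),
        )
        prices = price_frame(
            [("d", 1.0, 0.0, "lowest"), ("test_item", 1.0, 150.0, "lowest")]
        )
        assert course_cost(reg, prices, PATIENT) == pytest.approx(150.0)

    def test_vial_rounding_never_cheaper(self, catalog, prices):
        for reg in catalog.regimens.values():
            exact = course_cost(reg, prices, PATIENT, vial_rounding=False)
            vial = course_cost(reg, prices, PATIENT, vial_rounding=True)
            assert vial >= exact - 1e-9

    def test_regimen_requires_exactly_one_duration(self):
        comp = (Component("d", DosingRule(DoseKind.FLAT, 1.0)),)
        with pytest.raises(CostError):
            Regimen("r", "adjuvant", comp)
        with pytest.raises(CostError):
            Regimen("r", "adjuvant", comp, n_cycles=4, duration_months=6.0)


def two_regimen_setup():
    """One-leaf tree with a single chemo indication over two regimens."""
    leaf = TreeNode(
        "leaf", "leaf", (),
        (Indication(Modality.CHEMOTHERAPY, Category.CAT1, "adjuvant", "rs"),),
    )
    tree = TreeSpec(ResourceLevel.CORE, "leaf", {"leaf": leaf}).validate()
    catalog = RegimenCatalog(
        {
            "cheap": Regimen(
                "cheap", "adjuvant",
                (Component("a", DosingRule(DoseKind.FLAT, 1.0)),), n_cycles=1,
            ),
            "dear": Regimen(
                "dear", "adjuvant",
                (Component("b", DosingRule(DoseKind.FLAT, 1.0)),), n_cycles=1,
            ),
        },
        {"rs": ("cheap", "dear")},
    )
    prices = price_frame(
        [("a", 1.0, 100.0, "lowest"), ("b", 1.0, 300.0, "lowest")]
    )
    return tree, catalog, prices


class TestLevelCostPerPerson:
    def test_equiprobable_regimens_mean(self):
        tree, catalog, prices = two_regimen_setup()
        pp = level_cost_per_person(tree, catalog, prices)
        assert pp["chemo_her2_io"] == pytest.approx(200.0)

    def test_min_max_regimen_selection(self):
        tree, catalog, prices = two_regimen_setup()
        low = level_cost_per_person(tree, catalog, prices, regimen_pick="min")
        high = level_cost_per_person(tree, catalog, prices, regimen_pick="max")
        assert low["chemo_her2_io"] == pytest.approx(100.0)
        assert high["chemo_her2_io"] == pytest.approx(300.0)

    def test_zero_denominator_reports_zero(self, trees, catalog, prices):
        pp = level_cost_per_person(trees[ResourceLevel.BASIC], catalog, prices)
        assert pp["chemo_her2_io"] == 0.0

    def test_empty_regimen_set_errors(self):
        tree, catalog, prices = two_regimen_setup()
        bad = RegimenCatalog(catalog.regimens, {"rs": ()})
        with pytest.raises(CostError, match="empty"):
            level_cost_per_person(tree, bad, prices)

    def test_headline_per_person_costs(self, trees, catalog, prices):
        expect = {
            (ResourceLevel.CORE, "chemo_her2_io"): 1278.0,
            (ResourceLevel.ENHANCED, "chemo_her2_io"): 5823.0,
            (ResourceLevel.MAXIMAL, "chemo_her2_io"): 22313.0,
            (ResourceLevel.BASIC, "endocrine_cdk46"): 1236.0,
            (ResourceLevel.MAXIMAL, "endocrine_cdk46"): 9809.0,
        }
        for (level, group), target in expect.items():
            pp = level_cost_per_person(trees[level], catalog, prices)
            assert pp[group] == pytest.approx(target, rel=0.005)

    def test_tier_ordering(self, trees, catalog, prices):
        for level in ResourceLevel:
            low = level_cost_per_person(trees[level], catalog, prices, tier="lowest")
            high = level_cost_per_person(trees[level], catalog, prices, tier="highest")
            for group in low:
                assert high[group] >= low[group] - 1e-9

    def test_linear_in_prices(self, trees, catalog, prices):
        doubled = PriceTable(prices.frame.assign(price_aud=prices.frame.price_aud * 2))
        for level in (ResourceLevel.CORE, ResourceLevel.MAXIMAL):
            base = level_cost_per_person(trees[level], catalog, prices)
            twice = level_cost_per_person(trees[level], catalog, doubled)
            for group in base:
                assert twice[group] == pytest.approx(2 * base[group], rel=1e-9)


class TestTotalCost:
    def make_need(self, persons):
        return pd.DataFrame(
            {
                "income_group": ["LM"],
                "level": ["Core"],
                "modality_group": ["chemo_her2_io"],
                "year": [2018],
                "persons": [persons],
            }
        )

    def pp_frame(self, value):
        return pd.DataFrame(
            {
                "level": ["Core"],
                "modality_group": ["chemo_her2_io"],
                "aud_per_person": [value],
            }
        )

    def test_zero_need_zero_total(self):
        out = total_cost(self.make_need(0.0), self.pp_frame(1278.0))
        assert out["cost_aud"].item() == 0.0

    def test_product_and_linearity(self):
        base = total_cost(self.make_need(1000.0), self.pp_frame(1278.0))
        assert base["cost_aud"].item() == pytest.approx(1_278_000.0)
        doubled_pp = total_cost(self.make_need(1000.0), self.pp_frame(2556.0))
        assert doubled_pp["cost_aud"].item() == pytest.approx(2 * 1_278_000.0)
        doubled_need = total_cost(self.make_need(2000.0), self.pp_frame(1278.0))
        assert doubled_need["cost_aud"].item() == pytest.approx(2 * 1_278_000.0)

    def test_dimension_mismatch_errors(self):
        with pytest.raises(CostError, match="Enhanced"):
            total_cost(
                self.make_need(10.0).assign(level="Enhanced"),
                self.pp_frame(1.0),
            )

    def test_missing_column_errors(self):
        with pytest.raises(CostError, match="persons"):
            total_cost(self.make_need(1.0).drop(columns="persons"), self.pp_frame(1))


class TestPriceTable:
    def test_duplicate_drug_tier_rejected(self):
        with pytest.raises(CostError, match="duplicate"):
            price_frame([("a", 1.0, 1.0, "lowest"), ("a", 1.0, 2.0, "lowest")])

    def test_negative_price_rejected(self):
        with pytest.raises(CostError):
            price_frame([("a", 1.0, -1.0, "lowest")])

    def test_unknown_tier_rejected(self):
        with pytest.raises(CostError, match="tier"):
            price_frame([("a", 1.0, 1.0, "median")])

    def test_fixture_prices_cover_all_catalog_drugs(self, catalog, prices):
        for reg in catalog.regimens.values():
            for comp in reg.components:
                for tier in ("lowest", "highest"):
                    prices.unit(comp.drug, tier)
            for item, _ in reg.add_ons:
                prices.unit(item, "lowest")
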