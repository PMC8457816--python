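"""Decision-tree model: parsing, validation, expectation, simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rsgneed import (
    Category,
    Indication,
    Modality,
    ResourceLevel,
    apply_category_policy,
    deescalation_adjust,
    default_category_policy,
    dump_tree,
    expected_utilization,
    load_tree,
    simulate_cohort,
)
from rsgneed.synthesis import DEESCALATED_NODE_NEG_CHEMO, build_tree
from rsgneed.trees import TreeError, TreeNode, TreeSpec, all_categories_policy

from conftest import make_random_tree

CHEMO = Modality.CHEMOTHERAPY


def brute_force(tree: TreeSpec) -> dict:
    """Independent oracle: explicit iterative path enumeration."""
    props = {m: 0.0 for m in Modality}
    stack = [(tree.root, 1.0)]
    while stack:
        nid, p = stack.pop()
        node = tree.nodes[nid]
        if node.is_leaf:
            for m in {i.modality for i in node.indications}:
                props[m] += p
        else:
            for br in node.branches:
                stack.append((br.child, p * br.probability))
    return props


def single_leaf_tree(indications) -> TreeSpec:
    return TreeSpec(
        ResourceLevel.CORE,
        "leaf",
        {"leaf": TreeNode("leaf", "leaf", (), tuple(indications))},
    ).validate()


CHEMO_CAT1_ADJ = Indication(CHEMO, Category.CAT1, "adjuvant", "rs")


class TestLoadTree:
    def test_fixture_roundtrip(self, trees):
        for level in ResourceLevel:
            text = dump_tree(build_tree(level))
            loaded = load_tree(text)
            assert loaded.level is level
            orig = expected_utilization(build_tree(level))
            back = expected_utilization(loaded)
            for m in Modality:
                assert back[m] == pytest.approx(orig[m], abs=1e-12)

    def test_probability_sum_violation_names_node(self):
        text = """
level: Core
root: r
nodes:
  r:
    attribute: x
    branches: [[a, 0.6, l1], [b, 0.5, l2]]
  l1: {attribute: leaf}
  l2: {attribute: leaf}
"""
        with pytest.raises(TreeError, match="'r'.*sum"):
            load_tree(text)

    def test_dangling_child_named(self):
        text = """
level: Core
root: r
nodes:
  r:
    attribute: x
    branches: [[a, 1.0, ghost]]
"""
        with pytest.raises(TreeError, match="ghost"):
            load_tree(text)

    def test_cycle_rejected(self):
        text = """
level: Core
root: r
nodes:
  r:
    attribute: x
    branches: [[a, 1.0, r]]
"""
        with pytest.raises(TreeError, match="cycle|parent"):
            load_tree(text)

    def test_missing_top_level_key(self):
        with pytest.raises(TreeError, match="root"):
            load_tree("level: Core\nnodes: {}")


class TestExpectedUtilization:
    def test_single_leaf_full_indication(self):
        tree = single_leaf_tree([CHEMO_CAT1_ADJ])
        assert expected_utilization(tree)[CHEMO] == 1.0

    def test_person_level_counting(self):
        both = single_leaf_tree(
            [
                CHEMO_CAT1_ADJ,
                Indication(CHEMO, Category.CAT2A, "metastatic", "rs2"),
            ]
        )
        one = single_leaf_tree([CHEMO_CAT1_ADJ])
        assert expected_utilization(both)[CHEMO] == expected_utilization(one)[CHEMO]

    def test_path_probability_conservation(self):
        for seed in range(20):
            tree = make_random_tree(seed)
            assert sum(p for _, p, _ in tree.leaf_paths()) == pytest.approx(
                1.0, abs=1e-9
            )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_matches_brute_force_enumeration(self, seed):
        tree = make_random_tree(seed)
        assert sum(1 for n in tree.nodes.values() if n.is_leaf) <= 12
        analytic = expected_utilization(tree)
        oracle = brute_force(tree)
        for m in Modality:
            assert analytic[m] == pytest.approx(oracle[m], abs=1e-12)


class TestCategoryPolicy:
    def test_cat2b_adjuvant_chemo_removed(self):
        tree = single_leaf_tree(
            [Indication(CHEMO, Category.CAT2B, "adjuvant", "rs")]
        )
        out = apply_category_policy(tree, default_category_policy())
        assert expected_utilization(out)[CHEMO] == 0.0

    def test_cat2b_adjuvant_endocrine_retained(self):
        tree = single_leaf_tree(
            [Indication(Modality.ENDOCRINE, Category.CAT2B, "adjuvant", "rs")]
        )
        out = apply_category_policy(tree, default_category_policy())
        assert expected_utilization(out)[Modality.ENDOCRINE] == 1.0

    def test_all_categories_is_identity(self):
        tree = make_random_tree(3)
        out = apply_category_policy(tree, all_categories_policy())
        before, after = expected_utilization(tree), expected_utilization(out)
        for m in Modality:
            assert after[m] == before[m]

    def test_structure_unchanged(self, trees):
        raw = build_tree(ResourceLevel.CORE)
        out = apply_category_policy(raw, default_category_policy())
        assert set(out.nodes) == set(raw.nodes)
        for nid in raw.nodes:
            assert out.nodes[nid].branches == raw.nodes[nid].branches

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6), st.integers(0, 10**6))
    def test_adding_categories_never_decreases(self, seed, subset_seed):
        tree = make_random_tree(seed)
        rng = np.random.default_rng(subset_seed)
        small = {
            (m, s): frozenset(c for c in Category if rng.random() < 0.5)
            for m in Modality
            for s in ("adjuvant", "metastatic")
        }
        big = {
            k: v | frozenset(c for c in Category if rng.random() < 0.5)
            for k, v in small.items()
        }
        u_small = expected_utilization(apply_category_policy(tree, small))
        u_big = expected_utilization(apply_category_policy(tree, big))
        for m in Modality:
            assert u_big[m] >= u_small[m] - 1e-12


class TestSimulateCohort:
    def test_deterministic_for_fixed_seed(self, trees):
        tree = trees[ResourceLevel.CORE]
        a = simulate_cohort(tree, 10, seed=42)
        b = simulate_cohort(tree, 10, seed=42)
        assert a.equals(b)

    def test_degenerate_tree_empty_records(self):
        tree = single_leaf_tree([])
        cohort = simulate_cohort(tree, 50, seed=0)
        assert not cohort[[m.value for m in Modality]].to_numpy().any()

    def test_empirical_matches_analytic_core(self, trees):
        tree = trees[ResourceLevel.CORE]
        n = 1_000_000
        cohort = simulate_cohort(tree, n, seed=123)
        analytic = expected_utilization(tree)
        for m in Modality:
            p = analytic[m]
            se = np.sqrt(max(p * (1 - p), 1e-12) / n)
            assert abs(cohort[m.value].mean() - p) <= max(3 * se, 1e-9)

    @settings(max_examples=8, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_empirical_matches_analytic_random_trees(self, seed):
        tree = make_random_tree(seed)
        n = 1_000_000
        cohort = simulate_cohort(tree, n, seed=seed + 1)
        analytic = expected_utilization(tree)
        for m in Modality:
            p = analytic[m]
            se = np.sqrt(max(p * (1 - p), 1e-12) / n)
            assert abs(cohort[m.value].mean() - p) <= max(4 * se, 1e-9)

    def test_rejects_nonpositive_n(self, trees):
        with pytest.raises(ValueError):
            simulate_cohort(trees[ResourceLevel.CORE], 0, seed=0)


class TestDeescalation:
    def test_identity_leaves_utilization_unchanged(self, trees):
        tree = trees[ResourceLevel.CORE]
        sub = [
            (leaf, p)
            for leaf, p, attrs in tree.leaf_paths()
            if attrs.get("stage") == "early"
            and attrs.get("er_status") == "positive"
            and attrs.get("her2_status") == "negative"
            and attrs.get("nodal_status") == "negative"
        ]
        mass = sum(p for _, p in sub)
        chemo = sum(
            p
            for leaf, p in sub
            if any(i.modality is CHEMO for i in leaf.indications)
        )
        out = deescalation_adjust(tree, chemo / mass)
        before, after = expected_utilization(tree), expected_utilization(out)
        for m in Modality:
            assert after[m] == pytest.approx(before[m], abs=1e-9)

    @pytest.mark.parametrize(
        "level,expected",
        [(ResourceLevel.CORE, 0.704), (ResourceLevel.ENHANCED, 0.752)],
    )
    def test_deescalated_overall_proportions(self, trees, level, expected):
        adjusted = deescalation_adjust(
            trees[level], DEESCALATED_NODE_NEG_CHEMO[level]
        )
        assert expected_utilization(adjusted)[CHEMO] == pytest.approx(
            expected, abs=0.005
        )

    def test_missing_subpath_errors(self):
        tree = single_leaf_tree([CHEMO_CAT1_ADJ])
        with pytest.raises(TreeError, match="subpath"):
            deescalation_adjust(tree, 0.5)

    def test_branch_sums_still_valid(self, trees):
        out = deescalation_adjust(trees[ResourceLevel.CORE], 0.3)
        out.validate()
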