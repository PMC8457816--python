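import numpy as np
import pytest

from rsgneed import (
    Category,
    Indication,
    Modality,
    ResourceLevel,
    build_price_table,
    build_regimen_catalog,
    make_fixture_bundle,
    policy_trees,
    write_fixture_bundle,
)
from rsgneed.trees import Branch, TreeNode, TreeSpec


@pytest.fixture(scope="session")
def trees():
    """Fixture trees with the default category policy applied."""
    return policy_trees()


@pytest.fixture(scope="session")
def catalog():
    return build_regimen_catalog()


@pytest.fixture(scope="session")
def prices():
    return build_price_table()


@pytest.fixture(scope="session")
def bundle():
    return make_fixture_bundle(seed=7)


@pytest.fixture(scope="session")
def bundle_dir(bundle, tmp_path_factory):
    path = tmp_path_factory.mktemp("bundle")
    write_fixture_bundle(bundle, path)
    return path


def make_random_tree(seed: int, max_leaves: int = 12) -> TreeSpec:
    """A random valid tree with random indications, for property tests."""
    rng = np.random.default_rng(seed)
    nodes: dict[str, TreeNode] = {}
    counter = [0]
    mods = list(Modality)
    cats = list(Category)

    def leaf_budget():
        return max_leaves - sum(1 for n in nodes.values() if n.is_leaf)

    def build(depth: int) -> str:
        nid = f"n{counter[0]}"
        counter[0] += 1
        width = int(rng.integers(2, 4))
        if depth >= 2 or leaf_budget() <= width or rng.random() < 0.3 * depth:
            inds = []
            for _ in range(int(rng.integers(0, 3))):
                inds.append(
                    Indication(
                        mods[rng.integers(len(mods))],
                        cats[rng.integers(len(cats))],
                        ("adjuvant", "metastatic")[rng.integers(2)],
                        "rs_any",
                    )
                )
            nodes[nid] = TreeNode(nid, "leaf", (), tuple(inds))
            return nid
        probs = rng.dirichlet(np.ones(width))
        branches = []
        for i, p in enumerate(probs):
            child = build(depth + 1)
            branches.append(Branch(f"v{i}", float(p), child))
        nodes[nid] = TreeNode(nid, f"attr{depth}", tuple(branches))
        return nid

    root = build(0)
    return TreeSpec(ResourceLevel.CORE, root, nodes).validate()
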