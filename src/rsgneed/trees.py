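"""Resource-stratified treatment decision trees.

A tree describes, for one NCCN resource level (Basic, Core, Enhanced,
Maximal), how incident breast-cancer patients partition over clinical
attributes (stage, ER, HER2, nodal status, performance status, multigene
risk, ...) and which systemic-therapy indications attach to each terminal
patient class.  The central quantity is the *utilization proportion*: the
fraction of incident patients with at least one first-course indication for
a modality, obtained analytically as a sum of root-to-leaf path
probabilities.  A seeded microsimulation provides an independent check of
the analytic expectation.
"""

from __future__ import annotations

import copy
import enum
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np
import yaml

#: tolerance for branch-probability and leaf-mass sums
PROB_TOL = 1e-9


class TreeError(ValueError):
    """Raised for malformed or invalid tree configurations."""


class ResourceLevel(enum.Enum):
    """NCCN resource-stratified guideline service level, ordered by rank."""

    BASIC = ("Basic", 1)
    CORE = ("Core", 2)
    ENHANCED = ("Enhanced", 3)
    MAXIMAL = ("Maximal", 4)

    def __init__(self, label: str, rank: int):
        self.label = label
        self.rank = rank

    @classmethod
    def from_label(cls, label: str) -> "ResourceLevel":
        for lv in cls:
            if lv.label.lower() == str(label).lower():
                return lv
        raise TreeError(f"unknown resource level: {label!r}")

    def __lt__(self, other: "ResourceLevel") -> bool:
        return self.rank < other.rank


class Modality(enum.Enum):
    """First-course systemic-therapy modality (plus costed services)."""

    CHEMOTHERAPY = "chemotherapy"
    ENDOCRINE = "endocrine"
    HER2 = "her2"
    CDK46 = "cdk46"
    IMMUNOTHERAPY = "immunotherapy"
    MULTIGENE_ASSAY = "multigene_assay"
    GCSF = "gcsf"
    OOPHORECTOMY = "oophorectomy"

    @classmethod
    def from_label(cls, label: str) -> "Modality":
        try:
            return cls(str(label))
        except ValueError:
            raise TreeError(f"unknown modality: {label!r}") from None


class Category(enum.Enum):
    """NCCN recommendation category (strength of evidence/consensus)."""

    CAT1 = "cat1"
    CAT2A = "cat2A"
    CAT2B = "cat2B"

    @classmethod
    def from_label(cls, label: str) -> "Category":
        for c in cls:
            if c.value.lower() == str(label).lower():
                return c
        raise TreeError(f"unknown recommendation category: {label!r}")


SETTINGS = ("adjuvant", "metastatic")


@dataclass(frozen=True)
class Indication:
    """A leaf-level treatment indication: what, how strongly, in which setting."""

    modality: Modality
    category: Category
    setting: str  # "adjuvant" | "metastatic"
    regimen_set: str

    def __post_init__(self):
        if self.setting not in SETTINGS:
            raise TreeError(f"unknown setting: {self.setting!r}")


@dataclass(frozen=True)
class Branch:
    value: str
    probability: float
    child: str


@dataclass
class TreeNode:
    id: str
    attribute: str  # patient-attribute name, or "leaf"
    branches: tuple[Branch, ...] = ()
    indications: tuple[Indication, ...] = ()

    @property
    def is_leaf(self) -> bool:
        return self.attribute == "leaf"


@dataclass
class TreeSpec:
    """A validated decision tree for one resource level."""

    level: ResourceLevel
    root: str
    nodes: dict[str, TreeNode]

    # -- validation ----------------------------------------------------

    def validate(self) -> "TreeSpec":
        if self.root not in self.nodes:
            raise TreeError(f"root node {self.root!r} not defined")
        for node in self.nodes.values():
            if node.is_leaf:
                if node.branches:
                    raise TreeError(f"leaf node {node.id!r} has branches")
                continue
            if not node.branches:
                raise TreeError(f"internal node {node.id!r} has no branches")
            for br in node.branches:
                if not (0.0 <= br.probability <= 1.0):
                    raise TreeError(
                        f"node {node.id!r}: branch probability "
                        f"{br.probability} outside [0, 1]"
                    )
                if br.child not in self.nodes:
                    raise TreeError(
                        f"node {node.id!r} references missing child {br.child!r}"
                    )
            total = sum(br.probability for br in node.branches)
            if abs(total - 1.0) > PROB_TOL:
                raise TreeError(
                    f"node {node.id!r}: branch probabilities sum to {total!r}, "
                    "expected 1"
                )
        self._check_acyclic_single_root()
        mass = sum(p for _, p, _ in self.leaf_paths())
        if abs(mass - 1.0) > PROB_TOL:
            raise TreeError(f"reachable leaf probability mass is {mass!r}, expected 1")
        return self

    def _check_acyclic_single_root(self) -> None:
        # DFS from root with colouring; also detects unreachable nodes with
        # multiple parents implicitly (a DAG that re-enters a node is rejected:
        # each node must have a single parent so path probabilities are
        # well defined as products along the unique root path).
        seen: set[str] = set()
        stack: set[str] = set()

        def visit(nid: str) -> None:
            if nid in stack:
                raise TreeError(f"cycle detected through node {nid!r}")
            if nid in seen:
                raise TreeError(f"node {nid!r} has more than one parent")
            seen.add(nid)
            stack.add(nid)
            for br in self.nodes[nid].branches:
                visit(br.child)
            stack.discard(nid)

        visit(self.root)

    # -- traversal -----------------------------------------------------

    def leaf_paths(self) -> Iterator[tuple[TreeNode, float, dict[str, str]]]:
        """Yield ``(leaf, path probability, {attribute: value})`` for every leaf."""

        def walk(nid: str, prob: float, attrs: dict[str, str]):
            node = self.nodes[nid]
            if node.is_leaf:
                yield node, prob, attrs
                return
            for br in node.branches:
                yield from walk(
                    br.child, prob * br.probability, {**attrs, node.attribute: br.value}
                )

        yield from walk(self.root, 1.0, {})

    def copy(self) -> "TreeSpec":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Category policy
# ---------------------------------------------------------------------------

#: recommendation categories modelled per (modality, setting), following the
#: guideline evidence tiers: category 1 only for adjuvant chemotherapy and
#: HER2 therapy, category 2A for metastatic chemotherapy, and categories
#: 1/2A/2B for endocrine therapy.
CategoryPolicy = Mapping[tuple[Modality, str], frozenset]

_ALL = frozenset(Category)
_1 = frozenset({Category.CAT1})
_12A = frozenset({Category.CAT1, Category.CAT2A})
_2A = frozenset({Category.CAT2A})


def default_category_policy() -> dict[tuple[Modality, str], frozenset]:
    policy: dict[tuple[Modality, str], frozenset] = {}
    for setting in SETTINGS:
        policy[(Modality.ENDOCRINE, setting)] = _ALL
        policy[(Modality.OOPHORECTOMY, setting)] = _ALL
    policy[(Modality.CHEMOTHERAPY, "adjuvant")] = _1
    policy[(Modality.CHEMOTHERAPY, "metastatic")] = _2A
    policy[(Modality.HER2, "adjuvant")] = _1
    policy[(Modality.HER2, "metastatic")] = _12A
    policy[(Modality.CDK46, "adjuvant")] = frozenset()
    policy[(Modality.CDK46, "metastatic")] = _12A
    policy[(Modality.IMMUNOTHERAPY, "adjuvant")] = frozenset()
    policy[(Modality.IMMUNOTHERAPY, "metastatic")] = _2A
    policy[(Modality.MULTIGENE_ASSAY, "adjuvant")] = _12A
    policy[(Modality.MULTIGENE_ASSAY, "metastatic")] = frozenset()
    policy[(Modality.GCSF, "adjuvant")] = _12A
    policy[(Modality.GCSF, "metastatic")] = _12A
    return policy


def all_categories_policy() -> dict[tuple[Modality, str], frozenset]:
    return {(m, s): _ALL for m in Modality for s in SETTINGS}


def apply_category_policy(tree: TreeSpec, policy: CategoryPolicy) -> TreeSpec:
    """Drop leaf indications whose category the policy excludes.

    Structure and branch probabilities are untouched; only indication lists
    shrink.  Pairs absent from the policy are treated as excluded.
    """
    out = tree.copy()
    for node in out.nodes.values():
        if node.is_leaf and node.indications:
            node.indications = tuple(
                ind
                for ind in node.indications
                if ind.category in policy.get((ind.modality, ind.setting), frozenset())
            )
    return out


# ---------------------------------------------------------------------------
# Configuration I/O (YAML dialect)
# ---------------------------------------------------------------------------


def load_tree(config_text: str) -> TreeSpec:
    """Parse a YAML tree configuration into a validated :class:`TreeSpec`.

    Expected layout::

        level: Maximal
        root: root
        nodes:
          root:
            attribute: stage
            branches:
              - [early, 0.94, node_early]
              - [metastatic, 0.06, node_met]
          some_leaf:
            attribute: leaf
            indications:
              - [chemotherapy, cat1, adjuvant, rs_chemo_adj]
    """
    try:
        raw = yaml.safe_load(config_text)
    except yaml.YAMLError as exc:
        raise TreeError(f"tree configuration is not valid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise TreeError("tree configuration must be a mapping")
    for key in ("level", "root", "nodes"):
        if key not in raw:
            raise TreeError(f"tree configuration missing top-level key {key!r}")
    level = ResourceLevel.from_label(raw["level"])
    nodes: dict[str, TreeNode] = {}
    for nid, spec in raw["nodes"].items():
        nid = str(nid)
        if not isinstance(spec, dict) or "attribute" not in spec:
            raise TreeError(f"node {nid!r}: missing 'attribute'")
        attribute = str(spec["attribute"])
        branches = []
        for item in spec.get("branches") or []:
            if not isinstance(item, (list, tuple)) or len(item) != 3:
                raise TreeError(
                    f"node {nid!r}: branch entries must be [value, probability, child]"
                )
            value, prob, child = item
            try:
                prob = float(prob)
            except (TypeError, ValueError):
                raise TreeError(
                    f"node {nid!r}: non-numeric branch probability {prob!r}"
                ) from None
            branches.append(Branch(str(value), prob, str(child)))
        indications = []
        for item in spec.get("indications") or []:
            if not isinstance(item, (list, tuple)) or len(item) != 4:
                raise TreeError(
                    f"node {nid!r}: indications must be "
                    "[modality, category, setting, regimen_set]"
                )
            mod, cat, setting, rset = item
            indications.append(
                Indication(
                    Modality.from_label(mod),
                    Category.from_label(cat),
                    str(setting),
                    str(rset),
                )
            )
        nodes[nid] = TreeNode(nid, attribute, tuple(branches), tuple(indications))
    return TreeSpec(level, str(raw["root"]), nodes).validate()


def dump_tree(tree: TreeSpec) -> str:
    """Serialize a tree back to the YAML configuration dialect."""
    nodes: dict[str, dict] = {}
    for nid, node in tree.nodes.items():
        entry: dict = {"attribute": node.attribute}
        if node.branches:
            entry["branches"] = [
                [br.value, float(br.probability), br.child] for br in node.branches
            ]
        if node.is_leaf:
            entry["indications"] = [
                [i.modality.value, i.category.value, i.setting, i.regimen_set]
                for i in node.indications
            ]
        nodes[nid] = entry
    doc = {"level": tree.level.label, "root": tree.root, "nodes": nodes}
    return yaml.safe_dump(doc, sort_keys=False, default_flow_style=None)


# ---------------------------------------------------------------------------
# Expected utilization
# ---------------------------------------------------------------------------


@dataclass
class UtilizationResult:
    """Person-level indication proportions for one resource level.

    ``proportions[m]`` is the fraction of incident patients with at least one
    first-course indication for modality ``m``; a patient indicated in both
    adjuvant and metastatic settings still counts once.
    """

    level: ResourceLevel
    proportions: dict[Modality, float] = field(default_factory=dict)

    def __getitem__(self, modality: Modality) -> float:
        return self.proportions.get(modality, 0.0)


def expected_utilization(tree: TreeSpec) -> UtilizationResult:
    """Analytic per-modality indication proportions.

    For each modality, sums path probability over leaves carrying at least
    one surviving indication for that modality (person-level counting:
    duplicate indications on one leaf contribute once).
    """
    props = {m: 0.0 for m in Modality}
    for leaf, prob, _ in tree.leaf_paths():
        for modality in {ind.modality for ind in leaf.indications}:
            props[modality] += prob
    return UtilizationResult(tree.level, props)


# ---------------------------------------------------------------------------
# Microsimulation oracle
# ---------------------------------------------------------------------------


def simulate_cohort(tree: TreeSpec, n: int, seed: int):
    """Sample ``n`` patients through the tree; one record per patient.

    Each patient follows a root-to-leaf path drawn from the branch
    probabilities (equivalently, a leaf drawn from the path-probability
    distribution).  Returns a DataFrame with the leaf id and one boolean
    column per modality, deterministic for a fixed seed.
    """
    import pandas as pd

    if n < 1:
        raise ValueError("n must be >= 1")
    leaves = list(tree.leaf_paths())
    probs = np.array([p for _, p, _ in leaves])
    probs = probs / probs.sum()  # guard rounding at the 1e-9 level
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(leaves), size=int(n), p=probs)
    flags = np.zeros((len(leaves), len(Modality)), dtype=bool)
    mod_order = list(Modality)
    for i, (leaf, _, _) in enumerate(leaves):
        for ind in leaf.indications:
            flags[i, mod_order.index(ind.modality)] = True
    data = {"leaf": [leaves[i][0].id for i in idx]}
    picked = flags[idx]
    for j, m in enumerate(mod_order):
        data[m.value] = picked[:, j]
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Chemotherapy de-escalation sensitivity
# ---------------------------------------------------------------------------

_DEESC_ATTRS = {
    "stage": "early",
    "er_status": "positive",
    "her2_status": "negative",
    "nodal_status": "negative",
}


def _chemo_leaf(leaf: TreeNode) -> bool:
    return any(ind.modality is Modality.CHEMOTHERAPY for ind in leaf.indications)


def deescalation_adjust(
    tree: TreeSpec, node_negative_chemo_proportion: float
) -> TreeSpec:
    """Retarget the chemotherapy rate among ER+/HER2-/node-negative disease.

    Models de-escalation driven by additional clinical and histologic
    features: the conditional probability that a patient in the early
    ER-positive, HER2-negative, node-negative subgroup carries a
    chemotherapy indication is reset to ``node_negative_chemo_proportion``
    by tilting the branch probabilities inside that subgroup (leaves keep
    their indications; the split between chemo-indicated and
    chemo-spared terminal classes is rescaled, then branch probabilities are
    renormalized bottom-up so every node still sums to one).
    """
    target = float(node_negative_chemo_proportion)
    if not (0.0 <= target <= 1.0):
        raise ValueError("node_negative_chemo_proportion must be in [0, 1]")

    out = tree.copy()
    sub = [
        (leaf, prob, attrs)
        for leaf, prob, attrs in out.leaf_paths()
        if all(attrs.get(k) == v for k, v in _DEESC_ATTRS.items())
    ]
    if not sub:
        raise TreeError(
            "tree has no early ER-positive / HER2-negative / node-negative subpath"
        )
    mass = sum(p for _, p, _ in sub)
    chemo_mass = sum(p for leaf, p, _ in sub if _chemo_leaf(leaf))
    current = chemo_mass / mass
    if current in (0.0, 1.0) and current != target:
        raise TreeError(
            "subgroup chemotherapy split is degenerate "
            f"(current proportion {current}); cannot rescale to {target}"
        )

    # per-leaf weights that tilt the subgroup split to the target
    weights: dict[str, float] = {}
    for leaf, _, _ in sub:
        if _chemo_leaf(leaf):
            weights[leaf.id] = target / current
        else:
            weights[leaf.id] = (1.0 - target) / (1.0 - current)

    def reweigh(nid: str) -> float:
        """Return weighted subtree mass share and rescale branch probs."""
        node = out.nodes[nid]
        if node.is_leaf:
            return weights.get(nid, 1.0)
        shares = []
        for br in node.branches:
            shares.append(br.probability * reweigh(br.child))
        total = sum(shares)
        if total > 0:
            node.branches = tuple(
                replace(br, probability=s / total)
                for br, s in zip(node.branches, shares)
            )
        return total

    reweigh(out.root)
    return out.validate()
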