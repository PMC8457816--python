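"""Readers, writers, run configuration, and report formatting.

All machine-readable outputs are plain UTF-8 CSV (comma-separated, header
row, unformatted numbers); trees, regimen catalogs and attribute
distributions travel as the YAML dialect documented in the corresponding
builders.  Human summaries format numbers only at the reporting layer.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .costs import (
    Component,
    CostError,
    DoseKind,
    DosingRule,
    PriceTable,
    Regimen,
    RegimenCatalog,
)
from .demand import DemandError, validate_incidence
from .synthesis import AttributeDistributions, FixtureBundle
from .trees import ResourceLevel, dump_tree, load_tree

log = logging.getLogger("rsgneed")


# ---------------------------------------------------------------------------
# Incidence and price CSV
# ---------------------------------------------------------------------------


def read_incidence_csv(path) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DemandError(f"{path}: cannot parse incidence CSV: {exc}") from exc
    try:
        return validate_incidence(frame)
    except DemandError as exc:
        raise DemandError(f"{path}: {exc}") from exc


def write_incidence_csv(frame: pd.DataFrame, path) -> None:
    validate_incidence(frame)
    frame.to_csv(path, index=False)


def read_prices_csv(path) -> PriceTable:
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover
        raise CostError(f"{path}: cannot parse price CSV: {exc}") from exc
    try:
        return PriceTable(frame)
    except CostError as exc:
        raise CostError(f"{path}: {exc}") from exc


def write_prices_csv(prices: PriceTable, path) -> None:
    prices.frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Regimen catalog and attribute distributions (YAML)
# ---------------------------------------------------------------------------


def dump_catalog(catalog: RegimenCatalog) -> str:
    regimens = {}
    for rid, reg in catalog.regimens.items():
        entry: dict = {"setting": reg.setting}
        if reg.n_cycles is not None:
            entry["n_cycles"] = reg.n_cycles
        else:
            entry["duration_months"] = reg.duration_months
        entry["components"] = [
            {
                "drug": c.drug,
                "kind": c.rule.kind.value,
                "amount": c.rule.amount,
                "doses_per_cycle": c.doses_per_cycle,
                "cycle_days": c.cycle_days,
                **({"duration_months": c.duration_months} if c.duration_months else {}),
                **({"is_gnrh": True} if c.is_gnrh else {}),
            }
            for c in reg.components
        ]
        if reg.add_ons:
            entry["add_ons"] = [[item, qty] for item, qty in reg.add_ons]
        regimens[rid] = entry
    doc = {
        "regimens": regimens,
        "regimen_sets": {k: list(v) for k, v in catalog.regimen_sets.items()},
    }
    return yaml.safe_dump(doc, sort_keys=False, default_flow_style=None)


def load_catalog(text: str) -> RegimenCatalog:
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict) or "regimens" not in raw or "regimen_sets" not in raw:
        raise CostError("regimen catalog must define 'regimens' and 'regimen_sets'")
    regimens: dict[str, Regimen] = {}
    for rid, entry in raw["regimens"].items():
        comps = []
        for c in entry.get("components", []):
            comps.append(
                Component(
                    drug=str(c["drug"]),
                    rule=DosingRule(DoseKind(c["kind"]), float(c["amount"])),
                    doses_per_cycle=float(c.get("doses_per_cycle", 1.0)),
                    cycle_days=float(c.get("cycle_days", 21.0)),
                    duration_months=(
                        float(c["duration_months"])
                        if c.get("duration_months")
                        else None
                    ),
                    is_gnrh=bool(c.get("is_gnrh", False)),
                )
            )
        regimens[rid] = Regimen(
            id=str(rid),
            setting=str(entry["setting"]),
            components=tuple(comps),
            n_cycles=(
                float(entry["n_cycles"]) if entry.get("n_cycles") is not None else None
            ),
            duration_months=(
                float(entry["duration_months"])
                if entry.get("duration_months") is not None
                else None
            ),
            add_ons=tuple(
                (str(i), float(q)) for i, q in entry.get("add_ons", [])
            ),
        )
    sets = {str(k): tuple(str(r) for r in v) for k, v in raw["regimen_sets"].items()}
    for sid, ids in sets.items():
        unknown = [r for r in ids if r not in regimens]
        if unknown:
            raise CostError(f"regimen set {sid!r} references unknown regimens {unknown}")
    return RegimenCatalog(regimens, sets)


def dump_distributions(dists: AttributeDistributions) -> str:
    return yaml.safe_dump(
        {"marginals": dists.marginals}, sort_keys=False, default_flow_style=False
    )


def load_distributions(text: str) -> AttributeDistributions:
    raw = yaml.safe_load(text)
    return AttributeDistributions(raw["marginals"]).validate()


# ---------------------------------------------------------------------------
# Fixture bundle on disk
# ---------------------------------------------------------------------------

TREE_FILES = {
    ResourceLevel.BASIC: "tree_basic.yaml",
    ResourceLevel.CORE: "tree_core.yaml",
    ResourceLevel.ENHANCED: "tree_enhanced.yaml",
    ResourceLevel.MAXIMAL: "tree_maximal.yaml",
}


def write_fixture_bundle(bundle: FixtureBundle, outdir) -> dict[str, str]:
    """Write the bundle to ``outdir``; return a {filename: sha256} manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_incidence_csv(bundle.incidence, outdir / "incidence.csv")
    for level, fname in TREE_FILES.items():
        (outdir / fname).write_text(dump_tree(bundle.trees[level]))
    (outdir / "attributes.yaml").write_text(dump_distributions(bundle.distributions))
    (outdir / "regimens.yaml").write_text(dump_catalog(bundle.catalog))
    write_prices_csv(bundle.prices, outdir / "prices.csv")
    manifest = {}
    for f in sorted(outdir.iterdir()):
        if f.is_file() and f.name != "MANIFEST.json":
            manifest[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def read_fixture_bundle(indir) -> FixtureBundle:
    indir = Path(indir)
    trees = {
        level: load_tree((indir / fname).read_text())
        for level, fname in TREE_FILES.items()
    }
    return FixtureBundle(
        incidence=read_incidence_csv(indir / "incidence.csv"),
        trees=trees,
        distributions=load_distributions((indir / "attributes.yaml").read_text()),
        catalog=load_catalog((indir / "regimens.yaml").read_text()),
        prices=read_prices_csv(indir / "prices.csv"),
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


class RunConfig(BaseModel):
    """Paths and options for a pipeline run."""

    incidence_csv: str
    tree_basic: str
    tree_core: str
    tree_enhanced: str
    tree_maximal: str
    regimens_yaml: str
    prices_csv: str
    years: list[int] = Field(default_factory=lambda: [2018, 2040])
    tier: str = "lowest"
    vial_rounding: bool = False
    seed: int = 0
    outdir: str = "results"

    def tree_paths(self) -> dict[ResourceLevel, str]:
        return {
            ResourceLevel.BASIC: self.tree_basic,
            ResourceLevel.CORE: self.tree_core,
            ResourceLevel.ENHANCED: self.tree_enhanced,
            ResourceLevel.MAXIMAL: self.tree_maximal,
        }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    @classmethod
    def for_bundle_dir(cls, bundle_dir, **overrides) -> "RunConfig":
        bundle_dir = Path(bundle_dir)
        return cls(
            incidence_csv=str(bundle_dir / "incidence.csv"),
            tree_basic=str(bundle_dir / TREE_FILES[ResourceLevel.BASIC]),
            tree_core=str(bundle_dir / TREE_FILES[ResourceLevel.CORE]),
            tree_enhanced=str(bundle_dir / TREE_FILES[ResourceLevel.ENHANCED]),
            tree_maximal=str(bundle_dir / TREE_FILES[ResourceLevel.MAXIMAL]),
            regimens_yaml=str(bundle_dir / "regimens.yaml"),
            prices_csv=str(bundle_dir / "prices.csv"),
            **overrides,
        )

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:12]


def log_run_header(config: RunConfig) -> None:
    log.info(
        "run seed=%s config_hash=%s python=%s numpy=%s pandas=%s",
        config.seed,
        config.config_hash(),
        platform.python_version(),
        np.__version__,
        pd.__version__,
    )
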