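"""The frozen feature schema (6 types, 26 subsets, 460 names) and the
per-node extraction driver that fills it.

The catalog is a pure constant: identical across runs, platforms and
seeds.  Feature names are qualified just enough to be unique — GLCM slots
carry a ``D<distance>A<angle>`` tag, morphology names a ``2D``/``3D``
prefix, edge names their disc radius.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import texture_features as tx
from .errors import Degenerate3DError, EmptyPairsError, SchemaError
from .io_preprocess import BAND_RADII, NodeImage, build_3d_node, section_geometry
from .morphology_features import (
    SHAPE2D_FEATURE_NAMES,
    SHAPE3D_FEATURE_NAMES,
    shape2d,
    shape3d,
)

log = logging.getLogger(__name__)

FEATURE_TYPES = (
    "Gray-Level Co-occurrence Matrix",
    "Gray-Level Size Zone Matrix",
    "Gray-Level",
    "LN morphology",
    "LN boundary",
    "Invariant moment",
)

SOURCE_REGIONS = ("inscribed-square", "largest-section", "3D-model", "boundary-band")

TOTAL_FEATURES = 460


@dataclass(frozen=True)
class Subset:
    name: str
    ftype: str
    features: tuple[str, ...]
    source_region: str


@dataclass(frozen=True)
class FeatureCatalog:
    subsets: tuple[Subset, ...]

    @property
    def types(self) -> tuple[str, ...]:
        return FEATURE_TYPES

    @property
    def total_count(self) -> int:
        return sum(len(s.features) for s in self.subsets)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(f for s in self.subsets for f in s.features)

    def subset(self, name: str) -> Subset:
        for s in self.subsets:
            if s.name == name:
                return s
        raise KeyError(name)

    def subset_union(self, names: list[str] | tuple[str, ...]) -> tuple[str, ...]:
        """Member features of the given subsets, catalog-ordered, deduplicated."""
        wanted = {f for n in names for f in self.subset(n).features}
        return tuple(f for f in self.feature_names if f in wanted)

    def to_json(self) -> str:
        return json.dumps([{
            "name": s.name, "type": s.ftype, "source_region": s.source_region,
            "features": list(s.features)} for s in self.subsets], indent=2)


@dataclass
class FeatureVector:
    node_id: str
    values: dict[str, float]
    label: Optional[str] = None

    def __post_init__(self) -> None:
        expected = catalog().feature_names
        if tuple(self.values.keys()) != expected:
            raise SchemaError("feature vector does not match the catalog schema")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.node_id)


def _build_catalog() -> FeatureCatalog:
    subsets: list[Subset] = []
    tags = [tx.glcm_config_tag(c) for c in tx.all_glcm_configs()]
    for ftype_name in tx.GLCM_FEATURE_TYPES:
        subsets.append(Subset(
            ftype_name, FEATURE_TYPES[0],
            tuple(f"{ftype_name} {t}" for t in tags), "inscribed-square"))
    subsets.append(Subset("GLSZM", FEATURE_TYPES[1],
                          tx.GLSZM_FEATURE_NAMES, "inscribed-square"))
    subsets.append(Subset("Gray-Level", FEATURE_TYPES[2],
                          tx.GRAY_LEVEL_FEATURE_NAMES, "largest-section"))
    subsets.append(Subset("3D Morphology", FEATURE_TYPES[3],
                          tuple(f"3D {n}" for n in SHAPE3D_FEATURE_NAMES),
                          "3D-model"))
    subsets.append(Subset("2D Morphology", FEATURE_TYPES[3],
                          tuple(f"2D {n}" for n in SHAPE2D_FEATURE_NAMES),
                          "largest-section"))
    for r in BAND_RADII:
        subsets.append(Subset(f"Edge {r}", FEATURE_TYPES[4],
                              tuple(f"Edge {r} {n}" for n in tx.EDGE_FEATURE_NAMES),
                              "boundary-band"))
    subsets.append(Subset("Invariant moment", FEATURE_TYPES[5],
                          tx.HU_FEATURE_NAMES, "inscribed-square"))
    cat = FeatureCatalog(tuple(subsets))
    names = cat.feature_names
    assert len(subsets) == 26 and cat.total_count == TOTAL_FEATURES
    assert len(set(names)) == len(names)
    return cat


_CATALOG = _build_catalog()


def catalog() -> FeatureCatalog:
    """The fixed 26-subset, 460-feature schema."""
    return _CATALOG


# ---------------------------------------------------------------------------
# extraction driver
# ---------------------------------------------------------------------------

def extract_all(node: NodeImage) -> FeatureVector:
    """Compute every catalog feature for one preprocessed node.

    Features whose geometry is degenerate on this node (single-slice 3D
    model, inscribed square smaller than a GLCM displacement) are imputed
    as 0 with a warning so vectors stay rectangular.
    """
    geom = section_geometry(node)
    section = node.volume[geom.largest_section_index].astype(np.float64)
    r0, c0, side = geom.inscribed_square
    patch = section[r0:r0 + side, c0:c0 + side]
    q = tx.quantize(patch)

    values: dict[str, float] = {}

    glcm_by_tag: dict[str, dict[str, float]] = {}
    for cfg in tx.all_glcm_configs():
        tag = tx.glcm_config_tag(cfg)
        try:
            glcm_by_tag[tag] = tx.glcm_features(tx.glcm(q, cfg))
        except EmptyPairsError:
            warnings.warn(
                f"inscribed square side {side} too small for {tag}; imputing 0")
            glcm_by_tag[tag] = {k: 0.0 for k in tx.GLCM_FEATURE_TYPES}
    for ftype_name in tx.GLCM_FEATURE_TYPES:
        for cfg in tx.all_glcm_configs():
            tag = tx.glcm_config_tag(cfg)
            values[f"{ftype_name} {tag}"] = glcm_by_tag[tag][ftype_name]

    values.update(tx.glszm_features(q))
    values.update(tx.gray_level_features(section[geom.section_mask]))

    try:
        model = build_3d_node(node)
        s3 = shape3d(model)
    except Degenerate3DError as exc:
        warnings.warn(f"3D features imputed as 0: {exc}")
        s3 = {n: 0.0 for n in SHAPE3D_FEATURE_NAMES}
    values.update({f"3D {k}": v for k, v in s3.items()})
    values.update({f"2D {k}": v for k, v in shape2d(geom.section_mask).items()})

    for r in BAND_RADII:
        ef = tx.edge_features(section, geom.boundary_bands[r])
        values.update({f"Edge {r} {k}": v for k, v in ef.items()})

    try:
        values.update(tx.invariant_moments(patch))
    except Exception as exc:  # zero-intensity patch
        warnings.warn(f"invariant moments imputed as 0: {exc}")
        values.update({n: 0.0 for n in tx.HU_FEATURE_NAMES})

    ordered = {name: float(values[name]) for name in _CATALOG.feature_names}
    bad = [k for k, v in ordered.items() if not np.isfinite(v)]
    if bad:
        warnings.warn(f"non-finite features imputed as 0: {bad[:5]}...")
        for k in bad:
            ordered[k] = 0.0
    return FeatureVector(node.node_id, ordered, node.label)


# ---------------------------------------------------------------------------
# feature-table I/O
# ---------------------------------------------------------------------------

def vectors_to_table(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into a table with node_id and label columns."""
    rows = []
    for v in vectors:
        row = {"node_id": v.node_id, "label": v.label}
        row.update(v.values)
        rows.append(row)
    return pd.DataFrame(rows, columns=["node_id", "label", *_CATALOG.feature_names])


def write_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, index=False)


def read_table(path: str) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in ("node_id", "label") if c not in table.columns]
    if missing:
        raise SchemaError(f"feature table missing columns: {missing}")
    return table


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Feature columns of a table (everything except the id/label columns)."""
    return [c for c in table.columns if c not in ("node_id", "label")]
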