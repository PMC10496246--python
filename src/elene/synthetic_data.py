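"""Synthetic lymph-node phantoms and planted-signal feature tables.

The phantom generator encodes the class-conditional trends the pipeline
is meant to pick up: interior texture variance ordered
normal > metastatic > ENE, boundary blur widest for ENE, and surface
perturbation smallest for ENE by default (so ENE nodes have the highest
solidity; the direction is a flag because it runs against naive
geometric intuition).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_preprocess import LABELS, NodeImage, write_bundle

DEFAULT_SPACING = (0.468, 0.468, 3.0)


@dataclass(frozen=True)
class ClassParams:
    """Generative texture/shape parameters of one node class."""

    texture_sigma: float      # gray-value SD of the interior random field
    texture_scale: float      # correlation length of the field, voxels
    surface_amp: float        # radial surface perturbation amplitude
    blur_width: float         # boundary blur half-width, pixels


@dataclass(frozen=True)
class PhantomSpec:
    """Class-conditional generative parameters for synthetic nodes."""

    normal: ClassParams = ClassParams(45.0, 0.8, 0.14, 0.5)
    metastatic: ClassParams = ClassParams(28.0, 1.6, 0.20, 1.5)
    ene: ClassParams = ClassParams(14.0, 2.6, 0.08, 3.0)
    axis_range_mm: tuple[float, float] = (6.0, 11.0)
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    interior_level: float = 150.0
    background_level: float = 70.0
    background_sigma: float = 6.0
    counts: tuple[int, int, int] = (100, 100, 100)  # per class
    seed: int = 0
    ene_highest_solidity: bool = True

    def __post_init__(self) -> None:
        if min(self.counts) < 1:
            raise ValueError("counts must be >= 1 per class")
        if min(self.spacing) <= 0:
            raise ValueError("spacing must be positive")
        for p in (self.normal, self.metastatic, self.ene):
            if p.texture_sigma <= 0:
                raise ValueError("texture variance levels must be positive")

    def params_for(self, label: str) -> ClassParams:
        p = {"normal": self.normal, "metastatic": self.metastatic,
             "ENE": self.ene}[label]
        if not self.ene_highest_solidity and label in ("normal", "ENE"):
            other = self.normal if label == "ENE" else self.ene
            p = replace(p, surface_amp=other.surface_amp)
        return p


def _smooth_field(rng: np.random.Generator, shape: tuple[int, ...],
                  scale: float) -> np.ndarray:
    """Unit-variance Gaussian random field with the given correlation length."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=scale)
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_node(spec: PhantomSpec, label: str, seed: int,
                  node_id: str | None = None) -> NodeImage:
    """One deterministic phantom node of the given class.

    An ellipsoid with smooth radial surface perturbation, interior
    Gaussian-random-field texture, and a distance-weighted boundary blur,
    rasterized at the spec spacing.
    """
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}")
    p = spec.params_for(label)
    rng = np.random.default_rng([spec.seed, LABELS.index(label), seed])

    lo, hi = spec.axis_range_mm
    sx, sy, sz = spec.spacing
    lo_z = max(lo, 2.1 * sz)
    if lo_z > hi or lo < 2.0 * max(sx, sy):
        raise ValueError("phantom axes smaller than 2 voxels at this spacing")
    ax, ay = rng.uniform(lo, hi, size=2)
    az = rng.uniform(lo_z, hi)

    margin_xy = 10.0 * sx + 3.0   # room for the radius-10 band + blur
    margin_z = sz
    nx = int(np.ceil(2 * (ax + margin_xy) / sx))
    ny = int(np.ceil(2 * (ay + margin_xy) / sy))
    nz = int(np.ceil(2 * (az + margin_z) / sz))
    z, y, x = np.meshgrid(
        (np.arange(nz) - (nz - 1) / 2) * sz,
        (np.arange(ny) - (ny - 1) / 2) * sy,
        (np.arange(nx) - (nx - 1) / 2) * sx,
        indexing="ij")
    d = np.sqrt((x / ax) ** 2 + (y / ay) ** 2 + (z / az) ** 2)

    surf = _smooth_field(rng, d.shape, scale=3.0)
    mask = d <= 1.0 + p.surface_amp * surf

    texture = _smooth_field(rng, d.shape, scale=p.texture_scale)
    interior = spec.interior_level + p.texture_sigma * texture
    background = spec.background_level + spec.background_sigma * \
        rng.standard_normal(d.shape)
    sharp = np.where(mask, interior, background)

    if p.blur_width > 0:
        blurred = np.stack([ndimage.gaussian_filter(s, sigma=p.blur_width)
                            for s in sharp])
        dist = np.stack([
            np.minimum(ndimage.distance_transform_edt(m),
                       ndimage.distance_transform_edt(~m))
            for m in mask])
        w = np.clip(1.0 - dist / (2.0 * p.blur_width + 1e-9), 0.0, 1.0)
        img = w * blurred + (1.0 - w) * sharp
    else:
        img = sharp

    vol = np.clip(np.round(img), 0, 255).astype(np.uint8)
    nid = node_id or f"{label}_{seed:04d}"
    return NodeImage(vol, mask, spec.spacing, node_id=nid, label=label)


@dataclass
class Cohort:
    train: list[NodeImage]
    test: list[NodeImage]
    manifest: pd.DataFrame


def generate_cohort(spec: PhantomSpec,
                    out_dir: str | Path | None = None) -> Cohort:
    """Generate all phantom nodes and split them train/test 8:2, stratified.

    With ``out_dir`` set, NIfTI+JSON bundles and a manifest CSV are written;
    the split and every node are deterministic functions of the spec seed.
    """
    rng = np.random.default_rng([spec.seed, 991])
    train, test, rows = [], [], []
    for ci, label in enumerate(LABELS):
        n = spec.counts[ci]
        n_test = int(round(n * 0.2))
        is_test = np.zeros(n, dtype=bool)
        is_test[rng.choice(n, size=n_test, replace=False)] = True
        for k in range(n):
            node = generate_node(spec, label, k)
            (test if is_test[k] else train).append(node)
            rows.append({"node_id": node.node_id, "label": label,
                         "split": "test" if is_test[k] else "train",
                         "seed": k})
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for split, nodes in (("train", train), ("test", test)):
            for node in nodes:
                write_bundle(node, out / split)
        manifest.to_csv(out / "manifest.csv", index=False)
        (out / "spec.json").write_text(json.dumps(
            {"seed": spec.seed, "counts": list(spec.counts),
             "spacing": list(spec.spacing)}, indent=2))
    return Cohort(train, test, manifest)


# ---------------------------------------------------------------------------
# planted-signal feature tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TableSpec:
    """Parameters of a planted-signal feature table."""

    n_per_class: int = 50
    p: int = 30
    k: int = 3
    effect: float = 3.0       # class-mean shift in SD units
    rho: float = 0.0          # shared-factor correlation of the noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k > self.p:
            raise ValueError("k must be <= p")
        if self.effect < 0:
            raise ValueError("effect size must be >= 0")


@dataclass
class PlantedTable:
    frame: pd.DataFrame
    informative: tuple[str, ...]


def generate_table(spec: TableSpec) -> PlantedTable:
    """Three balanced classes; ``k`` informative columns receive
    class-conditional mean shifts of ``effect`` SD units, the rest are
    standard normal noise.

    Informative columns carry one-vs-rest patterns that cycle through the
    classes, so no informative column is redundant: dropping one collapses
    the margin of the class pair it tells apart.
    """
    rng = np.random.default_rng(spec.seed)
    n = 3 * spec.n_per_class
    labels = np.repeat(LABELS, spec.n_per_class)
    X = rng.standard_normal((n, spec.p))
    if spec.rho > 0:
        shared = rng.standard_normal((n, 1))
        X = np.sqrt(1 - spec.rho) * X + np.sqrt(spec.rho) * shared
    cols = [f"f{i:03d}" for i in range(spec.p)]
    info_idx = rng.choice(spec.p, size=spec.k, replace=False)
    for rank, j in enumerate(info_idx):
        ci = rank % 3
        sel = slice(ci * spec.n_per_class, (ci + 1) * spec.n_per_class)
        X[sel, j] += spec.effect
    frame = pd.DataFrame(X, columns=cols)
    frame.insert(0, "label", labels)
    frame.insert(0, "node_id", [f"s{i:04d}" for i in range(n)])
    return PlantedTable(frame, tuple(cols[i] for i in sorted(info_idx)))
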