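"""Texture feature extractors: GLCM, GLSZM, gray-level statistics, Hu moments,
and boundary-band (edge) features.

Conventions fixed across the package: gray values are quantized from the
display range [0, 255] into 16 equal-width bins; GLCMs are symmetrized and
normalized; logarithms are base 2 with 0*log(0) := 0; GLSZM zones are
8-connected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import stats as sstats

from .errors import (
    ContractError,
    DegenerateMomentsError,
    EmptyPairsError,
    EmptyROIError,
    ParameterError,
)

N_LEVELS = 16
GLCM_DIRECTIONS = (0, 45, 90, 135)
GLCM_DISTANCES = (1, 2, 3, 4, 5)

GLCM_FEATURE_TYPES = (
    "Cluster Shade", "Cluster Proximity", "Contrast", "Correlation",
    "Different Entropy", "Different Variance", "Dissimilarity", "Energy",
    "Entropy", "Homogeneity Normalized", "Homogeneity", "InfoCorrelation1",
    "InfoCorrelation2", "Max Probability", "Sum Average", "Sum Entropy",
    "Sum of variance", "Variance",
)

GLSZM_FEATURE_NAMES = (
    "Small area emphasis", "Large area emphasis",
    "Low intensity emphasis", "High intensity emphasis",
    "Low intensity small area emphasis", "Low intensity large area emphasis",
    "High intensity small area emphasis", "High intensity large area emphasis",
    "Intensity variance", "Size zone variance", "Zone%",
)

GRAY_LEVEL_FEATURE_NAMES = (
    "Mean", "Median", "Variance", "Standard deviation", "Max Pixel Value",
    "Min Pixel Value", "Skewness", "Kurtosis", "Energy", "Entropy", "Range",
)

EDGE_FEATURE_NAMES = (
    "Mean inside", "Mean outside", "SD inside", "SD outside",
    "Mean difference", "SD difference",
)

HU_FEATURE_NAMES = tuple(f"Hu{i}" for i in range(1, 8))


@dataclass(frozen=True)
class GLCMConfig:
    """Displacement configuration of one co-occurrence matrix."""

    levels: int = N_LEVELS
    direction: int = 0       # degrees, one of {0, 45, 90, 135}
    distance: int = 1        # pixels
    symmetric: bool = True
    normalized: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ParameterError("levels must be >= 2")
        if self.distance < 1:
            raise ParameterError("distance must be >= 1")
        if self.direction not in (0, 45, 90, 135):
            raise ParameterError("direction must be one of 0, 45, 90, 135")

    @property
    def offset(self) -> tuple[int, int]:
        """(drow, dcol) displacement for this direction/distance."""
        d = self.distance
        return {0: (0, d), 45: (-d, d), 90: (-d, 0), 135: (-d, -d)}[self.direction]


def quantize(patch: np.ndarray, levels: int = N_LEVELS) -> np.ndarray:
    """Uniformly bin the fixed [0, 255] display range into ``levels`` bins."""
    if levels < 2:
        raise ParameterError("levels must be >= 2")
    patch = np.asarray(patch)
    if patch.size == 0:
        raise EmptyROIError("quantize: empty patch")
    return np.clip((patch.astype(np.int64) * levels) // 256, 0, levels - 1)


def glcm(patch: np.ndarray, cfg: GLCMConfig = GLCMConfig()) -> np.ndarray:
    """Symmetric, normalized gray-level co-occurrence matrix of a quantized patch."""
    patch = np.asarray(patch)
    dr, dc = cfg.offset
    h, w = patch.shape
    if h <= abs(dr) or w <= abs(dc):
        raise EmptyPairsError(
            f"patch {patch.shape} too small for displacement {(dr, dc)}")
    r0 = slice(max(0, -dr), min(h, h - dr))
    c0 = slice(max(0, -dc), min(w, w - dc))
    r1 = slice(max(0, dr), min(h, h + dr))
    c1 = slice(max(0, dc), min(w, w + dc))
    a = patch[r0, c0].ravel()
    b = patch[r1, c1].ravel()
    mat = np.zeros((cfg.levels, cfg.levels), dtype=np.float64)
    np.add.at(mat, (a, b), 1.0)
    if cfg.symmetric:
        mat = mat + mat.T
    if cfg.normalized:
        mat /= mat.sum()
    return mat


def glcm_features(P: np.ndarray) -> dict[str, float]:
    """The 18 co-occurrence statistics of one normalized GLCM.

    Haralick definitions with log base 2; "Cluster Proximity" is cluster
    prominence and "Homogeneity Normalized" is the inverse difference
    moment normalized by level count.
    """
    P = np.asarray(P, dtype=np.float64)
    if not np.isclose(P.sum(), 1.0, atol=1e-8):
        raise ContractError("GLCM must be normalized to sum 1")
    n = P.shape[0]
    i = np.arange(n, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mux = float((i * px).sum())
    muy = float((i * py).sum())
    sx = float(np.sqrt(((i - mux) ** 2 * px).sum()))
    sy = float(np.sqrt(((i - muy) ** 2 * py).sum()))

    # p_{x+y}(k), k = 0..2n-2 and p_{x-y}(k), k = 0..n-1
    psum = np.zeros(2 * n - 1)
    np.add.at(psum, (ii + jj).astype(int).ravel(), P.ravel())
    pdiff = np.zeros(n)
    np.add.at(pdiff, np.abs(ii - jj).astype(int).ravel(), P.ravel())
    k_sum = np.arange(2 * n - 1, dtype=np.float64)
    k_diff = np.arange(n, dtype=np.float64)

    contrast = float((pdiff * k_diff ** 2).sum())
    dissimilarity = float((pdiff * k_diff).sum())
    energy = float((P ** 2).sum())
    entropy = float(-_xlog2(P).sum())
    homogeneity = float((P / (1.0 + (ii - jj) ** 2)).sum())
    hom_norm = float((P / (1.0 + np.abs(ii - jj) / n)).sum())
    maxprob = float(P.max())
    variance = float(((ii - mux) ** 2 * P).sum())
    if sx > 0 and sy > 0:
        correlation = float((((ii - mux) * (jj - muy) * P).sum()) / (sx * sy))
    else:
        correlation = 1.0
    cluster_shade = float((((ii + jj) - mux - muy) ** 3 * P).sum())
    cluster_prox = float((((ii + jj) - mux - muy) ** 4 * P).sum())
    sum_avg = float((k_sum * psum).sum())
    sum_entropy = float(-_xlog2(psum).sum())
    sum_var = float(((k_sum - sum_avg) ** 2 * psum).sum())
    diff_entropy = float(-_xlog2(pdiff).sum())
    diff_avg = float((k_diff * pdiff).sum())
    diff_var = float(((k_diff - diff_avg) ** 2 * pdiff).sum())

    hx = float(-_xlog2(px).sum())
    hy = float(-_xlog2(py).sum())
    pxy = np.outer(px, py)
    hxy1 = float(-(P * _log2s(pxy)).sum())
    hxy2 = float(-(pxy * _log2s(pxy)).sum())
    denom = max(hx, hy)
    ic1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    arg = max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))
    ic2 = float(np.sqrt(arg))

    return {
        "Cluster Shade": cluster_shade,
        "Cluster Proximity": cluster_prox,
        "Contrast": contrast,
        "Correlation": correlation,
        "Different Entropy": diff_entropy,
        "Different Variance": diff_var,
        "Dissimilarity": dissimilarity,
        "Energy": energy,
        "Entropy": entropy,
        "Homogeneity Normalized": hom_norm,
        "Homogeneity": homogeneity,
        "InfoCorrelation1": float(ic1),
        "InfoCorrelation2": ic2,
        "Max Probability": maxprob,
        "Sum Average": sum_avg,
        "Sum Entropy": sum_entropy,
        "Sum of variance": sum_var,
        "Variance": variance,
    }


def _xlog2(p: np.ndarray) -> np.ndarray:
    """p * log2(p) with the 0*log(0) = 0 convention."""
    out = np.zeros_like(p, dtype=np.float64)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _log2s(p: np.ndarray) -> np.ndarray:
    """log2(p) with log(0) masked to 0 (only ever multiplied by 0 there)."""
    out = np.zeros_like(p, dtype=np.float64)
    nz = p > 0
    out[nz] = np.log2(p[nz])
    return out


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

_EIGHT = np.ones((3, 3), dtype=int)


def size_zone_matrix(patch: np.ndarray, levels: int = N_LEVELS) -> np.ndarray:
    """Counts of 8-connected constant-level zones, indexed (level, size-1)."""
    patch = np.asarray(patch)
    if patch.size == 0:
        raise EmptyROIError("size_zone_matrix: empty patch")
    max_size = patch.size
    Z = np.zeros((levels, max_size), dtype=np.float64)
    for lev in range(levels):
        lab, nlab = ndimage.label(patch == lev, structure=_EIGHT)
        if nlab == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            Z[lev, s - 1] += 1
    return Z


def glszm_features(patch: np.ndarray, levels: int = N_LEVELS) -> dict[str, float]:
    """The 11 size-zone statistics (Thibault definitions).

    Intensity indices use level value + 1 so the lowest bin does not
    divide by zero.
    """
    Z = size_zone_matrix(patch, levels)
    total = Z.sum()
    n_pix = np.asarray(patch).size
    lev = np.arange(1, levels + 1, dtype=np.float64)[:, None]     # i
    size = np.arange(1, Z.shape[1] + 1, dtype=np.float64)[None, :]  # s

    sae = float((Z / size ** 2).sum() / total)
    lae = float((Z * size ** 2).sum() / total)
    lie = float((Z / lev ** 2).sum() / total)
    hie = float((Z * lev ** 2).sum() / total)
    lisae = float((Z / (lev ** 2 * size ** 2)).sum() / total)
    lilae = float((Z * size ** 2 / lev ** 2).sum() / total)
    hisae = float((Z * lev ** 2 / size ** 2).sum() / total)
    hilae = float((Z * lev ** 2 * size ** 2).sum() / total)

    p = Z / total
    mu_i = float((p * lev).sum())
    iv = float((p * (lev - mu_i) ** 2).sum())
    mu_s = float((p * size).sum())
    szv = float((p * (size - mu_s) ** 2).sum())
    zp = float(total / n_pix)

    return dict(zip(GLSZM_FEATURE_NAMES,
                    (sae, lae, lie, hie, lisae, lilae, hisae, hilae,
                     iv, szv, zp)))


# ---------------------------------------------------------------------------
# gray-level statistics
# ---------------------------------------------------------------------------

def gray_level_features(pixels: np.ndarray) -> dict[str, float]:
    """First-order statistics of a masked gray-value selection.

    Energy and entropy are computed on the 256-bin value histogram;
    variance/SD are population statistics; skewness and kurtosis (Fisher)
    of a constant region are imputed as 0.
    """
    v = np.asarray(pixels, dtype=np.float64).ravel()
    if v.size == 0:
        raise EmptyROIError("gray_level_features: empty selection")
    hist = np.bincount(np.clip(v.astype(int), 0, 255), minlength=256)
    p = hist / hist.sum()
    var = float(v.var())
    if var > 0:
        skew = float(sstats.skew(v, bias=True))
        kurt = float(sstats.kurtosis(v, fisher=True, bias=True))
    else:
        skew = kurt = 0.0
    return {
        "Mean": float(v.mean()),
        "Median": float(np.median(v)),
        "Variance": var,
        "Standard deviation": float(np.sqrt(var)),
        "Max Pixel Value": float(v.max()),
        "Min Pixel Value": float(v.min()),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Energy": float((p ** 2).sum()),
        "Entropy": float(-_xlog2(p).sum()),
        "Range": float(v.max() - v.min()),
    }


# ---------------------------------------------------------------------------
# invariant moments
# ---------------------------------------------------------------------------

def invariant_moments(patch: np.ndarray) -> dict[str, float]:
    """The seven Hu moments of a gray-value patch."""
    patch = np.asarray(patch, dtype=np.float64)
    if patch.sum() <= 0:
        raise DegenerateMomentsError("invariant_moments: zero total intensity")
    from skimage.measure import moments_central, moments_hu, moments_normalized

    m00 = patch.sum()
    r, c = np.mgrid[0:patch.shape[0], 0:patch.shape[1]]
    cr = (r * patch).sum() / m00
    cc = (c * patch).sum() / m00
    mu = moments_central(patch, center=(cr, cc), order=3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        nu = moments_normalized(mu, order=3)
    hu = moments_hu(nu)
    return dict(zip(HU_FEATURE_NAMES, (float(h) for h in hu)))


# ---------------------------------------------------------------------------
# boundary (edge) features
# ---------------------------------------------------------------------------

def edge_features(section: np.ndarray,
                  bands: tuple[np.ndarray, np.ndarray]) -> dict[str, float]:
    """Gray-value statistics of the inner vs. outer boundary band.

    An empty band (node touching the image border) imputes its statistics
    as 0 with a warning rather than failing the whole vector.
    """
    inside_band, outside_band = bands
    section = np.asarray(section, dtype=np.float64)
    stats = []
    for name, band in (("inside", inside_band), ("outside", outside_band)):
        if band.sum() == 0:
            warnings.warn(f"empty {name} boundary band, imputing 0")
            stats.append((0.0, 0.0))
        else:
            vals = section[band.astype(bool)]
            stats.append((float(vals.mean()), float(vals.std())))
    (mi, si), (mo, so) = stats
    return {
        "Mean inside": mi,
        "Mean outside": mo,
        "SD inside": si,
        "SD outside": so,
        "Mean difference": mi - mo,
        "SD difference": si - so,
    }


def all_glcm_configs() -> list[GLCMConfig]:
    """The 20 (direction, distance) GLCM configurations, distance-major."""
    return [GLCMConfig(direction=a, distance=d)
            for d in GLCM_DISTANCES for a in GLCM_DIRECTIONS]


def glcm_config_tag(cfg: GLCMConfig) -> str:
    """Catalog tag for one configuration, e.g. ``D1A45``."""
    return f"D{cfg.distance}A{cfg.direction}"
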