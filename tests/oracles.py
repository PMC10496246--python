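"""Independent brute-force oracles used to cross-check the package.

Everything here is written as literal transcriptions of textbook
definitions (scalar loops, exhaustive enumeration) and shares no code
path with the implementations under test.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------

def window_scalar(pixel: float, slope: float, intercept: float,
                  wc: float, ww: float) -> int:
    hu = pixel * slope + intercept
    frac = (hu - (wc - ww / 2.0)) / ww
    frac = min(max(frac, 0.0), 1.0)
    return int(math.floor(frac * 255.0 + 0.5))


# ---------------------------------------------------------------------------
# point in polygon (even-odd), scalar
# ---------------------------------------------------------------------------

def point_in_polygon(qx: float, qy: float, poly: np.ndarray) -> bool:
    inside = False
    n = len(poly)
    j = n - 1
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[j]
        if (y1 > qy) != (y2 > qy):
            xs = (x2 - x1) * (qy - y1) / (y2 - y1) + x1
            if qx < xs:
                inside = not inside
        j = i
    return inside


# ---------------------------------------------------------------------------
# largest inscribed square, exhaustive
# ---------------------------------------------------------------------------

def inscribed_square_bruteforce(mask: np.ndarray) -> tuple[int, int, int]:
    h, w = mask.shape
    best = None
    for side in range(min(h, w), 0, -1):
        for r in range(h - side + 1):
            for c in range(w - side + 1):
                if mask[r:r + side, c:c + side].all():
                    if best is None or (r, c) < best[:2]:
                        best = (r, c, side)
        if best is not None:
            return best
    raise ValueError("empty mask")


# ---------------------------------------------------------------------------
# GLCM: pair counting + Haralick formulas, all scalar loops
# ---------------------------------------------------------------------------

def glcm_bruteforce(patch: np.ndarray, dr: int, dc: int,
                    levels: int) -> np.ndarray:
    h, w = patch.shape
    mat = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                mat[patch[r, c], patch[r2, c2]] += 1
    mat = mat + mat.T
    return mat / mat.sum()


def _log2(x: float) -> float:
    return math.log(x, 2) if x > 0 else 0.0


def haralick_oracle(P: np.ndarray) -> dict[str, float]:
    n = P.shape[0]
    px = [sum(P[i][j] for j in range(n)) for i in range(n)]
    py = [sum(P[i][j] for i in range(n)) for j in range(n)]
    mux = sum(i * px[i] for i in range(n))
    muy = sum(j * py[j] for j in range(n))
    sx = math.sqrt(sum((i - mux) ** 2 * px[i] for i in range(n)))
    sy = math.sqrt(sum((j - muy) ** 2 * py[j] for j in range(n)))

    psum = [0.0] * (2 * n - 1)
    pdiff = [0.0] * n
    for i in range(n):
        for j in range(n):
            psum[i + j] += P[i][j]
            pdiff[abs(i - j)] += P[i][j]

    contrast = sum(P[i][j] * (i - j) ** 2 for i in range(n) for j in range(n))
    dissim = sum(P[i][j] * abs(i - j) for i in range(n) for j in range(n))
    energy = sum(P[i][j] ** 2 for i in range(n) for j in range(n))
    entropy = -sum(P[i][j] * _log2(P[i][j]) for i in range(n) for j in range(n))
    homog = sum(P[i][j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n))
    homn = sum(P[i][j] / (1 + abs(i - j) / n) for i in range(n) for j in range(n))
    maxp = max(P[i][j] for i in range(n) for j in range(n))
    variance = sum((i - mux) ** 2 * P[i][j] for i in range(n) for j in range(n))
    if sx > 0 and sy > 0:
        corr = sum((i - mux) * (j - muy) * P[i][j]
                   for i in range(n) for j in range(n)) / (sx * sy)
    else:
        corr = 1.0
    shade = sum((i + j - mux - muy) ** 3 * P[i][j]
                for i in range(n) for j in range(n))
    prox = sum((i + j - mux - muy) ** 4 * P[i][j]
               for i in range(n) for j in range(n))
    sum_avg = sum(k * psum[k] for k in range(2 * n - 1))
    sum_ent = -sum(psum[k] * _log2(psum[k]) for k in range(2 * n - 1))
    sum_var = sum((k - sum_avg) ** 2 * psum[k] for k in range(2 * n - 1))
    diff_ent = -sum(pdiff[k] * _log2(pdiff[k]) for k in range(n))
    diff_avg = sum(k * pdiff[k] for k in range(n))
    diff_var = sum((k - diff_avg) ** 2 * pdiff[k] for k in range(n))

    hx = -sum(px[i] * _log2(px[i]) for i in range(n))
    hy = -sum(py[j] * _log2(py[j]) for j in range(n))
    hxy1 = -sum(P[i][j] * _log2(px[i] * py[j])
                for i in range(n) for j in range(n))
    hxy2 = -sum(px[i] * py[j] * _log2(px[i] * py[j])
                for i in range(n) for j in range(n))
    denom = max(hx, hy)
    ic1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    ic2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - entropy))))

    return {
        "Cluster Shade": shade, "Cluster Proximity": prox,
        "Contrast": contrast, "Correlation": corr,
        "Different Entropy": diff_ent, "Different Variance": diff_var,
        "Dissimilarity": dissim, "Energy": energy, "Entropy": entropy,
        "Homogeneity Normalized": homn, "Homogeneity": homog,
        "InfoCorrelation1": ic1, "InfoCorrelation2": ic2,
        "Max Probability": maxp, "Sum Average": sum_avg,
        "Sum Entropy": sum_ent, "Sum of variance": sum_var,
        "Variance": variance,
    }


# ---------------------------------------------------------------------------
# GLSZM via explicit flood fill
# ---------------------------------------------------------------------------

def _zones_floodfill(patch: np.ndarray, level: int) -> list[int]:
    h, w = patch.shape
    seen = np.zeros((h, w), dtype=bool)
    sizes = []
    for r in range(h):
        for c in range(w):
            if patch[r, c] != level or seen[r, c]:
                continue
            stack = [(r, c)]
            seen[r, c] = True
            size = 0
            while stack:
                rr, cc = stack.pop()
                size += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        r2, c2 = rr + dr, cc + dc
                        if (0 <= r2 < h and 0 <= c2 < w and not seen[r2, c2]
                                and patch[r2, c2] == level):
                            seen[r2, c2] = True
                            stack.append((r2, c2))
            sizes.append(size)
    return sizes


def glszm_oracle(patch: np.ndarray, levels: int) -> dict[str, float]:
    zones = [(lev + 1, s) for lev in range(levels)
             for s in _zones_floodfill(patch, lev)]
    Z = len(zones)
    N = patch.size
    sae = sum(1.0 / s ** 2 for _, s in zones) / Z
    lae = sum(float(s) ** 2 for _, s in zones) / Z
    lie = sum(1.0 / i ** 2 for i, _ in zones) / Z
    hie = sum(float(i) ** 2 for i, _ in zones) / Z
    lisae = sum(1.0 / (i ** 2 * s ** 2) for i, s in zones) / Z
    lilae = sum(s ** 2 / i ** 2 for i, s in zones) / Z
    hisae = sum(i ** 2 / s ** 2 for i, s in zones) / Z
    hilae = sum(float(i) ** 2 * s ** 2 for i, s in zones) / Z
    mu_i = sum(i for i, _ in zones) / Z
    iv = sum((i - mu_i) ** 2 for i, _ in zones) / Z
    mu_s = sum(s for _, s in zones) / Z
    szv = sum((s - mu_s) ** 2 for _, s in zones) / Z
    return {
        "Small area emphasis": sae, "Large area emphasis": lae,
        "Low intensity emphasis": lie, "High intensity emphasis": hie,
        "Low intensity small area emphasis": lisae,
        "Low intensity large area emphasis": lilae,
        "High intensity small area emphasis": hisae,
        "High intensity large area emphasis": hilae,
        "Intensity variance": iv, "Size zone variance": szv,
        "Zone%": Z / N,
    }


# ---------------------------------------------------------------------------
# first-order statistics
# ---------------------------------------------------------------------------

def gray_level_oracle(vals: np.ndarray) -> dict[str, float]:
    v = [float(x) for x in np.ravel(vals)]
    n = len(v)
    mean = sum(v) / n
    var = sum((x - mean) ** 2 for x in v) / n
    sd = math.sqrt(var)
    sv = sorted(v)
    median = (sv[n // 2] if n % 2 else (sv[n // 2 - 1] + sv[n // 2]) / 2.0)
    if sd > 0:
        skew = sum(((x - mean) / sd) ** 3 for x in v) / n
        kurt = sum(((x - mean) / sd) ** 4 for x in v) / n - 3.0
    else:
        skew = kurt = 0.0
    counts = [0] * 256
    for x in v:
        counts[int(x)] += 1
    p = [c / n for c in counts]
    energy = sum(q ** 2 for q in p)
    entropy = -sum(q * _log2(q) for q in p)
    return {
        "Mean": mean, "Median": median, "Variance": var,
        "Standard deviation": sd, "Max Pixel Value": max(v),
        "Min Pixel Value": min(v), "Skewness": skew, "Kurtosis": kurt,
        "Energy": energy, "Entropy": entropy, "Range": max(v) - min(v),
    }


# ---------------------------------------------------------------------------
# Hu moments, literal formulas
# ---------------------------------------------------------------------------

def hu_oracle(patch: np.ndarray) -> list[float]:
    patch = np.asarray(patch, dtype=float)
    h, w = patch.shape
    m00 = patch.sum()
    cr = sum(r * patch[r, c] for r in range(h) for c in range(w)) / m00
    cc = sum(c * patch[r, c] for r in range(h) for c in range(w)) / m00

    def mu(p, q):
        return sum((r - cr) ** p * (c - cc) ** q * patch[r, c]
                   for r in range(h) for c in range(w))

    def eta(p, q):
        return mu(p, q) / m00 ** (1 + (p + q) / 2.0)

    n20, n02, n11 = eta(2, 0), eta(0, 2), eta(1, 1)
    n30, n03, n21, n12 = eta(3, 0), eta(0, 3), eta(2, 1), eta(1, 2)
    a = n30 + n12
    b = n21 + n03
    phi1 = n20 + n02
    phi2 = (n20 - n02) ** 2 + 4 * n11 ** 2
    phi3 = (n30 - 3 * n12) ** 2 + (3 * n21 - n03) ** 2
    phi4 = a ** 2 + b ** 2
    phi5 = (n30 - 3 * n12) * a * (a ** 2 - 3 * b ** 2) + \
        (3 * n21 - n03) * b * (3 * a ** 2 - b ** 2)
    phi6 = (n20 - n02) * (a ** 2 - b ** 2) + 4 * n11 * a * b
    phi7 = (3 * n21 - n03) * a * (a ** 2 - 3 * b ** 2) - \
        (n30 - 3 * n12) * b * (3 * a ** 2 - b ** 2)
    return [phi1, phi2, phi3, phi4, phi5, phi6, phi7]


# ---------------------------------------------------------------------------
# AUC by all-pairs counting
# ---------------------------------------------------------------------------

def auc_pairs_oracle(scores: np.ndarray, truth: np.ndarray) -> float:
    pos = [s for s, t in zip(scores, truth) if t == 1]
    neg = [s for s, t in zip(scores, truth) if t == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return 100.0 * wins / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# morphology helpers
# ---------------------------------------------------------------------------

def band_oracle(mask: np.ndarray, radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel dilation/erosion by a disc: a pixel is in the dilation iff
    some mask pixel lies within the disc, in the erosion iff every disc
    offset stays inside the mask."""
    h, w = mask.shape
    offs = [(dr, dc) for dr in range(-radius, radius + 1)
            for dc in range(-radius, radius + 1)
            if dr * dr + dc * dc <= radius * radius]
    dil = np.zeros_like(mask)
    ero = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            hit = any(0 <= r + dr < h and 0 <= c + dc < w
                      and mask[r + dr, c + dc] for dr, dc in offs)
            dil[r, c] = hit
            # out-of-bounds counts as background (scipy border_value=0)
            ero[r, c] = mask[r, c] and all(
                0 <= r + dr < h and 0 <= c + dc < w and mask[r + dr, c + dc]
                for dr, dc in offs)
    inside = mask & ~ero
    outside = dil & ~mask
    return inside, outside
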