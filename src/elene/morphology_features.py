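"""2D and 3D shape descriptors of the node region.

2D features are measured on the largest mask section (pixel units unless
scaled by spacing); 3D features on the isotropic model from
``io_preprocess.build_3d_node`` (mm units).  Where the literature offers
several conventions, the one used here is stated in the docstring and
frozen so values are reproducible:

* Convexity = convex perimeter (surface) / perimeter (surface).
* Defects Ratio = (convex area - area) / convex area (volume analogue in 3D).
* Rectangularity = area / minimum-area rotated bounding rectangle
  (3D: volume / principal-axis-aligned bounding box).
* Elongation = 1 - minor/major axis length.
* Roundness = 4*area / (pi * major_axis^2); in 3D the sphericity-type
  ratio (36*pi*V^2)^(1/3) / S.
* Ellipticity = area / area of the fitted second-moment ellipse
  (3D: volume / volume of the fitted ellipsoid).
* Sphericity (2D) = perimeter of the equal-area circle / perimeter.
* Aspect radii (3D) = pairwise ratios of sorted principal axis lengths.

Perimeter uses the Crofton estimator (4 directions); pixel-edge counting
overestimates smooth boundaries and biases Compactness.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

from .errors import EmptyROIError
from .io_preprocess import Node3D

log = logging.getLogger(__name__)

SHAPE2D_FEATURE_NAMES = (
    "Area", "Perimeter", "Major Axis Length", "Minor Axis Length",
    "Orientation", "Convexity", "Convex Area", "Convex Perimeter",
    "Maximum radius", "Bounding Box Area", "Defects Ratio",
    "Perimeter Area Ratio", "Aspect Ratio", "Bending Energy", "Eccentricity",
    "Equivalent Diameter", "Solidity", "Extent", "Compactness",
    "Rectangularity", "Elongation", "Roundness", "Ellipticity", "Sphericity",
)

SHAPE3D_FEATURE_NAMES = (
    "Volume", "Surface", "Equivalent diameter", "Extent",
    "Principal Axis Length1", "Principal Axis Length2", "Principal Axis Length3",
    "Orientation1", "Orientation2", "Orientation3",
    "Eccentricity", "Solidity", "Convex volume", "Convex surface", "Convexity",
    "Compactness", "Rectangularity", "Elongation", "Roundness",
    "Area volume ratio", "Aspect radius1", "Aspect radius2", "Aspect radius3",
    "Max radius", "Bounding box volume", "Ellipticity", "Defect ratio",
    "Gaussian Curvature sum", "Mean Curvature sum",
)


def shape2d(section_mask: np.ndarray) -> dict[str, float]:
    """The 24 planar shape features of a section mask (pixel units)."""
    mask = np.asarray(section_mask, dtype=bool)
    if not mask.any():
        raise EmptyROIError("shape2d: empty mask")
    lab, nlab = ndimage.label(mask)
    if nlab > 1:
        log.info("shape2d: %d components, keeping largest", nlab)
        sizes = np.bincount(lab.ravel())[1:]
        mask = lab == (int(np.argmax(sizes)) + 1)

    props = measure.regionprops(mask.astype(np.uint8))[0]
    area = float(props.area)
    perimeter = float(measure.perimeter_crofton(mask, directions=4))
    major = float(props.axis_major_length)
    minor = float(props.axis_minor_length)
    orientation = float(np.degrees(props.orientation))
    convex_area = float(props.area_convex)
    convex_perimeter = float(
        measure.perimeter_crofton(props.image_convex, directions=4))
    bbox_area = float(props.image.shape[0] * props.image.shape[1])

    cy, cx = props.centroid
    rr, cc = np.nonzero(mask)
    max_radius = float(np.sqrt(((rr - cy) ** 2 + (cc - cx) ** 2).max()))

    bending = _bending_energy(mask)
    rect = _min_rect_area(mask)

    minor_s = max(minor, 1.0)  # single-pixel-wide shapes have zero axis
    major_s = max(major, 1.0)
    return {
        "Area": area,
        "Perimeter": perimeter,
        "Major Axis Length": major,
        "Minor Axis Length": minor,
        "Orientation": orientation,
        "Convexity": convex_perimeter / max(perimeter, 1e-12),
        "Convex Area": convex_area,
        "Convex Perimeter": convex_perimeter,
        "Maximum radius": max_radius,
        "Bounding Box Area": bbox_area,
        "Defects Ratio": (convex_area - area) / convex_area,
        "Perimeter Area Ratio": perimeter / area,
        "Aspect Ratio": major_s / minor_s,
        "Bending Energy": bending,
        "Eccentricity": float(props.eccentricity),
        "Equivalent Diameter": float(props.equivalent_diameter_area),
        "Solidity": area / convex_area,
        "Extent": area / bbox_area,
        "Compactness": 4.0 * np.pi * area / max(perimeter, 1e-12) ** 2,
        "Rectangularity": area / max(rect, 1e-12),
        "Elongation": 1.0 - minor_s / major_s,
        "Roundness": 4.0 * area / (np.pi * major_s ** 2),
        "Ellipticity": area / (np.pi * (major_s / 2.0) * (minor_s / 2.0)),
        "Sphericity": 2.0 * np.sqrt(np.pi * area) / max(perimeter, 1e-12),
    }


def _bending_energy(mask: np.ndarray) -> float:
    """Sum of squared discrete curvature along the longest boundary contour."""
    contours = measure.find_contours(np.pad(mask.astype(float), 1), 0.5)
    if not contours:
        return 0.0
    c = max(contours, key=len)[:-1]  # closed: last point repeats the first
    if len(c) < 5:
        return 0.0
    prev = np.roll(c, 1, axis=0)
    nxt = np.roll(c, -1, axis=0)
    d1 = (nxt - prev) / 2.0
    d2 = nxt - 2.0 * c + prev
    speed2 = (d1 ** 2).sum(axis=1)
    cross = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(speed2 > 0, cross / np.power(speed2, 1.5), 0.0)
    return float((kappa ** 2).sum())


def _min_rect_area(mask: np.ndarray) -> float:
    """Area of the minimum-area rotated rectangle containing the region."""
    from shapely import MultiPoint

    rr, cc = np.nonzero(mask)
    pts = MultiPoint(list(zip(cc.tolist(), rr.tolist())))
    rect = pts.convex_hull.minimum_rotated_rectangle
    # each pixel is a unit cell; pad the point rectangle by the half-pixel rim
    area = rect.area if rect.geom_type == "Polygon" else 0.0
    return float(max(area, mask.sum()))


def shape3d(model: Node3D) -> dict[str, float]:
    """The 29 volumetric shape features of an isotropic node model (mm units)."""
    mask = model.mask
    if not mask.any():
        raise EmptyROIError("shape3d: empty 3D mask")
    vs = model.voxel_size
    voxvol = vs ** 3
    volume = float(mask.sum() * voxvol)
    surface = float(mesh_area(model.vertices, model.faces))

    zz, yy, xx = np.nonzero(mask)
    pts = np.column_stack([zz, yy, xx]).astype(np.float64) * vs
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)          # ascending
    evals = np.clip(evals, 0.0, None)
    # uniform solid ellipsoid: eigenvalue = semi_axis^2 / 5
    semi = np.sqrt(5.0 * evals)
    lengths = np.sort(2.0 * semi)[::-1]          # descending: L1 >= L2 >= L3
    L1, L2, L3 = (float(v) for v in lengths)
    orient = _euler_angles(evecs)

    bbox_extent = np.ptp(pts, axis=0) + vs       # voxel-centre span + 1 voxel
    bbox_volume = float(np.prod(bbox_extent))
    proj = centered @ evecs
    pbox = np.ptp(proj, axis=0) + vs
    pbox_volume = float(np.prod(pbox))

    try:
        hull = ConvexHull(pts)
        convex_volume = float(hull.volume)
        convex_surface = float(hull.area)
    except QhullError:
        convex_volume, convex_surface = volume, surface
    convex_volume = max(convex_volume, volume)   # voxelized hull can undershoot

    max_radius = float(np.sqrt((centered ** 2).sum(axis=1).max()))
    eq_diam = float((6.0 * volume / np.pi) ** (1.0 / 3.0))
    roundness = float((36.0 * np.pi * volume ** 2) ** (1.0 / 3.0)
                      / max(surface, 1e-12))
    gauss_sum, mean_sum = curvature_sums(model.vertices, model.faces)

    l3s = max(L3, vs)
    l1s = max(L1, vs)
    l2s = max(L2, vs)
    ell_vol = 4.0 / 3.0 * np.pi * (l1s / 2) * (l2s / 2) * (l3s / 2)
    return {
        "Volume": volume,
        "Surface": surface,
        "Equivalent diameter": eq_diam,
        "Extent": volume / bbox_volume,
        "Principal Axis Length1": L1,
        "Principal Axis Length2": L2,
        "Principal Axis Length3": L3,
        "Orientation1": orient[0],
        "Orientation2": orient[1],
        "Orientation3": orient[2],
        "Eccentricity": float(np.sqrt(max(0.0, 1.0 - (l3s / l1s) ** 2))),
        "Solidity": volume / convex_volume,
        "Convex volume": convex_volume,
        "Convex surface": convex_surface,
        "Convexity": convex_surface / max(surface, 1e-12),
        "Compactness": 36.0 * np.pi * volume ** 2 / max(surface, 1e-12) ** 3,
        "Rectangularity": volume / max(pbox_volume, 1e-12),
        "Elongation": 1.0 - l2s / l1s,
        "Roundness": roundness,
        "Area volume ratio": surface / volume,
        "Aspect radius1": l1s / l2s,
        "Aspect radius2": l1s / l3s,
        "Aspect radius3": l2s / l3s,
        "Max radius": max_radius,
        "Bounding box volume": bbox_volume,
        "Ellipticity": volume / ell_vol,
        "Defect ratio": (convex_volume - volume) / convex_volume,
        "Gaussian Curvature sum": gauss_sum,
        "Mean Curvature sum": mean_sum,
    }


def _euler_angles(evecs: np.ndarray) -> tuple[float, float, float]:
    """ZYX Euler angles (degrees) of the inertia eigenvector frame.

    Eigenvectors come in ascending-eigenvalue order; each is sign-fixed so
    its first nonzero component is positive, and the frame is made
    right-handed before decomposition.
    """
    R = evecs.copy()
    for k in range(3):
        col = R[:, k]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if len(nz) and col[nz[0]] < 0:
            R[:, k] = -col
    if np.linalg.det(R) < 0:
        R[:, 2] = -R[:, 2]
    sy = np.sqrt(R[0, 0] ** 2 + R[1, 0] ** 2)
    if sy > 1e-8:
        ang = (np.arctan2(R[2, 1], R[2, 2]),
               np.arctan2(-R[2, 0], sy),
               np.arctan2(R[1, 0], R[0, 0]))
    else:
        ang = (np.arctan2(-R[1, 2], R[1, 1]), np.arctan2(-R[2, 0], sy), 0.0)
    return tuple(float(np.degrees(a)) for a in ang)


def mesh_area(verts: np.ndarray, faces: np.ndarray) -> float:
    """Total triangle area of a mesh."""
    v = verts[faces]
    cross = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    return float(0.5 * np.linalg.norm(cross, axis=1).sum())


def mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    """Enclosed volume of a closed mesh (signed tetrahedron sum)."""
    v = verts[faces]
    return float(abs(np.einsum("ij,ij->i", v[:, 0],
                               np.cross(v[:, 1], v[:, 2])).sum()) / 6.0)


def is_watertight(faces: np.ndarray) -> bool:
    """True iff every edge is shared by exactly two faces."""
    edges = np.sort(np.concatenate(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return bool((counts == 2).all())


def curvature_sums(verts: np.ndarray, faces: np.ndarray) -> tuple[float, float]:
    """Discrete total Gaussian and mean curvature of a triangle mesh.

    Gaussian: angle defect 2*pi - sum(incident angles) summed over
    vertices (Gauss-Bonnet: 4*pi for genus 0).  Mean: sum over edges of
    |e| * dihedral_angle / 2.
    """
    v = verts[faces]
    angle_sum = np.zeros(len(verts))
    for k in range(3):
        a = v[:, k] - v[:, (k + 1) % 3]
        b = v[:, k] - v[:, (k + 2) % 3]
        cosang = np.einsum("ij,ij->i", a, b) / (
            np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1) + 1e-300)
        ang = np.arccos(np.clip(cosang, -1.0, 1.0))
        np.add.at(angle_sum, faces[:, k], ang)
    used = np.zeros(len(verts), dtype=bool)
    used[faces.ravel()] = True
    gauss = float((2.0 * np.pi - angle_sum)[used].sum())

    normals = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    normals /= (np.linalg.norm(normals, axis=1, keepdims=True) + 1e-300)
    edge_faces: dict[tuple[int, int], list[int]] = {}
    for fi, f in enumerate(faces):
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            key = (int(min(a, b)), int(max(a, b)))
            edge_faces.setdefault(key, []).append(fi)
    mean = 0.0
    for (a, b), fs in edge_faces.items():
        if len(fs) != 2:
            continue
        cosd = float(np.clip(np.dot(normals[fs[0]], normals[fs[1]]), -1.0, 1.0))
        dihedral = float(np.arccos(cosd))
        elen = float(np.linalg.norm(verts[a] - verts[b]))
        mean += elen * dihedral / 2.0
    return gauss, float(mean)
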