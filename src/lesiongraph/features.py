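"""Ten clinically motivated ROI features for breast-ultrasound lesions.

Morphology: circularity, solidity, enclosing-ellipse ratio, rim brightness.
Texture: Shannon entropy, GLCM entropy/correlation/dissimilarity/contrast,
and histogram energy.  All texture statistics are computed over lesion
pixels only (mask = 1); the zero background introduced by the bitwise-AND
ROI extraction would otherwise dominate every histogram and co-occurrence
count.

Conventions: coordinates are 0-based (row, col); masks are binarized at
``> 0``; both entropies use log base 2 with 0*log(0) := 0.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as _dc_fields

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import regionprops, label as _sk_label

DEFAULT_GLCM_LEVELS = 8
DEFAULT_GLCM_DISTANCE = 1
DEFAULT_BAND_K = 10
GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)

FEATURE_NAMES = [
    "circularity",
    "solidity",
    "shannon_entropy",
    "glcm_entropy",
    "glcm_correlation",
    "glcm_dissimilarity",
    "glcm_contrast",
    "hist_energy",
    "ellipse_ratio",
    "brightness",
]


class DimensionError(ValueError):
    pass


class EmptyROIError(ValueError):
    pass


class DegenerateRegionError(ValueError):
    pass


class BandEmptyError(ValueError):
    pass


class NoPairsError(ValueError):
    pass


class NormalizationError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureVector:
    """The ten feature values for one lesion, in table column order."""

    circularity: float
    solidity: float
    shannon_entropy: float
    glcm_entropy: float
    glcm_correlation: float
    glcm_dissimilarity: float
    glcm_contrast: float
    hist_energy: float
    ellipse_ratio: float
    brightness: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in _dc_fields(self)], dtype=float)


def _as_mask(mask) -> np.ndarray:
    m = np.asarray(mask)
    if m.ndim != 2:
        raise DimensionError("mask must be 2-D")
    return (m > 0).astype(np.uint8)


def _require_nonempty(mask: np.ndarray) -> None:
    if not mask.any():
        raise EmptyROIError("mask has no foreground pixels")


def extract_roi(image, mask) -> np.ndarray:
    """Bitwise-AND ROI: image pixel where mask=1, else 0."""
    image = np.asarray(image)
    m = _as_mask(mask)
    if image.shape != m.shape:
        raise DimensionError(
            f"image shape {image.shape} != mask shape {m.shape}")
    _require_nonempty(m)
    return (image * m).astype(image.dtype)


def _single_region(mask: np.ndarray):
    lab = _sk_label(mask, connectivity=2)
    props = regionprops(lab)
    # features are defined on the lesion = largest component
    return max(props, key=lambda p: p.area)


def circularity(mask) -> float:
    """4*area / (pi * d_max^2), d_max = major axis of the equivalent ellipse.

    1 for a disk, smaller for elongated or spiculated shapes.
    """
    m = _as_mask(mask)
    _require_nonempty(m)
    p = _single_region(m)
    d_max = p.axis_major_length
    if d_max <= 0:
        raise DegenerateRegionError("region has zero major axis")
    return 4.0 * p.area / (np.pi * d_max**2)


_CORNER_OFFSETS = np.array([[0.5, 0.5], [0.5, -0.5], [-0.5, 0.5], [-0.5, -0.5]])


def solidity(mask) -> float:
    """Region area divided by convex-hull area; 1 for convex regions.

    Both numerator and denominator count pixel centers: the hull area is
    the number of grid centers inside the convex hull polygon of the
    region's boundary centers.  This keeps the two measures on the same
    discretization footing (a convex region scores ~1, and the ratio can
    never exceed 1, since every region center lies in the hull).
    """
    from scipy.spatial import ConvexHull, Delaunay

    m = _as_mask(mask)
    _require_nonempty(m)
    p = _single_region(m)
    coords = p.coords.astype(float)
    if coords.shape[0] < 3 or np.linalg.matrix_rank(coords - coords.mean(0)) < 2:
        raise DegenerateRegionError("need >= 3 non-collinear foreground pixels")
    region = np.zeros(m.shape, dtype=bool)
    region[tuple(p.coords.T)] = True
    eroded = ndimage.binary_erosion(region, border_value=0)
    boundary = np.argwhere(region & ~eroded).astype(float)
    hull = ConvexHull(boundary)
    tri = Delaunay(boundary[hull.vertices])
    (r0, c0), (r1, c1) = boundary.min(0).astype(int), boundary.max(0).astype(int)
    rr, cc = np.mgrid[r0:r1 + 1, c0:c1 + 1]
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    hull_area = int((tri.find_simplex(pts) >= 0).sum())
    return float(p.area / hull_area)


def min_area_enclosing_ellipse(points: np.ndarray, tol: float = 1e-6,
                               max_iter: int = 100_000):
    """Minimum-volume enclosing ellipsoid (Khachiyan's algorithm) in 2-D.

    Returns (center, shape matrix A) with the ellipse {x : (x-c)' A (x-c) <= 1}.
    Only the convex-hull vertices of ``points`` enter the iteration (the
    solution depends on them alone); iteration stops when the relative
    optimality gap max_i M_i/(d+1) - 1 drops below ``tol``.
    """
    from scipy.spatial import ConvexHull

    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise DegenerateRegionError("need >= 3 boundary points")
    try:
        pts = pts[ConvexHull(pts).vertices]
    except Exception as exc:  # coplanar/collinear input
        raise DegenerateRegionError(f"degenerate point set: {exc}") from exc
    n, d = pts.shape
    Q = np.column_stack([pts, np.ones(n)]).T  # (d+1, n)
    u = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        X = (Q * u) @ Q.T
        M = np.einsum("ij,ji->i", Q.T, np.linalg.solve(X, Q))
        j_add = int(np.argmax(M))
        gap = M[j_add] / (d + 1.0) - 1.0
        if gap <= tol:
            break
        # away-step variant: also consider shrinking the least useful
        # support point, which gives linear instead of sublinear convergence
        support = u > 0
        j_away = int(np.flatnonzero(support)[np.argmin(M[support])])
        eps_away = 1.0 - M[j_away] / (d + 1.0)
        if gap >= eps_away:
            j = j_add
            step = (M[j] - d - 1.0) / ((d + 1.0) * (M[j] - 1.0))
        else:
            j = j_away
            step = (M[j] - d - 1.0) / ((d + 1.0) * (M[j] - 1.0))
            step = max(step, -u[j] / (1.0 - u[j]))
        u *= 1.0 - step
        u[j] += step
    center = pts.T @ u
    cov = (pts.T * u) @ pts - np.outer(center, center)
    A = np.linalg.inv(cov) / d
    return center, A


def ellipse_ratio(mask) -> float:
    """Area of the minimum enclosing ellipse of the boundary / lesion area.

    Near 1 for elliptical lesions; grows with spiculation, since spikes push
    the enclosing ellipse out while adding little area.
    """
    m = _as_mask(mask)
    _require_nonempty(m)
    p = _single_region(m)
    region = np.zeros(m.shape, dtype=bool)
    region[tuple(p.coords.T)] = True
    eroded = ndimage.binary_erosion(region, border_value=0)
    boundary = np.argwhere(region & ~eroded).astype(float)
    if boundary.shape[0] < 3 or np.linalg.matrix_rank(boundary - boundary.mean(0)) < 2:
        raise DegenerateRegionError("degenerate boundary")
    # +/- 0.5 px corner offsets so the ellipse encloses whole pixels, which
    # keeps the ratio >= 1 up to discretization
    corners = (boundary[:, None, :] + _CORNER_OFFSETS[None, :, :]).reshape(-1, 2)
    _, A = min_area_enclosing_ellipse(corners)
    ell_area = np.pi / np.sqrt(np.linalg.det(A))
    return float(ell_area / p.area)


def brightness(image, mask, band_k: int = DEFAULT_BAND_K) -> float:
    """|mean intensity just outside - mean just inside| the lesion boundary.

    Both bands extend ``band_k`` pixels from the boundary (Euclidean distance
    map); measures the sharpness/contrast of the lesion rim.
    """
    image = np.asarray(image, dtype=float)
    m = _as_mask(mask)
    if image.shape != m.shape:
        raise DimensionError("image and mask shapes differ")
    _require_nonempty(m)
    if band_k < 1:
        raise ValueError("band_k must be >= 1")
    dist_out = ndimage.distance_transform_edt(m == 0)   # distance to lesion
    dist_in = ndimage.distance_transform_edt(m == 1)    # distance to background
    outer = (dist_out > 0) & (dist_out <= band_k)
    inner = (dist_in > 0) & (dist_in <= band_k)
    if not outer.any() or not inner.any():
        raise BandEmptyError("boundary band is empty")
    avg_tissue = image[outer].mean()
    avg_out = image[inner].mean()
    return float(abs(avg_tissue - avg_out))


def shannon_entropy(roi, mask) -> float:
    """Shannon entropy (bits) of the intensity histogram of masked pixels."""
    roi = np.asarray(roi)
    m = _as_mask(mask)
    if roi.shape != m.shape:
        raise DimensionError("roi and mask shapes differ")
    _require_nonempty(m)
    vals = roi[m > 0]
    _, counts = np.unique(vals, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum()) + 0.0


def hist_energy(roi, mask) -> float:
    """Sum of squared histogram proportions of masked pixels; in (0, 1]."""
    roi = np.asarray(roi)
    m = _as_mask(mask)
    if roi.shape != m.shape:
        raise DimensionError("roi and mask shapes differ")
    _require_nonempty(m)
    vals = roi[m > 0]
    _, counts = np.unique(vals, return_counts=True)
    r = counts / counts.sum()
    return float((r**2).sum())


def _quantize(roi: np.ndarray, levels: int) -> np.ndarray:
    """Uniform binning of [0, 255] into ``levels`` gray levels."""
    q = (roi.astype(np.int64) * levels) // 256
    return np.clip(q, 0, levels - 1)


_ANGLE_OFFSETS = {
    0.0: (0, 1),
    np.pi / 4: (-1, 1),
    np.pi / 2: (-1, 0),
    3 * np.pi / 4: (-1, -1),
}


def glcm(roi, mask, levels: int = DEFAULT_GLCM_LEVELS,
         distance: int = DEFAULT_GLCM_DISTANCE,
         angles=GLCM_ANGLES) -> np.ndarray:
    """Masked gray-level co-occurrence matrix.

    Counts pairs of quantized levels at offset ``distance`` along each angle,
    keeping only pairs with *both* pixels inside the mask; accumulated over
    the angles, symmetrized, normalized to sum 1.
    """
    roi = np.asarray(roi)
    m = _as_mask(mask)
    if roi.shape != m.shape:
        raise DimensionError("roi and mask shapes differ")
    _require_nonempty(m)
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if distance < 1:
        raise ValueError("distance must be >= 1")
    q = _quantize(roi, levels)
    P = np.zeros((levels, levels), dtype=np.float64)
    H, W = roi.shape
    for ang in angles:
        dr, dc = _ANGLE_OFFSETS[float(ang)]
        dr, dc = dr * distance, dc * distance
        r0s, r0e = max(0, -dr), min(H, H - dr)
        c0s, c0e = max(0, -dc), min(W, W - dc)
        if r0s >= r0e or c0s >= c0e:
            continue
        a = q[r0s:r0e, c0s:c0e]
        b = q[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
        valid = (m[r0s:r0e, c0s:c0e] > 0) & (m[r0s + dr:r0e + dr, c0s + dc:c0e + dc] > 0)
        np.add.at(P, (a[valid], b[valid]), 1.0)
    total = P.sum()
    if total == 0:
        raise NoPairsError("no co-occurring pixel pairs inside the mask")
    P = (P + P.T) / (2.0 * total)
    return P


def glcm_features(P: np.ndarray, normalized_correlation: bool = True):
    """GLCM entropy (bits), correlation, dissimilarity and contrast.

    ``normalized_correlation=True`` divides the covariance form by the
    marginal standard deviations so the value lies in [-1, 1]; ``False``
    returns the raw covariance form.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise DimensionError("P must be square")
    if (P < 0).any() or abs(P.sum() - 1.0) > 1e-9:
        raise NormalizationError("P must be non-negative and sum to 1")
    G = P.shape[0]
    i = np.arange(G)[:, None]
    j = np.arange(G)[None, :]
    nz = P > 0
    entropy = float(-(P[nz] * np.log2(P[nz])).sum()) + 0.0  # avoid -0.0
    dissimilarity = float((P * np.abs(i - j)).sum())
    contrast = float((P * (i - j) ** 2).sum())
    mu_i = float((P * i).sum())
    mu_j = float((P * j).sum())
    cov = float((P * (i - mu_i) * (j - mu_j)).sum())
    if normalized_correlation:
        var_i = float((P * (i - mu_i) ** 2).sum())
        var_j = float((P * (j - mu_j) ** 2).sum())
        if var_i <= 0 or var_j <= 0:
            correlation = 1.0  # degenerate single-level texture
        else:
            correlation = cov / np.sqrt(var_i * var_j)
    else:
        correlation = cov
    return entropy, float(correlation), dissimilarity, contrast


def compute_features(image, mask, glcm_levels: int = DEFAULT_GLCM_LEVELS,
                     glcm_distance: int = DEFAULT_GLCM_DISTANCE,
                     band_k: int = DEFAULT_BAND_K,
                     normalized_correlation: bool = True) -> FeatureVector:
    """All ten features for one image/mask pair."""
    roi = extract_roi(image, mask)
    P = glcm(roi, mask, levels=glcm_levels, distance=glcm_distance)
    g_ent, g_cor, g_dis, g_con = glcm_features(
        P, normalized_correlation=normalized_correlation)
    return FeatureVector(
        circularity=circularity(mask),
        solidity=solidity(mask),
        shannon_entropy=shannon_entropy(roi, mask),
        glcm_entropy=g_ent,
        glcm_correlation=g_cor,
        glcm_dissimilarity=g_dis,
        glcm_contrast=g_con,
        hist_energy=hist_energy(roi, mask),
        ellipse_ratio=ellipse_ratio(mask),
        brightness=brightness(image, mask, band_k=band_k),
    )


def build_feature_table(cohort, malignant_first: bool = True,
                        **feature_kwargs) -> pd.DataFrame:
    """One row per image: id, the ten features, class label (0/1).

    With ``malignant_first`` (default) malignant rows get the lowest ids,
    mirroring the node numbering convention of the source dataset; ids are
    sequential from 0.
    """
    if len(cohort) == 0:
        raise EmptyROIError("cohort is empty")
    rows = []
    for idx, (image, mask, label) in enumerate(cohort):
        try:
            fv = compute_features(image, mask, **feature_kwargs)
        except Exception as exc:
            raise type(exc)(f"image {idx}: {exc}") from exc
        rows.append({"id": idx, **{n: getattr(fv, n) for n in FEATURE_NAMES},
                     "label": int(label)})
    df = pd.DataFrame(rows, columns=["id", *FEATURE_NAMES, "label"])
    if malignant_first:
        df = df.sort_values(["label", "id"], ascending=[False, True],
                            kind="stable").reset_index(drop=True)
        df["id"] = np.arange(len(df))
    return df
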