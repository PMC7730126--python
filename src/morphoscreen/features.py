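"""Per-colony morphometry: the 102-measurement feature vector.

Measurements fall into three families, mirroring the structure of
high-content screening feature sets:

* ``areashape`` (20): area, perimeter, convexity/solidity descriptors,
  ellipse-equivalent axes and eccentricity, compactness/form factor, max
  Feret diameter and the seven Hu moment invariants of the binary mask.
* ``intensity`` (30): order statistics and integrated intensity, mass
  displacement, boundary (edge) versus interior statistics, plus a 4-ring
  radial distribution (FracAtD, MeanFrac and RadialCV per ring, with
  RadialCV taken over 8 angular wedges).
* ``texture`` (52): 13 Haralick co-occurrence statistics at pixel offsets
  d ∈ {1, 4}, summarized over the four offset directions by their mean and
  range, on intensities quantized to 8 gray levels within the colony.

Conventions that make the oracles well-defined: eccentricity comes from the
ellipse of equal second central moments; the perimeter estimator is the
weighted boundary-pixel count of ``skimage.measure.perimeter`` (slightly
over-estimating smooth contours, so compactness = P^2/(4*pi*A) >= 1 for
rasterized shapes); compactness and form factor are reciprocals.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import graycomatrix
from skimage.measure import label as sk_label
from skimage.measure import perimeter as sk_perimeter
from skimage.measure import regionprops

log = logging.getLogger(__name__)

__all__ = [
    "FEATURE_NAMES",
    "FEATURE_FAMILIES",
    "N_FEATURES",
    "areashape_features",
    "intensity_features",
    "radial_distribution",
    "texture_features",
    "colony_features",
    "feature_table",
    "write_manifest",
    "masked_glcm",
    "haralick_statistics",
]

N_RINGS = 4
N_WEDGES = 8
N_GRAY_LEVELS = 8
TEXTURE_DISTANCES = (1, 4)
_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)

_HARALICK_STATS = (
    "asm", "contrast", "correlation", "variance", "idm", "sum_average",
    "sum_variance", "sum_entropy", "entropy", "difference_variance",
    "difference_entropy", "imc1", "imc2",
)

_AREASHAPE = (
    "area", "perimeter", "convex_area", "solidity", "extent",
    "equivalent_diameter", "major_axis_length", "minor_axis_length",
    "axis_ratio", "eccentricity", "compactness", "form_factor",
    "feret_diameter_max",
) + tuple(f"hu_moment_{i}" for i in range(1, 8))

_INTENSITY = (
    "mean", "median", "std", "min", "max", "range", "integrated", "mad",
    "q25", "q75", "mass_displacement", "edge_mean", "edge_std", "edge_min",
    "edge_max", "edge_integrated", "interior_mean", "edge_interior_ratio",
)

_RADIAL = tuple(
    f"{stat}_ring{r}"
    for stat in ("frac_at_d", "mean_frac", "radial_cv")
    for r in range(1, N_RINGS + 1)
)

_TEXTURE = tuple(
    f"texture_{stat}_d{d}_{agg}"
    for d in TEXTURE_DISTANCES
    for stat in _HARALICK_STATS
    for agg in ("mean", "range")
)

FEATURE_NAMES: tuple[str, ...] = _AREASHAPE + _INTENSITY + _RADIAL + _TEXTURE
FEATURE_FAMILIES: dict[str, str] = (
    {n: "areashape" for n in _AREASHAPE}
    | {n: "intensity" for n in _INTENSITY + _RADIAL}
    | {n: "texture" for n in _TEXTURE}
)
N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 102


def _check_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, bool)
    if mask.sum() < 4:
        raise ValueError("colony mask must contain at least 4 pixels")
    if sk_label(mask, connectivity=2).max() != 1:
        raise ValueError("mask must be a single connected component")
    return mask


def areashape_features(mask: np.ndarray) -> dict[str, float]:
    """Shape descriptors of a single-colony binary mask."""
    mask = _check_mask(mask)
    prop = regionprops(mask.astype(np.uint8))[0]
    area = float(prop.area)
    perim = float(sk_perimeter(mask, neighborhood=4))
    minor = float(prop.axis_minor_length)
    out = {
        "area": area,
        "perimeter": perim,
        "convex_area": float(prop.area_convex),
        "solidity": float(prop.solidity),
        "extent": float(prop.extent),
        "equivalent_diameter": float(prop.equivalent_diameter_area),
        "major_axis_length": float(prop.axis_major_length),
        "minor_axis_length": minor,
        "axis_ratio": float(prop.axis_major_length) / minor if minor > 0 else 0.0,
        "eccentricity": float(prop.eccentricity),
        "compactness": perim**2 / (4 * np.pi * area),
        "form_factor": 4 * np.pi * area / perim**2 if perim > 0 else 0.0,
        "feret_diameter_max": float(prop.feret_diameter_max),
    }
    for i, h in enumerate(prop.moments_hu, start=1):
        out[f"hu_moment_{i}"] = float(h)
    return out


def _edge_interior(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    interior = ndimage.binary_erosion(mask)
    edge = mask & ~interior
    if not interior.any():
        interior = mask
    return edge, interior


def intensity_features(mask: np.ndarray, pixels: np.ndarray) -> dict[str, float]:
    """Intensity statistics of the colony, including edge/interior split."""
    mask = _check_mask(mask)
    pixels = np.asarray(pixels, float)
    vals = pixels[mask]
    edge, interior = _edge_interior(mask)
    evals, ivals = pixels[edge], pixels[interior]

    cy, cx = ndimage.center_of_mass(mask)
    total = vals.sum()
    if total > 0:
        wy, wx = ndimage.center_of_mass(pixels * mask)
        displacement = float(np.hypot(wy - cy, wx - cx))
    else:
        displacement = 0.0
    med = float(np.median(vals))
    interior_mean = float(ivals.mean())
    return {
        "mean": float(vals.mean()),
        "median": med,
        "std": float(vals.std()),
        "min": float(vals.min()),
        "max": float(vals.max()),
        "range": float(vals.max() - vals.min()),
        "integrated": float(total),
        "mad": float(np.median(np.abs(vals - med))),
        "q25": float(np.percentile(vals, 25)),
        "q75": float(np.percentile(vals, 75)),
        "mass_displacement": displacement,
        "edge_mean": float(evals.mean()),
        "edge_std": float(evals.std()),
        "edge_min": float(evals.min()),
        "edge_max": float(evals.max()),
        "edge_integrated": float(evals.sum()),
        "interior_mean": interior_mean,
        "edge_interior_ratio": float(evals.mean()) / interior_mean
        if interior_mean != 0 else 0.0,
    }


def radial_distribution(
    mask: np.ndarray, pixels: np.ndarray, n_rings: int = N_RINGS
) -> dict[str, float]:
    """Ring-wise radial intensity distribution.

    Pixels are assigned a normalized distance d = dc / (dc + de), where dc is
    the distance to the binary centroid and de the distance to the nearest
    point outside the colony, then binned into ``n_rings`` equal-width rings.
    Per ring: FracAtD (fraction of total intensity), MeanFrac (FracAtD
    relative to the ring's area fraction) and RadialCV (coefficient of
    variation of mean intensity over 8 angular wedges).
    """
    mask = _check_mask(mask)
    pixels = np.asarray(pixels, float)
    cy, cx = ndimage.center_of_mass(mask)
    yy, xx = np.nonzero(mask)
    dc = np.hypot(yy - cy, xx - cx)
    de = ndimage.distance_transform_edt(mask)[yy, xx]
    dnorm = np.clip(dc / np.maximum(dc + de, 1e-12), 0.0, 1.0 - 1e-9)
    ring = np.minimum((dnorm * n_rings).astype(int), n_rings - 1)
    wedge = ((np.arctan2(yy - cy, xx - cx) + np.pi) / (2 * np.pi) * N_WEDGES)
    wedge = np.minimum(wedge.astype(int), N_WEDGES - 1)

    vals = pixels[yy, xx]
    total_i = vals.sum()
    total_a = len(vals)
    out: dict[str, float] = {}
    for r in range(n_rings):
        sel = ring == r
        name = f"ring{r + 1}"
        if not sel.any():
            log.warning("radial_distribution: empty ring %d", r + 1)
            out[f"frac_at_d_{name}"] = 0.0
            out[f"mean_frac_{name}"] = 0.0
            out[f"radial_cv_{name}"] = 0.0
            continue
        frac_i = float(vals[sel].sum() / total_i) if total_i > 0 else 0.0
        frac_a = sel.sum() / total_a
        out[f"frac_at_d_{name}"] = frac_i
        out[f"mean_frac_{name}"] = frac_i / frac_a if frac_a > 0 else 0.0
        wedge_means = [
            vals[sel & (wedge == w)].mean()
            for w in range(N_WEDGES)
            if (sel & (wedge == w)).any()
        ]
        wm = np.asarray(wedge_means)
        out[f"radial_cv_{name}"] = (
            float(wm.std() / wm.mean()) if len(wm) > 1 and wm.mean() != 0 else 0.0
        )
    return out


def masked_glcm(
    quantized: np.ndarray, mask: np.ndarray, distance: int, angle: float
) -> np.ndarray:
    """Normalized symmetric gray-level co-occurrence matrix within a mask.

    Pixels outside the mask are mapped to a sentinel level whose row/column
    are discarded before normalization, so only in-colony pixel pairs count.
    Returns the ``(levels, levels)`` matrix; all-zero if no valid pair exists.
    """
    img = np.where(mask, quantized, N_GRAY_LEVELS).astype(np.uint8)
    glcm = graycomatrix(
        img, [distance], [angle], levels=N_GRAY_LEVELS + 1, symmetric=True
    )[:, :, 0, 0].astype(float)
    glcm = glcm[:N_GRAY_LEVELS, :N_GRAY_LEVELS]
    s = glcm.sum()
    return glcm / s if s > 0 else glcm


def haralick_statistics(P: np.ndarray) -> dict[str, float]:
    """The 13 Haralick statistics of a normalized co-occurrence matrix."""
    n = P.shape[0]
    if P.sum() == 0:
        return {s: 0.0 for s in _HARALICK_STATS}
    i = np.arange(n)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mux, muy = (i * px).sum(), (i * py).sum()
    sx = np.sqrt(((i - mux) ** 2 * px).sum())
    sy = np.sqrt(((i - muy) ** 2 * py).sum())

    def _ent(p):
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    p_sum = np.zeros(2 * n - 1)       # p_{x+y}(k), k = i+j in [0, 2n-2]
    p_diff = np.zeros(n)              # p_{|x-y|}(k)
    np.add.at(p_sum, (ii + jj).ravel(), P.ravel())
    np.add.at(p_diff, np.abs(ii - jj).ravel(), P.ravel())

    k_sum = np.arange(2 * n - 1)
    k_diff = np.arange(n)
    sum_avg = float((k_sum * p_sum).sum())
    diff_avg = float((k_diff * p_diff).sum())
    hxy = _ent(P.ravel())
    hx, hy = _ent(px), _ent(py)
    pxy_outer = np.outer(px, py)
    pos = pxy_outer > 0
    hxy1 = float(-(P[pos] * np.log2(pxy_outer[pos])).sum())
    hxy2 = float(-(pxy_outer[pos] * np.log2(pxy_outer[pos])).sum())

    corr = float((((ii - mux) * (jj - muy) * P).sum()) / (sx * sy)) \
        if sx > 0 and sy > 0 else 0.0
    denom = max(hx, hy)
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    return {
        "asm": float((P**2).sum()),
        "contrast": float(((ii - jj) ** 2 * P).sum()),
        "correlation": corr,
        "variance": float(((ii - mux) ** 2 * P).sum()),
        "idm": float((P / (1.0 + (ii - jj) ** 2)).sum()),
        "sum_average": sum_avg,
        "sum_variance": float(((k_sum - sum_avg) ** 2 * p_sum).sum()),
        "sum_entropy": _ent(p_sum),
        "entropy": hxy,
        "difference_variance": float(((k_diff - diff_avg) ** 2 * p_diff).sum()),
        "difference_entropy": _ent(p_diff),
        "imc1": float(imc1),
        "imc2": imc2,
    }


def quantize(mask: np.ndarray, pixels: np.ndarray) -> np.ndarray:
    """Min-max quantization of in-colony intensities to 8 gray levels."""
    vals = np.asarray(pixels, float)
    lo = vals[mask].min()
    hi = vals[mask].max()
    if hi <= lo:
        return np.zeros_like(mask, dtype=np.uint8)
    q = np.floor((vals - lo) / (hi - lo) * N_GRAY_LEVELS).astype(int)
    return np.clip(q, 0, N_GRAY_LEVELS - 1).astype(np.uint8)


def texture_features(mask: np.ndarray, pixels: np.ndarray) -> dict[str, float]:
    """Haralick statistics, mean and range over 4 directions per distance."""
    mask = _check_mask(mask)
    q = quantize(mask, pixels)
    out: dict[str, float] = {}
    for d in TEXTURE_DISTANCES:
        per_angle: list[dict[str, float]] = []
        for ang in _ANGLES:
            P = masked_glcm(q, mask, d, ang)
            if P.sum() == 0:
                log.warning("texture_features: no pixel pairs at distance %d", d)
            per_angle.append(haralick_statistics(P))
        for stat in _HARALICK_STATS:
            vals = np.array([pa[stat] for pa in per_angle])
            out[f"texture_{stat}_d{d}_mean"] = float(vals.mean())
            out[f"texture_{stat}_d{d}_range"] = float(vals.max() - vals.min())
    return out


def colony_features(mask: np.ndarray, pixels: np.ndarray) -> dict[str, float]:
    """All 102 measurements for one colony, in manifest order."""
    feats = (
        areashape_features(mask)
        | intensity_features(mask, pixels)
        | radial_distribution(mask, pixels)
        | texture_features(mask, pixels)
    )
    return {name: feats[name] for name in FEATURE_NAMES}


@dataclass(frozen=True)
class _Crop:
    mask: np.ndarray
    pixels: np.ndarray


def _crop(label_mask: np.ndarray, pixels: np.ndarray, cid: int, pad: int = 2) -> _Crop:
    ys, xs = np.nonzero(label_mask == cid)
    y0, y1 = max(ys.min() - pad, 0), min(ys.max() + pad + 1, label_mask.shape[0])
    x0, x1 = max(xs.min() - pad, 0), min(xs.max() + pad + 1, label_mask.shape[1])
    return _Crop(label_mask[y0:y1, x0:x1] == cid, pixels[y0:y1, x0:x1])


def feature_table(results, images) -> pd.DataFrame:
    """Colony x 102 feature matrix for a plate.

    ``results`` is an iterable of segmentation results; ``images`` maps
    well_id to its well image.  Colonies whose measurement fails (degenerate
    masks) are dropped with a log entry.  Column order is fixed by the
    manifest, so reruns on identical inputs are bit-identical.
    """
    rows = []
    for res in results:
        pixels = np.asarray(images[res.well_id].pixels, float)
        for cid in res.colony_ids:
            crop = _crop(res.label_mask, pixels, cid)
            try:
                feats = colony_features(crop.mask, crop.pixels)
            except ValueError as err:
                log.warning("dropping %s colony %d: %s", res.well_id, cid, err)
                continue
            rows.append({"well_id": res.well_id, "colony_id": cid, **feats})
    return pd.DataFrame(rows, columns=["well_id", "colony_id", *FEATURE_NAMES])


def write_manifest(path) -> None:
    """Feature-name manifest (name -> family) as JSON."""
    with open(path, "w") as fh:
        json.dump(
            {"n_features": N_FEATURES, "families": FEATURE_FAMILIES}, fh, indent=1
        )
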