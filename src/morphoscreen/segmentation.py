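"""Colony segmentation of whole-well images.

Segmentation is deliberately simple — Gaussian smoothing, a global Otsu
threshold (or a fixed override), hole filling, 8-connected labeling and a
minimum-area gate — because synthetic wells have a flat background and the
generator guarantees colonies never touch.  Declumping is out of scope.

A contrast guard handles wells with no foreground: Otsu always returns *a*
threshold, so a blank noisy well would otherwise shatter into spurious noise
blobs.  If the candidate foreground is not clearly brighter than the
background (``min_contrast_sd`` background-noise standard deviations), the
well is reported empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import regionprops

from .render import WellImage

__all__ = [
    "SegmentationParams",
    "SegmentationResult",
    "segment_well",
    "count_colonies",
    "match_to_truth",
]


@dataclass(frozen=True)
class SegmentationParams:
    smooth_sigma: float = 2.0
    min_area: int = 100
    fixed_threshold: float | None = None  # overrides Otsu when set
    min_contrast_sd: float = 3.0


@dataclass
class SegmentationResult:
    """Labelled colonies of one well.

    ``label_mask`` uses 0 for background and consecutive positive integers
    for colonies; coordinates are 0-based (row, col) pixel centers and
    bounding boxes are half-open ``(min_row, min_col, max_row, max_col)``.
    """

    well_id: str
    label_mask: np.ndarray
    colony_ids: list[int] = field(default_factory=list)
    centroids: dict[int, tuple[float, float]] = field(default_factory=dict)
    bboxes: dict[int, tuple[int, int, int, int]] = field(default_factory=dict)
    threshold: float = float("nan")

    @property
    def n_colonies(self) -> int:
        return len(self.colony_ids)

    def frame(self) -> pd.DataFrame:
        rows = []
        for cid in self.colony_ids:
            cy, cx = self.centroids[cid]
            bbox = self.bboxes[cid]
            area = int((self.label_mask == cid).sum())
            rows.append({"well_id": self.well_id, "colony_id": cid,
                         "cx": cx, "cy": cy, "area_px": area,
                         "bbox": "-".join(map(str, bbox))})
        return pd.DataFrame(
            rows, columns=["well_id", "colony_id", "cx", "cy", "area_px", "bbox"]
        )


def segment_well(
    image: WellImage | np.ndarray,
    params: SegmentationParams = SegmentationParams(),
) -> SegmentationResult:
    """Threshold and label one well image."""
    if isinstance(image, WellImage):
        pixels, well_id = image.pixels, image.well_id
    else:
        pixels, well_id = image, ""
    pixels = np.asarray(pixels, float)
    if not np.all(np.isfinite(pixels)):
        raise ValueError("well image contains non-finite pixels")
    if np.any(pixels < 0):
        raise ValueError("well image contains negative pixels")

    smoothed = (
        ndimage.gaussian_filter(pixels, params.smooth_sigma)
        if params.smooth_sigma > 0 else pixels
    )

    empty = SegmentationResult(well_id, np.zeros(pixels.shape, np.int32))
    if params.fixed_threshold is not None:
        thr = float(params.fixed_threshold)
    else:
        if smoothed.max() == smoothed.min():
            return empty
        thr = float(threshold_otsu(smoothed))
        fg = smoothed > thr
        if not fg.any():
            return empty
        bg = ~fg
        contrast = smoothed[fg].mean() - smoothed[bg].mean()
        if contrast < params.min_contrast_sd * max(smoothed[bg].std(), 1e-12):
            return empty

    binary = ndimage.binary_fill_holes(smoothed > thr)
    labels, _ = ndimage.label(binary, structure=np.ones((3, 3), int))  # 8-conn

    result = SegmentationResult(well_id, np.zeros(pixels.shape, np.int32),
                                threshold=thr)
    next_id = 1
    for prop in regionprops(labels):
        if prop.area < params.min_area:
            continue
        result.label_mask[labels == prop.label] = next_id
        result.colony_ids.append(next_id)
        result.centroids[next_id] = tuple(map(float, prop.centroid))
        result.bboxes[next_id] = tuple(map(int, prop.bbox))
        next_id += 1
    return result


def count_colonies(results: list[SegmentationResult]) -> dict:
    """Per-well and plate-level colony counts."""
    per_well = {r.well_id: r.n_colonies for r in results}
    counts = np.array(list(per_well.values()), float)
    return {
        "per_well": per_well,
        "total": int(counts.sum()) if counts.size else 0,
        "median": float(np.median(counts)) if counts.size else float("nan"),
        "mad": float(np.median(np.abs(counts - np.median(counts))))
        if counts.size else float("nan"),
    }


def match_to_truth(
    result: SegmentationResult, truth: pd.DataFrame
) -> pd.DataFrame:
    """1:1 match segmented colonies to ground truth by nearest centroid.

    A pair matches when the segmented centroid lies within the true colony's
    radius of its planted center.  Returns the truth rows of this well with a
    ``matched_colony_id`` column (NA where unmatched).
    """
    t = truth[truth["well_id"] == result.well_id].reset_index(drop=True)
    matched = pd.array([pd.NA] * len(t), dtype="Int64")
    if result.n_colonies and len(t):
        cents = np.array([result.centroids[c] for c in result.colony_ids])
        ids = np.array(result.colony_ids)
        used = np.zeros(len(ids), bool)
        for i, row in t.iterrows():
            d = np.hypot(cents[:, 0] - row.cy, cents[:, 1] - row.cx)
            d[used] = np.inf
            j = int(np.argmin(d))
            if d[j] <= row.radius:
                matched[i] = int(ids[j])
                used[j] = True
    t["matched_colony_id"] = matched
    return t
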