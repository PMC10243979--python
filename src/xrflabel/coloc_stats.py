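"""Label-cell colocalization statistics.

Cells are segmented from an elemental intensity map (between-class-variance
global threshold + 8-connected components + area filter); per-pixel label
positivity against the segmentation yields sensitivity over cell pixels and
a false-positive rate over background pixels, with an optional ECM class
excluded from both denominators.  Cell-size agreement between modalities is
tested with Pearson's product-moment correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.stats
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops

from .errors import DegenerateDataError

__all__ = [
    "SegmentationResult",
    "PositivityStats",
    "CorrelationResult",
    "segment_cells",
    "positivity",
    "pearson",
]

BACKGROUND_CLASS = 0
ECM_CLASS = 1
FIRST_CELL_ID = 2


@dataclass
class SegmentationResult:
    """Label image (0 background, 1 ECM, >= 2 cell ids) with per-cell sizes."""

    labels: np.ndarray
    sizes: pd.DataFrame  # columns: cell_id, area_um2, equivalent_diameter_um
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        ids = self.cell_ids
        if len(ids) and not np.array_equal(
                ids, np.arange(FIRST_CELL_ID, FIRST_CELL_ID + len(ids))):
            raise ValueError("cell ids must be contiguous starting at 2")
        if set(self.sizes["cell_id"]) != set(ids.tolist()):
            raise ValueError("size table does not match label image")

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids >= FIRST_CELL_ID]

    @property
    def cell_mask(self) -> np.ndarray:
        return self.labels >= FIRST_CELL_ID

    @property
    def background_mask(self) -> np.ndarray:
        return self.labels == BACKGROUND_CLASS


@dataclass(frozen=True)
class PositivityStats:
    """Fractions of label-positive pixels over cells and over background."""

    sensitivity: float
    false_positive_rate: float
    n_cell_px: int
    n_cell_positive: int
    n_background_px: int
    n_background_positive: int

    def __post_init__(self) -> None:
        if not (0 <= self.sensitivity <= 1 and 0 <= self.false_positive_rate <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if (self.n_cell_positive > self.n_cell_px
                or self.n_background_positive > self.n_background_px):
            raise ValueError("numerators exceed denominators")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if not -1 <= self.r <= 1 or not 0 <= self.p <= 1 or self.n < 3:
            raise ValueError("invalid correlation result")


def segment_cells(image: np.ndarray, min_area_um2: float, max_area_um2: float,
                  pixel_size_um: float = 1.0,
                  ecm_mask: np.ndarray | None = None) -> SegmentationResult:
    """Segment cells from an elemental intensity map.

    Global between-class-variance (Otsu) threshold, 8-connected components,
    then an area filter in square micrometres.  Pixels of ``ecm_mask`` not
    claimed by a cell are marked as the ECM class.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    if not min_area_um2 < max_area_um2:
        raise ValueError("min_area_um2 must be below max_area_um2")
    if np.ptp(image[np.isfinite(image)]) == 0:
        raise DegenerateDataError("uniform image: no threshold separates classes")
    threshold = threshold_otsu(image[np.isfinite(image)])
    binary = np.nan_to_num(image, nan=-np.inf) > threshold
    components = cc_label(binary, connectivity=2)

    px_area = pixel_size_um ** 2
    labels = np.zeros(image.shape, dtype=np.uint16)
    rows = []
    next_id = FIRST_CELL_ID
    for prop in regionprops(components):
        area_um2 = prop.area * px_area
        if not min_area_um2 <= area_um2 <= max_area_um2:
            continue
        labels[components == prop.label] = next_id
        rows.append({
            "cell_id": next_id,
            "area_um2": area_um2,
            "equivalent_diameter_um": prop.equivalent_diameter_area * pixel_size_um,
        })
        next_id += 1
    if ecm_mask is not None:
        ecm_mask = np.asarray(ecm_mask, dtype=bool)
        if ecm_mask.shape != image.shape:
            raise ValueError("ecm_mask shape does not match image")
        labels[ecm_mask & (labels == 0)] = ECM_CLASS
    sizes = pd.DataFrame(rows, columns=["cell_id", "area_um2",
                                        "equivalent_diameter_um"])
    return SegmentationResult(labels=labels, sizes=sizes,
                              pixel_size_um=pixel_size_um)


def positivity(seg: SegmentationResult, label_map: np.ndarray,
               background_level: float, k: float = 1.0,
               per_region: bool = False) -> PositivityStats:
    """Sensitivity and false-positive rate of label positivity.

    A pixel is positive iff ``label_map > k * background_level`` (strict).
    ECM pixels are excluded from both denominators.  With ``per_region``,
    fractions are over regions instead of pixels: a cell (or 8-connected
    background component) counts as positive when more than half of its
    pixels are positive.
    """
    label_map = np.asarray(label_map, dtype=float)
    if label_map.shape != seg.labels.shape:
        raise ValueError("label map shape does not match segmentation")
    if background_level < 0:
        raise ValueError("background_level must be non-negative")
    cell_mask = seg.cell_mask
    bg_mask = seg.background_mask
    if not cell_mask.any():
        raise DegenerateDataError("segmentation contains no cell pixels")
    positive = label_map > k * background_level

    if per_region:
        cell_ids = seg.cell_ids
        cell_hits = sum(
            1 for cid in cell_ids
            if positive[seg.labels == cid].mean() > 0.5)
        bg_components, n_bg = scipy.ndimage.label(bg_mask)
        bg_hits = sum(
            1 for b in range(1, n_bg + 1)
            if positive[bg_components == b].mean() > 0.5)
        return PositivityStats(
            sensitivity=cell_hits / len(cell_ids),
            false_positive_rate=bg_hits / n_bg if n_bg else 0.0,
            n_cell_px=int(len(cell_ids)), n_cell_positive=int(cell_hits),
            n_background_px=int(n_bg), n_background_positive=int(bg_hits))

    n_cell = int(cell_mask.sum())
    n_bg = int(bg_mask.sum())
    n_cell_pos = int(positive[cell_mask].sum())
    n_bg_pos = int(positive[bg_mask].sum())
    return PositivityStats(
        sensitivity=n_cell_pos / n_cell,
        false_positive_rate=n_bg_pos / n_bg if n_bg else 0.0,
        n_cell_px=n_cell, n_cell_positive=n_cell_pos,
        n_background_px=n_bg, n_background_positive=n_bg_pos)


def pearson(sizes_a: np.ndarray, sizes_b: np.ndarray) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t-test p-value."""
    a = np.asarray(sizes_a, dtype=float)
    b = np.asarray(sizes_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("size vectors must be 1-D and equal length")
    if len(a) < 3:
        raise ValueError(f"need n >= 3 paired observations, got {len(a)}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateDataError("zero variance in a size vector")
    result = scipy.stats.pearsonr(a, b)
    r = float(np.clip(result.statistic, -1.0, 1.0))
    return CorrelationResult(r=r, p=float(result.pvalue), n=len(a))
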