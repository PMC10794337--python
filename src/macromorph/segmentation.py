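"""Nucleus-seeded watershed segmentation of fluorescence scenes.

The segmentation strategy mirrors the classic ImageJ/Fiji recipe for
cultured-cell micrographs: binarize the F-actin (cell body) channel by
intensity, detect nuclei in the DAPI channel as seeds, split touching
cells with a watershed on the negated Euclidean distance transform of
the body mask, then filter small and border-touching objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from scipy.cluster.hierarchy import fcluster, linkage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.segmentation import watershed

logger = logging.getLogger(__name__)

__all__ = [
    "LabelMap",
    "SingleCell",
    "DegenerateImageError",
    "binarize",
    "detect_nuclei",
    "split_touching",
    "extract_cells",
    "segment_scene",
]


class DegenerateImageError(ValueError):
    """Auto-thresholding was requested on an image with no contrast."""


@dataclass
class LabelMap:
    """Integer-labelled segmentation of one scene.

    ``labels`` is an integer raster with 0 = background and contiguous
    cell labels 1..n; ``pixel_size`` is µm/px.
    """

    labels: np.ndarray
    pixel_size: float = 1.0

    @property
    def n_cells(self) -> int:
        return int(self.labels.max())

    def areas_px(self) -> np.ndarray:
        return np.bincount(self.labels.ravel())[1:]

    def write_tiff(self, path: str | Path) -> None:
        if self.n_cells > np.iinfo(np.uint16).max:
            raise ValueError("too many labels for 16-bit output")
        tifffile.imwrite(path, self.labels.astype(np.uint16))

    def to_frame(self) -> pd.DataFrame:
        """Per-cell summary: label, centroid_x, centroid_y, area_px, border_flag."""
        rows = []
        h, w = self.labels.shape
        for p in regionprops(self.labels):
            miny, minx, maxy, maxx = p.bbox
            rows.append(
                {
                    "label": p.label,
                    "centroid_x": p.centroid[1],
                    "centroid_y": p.centroid[0],
                    "area_px": p.area,
                    "border_flag": miny == 0 or minx == 0 or maxy == h or maxx == w,
                }
            )
        return pd.DataFrame(rows, columns=["label", "centroid_x", "centroid_y", "area_px", "border_flag"])


@dataclass
class SingleCell:
    """One extracted cell: full-frame label plus a tight local mask."""

    label: int
    mask: np.ndarray  # local boolean mask
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)
    centroid: tuple[float, float]  # (row, col), full-frame coords
    area_px: int
    border: bool


def binarize(image: np.ndarray, method: str | float = "otsu") -> np.ndarray:
    """Foreground mask of the cell-body channel.

    ``method`` is either a fixed intensity threshold or ``"otsu"``.
    Pixels strictly above the threshold are foreground.
    """
    image = np.asarray(image)
    if image.ndim != 2 or not np.all(np.isfinite(image)):
        raise ValueError("binarize expects a finite single-channel image")
    if isinstance(method, str):
        if method != "otsu":
            raise ValueError(f"unknown threshold method {method!r}")
        if image.max() == image.min():
            raise DegenerateImageError("constant image: auto-threshold is undefined")
        thresh = threshold_otsu(image)
    else:
        thresh = float(method)
    return image > thresh


def detect_nuclei(
    nucleus_channel: np.ndarray,
    method: str | float = "otsu",
    min_area_px: int = 10,
    min_distance_px: float = 5.0,
) -> np.ndarray:
    """Seed points (row, col) — centroids of thresholded nucleus blobs.

    Blobs smaller than ``min_area_px`` are dropped; seeds closer than
    ``min_distance_px`` are merged to their mean position (single-link
    clustering), so two abutting nuclei yield one seed. An empty result
    is valid.
    """
    try:
        mask = binarize(nucleus_channel, method)
    except DegenerateImageError:
        return np.empty((0, 2))
    lab = cc_label(mask, connectivity=2)
    centroids = [p.centroid for p in regionprops(lab) if p.area >= min_area_px]
    if not centroids:
        return np.empty((0, 2))
    pts = np.asarray(centroids, dtype=float)
    if len(pts) > 1 and min_distance_px > 0:
        groups = fcluster(linkage(pts, method="single"), t=min_distance_px, criterion="distance")
        pts = np.vstack([pts[groups == g].mean(axis=0) for g in np.unique(groups)])
    # deterministic order: scan order (row, then col)
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    return pts[order]


def split_touching(
    mask: np.ndarray, seeds: np.ndarray, pixel_size: float = 1.0
) -> LabelMap:
    """Partition the foreground into one region per nucleus seed.

    Watershed of the negated Euclidean distance transform of the mask,
    flooded from the seeds, so the split between touching cells falls on
    the distance-map ridge between their nuclei. Foreground pixels in
    components containing no seed keep a connected-component label, so
    the output partitions the input mask exhaustively.
    """
    mask = np.asarray(mask, dtype=bool)
    seeds = np.asarray(seeds, dtype=float).reshape(-1, 2)
    markers = np.zeros(mask.shape, dtype=np.int32)
    for k, (r, c) in enumerate(seeds, start=1):
        ri, ci = int(round(r)), int(round(c))
        if not (0 <= ri < mask.shape[0] and 0 <= ci < mask.shape[1]) or not mask[ri, ci]:
            raise ValueError(f"seed {k} at (row={r:.1f}, col={c:.1f}) is not on the foreground")
        markers[ri, ci] = k
    dist = ndi.distance_transform_edt(mask)
    labels = watershed(-dist, markers=markers, mask=mask)
    # orphan components (no seed) keep a label so the partition is exhaustive
    orphan = mask & (labels == 0)
    if orphan.any():
        extra = cc_label(orphan, connectivity=2)
        labels = labels + np.where(extra > 0, extra + labels.max(), 0)
    return LabelMap(labels=labels.astype(np.int32), pixel_size=pixel_size)


def extract_cells(
    label_map: LabelMap,
    min_area_px: int = 50,
    border_policy: str = "drop",
) -> tuple[LabelMap, list[SingleCell]]:
    """Filter and re-index cells; return the new map plus per-cell masks.

    Cells below ``min_area_px`` are removed; with ``border_policy="drop"``
    cells touching the image edge are removed too. Survivors are
    re-labelled 1..n in original label order.
    """
    if border_policy not in ("keep", "drop"):
        raise ValueError(f"border_policy must be 'keep' or 'drop', got {border_policy!r}")
    labels = label_map.labels
    h, w = labels.shape
    out = np.zeros_like(labels)
    cells: list[SingleCell] = []
    n_dropped = 0
    for p in regionprops(labels):
        miny, minx, maxy, maxx = p.bbox
        border = miny == 0 or minx == 0 or maxy == h or maxx == w
        if p.area < min_area_px or (border and border_policy == "drop"):
            n_dropped += 1
            continue
        new_label = len(cells) + 1
        out[labels == p.label] = new_label
        cells.append(
            SingleCell(
                label=new_label,
                mask=p.image.copy(),
                bbox=p.bbox,
                centroid=p.centroid,
                area_px=int(p.area),
                border=border,
            )
        )
    if n_dropped:
        logger.info("extract_cells: dropped %d cells (min_area=%d, border=%s)",
                    n_dropped, min_area_px, border_policy)
    return LabelMap(labels=out, pixel_size=label_map.pixel_size), cells


def segment_scene(
    nucleus_channel: np.ndarray,
    actin_channel: np.ndarray,
    pixel_size: float = 1.0,
    threshold: str | float = "otsu",
    min_area_px: int = 50,
    border_policy: str = "drop",
    min_nucleus_distance_px: float = 5.0,
) -> tuple[LabelMap, list[SingleCell]]:
    """Full scene segmentation: binarize, seed, split, filter."""
    mask = binarize(actin_channel, threshold)
    seeds = detect_nuclei(nucleus_channel, min_distance_px=min_nucleus_distance_px)
    seeds = np.asarray([s for s in seeds if mask[int(round(s[0])), int(round(s[1]))]])
    label_map = split_touching(mask, seeds, pixel_size=pixel_size)
    return extract_cells(label_map, min_area_px=min_area_px, border_policy=border_policy)
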