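"""The seven-descriptor shape panel and bead-calibrated intensities.

Descriptors (ImageJ conventions):

* area (µm²) — pixel count × pixel_size²
* major / minor axis (µm) — axes of the moment-equivalent ellipse
* circularity — 4π·area / perimeter², clamped to ≤ 1
* aspect ratio — major / minor (≥ 1, an elongation index)
* roundness — 4·area / (π·major²); equals minor/major for an ellipse
* solidity — area / convex hull area; < 1 for irregular boundaries

Marker intensity per cell is the raw integrated intensity (pixel sum of
the background-subtracted channel over the cell mask), normalized by a
linear bead standard curve evaluated at the acquisition exposure, which
makes values comparable across exposure times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.measure import label as cc_label
from skimage.measure import perimeter_crofton
from skimage.measure import regionprops

from macromorph._geometry import DESCRIPTOR_COLUMNS
from macromorph.segmentation import LabelMap, SingleCell

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationCurve",
    "shape_descriptors",
    "perimeter",
    "raw_integrated_intensity",
    "estimate_background",
    "fit_bead_curve",
    "normalize_intensity",
    "measure_cells",
]


def _check_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-d")
    if not mask.any():
        raise ValueError("empty mask")
    if cc_label(mask, connectivity=2).max() > 1:
        raise ValueError("mask has more than one connected component")
    return mask


def perimeter(mask: np.ndarray, pixel_size: float = 1.0) -> float:
    """Boundary length (µm) by the 4-direction Crofton estimator.

    Crofton's formula converts intercept counts along 4 directions into
    a perimeter estimate; unlike naive or √2-weighted boundary-step
    counting it is nearly unbiased on smooth shapes, so the circularity
    of a digitized disk approaches 1 (disk error < 2% at r ≥ 20 px).
    """
    mask = _check_mask(mask)
    return float(perimeter_crofton(mask, directions=4)) * pixel_size


def shape_descriptors(mask: np.ndarray, pixel_size: float = 1.0) -> dict[str, float]:
    """The seven-descriptor panel for one single-cell mask."""
    mask = _check_mask(mask)
    props = regionprops(mask.astype(np.uint8))[0]
    area = props.area * pixel_size**2
    major = props.axis_major_length * pixel_size
    minor = props.axis_minor_length * pixel_size
    if minor <= 0:  # degenerate (line-like) region: fall back to 1 px width
        minor = pixel_size
    perim = perimeter(mask, pixel_size)
    circ = 4.0 * np.pi * area / perim**2
    if circ > 1.0:
        logger.debug("circularity %.4f clamped to 1", circ)
        circ = 1.0
    solidity = min(float(props.solidity), 1.0)
    return {
        "area_um2": float(area),
        "major_um": float(major),
        "minor_um": float(minor),
        "circularity": float(circ),
        "aspect_ratio": float(major / minor),
        "roundness": float(min(4.0 * area / (np.pi * major**2), 1.0)),
        "solidity": solidity,
    }


def estimate_background(channel: np.ndarray, cell_mask: np.ndarray) -> float:
    """Scalar background: median of the non-cell pixels of the channel."""
    channel = np.asarray(channel)
    bg_pixels = channel[~np.asarray(cell_mask, dtype=bool)]
    if bg_pixels.size == 0:
        raise ValueError("no background pixels: cell mask covers the whole image")
    return float(np.median(bg_pixels))


def raw_integrated_intensity(
    mask: np.ndarray, channel: np.ndarray, background: float | np.ndarray = 0.0
) -> float:
    """Pixel sum of max(channel − background, 0) over the mask."""
    mask = np.asarray(mask, dtype=bool)
    channel = np.asarray(channel, dtype=float)
    if mask.shape != channel.shape:
        raise ValueError(f"mask shape {mask.shape} != channel shape {channel.shape}")
    corrected = np.clip(channel - background, 0.0, None)
    return float(corrected[mask].sum())


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear bead standard curve: intensity = slope·exposure + intercept."""

    slope: float
    intercept: float
    exposure_range: tuple[float, float]
    r_squared: float
    n_beads: int

    def predict(self, exposure_ms: float) -> float:
        return self.slope * exposure_ms + self.intercept


def fit_bead_curve(
    bead_table: pd.DataFrame,
    exposure_col: str = "exposure_ms",
    intensity_col: str = "intensity",
) -> CalibrationCurve:
    """OLS fit of bead intensity against exposure time."""
    x = bead_table[exposure_col].to_numpy(dtype=float)
    y = bead_table[intensity_col].to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("bead curve needs at least 2 distinct exposure times")
    res = stats.linregress(x, y)
    if not np.isfinite(res.slope):
        raise ValueError("rank-deficient bead table: slope is not finite")
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        exposure_range=(float(x.min()), float(x.max())),
        r_squared=float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0,
        n_beads=len(x),
    )


def normalize_intensity(raw: float, curve: CalibrationCurve, exposure_ms: float) -> float:
    """Raw integrated intensity / predicted bead intensity at this exposure."""
    predicted = curve.predict(exposure_ms)
    if predicted <= 0:
        raise ValueError(
            f"predicted bead intensity {predicted:.3g} at {exposure_ms} ms is not positive"
        )
    return float(raw) / predicted


def measure_cells(
    cells: list[SingleCell],
    pixel_size: float,
    marker_channels: dict[str, np.ndarray] | None = None,
    calibration: dict[str, tuple[CalibrationCurve, float]] | None = None,
    cell_mask: np.ndarray | None = None,
    class_id: int = -1,
    donor_id: int = 0,
) -> pd.DataFrame:
    """Assemble the canonical feature table for extracted cells.

    ``marker_channels`` maps marker name → full-frame image;
    ``calibration`` maps marker name → (CalibrationCurve, exposure_ms).
    Without calibration, raw integrated intensities are reported in the
    ``<marker>_norm`` columns unscaled. ``cell_mask`` (all cells
    foreground) is used for background estimation; if omitted it is the
    union of the cell bboxes' masks.
    """
    marker_channels = marker_channels or {}
    rows = []
    shape = None
    if marker_channels:
        shape = next(iter(marker_channels.values())).shape
        if cell_mask is None:
            cell_mask = np.zeros(shape, dtype=bool)
            for cell in cells:
                r0, c0, r1, c1 = cell.bbox
                cell_mask[r0:r1, c0:c1] |= cell.mask
        backgrounds = {m: estimate_background(ch, cell_mask) for m, ch in marker_channels.items()}
    for cell in cells:
        rec = {"cell_id": cell.label, "donor_id": donor_id, "class_id": class_id}
        rec.update(shape_descriptors(cell.mask, pixel_size))
        for marker, channel in marker_channels.items():
            full = np.zeros(shape, dtype=bool)
            r0, c0, r1, c1 = cell.bbox
            full[r0:r1, c0:c1] = cell.mask
            raw = raw_integrated_intensity(full, channel, backgrounds[marker])
            if calibration and marker in calibration:
                curve, exposure = calibration[marker]
                rec[f"{marker}_norm"] = normalize_intensity(raw, curve, exposure)
            else:
                rec[f"{marker}_norm"] = raw
        rows.append(rec)
    cols = ["cell_id", "donor_id", "class_id"] + DESCRIPTOR_COLUMNS + [
        f"{m}_norm" for m in marker_channels
    ]
    return pd.DataFrame(rows, columns=cols)
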