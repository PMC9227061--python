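"""Bright-field micrograph analysis: segmentation, morphometry, calibration.

The pipeline mirrors what a bench scientist does with a classical
computer-vision stack, in four steps:

1. grayscale conversion (luma weighting of RGB);
2. inverted binary threshold — pixels *darker* than the threshold become
   foreground, since cells appear dark on the illuminated background;
3. a morphological pass that enlarges foreground regions (binary dilation,
   optionally closing) to connect nearby pixels and close cell outlines;
4. contour analysis: connected components are measured, components smaller
   than a minimum area are discarded as debris, and survivors are reported
   with centroid, bounding-box width/height (µm), area (µm²) and mean colour.

Pixel-to-micrometre conversion comes from a graduated calibration slide: the
slide's line spacing in pixels is measured from the 1-D intensity projection
perpendicular to the lines, and ``um_per_px = division_um / median spacing``.
The factor rescales inversely with vertical resolution (0.5 µm/px at 1080p is
0.75 µm/px at 720p).
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, signal
from skimage import measure, morphology
from skimage.filters import threshold_otsu

__all__ = [
    "SegmentationParams",
    "Calibration",
    "CellRecord",
    "calibrate",
    "rescale_calibration",
    "segment",
    "detect_cells",
    "export_measurements",
    "CalibrationError",
]

_LUMA = np.array([0.299, 0.587, 0.114])


class CalibrationError(RuntimeError):
    """Raised when a calibration slide cannot be read."""


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholding and morphology knobs for :func:`segment`.

    ``gray_threshold = None`` selects the threshold automatically by Otsu's
    method. ``erosion_iterations`` counts the foreground-enlarging passes
    (0 disables them; keep 0 when unbiased size measurements matter, since
    each pass grows every object by about one kernel radius).
    """

    gray_threshold: int | None = None
    erosion_iterations: int = 0
    erosion_kernel: int = 3  # px, square structuring element side
    min_area: float = 20.0  # px^2

    def __post_init__(self) -> None:
        if self.gray_threshold is not None and not 0 <= self.gray_threshold <= 255:
            raise ValueError("gray_threshold must be in [0, 255]")
        if self.erosion_iterations < 0 or self.min_area < 0:
            raise ValueError("erosion_iterations and min_area must be >= 0")


@dataclass(frozen=True)
class Calibration:
    """Lens calibration: physical size of one pixel."""

    um_per_px: float
    image_size: tuple[int, int] = (1920, 1080)  # (w, h)
    lens_focal_length: float | None = None  # mm, informational

    def __post_init__(self) -> None:
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")


@dataclass(frozen=True)
class CellRecord:
    """Per-object measurement in physical units."""

    id: int
    centroid: tuple[float, float]  # (x, y) px
    width: float  # µm, bounding-box extent along image x
    height: float  # µm, along image y
    area: float  # µm^2
    mean_color: tuple[float, float, float]  # RGB of the source image under the mask


def _as_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim == 3:
        img = img[..., :3] @ _LUMA
    return img.astype(np.float64)


# -- calibration -----------------------------------------------------------


def _projection_spacing(gray: np.ndarray, angle_deg: float) -> tuple[float, int]:
    """Median peak spacing (px) of the intensity projection at ``angle_deg``."""
    if abs(angle_deg) > 1e-6:
        gray = ndimage.rotate(gray, angle_deg, reshape=False, order=1, mode="nearest")
    profile = gray.mean(axis=0)
    inverted = profile.max() - profile  # graduation lines are dark
    prominence = 0.25 * (inverted.max() - inverted.min() + 1e-9)
    peaks, _ = signal.find_peaks(inverted, prominence=prominence)
    if len(peaks) < 2:
        return float("nan"), len(peaks)
    return float(np.median(np.diff(peaks))), len(peaks)


def calibrate(
    slide_image: np.ndarray,
    division_um: float,
    angle_search_deg: float = 8.0,
) -> Calibration:
    """Measure µm/px from an image of a graduated calibration slide.

    The slide shows parallel dark graduation lines ``division_um`` apart.
    Line positions are found as peaks of the column-mean intensity
    projection; a small angle search (±``angle_search_deg``) makes the
    measurement robust to slide rotation. The median adjacent-peak spacing
    converts as ``um_per_px = division_um / spacing_px``.
    """
    gray = _as_gray(slide_image)
    if gray.size == 0:
        raise CalibrationError("empty slide image")
    # pick the projection angle that maximises profile contrast
    best_angle, best_var = 0.0, -1.0
    for angle in np.linspace(-angle_search_deg, angle_search_deg, 17):
        rot = ndimage.rotate(gray, angle, reshape=False, order=1, mode="nearest") \
            if abs(angle) > 1e-6 else gray
        var = rot.mean(axis=0).var()
        if var > best_var:
            best_angle, best_var = float(angle), var
    spacing, n_peaks = _projection_spacing(gray, best_angle)
    if n_peaks < 2 or not math.isfinite(spacing) or spacing <= 0:
        raise CalibrationError(
            f"found only {n_peaks} graduation line(s); need at least 2"
        )
    h, w = gray.shape
    return Calibration(um_per_px=division_um / spacing, image_size=(w, h))


def rescale_calibration(cal: Calibration, new_size: tuple[int, int]) -> Calibration:
    """Calibration at a different camera resolution (same sensor crop).

    The physical field of view is fixed, so µm/px scales by
    ``old_height / new_height``.
    """
    if new_size[0] <= 0 or new_size[1] <= 0:
        raise ValueError("new_size must be positive")
    factor = cal.image_size[1] / new_size[1]
    return replace(cal, um_per_px=cal.um_per_px * factor, image_size=tuple(new_size))


# -- segmentation and measurement -----------------------------------------


def segment(image: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Binary foreground mask of dark objects in a bright-field image.

    Returns a uint8 mask with foreground = 255. Thresholding is inverted
    (dark pixels become foreground); the subsequent morphological pass
    *enlarges* foreground regions to close cell outlines.
    """
    if params is None:
        params = SegmentationParams()
    gray = _as_gray(image)
    thr = params.gray_threshold
    if thr is None:
        thr = float(threshold_otsu(gray))
    mask = gray < thr
    if params.erosion_iterations > 0:
        footprint = morphology.footprint_rectangle(
            (params.erosion_kernel, params.erosion_kernel)
        )
        for _ in range(params.erosion_iterations):
            mask = morphology.dilation(mask, footprint)
    return (mask * 255).astype(np.uint8)


def detect_cells(
    mask: np.ndarray,
    cal: Calibration,
    min_area: float = 20.0,
    source_image: np.ndarray | None = None,
) -> tuple[list[CellRecord], np.ndarray]:
    """Measure connected foreground components of a segmentation mask.

    Components with pixel area below ``min_area`` (px²) are discarded as
    debris. Each survivor is reported with its axis-aligned bounding-box
    extents converted to µm via ``cal``, its centroid, area, and the mean
    colour of ``source_image`` under the component (the mask itself when no
    source is given). Also returns an annotated RGB copy with bounding boxes
    and the total count drawn in.
    """
    mask = np.asarray(mask) > 0
    labels = measure.label(mask, connectivity=2)
    props = measure.regionprops(labels)

    if source_image is not None:
        src = np.asarray(source_image)
        if src.ndim == 2:
            src = np.stack([src] * 3, axis=-1)
    else:
        src = np.stack([mask.astype(np.uint8) * 255] * 3, axis=-1)
    annotated = src.astype(np.uint8).copy()

    records: list[CellRecord] = []
    next_id = 0
    for p in sorted(props, key=lambda p: (p.centroid[0], p.centroid[1])):
        if p.area < min_area:
            continue
        minr, minc, maxr, maxc = p.bbox
        width_px = maxc - minc
        height_px = maxr - minr
        region = src[p.slice][p.image]
        mean_color = tuple(float(v) for v in region.reshape(-1, 3).mean(axis=0))
        records.append(
            CellRecord(
                id=next_id,
                centroid=(float(p.centroid[1]), float(p.centroid[0])),
                width=width_px * cal.um_per_px,
                height=height_px * cal.um_per_px,
                area=float(p.area) * cal.um_per_px**2,
                mean_color=mean_color,
            )
        )
        _draw_box(annotated, minr, minc, maxr, maxc)
        next_id += 1
    _draw_count(annotated, len(records))
    return records, annotated


def _draw_box(img: np.ndarray, minr: int, minc: int, maxr: int, maxc: int) -> None:
    color = np.array([0, 220, 0], dtype=np.uint8)
    maxr, maxc = min(maxr, img.shape[0] - 1), min(maxc, img.shape[1] - 1)
    img[minr, minc : maxc + 1] = color
    img[maxr, minc : maxc + 1] = color
    img[minr : maxr + 1, minc] = color
    img[minr : maxr + 1, maxc] = color


def _draw_count(img: np.ndarray, count: int) -> None:
    """Tally bar in the top-left corner: one tick per detected cell."""
    color = np.array([255, 40, 40], dtype=np.uint8)
    for i in range(count):
        c = 2 + 3 * i
        if c + 1 >= img.shape[1]:
            break
        img[2:8, c] = color


def export_measurements(records: list[CellRecord], path=None) -> str:
    """Write per-cell measurements as CSV; returns the CSV text.

    Columns: id, centroid_x_px, centroid_y_px, width_um, height_um, area_um2,
    r, g, b. Rows are ordered by id. When ``path`` is given the text is also
    written there.
    """
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(
        ["id", "centroid_x_px", "centroid_y_px", "width_um", "height_um", "area_um2", "r", "g", "b"]
    )
    for rec in sorted(records, key=lambda r: r.id):
        writer.writerow(
            [
                rec.id,
                f"{rec.centroid[0]:.3f}",
                f"{rec.centroid[1]:.3f}",
                f"{rec.width:.4f}",
                f"{rec.height:.4f}",
                f"{rec.area:.4f}",
                f"{rec.mean_color[0]:.2f}",
                f"{rec.mean_color[1]:.2f}",
                f"{rec.mean_color[2]:.2f}",
            ]
        )
    text = buf.getvalue()
    if path is not None:
        from pathlib import Path

        Path(path).write_text(text)
    return text
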