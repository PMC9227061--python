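"""Two-phase coarse-to-fine autofocus on a Laplacian sharpness score.

The camera first descends through a coarse ladder of heights (default ten
0.1 mm steps starting 0.5 mm above the theoretical focus), scoring each
frame, then re-centres 0.05 mm above the coarse optimum and repeats with ten
0.01 mm steps. The chosen height is the global sharpness argmax over all
evaluations; ties resolve to the **highest** camera position, which favours
the top liquid layer where free-swimming cells are imaged.

The sharpness score is the variance of the discrete Laplacian of the
grayscale image — the standard focus measure for bright-field stacks. It is
invariant to constant illumination shifts and zero on a featureless frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage

__all__ = [
    "FocusParams",
    "FocusSweep",
    "sharpness",
    "autofocus",
    "theoretical_focus_from_volume",
]


@dataclass(frozen=True)
class FocusParams:
    """Sweep geometry; defaults give 20 evaluations over a 1 mm coarse span."""

    start_above: float = 0.5  # mm above the theoretical focus
    coarse_step: float = 0.1  # mm
    coarse_n: int = 10
    fine_recenter: float = 0.05  # mm above the coarse argmax
    fine_step: float = 0.01  # mm
    fine_n: int = 10

    def __post_init__(self) -> None:
        vals = (
            self.start_above,
            self.coarse_step,
            self.coarse_n,
            self.fine_recenter,
            self.fine_step,
            self.fine_n,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("all focus parameters must be positive")
        if self.fine_step >= self.coarse_step:
            raise ValueError("fine_step must be smaller than coarse_step")
        if self.coarse_n * self.coarse_step < 2 * self.fine_recenter:
            raise ValueError("coarse span must cover at least twice fine_recenter")


@dataclass
class FocusSweep:
    """Record of one autofocus run: every (height, score) pair visited."""

    evaluations: list[tuple[float, float]] = field(default_factory=list)
    best_height: float = float("nan")

    @property
    def n_evaluations(self) -> int:
        return len(self.evaluations)

    @property
    def best_score(self) -> float:
        return max(s for _, s in self.evaluations)


class CaptureError(RuntimeError):
    """Image capture failed during a sweep; carries the offending height."""

    def __init__(self, height: float, cause: Exception):
        super().__init__(f"capture failed at height {height:.3f} mm: {cause}")
        self.height = height
        self.cause = cause


def _as_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    if img.ndim == 3:
        img = img[..., :3] @ np.array([0.299, 0.587, 0.114])
    return img.astype(np.float64)


def sharpness(image: np.ndarray) -> float:
    """Variance of the 3x3 discrete Laplacian response of ``image``."""
    lap = ndimage.laplace(_as_gray(image))
    return float(lap.var())


def theoretical_focus_from_volume(
    volume_ml: float, well_diameter_mm: float, bottom_focus_mm: float = 0.0
) -> float:
    """Camera height (mm) focusing the liquid surface of a known sample volume.

    The liquid column height is ``volume / well area``; the camera focuses the
    column top, i.e. ``bottom_focus_mm`` (the height focusing the dry well
    bottom) plus the column height.
    """
    if volume_ml <= 0 or well_diameter_mm <= 0:
        raise ValueError("volume and well diameter must be positive")
    area_mm2 = np.pi * (well_diameter_mm / 2.0) ** 2
    column_mm = volume_ml * 1000.0 / area_mm2  # 1 mL = 1000 mm^3
    return bottom_focus_mm + column_mm


def autofocus(
    capture_at: Callable[[float], np.ndarray],
    theoretical_focus: float,
    params: FocusParams | None = None,
    z_range: tuple[float, float] = (0.0, 240.0),
) -> FocusSweep:
    """Run the two-phase sweep; returns the full evaluation record.

    ``capture_at`` maps a camera height in mm to an image (typically
    ``VirtualDevice.capture_at`` or a hardware transport). Visited heights are
    clamped to ``z_range`` (the stage working volume). Phase 2 re-captures
    even at heights coincident with phase 1 — under noise the scores differ.
    """
    if params is None:
        params = FocusParams()
    sweep = FocusSweep()

    def clamp(height: float) -> float:
        return min(max(height, z_range[0]), z_range[1])

    def score(height: float) -> float:
        try:
            img = capture_at(height)
        except Exception as exc:  # attach the height for diagnostics
            raise CaptureError(height, exc) from exc
        s = sharpness(img)
        sweep.evaluations.append((height, s))
        return s

    start = theoretical_focus + params.start_above
    for i in range(params.coarse_n):
        score(clamp(start - (i + 1) * params.coarse_step))
    coarse_best = _argmax_highest(sweep.evaluations)

    fine_start = coarse_best + params.fine_recenter
    for i in range(params.fine_n):
        score(clamp(fine_start - (i + 1) * params.fine_step))

    sweep.best_height = _argmax_highest(sweep.evaluations)
    return sweep


def _argmax_highest(evals: list[tuple[float, float]]) -> float:
    """Height of the max score; ties go to the highest camera position."""
    best = max(evals, key=lambda hs: (hs[1], hs[0]))
    return best[0]
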