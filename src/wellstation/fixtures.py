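"""Synthetic test inputs with full ground truth.

Every input the analysis layer consumes — calibration slides, focus stacks,
micrographs, motility and photoresponse videos — can be generated here from
a seed, with a JSON-serialisable truth sidecar, so the whole stack runs and
is scored offline with no external data.

Cell size distributions follow the two model organisms the instrument was
built around: *Chlamydomonas reinhardtii* (diameter 5-12 µm) and the much
larger *Euglena gracilis* (length around 100 µm). Defaults use the
Chlamydomonas range at the 2.8 mm-lens calibration of 0.5 µm/px.

The module also carries the two reference automation scripts exercised
against the virtual device: a three-well demonstration sequence covering
every device function, and a 24-well maximum-throughput fill-and-capture
run.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from wellstation.device import (
    LedState,
    RenderModel,
    Scene,
    SceneCell,
    StageState,
    capture_video,
    render_frame,
)

__all__ = [
    "DEMO_SEQ_SCRIPT",
    "MAX_THROUGHPUT_SCRIPT",
    "FixtureSpec",
    "make_fixture",
    "calibration_slide",
    "micrograph",
    "focus_stack",
    "motility_video",
    "photoresponse_video",
    "random_scene",
]

# Reference automation scripts (JSON text, ready for automation.validate).
# DemoSeq: three wells, distinct colours/volumes/delays, purge + capture.
DEMO_SEQ_SCRIPT = (
    '{"name": "DemoSeq", "pos": [[0,0], [2,3], [3,0]],'
    ' "light": [[255,0,0,0], [0,255,0,0], [0,0,255,0]],'
    ' "delay": [30,60,0], "sampling": true, "volume": [1,2,3],'
    ' "trash": true, "capture": true}'
)

# MaxThroughput: fill and image every well of two 12-well plates.
MAX_THROUGHPUT_SCRIPT = (
    '{"name":"MaxThroughput",'
    '"pos":[[0,0],[1,0],[2,0],[0,1],[1,1],[2,1],[0,2],[1,2],[2,2],'
    '[0,3],[1,3],[2,3],[3,0],[4,0],[5,0],[3,1],[4,1],[5,1],[3,2],[4,2],[5,2],'
    '[3,3],[4,3],[5,3]],'
    '"light": [[0,0,0,255]], "delay": [0], "sampling": true, "volume": [1],'
    ' "trash": false, "capture": true}'
)

WHITE = LedState(w=255)
RED = LedState(r=255)


# -- calibration slide -----------------------------------------------------


def calibration_slide(
    division_um: float = 10.0,
    um_per_px: float = 0.5,
    image_size: tuple[int, int] = (1920, 1080),
    angle_deg: float = 0.0,
    line_width_px: int = 3,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Render a graduated slide: dark vertical lines ``division_um`` apart.

    Returns (uint8 image, truth) where truth records the generating µm/px
    and the line spacing in pixels.
    """
    w, h = image_size
    spacing_px = division_um / um_per_px
    rng = np.random.default_rng(seed)
    img = np.full((h, w), 210.0)
    # draw lines in a rotated coordinate frame
    yy, xx = np.mgrid[0:h, 0:w]
    theta = math.radians(angle_deg)
    u = xx * math.cos(theta) + yy * math.sin(theta)  # distance along the ruler
    phase = (u - w / 4.0) % spacing_px
    dist = np.minimum(phase, spacing_px - phase)
    lines = np.clip(line_width_px / 2.0 + 0.5 - dist, 0.0, 1.0)
    img -= 170.0 * lines
    img += rng.normal(0.0, noise_sd, img.shape)
    truth = {
        "um_per_px": um_per_px,
        "division_um": division_um,
        "spacing_px": spacing_px,
        "angle_deg": angle_deg,
    }
    return np.clip(img, 0, 255).astype(np.uint8), truth


# -- still micrograph ------------------------------------------------------


def _place_cells(
    rng: np.random.Generator,
    n_cells: int,
    diam_um: tuple[float, float],
    um_per_px: float,
    image_size: tuple[int, int],
    z_um: float,
    speed_um_s: tuple[float, float] = (0.0, 0.0),
    margin_px: float = 8.0,
) -> list[SceneCell]:
    """Non-overlapping cells inside the field of view (well-local µm coords)."""
    w, h = image_size
    half_w_um = (w / 2.0 - margin_px) * um_per_px
    half_h_um = (h / 2.0 - margin_px) * um_per_px
    cells: list[SceneCell] = []
    max_r_um = diam_um[1] / 2.0
    for _ in range(n_cells):
        for _attempt in range(2000):
            x = rng.uniform(-half_w_um + max_r_um, half_w_um - max_r_um)
            y = rng.uniform(-half_h_um + max_r_um, half_h_um - max_r_um)
            r = rng.uniform(*diam_um) / 2.0
            gap_um = 6.0 * um_per_px
            if all(
                math.hypot(x - c.center[0], y - c.center[1]) > r + c.radius + gap_um
                for c in cells
            ):
                break
        else:
            raise RuntimeError("could not place cells without overlap; lower n_cells")
        speed = rng.uniform(*speed_um_s)
        phi = rng.uniform(0.0, 2.0 * math.pi)
        vel = (speed * math.cos(phi), speed * math.sin(phi), 0.0)
        cells.append(SceneCell(center=(x, y, z_um), radius=r, velocity=vel))
    return cells


def micrograph(
    n_cells: int = 25,
    diam_um: tuple[float, float] = (5.0, 12.0),
    um_per_px: float = 0.5,
    image_size: tuple[int, int] = (640, 480),
    noise_sd: float = 1.5,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """In-focus still of non-overlapping cells under white light.

    Truth lists each cell's centre (px), diameter (µm and px) and the image
    calibration, so segmentation can be scored for count recall and size
    bias.
    """
    rng = np.random.default_rng(seed)
    scene = Scene(
        cells=_place_cells(rng, n_cells, diam_um, um_per_px, image_size, z_um=2600.0),
        column_depth=2600.0,
        rng_seed=seed,
    )
    render = RenderModel(
        pixel_size=um_per_px,
        image_size=image_size,
        base_blur=0.0,  # crisp optics so bounding boxes measure true size
        noise_sd=noise_sd,
    )
    stage = StageState(z=render.focal_offset)
    img = render_frame(scene, render, stage, WHITE)
    w, h = image_size
    truth = {
        "n_cells": n_cells,
        "um_per_px": um_per_px,
        "centers_px": [
            [c.center[0] / um_per_px + w / 2.0, c.center[1] / um_per_px + h / 2.0]
            for c in scene.cells
        ],
        "diameters_um": [2.0 * c.radius for c in scene.cells],
        "diameters_px": [2.0 * c.radius / um_per_px for c in scene.cells],
    }
    return img, truth


# -- focus stack -----------------------------------------------------------


def focus_stack(
    peak_mm: float = 5.0,
    heights_mm: list[float] | None = None,
    n_cells: int = 15,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[list[float], list[np.ndarray], dict]:
    """Images of one scene at a ladder of camera heights.

    The scene's top cell layer is in focus at ``peak_mm``, so image
    sharpness over the stack is unimodal with its maximum at the height
    nearest ``peak_mm``.
    """
    if heights_mm is None:
        heights_mm = [peak_mm - 0.6 + 0.05 * i for i in range(25)]
    rng = np.random.default_rng(seed)
    render = RenderModel(
        focal_offset=peak_mm, image_size=(320, 240), noise_sd=noise_sd
    )
    scene = Scene(
        cells=_place_cells(
            rng, n_cells, (8.0, 12.0), render.pixel_size, render.image_size, z_um=2600.0
        ),
        column_depth=2600.0,
        rng_seed=seed,
    )
    frames = [
        render_frame(scene, render, StageState(z=z), WHITE) for z in heights_mm
    ]
    truth = {"peak_mm": peak_mm, "heights_mm": list(heights_mm), "n_cells": n_cells}
    return list(heights_mm), frames, truth


def focus_capture(
    peak_mm: float = 5.0,
    n_cells: int = 15,
    noise_sd: float = 1.0,
    image_size: tuple[int, int] = (320, 240),
    seed: int = 0,
):
    """A ``capture_at`` callable over one synthetic scene, plus its truth.

    This is the image-at-height source the autofocus sweep consumes; the
    truth records the true sharpness peak.
    """
    rng = np.random.default_rng(seed)
    render = RenderModel(focal_offset=peak_mm, image_size=image_size, noise_sd=noise_sd)
    scene = Scene(
        cells=_place_cells(
            rng, n_cells, (8.0, 12.0), render.pixel_size, render.image_size, z_um=2600.0
        ),
        column_depth=2600.0,
        rng_seed=seed,
    )

    def capture_at(z: float) -> np.ndarray:
        return render_frame(scene, render, StageState(z=z), WHITE)

    return capture_at, {"peak_mm": peak_mm, "n_cells": n_cells}


# -- motility --------------------------------------------------------------


def random_scene(
    n_cells: int = 25,
    speed_um_s: tuple[float, float] = (20.0, 40.0),
    diam_um: tuple[float, float] = (10.0, 16.0),
    um_per_px: float = 0.5,
    image_size: tuple[int, int] = (320, 240),
    speed_decay_tau: float = 60.0,
    seed: int = 0,
) -> Scene:
    """Top-layer scene of swimming cells (photoresponse trigger: blue/white)."""
    rng = np.random.default_rng(seed)
    return Scene(
        cells=_place_cells(
            rng, n_cells, diam_um, um_per_px, image_size, z_um=2600.0,
            speed_um_s=speed_um_s,
        ),
        column_depth=2600.0,
        speed_decay_tau=speed_decay_tau,
        rng_seed=seed,
    )


def motility_video(
    speed_um_s: float = 30.0,
    n_cells: int = 1,
    n_frames: int = 20,
    fps: float = 30.0,
    um_per_px: float = 0.5,
    image_size: tuple[int, int] = (320, 240),
    direction_deg: float | None = None,
    noise_sd: float = 1.5,
    seed: int = 0,
) -> tuple[list[np.ndarray], dict]:
    """Clip of cells swimming at exactly ``speed_um_s`` under red light.

    Red light does not trigger the photoresponse, so the ground-truth speed
    is constant through the clip. Truth carries each cell's start position
    (px) and velocity.
    """
    rng = np.random.default_rng(seed)
    cells = _place_cells(
        rng, n_cells, (8.0, 12.0), um_per_px, image_size, z_um=2600.0,
        margin_px=30.0,
    )
    if n_cells == 1:
        # start at the frame centre so fast cells stay in view for the clip
        cells[0].center = (0.0, 0.0, 2600.0)
    for c in cells:
        phi = (
            math.radians(direction_deg)
            if direction_deg is not None
            else rng.uniform(0.0, 2.0 * math.pi)
        )
        c.velocity = (speed_um_s * math.cos(phi), speed_um_s * math.sin(phi), 0.0)
    scene = Scene(cells=cells, column_depth=2600.0, rng_seed=seed)
    render = RenderModel(
        pixel_size=um_per_px, image_size=image_size, noise_sd=noise_sd, wrap=True
    )
    frames = capture_video(scene, render, StageState(z=render.focal_offset), RED, n_frames / fps, fps)
    w, h = image_size
    truth = {
        "speed_um_s": speed_um_s,
        "um_per_px": um_per_px,
        "fps": fps,
        "px_per_frame": speed_um_s / um_per_px / fps,
        "starts_px": [
            [c.center[0] / um_per_px + w / 2.0, c.center[1] / um_per_px + h / 2.0]
            for c in scene.cells
        ],
        "velocities_um_s": [list(c.velocity) for c in scene.cells],
    }
    return frames, truth


def photoresponse_video(
    light: str = "white",
    burst_times_s: tuple[float, ...] = (0.0, 300.0),
    frames_per_burst: int = 4,
    fps: float = 30.0,
    n_cells: int = 25,
    speed_um_s: tuple[float, float] = (25.0, 40.0),
    speed_decay_tau: float = 60.0,
    noise_sd: float = 1.5,
    seed: int = 0,
) -> tuple[dict[float, list[np.ndarray]], dict]:
    """Short frame bursts of one culture at several exposure times.

    Under ``light="white"`` (or ``"blue"``) the trigger channel is lit from
    t=0, so cell speed at burst time t is scaled by ``exp(-t / tau)``; under
    ``"red"`` speed is constant. Returns {burst_time: frames} plus truth
    with the expected speeds per burst.
    """
    leds = {"white": WHITE, "red": RED, "blue": LedState(b=255)}[light]
    scene = random_scene(
        n_cells=n_cells,
        speed_um_s=speed_um_s,
        speed_decay_tau=speed_decay_tau,
        seed=seed,
    )
    render = RenderModel(image_size=(320, 240), noise_sd=noise_sd, wrap=True)
    stage = StageState(z=render.focal_offset)
    lit = scene.triggered_by(leds)
    bursts: dict[float, list[np.ndarray]] = {}
    for t in burst_times_s:
        bursts[t] = capture_video(
            scene, render, stage, leds, frames_per_burst / fps, fps,
            t0=t, exposed0=t if lit else 0.0,
        )
    truth = {
        "light": light,
        "triggered": lit,
        "tau_s": speed_decay_tau,
        "fps": fps,
        "mean_speed_um_s": {
            t: float(np.mean(scene.true_speeds(t if lit else 0.0))) for t in burst_times_s
        },
    }
    return bursts, truth


# -- file-level interface --------------------------------------------------


@dataclass
class FixtureSpec:
    """What to generate: a kind, its parameters, and a seed."""

    kind: str
    parameters: dict = field(default_factory=dict)
    seed: int = 0


_GENERATORS = {
    "calibration_slide": calibration_slide,
    "micrograph": micrograph,
    "focus_stack": focus_stack,
    "motility_video": motility_video,
    "photoresponse_video": photoresponse_video,
}


def make_fixture(spec: FixtureSpec | dict, out_dir: str | Path) -> list[Path]:
    """Write a fixture's image(s) plus its ``truth.json`` sidecar to disk."""
    if isinstance(spec, dict):
        spec = FixtureSpec(**spec)
    if spec.kind not in _GENERATORS:
        raise ValueError(
            f"unknown fixture kind {spec.kind!r}; choose from {sorted(_GENERATORS)}"
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gen = _GENERATORS[spec.kind]
    result = gen(**spec.parameters, seed=spec.seed)
    written: list[Path] = []

    if spec.kind in ("calibration_slide", "micrograph"):
        img, truth = result
        path = out / f"{spec.kind}.png"
        iio.imwrite(path, img)
        written.append(path)
    elif spec.kind == "focus_stack":
        heights, frames, truth = result
        for h, f in zip(heights, frames):
            path = out / f"z{h:07.3f}.png"
            iio.imwrite(path, f)
            written.append(path)
    elif spec.kind == "motility_video":
        frames, truth = result
        for i, f in enumerate(frames):
            path = out / f"frame{i:04d}.png"
            iio.imwrite(path, f)
            written.append(path)
    else:  # photoresponse_video
        bursts, truth = result
        for t, frames in bursts.items():
            for i, f in enumerate(frames):
                path = out / f"t{t:06.1f}_frame{i:02d}.png"
                iio.imwrite(path, f)
                written.append(path)

    sidecar = out / "truth.json"
    sidecar.write_text(json.dumps(truth, indent=1))
    written.append(sidecar)
    return written
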