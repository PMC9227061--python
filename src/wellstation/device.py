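"""Virtual hardware backend: stage, peristaltic pump, RGBW LEDs, camera.

Everything the physical machine does is simulated here behind the same call
surface the automation engine would use against a real transport, so the full
software stack runs and is testable with no device attached.

Simulated physics, in brief:

* **Stage** — exact moves inside a 220 x 220 x 240 mm working volume; a
  Gaussian positioning error (per-axis sigma in µm) is drawn once per homing
  event, mirroring how end-stop repeatability manifests on the real frame.
* **Pump** — each dispense returns ``volume * (1 + eps)`` with
  ``eps ~ N(0, relative_error_sd)``; the default 3.5 % relative error matches
  the characterised accuracy of the 3D-printed peristaltic pump at 1 mL.
* **LEDs** — one 4-channel (R, G, B, cold white) LED per well, each channel
  0-255.
* **Camera** — renders the well's :class:`Scene` in bright-field convention:
  dark cells on a background tinted by the active LED. Per-cell blur grows
  linearly with defocus, and cells deeper in the liquid column carry an extra
  depth penalty so that image sharpness over camera heights peaks at the
  height focusing the top liquid layer.
* **Photoresponse** — while a trigger channel (blue or white by default) is
  lit, cell speed decays as ``exp(-t_exposed / tau)``, emulating the
  light-dependent flagellar arrest of *C. reinhardtii*; under red light
  speed is constant.

A single seeded RNG stream per device instance makes whole runs, including
dispense errors and image noise, bit-reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from wellstation.plate_geometry import (
    WORKING_SURFACE_MM,
    PlateLayout,
    WellAddress,
    enumerate_wells,
    well_to_stage,
)

__all__ = [
    "WORKING_VOLUME_MM",
    "StageState",
    "PumpModel",
    "LedState",
    "SceneCell",
    "Scene",
    "RenderModel",
    "render_frame",
    "capture_video",
    "move_to",
    "dispense",
    "VirtualDevice",
]

#: Stage working volume (x, y, z) in mm.
WORKING_VOLUME_MM = (WORKING_SURFACE_MM[0], WORKING_SURFACE_MM[1], 240.0)


@dataclass
class StageState:
    """Cartesian stage pose in mm plus homing repeatability parameters."""

    x: float = 0.0
    y: float = 0.0
    z: float = 0.0
    homed: bool = False
    #: Per-axis 1-sigma homing deviation in µm, defaults from the measured
    #: repeatability of the printer frame (X 22, Y 11, Z 2 µm).
    homing_noise_sd: tuple[float, float, float] = (22.0, 11.0, 2.0)
    #: Residual offset (mm) drawn at the last homing event.
    home_error: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass
class PumpModel:
    """Peristaltic pump: flow rate plus multiplicative dispense error."""

    flow_rate: float = 0.5  # mL/s
    relative_error_sd: float = 0.035  # 3.5 % relative error at 1 mL
    purge_volume: float = 1.0  # mL pushed through when purging the circuit

    def __post_init__(self) -> None:
        if self.flow_rate <= 0:
            raise ValueError("flow_rate must be positive")
        if self.relative_error_sd < 0:
            raise ValueError("relative_error_sd must be >= 0")


@dataclass(frozen=True)
class LedState:
    """Channel intensities of one RGBW LED, each 0-255."""

    r: int = 0
    g: int = 0
    b: int = 0
    w: int = 0

    def __post_init__(self) -> None:
        for name in ("r", "g", "b", "w"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"LED channel {name} = {v} outside [0, 255]")

    @property
    def effective_rgb(self) -> tuple[int, int, int]:
        """RGB with the white channel folded in (clipped at 255)."""
        return (
            min(self.r + self.w, 255),
            min(self.g + self.w, 255),
            min(self.b + self.w, 255),
        )

    @property
    def luma(self) -> float:
        r, g, b = self.effective_rgb
        return 0.299 * r + 0.587 * g + 0.114 * b

    def any_on(self) -> bool:
        return any((self.r, self.g, self.b, self.w))


OFF = LedState()


@dataclass
class SceneCell:
    """One simulated cell: position/velocity in well-local µm coordinates."""

    center: tuple[float, float, float]  # (x, y, z) µm; z measured from well bottom
    radius: float  # µm
    velocity: tuple[float, float, float] = (0.0, 0.0, 0.0)  # µm/s
    base_color: tuple[int, int, int] = (60, 90, 55)  # dark algal green


@dataclass
class Scene:
    """Ground-truth synthetic world inside one well.

    Coordinates are µm, origin at the well centre on the well bottom, x/y in
    the image plane and z up through the liquid column.
    """

    cells: list[SceneCell] = field(default_factory=list)
    column_depth: float = 2600.0  # µm of liquid (~1 mL in a 12-well plate)
    well_radius: float = 11050.0  # µm
    trigger_channels: frozenset[str] = frozenset({"b", "w"})
    speed_decay_tau: float = 60.0  # s; e-folding time of light-induced arrest
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for c in self.cells:
            if c.radius <= 0:
                raise ValueError("cell radius must be positive")
            if not 0.0 <= c.center[2] <= self.column_depth:
                raise ValueError("cell z outside the liquid column")
            if math.hypot(c.center[0], c.center[1]) > self.well_radius:
                raise ValueError("cell outside the well cylinder")

    # -- ground truth ------------------------------------------------------

    def triggered_by(self, leds: LedState) -> bool:
        on = {"r": leds.r, "g": leds.g, "b": leds.b, "w": leds.w}
        return any(on[ch] > 0 for ch in self.trigger_channels)

    def speed_factor(self, exposed_s: float) -> float:
        """Multiplier on cell speed after ``exposed_s`` seconds of trigger light."""
        if exposed_s <= 0:
            return 1.0
        return math.exp(-exposed_s / self.speed_decay_tau)

    def positions_at(self, t: float, exposed_s: float = 0.0) -> np.ndarray:
        """(n, 3) cell centres at time ``t``.

        Cells drift freely for ``t - exposed_s`` seconds, then decay toward
        arrest during the trailing ``exposed_s`` seconds of trigger-light
        exposure (closed-form integral of the exponential speed decay).
        """
        exposed_s = min(max(exposed_s, 0.0), t) if t > 0 else 0.0
        free = t - exposed_s
        tau = self.speed_decay_tau
        decayed = tau * (1.0 - math.exp(-exposed_s / tau))
        out = np.empty((len(self.cells), 3))
        for i, c in enumerate(self.cells):
            v = np.asarray(c.velocity)
            out[i] = np.asarray(c.center) + v * free + v * decayed
        return out

    def true_speeds(self, exposed_s: float = 0.0) -> np.ndarray:
        """Instantaneous 2-D (image-plane) speeds in µm/s."""
        f = self.speed_factor(exposed_s)
        return np.array([math.hypot(c.velocity[0], c.velocity[1]) * f for c in self.cells])

    def truth(self) -> dict:
        """JSON-serialisable ground-truth sidecar."""
        return {
            "n_cells": len(self.cells),
            "centers_um": [list(c.center) for c in self.cells],
            "radii_um": [c.radius for c in self.cells],
            "diameters_um": [2 * c.radius for c in self.cells],
            "velocities_um_s": [list(c.velocity) for c in self.cells],
            "speeds_um_s": self.true_speeds().tolist(),
            "column_depth_um": self.column_depth,
            "speed_decay_tau_s": self.speed_decay_tau,
        }


@dataclass
class RenderModel:
    """Synthetic bright-field optics.

    ``focal_offset`` is the camera height (mm) at which the top liquid layer
    is in focus. A cell at depth ``d`` mm below the surface is sharpest at
    camera height ``focal_offset - d`` and additionally blurred by
    ``depth_penalty * d`` pixels, which makes the global sharpness optimum the
    top layer — the layer the instrument is designed to image.
    """

    focal_offset: float = 5.0  # mm
    blur_scale: float = 18.0  # px of Gaussian sigma per mm of defocus
    depth_penalty: float = 15.0  # px per mm of depth below the surface
    base_blur: float = 0.6  # px; optics are never perfectly crisp
    pixel_size: float = 0.5  # µm/px
    image_size: tuple[int, int] = (320, 240)  # (w, h) px
    noise_sd: float = 2.0  # gray levels
    ambient: float = 20.0  # background level with all LEDs off
    rgb: bool = False
    #: wrap cell positions periodically over the field of view, so long
    #: simulations keep a constant cell density instead of emptying the frame
    wrap: bool = False

    def __post_init__(self) -> None:
        if self.blur_scale <= 0:
            raise ValueError("blur_scale must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


def _paint_cell(
    canvas: np.ndarray,
    cx: float,
    cy: float,
    r_px: float,
    sigma: float,
    depth: float,
) -> None:
    """Subtractive paint of one blurred dark disk onto a float canvas.

    ``depth`` in [0, 1] scales the darkness (0 = invisible, 1 = full).
    """
    h, w = canvas.shape[:2]
    pad = int(math.ceil(r_px + 4 * sigma + 2))
    x0, x1 = int(math.floor(cx)) - pad, int(math.floor(cx)) + pad + 1
    y0, y1 = int(math.floor(cy)) - pad, int(math.floor(cy)) + pad + 1
    if x1 <= 0 or y1 <= 0 or x0 >= w or y0 >= h:
        return
    xs = np.arange(x0, x1)
    ys = np.arange(y0, y1)
    dist = np.hypot(xs[None, :] - cx, ys[:, None] - cy)
    disk = np.clip(r_px + 0.5 - dist, 0.0, 1.0)  # anti-aliased coverage
    if sigma > 0.05:
        disk = ndimage.gaussian_filter(disk, sigma, mode="constant")
    sy0, sy1 = max(y0, 0), min(y1, h)
    sx0, sx1 = max(x0, 0), min(x1, w)
    patch = disk[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] * depth
    if canvas.ndim == 2:
        canvas[sy0:sy1, sx0:sx1] *= 1.0 - patch
    else:
        canvas[sy0:sy1, sx0:sx1] *= 1.0 - patch[..., None]


def render_frame(
    scene: Scene,
    render: RenderModel,
    stage: StageState,
    leds: LedState,
    t: float = 0.0,
    exposed_s: float | None = None,
    well_center: tuple[float, float] | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one camera frame of ``scene`` at simulation time ``t``.

    ``exposed_s`` is how long a photoresponse trigger channel has been lit;
    if ``None`` it is taken to be ``t`` when ``leds`` contains a lit trigger
    channel and 0 otherwise. ``well_center`` (mm) anchors the scene on the
    stage; when ``None`` the camera is assumed centred over the well.

    Returns a ``(h, w)`` uint8 image, or ``(h, w, 3)`` when ``render.rgb``.
    """
    if exposed_s is None:
        exposed_s = t if scene.triggered_by(leds) else 0.0
    if rng is None:
        rng = np.random.default_rng(
            (scene.rng_seed * 1_000_003 + int(round(t * 1e4))) % (2**31)
        )
    w, h = render.image_size
    if leds.any_on():
        lr, lg, lb = leds.effective_rgb
        bg_rgb = render.ambient + (240.0 - render.ambient) * np.array([lr, lg, lb]) / 255.0
    else:
        bg_rgb = np.full(3, render.ambient)

    if render.rgb:
        canvas = np.ones((h, w, 3))
    else:
        canvas = np.ones((h, w))

    # camera offset of image centre from the well centre, in px
    if well_center is None:
        off_x_um = off_y_um = 0.0
    else:
        off_x_um = (stage.x - well_center[0]) * 1000.0
        off_y_um = (stage.y - well_center[1]) * 1000.0

    positions = scene.positions_at(t, exposed_s)
    for cell, pos in zip(scene.cells, positions):
        cx = (pos[0] - off_x_um) / render.pixel_size + w / 2.0
        cy = (pos[1] - off_y_um) / render.pixel_size + h / 2.0
        if render.wrap:
            cx, cy = cx % w, cy % h
        r_px = cell.radius / render.pixel_size
        depth_mm = (scene.column_depth - pos[2]) / 1000.0
        focus_z = render.focal_offset - depth_mm
        sigma = (
            render.base_blur
            + render.blur_scale * abs(stage.z - focus_z)
            + render.depth_penalty * depth_mm
        )
        # heavily defocused cells fade as well as blur
        darkness = 0.85 / (1.0 + 0.02 * sigma**2)
        if render.wrap:
            # ghost copies keep objects continuous across the wrap seam
            for gx in (-w, 0, w):
                for gy in (-h, 0, h):
                    _paint_cell(canvas, cx + gx, cy + gy, r_px, sigma, darkness)
        else:
            _paint_cell(canvas, cx, cy, r_px, sigma, darkness)

    if render.rgb:
        img = canvas * bg_rgb[None, None, :]
        # absorb toward the cell's own colour where cells darken the field
        img = img + (1.0 - canvas) * (np.ones((h, w, 3)) * 0.0)
    else:
        img = canvas * (0.299 * bg_rgb[0] + 0.587 * bg_rgb[1] + 0.114 * bg_rgb[2])
    if render.noise_sd > 0:
        img = img + rng.normal(0.0, render.noise_sd, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def capture_video(
    scene: Scene,
    render: RenderModel,
    stage: StageState,
    leds: LedState,
    duration: float,
    fps: float,
    t0: float = 0.0,
    exposed0: float | None = None,
    well_center: tuple[float, float] | None = None,
) -> list[np.ndarray]:
    """``ceil(duration * fps)`` frames starting at ``t0``, 1/fps apart.

    Deterministic given ``scene.rng_seed``. ``exposed0`` is the trigger-light
    exposure already accumulated at ``t0`` (it keeps growing during the clip
    if a trigger channel is lit).
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    n = math.ceil(duration * fps)
    lit = scene.triggered_by(leds)
    if exposed0 is None:
        exposed0 = t0 if lit else 0.0
    frames = []
    for i in range(n):
        t = t0 + i / fps
        exp = exposed0 + i / fps if lit else 0.0
        frames.append(
            render_frame(scene, render, stage, leds, t, exposed_s=exp, well_center=well_center)
        )
    return frames


# -- stateless op wrappers used directly in tests and docs ----------------


def move_to(state: StageState, target: tuple[float, float, float]) -> StageState:
    """Pure stage move: returns the new state; raises on out-of-volume targets."""
    for val, lim, axis in zip(target, WORKING_VOLUME_MM, "xyz"):
        if not 0.0 <= val <= lim:
            raise ValueError(f"target {axis} = {val:.2f} mm outside [0, {lim}] working volume")
    return replace(state, x=target[0], y=target[1], z=target[2])


def dispense(pump: PumpModel, volume: float, rng: np.random.Generator) -> float:
    """Simulate one dispense; returns the volume actually delivered (mL)."""
    if volume <= 0:
        raise ValueError("dispense volume must be positive")
    eps = rng.normal(0.0, pump.relative_error_sd)
    return volume * (1.0 + eps)


class VirtualDevice:
    """Complete simulated instrument with a simulated clock.

    Implements the device contract the automation engine drives: ``home``,
    ``move_to``, ``set_led`` / ``leds_off``, ``purge``, ``dispense``,
    ``capture`` and ``wait``. Durations are accounted on :attr:`clock`
    (simulated seconds) — nothing sleeps.
    """

    #: default lateral camera->pipette-tip offset, mm
    TOOL_OFFSET = (-30.0, 0.0)

    def __init__(
        self,
        layout: PlateLayout,
        render: RenderModel | None = None,
        pump: PumpModel | None = None,
        stage: StageState | None = None,
        scenes: dict[WellAddress, Scene] | None = None,
        seed: int = 0,
        axis_speed_xy: float = 50.0,  # mm/s
        axis_speed_z: float = 5.0,
        capture_s: float = 0.5,
        settle_s: float = 1.0,
        tool_offset: tuple[float, float] | None = None,
    ) -> None:
        self.layout = layout
        self.render = render if render is not None else RenderModel()
        self.pump = pump if pump is not None else PumpModel()
        self.stage = stage if stage is not None else StageState()
        self.scenes = dict(scenes) if scenes else {}
        self.rng = np.random.default_rng(seed)
        self.axis_speed_xy = axis_speed_xy
        self.axis_speed_z = axis_speed_z
        self.capture_s = capture_s
        self.settle_s = settle_s
        self.tool_offset = tool_offset if tool_offset is not None else self.TOOL_OFFSET
        self.clock = 0.0  # simulated seconds
        #: last commanded (nominal) pose; the stage holds nominal + homing error
        self.nominal = (self.stage.x, self.stage.y, self.stage.z)
        self.leds: dict[WellAddress, LedState] = {}
        self._lit_since: dict[WellAddress, float] = {}
        self.log: list[dict] = []

    # -- bookkeeping -------------------------------------------------------

    def _log(self, action: str, **params) -> None:
        self.log.append({"t": round(self.clock, 3), "action": action, **params})

    def wait(self, seconds: float) -> None:
        if seconds < 0:
            raise ValueError("cannot wait a negative time")
        self.clock += seconds
        self._log("wait", seconds=seconds)

    # -- stage -------------------------------------------------------------

    def home(self) -> None:
        """Home all axes; draws the once-per-homing positioning error."""
        sd_mm = np.asarray(self.stage.homing_noise_sd) / 1000.0
        err = tuple(self.rng.normal(0.0, sd_mm))
        dist_xy = math.hypot(self.stage.x, self.stage.y)
        self.clock += dist_xy / self.axis_speed_xy + abs(self.stage.z) / self.axis_speed_z
        self.stage = replace(
            self.stage, x=err[0], y=err[1], z=err[2], homed=True, home_error=err
        )
        self.nominal = (0.0, 0.0, 0.0)
        self._log("home", error_um=[round(e * 1000, 2) for e in err])

    def move_to(self, x: float, y: float, z: float) -> None:
        new = move_to(self.stage, (x, y, z))
        dt = (
            math.hypot(new.x - self.stage.x, new.y - self.stage.y) / self.axis_speed_xy
            + abs(new.z - self.stage.z) / self.axis_speed_z
        )
        self.clock += dt
        # the homing residual rides along: commanded coordinates are nominal
        self.stage = replace(
            new,
            x=new.x + self.stage.home_error[0],
            y=new.y + self.stage.home_error[1],
            z=new.z + self.stage.home_error[2],
            homed=self.stage.homed,
            home_error=self.stage.home_error,
        )
        self.nominal = (x, y, z)
        self._log("move", x=x, y=y, z=z, duration=round(dt, 3))

    # -- LEDs --------------------------------------------------------------

    def set_led(self, addr: WellAddress, channels: tuple[int, int, int, int]) -> None:
        state = LedState(*channels)
        prev = self.leds.get(addr, OFF)
        scene = self.scenes.get(addr)
        trig = scene.triggered_by(state) if scene else state.b > 0 or state.w > 0
        prev_trig = (
            scene.triggered_by(prev) if scene else prev.b > 0 or prev.w > 0
        )
        if trig and not prev_trig:
            self._lit_since[addr] = self.clock
        elif not trig:
            self._lit_since.pop(addr, None)
        self.leds[addr] = state
        self._log("led", well=[addr.x, addr.y], channels=list(channels))

    def leds_off(self) -> None:
        self.leds = {}
        self._lit_since = {}
        self._log("led", well=None, channels=[0, 0, 0, 0])

    # -- pump --------------------------------------------------------------

    def purge(self) -> None:
        self.clock += self.pump.purge_volume / self.pump.flow_rate
        self._log("purge", volume=self.pump.purge_volume)

    def dispense(self, volume: float) -> float:
        actual = dispense(self.pump, volume, self.rng)
        self.clock += volume / self.pump.flow_rate
        self._log("dispense", requested=volume, actual=round(actual, 5))
        return actual

    # -- camera ------------------------------------------------------------

    def current_well(self) -> WellAddress | None:
        """Nearest well to the camera axis, or None when off-plate."""
        best, best_d = None, float("inf")
        for addr in enumerate_wells(self.layout):
            wx, wy = well_to_stage(self.layout, addr)
            d = math.hypot(self.stage.x - wx, self.stage.y - wy)
            if d < best_d:
                best, best_d = addr, d
        if best is not None and best_d <= self.layout.format.well_diameter:
            return best
        return None

    def capture(self) -> np.ndarray:
        """Capture a frame of whatever well the camera is over."""
        addr = self.current_well()
        scene = self.scenes.get(addr) if addr is not None else None
        leds = self.leds.get(addr, OFF) if addr is not None else OFF
        self.clock += self.capture_s
        if scene is None:
            scene = Scene(cells=[], rng_seed=int(self.rng.integers(2**31)))
            frame = render_frame(scene, self.render, self.stage, leds, t=self.clock)
        else:
            lit_since = self._lit_since.get(addr)
            exposed = self.clock - lit_since if lit_since is not None else 0.0
            frame = render_frame(
                scene,
                self.render,
                self.stage,
                leds,
                t=self.clock,
                exposed_s=exposed,
                well_center=well_to_stage(self.layout, addr),
            )
        self._log("capture", well=None if addr is None else [addr.x, addr.y])
        return frame

    def capture_at(self, z: float) -> np.ndarray:
        """Move the camera to height ``z`` and capture (autofocus hook)."""
        self.move_to(self.nominal[0], self.nominal[1], z)
        return self.capture()

    def capture_video(self, duration: float, fps: float) -> list[np.ndarray]:
        """Film the current well; the simulated clock advances by ``duration``."""
        addr = self.current_well()
        scene = self.scenes.get(addr) if addr is not None else Scene(cells=[])
        if scene is None:
            scene = Scene(cells=[])
        leds = self.leds.get(addr, OFF) if addr is not None else OFF
        lit_since = self._lit_since.get(addr) if addr is not None else None
        exposed0 = self.clock - lit_since if lit_since is not None else None
        frames = capture_video(
            scene,
            self.render,
            self.stage,
            leds,
            duration,
            fps,
            t0=self.clock,
            exposed0=exposed0,
            well_center=(
                well_to_stage(self.layout, addr) if addr is not None else None
            ),
        )
        self.clock += duration
        self._log("capture_video", n_frames=len(frames), fps=fps)
        return frames

    # -- config ------------------------------------------------------------

    @classmethod
    def from_config(cls, layout: PlateLayout, path: str | Path) -> "VirtualDevice":
        """Build a device from a JSON config (render/pump/timing overrides)."""
        obj = json.loads(Path(path).read_text())
        kwargs = {}
        if "render" in obj:
            r = dict(obj["render"])
            if "image_size" in r:
                r["image_size"] = tuple(r["image_size"])
            kwargs["render"] = RenderModel(**r)
        if "pump" in obj:
            kwargs["pump"] = PumpModel(**obj["pump"])
        for key in ("seed", "axis_speed_xy", "axis_speed_z", "capture_s", "settle_s"):
            if key in obj:
                kwargs[key] = obj[key]
        return cls(layout, **kwargs)
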