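"""JSON automation scripts: validation, time estimation, execution.

A script is a single JSON object describing a sequence of per-well actions::

    {"name": "DemoSeq",
     "pos": [[0,0], [2,3], [3,0]],
     "light": [[255,0,0,0], [0,255,0,0], [0,0,255,0]],
     "delay": [30, 60, 0],
     "sampling": true, "volume": [1, 2, 3],
     "trash": true, "capture": true}

``pos`` lists well addresses in visit order. ``volume`` (mL), ``light``
(RGBW 0-255) and ``delay`` (s) may each hold a single entry, broadcast to
every well, or exactly one entry per well. ``sampling`` dispenses into the
well (purging the circuit first when ``trash`` is set); ``capture`` runs the
autofocus and saves an image named ``<name>X<x>Y<y>.png``. ``delay[i]`` is
the wait after completing well *i*, before the next one.

After the last well the engine switches every LED off, parks the stage in
the safe position (camera at the far corner, bed advanced toward the user)
and reports the elapsed time.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio

from wellstation.device import WORKING_VOLUME_MM, VirtualDevice
from wellstation.focus import FocusParams, autofocus
from wellstation.plate_geometry import (
    PlateLayout,
    WellAddress,
    tip_position_for_well,
    well_to_stage,
)

__all__ = [
    "ScriptError",
    "AutomationScript",
    "TimingModel",
    "RunReport",
    "validate",
    "estimate_runtime",
    "execute",
    "safe_position",
]

_REQUIRED = ("name", "pos")
_KNOWN = {"name", "pos", "sampling", "volume", "capture", "light", "delay", "trash"}


class ScriptError(ValueError):
    """Invalid automation script; the message names the offending property."""


@dataclass
class AutomationScript:
    """Validated, normalized script: all per-well lists expanded to |pos|."""

    name: str
    pos: list[WellAddress]
    sampling: bool = False
    volume: list[float] = field(default_factory=list)  # mL, per well
    capture: bool = False
    light: list[tuple[int, int, int, int]] = field(default_factory=list)
    delay: list[float] = field(default_factory=list)  # s, after each well
    trash: bool = False

    def image_name(self, addr: WellAddress) -> str:
        return f"{self.name}{addr}.png"


def _broadcast(name: str, values: list, n: int) -> list:
    if len(values) == 1:
        return list(values) * n
    if len(values) == n:
        return list(values)
    raise ScriptError(
        f'property "{name}" has {len(values)} entries; expected 1 or {n}'
    )


def validate(script: str | dict) -> AutomationScript:
    """Check and normalize a script (JSON text or already-parsed dict).

    Raises :class:`ScriptError` naming the missing or malformed property;
    unknown properties produce a warning and are ignored.
    """
    obj = json.loads(script) if isinstance(script, str) else dict(script)
    if not isinstance(obj, dict):
        raise ScriptError("script must be a JSON object")

    unknown = set(obj) - _KNOWN
    if unknown:
        warnings.warn(f"ignoring unknown script properties: {sorted(unknown)}", stacklevel=2)

    for key in _REQUIRED:
        if key not in obj:
            raise ScriptError(f'missing required property "{key}"')
    name = obj["name"]
    if not isinstance(name, str) or not name:
        raise ScriptError('property "name" must be a non-empty string')

    raw_pos = obj["pos"]
    if not isinstance(raw_pos, list) or not raw_pos:
        raise ScriptError('property "pos" must be a non-empty list of [x, y] pairs')
    try:
        pos = [WellAddress(int(p[0]), int(p[1])) for p in raw_pos]
    except (TypeError, IndexError, ValueError) as exc:
        raise ScriptError(f'property "pos" entries must be [x, y] pairs: {exc}') from exc
    n = len(pos)

    sampling = bool(obj.get("sampling", False))
    capture = bool(obj.get("capture", False))
    trash = bool(obj.get("trash", False))

    if sampling:
        if "volume" not in obj:
            raise ScriptError('property "volume" is required when "sampling" is true')
        volume = _broadcast("volume", [float(v) for v in obj["volume"]], n)
        if any(v <= 0 for v in volume):
            raise ScriptError('property "volume" entries must be positive')
    else:
        volume = []

    if "light" in obj:
        light = []
        for entry in _broadcast("light", list(obj["light"]), n):
            ch = tuple(int(c) for c in entry)
            if len(ch) != 4 or any(not 0 <= c <= 255 for c in ch):
                raise ScriptError('property "light" entries must be 4 channels in [0, 255]')
            light.append(ch)
    else:
        light = []

    if "delay" in obj:
        delay = _broadcast("delay", [float(d) for d in obj["delay"]], n)
        if any(d < 0 for d in delay):
            raise ScriptError('property "delay" entries must be >= 0')
    else:
        delay = [0.0] * n

    return AutomationScript(
        name=name,
        pos=pos,
        sampling=sampling,
        volume=volume,
        capture=capture,
        light=light,
        delay=delay,
        trash=trash,
    )


@dataclass
class TimingModel:
    """Per-action durations used by the run-time estimator (seconds, mm/s)."""

    axis_speed_xy: float = 50.0
    axis_speed_z: float = 5.0
    purge_s: float = 2.0  # purge_volume / flow_rate at defaults
    pump_s_per_ml: float = 2.0  # 1 / flow_rate
    capture_s: float = 0.5
    settle_s: float = 1.0
    #: nominal camera height (mm) during imaging; only the final park move
    #: to the top of the working volume depends on it
    focus_z_mm: float = 5.0
    focus_params: FocusParams = field(default_factory=FocusParams)

    @classmethod
    def from_device(cls, device: VirtualDevice, focus_params: FocusParams | None = None) -> "TimingModel":
        """Timing constants matching a virtual device's configuration."""
        return cls(
            axis_speed_xy=device.axis_speed_xy,
            axis_speed_z=device.axis_speed_z,
            purge_s=device.pump.purge_volume / device.pump.flow_rate,
            pump_s_per_ml=1.0 / device.pump.flow_rate,
            capture_s=device.capture_s,
            settle_s=device.settle_s,
            focus_z_mm=device.render.focal_offset,
            focus_params=focus_params or FocusParams(),
        )

    @property
    def autofocus_s(self) -> float:
        """Sweep cost: one capture per evaluation plus the z travel."""
        p = self.focus_params
        n = p.coarse_n + p.fine_n
        z_travel = (
            p.start_above
            + p.coarse_n * p.coarse_step  # coarse descent
            + p.coarse_n * p.coarse_step / 2 + p.fine_recenter  # recenter (mean)
            + p.fine_n * p.fine_step  # fine descent
            + p.fine_n * p.fine_step / 2  # return to best (mean)
        )
        return n * self.capture_s + z_travel / self.axis_speed_z


def estimate_runtime(
    script: AutomationScript,
    layout: PlateLayout,
    timing: TimingModel | None = None,
    tool_offset: tuple[float, float] = VirtualDevice.TOOL_OFFSET,
) -> float:
    """Predicted run time (s) of a validated script.

    Sums, per well: travel to the well, the purge/dispense time when
    sampling, the settle wait plus autofocus and capture when capturing, and
    the scripted delay. Always at least the sum of the delays.
    """
    if timing is None:
        timing = TimingModel()
    total = 0.0
    prev_xy: tuple[float, float] | None = (0.0, 0.0)  # from home
    for i, addr in enumerate(script.pos):
        cam = well_to_stage(layout, addr)
        if script.sampling:
            tip = tip_position_for_well(layout, addr, tool_offset)
            total += _xy_time(prev_xy, tip, timing)
            if script.trash:
                total += timing.purge_s
            total += script.volume[i] * timing.pump_s_per_ml
            prev_xy = tip
        if script.capture:
            total += _xy_time(prev_xy, cam, timing)
            prev_xy = cam
            total += timing.settle_s + timing.autofocus_s + timing.capture_s
        elif not script.sampling:
            total += _xy_time(prev_xy, cam, timing)
            prev_xy = cam
        total += script.delay[i]
    # final park: camera to the far corner at the top of the working volume
    total += _xy_time(prev_xy, (WORKING_VOLUME_MM[0], WORKING_VOLUME_MM[1]), timing)
    total += (WORKING_VOLUME_MM[2] - timing.focus_z_mm) / timing.axis_speed_z
    return max(total, sum(script.delay))


def _xy_time(a: tuple[float, float] | None, b: tuple[float, float], timing: TimingModel) -> float:
    if a is None:
        return 0.0
    return ((b[0] - a[0]) ** 2 + (b[1] - a[1]) ** 2) ** 0.5 / timing.axis_speed_xy


@dataclass
class RunReport:
    """Outcome of one script execution."""

    script_name: str
    elapsed: float  # s (simulated time on a virtual device)
    images: list[str] = field(default_factory=list)
    dispensed: list[float] = field(default_factory=list)  # mL actually delivered
    log: list[dict] = field(default_factory=list)
    completed: bool = True
    error: str | None = None


def safe_position(device: VirtualDevice) -> None:
    """Park: camera to the far X corner at max height, bed advanced (max Y)."""
    if not device.stage.homed:
        device.home()
    device.move_to(WORKING_VOLUME_MM[0], WORKING_VOLUME_MM[1], WORKING_VOLUME_MM[2])


def execute(
    script: AutomationScript,
    device: VirtualDevice,
    layout: PlateLayout | None = None,
    out_dir: str | Path = ".",
    focus_params: FocusParams | None = None,
    notify=None,
) -> RunReport:
    """Run a validated script on a device implementing the device contract.

    Images are written to ``out_dir`` as ``<name>X<x>Y<y>.png``. Device
    errors abort the run and return a partial report (``completed=False``).
    ``notify``, when given, is called with the report on completion — the
    hook point for push/email notification.
    """
    if layout is None:
        layout = device.layout
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(script_name=script.name, elapsed=0.0)
    t0 = device.clock
    focus_z = device.render.focal_offset  # camera z giving a focus-ready start

    try:
        if not device.stage.homed:
            device.home()
        for i, addr in enumerate(script.pos):
            if script.light:
                device.leds_off()  # only the active well is lit
                device.set_led(addr, script.light[i])
            if script.sampling:
                tip = tip_position_for_well(layout, addr, device.tool_offset)
                device.move_to(tip[0], tip[1], device.nominal[2])
                if script.trash:
                    device.purge()
                report.dispensed.append(device.dispense(script.volume[i]))
            if script.capture:
                cam = well_to_stage(layout, addr)
                device.move_to(cam[0], cam[1], focus_z)
                device.wait(device.settle_s)
                sweep = autofocus(
                    device.capture_at,
                    theoretical_focus=focus_z,
                    params=focus_params,
                    z_range=(0.0, WORKING_VOLUME_MM[2]),
                )
                device.move_to(cam[0], cam[1], sweep.best_height)
                frame = device.capture()
                fname = script.image_name(addr)
                iio.imwrite(out_dir / fname, frame)
                report.images.append(fname)
            if script.delay[i] > 0:
                device.wait(script.delay[i])
    except Exception as exc:  # partial report on device failure
        report.completed = False
        report.error = str(exc)
    finally:
        device.leds_off()
        try:
            safe_position(device)
        except Exception:
            pass
        report.elapsed = device.clock - t0
        report.log = list(device.log)
    if notify is not None:
        notify(report)
    return report
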