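"""Well-address to stage-coordinate mapping for the two-plate holder.

The sample holder carries up to two multiwell plates side by side along the
stage X axis. Wells are addressed with a 0-based ``(x, y)`` pair where ``x``
is the column index running continuously across both plates (columns
``0..n_cols-1`` belong to plate 1, ``n_cols..2*n_cols-1`` to plate 2) and
``y`` is the row index, ``(0, 0)`` being the top-left well of plate 1. All
stage coordinates are millimetres in the machine frame (origin at home); the
working surface is 220 x 220 mm.

Well pitches default to the ANSI/SLAS microplate standard; every constant is
configurable per :class:`PlateFormat` for non-standard labware.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "WORKING_SURFACE_MM",
    "PlateFormat",
    "WellAddress",
    "PlateLayout",
    "well_to_stage",
    "enumerate_wells",
    "tip_position_for_well",
    "load_layout",
    "save_layout",
]

#: Usable stage travel (x, y) in mm.
WORKING_SURFACE_MM = (220.0, 220.0)

# ANSI/SLAS well pitches (mm) and typical well diameters (mm). The plates sit
# portrait on the holder (short edge along X), so a 12-well plate presents
# 3 columns x 4 rows.
_SLAS = {
    12: dict(n_cols=3, n_rows=4, well_pitch=26.01, well_diameter=22.1),
    24: dict(n_cols=4, n_rows=6, well_pitch=19.3, well_diameter=15.6),
    96: dict(n_cols=8, n_rows=12, well_pitch=9.0, well_diameter=6.35),
}


@dataclass(frozen=True)
class PlateFormat:
    """Physical geometry of a single multiwell plate."""

    wells_per_plate: int
    n_cols: int
    n_rows: int
    well_pitch: float  # mm, centre-to-centre
    # holder origin to well (0,0) centre; the X margin leaves room for the
    # pipette tip, which rides ~30 mm to the left of the camera axis
    a1_offset_x: float = 45.0  # mm
    a1_offset_y: float = 20.0
    well_diameter: float = 10.0  # mm

    def __post_init__(self) -> None:
        if self.n_cols * self.n_rows != self.wells_per_plate:
            raise ValueError(
                f"n_cols*n_rows = {self.n_cols * self.n_rows} != "
                f"wells_per_plate = {self.wells_per_plate}"
            )
        if not (self.well_pitch > self.well_diameter > 0):
            raise ValueError("require well_pitch > well_diameter > 0")

    @classmethod
    def standard(cls, wells_per_plate: int) -> "PlateFormat":
        """SLAS-standard format for 12-, 24- or 96-well plates."""
        try:
            geom = _SLAS[wells_per_plate]
        except KeyError:
            raise ValueError(
                f"no standard format for {wells_per_plate}-well plates "
                f"(supported: {sorted(_SLAS)})"
            ) from None
        return cls(wells_per_plate=wells_per_plate, **geom)

    @property
    def plate_width(self) -> float:
        """Nominal X footprint of one plate's well block (mm)."""
        return self.n_cols * self.well_pitch


@dataclass(frozen=True, order=True)
class WellAddress:
    """0-based (column, row) address; the column spans both plates."""

    x: int
    y: int

    def __str__(self) -> str:  # used in image file names: X<x>Y<y>
        return f"X{self.x}Y{self.y}"


@dataclass
class PlateLayout:
    """Plates on the holder plus offsets and optional custom well positions."""

    format: PlateFormat
    n_plates: int = 2
    global_offset_x: float = 0.0  # mm
    global_offset_y: float = 0.0
    plate_gap: float = 10.0  # mm between the two plates' well blocks
    custom_positions: dict[WellAddress, tuple[float, float]] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.n_plates not in (1, 2):
            raise ValueError("holder carries 1 or 2 plates")
        if self.custom_positions is not None:
            missing = [a for a in enumerate_wells(self) if a not in self.custom_positions]
            if missing:
                raise ValueError(
                    f"custom_positions missing {len(missing)} wells, first {missing[0]}"
                )

    @property
    def n_wells(self) -> int:
        return self.n_plates * self.format.wells_per_plate


def _check_address(layout: PlateLayout, addr: WellAddress) -> None:
    fmt = layout.format
    max_x = layout.n_plates * fmt.n_cols
    if not 0 <= addr.x < max_x:
        raise ValueError(f"well x index {addr.x} out of range [0, {max_x})")
    if not 0 <= addr.y < fmt.n_rows:
        raise ValueError(f"well y index {addr.y} out of range [0, {fmt.n_rows})")


def well_to_stage(layout: PlateLayout, addr: WellAddress) -> tuple[float, float]:
    """Stage (x, y) in mm of the well centre.

    Custom positions, when configured, take precedence over the pitch
    arithmetic; the global offset applies in both cases.
    """
    _check_address(layout, addr)
    ox, oy = layout.global_offset_x, layout.global_offset_y
    if layout.custom_positions is not None:
        cx, cy = layout.custom_positions[addr]
        return (cx + ox, cy + oy)
    fmt = layout.format
    plate = addr.x // fmt.n_cols
    col = addr.x % fmt.n_cols
    x = fmt.a1_offset_x + col * fmt.well_pitch + plate * (fmt.plate_width + layout.plate_gap)
    y = fmt.a1_offset_y + addr.y * fmt.well_pitch
    x, y = x + ox, y + oy
    if not (0.0 <= x <= WORKING_SURFACE_MM[0]):
        raise ValueError(f"well {addr} stage x = {x:.2f} mm outside working surface")
    if not (0.0 <= y <= WORKING_SURFACE_MM[1]):
        raise ValueError(f"well {addr} stage y = {y:.2f} mm outside working surface")
    return (x, y)


def enumerate_wells(layout: PlateLayout) -> list[WellAddress]:
    """All addressable wells, row-major within a plate, plate 1 before plate 2."""
    fmt = layout.format
    out: list[WellAddress] = []
    for plate in range(layout.n_plates):
        for row in range(fmt.n_rows):
            for col in range(fmt.n_cols):
                out.append(WellAddress(plate * fmt.n_cols + col, row))
    return out


def tip_position_for_well(
    layout: PlateLayout, addr: WellAddress, tool_offset: tuple[float, float]
) -> tuple[float, float]:
    """Stage (x, y) placing the pipette tip over the well centre.

    The tip sits at a fixed lateral offset from the camera axis, so the stage
    target is the camera position shifted by ``tool_offset`` (mm).
    """
    wx, wy = well_to_stage(layout, addr)
    x, y = wx + tool_offset[0], wy + tool_offset[1]
    if not (0.0 <= x <= WORKING_SURFACE_MM[0]):
        raise ValueError(f"tip x = {x:.2f} mm outside working surface for well {addr}")
    if not (0.0 <= y <= WORKING_SURFACE_MM[1]):
        raise ValueError(f"tip y = {y:.2f} mm outside working surface for well {addr}")
    return (x, y)


def load_layout(path: str | Path) -> PlateLayout:
    """Read a layout JSON file.

    Two dialects are accepted: ``{"format": {...}, "n_plates": ..,
    "global_offset_x": .., ...}`` describing a regular grid, or the same
    object with a ``custom_positions`` list of ``[x_idx, y_idx, x_mm, y_mm]``
    rows for hand-measured supports.
    """
    obj = json.loads(Path(path).read_text())
    fmt_obj = obj["format"]
    if isinstance(fmt_obj, int):
        fmt = PlateFormat.standard(fmt_obj)
    else:
        fmt = PlateFormat(**fmt_obj)
    custom = None
    if obj.get("custom_positions") is not None:
        custom = {
            WellAddress(int(xi), int(yi)): (float(xm), float(ym))
            for xi, yi, xm, ym in obj["custom_positions"]
        }
    return PlateLayout(
        format=fmt,
        n_plates=int(obj.get("n_plates", 2)),
        global_offset_x=float(obj.get("global_offset_x", 0.0)),
        global_offset_y=float(obj.get("global_offset_y", 0.0)),
        plate_gap=float(obj.get("plate_gap", 10.0)),
        custom_positions=custom,
    )


def save_layout(layout: PlateLayout, path: str | Path) -> None:
    """Write a layout to the JSON dialect read by :func:`load_layout`."""
    fmt = layout.format
    obj: dict = {
        "format": {
            "wells_per_plate": fmt.wells_per_plate,
            "n_cols": fmt.n_cols,
            "n_rows": fmt.n_rows,
            "well_pitch": fmt.well_pitch,
            "a1_offset_x": fmt.a1_offset_x,
            "a1_offset_y": fmt.a1_offset_y,
            "well_diameter": fmt.well_diameter,
        },
        "n_plates": layout.n_plates,
        "global_offset_x": layout.global_offset_x,
        "global_offset_y": layout.global_offset_y,
        "plate_gap": layout.plate_gap,
    }
    if layout.custom_positions is not None:
        obj["custom_positions"] = [
            [a.x, a.y, p[0], p[1]] for a, p in sorted(layout.custom_positions.items())
        ]
    Path(path).write_text(json.dumps(obj, indent=1))
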