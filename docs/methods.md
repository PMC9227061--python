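# Methods

This note documents the models behind the simulated imaging station, the
defaults chosen where the physical instrument left them open, and what the
synthetic scenes do and do not say about real micrographs.

## Plate geometry

Wells are addressed `(x, y)` with `x` the 0-based column index running
continuously across the two plates (columns 0–2 are plate 1 and 3–5 plate 2
for 12-well plates) and `y` the row, `(0,0)` top-left — the convention used
by the automation scripts. Plates sit portrait on the holder, so a 12-well
plate presents 3 columns × 4 rows. Pitches default to the ANSI/SLAS
standard: 26.01 mm (12-well), 19.3 mm (24-well), 9.0 mm (96-well); every
constant is per-`PlateFormat` configurable for non-standard labware. The
gap between the two plates' well blocks defaults to 10 mm and plate 2's X
origin is one nominal plate width (`n_cols × pitch`) plus that gap beyond
plate 1's. The default A1 offset (45, 20) mm leaves room on the X axis for
the pipette tip, which rides 30 mm to the left of the camera axis; all
coordinates are validated against the 220 × 220 mm working surface.

The 96-well support is modelled with a single global white channel rather
than per-well RGBW LEDs, matching the physical holder's white back-panel.

## Virtual device

**Stage.** Moves are exact and instantaneous in space; durations are
`distance / axis speed` with defaults of 50 mm/s (XY) and 5 mm/s (Z) —
these affect only the simulated clock, never positions. A positioning
error is drawn once per homing event from per-axis Gaussians with sigmas of
22/11/2 µm (X/Y/Z), the measured end-stop repeatability of the frame; the
residual then rides on every commanded coordinate until the next homing.
Commanded (nominal) and actual poses are tracked separately, as on a real
controller.

**Pump.** A dispense of volume $V$ returns $V(1+\varepsilon)$,
$\varepsilon \sim N(0, 0.035)$ — the characterised 3.5 % relative error of
the 3D-printed peristaltic pump at 1 mL. Flow rate defaults to 0.5 mL/s;
purging pushes one purge volume (1 mL) through the circuit.

**Camera and optics.** Frames are bright-field by convention: dark cells on
a background whose level follows the active LED's luma (ambient 20 gray
levels with all channels off, ~240 under full white). Each cell is an
anti-aliased disk blurred by a Gaussian of sigma

```
sigma(px) = base_blur + blur_scale * |z_cam - (focal_offset - depth)| + depth_penalty * depth
```

with `base_blur` 0.6 px, `blur_scale` 18 px/mm, `depth_penalty` 15 px/mm
and `depth` the cell's distance (mm) below the liquid surface. The depth
penalty makes the global sharpness optimum the height focusing the *top*
liquid layer — the behaviour the instrument is designed around, since algae
distribute through a multi-millimetre column and only the top layer is
imaged reproducibly. Heavily defocused cells also fade
(`0.85 / (1 + 0.02 sigma²)`), so deep cells blend into background rather
than darkening it indefinitely. Gaussian sensor noise (default sd 2 gray
levels) is seeded per frame from the scene seed and frame time, making
whole runs bit-reproducible.

**Photoresponse.** While any trigger channel (blue or white by default) is
lit, cell speed is multiplied by $e^{-t_\text{exposed}/\tau}$ with τ = 60 s.
The value is chosen so motion has decayed by more than 99 % after 300 s,
consistent with cultures arresting within five minutes of white-light
exposure; red light leaves speed untouched. Positions integrate the decay
in closed form, so burst renders at arbitrary times need no stepping.

**Timekeeping.** The device advances a simulated clock — moves, dispenses,
captures, settles and scripted delays cost simulated seconds, nothing
sleeps. A settle delay (default 1 s, configurable) is inserted between
arriving over a well and imaging it, standing in for liquid stabilisation.

## Autofocus

Sharpness is the variance of the 3 × 3 discrete Laplacian on grayscale —
non-negative, zero on a constant image, invariant to illumination offsets.
The theoretical focus derives from the known sample volume: column height =
volume / well area, focus at the column top. Phase 1 starts 0.5 mm above
that and descends ten 0.1 mm steps, scoring each height; phase 2 re-centres
0.05 mm above the coarse argmax and descends ten 0.01 mm steps. The result
is the global argmax over all 20 evaluations; ties resolve to the highest
camera position (top layer preference). Heights are clamped to the stage's
Z range. Phase 2 re-captures at heights coincident with phase 1 — under
noise the two scores legitimately differ. On strictly unimodal profiles
whose peak lies at least one coarse step inside the swept interval, the
procedure lands within one fine step (0.01 mm) of an exhaustive fine-grid
search; the suite verifies this on 100 seeded stacks.

## Cell analysis

Segmentation inverts the usual threshold because cells are darker than the
illuminated background: pixels *below* the gray threshold become
foreground. The threshold defaults to Otsu's method when unset. The
subsequent morphological pass **dilates** the foreground: its purpose is to
connect nearby pixels and close cell outlines, which in standard
morphological vocabulary is dilation (of the foreground) even when
described as "erosion" of the bright background. It defaults to zero
iterations — each pass grows every object by about one kernel radius, so
it is left off when unbiased size measurements matter and enabled when
fragmented outlines need closing.

"Edge detection" is realised as connected-component contour analysis on the
binary mask: the quantities reported (counts, areas, bounding boxes) are
component properties, not edge maps. Components below `min_area` (px²,
default 20) are discarded as debris. Width/height are axis-aligned
bounding-box extents in the image frame, converted to µm; no orientation
fitting is attempted. Mean colour is averaged under the component in the
source image. The annotated output draws component boxes and a tally bar.

Calibration projects the slide image perpendicular to the graduation lines
(a ±8° angle search maximises projection contrast, handling slide
rotation), finds line positions as prominence-gated peaks, and divides the
division spacing by the median adjacent-peak distance. Median spacing makes
the estimate robust to a missed or spurious line. Rescaling multiplies
µm/px by the vertical-resolution ratio; the exact-ratio law is asserted on
synthetic data only, since measured lens pairs deviate from it by lens
distortion and crop differences.

## Motility

The single-cell tracker is pyramidal Lucas–Kanade (3 levels, 25 px window,
12 Gauss–Newton iterations per level) written against
`scipy.ndimage.map_coordinates`. Two gates terminate a track rather than
let it drift: a texture gate (minimum structure-tensor eigenvalue per pixel
≥ 10 in the finest-level window, rejecting featureless background) and a
forward–backward consistency check (re-tracking backwards must return
within 1 px). The window is sized to contain the edge of a
Chlamydomonas-scale cell when seeded at its centre, where the interior is
flat.

Dense flow uses the iterative Lucas–Kanade solver
(`skimage.registration.optical_flow_ilk`), subsampled on a 16 px stride
grid. Speed summaries are taken **only over textured grid points**
(smoothed gradient magnitude ≥ 6 gray/px): where the image is featureless
the LK system is near-singular and its output is noise, which would
otherwise dominate scenes of sparse cells. `mean_speed` averages textured
points; `active_speed` averages their fastest decile, tracking the moving
cells specifically. Speeds convert as px/frame × µm/px × fps. Both
measures are two-dimensional: motion along the optical axis appears as blur
change, not displacement, and is not measured.

## Automation

Scripts are single JSON objects; `volume`, `light` and `delay` broadcast
from singletons or must match `pos` in length. `delay[i]` is the wait
after completing well *i* (the final entry is conventionally 0); `delay`
itself is optional, defaulting to zero. Only the active well's LED is lit
during its turn (avoiding photoresponse contamination of neighbours);
unknown script keys warn, missing required keys raise errors naming the
key. Execution order per well: light → tip move, purge, dispense (if
sampling) → camera move, settle, autofocus, capture (if capture) → delay.
Afterwards the engine switches all LEDs off and parks at the safe position
(camera at the far corner of the working volume, bed advanced). Images are
named `<name>X<x>Y<y>.png` with the raw 0-based indices. Push/email
notification is reduced to an optional callback invoked with the run
report.

The run-time estimator sums per-action durations from a `TimingModel`
(travel from axis speeds and well distances, purge and pump times from the
flow rate, a per-sweep autofocus cost of 20 captures plus expected Z
travel, settle, capture, delays, and the final park move). When its
constants match the simulator's — `TimingModel.from_device` — simulated
elapsed time agrees with the estimate within 10 % for both reference
scripts; the residual comes from autofocus travel varying with the found
height and from home-to-first-well distances.

## Synthetic fixtures: scope and limits

The generators produce calibration slides (dark graduations at exact
spacing, optional rotation), in-focus micrographs of non-overlapping cells
(diameters uniform in 5–12 µm at 0.5 µm/px by default), focus stacks,
constant-speed swimming clips, and photoresponse bursts at chosen exposure
times. Long clips wrap cell positions periodically over the field of view
so density stays constant. Every fixture is bit-reproducible from its seed
and ships a ground-truth sidecar (counts, positions, sizes, speeds, focus
peak).

What the scenes deliberately do not emulate: overlapping and touching
cells, non-circular morphology (*E. gracilis* is spindle-shaped, not a
disk), intensity gradients and vignetting, debris, Brownian jitter,
swimming direction changes within a clip, settling dynamics, and realistic
point-spread functions. Tests passing on these scenes therefore establish
that the *algorithms* are implemented correctly and unbiased under their
stated assumptions (separated dark objects, adequate contrast, 2-D motion);
they do not certify segmentation accuracy on crowded real cultures, where
threshold choice and touching-cell splitting dominate error.

## Problem sizes

The suite and the acceptance script keep simulations small enough for a
single CPU: 320 × 240 px rendered frames (160 × 120 for the 100-stack
autofocus accuracy sweep), 15–30 frame motility clips, 4-frame
photoresponse bursts at two exposure times, 10,000 pump draws, and full
24-well script executions against the virtual device. These sizes hold all
Monte-Carlo checks comfortably inside their tolerances while the whole
suite completes in about a minute.
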