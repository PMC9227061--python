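"""Cell motility from video: point tracking and whole-field optical flow.

Two complementary measurements, both reporting speeds in µm/s given a lens
calibration and the capture frame rate:

* :func:`track_cell` follows a single cell from a user-supplied seed point
  with a pyramidal Lucas–Kanade tracker. A forward–backward consistency
  check (re-tracking the point backwards must land within 1 px of where it
  started) terminates the track when the flow estimate becomes unreliable,
  e.g. when the cell leaves the focal plane.
* :func:`flow_field` estimates dense optical flow between consecutive frames
  (iterative Lucas–Kanade solver), subsamples it on a stride grid and draws
  the classic green-vector overlay; vector length is proportional to speed.

Speeds are two-dimensional: motion along the optical axis shows up as a blur
change, not a displacement, and is not measured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.registration import optical_flow_ilk
from skimage.transform import pyramid_gaussian

from wellstation.cells import Calibration

__all__ = ["Track", "FlowField", "track_cell", "flow_field", "speed_timeseries"]

_LUMA = np.array([0.299, 0.587, 0.114])


def _gray(frame: np.ndarray) -> np.ndarray:
    f = np.asarray(frame)
    if f.ndim == 3:
        f = f[..., :3] @ _LUMA
    return f.astype(np.float64)


@dataclass
class Track:
    """Single-cell trajectory: (t, x, y) samples plus derived speeds."""

    points: list[tuple[float, float, float]]  # (t s, x px, y px)
    mean_speed: float  # µm/s, mean of per-step speeds
    net_speed: float  # µm/s, net displacement / elapsed time
    path_length_um: float
    complete: bool  # False when tracking terminated early
    n_frames_tracked: int

    @property
    def path(self) -> np.ndarray:
        """(n, 2) polyline of (x, y) pixel positions."""
        return np.array([(x, y) for _, x, y in self.points])


@dataclass
class FlowField:
    """Dense flow between one frame pair, subsampled on a stride grid."""

    u: np.ndarray  # px/frame along image x, shape (gh, gw)
    v: np.ndarray  # px/frame along image y
    grid_x: np.ndarray
    grid_y: np.ndarray
    mean_speed: float  # µm/s over the whole grid
    active_speed: float  # µm/s over the fastest decile (the moving cells)
    dominant_direction: float  # radians, atan2 of the mean vector

    @property
    def magnitudes(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


# -- pyramidal Lucas–Kanade point tracker ---------------------------------


def _lk_point(
    img0: np.ndarray,
    img1: np.ndarray,
    pt: np.ndarray,
    guess: np.ndarray,
    win: int,
    n_iter: int = 12,
) -> tuple[np.ndarray, float]:
    """Refine displacement of ``pt`` from img0 to img1 at one pyramid level.

    Returns (displacement, min structure-tensor eigenvalue per pixel).
    """
    half = win // 2
    ys = pt[1] + np.arange(-half, half + 1)
    xs = pt[0] + np.arange(-half, half + 1)
    grid = np.meshgrid(ys, xs, indexing="ij")
    coords = np.stack(grid)  # (2, win, win): row, col

    patch0 = ndimage.map_coordinates(img0, coords, order=1, mode="nearest")
    gy, gx = np.gradient(patch0)
    gxx = (gx * gx).sum()
    gxy = (gx * gy).sum()
    gyy = (gy * gy).sum()
    tr, det = gxx + gyy, gxx * gyy - gxy * gxy
    disc = max(tr * tr / 4.0 - det, 0.0)
    min_eig = (tr / 2.0 - math.sqrt(disc)) / (win * win)
    denom = det
    if denom < 1e-9:
        return guess, min_eig

    d = guess.astype(np.float64).copy()
    for _ in range(n_iter):
        shifted = np.stack([coords[0] + d[1], coords[1] + d[0]])
        patch1 = ndimage.map_coordinates(img1, shifted, order=1, mode="nearest")
        err = patch1 - patch0
        bx = -(gx * err).sum()
        by = -(gy * err).sum()
        dx = (gyy * bx - gxy * by) / denom
        dy = (gxx * by - gxy * bx) / denom
        d += np.array([dx, dy])
        if dx * dx + dy * dy < 1e-6:
            break
    return d, min_eig


def _pyramids(img: np.ndarray, levels: int) -> list[np.ndarray]:
    return list(pyramid_gaussian(img, max_layer=levels - 1, downscale=2, channel_axis=None, preserve_range=True))


def _track_point(
    img0: np.ndarray,
    img1: np.ndarray,
    pt: tuple[float, float],
    win: int = 25,
    levels: int = 3,
    min_texture: float = 10.0,
) -> tuple[np.ndarray, bool]:
    """One frame-to-frame pyramidal LK step with texture gating."""
    pyr0 = _pyramids(img0, levels)
    pyr1 = _pyramids(img1, levels)
    d = np.zeros(2)
    min_eig_fine = 0.0
    for lvl in range(levels - 1, -1, -1):
        scale = 2.0**lvl
        p_lvl = np.asarray(pt) / scale
        d, min_eig = _lk_point(pyr0[lvl], pyr1[lvl], p_lvl, d, win)
        if lvl > 0:
            d = d * 2.0
        else:
            min_eig_fine = min_eig
    ok = min_eig_fine >= min_texture
    return np.asarray(pt) + d, ok


def track_cell(
    frames: list[np.ndarray],
    seed: tuple[float, float],
    cal: Calibration,
    fps: float,
    win: int = 25,
    levels: int = 3,
    fb_threshold: float = 1.0,
    min_texture: float = 10.0,
) -> Track:
    """Track the cell under ``seed`` through ``frames``.

    Tracking stops early (``complete=False``) when the seed sits on
    featureless background, the point drifts out of frame, or the
    forward–backward check exceeds ``fb_threshold`` px.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to track")
    if fps <= 0:
        raise ValueError("fps must be positive")
    grays = [_gray(f) for f in frames]
    h, w = grays[0].shape
    if not (0 <= seed[0] < w and 0 <= seed[1] < h):
        raise ValueError("seed outside frame 0")

    pts: list[tuple[float, float, float]] = [(0.0, float(seed[0]), float(seed[1]))]
    p = np.asarray(seed, dtype=np.float64)
    complete = True
    for i in range(len(grays) - 1):
        p_new, ok = _track_point(grays[i], grays[i + 1], tuple(p), win, levels, min_texture)
        if ok:
            p_back, ok_b = _track_point(grays[i + 1], grays[i], tuple(p_new), win, levels, min_texture)
            ok = ok_b and float(np.hypot(*(p_back - p))) <= fb_threshold
        in_frame = 0 <= p_new[0] < w and 0 <= p_new[1] < h
        if not (ok and in_frame):
            complete = False
            break
        p = p_new
        pts.append(((i + 1) / fps, float(p[0]), float(p[1])))

    xy = np.array([(x, y) for _, x, y in pts])
    if len(xy) > 1:
        steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)  # px/frame
        mean_speed = float(steps.mean() * cal.um_per_px * fps)
        path_um = float(steps.sum() * cal.um_per_px)
        elapsed = pts[-1][0]
        net = float(np.linalg.norm(xy[-1] - xy[0]) * cal.um_per_px / elapsed) if elapsed > 0 else 0.0
    else:
        mean_speed = path_um = net = 0.0
    return Track(
        points=pts,
        mean_speed=mean_speed,
        net_speed=net,
        path_length_um=path_um,
        complete=complete,
        n_frames_tracked=len(pts),
    )


# -- dense flow ------------------------------------------------------------


def _flow_pair(
    g0: np.ndarray,
    g1: np.ndarray,
    cal: Calibration,
    fps: float,
    stride: int,
    texture_threshold: float = 6.0,
) -> FlowField:
    v, u = optical_flow_ilk(g0, g1, radius=9, gaussian=True)
    gy = np.arange(stride // 2, g0.shape[0], stride)
    gx = np.arange(stride // 2, g0.shape[1], stride)
    us = u[np.ix_(gy, gx)]
    vs = v[np.ix_(gy, gx)]
    mags = np.hypot(us, vs)
    # flow is only defined where there is image structure; summarise over
    # textured grid points so featureless background (where the LK system is
    # near-singular and the estimate is noise) does not pollute the speeds
    g0y, g0x = np.gradient(ndimage.gaussian_filter(g0, 1.0))
    grad = np.hypot(g0x, g0y)[np.ix_(gy, gx)]
    textured = grad >= texture_threshold
    sel = mags[textured] if textured.any() else np.array([0.0])
    mean_speed = float(sel.mean() * cal.um_per_px * fps)
    thresh = np.quantile(sel, 0.9)
    active = sel[sel >= thresh]
    active_speed = float(active.mean() * cal.um_per_px * fps) if active.size else 0.0
    if textured.any():
        direction = float(math.atan2(vs[textured].mean(), us[textured].mean()))
    else:
        direction = 0.0
    return FlowField(
        u=us,
        v=vs,
        grid_x=gx,
        grid_y=gy,
        mean_speed=mean_speed,
        active_speed=active_speed,
        dominant_direction=direction,
    )


def _overlay(frame: np.ndarray, ff: FlowField, gain: float = 4.0) -> np.ndarray:
    img = np.asarray(frame)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    img = img.astype(np.uint8).copy()
    h, w = img.shape[:2]
    for iy, y in enumerate(ff.grid_y):
        for ix, x in enumerate(ff.grid_x):
            dx, dy = ff.u[iy, ix] * gain, ff.v[iy, ix] * gain
            x1 = int(np.clip(x + dx, 0, w - 1))
            y1 = int(np.clip(y + dy, 0, h - 1))
            rr, cc = draw_line(int(y), int(x), y1, x1)
            img[rr, cc] = (0, 255, 0)
    return img


def flow_field(
    frames: list[np.ndarray],
    cal: Calibration,
    fps: float,
    stride: int = 16,
    with_overlay: bool = False,
) -> tuple[list[FlowField], list[np.ndarray]]:
    """Dense optical flow for every consecutive frame pair.

    Returns the per-pair :class:`FlowField` list and, when requested, the
    green-vector overlay frames (one per pair, drawn on the earlier frame).
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    grays = [_gray(f) for f in frames]
    fields, overlays = [], []
    for g0, g1, f0 in zip(grays[:-1], grays[1:], frames[:-1]):
        ff = _flow_pair(g0, g1, cal, fps, stride)
        fields.append(ff)
        if with_overlay:
            overlays.append(_overlay(f0, ff, gain=max(1.0, stride / 4)))
    return fields, overlays


def speed_timeseries(
    frames: list[np.ndarray],
    cal: Calibration,
    fps: float,
    window: float,
    stride: int = 16,
) -> list[tuple[float, float]]:
    """Windowed mean whole-field speed (µm/s) over the clip.

    ``window`` is the averaging window in seconds (at least two frame
    intervals). Each output sample is (window-centre time, mean speed).
    """
    if window < 2.0 / fps:
        raise ValueError("window must cover at least two frame intervals")
    fields, _ = flow_field(frames, cal, fps, stride)
    speeds = np.array([f.mean_speed for f in fields])
    times = (np.arange(len(speeds)) + 0.5) / fps
    n_per = max(int(round(window * fps)), 1)
    out = []
    for start in range(0, len(speeds), n_per):
        chunk = speeds[start : start + n_per]
        tchunk = times[start : start + n_per]
        out.append((float(tchunk.mean()), float(chunk.mean())))
    return out
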