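"""Marker-free machine vision for lateral chick-head frames.

Four steps per frame, mirroring the measurement chain used for beak-gape
kinematics on high-speed feeding video: (1) eye detection — the eye is the
darkest compact blob in a lateral view and serves as the head reference
point; (2) head-ROI extraction around the eye to discard the uninformative surround;
(3) feed-particle pixel removal, so particles overlapping the beak tips do
not corrupt tip detection; (4) beak-tip detection on the cleaned silhouette,
giving the gape as the upper-to-lower tip distance.  A ruler image converts
pixels to millimetres.

Eye detection uses intensity thresholding plus a circularity filter rather
than a Hough transform: a two-pass Otsu (the second pass restricted to the
below-global-threshold pixels) isolates the darkest intensity class, and
4*pi*A/P^2 >= c_min keeps compact blobs.  Candidates are ranked by
circularity, then area, then smallest y, so output is deterministic.

Failed frames are flagged and filled by linear interpolation from their
neighbours instead of being dropped, preserving frame-count-based durations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import footprint_rectangle, opening


class DetectionFailure(RuntimeError):
    """A per-frame detector found no acceptable candidate (flagged, not fatal)."""


class TipDetectionFailure(DetectionFailure):
    pass


class CalibrationError(RuntimeError):
    pass


class SequenceRejectedError(RuntimeError):
    """Too large a fraction of frames failed detection."""


@dataclass
class Calibration:
    """Pixel-to-millimetre scale."""

    mm_per_px: float

    def __post_init__(self) -> None:
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")


@dataclass
class VisionParams:
    """Tunable detector parameters.

    ``eye_radius_px`` is the expected eye radius and sets the defaults that
    scale with head size: the candidate area band (0.4..2.5 of the disc area)
    and the ROI extent (6 eye radii back/up/down, 14 toward the beak — the
    ROI must contain the whole beak).  ``particle_band`` is the gray-level
    interval excised as feed-particle pixels; ``particle_kernel`` <= 1 skips
    the morphological opening (an opening blunts the thin beak-tip taper, so
    it is reserved for messy scenes).
    """

    beak_facing: str = "right"
    eye_radius_px: float = 9.0
    eye_threshold: float | None = None  # None -> two-pass Otsu
    area_min: float | None = None
    area_max: float | None = None
    c_min: float = 0.7
    roi_forward: float | None = None
    roi_back: float | None = None
    roi_up: float | None = None
    roi_down: float | None = None
    remove_particles: bool = True
    particle_band: tuple[float, float] = (60.0, 120.0)
    particle_kernel: int = 1
    tip_min_offset: float | None = None
    tip_depth: int = 3
    tip_row_gap: int = 3
    max_fail_fraction: float = 0.2

    def resolved(self) -> "VisionParams":
        r = self.eye_radius_px
        out = VisionParams(**self.__dict__)
        if out.area_min is None:
            out.area_min = 0.4 * np.pi * r * r
        if out.area_max is None:
            out.area_max = 2.5 * np.pi * r * r
        if out.roi_forward is None:
            out.roi_forward = 14.0 * r
        for name in ("roi_back", "roi_up", "roi_down"):
            if getattr(out, name) is None:
                setattr(out, name, 6.0 * r)
        if out.tip_min_offset is None:
            out.tip_min_offset = 3.0 * r
        return out


@dataclass
class HeadTrack:
    """Per-frame detected head geometry for one sequence."""

    eye: np.ndarray  # (T, 2) px, (x, y)
    upper_tip: np.ndarray  # (T, 2)
    lower_tip: np.ndarray  # (T, 2)
    flag: np.ndarray  # (T,) bool, True where detection failed and was filled
    mm_per_px: float

    @property
    def gape_px(self) -> np.ndarray:
        d = self.upper_tip - self.lower_tip
        return np.hypot(d[:, 0], d[:, 1])

    @property
    def gape_mm(self) -> np.ndarray:
        return self.gape_px * self.mm_per_px

    def __len__(self) -> int:
        return int(self.eye.shape[0])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self)),
                "eye_x": self.eye[:, 0],
                "eye_y": self.eye[:, 1],
                "up_x": self.upper_tip[:, 0],
                "up_y": self.upper_tip[:, 1],
                "lo_x": self.lower_tip[:, 0],
                "lo_y": self.lower_tip[:, 1],
                "gape_px": self.gape_px,
                "gape_mm": self.gape_mm,
                "flag": self.flag.astype(int),
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, mm_per_px: float) -> "HeadTrack":
        return cls(
            eye=df[["eye_x", "eye_y"]].to_numpy(float),
            upper_tip=df[["up_x", "up_y"]].to_numpy(float),
            lower_tip=df[["lo_x", "lo_y"]].to_numpy(float),
            flag=df["flag"].to_numpy().astype(bool),
            mm_per_px=mm_per_px,
        )


# ---------------------------------------------------------------------------
# Calibration


def _tick_spacing(profile: np.ndarray) -> tuple[int, float]:
    """Count of dark peaks and their median spacing along one axis."""
    inv = profile.max() - profile.astype(float)
    if inv.max() < 60:  # no resolvable dark ticks
        return 0, np.nan
    peaks, _ = find_peaks(inv, prominence=60)
    if peaks.size < 3:
        return int(peaks.size), np.nan
    return int(peaks.size), float(np.median(np.diff(peaks)))


def calibrate_from_ruler(image: np.ndarray, tick_spacing_mm: float) -> Calibration:
    """Estimate mm/px from a ruler image with equally spaced dark ticks.

    The tick axis is chosen automatically (the axis showing more dark peaks);
    spacing is the median inter-peak distance.  Fewer than three resolvable
    ticks raises :class:`CalibrationError`.
    """
    if tick_spacing_mm <= 0:
        raise ValueError("tick_spacing_mm must be positive")
    img = np.asarray(image)
    nx, sx = _tick_spacing(img.min(axis=0))
    ny, sy = _tick_spacing(img.min(axis=1))
    n, s = (nx, sx) if nx >= ny else (ny, sy)
    if n < 3 or not np.isfinite(s) or s <= 0:
        raise CalibrationError(f"found only {n} ruler ticks; need >= 3")
    return Calibration(mm_per_px=tick_spacing_mm / s)


# ---------------------------------------------------------------------------
# Per-frame detectors


def _eye_threshold(frame: np.ndarray) -> float:
    """Two-pass Otsu: isolate the darkest intensity class (the eye).

    Thresholds follow the darker-at-or-below convention (Otsu values sit on
    the upper edge of the dark class for discrete histograms).
    """
    try:
        t1 = threshold_otsu(frame)
    except ValueError:
        return -np.inf
    dark = frame[frame <= t1]
    if dark.size < 16 or np.ptp(dark) == 0:
        return float(t1)
    return float(threshold_otsu(dark))


def detect_eye(frame: np.ndarray, params: VisionParams | None = None) -> tuple[float, float]:
    """Centroid (x, y) of the best eye candidate in a single-channel frame.

    Candidates are connected components below the eye threshold, filtered by
    area and circularity, scored by circularity (ties: larger area, then
    smaller y).  Raises :class:`DetectionFailure` when nothing qualifies.
    """
    p = (params or VisionParams()).resolved()
    if frame.ndim != 2:
        raise ValueError("frame must be single-channel")
    thr = p.eye_threshold if p.eye_threshold is not None else _eye_threshold(frame)
    mask = frame <= thr
    if not mask.any():
        raise DetectionFailure("no below-threshold pixels")
    best = None
    for rp in regionprops(label(mask)):
        if not (p.area_min <= rp.area <= p.area_max):
            continue
        if rp.perimeter <= 0:
            continue
        circ = 4.0 * np.pi * rp.area / (rp.perimeter**2)
        if circ < p.c_min:
            continue
        cy, cx = rp.centroid
        key = (circ, rp.area, -cy)
        if best is None or key > best[0]:
            best = (key, (float(cx), float(cy)))
    if best is None:
        raise DetectionFailure("no candidate passed area/circularity filters")
    return best[1]


def extract_head_roi(
    frame: np.ndarray, eye_center: tuple[float, float], params: VisionParams | None = None
) -> tuple[np.ndarray, tuple[int, int]]:
    """Rectangular head window anchored at the eye, clipped to frame bounds.

    Returns (roi, (ox, oy)); ROI pixel (x, y) maps back to frame (x+ox, y+oy).
    """
    p = (params or VisionParams()).resolved()
    H, W = frame.shape
    ex, ey = eye_center
    if not (0 <= ex < W and 0 <= ey < H):
        raise ValueError("eye_center outside frame")
    fwd, back = p.roi_forward, p.roi_back
    dx_lo, dx_hi = (back, fwd) if p.beak_facing == "right" else (fwd, back)
    x0 = max(int(np.floor(ex - dx_lo)), 0)
    x1 = min(int(np.ceil(ex + dx_hi)) + 1, W)
    y0 = max(int(np.floor(ey - p.roi_up)), 0)
    y1 = min(int(np.ceil(ey + p.roi_down)) + 1, H)
    return frame[y0:y1, x0:x1], (x0, y0)


def remove_particle_pixels(
    roi: np.ndarray,
    eye_center_roi: tuple[float, float],
    params: VisionParams | None = None,
) -> tuple[np.ndarray, bool]:
    """Binary head/beak mask with feed-particle pixels excised.

    Foreground is the below-Otsu (darker-than-background) region; components
    not 4-connected to the component containing the eye are dropped; pixels in
    the particle intensity band are excised and, for particle_kernel >= 2, the
    mask is morphologically opened.  Returns (mask, warning): warning is True
    when no foreground/eye component was found, in which case the thresholded
    mask passes through unmodified (empty for an all-background ROI).
    """
    p = (params or VisionParams()).resolved()
    if roi.ndim != 2:
        raise ValueError("roi must be single-channel")
    if np.ptp(roi) == 0:
        return np.zeros(roi.shape, bool), True
    fg = roi <= threshold_otsu(roi)
    if not fg.any():
        return fg, True
    lbl = label(fg, connectivity=1)
    ex = int(round(eye_center_roi[0]))
    ey = int(round(eye_center_roi[1]))
    if not (0 <= ex < roi.shape[1] and 0 <= ey < roi.shape[0]) or lbl[ey, ex] == 0:
        return fg, True
    mask = lbl == lbl[ey, ex]
    if p.remove_particles:
        lo, hi = p.particle_band
        mask &= ~((roi >= lo) & (roi <= hi))
        if p.particle_kernel >= 2:
            mask = opening(
                mask, footprint_rectangle((p.particle_kernel, p.particle_kernel))
            )
    return mask, False


def detect_beak_tips(
    mask: np.ndarray,
    eye_center: tuple[float, float],
    beak_facing: str = "right",
    params: VisionParams | None = None,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Most distal silhouette points of the upper and lower beak lobes.

    Looks at foreground pixels on the beak side of the eye (at least
    tip_min_offset px beyond it), keeps those within tip_depth px of the
    maximal extent, and splits them into lobes by row gaps; each lobe's tip is
    its most distal pixel.  A closed beak yields one lobe, whose single distal
    point is returned for both tips.  upper.y <= lower.y always holds.
    """
    p = (params or VisionParams()).resolved()
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        raise TipDetectionFailure("empty mask")
    ex = eye_center[0]
    if beak_facing == "right":
        d = xs.astype(float)
        sel = xs >= ex + p.tip_min_offset
    else:
        d = -xs.astype(float)
        sel = xs <= ex - p.tip_min_offset
    if not sel.any():
        raise TipDetectionFailure("no foreground beyond the eye on the beak side")
    dd, yy, xx = d[sel], ys[sel], xs[sel]
    distal = dd >= dd.max() - p.tip_depth
    yy, xx, dd = yy[distal], xx[distal], dd[distal]
    rows = np.unique(yy)
    splits = np.nonzero(np.diff(rows) >= p.tip_row_gap)[0]
    groups = np.split(rows, splits + 1)

    def lobe_tip(rows_in: np.ndarray, pick_upper: bool) -> tuple[float, float]:
        m = np.isin(yy, rows_in)
        dmax = dd[m].max()
        at = m & (dd == dmax)
        cand_y = yy[at]
        y = cand_y.min() if pick_upper else cand_y.max()
        x = xx[at][cand_y == y][0]
        return float(x), float(y)

    if len(groups) == 1:
        tip = lobe_tip(groups[0], pick_upper=True)
        return tip, tip
    up = lobe_tip(groups[0], pick_upper=True)
    lo = lobe_tip(groups[-1], pick_upper=False)
    return up, lo


# ---------------------------------------------------------------------------
# Sequence tracking


def _interp_nan(a: np.ndarray) -> np.ndarray:
    """Linear interpolation over NaNs, nearest-value extension at the edges."""
    out = a.copy()
    bad = np.isnan(out)
    if bad.any() and not bad.all():
        idx = np.arange(a.size)
        out[bad] = np.interp(idx[bad], idx[~bad], out[~bad])
    return out


def track_sequence(
    frames: np.ndarray,
    calibration: Calibration,
    params: VisionParams | None = None,
) -> HeadTrack:
    """Run the four-step detector over a frame stack.

    Frames where any step fails are flagged and filled by linear interpolation
    from neighbouring detections; if more than ``max_fail_fraction`` of frames
    fail, the whole sequence is rejected.
    """
    p = (params or VisionParams()).resolved()
    frames = np.asarray(frames)
    T = frames.shape[0]
    if T < 2:
        raise ValueError("need at least two frames")
    eye = np.full((T, 2), np.nan)
    up = np.full((T, 2), np.nan)
    lo = np.full((T, 2), np.nan)
    flag = np.zeros(T, bool)
    for t in range(T):
        try:
            e = detect_eye(frames[t], p)
            roi, (ox, oy) = extract_head_roi(frames[t], e, p)
            mask, warn = remove_particle_pixels(roi, (e[0] - ox, e[1] - oy), p)
            (ux, uy), (lx, ly) = detect_beak_tips(
                mask, (e[0] - ox, e[1] - oy), p.beak_facing, p
            )
            eye[t] = e
            up[t] = (ux + ox, uy + oy)
            lo[t] = (lx + ox, ly + oy)
        except DetectionFailure:
            flag[t] = True
    n_fail = int(flag.sum())
    if n_fail > p.max_fail_fraction * T:
        raise SequenceRejectedError(
            f"{n_fail}/{T} frames failed detection "
            f"(limit {p.max_fail_fraction:.0%})"
        )
    if n_fail == T:
        raise SequenceRejectedError("every frame failed detection")
    for arr in (eye, up, lo):
        arr[:, 0] = _interp_nan(arr[:, 0])
        arr[:, 1] = _interp_nan(arr[:, 1])
    return HeadTrack(
        eye=eye, upper_tip=up, lower_tip=lo, flag=flag, mm_per_px=calibration.mm_per_px
    )
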