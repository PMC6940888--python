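"""Mandibulation segmentation, ordering, and kinematic variables.

A *mandibulation* is one cycle of beak opening and closing during the
stationing, transport, or swallowing phase of a feeding sequence: the gape
rises from a (non-zero) minimum to the maximum beak gape and closes again.
The beak never shuts fully at either end of a cycle, so cycle boundaries
sit at gape minima, never at zero.

Four variables are computed per mandibulation: maximum beak gape (mm), head
displacement (mm, the eye's cumulative 2-D path length over the cycle; the
net start-to-end distance is also emitted), time (ms, from the frame count at
the known frame rate), and average head speed (mm/s, displacement divided by
time).  Mandibulations are numbered in temporal order within each feeding
sequence — 1, 2, 3, and 4 for the fourth and every later one — starting right
after the withdrawal phase.  Catch-and-throw repositioning movements are
flagged from annotations when supplied; otherwise a labelled convenience
heuristic flags cycles whose gape and displacement both exceed their
episode's medians (catch-and-throw shows augmented head and beak movement).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .vision import Calibration, HeadTrack

__all__ = [
    "SegmentationParams",
    "WithdrawalParams",
    "MandibulationRecord",
    "segment_mandibulations",
    "assign_orders",
    "detect_withdrawals",
    "compute_kinematics",
    "flag_catch_and_throw",
    "records_to_dataframe",
]

RECORD_COLUMNS = [
    "bird_id",
    "feed_type",
    "sequence_id",
    "order",
    "start",
    "end",
    "peak_frame",
    "max_gape_mm",
    "displacement_mm",
    "net_displacement_mm",
    "duration_ms",
    "speed_mm_s",
    "catch_and_throw",
]


@dataclass
class SegmentationParams:
    """Gape-cycle segmentation knobs.

    Smoothing and peak criteria are sized for chick-scale gapes (cycle maxima
    of 2–4 mm over tens of frames at 250 fps): a 3-frame moving average, a
    0.3 mm peak prominence, a 4-frame minimum peak separation, and a 1.0 mm
    minimum peak height (near-closed rest plateaus between feeding sequences
    stay well below it).  ``boundary_tol_mm`` widens the boundary search: a
    cycle's end is the earliest frame within that tolerance of the inter-peak
    raw-gape minimum, its start the latest such frame, so flat valleys attach
    to neither cycle and ties resolve deterministically.
    """

    window: int = 3
    prominence_mm: float = 0.3
    min_separation: int = 4
    min_peak_mm: float = 1.0
    boundary_tol_mm: float = 0.15


@dataclass
class WithdrawalParams:
    """Withdrawal (upward head excursion) detection knobs, in mm/frames."""

    min_rise_mm: float = 2.0
    max_frames: int = 50
    min_approach_mm: float = 1.0
    hysteresis_mm: float = 1.0
    min_gap_frames: int = 30  # two feeding sequences cannot start closer


@dataclass
class MandibulationRecord:
    """One beak open–close cycle with its kinematic variables."""

    bird_id: str
    feed_type: str
    sequence_id: int  # feeding-sequence (episode) index within the recording
    order: int  # 1, 2, 3; 4 = fourth and further
    start: int
    end: int  # half-open frame interval
    peak_frame: int
    max_gape_mm: float
    displacement_mm: float
    net_displacement_mm: float
    duration_ms: float
    speed_mm_s: float
    catch_and_throw: bool = False


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    pad = window // 2
    xp = np.pad(x.astype(float), pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(xp, kernel, mode="valid")[: x.size]


def segment_mandibulations(
    gape_mm: np.ndarray, params: SegmentationParams | None = None
) -> list[tuple[int, int, int]]:
    """Split a per-frame gape series into open–close cycles.

    Peaks are found on the smoothed series (prominence, separation, and
    minimum height filters); each cycle spans from the gape minimum before
    its peak to the minimum after it, half-open, with boundaries at minima
    rather than zero gape.  The reported peak frame is the argmax of the raw
    (unsmoothed) gape within the interval.  Returns (start, end, peak_frame)
    triples; an empty list when no complete cycle exists.
    """
    p = params or SegmentationParams()
    g = np.asarray(gape_mm, float)
    if g.size < 5:
        raise ValueError("gape series must have at least 5 frames")
    sm = _moving_average(g, p.window)
    peaks, _ = find_peaks(
        sm,
        prominence=p.prominence_mm,
        distance=p.min_separation,
        height=p.min_peak_mm,
    )
    if peaks.size == 0:
        return []

    def boundary(lo: int, hi: int, latest: bool) -> int:
        """Frame of the valley minimum in (lo, hi); earliest qualifying frame
        for cycle ends, latest for cycle starts."""
        window = g[lo + 1 : hi]
        vmin = window.min()
        ok = np.nonzero(window <= vmin + p.boundary_tol_mm)[0]
        pick = ok[-1] if latest else ok[0]
        return lo + 1 + int(pick)

    intervals = []
    for i, pk in enumerate(peaks):
        left = int(peaks[i - 1]) if i > 0 else -1
        right = int(peaks[i + 1]) if i < peaks.size - 1 else g.size
        start = boundary(left, pk, latest=True)
        end = boundary(pk, right, latest=False)
        peak_frame = start + int(np.argmax(g[start:end]))
        intervals.append((start, end, peak_frame))
    return intervals


def detect_withdrawals(
    eye_track_mm: np.ndarray, params: WithdrawalParams | None = None
) -> list[int]:
    """Feeding-sequence boundary frames from the vertical eye trajectory.

    y grows downward, so a withdrawal is a drop in y (the head rises) of at
    least ``min_rise_mm`` completed within ``max_frames``, preceded by a
    downward approach excursion of at least ``min_approach_mm``.  The
    boundary opens where the upward excursion ends (mandibulations start
    right after the withdrawal).  Zero boundaries means the whole recording
    is one episode.  Annotation files, when available, override this
    heuristic entirely (see :func:`assign_orders`).
    """
    p = params or WithdrawalParams()
    y = np.asarray(eye_track_mm, float)
    if y.ndim == 2:
        y = y[:, 1]
    # zig-zag pivots with amplitude hysteresis
    extrema: list[tuple[int, float, int]] = []  # (frame, value, +1 max / -1 min)
    direction = 0
    max_i, max_v = 0, y[0]
    min_i, min_v = 0, y[0]
    for i in range(1, y.size):
        v = y[i]
        if v > max_v:
            max_i, max_v = i, v
        if v < min_v:
            min_i, min_v = i, v
        if direction >= 0 and max_v - v >= p.hysteresis_mm:
            extrema.append((max_i, max_v, +1))
            direction, min_i, min_v = -1, i, v
        elif direction <= 0 and v - min_v >= p.hysteresis_mm:
            extrema.append((min_i, min_v, -1))
            direction, max_i, max_v = +1, i, v
    extrema.append((max_i, max_v, +1) if direction >= 0 else (min_i, min_v, -1))

    boundaries: list[int] = []
    prev_min_v = y[0]
    slope_eps = p.hysteresis_mm / 4.0
    for k, (fi, vi, kind) in enumerate(extrema):
        if kind == +1:  # local maximum: head at its lowest (approach endpoint)
            lo = fi + 1
            hi = min(fi + p.max_frames + 1, y.size)
            if lo >= hi:
                continue
            rise = vi - float(y[lo:hi].min())
            approach = vi - prev_min_v
            if rise >= p.min_rise_mm and approach >= p.min_approach_mm:
                # withdrawal end: where the steep upward excursion flattens
                j = lo
                while j + 1 < hi and y[j + 1] - y[j] <= -slope_eps:
                    j += 1
                if not boundaries or j - boundaries[-1] >= p.min_gap_frames:
                    boundaries.append(j)
        else:
            prev_min_v = vi
    return boundaries


def compute_kinematics(
    interval: tuple[int, int, int],
    head_track: HeadTrack,
    calibration: Calibration,
    fps: float,
    *,
    bird_id: str = "",
    feed_type: str = "",
    sequence_id: int = 0,
    order: int = 0,
) -> MandibulationRecord:
    """Kinematic variables for one segmented cycle.

    duration = n_frames * 1000/fps (time comes from the total frame count);
    displacement = eye path length over the interval's n_frames frame
    periods (the final step, into the frame that starts the next cycle, is
    clamped at the series end); speed = displacement / time.
    """
    start, end, peak_frame = interval
    if fps <= 0:
        raise ValueError("fps must be positive")
    T = len(head_track)
    if end - start < 2:
        raise ValueError("interval must span at least 2 frames")
    if not (0 <= start < end <= T):
        raise ValueError("interval outside the tracked sequence")
    gape = head_track.gape_mm
    eye_mm = head_track.eye * calibration.mm_per_px
    idx_from = np.arange(start, end)
    idx_to = np.minimum(idx_from + 1, T - 1)
    steps = eye_mm[idx_to] - eye_mm[idx_from]
    displacement = float(np.sum(np.hypot(steps[:, 0], steps[:, 1])))
    net = float(np.hypot(*(eye_mm[min(end, T - 1)] - eye_mm[start])))
    duration_ms = (end - start) * 1000.0 / fps
    return MandibulationRecord(
        bird_id=bird_id,
        feed_type=feed_type,
        sequence_id=sequence_id,
        order=order,
        start=start,
        end=end,
        peak_frame=peak_frame,
        max_gape_mm=float(np.max(gape[start:end])),
        displacement_mm=displacement,
        net_displacement_mm=net,
        duration_ms=duration_ms,
        speed_mm_s=displacement / (duration_ms / 1000.0),
        catch_and_throw=False,
    )


def assign_orders(
    intervals: list[tuple[int, int, int]],
    sequence_boundaries: list[int],
    n_frames: int | None = None,
) -> list[list[tuple[int, tuple[int, int, int]]]]:
    """Group cycles into feeding sequences and number them temporally.

    ``sequence_boundaries`` are sorted episode start frames (from annotations
    or :func:`detect_withdrawals`); within each episode, cycles are numbered
    1, 2, 3 and then 4 for the fourth and all further mandibulations.  A
    cycle belongs to the episode containing its peak frame (intervals that
    straddle a boundary therefore follow their peak).  Returns one list of
    (order, interval) pairs per episode, episodes in temporal order.
    """
    if not intervals:
        return []
    bounds = sorted(int(b) for b in sequence_boundaries)
    if not bounds or bounds[0] > 0:
        bounds = [0] + bounds
    episodes: list[list[tuple[int, int, int]]] = [[] for _ in bounds]
    for iv in sorted(intervals, key=lambda iv: iv[0]):
        peak = iv[2]
        k = int(np.searchsorted(bounds, peak, side="right")) - 1
        episodes[k].append(iv)
    out = []
    for eps in episodes:
        if not eps:
            continue
        out.append([(min(i + 1, 4), iv) for i, iv in enumerate(eps)])
    return out


def flag_catch_and_throw(
    records: list[MandibulationRecord],
    annotations: dict[tuple[str, int, int], bool] | None = None,
) -> list[MandibulationRecord]:
    """Set catch-and-throw flags, in place, and return the records.

    With annotations — a mapping (bird_id, sequence_id, order-position index
    within the episode) -> bool — flags are copied verbatim, and a record
    without a matching key is a hard error.  Without annotations, a labelled
    heuristic flags records whose max gape AND displacement both strictly
    exceed their episode medians (a single-record episode can never exceed
    its own median, hence is never flagged).
    """
    if annotations is not None:
        by_episode: dict[tuple[str, int], int] = {}
        for r in records:
            key_ep = (r.bird_id, r.sequence_id)
            ordinal = by_episode.get(key_ep, 0)
            by_episode[key_ep] = ordinal + 1
            key = (r.bird_id, r.sequence_id, ordinal)
            if key not in annotations:
                raise KeyError(f"no catch-and-throw annotation for record {key}")
            r.catch_and_throw = bool(annotations[key])
        return records
    groups: dict[tuple[str, int], list[MandibulationRecord]] = {}
    for r in records:
        groups.setdefault((r.bird_id, r.sequence_id), []).append(r)
    for grp in groups.values():
        med_g = float(np.median([r.max_gape_mm for r in grp]))
        med_d = float(np.median([r.displacement_mm for r in grp]))
        for r in grp:
            r.catch_and_throw = r.max_gape_mm > med_g and r.displacement_mm > med_d
    return records


def records_to_dataframe(records: list[MandibulationRecord]) -> pd.DataFrame:
    """Tidy records table (one row per mandibulation)."""
    rows = [
        {
            "bird_id": r.bird_id,
            "feed_type": r.feed_type,
            "sequence_id": r.sequence_id,
            "order": r.order,
            "start": r.start,
            "end": r.end,
            "peak_frame": r.peak_frame,
            "max_gape_mm": r.max_gape_mm,
            "displacement_mm": r.displacement_mm,
            "net_displacement_mm": r.net_displacement_mm,
            "duration_ms": r.duration_ms,
            "speed_mm_s": r.speed_mm_s,
            "catch_and_throw": r.catch_and_throw,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)
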