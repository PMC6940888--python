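"""Synthetic lateral-view feeding scenes with exact ground truth.

Young broiler chicks feeding from a trough are conventionally filmed with a
high-speed camera from a lateral-perpendicular viewpoint (here emulated at
250 fps).  A feeding sequence consists of an approach (head moves down toward
the feed), a grasp, a withdrawal (head moves up), and then a run of
*mandibulations* — beak open/close cycles during stationing, transport and
swallowing — until the bird starts the next sequence.

This module renders grayscale frame stacks of such scenes: a filled-ellipse
head silhouette, a dark circular eye, two beak wedges hinged at a vertex whose
tip-to-tip distance (the gape) follows a scripted cycle profile, feed
particles near the beak, and additive Gaussian imaging noise.  Only the eye
centre, the two beak tips, and the gape are metrically exact; the rest of the
head is scenery.  Ground truth (recorded before noise is added) carries the
exact scripted geometry per frame and one true kinematic record per
mandibulation, so the vision and kinematics stages can be validated by
parameter recovery without any recorded video.

Conventions: pixel coordinates are 0-based with x rightward and y downward;
points are (x, y); all frame intervals are half-open [start, end).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
from skimage import draw as skdraw

__all__ = [
    "SceneConfig",
    "MandibulationSpec",
    "EpisodeSpec",
    "KinematicScript",
    "TrueMandibulation",
    "GroundTruth",
    "FrameSequence",
    "GeometryError",
    "render_sequence",
    "render_ruler",
    "make_episode",
    "make_script",
]


class GeometryError(ValueError):
    """Scripted geometry leaves the frame (message names the offending frame)."""


# Gape floor profile (mm) used at cycle boundaries and between feeding
# sequences: the beak never shuts fully at either end of a cycle.  Cycles
# start at GAPE_START, close down to GAPE_END,
# and between sequences the beak sits nearly closed at GAPE_REST.
GAPE_START = 0.25
GAPE_END = 0.9
GAPE_REST = 0.8


@dataclass
class SceneConfig:
    """Rendering parameters for a synthetic feeding scene.

    The default 384x256 px frame at 0.1 mm/px is a quarter-scale stand-in for
    a 1536x1024 px recording; fps defaults to 250 frames/s.  Gray levels are
    8-bit intensities chosen pairwise separable (>= 20 units) so that simple
    thresholding is meaningful: background is bright, head silhouette mid,
    feed particles darker, eye darkest.
    """

    image_width: int = 384
    image_height: int = 256
    fps: float = 250.0
    mm_per_px: float = 0.1
    background_gray: int = 220
    head_gray: int = 150
    eye_gray: int = 30
    particle_gray: int = 90
    eye_radius: int = 9
    beak_length: int = 46
    beak_facing: str = "right"
    noise_sd: float = 3.0
    particle_count: int = 3
    particle_radius_px: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.image_width <= 0 or self.image_height <= 0:
            raise ValueError("image dimensions must be positive")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")
        if self.eye_gray >= self.head_gray:
            raise ValueError("eye must be darker than the head")
        if self.beak_facing not in ("left", "right"):
            raise ValueError("beak_facing must be 'left' or 'right'")
        if self.noise_sd < 0 or self.particle_count < 0:
            raise ValueError("noise_sd and particle_count must be >= 0")
        if self.eye_radius < 2 or self.beak_length < 4 * self.eye_radius // 2:
            raise ValueError("eye_radius/beak_length too small to render")

    def gray_separation(self) -> int:
        """Smallest pairwise gray-level distance among the four classes."""
        g = sorted(
            [self.background_gray, self.head_gray, self.eye_gray, self.particle_gray]
        )
        return int(min(b - a for a, b in zip(g, g[1:])))


@dataclass
class MandibulationSpec:
    """One scripted beak open/close cycle.

    ``head_steps_mm`` holds the per-frame head displacement (dx, dy) in mm for
    each of the cycle's n_frames frame periods; the last step carries the head
    into the first frame of whatever follows the cycle.
    """

    order: int
    n_frames: int
    peak_gape_mm: float
    head_steps_mm: np.ndarray  # (n_frames, 2)
    catch_and_throw: bool = False
    start_gape_mm: float = GAPE_START
    end_gape_mm: float = GAPE_END
    peak_index: int | None = None  # defaults to n_frames // 2

    def validate(self) -> None:
        if self.n_frames < 3:
            raise ValueError("mandibulation needs >= 3 frames")
        if not 1 <= self.order <= 4:
            raise ValueError("order must be in 1..4")
        if self.start_gape_mm <= 0 or self.end_gape_mm <= 0:
            raise ValueError("boundary gape must stay > 0 (beak never fully closed)")
        if self.peak_gape_mm <= max(self.start_gape_mm, self.end_gape_mm):
            raise ValueError("peak gape must exceed both boundary gapes")
        k = self.n_frames // 2 if self.peak_index is None else self.peak_index
        if not 0 < k < self.n_frames - 1:
            raise ValueError("peak must be interior to the cycle")
        steps = np.asarray(self.head_steps_mm, float)
        if steps.shape != (self.n_frames, 2):
            raise ValueError("head_steps_mm must have shape (n_frames, 2)")

    def gape_profile(self) -> np.ndarray:
        """Unimodal gape trajectory (mm): rises to the peak, then falls.

        The first rise step is at least ~0.5 mm so the cycle's opening frame
        is a sharp minimum even under pixel quantisation of the tip
        positions (a beak opening is fast relative to the frame period).
        """
        k = self.n_frames // 2 if self.peak_index is None else self.peak_index
        first = min(
            self.start_gape_mm + 0.5, (self.start_gape_mm + self.peak_gape_mm) / 2.0
        )
        up = np.concatenate([[self.start_gape_mm], np.linspace(first, self.peak_gape_mm, k)])
        down = np.linspace(self.peak_gape_mm, self.end_gape_mm, self.n_frames - k)[1:]
        return np.concatenate([up, down])


@dataclass
class EpisodeSpec:
    """One feeding sequence: approach (head down), withdrawal (head up),
    then the mandibulation run."""

    mandibulations: list[MandibulationSpec]
    approach_frames: int = 10
    approach_drop_mm: float = 5.0
    withdrawal_frames: int = 12
    withdrawal_rise_mm: float = 5.0
    drift_mm_per_frame: tuple[float, float] = (0.0, 0.0)

    def validate(self) -> None:
        if self.approach_frames < 2 or self.withdrawal_frames < 2:
            raise ValueError("approach/withdrawal need >= 2 frames each")
        if not self.mandibulations:
            raise ValueError("episode needs at least one mandibulation")
        for m in self.mandibulations:
            m.validate()

    @property
    def prefix_frames(self) -> int:
        return self.approach_frames + self.withdrawal_frames


@dataclass
class KinematicScript:
    """Full scripted recording: one or more episodes plus a short settle tail.

    ``start_hinge_px`` places the beak hinge in the first frame; when None the
    renderer centres the head with room for the scripted motion.
    """

    episodes: list[EpisodeSpec]
    tail_frames: int = 6
    start_hinge_px: tuple[float, float] | None = None

    def validate(self) -> None:
        if not self.episodes:
            raise ValueError("script needs at least one episode")
        if self.tail_frames < 3:
            raise ValueError("tail_frames must be >= 3")
        for ep in self.episodes:
            ep.validate()

    @property
    def n_frames(self) -> int:
        n = self.tail_frames
        for ep in self.episodes:
            n += ep.prefix_frames + sum(m.n_frames for m in ep.mandibulations)
        return n


@dataclass
class TrueMandibulation:
    """Ground-truth kinematic record for one scripted cycle."""

    order: int
    start: int
    end: int  # half-open
    peak_frame: int
    max_gape_mm: float
    displacement_mm: float
    net_displacement_mm: float
    duration_ms: float
    speed_mm_s: float
    catch_and_throw: bool
    episode: int = 0

    @property
    def n_frames(self) -> int:
        return self.end - self.start


@dataclass
class GroundTruth:
    """Exact pre-noise scene geometry, per frame and per mandibulation."""

    eye_center: np.ndarray  # (T, 2) px, (x, y)
    upper_tip: np.ndarray  # (T, 2) px
    lower_tip: np.ndarray  # (T, 2) px
    gape_mm: np.ndarray  # (T,)
    mandibulations: list[TrueMandibulation]
    episode_starts: list[int]  # first mandibulation frame of each episode
    fps: float
    mm_per_px: float

    def to_json(self) -> str:
        d = {
            "fps": self.fps,
            "mm_per_px": self.mm_per_px,
            "eye_center": self.eye_center.tolist(),
            "upper_tip": self.upper_tip.tolist(),
            "lower_tip": self.lower_tip.tolist(),
            "gape_mm": self.gape_mm.tolist(),
            "episode_starts": list(self.episode_starts),
            "mandibulations": [dataclasses.asdict(m) for m in self.mandibulations],
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            eye_center=np.asarray(d["eye_center"], float),
            upper_tip=np.asarray(d["upper_tip"], float),
            lower_tip=np.asarray(d["lower_tip"], float),
            gape_mm=np.asarray(d["gape_mm"], float),
            mandibulations=[TrueMandibulation(**m) for m in d["mandibulations"]],
            episode_starts=[int(b) for b in d["episode_starts"]],
            fps=float(d["fps"]),
            mm_per_px=float(d["mm_per_px"]),
        )


@dataclass
class FrameSequence:
    """Ordered grayscale frames with acquisition metadata."""

    frames: np.ndarray  # (T, H, W) uint8
    fps: float
    bird_id: str = ""
    feed_type: str = ""

    def __len__(self) -> int:
        return int(self.frames.shape[0])


# ---------------------------------------------------------------------------
# Script expansion


def _gap_gape_profile(n: int) -> np.ndarray:
    """Near-closed gape (mm) across an inter-sequence gap of n frames.

    Opens the gap at a strict minimum (so the preceding cycle's closure has an
    unambiguous end), ramps to a low rest plateau, and holds; the following
    cycle then starts at its own strict minimum.
    """
    prof = np.full(n, GAPE_REST)
    prof[0] = GAPE_START - 0.05
    if n > 1:
        prof[1] = (GAPE_START + GAPE_REST) / 2.0
    return prof


def _expand_script(script: KinematicScript):
    """Per-frame gape (mm) and head steps (mm), plus truth bookkeeping."""
    script.validate()
    gape: list[np.ndarray] = []
    steps: list[np.ndarray] = []
    mand_spans: list[tuple[MandibulationSpec, int, int, int]] = []  # spec, ep, s, e
    episode_starts: list[int] = []
    t = 0
    for ei, ep in enumerate(script.episodes):
        n_gap = ep.prefix_frames
        gape.append(_gap_gape_profile(n_gap))
        gap_steps = np.zeros((n_gap, 2))
        gap_steps[: ep.approach_frames, 1] = ep.approach_drop_mm / ep.approach_frames
        gap_steps[ep.approach_frames :, 1] = -ep.withdrawal_rise_mm / ep.withdrawal_frames
        gap_steps += np.asarray(ep.drift_mm_per_frame, float)
        steps.append(gap_steps)
        t += n_gap
        episode_starts.append(t)
        for m in ep.mandibulations:
            gape.append(m.gape_profile())
            steps.append(np.asarray(m.head_steps_mm, float))
            mand_spans.append((m, ei, t, t + m.n_frames))
            t += m.n_frames
    gape.append(_gap_gape_profile(script.tail_frames))
    steps.append(np.zeros((script.tail_frames, 2)))
    return np.concatenate(gape), np.vstack(steps), mand_spans, episode_starts


def path_length_mm(positions_mm: np.ndarray, start: int, end: int) -> float:
    """Head path length over [start, end): sum of the interval's n_frames
    per-frame steps, the last one clamped at the series end."""
    T = positions_mm.shape[0]
    idx_from = np.arange(start, end)
    idx_to = np.minimum(idx_from + 1, T - 1)
    d = positions_mm[idx_to] - positions_mm[idx_from]
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


def _true_records(
    mand_spans, positions_mm: np.ndarray, gape_mm: np.ndarray, fps: float
) -> list[TrueMandibulation]:
    records = []
    T = positions_mm.shape[0]
    for spec, ei, s, e in mand_spans:
        k = spec.n_frames // 2 if spec.peak_index is None else spec.peak_index
        duration_ms = (e - s) * 1000.0 / fps
        disp = path_length_mm(positions_mm, s, e)
        net = float(
            np.hypot(*(positions_mm[min(e, T - 1)] - positions_mm[s]))
        )
        records.append(
            TrueMandibulation(
                order=spec.order,
                start=s,
                end=e,
                peak_frame=s + k,
                max_gape_mm=float(gape_mm[s + k]),
                displacement_mm=disp,
                net_displacement_mm=net,
                duration_ms=duration_ms,
                speed_mm_s=disp / (duration_ms / 1000.0),
                catch_and_throw=spec.catch_and_throw,
                episode=ei,
            )
        )
    return records


def script_records(
    script: KinematicScript, fps: float
) -> tuple[list[TrueMandibulation], list[int]]:
    """True per-mandibulation records and episode starts from the script
    alone, without rendering (for bookkeeping at study scale)."""
    gape_mm, steps_mm, mand_spans, episode_starts = _expand_script(script)
    T = gape_mm.shape[0]
    positions_mm = np.vstack([np.zeros(2), np.cumsum(steps_mm, axis=0)])[:T]
    return _true_records(mand_spans, positions_mm, gape_mm, fps), episode_starts


# ---------------------------------------------------------------------------
# Rendering


def _geometry(config: SceneConfig, hinge: np.ndarray, gape_px: float):
    """Exact eye centre and beak tips for one frame; (x, y) floats."""
    r = float(config.eye_radius)
    L = float(config.beak_length)
    fx = 1.0 if config.beak_facing == "right" else -1.0
    half = min(gape_px / (2.0 * L), 0.999)
    theta = float(np.arcsin(half))
    eye = hinge + np.array([-3.4 * r * fx, -0.9 * r])
    up = hinge + np.array([L * np.cos(theta) * fx, -L * np.sin(theta)])
    lo = hinge + np.array([L * np.cos(theta) * fx, L * np.sin(theta)])
    return eye, up, lo, theta


def _rot(p: np.ndarray, theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([p[0] * c - p[1] * s, p[0] * s + p[1] * c])


def _draw_wedge(img, hinge, theta, config: SceneConfig, upper: bool) -> None:
    """Filled tapering triangle for one beak lobe, rotated about the hinge."""
    r = float(config.eye_radius)
    L = float(config.beak_length)
    fx = 1.0 if config.beak_facing == "right" else -1.0
    sgn = -1.0 if upper else 1.0
    base = [(-1.3 * r, sgn * 0.9 * r), (-1.3 * r, 0.0), (L, 0.0)]
    rot = sgn * theta  # upper lobe rotates up (negative y), lower down
    pts = [hinge + _rot(np.array([px * fx, py]), rot * fx) for px, py in base]
    rr, cc = skdraw.polygon(
        [p[1] for p in pts], [p[0] for p in pts], shape=img.shape
    )
    img[rr, cc] = config.head_gray
    # Guarantee the exact tip pixel survives discretisation of the thin
    # taper.  The spur is drawn twice, the copy shifted one row toward the
    # lobe interior: the union is 4-connected (a bare Bresenham line is only
    # 8-connected and would fall off the silhouette under a 4-connectivity
    # component filter) and the extremal tip pixel stays the rounded tip.
    tip = pts[2]
    u = (tip - hinge) / np.hypot(*(tip - hinge))
    base = tip - 12.0 * u
    interior = 1 if upper else -1  # rows grow downward; interior of the lobe
    for dy in (0, interior):
        rr, cc = skdraw.line(
            int(round(base[1])) + dy,
            int(round(base[0])),
            int(round(tip[1])) + dy,
            int(round(tip[0])),
        )
        ok = (rr >= 0) & (rr < img.shape[0]) & (cc >= 0) & (cc < img.shape[1])
        img[rr[ok], cc[ok]] = config.head_gray


def _silhouette_margins(config: SceneConfig) -> tuple[float, float, float, float]:
    """(back, forward, up, down) extent of the silhouette around the hinge.

    The head ellipse reaches 10.3 eye radii behind and 4 above the hinge;
    the beak reaches beak_length forward and the tips at most ~0.5 L off
    axis (gape angles stay under ~30 degrees)."""
    r = float(config.eye_radius)
    L = float(config.beak_length)
    back = 10.3 * r + 1
    fwd = L + 2
    up = 4.0 * r + 1
    down = max(2.6 * r, 0.55 * L) + 2
    return back, fwd, up, down


def _check_bounds(config: SceneConfig, hinge: np.ndarray, t: int) -> None:
    back, fwd, up, down = _silhouette_margins(config)
    if config.beak_facing == "left":
        back, fwd = fwd, back
    if (
        hinge[0] - back < 0
        or hinge[0] + fwd >= config.image_width
        or hinge[1] - up < 0
        or hinge[1] + down >= config.image_height
    ):
        raise GeometryError(
            f"frame {t}: scripted head geometry leaves the "
            f"{config.image_width}x{config.image_height} frame"
        )


def _default_start_hinge(config: SceneConfig, positions_px: np.ndarray) -> np.ndarray:
    """Centre the scripted trajectory inside the frame."""
    span_min = positions_px.min(axis=0)
    span_max = positions_px.max(axis=0)
    back, fwd, up, down = _silhouette_margins(config)
    if config.beak_facing == "left":
        back, fwd = fwd, back
    usable_w = config.image_width - back - fwd
    usable_h = config.image_height - up - down
    mid = (span_min + span_max) / 2.0
    cx = back + usable_w / 2.0 - mid[0]
    cy = up + usable_h / 2.0 - mid[1]
    return np.array([cx, cy])


def render_sequence(
    config: SceneConfig, script: KinematicScript
) -> tuple[FrameSequence, GroundTruth]:
    """Render a scripted feeding scene; ground truth records pre-noise geometry.

    Raises :class:`GeometryError` naming the first frame whose scripted head
    position would push the silhouette outside the image.
    """
    config.validate()
    gape_mm, steps_mm, mand_spans, episode_starts = _expand_script(script)
    T = gape_mm.shape[0]
    positions_mm = np.vstack([np.zeros(2), np.cumsum(steps_mm, axis=0)])[:T]
    positions_px = positions_mm / config.mm_per_px
    if script.start_hinge_px is not None:
        origin = np.asarray(script.start_hinge_px, float)
    else:
        origin = _default_start_hinge(config, positions_px)
    hinges = positions_px + origin

    rng = np.random.default_rng(config.seed)
    H, W = config.image_height, config.image_width
    frames = np.empty((T, H, W), dtype=np.uint8)
    eye_c = np.empty((T, 2))
    up_t = np.empty((T, 2))
    lo_t = np.empty((T, 2))

    # static scattered particles around the beak working area (frame coords)
    n_static = max(config.particle_count - 1, 0)
    beak_zone = hinges[0] + np.array(
        [(config.beak_length * (1 if config.beak_facing == "right" else -1)), 0.0]
    )
    static_xy = beak_zone + rng.uniform(-1, 1, size=(n_static, 2)) * np.array(
        [4.0 * config.eye_radius, 5.0 * config.eye_radius]
    ) + np.array([0.0, 3.0 * config.eye_radius])

    fx = 1.0 if config.beak_facing == "right" else -1.0
    for t in range(T):
        hinge = hinges[t]
        _check_bounds(config, hinge, t)
        img = frames[t]
        img[:] = config.background_gray
        gape_px = gape_mm[t] / config.mm_per_px
        eye, up, lo, theta = _geometry(config, hinge, gape_px)

        if config.particle_count > 0:
            # grasped particle follows the beak, overlapping the tip region
            mid = (up + lo) / 2.0
            gx = mid + np.array([(config.particle_radius_px + 1.0) * fx, 0.0])
            for px, py in [tuple(gx)] + [tuple(p) for p in static_xy]:
                rr, cc = skdraw.disk((py, px), config.particle_radius_px, shape=img.shape)
                img[rr, cc] = config.particle_gray

        r = float(config.eye_radius)
        ell_c = hinge + np.array([-5.8 * r * fx, -0.7 * r])
        rr, cc = skdraw.ellipse(ell_c[1], ell_c[0], 3.3 * r, 4.5 * r, shape=img.shape)
        img[rr, cc] = config.head_gray
        _draw_wedge(img, hinge, theta, config, upper=True)
        _draw_wedge(img, hinge, theta, config, upper=False)
        rr, cc = skdraw.disk((eye[1], eye[0]), config.eye_radius, shape=img.shape)
        img[rr, cc] = config.eye_gray

        eye_c[t], up_t[t], lo_t[t] = eye, up, lo

    # ground truth is recorded before noise
    gape_exact = (
        np.hypot(up_t[:, 0] - lo_t[:, 0], up_t[:, 1] - lo_t[:, 1]) * config.mm_per_px
    )
    truth = GroundTruth(
        eye_center=eye_c,
        upper_tip=up_t,
        lower_tip=lo_t,
        gape_mm=gape_exact,
        mandibulations=_true_records(mand_spans, positions_mm, gape_exact, config.fps),
        episode_starts=episode_starts,
        fps=config.fps,
        mm_per_px=config.mm_per_px,
    )
    if config.noise_sd > 0:
        noisy = rng.standard_normal(frames.shape, dtype=np.float32)
        np.multiply(noisy, config.noise_sd, out=noisy)
        noisy += frames
        np.clip(noisy, 0, 255, out=noisy)
        frames = noisy.astype(np.uint8)
    return FrameSequence(frames=frames, fps=config.fps), truth


def render_ruler(config: SceneConfig, tick_spacing_mm: float) -> np.ndarray:
    """Calibration ruler: equally spaced dark vertical ticks on background.

    Tick pixel spacing is tick_spacing_mm / mm_per_px; spacings that land
    below 2 px are unresolvable and rejected.
    """
    if tick_spacing_mm <= 0:
        raise ValueError("tick_spacing_mm must be positive")
    spacing_px = tick_spacing_mm / config.mm_per_px
    if spacing_px < 2.0:
        raise ValueError(
            f"tick spacing {spacing_px:.2f} px is below the 2 px resolution limit"
        )
    H, W = config.image_height, config.image_width
    img = np.full((H, W), config.background_gray, dtype=np.uint8)
    y0, y1 = int(0.7 * H), int(0.95 * H)
    x = 4.0
    while x < W - 2:
        c = int(round(x))
        img[y0:y1, c] = 20
        x += spacing_px
    return img


# ---------------------------------------------------------------------------
# Script builders


def make_episode(
    rng: np.random.Generator,
    orders_and_gapes: list[tuple[int, float, int, bool]],
    jitter_mm: float = 0.04,
    order1_extra_mm: float = 0.05,
) -> EpisodeSpec:
    """Build an EpisodeSpec from (order, peak_gape_mm, n_frames, catch_and_throw)
    tuples, with stationary head jitter around the trough position (larger in
    the first mandibulation and in catch-and-throw cycles, which show
    augmented head motion and beak aperture).  Jitter is generated as
    independent per-frame offsets, so the head wanders but never drifts."""
    mands = []
    for order, peak, n, ct in orders_and_gapes:
        scale = jitter_mm + (order1_extra_mm if order == 1 else 0.0)
        if ct:
            scale *= 2.0
        offsets = rng.normal(0.0, scale, size=(n + 1, 2))
        steps = np.diff(offsets, axis=0)
        mands.append(
            MandibulationSpec(
                order=order,
                n_frames=n,
                peak_gape_mm=peak + (0.8 if ct else 0.0),
                head_steps_mm=steps,
                catch_and_throw=ct,
            )
        )
    return EpisodeSpec(
        mandibulations=mands,
        approach_frames=int(rng.integers(8, 13)),
        approach_drop_mm=float(rng.normal(5.0, 0.7)),
        withdrawal_frames=int(rng.integers(10, 15)),
        withdrawal_rise_mm=float(rng.normal(5.0, 0.7)),
    )


def make_script(
    rng: np.random.Generator, episodes: list[EpisodeSpec]
) -> KinematicScript:
    """Wrap episodes into a script, balancing approach/withdrawal so the head
    returns near its baseline between sequences."""
    for ep in episodes:
        ep.withdrawal_rise_mm = ep.approach_drop_mm  # net-zero vertical drift
    return KinematicScript(episodes=episodes)
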