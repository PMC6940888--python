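"""Study-scale batch planning and end-to-end orchestration.

The default batch is the package's reference recording design: 19 broiler
chicks, each recorded with three feed types — fine mash (F1), coarse mash
(F2) and crumbled feed (F3) — for 57 sequences in total, with scripted
per-feed mandibulation totals of 576 (F1), 602 (F2) and 551 (F3), i.e.
1729 mandibulations overall.  Scripted
cycle durations and peak gapes are drawn around feed- and order-specific
central values at the scale reported for 3–4-day-old chicks (gapes of
2–4.5 mm, cycle times of 56–104 ms at 250 fps), and catch-and-throw cycles
occur with per-feed probabilities 0.26 (F1), 0.20 (F2) and 0.33 (F3), with
augmented gape and head motion.

``analyze_sequence`` is the full measurement chain for one recording:
track -> segment -> order -> kinematics -> catch-and-throw flags.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np
import pandas as pd

from . import scene
from .kinematics import (
    MandibulationRecord,
    SegmentationParams,
    WithdrawalParams,
    assign_orders,
    compute_kinematics,
    detect_withdrawals,
    flag_catch_and_throw,
    records_to_dataframe,
    segment_mandibulations,
)
from .vision import Calibration, HeadTrack, VisionParams, track_sequence

__all__ = [
    "FEED_TYPES",
    "PER_FEED_TOTALS",
    "CATCH_AND_THROW_RATES",
    "SequencePlan",
    "plan_default_batch",
    "scripted_records",
    "simulate_plans",
    "analyze_sequence",
]

FEED_TYPES = ("F1", "F2", "F3")

# per-feed scripted mandibulation totals across the 19-bird batch
PER_FEED_TOTALS = {"F1": 576, "F2": 602, "F3": 551}

# probability that a mandibulation is a catch-and-throw repositioning move
CATCH_AND_THROW_RATES = {"F1": 0.26, "F2": 0.20, "F3": 0.33}

# central peak gape (mm) per feed and mandibulation order 1..4
PEAK_GAPE_MM = {
    "F1": (4.3, 3.8, 3.1, 2.7),
    "F2": (3.7, 3.4, 2.6, 2.5),
    "F3": (4.3, 4.0, 3.6, 3.0),
}

# central cycle length (frames at 250 fps, 4 ms each) per feed and order
CYCLE_FRAMES = {
    "F1": (20, 24, 23, 26),
    "F2": (17, 21, 21, 20),
    "F3": (14, 20, 22, 23),
}


@dataclass
class SequencePlan:
    """One bird x feed recording: its scene config and kinematic script."""

    bird_id: str
    feed_type: str
    config: scene.SceneConfig
    script: scene.KinematicScript


def _split_counts(total: int, parts: int) -> list[int]:
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def _make_sequence_plan(
    rng: np.random.Generator,
    bird_id: str,
    feed: str,
    n_mandibulations: int,
    config: scene.SceneConfig,
) -> SequencePlan:
    episodes = []
    remaining = n_mandibulations
    while remaining > 0:
        k = int(min(remaining, rng.integers(4, 8)))
        remaining -= k
        specs = []
        for i in range(k):
            order = min(i + 1, 4)
            peak = float(
                np.clip(rng.normal(PEAK_GAPE_MM[feed][order - 1], 0.35), 1.8, 4.8)
            )
            n = int(max(CYCLE_FRAMES[feed][order - 1] + rng.integers(-3, 4), 12))
            ct = bool(rng.random() < CATCH_AND_THROW_RATES[feed])
            specs.append((order, peak, n, ct))
        episodes.append(scene.make_episode(rng, specs))
    script = scene.make_script(rng, episodes)
    return SequencePlan(bird_id=bird_id, feed_type=feed, config=config, script=script)


def plan_default_batch(
    seed: int = 0,
    n_birds: int = 19,
    feeds: tuple[str, ...] = FEED_TYPES,
    per_feed_totals: dict[str, int] | None = None,
    mandibulations_per_sequence: int | None = None,
    noise_sd: float | None = None,
    base_config: scene.SceneConfig | None = None,
) -> list[SequencePlan]:
    """Plan the default batch: one sequence per bird x feed.

    With the defaults this is the 19 x 3 = 57-sequence design with per-feed
    mandibulation totals 576/602/551; ``mandibulations_per_sequence``
    overrides those totals with a fixed per-sequence count (for small runs).
    Per-sequence scripts and render seeds derive deterministically from
    ``seed``.
    """
    totals = dict(PER_FEED_TOTALS if per_feed_totals is None else per_feed_totals)
    master = np.random.default_rng(seed)
    plans = []
    for feed in feeds:
        if mandibulations_per_sequence is not None:
            counts = [mandibulations_per_sequence] * n_birds
        else:
            counts = _split_counts(totals.get(feed, 30 * n_birds), n_birds)
        for b in range(n_birds):
            cfg_seed = int(master.integers(2**31))
            script_seed = int(master.integers(2**31))
            cfg = replace(base_config or scene.SceneConfig(), seed=cfg_seed)
            if noise_sd is not None:
                cfg = replace(cfg, noise_sd=noise_sd)
            plans.append(
                _make_sequence_plan(
                    np.random.default_rng(script_seed),
                    bird_id=f"bird{b + 1:02d}",
                    feed=feed,
                    n_mandibulations=counts[b],
                    config=cfg,
                )
            )
    return plans


def scripted_records(plans: list[SequencePlan]) -> pd.DataFrame:
    """Aggregate the planned (ground-truth) mandibulation records of a batch
    into a tidy table, without rendering any frames."""
    records: list[MandibulationRecord] = []
    for plan in plans:
        true_recs, _ = scene.script_records(plan.script, plan.config.fps)
        for r in true_recs:
            records.append(
                MandibulationRecord(
                    bird_id=plan.bird_id,
                    feed_type=plan.feed_type,
                    sequence_id=r.episode,
                    order=r.order,
                    start=r.start,
                    end=r.end,
                    peak_frame=r.peak_frame,
                    max_gape_mm=r.max_gape_mm,
                    displacement_mm=r.displacement_mm,
                    net_displacement_mm=r.net_displacement_mm,
                    duration_ms=r.duration_ms,
                    speed_mm_s=r.speed_mm_s,
                    catch_and_throw=r.catch_and_throw,
                )
            )
    return records_to_dataframe(records)


def simulate_plans(
    plans: list[SequencePlan],
) -> Iterator[tuple[SequencePlan, scene.FrameSequence, scene.GroundTruth]]:
    """Render the planned sequences one at a time (frames are large; stream)."""
    for plan in plans:
        frames, truth = scene.render_sequence(plan.config, plan.script)
        frames.bird_id, frames.feed_type = plan.bird_id, plan.feed_type
        yield plan, frames, truth


def analyze_sequence(
    frames: np.ndarray,
    calibration: Calibration,
    fps: float,
    *,
    bird_id: str = "",
    feed_type: str = "",
    vision_params: VisionParams | None = None,
    segmentation_params: SegmentationParams | None = None,
    withdrawal_params: WithdrawalParams | None = None,
    annotations: dict | None = None,
) -> tuple[list[MandibulationRecord], HeadTrack]:
    """Full per-sequence pipeline: track, segment, order, kinematics, flags."""
    track = track_sequence(frames, calibration, vision_params)
    intervals = segment_mandibulations(track.gape_mm, segmentation_params)
    bounds = detect_withdrawal_boundaries(track, calibration, withdrawal_params)
    episodes = assign_orders(intervals, bounds)
    records: list[MandibulationRecord] = []
    for sid, ep in enumerate(episodes):
        for order, iv in ep:
            records.append(
                compute_kinematics(
                    iv,
                    track,
                    calibration,
                    fps,
                    bird_id=bird_id,
                    feed_type=feed_type,
                    sequence_id=sid,
                    order=order,
                )
            )
    flag_catch_and_throw(records, annotations)
    return records, track


def detect_withdrawal_boundaries(
    track: HeadTrack, calibration: Calibration, params: WithdrawalParams | None = None
) -> list[int]:
    """Feeding-sequence boundaries from a tracked eye path, in mm units."""
    return detect_withdrawals(track.eye * calibration.mm_per_px, params)
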