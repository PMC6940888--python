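"""Parameter-recovery and self-validation batches.

Because no feeding video ships with the package, its accuracy claims rest on
parameter recovery: render synthetic batches whose ground truth is known
exactly, run the measurement chain, and score how well the scripted
quantities come back.  The functions here build those batches at study scale
(57 sequences, 1729 scripted mandibulations) or reduced scale, and collect
the headline metrics: max-gape and duration recovery, segmentation counts,
particle-removal efficacy, and the calibration of Mood's median test
(type-I error and agreement with an independent implementation).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import batch, scene, stats
from .kinematics import records_to_dataframe, segment_mandibulations
from .vision import Calibration, VisionParams, track_sequence

__all__ = [
    "recover_batch",
    "segmentation_counts_noise_free",
    "particle_removal_efficacy",
    "moods_type1_rate",
    "moods_vs_oracle",
    "spearman_vs_oracle",
]


def recover_batch(
    plans: list[batch.SequencePlan], gape_tol_mm: float | None = None
) -> dict:
    """Render, track and analyze every planned sequence; score recovery.

    For each scripted mandibulation the matching measured cycle is the one
    whose interval contains the scripted peak frame; a scripted cycle with no
    such interval counts as a recovery failure.  Returns per-record recovery
    fractions, the per-sequence count-match fraction, and the measured and
    scripted record tables.
    """
    n_true = n_gape_ok = n_dur_ok = n_order_ok = n_matched = 0
    n_seq = n_count_match = 0
    measured_records = []
    for plan, frames, truth in batch.simulate_plans(plans):
        cal = Calibration(mm_per_px=plan.config.mm_per_px)
        tol = gape_tol_mm if gape_tol_mm is not None else 2.0 * plan.config.mm_per_px
        recs, _ = batch.analyze_sequence(
            frames.frames,
            cal,
            plan.config.fps,
            bird_id=plan.bird_id,
            feed_type=plan.feed_type,
        )
        measured_records.extend(recs)
        n_seq += 1
        n_count_match += len(recs) == len(truth.mandibulations)
        by_peak = {}
        for r in recs:
            for f in range(r.start, r.end):
                by_peak[f] = r
        for t in truth.mandibulations:
            n_true += 1
            r = by_peak.get(t.peak_frame)
            if r is None:
                continue
            n_matched += 1
            n_gape_ok += abs(r.max_gape_mm - t.max_gape_mm) <= tol
            n_dur_ok += (r.start, r.end) == (t.start, t.end)
            n_order_ok += r.order == t.order
    return {
        "n_sequences": n_seq,
        "n_true_records": n_true,
        "n_matched": n_matched,
        "count_match_frac": n_count_match / n_seq,
        "gape_ok_frac": n_gape_ok / n_true,
        "duration_exact_frac": n_dur_ok / n_true,
        "order_ok_frac": n_order_ok / n_true,
        "measured": records_to_dataframe(measured_records),
        "scripted": batch.scripted_records(plans),
    }


def segmentation_counts_noise_free(
    seed: int, n_birds: int = 4, mandibulations_per_sequence: int = 8
) -> dict:
    """Fraction of noise-free sequences whose segmented cycle count equals
    the scripted count (and whose intervals match exactly)."""
    plans = batch.plan_default_batch(
        seed=seed,
        n_birds=n_birds,
        mandibulations_per_sequence=mandibulations_per_sequence,
        noise_sd=0.0,
    )
    n_seq = n_count = n_exact = 0
    for plan, frames, truth in batch.simulate_plans(plans):
        cal = Calibration(mm_per_px=plan.config.mm_per_px)
        track = track_sequence(frames.frames, cal)
        ivs = segment_mandibulations(track.gape_mm)
        n_seq += 1
        n_count += len(ivs) == len(truth.mandibulations)
        n_exact += [iv[:2] for iv in ivs] == [
            (t.start, t.end) for t in truth.mandibulations
        ]
    return {
        "n_sequences": n_seq,
        "count_match_frac": n_count / n_seq,
        "interval_exact_frac": n_exact / n_seq,
    }


def particle_removal_efficacy(seed: int, n_scenes: int = 50) -> dict:
    """Tip error with vs without particle removal on scenes whose grasped
    particle overlaps the beak-tip region.

    The per-scene error is the mean over frames of the larger of the two tip
    errors; removal is effective when it never increases that error.
    """
    master = np.random.default_rng(seed)
    pairs = []
    p_on = VisionParams(remove_particles=True)
    p_off = VisionParams(remove_particles=False)
    for _ in range(n_scenes):
        rng = np.random.default_rng(int(master.integers(2**31)))
        ep = scene.make_episode(
            rng,
            [(1, float(rng.uniform(3.0, 4.5)), int(rng.integers(16, 24)), False)],
        )
        script = scene.KinematicScript(episodes=[ep])
        cfg = scene.SceneConfig(seed=int(master.integers(2**31)))
        frames, truth = scene.render_sequence(cfg, script)
        cal = Calibration(mm_per_px=cfg.mm_per_px)
        errs = []
        for params in (p_on, p_off):
            ht = track_sequence(frames.frames, cal, params)
            eu = np.hypot(*(ht.upper_tip - truth.upper_tip).T)
            el = np.hypot(*(ht.lower_tip - truth.lower_tip).T)
            errs.append(float(np.maximum(eu, el).mean()))
        pairs.append(tuple(errs))
    arr = np.asarray(pairs)
    return {
        "n_scenes": n_scenes,
        "err_with_removal": arr[:, 0],
        "err_without_removal": arr[:, 1],
        "no_worse_frac": float((arr[:, 0] <= arr[:, 1]).mean()),
    }


def moods_type1_rate(
    seed: int,
    n_sim: int = 1000,
    n_per_group: int = 50,
    k_groups: int = 3,
    alpha: float = 0.05,
) -> dict:
    """Empirical type-I error of Mood's median test under a common normal
    null (k groups drawn from one distribution)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sim):
        groups = [rng.normal(size=n_per_group) for _ in range(k_groups)]
        rejections += stats.moods_median_test(groups).p_value < alpha
    return {"n_sim": n_sim, "rate": rejections / n_sim}


def moods_vs_oracle(seed: int, n_datasets: int = 100) -> dict:
    """Largest statistic/p-value deviation between the package's Mood's
    median test and an independent implementation (scipy.stats.median_test
    with matching tie handling and no continuity correction)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_datasets):
        k = int(rng.integers(2, 5))
        groups = [
            np.round(rng.normal(rng.uniform(-1, 1), 1.0, size=int(rng.integers(8, 40))), 1)
            for _ in range(k)
        ]
        mine = stats.moods_median_test(groups)
        s, p, _, _ = sps.median_test(*groups, ties="below", correction=False)
        worst = max(worst, abs(mine.statistic - s), abs(mine.p_value - p))
    return {"n_datasets": n_datasets, "max_abs_diff": worst}


def spearman_vs_oracle(seed: int, n_datasets: int = 100) -> dict:
    """Largest rho/p deviation between the package's Spearman test and
    scipy.stats.spearmanr (t-approximation) on random data with ties."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_datasets):
        n = int(rng.integers(6, 60))
        x = np.round(rng.normal(size=n), 1)  # rounding forces ties
        y = np.round(0.5 * x + rng.normal(size=n), 1)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        mine = stats.spearman(x, y)
        ref = sps.spearmanr(x, y)
        worst = max(
            worst,
            abs(mine.statistic - ref.statistic),
            abs(mine.p_value - ref.pvalue),
        )
    return {"n_datasets": n_datasets, "max_abs_diff": worst}
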