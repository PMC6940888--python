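"""Reading and writing the pipeline's on-disk formats.

Frames travel as zero-padded PNG sequences (frame_000001.png, ...) or a
single multi-page TIFF; ground truth and stats as JSON; tracks and records
as tidy CSV (UTF-8, header row, '.' decimal); configs as YAML or JSON;
catch-and-throw annotations as CSV or JSON keyed by
(bird_id, sequence_id, ordinal).
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

import dataclasses

from .scene import (
    EpisodeSpec,
    FrameSequence,
    GroundTruth,
    KinematicScript,
    MandibulationSpec,
    SceneConfig,
)

FRAME_EXTS = (".png", ".tif", ".tiff")


def save_frames(seq: FrameSequence, path: str | Path, fmt: str = "png") -> Path:
    """Write a frame stack as a PNG sequence directory or one multi-page TIFF."""
    path = Path(path)
    if fmt == "png":
        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(seq.frames):
            iio.imwrite(path / f"frame_{i + 1:06d}.png", frame)
        return path
    if fmt == "tiff":
        path.parent.mkdir(parents=True, exist_ok=True)
        if path.suffix.lower() not in (".tif", ".tiff"):
            path = path.with_suffix(".tiff")
        tifffile.imwrite(path, seq.frames)
        return path
    raise ValueError("fmt must be 'png' or 'tiff'")


def load_frames(path: str | Path) -> np.ndarray:
    """Load a (T, H, W) uint8 stack from a frame directory or multi-page TIFF."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in FRAME_EXTS
        )
        if not files:
            raise FileNotFoundError(f"no frames found in {path}")
        frames = np.stack([np.asarray(iio.imread(f)) for f in files])
    elif path.suffix.lower() in (".tif", ".tiff"):
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
    else:
        raise ValueError(f"cannot read frames from {path}")
    if frames.ndim == 3 and frames.shape[-1] in (3, 4):  # RGB(A) -> gray
        frames = frames[..., :3].mean(axis=-1).astype(np.uint8)
    return frames


def save_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(truth.to_json())


def load_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())


def save_records(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def load_records(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "catch_and_throw" in df.columns:
        df["catch_and_throw"] = df["catch_and_throw"].astype(bool)
    return df


def load_config(path: str | Path) -> dict:
    """YAML or JSON parameter file -> dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}


def save_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def save_scene_config(config: SceneConfig, path: str | Path) -> None:
    """Scene config as YAML (or JSON when the suffix says so)."""
    d = dataclasses.asdict(config)
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def load_scene_config(path: str | Path) -> SceneConfig:
    return SceneConfig(**load_config(path))


def save_script(script: KinematicScript, path: str | Path) -> None:
    """Kinematic script as YAML/JSON (head steps become nested lists)."""
    d = dataclasses.asdict(script)
    for ep in d["episodes"]:
        for m in ep["mandibulations"]:
            m["head_steps_mm"] = np.asarray(m["head_steps_mm"]).tolist()
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def load_script(path: str | Path) -> KinematicScript:
    d = load_config(path)
    episodes = []
    for ep in d["episodes"]:
        mands = [
            MandibulationSpec(
                **{**m, "head_steps_mm": np.asarray(m["head_steps_mm"], float)}
            )
            for m in ep["mandibulations"]
        ]
        episodes.append(EpisodeSpec(**{**ep, "mandibulations": mands}))
    extra = {k: v for k, v in d.items() if k != "episodes"}
    if extra.get("start_hinge_px") is not None:
        extra["start_hinge_px"] = tuple(extra["start_hinge_px"])
    return KinematicScript(episodes=episodes, **extra)


def load_annotations(path: str | Path) -> dict[tuple[str, int, int], bool]:
    """Catch-and-throw annotations keyed by (bird_id, sequence_id, ordinal).

    CSV needs columns bird_id, sequence_id, ordinal, catch_and_throw; JSON is
    a list of objects with the same fields.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        rows = pd.read_csv(path).to_dict(orient="records")
    out = {}
    for row in rows:
        key = (str(row["bird_id"]), int(row["sequence_id"]), int(row["ordinal"]))
        out[key] = bool(row["catch_and_throw"])
    return out
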