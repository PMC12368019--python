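"""Readers and writers for session artifacts.

Formats: PNG sequences or TIFF stacks for video (other containers go
through imageio when a suitable plugin is installed), CSV for command
logs and trial/video tables (UTF-8, comma separator, "." decimal),
JSON for ROIs and ground truth, YAML for pipeline configuration.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .detection import (
    COMMAND_TYPES,
    CommandEvent,
    DetectionThresholds,
    TrialResult,
    TrialWindowSpec,
    VideoResult,
)
from .tracking import ROISpec


# ---------------------------------------------------------------------------
# command logs


def read_command_log(path: str | Path) -> list[CommandEvent]:
    """Load a command log CSV with columns (command_id, command_type, onset_s).

    Events are returned sorted by onset (with a warning if the file was
    unsorted); unknown command types or malformed rows raise with the
    offending line number.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"command_id", "command_type", "onset_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"command log must have columns {sorted(required)}")
    events = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        ctype = str(row["command_type"]).strip().upper()
        if ctype not in COMMAND_TYPES:
            raise ValueError(f"line {line}: unknown command_type {ctype!r}")
        try:
            onset = float(row["onset_s"])
        except (TypeError, ValueError):
            raise ValueError(f"line {line}: onset_s not a number") from None
        events.append(
            CommandEvent(command_type=ctype, onset_s=onset, trial_index=int(i) + 1)
        )
    onsets = [e.onset_s for e in events]
    if onsets != sorted(onsets):
        warnings.warn("command log onsets unsorted; sorting by onset")
        events = sorted(events, key=lambda e: e.onset_s)
        events = [
            CommandEvent(e.command_type, e.onset_s, i + 1)
            for i, e in enumerate(events)
        ]
    return events


def write_command_log(events: Sequence[CommandEvent], path: str | Path) -> None:
    pd.DataFrame(
        {
            "command_id": [e.trial_index for e in events],
            "command_type": [e.command_type for e in events],
            "onset_s": [e.onset_s for e in events],
        }
    ).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# ROIs


def read_rois(path: str | Path) -> dict[str, ROISpec]:
    """ROI polygons from JSON: {roi_id: {polygon: [[x, y], ...],
    command_type: ...}}."""
    data = json.loads(Path(path).read_text())
    out = {}
    for rid, spec in data.items():
        out[rid] = ROISpec(
            roi_id=rid,
            polygon=np.asarray(spec["polygon"], dtype=float),
            command_type=spec.get("command_type"),
        )
    return out


def write_rois(rois: dict[str, ROISpec], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                rid: {
                    "polygon": r.polygon.tolist(),
                    "command_type": r.command_type,
                }
                for rid, r in rois.items()
            },
            indent=2,
        )
    )


# ---------------------------------------------------------------------------
# video frames


def read_frames(path: str | Path) -> np.ndarray:
    """Load video as a (T, H, W) uint8 grayscale array.

    A directory is read as a sorted PNG/TIFF sequence; a .tif/.tiff file
    as a stack; anything else is handed to imageio (which needs an
    appropriate plugin for compressed containers).
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if not files:
            raise FileNotFoundError(f"no frame images in {path}")
        frames = np.stack([iio.imread(f) for f in files])
    else:
        frames = np.asarray(iio.imread(path))
        if frames.ndim == 2:
            frames = frames[None]
    if frames.ndim == 4:  # RGB(A) -> luminance
        frames = frames[..., :3].mean(axis=-1)
    return np.clip(frames, 0, 255).astype(np.uint8)


def write_frames(frames: np.ndarray, out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = out_dir / f"frame_{i:06d}.png"
        iio.imwrite(p, np.asarray(frame, dtype=np.uint8))
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# result tables


def trial_table(
    video_id: str, command_type: str, trials: Sequence[TrialResult]
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "video_id": video_id,
            "command_type": command_type,
            "trial_index": [t.trial_index for t in trials],
            "ks_D": [t.ks_d for t in trials],
            "ks_p": [t.ks_p for t in trials],
            "post_peak": [t.post_peak for t in trials],
            "contaminated": [t.artifact_contaminated for t in trials],
            "positive": [t.positive for t in trials],
        }
    )


def video_table(video_id: str, results: Sequence[VideoResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "video_id": video_id,
            "command_type": [r.command_type for r in results],
            "n_trials": [r.n_trials for r in results],
            "n_positive": [r.n_positive for r in results],
            "fraction_positive": [r.fraction_positive for r in results],
            "max_amplitude": [r.max_amplitude for r in results],
            "seeme_positive": [r.seeme_positive for r in results],
        }
    )


# ---------------------------------------------------------------------------
# pipeline configuration


@dataclasses.dataclass
class TrackingParams:
    min_separation_px: float = 3.0
    response_threshold: float = 8.0
    pore_radius_px: float = 1.5
    window_px: int = 9
    pyramid_levels: int = 2
    residual_threshold: float = 10.0
    artifact_threshold_px: float = 1.0


@dataclasses.dataclass
class PipelineConfig:
    """Everything one analysis run needs; round-trips through YAML."""

    video: str
    command_log: str
    roi_file: str
    output_dir: str
    fps: float = 5.0
    windows: TrialWindowSpec = dataclasses.field(default_factory=TrialWindowSpec)
    thresholds: DetectionThresholds = dataclasses.field(
        default_factory=DetectionThresholds
    )
    tracking: TrackingParams = dataclasses.field(default_factory=TrackingParams)
    ks_mode: str = "p_value"
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["windows"] = TrialWindowSpec(**raw.get("windows", {}))
        raw["thresholds"] = DetectionThresholds(**raw.get("thresholds", {}))
        raw["tracking"] = TrackingParams(**raw.get("tracking", {}))
        return cls(**raw)

    def validate_paths(self) -> None:
        for name in ("video", "command_log", "roi_file"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
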