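"""End-to-end analysis driver: video in, trial/video decisions out.

Stages: load frames -> detect pores on frame 0 -> track -> compensate
global motion -> per-ROI movement traces -> event-locked trials -> KS +
post-peak gates -> video decision, with every table, heatmap and a
reproducibility record written to the output directory.  A mixed command
log is split automatically: each command type is analyzed against its
own ROI, as in per-command session videos.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import __version__
from .detection import COMMAND_FAMILY, analyze_trace
from .io import (
    PipelineConfig,
    read_command_log,
    read_frames,
    read_rois,
    trial_table,
    video_table,
)
from .tracking import (
    compensate_global_motion,
    detect_pores,
    summarize_roi,
    track_landmarks,
)
from .viz import render_heatmap

log = logging.getLogger(__name__)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full detection pipeline; returns the artifact paths.

    Deterministic given the same inputs: reruns produce byte-identical
    CSV outputs.  Raises on any stage failure after labeling partial
    outputs in the summary.
    """
    logging.basicConfig(level=config.log_level)
    config.validate_paths()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    video_id = Path(config.video).stem or "video"

    frames = read_frames(config.video)
    events = read_command_log(config.command_log)
    rois = read_rois(config.roi_file)
    tp = config.tracking
    log.info(
        "thresholds: ks=%s post_peak=%s min_trials=%s mode=%s artifact=%s px",
        config.thresholds.ks_threshold,
        config.thresholds.post_peak_threshold,
        config.thresholds.min_positive_trials,
        config.ks_mode,
        tp.artifact_threshold_px,
    )

    landmarks = detect_pores(
        frames[0],
        min_separation_px=tp.min_separation_px,
        response_threshold=tp.response_threshold,
        pore_radius_px=tp.pore_radius_px,
    )
    field = track_landmarks(
        frames,
        landmarks,
        window_px=tp.window_px,
        pyramid_levels=tp.pyramid_levels,
        residual_threshold=tp.residual_threshold,
        fps=config.fps,
    )
    field, artifact_flags = compensate_global_motion(
        field, artifact_threshold_px=tp.artifact_threshold_px
    )

    roi_for_command = {
        r.command_type: rid for rid, r in rois.items() if r.command_type
    }
    # mouth commands share the mouth ROI even if only one is listed
    for cmd, fam in COMMAND_FAMILY.items():
        if cmd not in roi_for_command:
            for rid, r in rois.items():
                if r.command_type and COMMAND_FAMILY.get(r.command_type) == fam:
                    roi_for_command[cmd] = rid

    trial_frames, video_rows, summary = [], [], {}
    for cmd in sorted({e.command_type for e in events}):
        cmd_events = [e for e in events if e.command_type == cmd]
        rid = roi_for_command.get(cmd)
        if rid is None:
            raise ValueError(f"no ROI configured for command {cmd}")
        trace = summarize_roi(field, rois[rid])
        trials, video = analyze_trace(
            trace,
            cmd_events,
            window_spec=config.windows,
            thresholds=config.thresholds,
            artifact_flags=artifact_flags,
            mode=config.ks_mode,
        )
        trial_frames.append(trial_table(video_id, cmd, trials))
        video_rows.append(video)

        w_resp = int(round(config.windows.response_window_s * config.fps))
        f0 = int(round(cmd_events[0].onset_s * config.fps))
        heat, bounds = render_heatmap(
            field, frames[0], (f0 + 1, min(f0 + w_resp, len(frames) - 1))
        )
        heat_path = out_dir / f"heatmap_{cmd.lower()}.png"
        iio.imwrite(heat_path, heat)
        summary[cmd] = {
            "roi": rid,
            "n_trials": video.n_trials,
            "n_positive": video.n_positive,
            "fraction_positive": video.fraction_positive,
            "max_amplitude": video.max_amplitude,
            "seeme_positive": video.seeme_positive,
            "heatmap": heat_path.name,
            "heatmap_scale_px_per_frame": bounds,
        }

    trials_path = out_dir / "trials.csv"
    videos_path = out_dir / "videos.csv"
    pd.concat(trial_frames, ignore_index=True).to_csv(trials_path, index=False)
    video_table(video_id, video_rows).to_csv(videos_path, index=False)

    summary_path = out_dir / "summary.json"
    summary_path.write_text(
        json.dumps(
            {
                "video_id": video_id,
                "n_landmarks": len(landmarks),
                "n_artifact_frames": int(np.asarray(artifact_flags).sum()),
                "commands": summary,
            },
            indent=2,
        )
    )
    repro_path = out_dir / "reproducibility.json"
    repro_path.write_text(
        json.dumps(
            {
                "software": "seeme",
                "version": __version__,
                "seed": config.seed,
                "config": {
                    "video": config.video,
                    "command_log": config.command_log,
                    "roi_file": config.roi_file,
                    "fps": config.fps,
                    "ks_mode": config.ks_mode,
                    "thresholds": vars(config.thresholds),
                    "windows": vars(config.windows),
                    "tracking": vars(config.tracking),
                },
            },
            indent=2,
            default=str,
        )
    )
    return {
        "trials": trials_path,
        "videos": videos_path,
        "summary": summary_path,
        "reproducibility": repro_path,
    }
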