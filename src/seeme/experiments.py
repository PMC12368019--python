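"""Study-scale synthetic experiments.

These reproduce, at desk scale, the validation studies behind the
detection pipeline: a null study measuring the end-to-end false-positive
rate on command sessions with no injected response, an amplitude sweep
measuring detection power and displacement-recovery accuracy, and the
command-classifier run on the separable fixture.  Each experiment
generates its sessions through :mod:`seeme.synthetic`, runs the full
detect–track–compensate–summarize–decide chain, and returns plain-dict
summaries.

Problem sizes default to 20 sessions x 10 trials (null) and 4 amplitudes
x 10 trials (sweep) at 160x160 px / 5 fps — small enough to run on one
CPU in minutes while leaving the protocol (baseline minute, blocks of
ten, 30–45 s gaps) exactly as specified.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .detection import (
    SYNTHETIC_THRESHOLDS,
    DetectionThresholds,
    TrialResult,
    TrialWindowSpec,
    VideoResult,
    analyze_trace,
)
from .classifier import (
    SplitSpec,
    balance_with_augmentation,
    evaluate_classifier,
    make_separable_dataset,
    split_train_test,
    train_sequence_classifier,
)
from .synthetic import (
    ROI_FOR_COMMAND,
    InjectedResponse,
    SceneConfig,
    SyntheticSession,
    build_schedule,
    responses_for_schedule,
    simulate_session,
)
from .tracking import (
    compensate_global_motion,
    detect_pores,
    roi_mean_displacement,
    summarize_roi,
    track_landmarks,
)


def _child_seeds(seed: int, n: int) -> list[int]:
    # stay below 2**31 so seeds remain portable
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def analyze_session(
    session: SyntheticSession,
    thresholds: DetectionThresholds = SYNTHETIC_THRESHOLDS,
    windows: TrialWindowSpec = TrialWindowSpec(),
    mode: str = "p_value",
    displacement_statistic: str = "mean",
) -> tuple[list[TrialResult], VideoResult, np.ndarray]:
    """Full chain on one synthetic session.

    Returns (trial results, video result, per-frame ROI displacement
    magnitude summary) for the session's command ROI.
    """
    frames = session.frames
    lm = detect_pores(frames[0])
    field = track_landmarks(frames, lm, fps=session.fps)
    field, artifact_flags = compensate_global_motion(field)
    roi = session.rois[ROI_FOR_COMMAND[session.events[0].command_type]]
    trace = summarize_roi(field, roi)
    trials, video = analyze_trace(
        trace,
        session.events,
        window_spec=windows,
        thresholds=thresholds,
        artifact_flags=artifact_flags,
        mode=mode,
    )
    return trials, video, roi_mean_displacement(
        field, roi, statistic=displacement_statistic
    )


def null_study(
    n_videos: int = 20,
    trials_per_video: int = 10,
    seed: int = 1234,
    thresholds: DetectionThresholds = SYNTHETIC_THRESHOLDS,
) -> dict:
    """False-positive control: sessions with no injected response.

    Every command presentation is a null trial — whatever the detector
    marks positive is a false alarm driven by pixel noise alone.  Returns
    the pooled trial-positivity fraction and the per-video decisions.
    """
    seeds = _child_seeds(seed, 2 * n_videos)
    n_pos = n_trials = 0
    videos: list[VideoResult] = []
    for i in range(n_videos):
        cfg = SceneConfig(seed=seeds[2 * i])
        schedule = build_schedule(
            n_trials=trials_per_video, seed=seeds[2 * i + 1]
        )
        session = simulate_session(cfg, schedule, responses=[])
        trials, video, _ = analyze_session(session, thresholds)
        n_pos += sum(t.positive for t in trials)
        n_trials += len(trials)
        videos.append(video)
    return {
        "n_trials": n_trials,
        "n_positive_trials": n_pos,
        "trial_positivity": n_pos / n_trials,
        "n_videos": len(videos),
        "n_seeme_positive_videos": sum(v.seeme_positive for v in videos),
        "videos": videos,
    }


def amplitude_sweep(
    amplitudes: Sequence[float] = (0.5, 1.0, 2.0, 4.0),
    trials_per_video: int = 10,
    seed: int = 99,
    thresholds: DetectionThresholds = SYNTHETIC_THRESHOLDS,
    windows: TrialWindowSpec = TrialWindowSpec(),
) -> dict:
    """Power and displacement-recovery sweep over injected amplitudes.

    One session per amplitude; every trial carries an injected eye-ROI
    response at that amplitude.  Recovery compares the tracked peak ROI
    displacement in each response window to the injected amplitude, using
    the per-landmark median across the ROI (robust to the tapered ROI
    boundary; baseline tracking noise enters only in quadrature, so no
    baseline subtraction is applied).
    """
    seeds = _child_seeds(seed, 2 * len(amplitudes))
    fps = None
    rows = []
    for k, amp in enumerate(amplitudes):
        cfg = SceneConfig(seed=seeds[2 * k])
        fps = cfg.fps
        schedule = build_schedule(n_trials=trials_per_video, seed=seeds[2 * k + 1])
        responses = responses_for_schedule(schedule, amplitude_px=amp)
        session = simulate_session(cfg, schedule, responses)
        trials, video, med_disp = analyze_session(
            session, thresholds, windows, displacement_statistic="median"
        )
        w_resp = int(round(windows.response_window_s * fps))
        rel_errs = []
        for ev in schedule:
            f0 = int(round(ev.onset_s * fps))
            peak = med_disp[f0 + 1 : f0 + w_resp + 1].max()
            rel_errs.append(abs(peak - amp) / amp)
        rows.append(
            {
                "amplitude_px": amp,
                "trial_positivity": sum(t.positive for t in trials) / len(trials),
                "seeme_positive": video.seeme_positive,
                "n_positive": video.n_positive,
                "recovery_rel_err_median": float(np.median(rel_errs)),
            }
        )
    return {"amplitudes": list(amplitudes), "rows": rows}


def classifier_experiment(
    seed: int = 0,
    n_per_class: int = 25,
    shuffled_n_per_class: int = 100,
    epochs: int = 80,
    shuffled_epochs: int = 40,
) -> dict:
    """Command-specificity check on the separable synthetic fixture.

    Trains the BiLSTM on command-specific sequences (disjoint active
    channel blocks per command) and on a label-shuffled copy; the first
    should classify far above chance, the second at chance.
    """
    seeds = _child_seeds(seed, 4)
    ds = make_separable_dataset(n_per_class=n_per_class, seed=seeds[0])
    train, test = split_train_test(ds, SplitSpec(seed=seeds[1]))
    train = balance_with_augmentation(train, seed=seeds[1])
    model = train_sequence_classifier(train, epochs=epochs, seed=seeds[1])
    report = evaluate_classifier(model, test)

    ds_sh = make_separable_dataset(
        n_per_class=shuffled_n_per_class, seed=seeds[2], shuffle_labels=True
    )
    tr_sh, te_sh = split_train_test(ds_sh, SplitSpec(seed=seeds[3]))
    model_sh = train_sequence_classifier(tr_sh, epochs=shuffled_epochs, seed=seeds[3])
    report_sh = evaluate_classifier(model_sh, te_sh)
    return {
        "n_train": len(train),
        "n_test": len(test),
        "overall_accuracy": report.overall_accuracy,
        "per_class_accuracy": report.per_class_accuracy,
        "shuffled_n_test": len(te_sh),
        "shuffled_accuracy": report_sh.overall_accuracy,
    }
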