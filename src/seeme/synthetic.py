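"""Ground-truth synthetic sessions for end-to-end validation.

No public video of unresponsive patients exists, so every downstream
stage is exercised on synthetic sessions: a textured plane standing in
for the face (smooth shading plus dark pore-scale blobs), polygonal ROIs
for the eye and mouth regions, stimulus-locked micro-displacements warped
into an ROI, i.i.d. Gaussian pixel noise, and optional whole-frame
translations emulating bed/camera bumps.  The generator records exactly
which trials carry a response and at what amplitude, so detection
accuracy downstream is computable exactly.

The face model is deliberately not photorealistic: a textured plane with
polygonal ROIs is sufficient to exercise sub-pixel tracking and the
trial statistics, which is all these sessions are for.

Default scene scale: 0.2 mm per pixel, so one pixel corresponds to the
pore resolution of the clinical recordings.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import polygon2mask

from .detection import COMMAND_TYPES, CommandEvent
from .tracking import ROISpec

WAVEFORMS = ("ramp", "gaussian-bump", "sine")


@dataclass(frozen=True)
class SceneConfig:
    """Synthetic scene parameters.

    pore_density is in pores per 100x100 px patch; pixel_pitch_mm converts
    pixels to physical scale (default 0.2 mm/px, i.e. one pixel per pore).
    noise_sd is the additive Gaussian pixel noise in 8-bit gray levels.
    The same seed reproduces the session bit for bit.
    """

    frame_size: tuple[int, int] = (160, 160)  # (width, height)
    fps: float = 5.0
    pore_density: float = 60.0
    pore_radius_px: float = 1.5
    pixel_pitch_mm: float = 0.2
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.frame_size
        if w <= 0 or h <= 0:
            raise ValueError("frame_size must be positive")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.pore_density < 0:
            raise ValueError("pore_density must be non-negative")


@dataclass(frozen=True)
class InjectedResponse:
    """One stimulus-evoked movement to inject.

    The movement starts ``latency_s`` after the command at ``onset_s``,
    lasts ``duration_s`` and peaks at ``amplitude_px`` of ROI-internal
    displacement along ``direction``.  Waveforms: "ramp" (smooth
    ramp–hold–release, the default facial-movement stand-in),
    "gaussian-bump" (peak-shaped), "sine" (oscillatory, for sub-pixel
    fidelity sweeps).  Real evoked-movement kinematics are unpublished;
    these are documented placeholders.
    """

    roi_id: str
    onset_s: float
    amplitude_px: float
    latency_s: float = 1.0
    duration_s: float = 8.0
    waveform: str = "ramp"
    direction: tuple[float, float] = (0.6, 0.8)

    def __post_init__(self) -> None:
        if self.latency_s < 0:
            raise ValueError("latency_s must be >= 0")
        if self.amplitude_px < 0:
            raise ValueError("amplitude_px must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.waveform not in WAVEFORMS:
            raise ValueError(f"waveform must be one of {WAVEFORMS}")

    def weight(self, t: np.ndarray) -> np.ndarray:
        """Temporal envelope in [-1, 1] at absolute times ``t`` (s)."""
        tau = np.asarray(t, dtype=float) - (self.onset_s + self.latency_s)
        d = self.duration_s
        w = np.zeros_like(tau)
        inside = (tau >= 0) & (tau <= d)
        if self.waveform == "ramp":
            r = 0.3 * d  # rise/release time
            w = np.where(inside, np.minimum(1.0, np.minimum(tau / r, (d - tau) / r)), 0.0)
            w = np.clip(w, 0.0, 1.0)
        elif self.waveform == "gaussian-bump":
            sig = d / 6.0
            w = np.where(inside, np.exp(-0.5 * ((tau - d / 2) / sig) ** 2), 0.0)
        else:  # sine, two full cycles
            w = np.where(inside, np.sin(2.0 * np.pi * 2.0 * tau / d), 0.0)
        return w


@dataclass
class TrialTruth:
    trial_index: int
    command_type: str
    onset_s: float
    responded: bool
    true_amplitude_px: float
    roi_id: str | None


@dataclass
class GroundTruth:
    """Exhaustive record of injected signal and artifacts."""

    trials: list[TrialTruth]
    global_shifts: list[tuple[int, float, float]]  # (frame, dx, dy)

    def to_json(self) -> str:
        return json.dumps(
            {
                "trials": [asdict(t) for t in self.trials],
                "global_shifts": [list(s) for s in self.global_shifts],
            },
            indent=2,
        )


@dataclass
class SyntheticSession:
    frames: np.ndarray  # (T, H, W) uint8
    events: list[CommandEvent]
    ground_truth: GroundTruth
    rois: dict[str, ROISpec]
    config: SceneConfig

    @property
    def fps(self) -> float:
        return self.config.fps


# ---------------------------------------------------------------------------
# texture


def generate_pore_field(config: SceneConfig) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless textured frame plus the true pore centroids (N, 2) (x, y)."""
    w, h = config.frame_size
    rng = np.random.default_rng(config.seed)

    # smooth shading: coarse random field upsampled by a spline zoom
    coarse = rng.normal(0.0, 1.0, size=(8, 8))
    shade = ndimage.zoom(coarse, (h / 8, w / 8), order=3)
    base = 170.0 + 10.0 * shade[:h, :w]

    n_target = int(round(config.pore_density * (w * h) / 1e4))
    if n_target == 0:
        warnings.warn("pore_density yields zero pores; featureless frame")
        return base, np.empty((0, 2))

    min_sep = max(6.0, 4.0 * config.pore_radius_px)
    margin = 3.0 * config.pore_radius_px + 1.0
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < n_target and attempts < 200 * n_target:
        attempts += 1
        c = rng.uniform([margin, margin], [w - 1 - margin, h - 1 - margin])
        if centers:
            d = np.hypot(*(np.array(centers) - c).T)
            if d.min() < min_sep:
                continue
        centers.append(c)
    if len(centers) < n_target:
        warnings.warn(
            f"placed only {len(centers)}/{n_target} pores at the requested density"
        )
    pores = np.array(centers)

    # subtract Gaussian blobs (dark pores) — rendered on local patches
    sig = config.pore_radius_px
    r = int(math.ceil(4 * sig))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    img = base.copy()
    for cx, cy in pores:
        ix, iy = int(round(cx)), int(round(cy))
        fx, fy = cx - ix, cy - iy
        blob = 70.0 * np.exp(-(((xx - fx) ** 2 + (yy - fy) ** 2) / (2 * sig**2)))
        img[iy - r : iy + r + 1, ix - r : ix + r + 1] -= blob
    return np.clip(img, 0.0, 255.0), pores


def generate_pore_texture(config: SceneConfig) -> np.ndarray:
    """Noiseless textured reference frame (H, W float, 0..255)."""
    return generate_pore_field(config)[0]


# ---------------------------------------------------------------------------
# schedule and ROIs


def build_schedule(
    command_type: str = "EYES",
    n_trials: int = 10,
    baseline_s: float = 60.0,
    gap_range_s: tuple[float, float] = (30.0, 45.0),
    jitter_s: float = 1.0,
    seed: int = 0,
) -> list[CommandEvent]:
    """Clinical presentation protocol: a resting baseline, then a block of
    ``n_trials`` commands separated by uniform gaps plus jitter (defaults:
    1 min baseline, blocks of ten, 30–45 s gaps with ±1 s jitter)."""
    if command_type not in COMMAND_TYPES:
        raise ValueError(f"unknown command_type {command_type!r}")
    rng = np.random.default_rng(seed)
    onsets = [baseline_s]
    for _ in range(n_trials - 1):
        gap = rng.uniform(*gap_range_s) + rng.uniform(-jitter_s, jitter_s)
        onsets.append(onsets[-1] + gap)
    return [
        CommandEvent(command_type=command_type, onset_s=float(t), trial_index=i + 1)
        for i, t in enumerate(onsets)
    ]


def default_rois(frame_size: tuple[int, int] = (160, 160)) -> dict[str, ROISpec]:
    """Eye-band and mouth-band rectangles on the synthetic face plane."""
    w, h = frame_size
    eye = np.array(
        [[0.10 * w, 0.20 * h], [0.90 * w, 0.20 * h],
         [0.90 * w, 0.45 * h], [0.10 * w, 0.45 * h]]
    )
    mouth = np.array(
        [[0.25 * w, 0.60 * h], [0.75 * w, 0.60 * h],
         [0.75 * w, 0.85 * h], [0.25 * w, 0.85 * h]]
    )
    return {
        "eyes": ROISpec(roi_id="eyes", polygon=eye, command_type="EYES"),
        "mouth": ROISpec(roi_id="mouth", polygon=mouth, command_type="TONGUE"),
    }


ROI_FOR_COMMAND = {"EYES": "eyes", "TONGUE": "mouth", "SMILE": "mouth"}


# ---------------------------------------------------------------------------
# session rendering


def _roi_profile(
    roi: ROISpec, frame_shape: tuple[int, int], taper_px: float = 2.5
) -> np.ndarray:
    """Spatial envelope: 1 in the ROI interior, tapering to 0 at the edge.

    The taper keeps the warp continuous; it lives just inside the polygon
    so no injected motion leaks outside the declared ROI.
    """
    mask = polygon2mask(frame_shape, roi.polygon[:, ::-1])  # (row, col) verts
    dist = ndimage.distance_transform_edt(mask)
    return np.clip(dist / taper_px, 0.0, 1.0)


def simulate_session(
    config: SceneConfig,
    schedule: Sequence[CommandEvent],
    responses: Sequence[InjectedResponse] = (),
    global_shifts: Sequence[tuple[int, float, float]] = (),
    rois: dict[str, ROISpec] | None = None,
    tail_s: float = 25.0,
) -> SyntheticSession:
    """Render a full command-session video with known ground truth.

    Frames are the pore texture inverse-warped by the sum of active
    response displacements (confined to their ROI) and any whole-frame
    shift listed in ``global_shifts``, plus fresh Gaussian noise per
    frame.  Outside response windows and artifact frames, nothing but
    noise moves.  Returns frames (uint8), the command log, and the
    exhaustive ground truth.
    """
    w, h = config.frame_size
    onsets = [e.onset_s for e in schedule]
    if any(b <= a for a, b in zip(onsets, onsets[1:])):
        raise ValueError("schedule onsets must be strictly increasing")
    if rois is None:
        rois = default_rois(config.frame_size)

    duration = (onsets[-1] if onsets else 0.0) + tail_s
    n_frames = int(math.ceil(duration * config.fps))
    for r in responses:
        if r.roi_id not in rois:
            raise ValueError(f"response references unknown ROI {r.roi_id!r}")
        if r.onset_s + r.latency_s + r.duration_s > duration:
            raise ValueError(
                f"response at {r.onset_s:.1f}s extends beyond video end "
                f"({duration:.1f}s)"
            )

    base, _ = generate_pore_field(config)
    spline = ndimage.spline_filter(base, order=3)
    profiles = {rid: _roi_profile(rois[rid], (h, w)) for rid in
                {r.roi_id for r in responses}}
    bboxes = {}
    for rid, prof in profiles.items():
        rr, cc = np.nonzero(prof > 0)
        pad = 6
        bboxes[rid] = (
            max(rr.min() - pad, 0), min(rr.max() + pad, h - 1),
            max(cc.min() - pad, 0), min(cc.max() + pad, w - 1),
        )

    shift_by_frame = {int(f): (float(dx), float(dy)) for f, dx, dy in global_shifts}
    noise_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7919]))

    times = np.arange(n_frames) / config.fps
    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    for t_idx in range(n_frames):
        t = times[t_idx]
        active = [r for r in responses if r.weight(np.array([t]))[0] != 0.0]
        gshift = shift_by_frame.get(t_idx)
        if not active and gshift is None:
            img = base
        elif active:
            img = base.copy()
            # composite displacement over the union bbox of active ROIs
            for r in active:
                r0, r1, c0, c1 = bboxes[r.roi_id]
                prof = profiles[r.roi_id][r0 : r1 + 1, c0 : c1 + 1]
                wgt = float(r.weight(np.array([t]))[0])
                ux = r.amplitude_px * wgt * r.direction[0] * prof
                uy = r.amplitude_px * wgt * r.direction[1] * prof
                gx, gy = gshift if gshift else (0.0, 0.0)
                cy = yy[r0 : r1 + 1, c0 : c1 + 1] - uy - gy
                cx = xx[r0 : r1 + 1, c0 : c1 + 1] - ux - gx
                img[r0 : r1 + 1, c0 : c1 + 1] = ndimage.map_coordinates(
                    spline, [cy, cx], order=3, prefilter=False, mode="nearest"
                )
            if gshift is not None:
                # shift the rest of the frame rigidly
                gx, gy = gshift
                img_glob = ndimage.map_coordinates(
                    spline, [yy - gy, xx - gx], order=3, prefilter=False,
                    mode="nearest",
                )
                outside = np.ones((h, w), dtype=bool)
                for r in active:
                    r0, r1, c0, c1 = bboxes[r.roi_id]
                    outside[r0 : r1 + 1, c0 : c1 + 1] = False
                img[outside] = img_glob[outside]
        else:  # global shift only
            gx, gy = gshift
            img = ndimage.map_coordinates(
                spline, [yy - gy, xx - gx], order=3, prefilter=False, mode="nearest"
            )
        noisy = img + noise_rng.normal(0.0, config.noise_sd, size=(h, w))
        frames[t_idx] = np.clip(noisy, 0, 255).astype(np.uint8)

    responded_rois = {}
    for r in responses:
        if r.amplitude_px > 0:
            responded_rois.setdefault(r.onset_s, []).append(r)
    trials = []
    for ev in schedule:
        rs = responded_rois.get(ev.onset_s, [])
        trials.append(
            TrialTruth(
                trial_index=ev.trial_index,
                command_type=ev.command_type,
                onset_s=ev.onset_s,
                responded=bool(rs),
                true_amplitude_px=max((r.amplitude_px for r in rs), default=0.0),
                roi_id=rs[0].roi_id if rs else None,
            )
        )
    truth = GroundTruth(trials=trials, global_shifts=[tuple(s) for s in global_shifts])
    return SyntheticSession(
        frames=frames,
        events=list(schedule),
        ground_truth=truth,
        rois=rois,
        config=config,
    )


def responses_for_schedule(
    schedule: Sequence[CommandEvent],
    amplitude_px: float,
    respond_trials: Sequence[int] | None = None,
    roi_id: str | None = None,
    **kwargs,
) -> list[InjectedResponse]:
    """Convenience: one injected response per (selected) trial."""
    out = []
    for ev in schedule:
        if respond_trials is not None and ev.trial_index not in respond_trials:
            continue
        rid = roi_id or ROI_FOR_COMMAND[ev.command_type]
        out.append(
            InjectedResponse(
                roi_id=rid, onset_s=ev.onset_s, amplitude_px=amplitude_px, **kwargs
            )
        )
    return out
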