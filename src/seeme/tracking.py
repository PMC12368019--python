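"""Pore-scale feature tracking into a displacement vector field.

The face is imaged close enough that individual skin pores (~0.2 mm) are
resolved as small dark blobs.  ``detect_pores`` tags them on a reference
frame; ``track_landmarks`` follows each one through the video with a
pyramidal Lucas–Kanade patch registration anchored to the reference-frame
template (anchoring avoids the random-walk drift that frame-to-frame
chaining accumulates over thousands of frames).  The per-landmark,
per-frame displacement vectors form the vector field that downstream
stages reduce to per-ROI movement traces.

Conventions: 0-based pixel coordinates, x rightward, y downward; time is
frame_index / fps.  Displacements are relative to frame 0, so frame 0 is
identically zero.  Landmarks whose photometric residual against their
reference template exceeds a threshold are marked lost and stay lost
(re-acquisition would risk identity switches that corrupt trial
statistics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from matplotlib.path import Path as MplPath
from scipy import ndimage
from skimage.feature import peak_local_max


class ROIError(ValueError):
    """Raised when an ROI cannot be analyzed (e.g. contains no landmarks)."""


@dataclass
class LandmarkSet:
    """Feature points tagged on a reference frame."""

    positions: np.ndarray  # (N, 2) float, columns (x, y)
    ids: np.ndarray  # (N,) int, unique
    frame_shape: tuple[int, int]  # (height, width)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        self.ids = np.asarray(self.ids, dtype=int)
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("landmark ids must be unique")
        h, w = self.frame_shape
        x, y = self.positions[:, 0], self.positions[:, 1]
        if len(x) and (x.min() < 0 or y.min() < 0 or x.max() > w - 1 or y.max() > h - 1):
            raise ValueError("landmark positions outside frame bounds")

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class DisplacementField:
    """Per-frame, per-landmark 2D displacement relative to frame 0."""

    dx: np.ndarray  # (T, N)
    dy: np.ndarray  # (T, N)
    valid: np.ndarray  # (T, N) bool; once False, stays False
    ids: np.ndarray  # (N,)
    ref_positions: np.ndarray  # (N, 2) (x, y) on frame 0
    fps: float = 1.0

    @property
    def n_frames(self) -> int:
        return self.dx.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.dx.shape[1]

    def magnitude(self) -> np.ndarray:
        """(T, N) displacement magnitude relative to frame 0."""
        return np.hypot(self.dx, self.dy)

    def step(self) -> tuple[np.ndarray, np.ndarray]:
        """Frame-to-frame displacement increments (T, N); row 0 is zero."""
        sx = np.zeros_like(self.dx)
        sy = np.zeros_like(self.dy)
        sx[1:] = np.diff(self.dx, axis=0)
        sy[1:] = np.diff(self.dy, axis=0)
        return sx, sy

    def to_dataframe(self):
        """Long-format table (frame, landmark_id, dx, dy, valid)."""
        import pandas as pd

        t_idx, n_idx = np.meshgrid(
            np.arange(self.n_frames), np.arange(self.n_landmarks), indexing="ij"
        )
        return pd.DataFrame(
            {
                "frame": t_idx.ravel(),
                "landmark_id": self.ids[n_idx.ravel()],
                "dx": self.dx.ravel(),
                "dy": self.dy.ravel(),
                "valid": self.valid.ravel(),
            }
        )


@dataclass(frozen=True)
class ROISpec:
    """Polygonal region of interest tied to one command type."""

    roi_id: str
    polygon: np.ndarray  # (V, 2) vertices, (x, y)
    command_type: str | None = None

    def __post_init__(self) -> None:
        poly = np.asarray(self.polygon, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "polygon", poly)
        if len(poly) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        if _self_intersects(poly):
            raise ValueError(f"ROI {self.roi_id!r}: polygon self-intersects")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of (N, 2) points inside the polygon."""
        return MplPath(self.polygon).contains_points(
            np.asarray(points, dtype=float).reshape(-1, 2)
        )


def _self_intersects(poly: np.ndarray) -> bool:
    """Brute-force check that non-adjacent edges do not cross."""
    n = len(poly)
    edges = [(poly[i], poly[(i + 1) % n]) for i in range(n)]

    def seg_intersect(p1, p2, p3, p4) -> bool:
        d = lambda a, b, c: (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        d1, d2 = d(p3, p4, p1), d(p3, p4, p2)
        d3, d4 = d(p1, p2, p3), d(p1, p2, p4)
        return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))

    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:  # adjacent around the wrap
                continue
            if seg_intersect(*edges[i], *edges[j]):
                return True
    return False


@dataclass
class ROITrace:
    """Per-frame summed displacement-step magnitude inside one ROI.

    ``values[t]`` is the sum over valid inside-ROI landmarks of the
    frame-to-frame displacement magnitude — a movement-rate signal that
    returns toward baseline between commands (summing cumulative position
    instead would integrate any sustained posture change indefinitely).
    """

    roi_id: str
    values: np.ndarray  # (T,) non-negative
    n_landmarks: np.ndarray  # (T,) valid inside-ROI landmark count
    fps: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("trace values must be non-negative")

    @property
    def normalized(self) -> np.ndarray:
        """Trace divided by the per-frame valid landmark count."""
        return self.values / np.maximum(self.n_landmarks, 1)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.fps


# ---------------------------------------------------------------------------
# pore detection


def detect_pores(
    frame: np.ndarray,
    min_separation_px: float = 3.0,
    response_threshold: float = 8.0,
    pore_radius_px: float = 1.5,
) -> LandmarkSet:
    """Tag dark pore-like blobs on a grayscale frame.

    The frame is band-passed with a difference of Gaussians matched to the
    pore radius (inverted so pores become maxima); local maxima above
    ``response_threshold`` and at least ``min_separation_px`` apart become
    landmarks, refined to sub-pixel by a quadratic fit around each peak.
    A featureless frame yields an empty set with a warning.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single grayscale frame")
    inv = -img
    bp = ndimage.gaussian_filter(inv, pore_radius_px) - ndimage.gaussian_filter(
        inv, 3.0 * pore_radius_px
    )
    peaks = peak_local_max(
        bp,
        min_distance=max(1, int(round(min_separation_px))),
        threshold_abs=response_threshold,
        exclude_border=2,
    )
    if len(peaks) == 0:
        warnings.warn("no pore-like features detected; empty landmark set")
        return LandmarkSet(
            positions=np.empty((0, 2)), ids=np.empty(0, dtype=int),
            frame_shape=img.shape,
        )
    # quadratic sub-pixel refinement, per axis
    ys, xs = peaks[:, 0].astype(float), peaks[:, 1].astype(float)
    for axis, coord in ((0, ys), (1, xs)):
        lo = bp[peaks[:, 0] - (axis == 0), peaks[:, 1] - (axis == 1)]
        mid = bp[peaks[:, 0], peaks[:, 1]]
        hi = bp[peaks[:, 0] + (axis == 0), peaks[:, 1] + (axis == 1)]
        denom = lo - 2 * mid + hi
        shift = np.where(np.abs(denom) > 1e-12, 0.5 * (lo - hi) / denom, 0.0)
        coord += np.clip(shift, -0.5, 0.5)
    positions = np.column_stack([xs, ys])
    return LandmarkSet(
        positions=positions,
        ids=np.arange(len(positions)),
        frame_shape=img.shape,
    )


# ---------------------------------------------------------------------------
# pyramidal Lucas–Kanade tracking, anchored to the frame-0 template


def _pyramid(img: np.ndarray, levels: int) -> list[np.ndarray]:
    pyr = [img]
    for _ in range(1, levels):
        pyr.append(ndimage.gaussian_filter(pyr[-1], 1.0)[::2, ::2])
    return pyr


def _sample(img: np.ndarray, xy: np.ndarray) -> np.ndarray:
    """Bilinear sample at (..., 2) (x, y) points."""
    coords = np.stack([xy[..., 1].ravel(), xy[..., 0].ravel()])
    return ndimage.map_coordinates(img, coords, order=1, mode="nearest").reshape(
        xy.shape[:-1]
    )


def track_landmarks(
    frames: Iterable[np.ndarray],
    landmarks: LandmarkSet,
    window_px: int = 9,
    pyramid_levels: int = 2,
    max_iterations: int = 10,
    convergence_px: float = 0.03,
    residual_threshold: float = 10.0,
    fps: float = 1.0,
) -> DisplacementField:
    """Track every landmark through the video, sub-pixel.

    Each landmark carries a ``window_px`` x ``window_px`` template cut from
    frame 0.  For every later frame the template is re-registered against
    the frame by Gauss–Newton iterations on the photometric error, coarse
    to fine over a Gaussian pyramid, initialized at the landmark's
    displacement in the previous frame.  Landmarks whose converged mean
    absolute residual exceeds ``residual_threshold`` gray levels, or that
    leave the frame, are marked lost for the rest of the video.
    """
    it = iter(frames)
    try:
        ref = np.asarray(next(it), dtype=float)
    except StopIteration:
        raise ValueError("need at least 2 frames") from None

    n = len(landmarks)
    half = window_px // 2
    off_1d = np.arange(-half, half + 1, dtype=float)
    ox, oy = np.meshgrid(off_1d, off_1d)
    offsets = np.stack([ox.ravel(), oy.ravel()], axis=-1)  # (K, 2)
    k = offsets.shape[0]

    # per-level templates, template gradients, and normal-equation inverses
    ref_pyr = _pyramid(ref, pyramid_levels)
    grad_pyr = [np.gradient(p) for p in ref_pyr]  # (gy, gx) per level
    templates, grads, ainv, usable = [], [], [], np.ones(n, dtype=bool)
    for lvl, img in enumerate(ref_pyr):
        scale = 0.5**lvl
        pts = landmarks.positions[:, None, :] * scale + offsets[None, :, :]
        t = _sample(img, pts)
        gy = _sample(grad_pyr[lvl][0], pts)
        gx = _sample(grad_pyr[lvl][1], pts)
        gxx = (gx * gx).sum(axis=1)
        gxy = (gx * gy).sum(axis=1)
        gyy = (gy * gy).sum(axis=1)
        det = gxx * gyy - gxy**2
        ok = det > 1e-6
        usable &= ok
        det = np.where(ok, det, 1.0)
        inv = np.empty((n, 2, 2))
        inv[:, 0, 0] = gyy / det
        inv[:, 1, 1] = gxx / det
        inv[:, 0, 1] = inv[:, 1, 0] = -gxy / det
        templates.append(t)
        grads.append((gx, gy))
        ainv.append(inv)
    if not usable.all():
        warnings.warn(f"{(~usable).sum()} landmark(s) lack texture; marked lost")

    h, w = ref.shape
    margin = half + 1

    disp = [np.zeros((n, 2))]
    valid = [usable.copy()]
    g = np.zeros((n, 2))  # current displacement estimate, full-res px

    for frame in it:
        img = np.asarray(frame, dtype=float)
        if img.shape != ref.shape:
            raise ValueError("frame size mismatch")
        pyr = _pyramid(img, pyramid_levels)
        alive = valid[-1].copy()
        for lvl in range(pyramid_levels - 1, -1, -1):
            scale = 0.5**lvl
            t, (gx, gy), inv = templates[lvl], grads[lvl], ainv[lvl]
            base = landmarks.positions * scale  # (N, 2)
            for _ in range(max_iterations):
                pts = (base + g * scale)[:, None, :] + offsets[None, :, :]
                cur = _sample(pyr[lvl], pts)
                err = cur - t
                bx = (gx * err).sum(axis=1)
                by = (gy * err).sum(axis=1)
                dp = -np.einsum("nij,nj->ni", inv, np.stack([bx, by], axis=-1))
                g += dp / scale
                if np.abs(dp[alive]).max(initial=0.0) < convergence_px:
                    break
        # residual + bounds checks on the finest level
        pts = (landmarks.positions + g)[:, None, :] + offsets[None, :, :]
        resid = np.abs(_sample(pyr[0], pts) - templates[0]).mean(axis=1)
        pos = landmarks.positions + g
        inb = (
            (pos[:, 0] >= margin)
            & (pos[:, 0] <= w - 1 - margin)
            & (pos[:, 1] >= margin)
            & (pos[:, 1] <= h - 1 - margin)
        )
        alive &= (resid <= residual_threshold) & inb
        disp.append(g.copy())
        valid.append(alive)
        g = g.copy()

    d = np.stack(disp)  # (T, N, 2)
    return DisplacementField(
        dx=d[..., 0],
        dy=d[..., 1],
        valid=np.stack(valid),
        ids=landmarks.ids.copy(),
        ref_positions=landmarks.positions.copy(),
        fps=fps,
    )


# ---------------------------------------------------------------------------
# global-motion compensation and ROI reduction


def compensate_global_motion(
    field: DisplacementField, artifact_threshold_px: float = 1.0
) -> tuple[DisplacementField, np.ndarray]:
    """Remove whole-face translation and flag artifact frames.

    The per-frame median displacement over all valid landmarks estimates
    rigid camera/bed motion (the median is robust as long as a genuine
    ROI response moves well under half the landmarks); it is subtracted
    from every landmark.  Frames whose pre-subtraction median magnitude
    exceeds ``artifact_threshold_px`` are flagged so downstream trials
    overlapping them can be excluded, mirroring the raters' artifact rule.
    """
    t_n = field.n_frames
    med = np.zeros((t_n, 2))
    for t in range(t_n):
        v = field.valid[t]
        if v.any():
            med[t, 0] = np.median(field.dx[t, v])
            med[t, 1] = np.median(field.dy[t, v])
    flags = np.hypot(med[:, 0], med[:, 1]) > artifact_threshold_px
    out = DisplacementField(
        dx=field.dx - med[:, 0][:, None],
        dy=field.dy - med[:, 1][:, None],
        valid=field.valid.copy(),
        ids=field.ids.copy(),
        ref_positions=field.ref_positions.copy(),
        fps=field.fps,
    )
    return out, flags


def summarize_roi(field: DisplacementField, roi: ROISpec) -> ROITrace:
    """Reduce the field to the ROI's summed movement trace.

    Landmarks are assigned to the ROI by their reference-frame position.
    ``values[t]`` sums ``|d_t - d_{t-1}|`` over landmarks valid in both
    frames; frame 0 is zero.
    """
    inside = roi.contains(field.ref_positions)
    if not inside.any():
        raise ROIError(f"ROI {roi.roi_id!r} contains no landmarks")
    sx, sy = field.step()
    step_mag = np.hypot(sx, sy)
    both = field.valid.copy()
    both[1:] &= field.valid[:-1]
    use = both & inside[None, :]
    values = np.where(use, step_mag, 0.0).sum(axis=1)
    values[0] = 0.0
    n_lm = (field.valid & inside[None, :]).sum(axis=1)
    return ROITrace(roi_id=roi.roi_id, values=values, n_landmarks=n_lm, fps=field.fps)


def roi_mean_displacement(
    field: DisplacementField, roi: ROISpec, statistic: str = "mean"
) -> np.ndarray:
    """Per-frame displacement magnitude of valid inside-ROI landmarks.

    This is the cumulative (relative to frame 0) signal used to recover
    injected movement amplitudes; the ROITrace, by contrast, is a rate.
    ``statistic="median"`` is robust to the minority of landmarks sitting
    on the tapered ROI boundary, so it estimates the plateau amplitude of
    a uniform ROI movement with less bias than the mean.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    inside = roi.contains(field.ref_positions)
    if not inside.any():
        raise ROIError(f"ROI {roi.roi_id!r} contains no landmarks")
    mag = field.magnitude()
    out = np.zeros(field.n_frames)
    for t in range(field.n_frames):
        use = field.valid[t] & inside
        if use.any():
            vals = mag[t, use]
            out[t] = vals.mean() if statistic == "mean" else np.median(vals)
    return out
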