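"""Movement heatmap overlays (per-command summary images)."""

from __future__ import annotations

import numpy as np
from matplotlib import colormaps
from scipy import ndimage
from scipy.interpolate import griddata

from .tracking import DisplacementField


def render_heatmap(
    field: DisplacementField,
    frame: np.ndarray,
    window: tuple[int, int],
    cmap: str = "inferno",
    alpha: float = 0.65,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Overlay interpolated movement magnitude on a video frame.

    Each landmark contributes its mean frame-to-frame displacement
    magnitude over ``window`` (inclusive frame indices); the sparse values
    are linearly interpolated across the frame, lightly smoothed, and
    blended over the grayscale frame with the given colormap.  Returns
    (RGB uint8 image with the input frame's dimensions, (vmin, vmax)
    color-scale bounds for the caller's legend).
    """
    t0, t1 = window
    if t1 < t0:
        raise ValueError("empty heatmap window")
    t1 = min(t1, field.n_frames - 1)
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape

    sx, sy = field.step()
    mag = np.hypot(sx, sy)[t0 : t1 + 1]
    valid = field.valid[t0 : t1 + 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        per_lm = np.where(valid, mag, np.nan)
        values = np.nanmean(per_lm, axis=0)
    values = np.nan_to_num(values)

    grid_y, grid_x = np.mgrid[0:h, 0:w]
    heat = griddata(
        field.ref_positions[:, ::-1],  # (y, x)
        values,
        (grid_y, grid_x),
        method="linear",
        fill_value=0.0,
    )
    heat = ndimage.gaussian_filter(heat, 2.0)
    vmin, vmax = 0.0, float(heat.max())
    norm = heat / vmax if vmax > 0 else np.zeros_like(heat)

    rgb_heat = colormaps[cmap](norm)[..., :3]
    gray = (frame / 255.0)[..., None].repeat(3, axis=-1)
    blend = (1 - alpha * norm[..., None]) * gray + alpha * norm[..., None] * rgb_heat
    return (np.clip(blend, 0, 1) * 255).astype(np.uint8), (vmin, vmax)
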