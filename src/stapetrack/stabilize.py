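"""Global-motion removal by NCC template registration on a reference patch.

Each frame is registered, translation-only, against the reference ROI (the
cochlear-promontory patch) extracted from the reference frame.  Rotation and
zoom are assumed negligible at fixed magnification.  The normalized
cross-correlation peak is refined to sub-pixel precision by quadratic
interpolation, and each frame is resampled by the negated shift with
bilinear interpolation so the scene holds still while local tendon motion
survives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.feature import match_template

from .io import FrameSequence, RegionOfInterest


class DegenerateTemplateError(ValueError):
    """The reference patch has no intensity variance to register against."""


@dataclass
class ShiftTrace:
    """Per-frame sub-pixel translation relative to the reference frame.

    ``quality`` is the peak normalized cross-correlation in [-1, 1];
    ``interpolated`` flags frames whose correlation fell below the confidence
    floor and whose shift was filled in from neighbours.
    """

    dx: np.ndarray
    dy: np.ndarray
    quality: np.ndarray
    interpolated: np.ndarray

    def __len__(self) -> int:
        return len(self.dx)

    @property
    def max_shift_px(self) -> float:
        """Largest absolute shift component; downstream ROIs within this
        margin of a frame edge see edge-padded pixels."""
        return float(max(np.max(np.abs(self.dx)), np.max(np.abs(self.dy))))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "frame": np.arange(len(self.dx)),
                "dx": self.dx,
                "dy": self.dy,
                "quality": self.quality,
                "interpolated": self.interpolated,
            }
        )


def _lk_refine(
    frame: np.ndarray,
    template: np.ndarray,
    grads: tuple[np.ndarray, np.ndarray],
    origin: tuple[int, int],
    dx: float,
    dy: float,
    iterations: int = 8,
    eps: float = 1e-3,
) -> tuple[float, float]:
    """Polish an integer/parabolic NCC shift by gradient-descent SSD matching.

    Quadratic interpolation of the correlation peak carries a pixel-locking
    bias of a few hundredths of a pixel, which is large against the
    displacement noise floor downstream; a few Gauss–Newton iterations on
    the brightness-constancy residual remove it.
    """
    gy, gx = grads
    gxx = np.sum(gx * gx)
    gxy = np.sum(gx * gy)
    gyy = np.sum(gy * gy)
    det = gxx * gyy - gxy * gxy
    if det <= 1e-9:
        return dx, dy
    x0, y0 = origin
    th, tw = template.shape
    yy, xx = np.mgrid[0:th, 0:tw].astype(float)
    frame = np.asarray(frame, dtype=float)
    for _ in range(iterations):
        patch = map_coordinates(
            frame, [yy + y0 + dy, xx + x0 + dx], order=1, mode="nearest"
        )
        r = patch - template
        bx = np.sum(gx * r)
        by = np.sum(gy * r)
        ddx = (gyy * bx - gxy * by) / det
        ddy = (gxx * by - gxy * bx) / det
        dx -= ddx
        dy -= ddy
        if abs(ddx) < eps and abs(ddy) < eps:
            break
    return dx, dy


def _parabolic_offset(cm1: float, c0: float, cp1: float) -> float:
    denom = cm1 - 2 * c0 + cp1
    if denom >= 0:  # not a local max; keep the integer peak
        return 0.0
    off = 0.5 * (cm1 - cp1) / denom
    return float(np.clip(off, -0.5, 0.5))


def estimate_shift(
    frame: np.ndarray,
    template: np.ndarray,
    template_origin: tuple[int, int],
    search_radius_px: int = 20,
    refine: bool = True,
) -> tuple[float, float, float]:
    """Locate ``template`` in ``frame`` around its nominal origin.

    Returns ``(dx, dy, quality)`` where the shift maximizes normalized
    cross-correlation over a ``±search_radius_px`` window, refined to
    sub-pixel first by quadratic interpolation of the correlation peak and
    then by Gauss–Newton brightness-constancy iterations (``refine``);
    ``quality`` is the peak NCC value.
    """
    if search_radius_px < 1:
        raise ValueError("search radius must be >= 1")
    template = np.asarray(template, dtype=float)
    if template.std() == 0:
        raise DegenerateTemplateError("reference template has zero variance")
    x0, y0 = template_origin
    th, tw = template.shape
    r = search_radius_px
    ys = max(0, y0 - r)
    xs = max(0, x0 - r)
    ye = min(frame.shape[0], y0 + th + r)
    xe = min(frame.shape[1], x0 + tw + r)
    search = np.asarray(frame[ys:ye, xs:xe], dtype=float)
    if search.shape[0] < th or search.shape[1] < tw:
        raise ValueError("template larger than the search window")
    corr = match_template(search, template, pad_input=False)
    iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
    quality = float(corr[iy, ix])
    sub_y = sub_x = 0.0
    if 0 < iy < corr.shape[0] - 1:
        sub_y = _parabolic_offset(corr[iy - 1, ix], corr[iy, ix], corr[iy + 1, ix])
    if 0 < ix < corr.shape[1] - 1:
        sub_x = _parabolic_offset(corr[iy, ix - 1], corr[iy, ix], corr[iy, ix + 1])
    dy = ys + iy + sub_y - y0
    dx = xs + ix + sub_x - x0
    if refine:
        dx, dy = _lk_refine(
            frame, template, np.gradient(template), (x0, y0), dx, dy
        )
    return dx, dy, quality


def translate_frame(frame: np.ndarray, dx: float, dy: float) -> np.ndarray:
    """Shift a frame by (dx, dy) with bilinear interpolation, edge-padded."""
    h, w = frame.shape
    pad = int(np.ceil(max(abs(dx), abs(dy)))) + 1
    big = np.pad(np.asarray(frame, dtype=float), pad, mode="edge")
    y0 = pad - dy
    x0 = pad - dx
    iy = int(np.floor(y0))
    ix = int(np.floor(x0))
    fy = y0 - iy
    fx = x0 - ix
    return (
        (1 - fy) * (1 - fx) * big[iy : iy + h, ix : ix + w]
        + (1 - fy) * fx * big[iy : iy + h, ix + 1 : ix + 1 + w]
        + fy * (1 - fx) * big[iy + 1 : iy + 1 + h, ix : ix + w]
        + fy * fx * big[iy + 1 : iy + 1 + h, ix + 1 : ix + 1 + w]
    )


def _fill_low_confidence(values: np.ndarray, bad: np.ndarray) -> np.ndarray:
    if not bad.any():
        return values
    out = values.copy()
    idx = np.arange(len(values))
    good = ~bad
    if not good.any():
        return out  # nothing to interpolate from; keep raw estimates
    out[bad] = np.interp(idx[bad], idx[good], values[good])
    return out


def stabilize_sequence(
    seq: FrameSequence,
    reference_roi: RegionOfInterest,
    reference_frame: int = 0,
    search_radius_px: int = 20,
    quality_floor: float = 0.5,
) -> tuple[FrameSequence, ShiftTrace]:
    """Register every frame to the reference patch and undo the shifts.

    Frames whose peak correlation falls below ``quality_floor`` are flagged
    and their shift linearly interpolated from confident neighbours.  Output
    frames keep the input dtype and dimensions; borders exposed by the shift
    are edge-padded (see :attr:`ShiftTrace.max_shift_px`).
    """
    reference_roi.validate_in(seq.shape)
    template = reference_roi.extract(seq.frames[reference_frame]).astype(float)
    n = len(seq)
    dx = np.zeros(n)
    dy = np.zeros(n)
    quality = np.ones(n)
    for k in range(n):
        if k == reference_frame:
            continue
        dx[k], dy[k], quality[k] = estimate_shift(
            seq.frames[k], template, (reference_roi.x, reference_roi.y), search_radius_px
        )
    bad = quality < quality_floor
    bad[reference_frame] = False
    dx = _fill_low_confidence(dx, bad)
    dy = _fill_low_confidence(dy, bad)
    dx[np.abs(dx) < 1e-6] = 0.0
    dy[np.abs(dy) < 1e-6] = 0.0

    out = np.empty_like(seq.frames)
    is_int = np.issubdtype(seq.frames.dtype, np.integer)
    for k in range(n):
        if dx[k] == 0 and dy[k] == 0:
            out[k] = seq.frames[k]
            continue
        shifted = translate_frame(seq.frames[k], -dx[k], -dy[k])
        out[k] = np.clip(np.round(shifted), 0, 255) if is_int else shifted
    trace = ShiftTrace(dx=dx, dy=dy, quality=quality, interpolated=bad)
    return FrameSequence(out, fps=seq.fps, timestamps=seq.timestamps), trace
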