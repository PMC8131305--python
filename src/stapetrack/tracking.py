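"""Pyramidal Kanade–Lucas–Tomasi point tracking on stabilized frames.

Each marker is followed frame-to-frame by the iterative Lucas–Kanade
solution of the translation-only brightness-constancy equations over a
Gaussian image pyramid.  Every step is validated by re-tracking backwards:
a marker whose backward track misses its origin by more than
``fb_error_max_px``, or whose window leaves the frame, is invalidated and
stays invalid (prefix-monotone validity) until an explicit re-detection
event replaces it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .io import FrameSequence
from .markers import MarkerSet


class TrackingFailureError(RuntimeError):
    """All markers lost; carries the frame index where tracking collapsed."""

    def __init__(self, frame_index: int):
        super().__init__(f"all markers lost at frame {frame_index}")
        self.frame_index = frame_index


@dataclass(frozen=True)
class KLTParams:
    window_px: int = 21
    pyramid_levels: int = 3
    max_iterations: int = 30
    convergence_eps_px: float = 0.01
    fb_error_max_px: float = 1.0

    def __post_init__(self) -> None:
        if self.window_px < 5 or self.window_px % 2 == 0:
            raise ValueError("window must be odd and >= 5")
        if self.pyramid_levels < 1:
            raise ValueError("at least one pyramid level required")
        if self.fb_error_max_px <= 0:
            raise ValueError("fb_error_max_px must be positive")


@dataclass
class TrajectorySet:
    """Per-marker, per-frame sub-pixel positions with validity flags.

    ``positions[f, m]`` is (x, y); ``valid[f, m]`` is False from the frame a
    marker is lost onwards.  ``baseline_positions`` anchors displacement
    measurements at each marker's track start.
    """

    positions: np.ndarray  # (n_frames, n_markers, 2)
    valid: np.ndarray  # (n_frames, n_markers)
    baseline_positions: np.ndarray  # (n_markers, 2)
    fps: float = 50.0

    @property
    def n_markers(self) -> int:
        return self.positions.shape[1]

    def to_dataframe(self):
        import pandas as pd

        f, m = np.meshgrid(
            np.arange(self.positions.shape[0]),
            np.arange(self.positions.shape[1]),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "frame": f.ravel(),
                "marker_id": m.ravel(),
                "x": self.positions[..., 0].ravel(),
                "y": self.positions[..., 1].ravel(),
                "valid": self.valid.ravel(),
            }
        )


def _pyramid(img: np.ndarray, levels: int) -> list[np.ndarray]:
    out = [np.asarray(img, dtype=float)]
    for _ in range(levels - 1):
        sm = gaussian_filter(out[-1], 1.0)
        out.append(sm[::2, ::2])
    return out


def _sample(img: np.ndarray, coords_xy: np.ndarray) -> np.ndarray:
    """Bilinear sample at (..., 2) (x, y) coordinates, edge-clamped."""
    h, w = img.shape
    x = np.clip(coords_xy[..., 0], 0.0, w - 1.0)
    y = np.clip(coords_xy[..., 1], 0.0, h - 1.0)
    ix = np.minimum(x.astype(np.intp), w - 2)
    iy = np.minimum(y.astype(np.intp), h - 2)
    fx = x - ix
    fy = y - iy
    flat = img.ravel()
    base = iy * w + ix
    v00 = flat[base]
    v01 = flat[base + 1]
    v10 = flat[base + w]
    v11 = flat[base + w + 1]
    return (
        (1 - fy) * ((1 - fx) * v00 + fx * v01) + fy * ((1 - fx) * v10 + fx * v11)
    )


class _TemplateData:
    """Per-level window samples and gradient normal matrices for fixed points."""

    def __init__(
        self,
        pyr: list[np.ndarray],
        pts: np.ndarray,
        params: KLTParams,
        finest_only: bool = False,
    ):
        half = params.window_px // 2
        oy, ox = np.mgrid[-half : half + 1, -half : half + 1]
        self.offs = np.stack([ox.ravel(), oy.ravel()], axis=-1).astype(float)
        self.levels: dict[int, tuple] = {}
        self.shape = pyr[0].shape
        for lv in range(1 if finest_only else len(pyr)):
            img = pyr[lv]
            if min(img.shape) <= params.window_px:
                continue
            gy_img, gx_img = np.gradient(img)
            win = pts[:, None, :] / (2.0**lv) + self.offs[None, :, :]
            T = _sample(img, win)
            gx = _sample(gx_img, win)
            gy = _sample(gy_img, win)
            gxx = np.sum(gx * gx, axis=1)
            gxy = np.sum(gx * gy, axis=1)
            gyy = np.sum(gy * gy, axis=1)
            det = gxx * gyy - gxy * gxy
            self.levels[lv] = (T, gx, gy, gxx, gxy, gyy, det)
        if not self.levels:
            raise ValueError("frame too small for the tracking window")


def _lk_solve(
    tpl: _TemplateData,
    curr_pyr: list[np.ndarray],
    pts: np.ndarray,
    params: KLTParams,
    init: np.ndarray | None = None,
    coarse_to_fine: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative LK displacement of fixed template points into ``curr_pyr``.

    ``init`` seeds the displacement guess (e.g. the previous frame's
    solution); with a good seed only the finest level is solved
    (``coarse_to_fine=False``).  Returns (new positions, success flags).
    """
    n = len(pts)
    half = params.window_px // 2
    g = np.zeros((n, 2)) if init is None else np.asarray(init, dtype=float).copy()
    ok = np.ones(n, dtype=bool)
    levels = sorted(tpl.levels, reverse=True) if coarse_to_fine else [min(tpl.levels)]
    for lv in levels:
        T, gx, gy, gxx, gxy, gyy, det = tpl.levels[lv]
        scale = 2.0**lv
        curr = curr_pyr[lv]
        solvable = det > 1e-6
        ok &= solvable
        safe_det = np.where(solvable, det, 1.0)
        p = pts / scale
        win = p[:, None, :] + tpl.offs[None, :, :]
        g_lv = g / scale
        for _ in range(params.max_iterations):
            I = _sample(curr, win + g_lv[:, None, :])
            r = T - I
            bx = np.sum(gx * r, axis=1)
            by = np.sum(gy * r, axis=1)
            dx = (gyy * bx - gxy * by) / safe_det
            dy = (gxx * by - gxy * bx) / safe_det
            g_lv[:, 0] += dx
            g_lv[:, 1] += dy
            if np.max(np.hypot(dx, dy), initial=0.0) < params.convergence_eps_px / scale:
                break
        g = g_lv * scale
    new = pts + g
    h, w = tpl.shape
    inside = (
        (new[:, 0] >= half)
        & (new[:, 0] <= w - 1 - half)
        & (new[:, 1] >= half)
        & (new[:, 1] <= h - 1 - half)
    )
    return new, ok & inside & np.all(np.isfinite(new), axis=1)


def _lk_step(
    prev_pyr: list[np.ndarray],
    curr_pyr: list[np.ndarray],
    pts: np.ndarray,
    params: KLTParams,
    init: np.ndarray | None = None,
    coarse_to_fine: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """One multi-level LK solve for a batch of points (template built ad hoc)."""
    tpl = _TemplateData(prev_pyr, pts, params)
    return _lk_solve(tpl, curr_pyr, pts, params, init=init, coarse_to_fine=coarse_to_fine)


def track(
    seq: FrameSequence,
    markers: MarkerSet,
    params: KLTParams = KLTParams(),
    template_image: np.ndarray | None = None,
    frame_offsets: np.ndarray | None = None,
) -> TrajectorySet:
    """Track every marker through the sequence with forward–backward checks.

    Each frame is solved against the marker's birth-frame template
    (anchored tracking), with the previous frame's displacement as the
    initial guess — frame-to-frame initialisation without frame-to-frame
    drift accumulation.  The backward re-track from the solution to the
    template frame must land within ``fb_error_max_px`` of the marker's
    origin.  ``frame_offsets`` (n_frames, 2) seeds the guess with known
    global motion, letting markers be tracked on unstabilized frames whose
    template was cut from a stabilized reference.  Raises
    :class:`TrackingFailureError` if all markers are lost at any frame.
    Identical inputs give bit-identical trajectories.
    """
    if len(markers) < 1:
        raise ValueError("at least one marker required")
    n_frames = len(seq)
    n = len(markers)
    off = np.zeros((n_frames, 2)) if frame_offsets is None else np.asarray(frame_offsets, float)
    if off.shape != (n_frames, 2):
        raise ValueError("frame_offsets must be (n_frames, 2)")
    positions = np.zeros((n_frames, n, 2))
    valid = np.zeros((n_frames, n), dtype=bool)
    positions[0] = markers.points + off[0]
    valid[0] = True

    origin = markers.points
    tpl_img = seq.frames[0] if template_image is None else template_image
    tpl_pyr = _pyramid(tpl_img, params.pyramid_levels)
    tpl_full = _TemplateData(tpl_pyr, origin, params)
    for k in range(n_frames - 1):
        curr_pyr = _pyramid(seq.frames[k + 1], params.pyramid_levels)
        active = valid[k]
        positions[k + 1] = positions[k]
        if active.any():
            idx = np.flatnonzero(active)
            base = origin[active]
            tpl = tpl_full if active.all() else _TemplateData(tpl_pyr, base, params)
            guess = positions[k, active] - base + (off[k + 1] - off[k])
            # coarse-to-fine only for acquisition; afterwards the previous
            # frame seeds the finest level directly
            fwd, ok_f = _lk_solve(
                tpl, curr_pyr, base, params, init=guess, coarse_to_fine=(k == 0)
            )
            back_tpl = _TemplateData(curr_pyr, fwd, params, finest_only=True)
            back, ok_b = _lk_solve(
                back_tpl, tpl_pyr, fwd, params, init=base - fwd, coarse_to_fine=False
            )
            fb_err = np.hypot(*(back - base).T)
            ok = ok_f & ok_b & (fb_err <= params.fb_error_max_px)
            new_valid = np.zeros(n, dtype=bool)
            new_valid[idx[ok]] = True
            pos_next = positions[k].copy()
            pos_next[active] = np.where(ok[:, None], fwd, positions[k, active])
            positions[k + 1] = pos_next
            valid[k + 1] = new_valid
        if not valid[k + 1].any():
            raise TrackingFailureError(k + 1)
    return TrajectorySet(
        positions=positions,
        valid=valid,
        baseline_positions=markers.points.copy(),
        fps=seq.fps,
    )


def displacement_magnitudes(traj: TrajectorySet) -> np.ndarray:
    """Euclidean distance of each marker from its baseline, per frame.

    Shape (n_frames, n_markers); entries are NaN where the track is invalid.
    """
    d = np.linalg.norm(traj.positions - traj.baseline_positions[None, :, :], axis=-1)
    return np.where(traj.valid, d, np.nan)
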