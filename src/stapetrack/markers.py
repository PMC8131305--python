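"""Marker seeding inside the tendon ROI via maximally stable extremal regions.

An extremal region is a connected component of a thresholded image; sweeping
the threshold over the 8-bit range, a region is *maximally stable* where its
area changes least across ``delta`` threshold steps.  Each stable region is
summarised by its second-moment (equivalent) ellipse, and marker points are
the ellipse centers, thinned by a greedy separation rule so the tracker gets
a handful of well-spread, geometrically distinctive points.

Both polarities (bright-on-dark and dark-on-bright) are detected, so the
result is symmetric under intensity inversion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.measure import regionprops

from .io import RegionOfInterest


@dataclass(frozen=True)
class MSERParams:
    """Stability-sweep parameters on the 8-bit intensity scale.

    ``max_area_px`` of ``None`` means 20% of the ROI area — large enough to
    admit blob-scale regions in small tendon ROIs while still rejecting the
    trivial whole-ROI component.
    """

    delta: int = 5
    min_area_px: int = 30
    max_area_px: int | None = None
    max_variation: float = 0.25

    def __post_init__(self) -> None:
        if self.delta < 1:
            raise ValueError("delta must be >= 1")
        if self.min_area_px <= 0:
            raise ValueError("min_area_px must be positive")
        if self.max_area_px is not None and self.max_area_px <= self.min_area_px:
            raise ValueError("max_area_px must exceed min_area_px")
        if self.max_variation <= 0:
            raise ValueError("max_variation must be positive")

    def resolved_max_area(self, roi_area: int) -> int:
        if self.max_area_px is not None:
            return self.max_area_px
        return max(self.min_area_px + 1, int(0.2 * roi_area))


@dataclass(frozen=True)
class EllipseRegion:
    """A stable region summarised by its equivalent ellipse.

    ``center`` is sub-pixel, in full-image coordinates.  ``orientation_rad``
    follows the scikit-image convention (angle from the vertical axis to the
    major axis, in (-pi/2, pi/2]).
    """

    center: tuple[float, float]
    major_axis_px: float
    minor_axis_px: float
    orientation_rad: float
    pixel_count: int
    polarity: str = "bright"  # bright | dark

    def __post_init__(self) -> None:
        if self.minor_axis_px < 0 or self.major_axis_px < self.minor_axis_px:
            raise ValueError("axes must satisfy major >= minor >= 0")


@dataclass
class MarkerSet:
    """Selected sub-pixel marker points and the separation rule they satisfy."""

    points: np.ndarray  # (n, 2) as (x, y)
    source_regions: list[int]
    min_separation_px: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if len(self.points) >= 2:
            d = np.linalg.norm(self.points[:, None] - self.points[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() < self.min_separation_px - 1e-9:
                raise ValueError("markers violate the minimum separation")

    def __len__(self) -> int:
        return len(self.points)


def _mser_one_polarity(img: np.ndarray, params: MSERParams, max_area: int):
    """Candidate stable regions of {img >= t} over the threshold sweep.

    Region identity across thresholds follows the position of the region's
    intensity maximum; for each such chain the single most stable threshold
    (smallest relative area variation, ties to the larger area) is kept.
    Returns (threshold, label-array, label, area, variation) tuples.
    """
    labels = []
    counts = []
    tmax = int(img.max()) if img.size else 0
    tmin = int(img.min()) if img.size else 0
    for t in range(256):
        if t < tmin or t > tmax + 1:
            labels.append(None)
            counts.append(None)
            continue
        lab, n = ndimage.label(img >= t)
        labels.append(lab)
        counts.append(np.bincount(lab.ravel(), minlength=n + 1))

    best: dict[tuple[int, int], tuple] = {}
    delta = params.delta
    for t in range(max(tmin, 1), tmax + 1):
        lab = labels[t]
        if lab is None:
            continue
        n = counts[t].shape[0] - 1
        if n == 0:
            continue
        reps = ndimage.maximum_position(img, lab, index=range(1, n + 1))
        for l, rep in enumerate(reps, start=1):
            area = int(counts[t][l])
            if not (params.min_area_px <= area <= max_area):
                continue
            tp = max(t - delta, tmin)
            parent_lab = labels[tp]
            area_parent = int(counts[tp][parent_lab[rep]]) if parent_lab is not None else area
            tc = t + delta
            if tc <= tmax and labels[tc] is not None and labels[tc][rep] > 0:
                area_child = int(counts[tc][labels[tc][rep]])
            else:
                area_child = 0
            variation = (area_parent - area_child) / area
            if variation > params.max_variation:
                continue
            key = (int(rep[0]), int(rep[1]))
            prev = best.get(key)
            if prev is None or (variation, -area) < (prev[4], -prev[3]):
                best[key] = (t, lab, l, area, variation)
    return list(best.values())


def _to_region(lab: np.ndarray, l: int, roi: RegionOfInterest, polarity: str) -> EllipseRegion:
    props = regionprops((lab == l).astype(np.uint8))[0]
    cy, cx = props.centroid
    return EllipseRegion(
        center=(cx + roi.x, cy + roi.y),
        major_axis_px=float(props.axis_major_length),
        minor_axis_px=float(props.axis_minor_length),
        orientation_rad=float(props.orientation),
        pixel_count=int(props.area),
        polarity=polarity,
    )


def detect_regions(
    image: np.ndarray,
    roi: RegionOfInterest,
    params: MSERParams = MSERParams(),
) -> list[EllipseRegion]:
    """Detect maximally stable extremal regions inside ``roi``.

    Runs both polarities and returns one :class:`EllipseRegion` per stable
    chain, in deterministic (polarity, y, x) order.  A uniform-intensity ROI
    yields an empty list; so does an ROI smaller than ``min_area_px``.
    """
    if image.ndim != 2:
        raise ValueError("image must be single-channel")
    roi.validate_in(image.shape)
    patch = np.asarray(roi.extract(image), dtype=np.uint8)
    if patch.size < params.min_area_px:
        return []
    max_area = params.resolved_max_area(patch.size)
    regions: list[EllipseRegion] = []
    for polarity, img in (("bright", patch), ("dark", 255 - patch)):
        for t, lab, l, area, variation in _mser_one_polarity(img, params, max_area):
            regions.append(_to_region(lab, l, roi, polarity))
    regions.sort(key=lambda r: (r.polarity, r.center[1], r.center[0]))
    return regions


def select_markers(
    regions: Sequence[EllipseRegion],
    max_markers: int = 8,
    min_separation_px: float = 6.0,
) -> MarkerSet:
    """Greedily pick region centers as markers, largest regions first.

    Candidates are visited in descending ``pixel_count`` order (ties broken
    by (y, x) lexicographic center order) and accepted when at least
    ``min_separation_px`` away from every accepted marker, up to
    ``max_markers``.  Deterministic for a fixed input.
    """
    if max_markers < 1:
        raise ValueError("max_markers must be >= 1")
    order = sorted(
        range(len(regions)),
        key=lambda i: (-regions[i].pixel_count, regions[i].center[1], regions[i].center[0]),
    )
    chosen: list[int] = []
    pts: list[tuple[float, float]] = []
    for i in order:
        c = regions[i].center
        if all(np.hypot(c[0] - p[0], c[1] - p[1]) >= min_separation_px for p in pts):
            chosen.append(i)
            pts.append(c)
            if len(chosen) >= max_markers:
                break
    return MarkerSet(
        points=np.array(pts, dtype=float).reshape(-1, 2),
        source_regions=chosen,
        min_separation_px=min_separation_px,
    )
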