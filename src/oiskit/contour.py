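"""Fragmentation-analysis contour detection of the evoked response.

Per frame: (1) keep pixels above a high percentile (95-98) of the frame's
intensity distribution; (2) estimate the 2D probability density of those pixel
coordinates with a Gaussian KDE (Silverman bandwidth by default); (3) the
response contour is the boundary of the connected region where the density
reaches half of its maximum. A detection is valid only if the chosen response
center (seed) lies inside the contour and the contour's fullness — the
fraction of its interior occupied by supra-threshold pixels — reaches the
configured minimum (50-90%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from shapely.geometry import Point, Polygon
from skimage import measure

from .preprocess import OISMapSequence, TimeProfile

__all__ = [
    "ContourResult",
    "ContourDensityMap",
    "threshold_pixels",
    "kde_density",
    "detect_contour",
    "polygon_area_mm2",
    "contour_density",
    "area_time_course",
]


@dataclass
class ContourResult:
    polygon: np.ndarray          # closed (row, col) vertex path, or None
    area_mm2: float
    fullness: float
    contains_seed: bool
    valid: bool
    threshold_percentile: float
    frame_index: int = -1
    region_mask: np.ndarray = None   # interior pixels (density >= half max)
    reason: str = ""

    def __post_init__(self) -> None:
        if self.area_mm2 < 0:
            raise ValueError("area must be >= 0")


@dataclass
class ContourDensityMap:
    counts: np.ndarray
    n_frames: int

    def __post_init__(self) -> None:
        if self.counts.min() < 0 or self.counts.max() > self.n_frames:
            raise ValueError("counts must lie in [0, n_frames]")


def threshold_pixels(map_frame: np.ndarray, percentile: float = 95.0) -> np.ndarray:
    """(N, 2) array of (row, col) of pixels strictly above the percentile.

    The percentile is taken over all finite pixels of the whole frame, so a
    constant frame yields an empty set.
    """
    if not 0.0 <= percentile <= 100.0:
        raise ValueError("percentile must be in [0, 100]")
    frame = np.asarray(map_frame, dtype=float)
    finite = np.isfinite(frame)
    if not finite.any():
        return np.empty((0, 2), dtype=int)
    level = np.percentile(frame[finite], percentile)
    rows, cols = np.nonzero(finite & (frame > level))
    return np.column_stack([rows, cols])


class DetectionFailure(RuntimeError):
    """Raised when a density estimate cannot be formed (e.g. < 2 points)."""


def kde_density(points: np.ndarray, bandwidth=None, grid_shape: tuple = None) -> np.ndarray:
    """Gaussian-kernel density of pixel coordinates, evaluated on the grid.

    bandwidth: None -> Silverman's rule on the point coordinates; a scalar is
    passed through as the KDE bandwidth factor. The returned field integrates
    to ~1 over the grid (pixel area = 1).
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 2:
        raise DetectionFailure("need at least 2 supra-threshold pixels for KDE")
    if grid_shape is None:
        grid_shape = (int(points[:, 0].max()) + 1, int(points[:, 1].max()) + 1)
    try:
        kde = stats.gaussian_kde(points.T, bw_method=bandwidth or "silverman")
    except np.linalg.LinAlgError as exc:
        raise DetectionFailure(f"degenerate point cloud: {exc}") from exc
    rr, cc = np.mgrid[: grid_shape[0], : grid_shape[1]]
    return kde(np.vstack([rr.ravel(), cc.ravel()])).reshape(grid_shape)


def _closed(path: np.ndarray) -> np.ndarray:
    if not np.allclose(path[0], path[-1]):
        path = np.vstack([path, path[0]])
    return path


def polygon_area_mm2(polygon: np.ndarray, px_size_um: float = 35.0) -> float:
    """Shoelace area of a closed pixel-coordinate polygon, in mm^2."""
    poly = np.asarray(polygon, dtype=float)
    if poly.shape[0] < 3 or not np.allclose(poly[0], poly[-1]):
        if poly.shape[0] < 4:  # closed triangle needs 4 vertices
            raise ValueError("polygon must be closed with at least 3 distinct vertices")
        raise ValueError("polygon must be closed (first vertex == last)")
    x, y = poly[:, 0], poly[:, 1]
    area_px = 0.5 * abs(np.dot(x[:-1], y[1:]) - np.dot(x[1:], y[:-1]))
    return float(area_px) * (px_size_um / 1000.0) ** 2


def _invalid(percentile, frame_index, reason, grid_shape):
    return ContourResult(polygon=None, area_mm2=0.0, fullness=0.0,
                         contains_seed=False, valid=False,
                         threshold_percentile=percentile, frame_index=frame_index,
                         region_mask=np.zeros(grid_shape, dtype=bool), reason=reason)


def detect_contour(map_frame: np.ndarray, seed_px: tuple,
                   percentile: float = 95.0, fullness_min: float = 0.5,
                   bandwidth=None, px_size_um: float = 35.0,
                   frame_index: int = -1) -> ContourResult:
    """Detect the response contour of one OIS map frame.

    The contour is the half-maximum region of the KDE density of the
    supra-threshold pixels: the connected component containing the density
    maximum (falling back to the component containing the seed). Validity
    requires the seed inside the contour and fullness >= fullness_min.
    """
    frame = np.asarray(map_frame, dtype=float)
    grid_shape = frame.shape
    h, w = grid_shape
    if not (0 <= seed_px[0] < h and 0 <= seed_px[1] < w):
        raise ValueError(f"seed {seed_px} outside the {h}x{w} grid")
    pts = threshold_pixels(frame, percentile)
    if pts.shape[0] < 2:
        return _invalid(percentile, frame_index, "fewer than 2 supra-threshold pixels", grid_shape)
    try:
        density = kde_density(pts, bandwidth=bandwidth, grid_shape=grid_shape)
    except DetectionFailure as exc:
        return _invalid(percentile, frame_index, str(exc), grid_shape)
    level = 0.5 * density.max()
    region = density >= level
    labels = measure.label(region)
    if labels.max() == 0:
        return _invalid(percentile, frame_index, "no half-maximum region", grid_shape)
    peak_rc = np.unravel_index(np.argmax(density), grid_shape)
    lab = labels[peak_rc]
    if lab == 0 or not _component_contains(labels, lab, seed_px):
        seed_lab = labels[int(seed_px[0]), int(seed_px[1])]
        if seed_lab > 0:
            lab = seed_lab
    component = labels == lab
    polygon = _component_polygon(density, level, component)
    if polygon is None:
        return _invalid(percentile, frame_index, "no closed contour", grid_shape)
    contains_seed = bool(component[int(seed_px[0]), int(seed_px[1])]) or \
        Polygon(polygon).contains(Point(seed_px[0], seed_px[1]))
    supra = np.zeros(grid_shape, dtype=bool)
    supra[pts[:, 0], pts[:, 1]] = True
    n_inside = int(component.sum())
    fullness = float((supra & component).sum()) / n_inside if n_inside else 0.0
    valid = contains_seed and fullness >= fullness_min
    reason = "" if valid else ("seed outside contour" if not contains_seed
                               else f"fullness {fullness:.2f} < {fullness_min}")
    return ContourResult(
        polygon=polygon, area_mm2=polygon_area_mm2(polygon, px_size_um),
        fullness=fullness, contains_seed=contains_seed, valid=valid,
        threshold_percentile=percentile, frame_index=frame_index,
        region_mask=component, reason=reason)


def _component_contains(labels, lab, seed_px):
    return labels[int(seed_px[0]), int(seed_px[1])] == lab


def _component_polygon(density, level, component):
    """Sub-pixel half-maximum boundary around the chosen component.

    Traced on the raw density so the crossing interpolates between the true
    values on both sides of the level; the path containing the component's
    densest pixel is kept.
    """
    padded = np.pad(density, 1, mode="constant")
    contours = measure.find_contours(padded, level)
    rep = np.unravel_index(np.argmax(np.where(component, density, -np.inf)),
                           density.shape)
    best = None
    for path in contours:
        path = _closed(path - 1.0)
        poly = Polygon(path)
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.contains(Point(rep[0], rep[1])) or poly.intersects(Point(rep[0], rep[1])):
            if best is None or poly.area > best[1]:
                best = (path, poly.area)
    return None if best is None else best[0]


def contour_density(map_sequence: OISMapSequence, seed_px: tuple,
                    percentile: float = 95.0, fullness_min: float = 0.5,
                    bandwidth=None, frame_indices=None) -> ContourDensityMap:
    """Per-pixel count of frames whose valid contour covers the pixel."""
    maps = map_sequence.maps
    if frame_indices is None:
        frame_indices = range(maps.shape[0])
    counts = np.zeros(maps.shape[1:], dtype=int)
    n = 0
    for i in frame_indices:
        n += 1
        res = detect_contour(maps[i], seed_px, percentile=percentile,
                             fullness_min=fullness_min, bandwidth=bandwidth,
                             px_size_um=map_sequence.px_size_um, frame_index=i)
        if res.valid:
            counts += res.region_mask
    return ContourDensityMap(counts=counts, n_frames=n)


def area_time_course(map_sequence: OISMapSequence, seed_px: tuple,
                     percentile: float = 95.0, fullness_min: float = 0.5,
                     bandwidth=None, window_points: int = 12,
                     kaiser_shape: float = 2.0) -> TimeProfile:
    """Valid-contour area per frame, smoothed with a 12-point Kaiser window."""
    from .metrics import smooth_kaiser

    maps = map_sequence.maps
    areas = np.zeros(maps.shape[0])
    for i in range(maps.shape[0]):
        res = detect_contour(maps[i], seed_px, percentile=percentile,
                             fullness_min=fullness_min, bandwidth=bandwidth,
                             px_size_um=map_sequence.px_size_um, frame_index=i)
        areas[i] = res.area_mm2 if res.valid else 0.0
    if len(areas) < window_points:
        warnings.warn(f"fewer than {window_points} frames; area course left unsmoothed",
                      stacklevel=2)
        smoothed = areas
    else:
        smoothed = smooth_kaiser(areas, window_points, kaiser_shape)
    return TimeProfile(values=smoothed, time_axis_s=map_sequence.time_axis_s)
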