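"""Geometric measurements: cross-sectional area, division angles,
and tubule-diameter distribution comparison."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from shapely.geometry import LinearRing

__all__ = [
    "PolygonSeries",
    "DivisionEvent",
    "polygon_area",
    "relative_area_change",
    "division_angle",
    "compare_diameter_distributions",
]


@dataclass
class PolygonSeries:
    """Closed tubule cross-section outlines over time.

    ``polygons`` is a list of ``(n_i, 2)`` vertex arrays (px), one per
    entry of ``times``.
    """

    polygons: list[np.ndarray]
    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.polygons) != len(self.times):
            raise ValueError("one polygon per time stamp required")
        self.polygons = [_check_polygon(p) for p in self.polygons]


@dataclass(frozen=True)
class DivisionEvent:
    """Daughter-cell centroids and the tubule longitudinal axis."""

    daughter1: tuple[float, float]
    daughter2: tuple[float, float]
    axis: tuple[float, float]

    def __post_init__(self) -> None:
        if np.allclose(self.daughter1, self.daughter2):
            raise ValueError("daughter centroids must be distinct")
        if np.hypot(*self.axis) == 0:
            raise ValueError("longitudinal axis must be nonzero")


def _check_polygon(polygon) -> np.ndarray:
    pts = np.asarray(polygon, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("polygon must be an (n>=3, 2) vertex array")
    if not np.isfinite(pts).all():
        raise ValueError("polygon vertices must be finite")
    ring = LinearRing(pts)
    if not ring.is_simple:
        raise ValueError("polygon is self-intersecting; refusing to repair it")
    return pts


def polygon_area(polygon) -> float:
    """Absolute shoelace area (px^2) of a simple closed polygon."""
    pts = _check_polygon(polygon)
    x, y = pts[:, 0], pts[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def relative_area_change(series: PolygonSeries) -> np.ndarray:
    """Cross-sectional area as a fraction of the initial area per time point."""
    if len(series.polygons) < 2:
        raise ValueError("need at least 2 time points")
    areas = np.array([polygon_area(p) for p in series.polygons])
    if areas[0] == 0:
        raise ValueError("initial polygon has zero area")
    return areas / areas[0]


def division_angle(event: DivisionEvent) -> float:
    """Acute angle (degrees, in [0, 90]) between the inter-centroid
    line and the tubule longitudinal axis."""
    d = np.subtract(event.daughter2, event.daughter1)
    a = np.asarray(event.axis, dtype=float)
    cosine = abs(np.dot(d, a)) / (np.linalg.norm(d) * np.linalg.norm(a))
    return float(np.degrees(np.arccos(np.clip(cosine, -1.0, 1.0))))


def compare_diameter_distributions(group_a, group_b, n_bins: int = 10) -> dict:
    """Median diameters per group with a two-sided Mann-Whitney U test.

    Uses exact enumeration for small tie-free samples (n <= 20 each)
    and the tie-corrected normal approximation otherwise.  Returns the
    per-group medians, the U statistic, the p-value, and a shared-bin
    histogram summary of both distributions.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size <= 20 and b.size <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    edges = np.histogram_bin_edges(np.concatenate([a, b]), bins=n_bins)
    return {
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "u_statistic": float(res.statistic),
        "pvalue": float(res.pvalue),
        "method": method,
        "histogram": {
            "edges": edges.tolist(),
            "counts_a": np.histogram(a, bins=edges)[0].tolist(),
            "counts_b": np.histogram(b, bins=edges)[0].tolist(),
        },
    }
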