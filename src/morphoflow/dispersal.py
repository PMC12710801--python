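"""Cell-cluster dispersal statistics and trend-comparison inference.

Clusters of 4-8 cells sharing a convergent point (within a 15 px
radius) are followed over time; dispersal is quantified as the
*standard distance* — the square root of the summed per-axis mean
squared deviations of member positions from their centroid.  Trunk
dynamics are summarized by a linear fit and compared between groups by
an ANCOVA slope-homogeneity F-test; tip dynamics by a quadratic fit
whose coefficient vectors are compared by two-sample Hotelling T^2
tests with Benjamini-Hochberg FDR adjustment.  Rosette detection and
track speed round out the per-cell measurements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "TrajectorySet",
    "CellCluster",
    "DispersalSeries",
    "TrendFit",
    "HotellingResult",
    "identify_clusters",
    "standard_distance",
    "dispersal_series",
    "normalize_series",
    "fit_linear_trend",
    "fit_quadratic_trend",
    "compare_slopes_ancova",
    "compare_slopes_per_cluster",
    "hotelling_t2",
    "adjust_fdr",
    "detect_rosettes",
    "track_speed",
]

TRUNK_WINDOW_MIN = 8 * 60.0  # analysis window for trunk clusters
TIP_WINDOW_MIN = 2 * 60.0  # shorter, more informative window for tip clusters


@dataclass
class TrajectorySet:
    """Per-cell tracks in pixel coordinates.

    ``data`` holds one row per cell per frame with columns
    ``track_id, frame, x, y`` and optionally ``z`` and ``cluster_id``;
    ``dt`` is the frame interval in minutes.
    """

    data: pd.DataFrame
    dt: float = 1.0

    def __post_init__(self) -> None:
        required = {"track_id", "frame", "x", "y"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"trajectory table missing columns {sorted(missing)}")
        if not np.isfinite(self.data[["x", "y"]].to_numpy(dtype=float)).all():
            raise ValueError("trajectory coordinates must be finite")
        self.data = self.data.sort_values(["track_id", "frame"]).reset_index(drop=True)
        grp = self.data.groupby("track_id")["frame"]
        if (grp.diff().dropna() <= 0).any():
            raise ValueError("frames must be strictly increasing within a track")

    @property
    def track_ids(self) -> np.ndarray:
        return self.data["track_id"].unique()

    def track(self, track_id) -> pd.DataFrame:
        return self.data[self.data["track_id"] == track_id]

    def positions_at(self, frame: int) -> pd.DataFrame:
        """Rows of all tracks alive at ``frame``."""
        return self.data[self.data["frame"] == frame]

    def positions_of(self, track_ids, frame: int) -> np.ndarray:
        sel = self.data[(self.data["frame"] == frame)
                        & self.data["track_id"].isin(track_ids)]
        if len(sel) != len(track_ids):
            missing = set(track_ids) - set(sel["track_id"])
            raise KeyError(f"tracks {sorted(missing)} not present at frame {frame}")
        return sel[["x", "y"]].to_numpy(dtype=float)


@dataclass(frozen=True)
class CellCluster:
    """A convergent group of 4-8 tracks selected at reference frame t0."""

    members: tuple
    t0: int
    convergent_point: tuple[float, float]
    cluster_id: int = 0
    group: str = ""

    def __post_init__(self) -> None:
        if not (4 <= len(self.members) <= 8):
            raise ValueError("cluster must have between 4 and 8 members")


@dataclass
class DispersalSeries:
    """Standard distance against time for one cluster."""

    times: np.ndarray  # minutes
    values: np.ndarray  # px (or dimensionless if normalized)
    cluster_id: int = 0
    group: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.normalized and self.values.size and abs(self.values[0] - 1.0) > 1e-12:
            raise ValueError("normalized series must start at 1")


@dataclass
class TrendFit:
    """Polynomial trend coefficients for one dispersal series.

    ``coefficients`` is (a, b) for the linear model a*t + b, or
    (a, b, c) for the quadratic a*t^2 + b*t + c.
    """

    model: str
    coefficients: tuple
    n: int
    residual_variance: float
    cluster_id: int = 0
    group: str = ""

    def __post_init__(self) -> None:
        expect = {"linear": 2, "quadratic": 3}[self.model]
        if len(self.coefficients) != expect:
            raise ValueError(f"{self.model} fit needs {expect} coefficients")


@dataclass
class HotellingResult:
    t2: float
    f: float
    df: tuple[int, int]
    pvalue: float
    groups: tuple[str, str] = ("A", "B")
    pvalue_adjusted: float | None = None


def standard_distance(points: np.ndarray) -> float:
    """Root of the summed per-axis mean squared deviations from the centroid.

    ``points`` is an ``(n, 2)`` array of (x, y) pixel coordinates with
    n >= 2.  Equivalent to the square root of the trace of the (biased)
    covariance matrix, hence invariant under rotation and translation.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] < 2:
        raise ValueError("points must be an (n, >=2) array")
    if pts.shape[0] < 2:
        raise ValueError("standard distance needs at least 2 points")
    xy = pts[:, :2]
    dev = xy - xy.mean(axis=0)
    return float(np.sqrt(np.mean(dev[:, 0] ** 2) + np.mean(dev[:, 1] ** 2)))


def identify_clusters(tracks: TrajectorySet, t0: int, radius: float = 15.0,
                      min_size: int = 4, max_size: int = 8, seed: int = 0,
                      allow_overlap: bool = False) -> list[CellCluster]:
    """Select clusters of cells sharing a convergent point at frame t0.

    Every cell position at ``t0`` whose ``radius``-neighbourhood holds
    at least ``min_size`` cells (itself included) is a candidate
    convergent point.  Candidates are visited in seeded random order;
    each cluster draws up to ``max_size`` members at random from the
    unused tracks in the neighbourhood.  By default a track joins at
    most one cluster.  Deterministic for a fixed seed.
    """
    alive = tracks.positions_at(t0)
    if len(alive) < min_size:
        return []
    rng = np.random.default_rng(seed)
    ids = alive["track_id"].to_numpy()
    xy = alive[["x", "y"]].to_numpy(dtype=float)
    order = np.argsort(ids, kind="stable")  # deterministic candidate enumeration
    ids, xy = ids[order], xy[order]

    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=-1)
    within = d2 <= radius * radius
    candidates = [i for i in range(len(ids)) if within[i].sum() >= min_size]
    rng.shuffle(candidates)

    used: set = set()
    clusters: list[CellCluster] = []
    for i in candidates:
        nbrs = [j for j in np.flatnonzero(within[i])
                if allow_overlap or ids[j] not in used]
        if len(nbrs) < min_size:
            continue
        if len(nbrs) > max_size:
            nbrs = list(rng.choice(nbrs, size=max_size, replace=False))
        members = tuple(sorted(ids[j] for j in nbrs))
        used.update(members)
        clusters.append(CellCluster(
            members=members, t0=t0,
            convergent_point=(float(xy[i, 0]), float(xy[i, 1])),
            cluster_id=len(clusters),
        ))
    return clusters


def dispersal_series(cluster: CellCluster, tracks: TrajectorySet,
                     t_end: int | None = None) -> DispersalSeries:
    """Standard distance of the cluster members at every frame in [t0, t_end].

    Raises ``KeyError`` if any member track ends before ``t_end`` — the
    caller should drop (and log) such clusters rather than truncate.
    """
    if t_end is None:
        member_rows = tracks.data[tracks.data["track_id"].isin(cluster.members)]
        t_end = int(member_rows.groupby("track_id")["frame"].max().min())
    frames = np.arange(cluster.t0, t_end + 1)
    values = np.empty(frames.shape)
    for k, f in enumerate(frames):
        values[k] = standard_distance(tracks.positions_of(cluster.members, int(f)))
    return DispersalSeries(times=(frames - cluster.t0) * tracks.dt, values=values,
                           cluster_id=cluster.cluster_id, group=cluster.group)


def collect_dispersal_series(clusters: list[CellCluster], tracks: TrajectorySet,
                             t_end: int | None = None) -> tuple[list[DispersalSeries], int]:
    """Series for every cluster whose members survive; returns (series, n_dropped)."""
    out, dropped = [], 0
    for c in clusters:
        try:
            out.append(dispersal_series(c, tracks, t_end))
        except KeyError as exc:
            dropped += 1
            logger.warning("cluster %d excluded: %s", c.cluster_id, exc)
    return out, dropped


def normalize_series(series: DispersalSeries) -> DispersalSeries:
    """Divide every value by the first; the first value becomes 1."""
    if series.values.size == 0 or series.values[0] <= 0:
        raise ValueError("cannot normalize a series whose first value is not > 0")
    return DispersalSeries(times=series.times.copy(),
                           values=series.values / series.values[0],
                           cluster_id=series.cluster_id, group=series.group,
                           normalized=True)


def _polyfit(series: DispersalSeries, degree: int, model: str) -> TrendFit:
    t, y = series.times, series.values
    if len(t) < degree + 2:
        raise ValueError(f"{model} fit needs at least {degree + 2} points")
    if np.ptp(t) == 0:
        raise ValueError("all time points identical")
    design = np.vander(t, degree + 1)
    if np.linalg.matrix_rank(design) < degree + 1:
        raise ValueError("rank-deficient design (too few distinct time points)")
    coef, res, *_ = np.linalg.lstsq(design, y, rcond=None)
    rss = float(res[0]) if res.size else float(np.sum((y - design @ coef) ** 2))
    dof = len(t) - (degree + 1)
    return TrendFit(model=model, coefficients=tuple(float(c) for c in coef),
                    n=len(t), residual_variance=rss / dof if dof > 0 else float("nan"),
                    cluster_id=series.cluster_id, group=series.group)


def fit_linear_trend(series: DispersalSeries) -> TrendFit:
    """Ordinary least squares y = a*t + b; coefficients (a, b)."""
    return _polyfit(series, 1, "linear")


def fit_quadratic_trend(series: DispersalSeries) -> TrendFit:
    """Ordinary least squares y = a*t^2 + b*t + c; coefficients (a, b, c)."""
    return _polyfit(series, 2, "quadratic")


def compare_slopes_ancova(group_a: list[DispersalSeries],
                          group_b: list[DispersalSeries]) -> tuple[float, float]:
    """Slope-homogeneity F-test between two groups of dispersal series.

    All (time, value) points are pooled per group and the nested models

        reduced:  y ~ 1 + group + t          (common slope)
        full:     y ~ 1 + group + t + group:t

    are compared by their residual sums of squares; the F statistic for
    the interaction term tests equality of the two regression slopes.
    Returns ``(F, p)``.
    """
    for name, grp in (("A", group_a), ("B", group_b)):
        if len(grp) < 2:
            raise ValueError(f"group {name} needs at least 2 series")
    t = np.concatenate([s.times for s in group_a] + [s.times for s in group_b])
    y = np.concatenate([s.values for s in group_a] + [s.values for s in group_b])
    g = np.concatenate([np.zeros(sum(s.times.size for s in group_a)),
                        np.ones(sum(s.times.size for s in group_b))])
    n = len(t)
    ones = np.ones(n)
    x_red = np.column_stack([ones, g, t])
    x_full = np.column_stack([ones, g, t, g * t])
    rss_red = _rss(x_red, y)
    rss_full = _rss(x_full, y)
    df2 = n - x_full.shape[1]
    if df2 <= 0:
        raise ValueError("not enough points for the interaction test")
    if rss_full <= 1e-300 * max(rss_red, 1.0):
        return float("inf"), 0.0
    f = (rss_red - rss_full) / 1.0 / (rss_full / df2)
    p = float(stats.f.sf(f, 1, df2))
    return float(f), p


def _rss(x: np.ndarray, y: np.ndarray) -> float:
    coef, res, *_ = np.linalg.lstsq(x, y, rcond=None)
    if res.size:
        return float(res[0])
    return float(np.sum((y - x @ coef) ** 2))


def compare_slopes_per_cluster(group_a: list[DispersalSeries],
                               group_b: list[DispersalSeries]) -> tuple[float, float]:
    """Alternative reading: two-sample t-test on per-cluster fitted slopes."""
    sa = [fit_linear_trend(s).coefficients[0] for s in group_a]
    sb = [fit_linear_trend(s).coefficients[0] for s in group_b]
    res = stats.ttest_ind(sa, sb)
    return float(res.statistic), float(res.pvalue)


def hotelling_t2(coeffs_a, coeffs_b, groups: tuple[str, str] = ("A", "B")) -> HotellingResult:
    """Two-sample Hotelling T^2 test on coefficient vectors.

    With pooled covariance S and mean difference d over samples of size
    n1, n2 in p dimensions:

        T^2 = n1*n2/(n1+n2) * d' S^-1 d
        F = T^2 * (n1+n2-p-1) / (p*(n1+n2-2))  on  (p, n1+n2-p-1) df
    """
    a = np.atleast_2d(np.asarray(coeffs_a, dtype=float))
    b = np.atleast_2d(np.asarray(coeffs_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must have the same coefficient dimension")
    n1, n2, p = a.shape[0], b.shape[0], a.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    if n1 + n2 < p + 2:
        raise ValueError(f"n1+n2={n1 + n2} too small for p={p} dimensions")
    d = a.mean(axis=0) - b.mean(axis=0)
    s_pooled = ((n1 - 1) * np.cov(a, rowvar=False, ddof=1).reshape(p, p)
                + (n2 - 1) * np.cov(b, rowvar=False, ddof=1).reshape(p, p)) / (n1 + n2 - 2)
    try:
        sol = np.linalg.solve(s_pooled, d)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"singular pooled covariance (condition unbounded): {exc}; "
            "coefficients may be collinear or groups too small"
        ) from exc
    t2 = float(n1 * n2 / (n1 + n2) * d @ sol)
    t2 = max(t2, 0.0)
    df2 = n1 + n2 - p - 1
    f = t2 * df2 / (p * (n1 + n2 - 2))
    pval = float(stats.f.sf(f, p, df2))
    return HotellingResult(t2=t2, f=float(f), df=(p, df2), pvalue=pval, groups=groups)


def adjust_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1D sequence")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def detect_rosettes(label_image: np.ndarray, min_cells: int = 5,
                    radius: int = 2) -> list[dict]:
    """Find vertices where at least ``min_cells`` labelled cells meet.

    For every pixel, the set of distinct nonzero labels within the
    ``(2*radius+1)``-square neighbourhood is collected; pixels seeing at
    least ``min_cells`` labels mark rosette vertices, and 8-connected
    runs of such pixels are merged into one rosette reported with its
    centroid and the union of participating labels.
    """
    lab = np.asarray(label_image)
    if lab.ndim != 2:
        raise ValueError("label image must be 2D")
    if lab.size == 0 or not (lab > 0).any():
        return []
    h, w = lab.shape
    k = 2 * radius + 1
    padded = np.pad(lab, radius, mode="constant", constant_values=0)
    stack = np.empty((h, w, k * k), dtype=lab.dtype)
    idx = 0
    for dy in range(k):
        for dx in range(k):
            stack[:, :, idx] = padded[dy:dy + h, dx:dx + w]
            idx += 1
    stack.sort(axis=-1)
    distinct = (np.diff(stack, axis=-1) != 0).sum(axis=-1) + 1
    distinct -= (stack[:, :, 0] == 0).astype(int)  # background is not a cell
    hot = distinct >= min_cells

    rosettes = []
    merged = measure.label(hot, connectivity=2)
    for region in measure.regionprops(merged):
        ys, xs = region.coords[:, 0], region.coords[:, 1]
        labels: set = set()
        for y, x in zip(ys, xs):
            vals = stack[y, x]
            labels.update(int(v) for v in vals if v != 0)
        cy, cx = region.centroid
        rosettes.append({"vertex": (float(cx), float(cy)),
                         "labels": tuple(sorted(labels))})
    return rosettes


def track_speed(track: np.ndarray | pd.DataFrame, dt: float) -> float:
    """Total path length divided by elapsed time (px/min).

    ``track`` is an ``(n, 2+)`` array of ordered (x, y[, z]) samples or
    a per-track frame of a :class:`TrajectorySet`; ``dt`` is the frame
    interval in minutes.
    """
    if isinstance(track, pd.DataFrame):
        cols = ["x", "y"] + (["z"] if "z" in track.columns else [])
        pts = track.sort_values("frame")[cols].to_numpy(dtype=float)
    else:
        pts = np.asarray(track, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("track speed needs at least 2 samples")
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return float(steps.sum() / ((pts.shape[0] - 1) * dt))
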