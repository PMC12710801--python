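"""Coarse-grained 3D particle image velocimetry and motion-coherence maps.

Displacement fields are estimated between consecutive frames by
zero-mean normalized cross-correlation of interrogation windows against
margin-extended search regions, with per-axis three-point sub-voxel peak
refinement.  Downstream summaries: mean speed, per-node motion
similarity against in-plane neighbours, and line-based coherence
profiles along the tissue long axis.

Conventions
-----------
Volumes are indexed ``[z, y, x]`` with 0-based voxel coordinates.
Vector components are reported in ``(u, v, w)`` = ``(x, y, z)`` image
order, i.e. ``u`` is displacement along the fastest-varying axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import match_template

__all__ = [
    "PivParams",
    "VelocityField",
    "SimilarityMap",
    "grid_starts",
    "grid_centers",
    "compute_piv",
    "mean_speed",
    "motion_similarity_map",
    "coherence_profile",
    "coherence_profile_series",
]


@dataclass(frozen=True)
class PivParams:
    """Interrogation parameters, given per axis in (x, y, z) order.

    ``window`` is the interrogation window size, ``overlap`` the tiling
    overlap between adjacent windows, and ``search_margin`` the extra
    extent searched in the second frame on each side of the window.
    Windows whose intensity variance falls below ``min_signal_variance``
    times the frame variance, or whose first-to-second correlation peak
    ratio falls below ``peak_ratio_threshold``, are marked invalid.
    """

    window: tuple[int, int, int] = (32, 32, 7)
    overlap: tuple[int, int, int] = (8, 8, 3)
    search_margin: tuple[int, int, int] = (10, 10, 3)
    min_signal_variance: float = 0.01
    peak_ratio_threshold: float = 1.2

    def __post_init__(self) -> None:
        for w, o in zip(self.window, self.overlap):
            if not (0 <= o < w):
                raise ValueError(
                    f"overlap {self.overlap} must satisfy 0 <= overlap < window "
                    f"{self.window} on every axis"
                )
        if any(m < 0 for m in self.search_margin):
            raise ValueError(f"search margins must be >= 0, got {self.search_margin}")
        if self.min_signal_variance < 0:
            raise ValueError("min_signal_variance must be >= 0")

    @property
    def window_zyx(self) -> tuple[int, int, int]:
        return self.window[::-1]

    @property
    def step_zyx(self) -> tuple[int, int, int]:
        return tuple(w - o for w, o in zip(self.window_zyx, self.overlap[::-1]))

    @property
    def margin_zyx(self) -> tuple[int, int, int]:
        return self.search_margin[::-1]


@dataclass
class VelocityField:
    """Displacement vectors on a coarse grid of interrogation windows.

    ``vectors`` has shape ``(nz, ny, nx, 3)`` holding ``(u, v, w)`` in
    px/frame; ``centers`` has the matching window-center voxel
    coordinates in ``(z, y, x)`` order; ``valid`` masks nodes that
    passed signal and peak-ratio checks.
    """

    centers: np.ndarray
    vectors: np.ndarray
    valid: np.ndarray
    frame_pair: tuple[int, int] = (0, 1)
    dt: float = 1.0
    params: PivParams = field(default_factory=PivParams)

    def __post_init__(self) -> None:
        if self.vectors.shape[:-1] != self.valid.shape:
            raise ValueError("vectors and validity mask disagree in grid shape")
        if not np.all(np.isfinite(self.vectors[self.valid])):
            raise ValueError("valid vectors must be finite")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.valid.shape

    def speeds(self) -> np.ndarray:
        """Euclidean vector norms, NaN at invalid nodes."""
        s = np.linalg.norm(self.vectors, axis=-1)
        return np.where(self.valid, s, np.nan)


@dataclass
class SimilarityMap:
    """Per-node scalar motion similarity on the velocity-field grid."""

    values: np.ndarray
    valid: np.ndarray
    mode: str = "normalized"

    def __post_init__(self) -> None:
        if self.values.shape != self.valid.shape:
            raise ValueError("values and validity mask disagree in shape")
        if self.mode == "normalized":
            ok = self.values[self.valid]
            if ok.size and (np.nanmax(ok) > 1 + 1e-9 or np.nanmin(ok) < -1 - 1e-9):
                raise ValueError("normalized similarity must lie in [-1, 1]")


def grid_starts(shape_zyx: tuple[int, int, int], params: PivParams) -> list[np.ndarray]:
    """Window start indices per (z, y, x) axis.

    Tiling begins at the search margin and runs with step
    ``window - overlap``; windows whose margin-extended search region
    would leave the volume are dropped.
    """
    starts = []
    for n, w, s, m in zip(shape_zyx, params.window_zyx, params.step_zyx, params.margin_zyx):
        last = n - w - m
        if last < m:
            starts.append(np.array([], dtype=int))
        else:
            starts.append(np.arange(m, last + 1, s))
    return starts


def grid_centers(shape_zyx: tuple[int, int, int], params: PivParams) -> np.ndarray:
    """Window-center voxel coordinates, shape ``(nz, ny, nx, 3)`` in (z,y,x)."""
    starts = grid_starts(shape_zyx, params)
    w = params.window_zyx
    axes = [s + (wi - 1) / 2.0 for s, wi in zip(starts, w)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    return np.stack([zz, yy, xx], axis=-1)


def _subpixel_offset(cm: float, c0: float, cp: float) -> float:
    """Per-axis peak refinement from three correlation samples.

    Three-point Gaussian fit; falls back to a parabolic fit when any
    sample is non-positive (log undefined).
    """
    if cm > 0 and c0 > 0 and cp > 0:
        lm, l0, lp = np.log(cm), np.log(c0), np.log(cp)
        denom = 2.0 * lm - 4.0 * l0 + 2.0 * lp
        if denom < 0:
            return float((lm - lp) / denom)
    denom = 2.0 * cm - 4.0 * c0 + 2.0 * cp
    if denom < 0:
        return float((cm - cp) / denom)
    return 0.0


def _peak_ratio(corr: np.ndarray, peak_idx: tuple[int, ...]) -> float:
    """First-to-second peak ratio; second peak excludes the 3^3 block at the first."""
    first = corr[peak_idx]
    masked = corr.copy()
    sl = tuple(
        slice(max(i - 1, 0), min(i + 2, n)) for i, n in zip(peak_idx, corr.shape)
    )
    masked[sl] = -np.inf
    second = float(masked.max())
    if not np.isfinite(second) or second <= 0:
        return np.inf
    return float(first) / second


def compute_piv(frame_a: np.ndarray, frame_b: np.ndarray, params: PivParams | None = None,
                dt: float = 1.0, frame_pair: tuple[int, int] = (0, 1)) -> VelocityField:
    """Estimate a coarse displacement field between two volumes.

    Each interrogation window of ``frame_a`` is correlated
    (zero-mean normalized) against the search region of ``frame_b``
    extended by the search margin on every side; the correlation peak
    is refined per axis to sub-voxel precision.

    Parameters
    ----------
    frame_a, frame_b:
        3D volumes of identical shape, each axis at least
        ``window + 2 * margin``.
    params:
        Interrogation settings; defaults to :class:`PivParams`.

    Returns
    -------
    VelocityField
        Vectors ``(u, v, w)`` in px/frame such that positive ``u``
        means content moved toward +x between the frames.
    """
    params = params or PivParams()
    a = np.asarray(frame_a, dtype=np.float64)
    b = np.asarray(frame_b, dtype=np.float64)
    if a.ndim != 3 or b.ndim != 3:
        raise ValueError("compute_piv expects 3D volumes (z, y, x)")
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    w = params.window_zyx
    m = params.margin_zyx
    for n, wi, mi in zip(a.shape, w, m):
        if n < wi + 2 * mi:
            raise ValueError(
                f"volume shape {a.shape} too small for window {w} with margin {m}"
            )

    starts = grid_starts(a.shape, params)
    grid_shape = tuple(len(s) for s in starts)
    vectors = np.zeros(grid_shape + (3,), dtype=np.float64)
    valid = np.zeros(grid_shape, dtype=bool)
    var_floor = params.min_signal_variance * float(a.var())

    for iz, z0 in enumerate(starts[0]):
        for iy, y0 in enumerate(starts[1]):
            for ix, x0 in enumerate(starts[2]):
                win = a[z0:z0 + w[0], y0:y0 + w[1], x0:x0 + w[2]]
                if win.var() < var_floor:
                    continue
                region = b[z0 - m[0]:z0 + w[0] + m[0],
                           y0 - m[1]:y0 + w[1] + m[1],
                           x0 - m[2]:x0 + w[2] + m[2]]
                corr = match_template(region, win, pad_input=False)
                peak = np.unravel_index(int(np.argmax(corr)), corr.shape)
                if corr[peak] <= 0:
                    continue
                if _peak_ratio(corr, peak) < params.peak_ratio_threshold:
                    continue
                # a peak at exactly 1 is a perfect match; refinement can
                # only add bias from asymmetric correlation flanks
                refine = corr[peak] < 1.0 - 1e-9
                disp = np.empty(3)
                for ax in range(3):
                    i = peak[ax]
                    lag = i - m[ax]
                    if refine and 0 < i < corr.shape[ax] - 1:
                        lo = list(peak); lo[ax] = i - 1
                        hi = list(peak); hi[ax] = i + 1
                        lag += _subpixel_offset(
                            corr[tuple(lo)], corr[peak], corr[tuple(hi)]
                        )
                    disp[ax] = lag
                # disp is (z, y, x); store as (u, v, w) = (x, y, z)
                vectors[iz, iy, ix] = disp[::-1]
                valid[iz, iy, ix] = True

    return VelocityField(
        centers=grid_centers(a.shape, params),
        vectors=vectors,
        valid=valid,
        frame_pair=frame_pair,
        dt=dt,
        params=params,
    )


def mean_speed(fld: VelocityField, pixel_size: float | None = None,
               dt_minutes: float | None = None) -> float:
    """Arithmetic mean of vector norms over valid nodes.

    Returned in px/frame, or in um/min when both ``pixel_size``
    (um/px) and ``dt_minutes`` (min/frame) are given.
    """
    if not fld.valid.any():
        raise ValueError("velocity field has no valid nodes")
    speeds = np.linalg.norm(fld.vectors[fld.valid], axis=-1)
    out = float(speeds.mean())
    if pixel_size is not None and dt_minutes is not None:
        out *= pixel_size / dt_minutes
    return out


_INPLANE_NEIGHBOURS = ((0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))
_3D_NEIGHBOURS = _INPLANE_NEIGHBOURS + ((1, 0, 0), (-1, 0, 0))


def motion_similarity_map(fld: VelocityField, mode: str = "normalized",
                          neighbourhood: str = "inplane") -> SimilarityMap:
    """Per-node mean scalar product with neighbouring vectors.

    For every valid node the dot product with each available valid
    neighbour is averaged.  The default neighbourhood is the in-plane
    4-neighbourhood (+/-x, +/-y at the same z slab); ``neighbourhood=
    "3d"`` adds the +/-z neighbours.  In ``normalized`` mode both
    vectors are unit-normalized first (cosine similarity); zero vectors
    cannot be normalized and invalidate their node.  In ``raw`` mode
    the plain scalar product is used, conflating alignment and speed.
    """
    if mode not in ("normalized", "raw"):
        raise ValueError(f"unknown similarity mode {mode!r}")
    if neighbourhood not in ("inplane", "3d"):
        raise ValueError(f"unknown neighbourhood {neighbourhood!r}")
    nz, ny, nx = fld.grid_shape
    if ny < 2 or nx < 2:
        raise ValueError("similarity needs >= 2 grid nodes per in-plane axis")

    vec = fld.vectors.astype(np.float64)
    ok = fld.valid.copy()
    if mode == "normalized":
        norms = np.linalg.norm(vec, axis=-1)
        nonzero = norms > 0
        ok &= nonzero
        vec = np.where(nonzero[..., None], vec / np.where(nonzero, norms, 1.0)[..., None], 0.0)

    offsets = _INPLANE_NEIGHBOURS if neighbourhood == "inplane" else _3D_NEIGHBOURS
    acc = np.zeros(fld.grid_shape)
    cnt = np.zeros(fld.grid_shape, dtype=int)
    for dz, dy, dx in offsets:
        shifted_vec = np.roll(vec, (dz, dy, dx), axis=(0, 1, 2))
        shifted_ok = np.roll(ok, (dz, dy, dx), axis=(0, 1, 2))
        edge = np.ones(fld.grid_shape, dtype=bool)
        # np.roll wraps; mask the wrapped border on the shifted axis
        for ax, d in zip(range(3), (dz, dy, dx)):
            if d == 1:
                sl = [slice(None)] * 3
                sl[ax] = slice(0, 1)
                edge[tuple(sl)] = False
            elif d == -1:
                sl = [slice(None)] * 3
                sl[ax] = slice(-1, None)
                edge[tuple(sl)] = False
        use = ok & shifted_ok & edge
        acc[use] += np.einsum("...i,...i->...", vec, shifted_vec)[use]
        cnt[use] += 1

    has_nbr = cnt > 0
    values = np.full(fld.grid_shape, np.nan)
    values[has_nbr] = acc[has_nbr] / cnt[has_nbr]
    if mode == "normalized":
        values = np.clip(values, -1.0, 1.0)
    return SimilarityMap(values=values, valid=ok & has_nbr, mode=mode)


def _line_rows(n_cross: int, n_lines: int) -> np.ndarray:
    """Nearest grid rows for equidistant lines at fractions k/(n_lines+1)."""
    fracs = np.arange(1, n_lines + 1) / (n_lines + 1)
    return np.round(fracs * (n_cross - 1)).astype(int)


def coherence_profile(sim: SimilarityMap, n_lines: int = 3, axis: str = "x",
                      z_index: int | None = None) -> list[dict]:
    """Mean and SD of similarity along equidistant parallel lines.

    Lines run parallel to the tissue long axis (``axis``, "x" or "y")
    at cross-axis fractions ``k/(n_lines+1)``, sampling the nearest
    grid row.  Operates on one z slab of the map (middle by default).

    Returns one record per line with keys ``line``, ``row``, ``mean``,
    ``sd``, ``n``; lines whose sampled nodes are all invalid report
    ``mean``/``sd`` as NaN with ``n = 0`` rather than a fabricated
    value.
    """
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    values, valid = sim.values, sim.valid
    if values.ndim == 3:
        zi = values.shape[0] // 2 if z_index is None else z_index
        values, valid = values[zi], valid[zi]
    if values.ndim != 2:
        raise ValueError("similarity map must be 2D or 3D")
    if axis == "y":
        values, valid = values.T, valid.T
    n_cross = values.shape[0]
    if n_cross < n_lines:
        raise ValueError(
            f"grid cross-axis extent {n_cross} cannot host {n_lines} distinct lines"
        )
    out = []
    for k, row in enumerate(_line_rows(n_cross, n_lines), start=1):
        vals = values[row][valid[row]]
        rec = {"line": k, "row": int(row), "n": int(vals.size)}
        if vals.size:
            rec["mean"] = float(vals.mean())
            rec["sd"] = float(vals.std(ddof=0))
        else:
            rec["mean"] = float("nan")
            rec["sd"] = float("nan")
        out.append(rec)
    return out


def coherence_profile_series(maps: list[SimilarityMap], n_lines: int = 3,
                             axis: str = "x", z_index: int | None = None) -> list[dict]:
    """Per-time coherence profile: one record per (time, line)."""
    out = []
    for t, sim in enumerate(maps):
        for rec in coherence_profile(sim, n_lines=n_lines, axis=axis, z_index=z_index):
            out.append({"time": t, **rec})
    return out
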