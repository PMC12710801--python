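"""Seeded generators for every input the analysis pipeline consumes.

Four families of fixtures, each carrying its ground truth:

* particle-texture movies advected by prescribed 3D velocity fields
  (validation input for the velocimetry module),
* clustered cell trajectories whose standard-distance-vs-time curve
  follows prescribed linear or quadratic dynamics,
* branching-tree images with a known terminal-tip count,
* division-angle samples from uniform or concentrated distributions.

All randomness flows through one ``numpy.random.Generator`` seeded per
call; a fixed seed gives bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage

from morphoflow.velocimetry import PivParams, grid_centers

__all__ = [
    "FlowSpec",
    "ClusterDynamicsSpec",
    "TubuleTreeSpec",
    "FlowMovie",
    "generate_flow_movie",
    "generate_cluster_trajectories",
    "generate_tree_image",
    "random_tree_spec",
    "generate_division_angles",
]

FLOW_KINDS = ("uniform", "rotation", "shear", "split", "random-jitter")


@dataclass(frozen=True)
class FlowSpec:
    """Recipe for an advected particle-texture movie.

    ``displacement`` (px/frame, in (x, y, z) order) parameterizes the
    ``uniform`` and ``split`` kinds; ``angular_rate`` (rad/frame) the
    in-plane ``rotation`` about the volume centre; ``shear_rate``
    (px/frame per px of y) the ``shear`` kind; ``jitter_scale``
    (px/frame RMS) the ``random-jitter`` kind.
    """

    kind: str = "uniform"
    shape: tuple[int, int, int] = (16, 96, 96)  # (Z, Y, X) voxels
    n_frames: int = 2
    displacement: tuple[float, float, float] = (0.0, 0.0, 0.0)
    angular_rate: float = 0.0
    shear_rate: float = 0.0
    jitter_scale: float = 0.0
    density: float = 0.003  # particles per voxel
    particle_sigma: float = 1.5
    noise_sigma: float = 0.0
    boundary: str = "periodic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in FLOW_KINDS:
            raise ValueError(f"unknown flow kind {self.kind!r}; one of {FLOW_KINDS}")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.density <= 0:
            raise ValueError("particle density must be > 0")
        if self.boundary not in ("periodic", "pad"):
            raise ValueError("boundary must be 'periodic' or 'pad'")


@dataclass
class FlowMovie:
    """Generated movie plus the ground truth it was advected with."""

    frames: np.ndarray  # (T, Z, Y, X)
    spec: FlowSpec
    truth_centers: np.ndarray  # (nz, ny, nx, 3) voxel coords (z, y, x)
    truth_vectors: np.ndarray  # (T-1, nz, ny, nx, 3) components (u, v, w)
    warnings: list[str] = field(default_factory=list)

    def displacement_at(self, points_zyx: np.ndarray) -> np.ndarray:
        """Evaluate the prescribed per-frame displacement (u, v, w) at points."""
        return _field_displacement(self.spec, np.asarray(points_zyx, dtype=float))


def _field_displacement(spec: FlowSpec, points_zyx: np.ndarray) -> np.ndarray:
    """Per-frame displacement vectors, components (u, v, w), at (z, y, x) points."""
    pts = np.asarray(points_zyx, dtype=float).reshape(-1, 3)
    z, y, x = pts[:, 0], pts[:, 1], pts[:, 2]
    out = np.zeros((pts.shape[0], 3))
    if spec.kind == "uniform":
        out[:] = spec.displacement
    elif spec.kind == "rotation":
        # linearized rigid rotation about the in-plane volume centre:
        # |d| = angular_rate * radius exactly
        cy = (spec.shape[1] - 1) / 2.0
        cx = (spec.shape[2] - 1) / 2.0
        out[:, 0] = -spec.angular_rate * (y - cy)
        out[:, 1] = spec.angular_rate * (x - cx)
    elif spec.kind == "shear":
        out[:, 0] = spec.shear_rate * y
    elif spec.kind == "split":
        # two opposing halves along y, moving +/- displacement
        half = np.where(y < spec.shape[1] / 2.0, 1.0, -1.0)
        out[:] = half[:, None] * np.asarray(spec.displacement)
    elif spec.kind == "random-jitter":
        # smooth incoherent field, frozen in time, from a seeded stream
        rng = np.random.default_rng(spec.seed + 104729)
        coarse = rng.normal(size=(3, 8, 8, 8))
        coarse = ndimage.gaussian_filter(coarse, sigma=(0, 1.0, 1.0, 1.0))
        rms = np.sqrt(np.mean(coarse ** 2))
        coarse *= spec.jitter_scale / max(rms, 1e-12)
        scale = [7.0 / max(s - 1, 1) for s in spec.shape]
        coords = np.stack([z * scale[0], y * scale[1], x * scale[2]])
        for c in range(3):
            out[:, 2 - c] = ndimage.map_coordinates(
                coarse[c], coords, order=1, mode="nearest"
            )
    return out.reshape(points_zyx.shape[:-1] + (3,)) if points_zyx.ndim > 1 else out[0]


def _render_particles(spec: FlowSpec, rng: np.random.Generator) -> np.ndarray:
    """Gaussian blobs at Poisson-distributed positions (periodic-safe)."""
    n = rng.poisson(spec.density * np.prod(spec.shape))
    n = max(int(n), 1)
    pos = rng.uniform(0, 1, size=(n, 3)) * np.asarray(spec.shape)
    img = np.zeros(spec.shape)
    zi = np.clip(np.round(pos[:, 0]).astype(int), 0, spec.shape[0] - 1)
    yi = np.clip(np.round(pos[:, 1]).astype(int), 0, spec.shape[1] - 1)
    xi = np.clip(np.round(pos[:, 2]).astype(int), 0, spec.shape[2] - 1)
    np.add.at(img, (zi, yi, xi), 1.0)
    mode = "wrap" if spec.boundary == "periodic" else "constant"
    return ndimage.gaussian_filter(img, sigma=spec.particle_sigma, mode=mode)


def generate_flow_movie(spec: FlowSpec, piv_params: PivParams | None = None) -> FlowMovie:
    """Render a particle texture and advect it frame to frame.

    Frame ``t+1`` is frame ``t`` advected by the prescribed field via
    cubic-spline resampling (semi-Lagrangian backward lookup), with
    independent Gaussian noise added afterwards.  The ground-truth
    displacement field is evaluated on the coarse grid the velocimetry
    module will use for ``piv_params`` (defaults).

    A displacement magnitude exceeding the PIV search margin is not an
    error, but a warning is recorded: the velocimetry stage cannot
    recover such motion.
    """
    piv_params = piv_params or PivParams()
    rng = np.random.default_rng(spec.seed)
    warn: list[str] = []

    centers = grid_centers(spec.shape, piv_params)
    truth = np.empty((spec.n_frames - 1,) + centers.shape)
    zz, yy, xx = np.meshgrid(*(np.arange(s, dtype=float) for s in spec.shape),
                             indexing="ij")
    dense_pts = np.stack([zz, yy, xx], axis=-1)
    disp = _field_displacement(spec, dense_pts)  # (Z, Y, X, 3) as (u, v, w)
    margin_xyz = piv_params.search_margin
    max_comp = np.abs(disp).reshape(-1, 3).max(axis=0)
    if np.any(max_comp > np.asarray(margin_xyz)):
        msg = (f"max displacement {tuple(np.round(max_comp, 2))} (x,y,z) exceeds "
               f"search margin {margin_xyz}; PIV cannot recover it")
        warn.append(msg)
        warnings.warn(msg, stacklevel=2)

    # backward-lookup coordinates: frame_{t+1}(x) = frame_t(x - d(x))
    lookup = np.stack([
        zz - disp[..., 2],
        yy - disp[..., 1],
        xx - disp[..., 0],
    ])
    mode = "grid-wrap" if spec.boundary == "periodic" else "constant"

    clean = np.empty((spec.n_frames,) + spec.shape)
    clean[0] = _render_particles(spec, rng)
    for t in range(spec.n_frames - 1):
        clean[t + 1] = ndimage.map_coordinates(clean[t], lookup, order=3, mode=mode)
        truth[t] = _field_displacement(spec, centers)

    frames = clean.copy()
    if spec.noise_sigma > 0:
        frames += rng.normal(0.0, spec.noise_sigma, size=frames.shape)
    return FlowMovie(frames=frames, spec=spec, truth_centers=centers,
                     truth_vectors=truth, warnings=warn)


# ---------------------------------------------------------------------------
# clustered trajectories


@dataclass(frozen=True)
class ClusterDynamicsSpec:
    """Recipe for cell clusters with a prescribed dispersal curve.

    ``model`` is ``("linear", a, b)`` giving target SD(t) = a*t + b, or
    ``("quadratic", a, b, c)`` giving a*t^2 + b*t + c, with t in
    minutes (frame index times ``dt``).  Cells are placed equally
    spaced on a circle of radius SD(t) about the cluster centroid and
    jittered isotropically with ``jitter_sigma``; with zero jitter the
    measured standard distance equals the target exactly.
    """

    n_clusters: int = 4
    cells_per_cluster: int = 6
    model: tuple = ("linear", 1.0, 10.0)
    jitter_sigma: float = 0.0
    dt: float = 10.0  # min/frame
    n_frames: int = 12
    drift: tuple[float, float] = (0.0, 0.0)  # common centroid drift px/frame
    spacing: float = 400.0  # centroid separation, px
    seed: int = 0

    def __post_init__(self) -> None:
        if not (4 <= self.cells_per_cluster <= 8):
            raise ValueError("cells_per_cluster must lie in [4, 8]")
        if self.n_clusters < 1 or self.n_frames < 2:
            raise ValueError("need >= 1 cluster and >= 2 frames")
        kind = self.model[0]
        if kind == "linear":
            if len(self.model) != 3:
                raise ValueError("linear model is ('linear', a, b)")
        elif kind == "quadratic":
            if len(self.model) != 4:
                raise ValueError("quadratic model is ('quadratic', a, b, c)")
        else:
            raise ValueError(f"unknown dispersal model {kind!r}")
        t = np.arange(self.n_frames) * self.dt
        if np.any(self.target_sd(t) <= 0):
            raise ValueError("target SD(t) must be > 0 at every generated frame")

    def target_sd(self, t: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.model[0] == "linear":
            a, b = self.model[1:]
            return a * t + b
        a, b, c = self.model[1:]
        return a * t * t + b * t + c


def generate_cluster_trajectories(spec: ClusterDynamicsSpec):
    """Build a :class:`~morphoflow.dispersal.TrajectorySet` of clustered cells.

    Returns ``(tracks, truth)`` where ``truth`` maps cluster id to the
    prescribed model coefficients.  Cluster centroids sit on a coarse
    grid (separation ``spec.spacing``) so clusters never mingle; each
    cluster's cells ride a circle of radius ``target_sd(t)`` at equally
    spaced angles with a per-cluster random phase.
    """
    from morphoflow.dispersal import TrajectorySet

    rng = np.random.default_rng(spec.seed)
    t_min = np.arange(spec.n_frames) * spec.dt
    radius = spec.target_sd(t_min)
    rows = []
    truth: dict[int, tuple] = {}
    n_side = int(np.ceil(np.sqrt(spec.n_clusters)))
    track_id = 0
    for ci in range(spec.n_clusters):
        cx0 = (ci % n_side) * spec.spacing
        cy0 = (ci // n_side) * spec.spacing
        phase = rng.uniform(0, 2 * np.pi)
        angles = phase + 2 * np.pi * np.arange(spec.cells_per_cluster) / spec.cells_per_cluster
        jit = rng.normal(0.0, spec.jitter_sigma,
                         size=(spec.n_frames, spec.cells_per_cluster, 2)) \
            if spec.jitter_sigma > 0 else np.zeros((spec.n_frames, spec.cells_per_cluster, 2))
        for k in range(spec.cells_per_cluster):
            x = cx0 + spec.drift[0] * np.arange(spec.n_frames) \
                + radius * np.cos(angles[k]) + jit[:, k, 0]
            y = cy0 + spec.drift[1] * np.arange(spec.n_frames) \
                + radius * np.sin(angles[k]) + jit[:, k, 1]
            for f in range(spec.n_frames):
                rows.append((track_id + k, ci, f, x[f], y[f], 0.0))
        truth[ci] = spec.model
        track_id += spec.cells_per_cluster

    import pandas as pd

    data = pd.DataFrame(rows, columns=["track_id", "cluster_id", "frame", "x", "y", "z"])
    return TrajectorySet(data=data, dt=spec.dt), truth


# ---------------------------------------------------------------------------
# branching trees


@dataclass(frozen=True)
class TubuleTreeSpec:
    """A connected tree of thick segments rendered into an image.

    ``segments`` holds ``((x0, y0), (x1, y1), width_px)`` triples that
    must form one connected tree; the ground-truth tip count is the
    number of degree-1 nodes of the segment graph.
    """

    segments: tuple
    shape: tuple[int, int] = (192, 192)
    blur_sigma: float = 1.0
    background: float = 0.05
    background_gradient: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        g = self.graph()
        if g.number_of_nodes() and not nx.is_connected(g):
            raise ValueError("segments must form a single connected tree")

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for (p0, p1, _w) in self.segments:
            g.add_edge(tuple(np.round(p0, 6)), tuple(np.round(p1, 6)))
        return g

    @property
    def ground_truth_tips(self) -> int:
        g = self.graph()
        return sum(1 for _n, d in g.degree() if d == 1)


def generate_tree_image(spec: TubuleTreeSpec) -> tuple[np.ndarray, int]:
    """Render the tree as anti-aliased thick segments plus blur/noise.

    Returns ``(image, ground_truth_tips)``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    img = np.zeros(spec.shape)
    for (x0, y0), (x1, y1), width in spec.segments:
        dx, dy = x1 - x0, y1 - y0
        L2 = dx * dx + dy * dy
        if L2 == 0:
            d = np.hypot(xx - x0, yy - y0)
        else:
            t = np.clip(((xx - x0) * dx + (yy - y0) * dy) / L2, 0.0, 1.0)
            d = np.hypot(xx - (x0 + t * dx), yy - (y0 + t * dy))
        # soft 1-px anti-aliasing ramp at the half-width boundary
        img = np.maximum(img, np.clip(width / 2.0 + 0.5 - d, 0.0, 1.0))
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma)
    img = img + spec.background + spec.background_gradient * (xx / max(w - 1, 1))
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return img, spec.ground_truth_tips


def random_tree_spec(seed: int, shape: tuple[int, int] = (192, 192),
                     depth: int = 3, branch_prob: float = 0.85,
                     noise_sigma: float = 0.0) -> TubuleTreeSpec:
    """A random binary tree grown from the image bottom edge.

    Segment lengths and branching angles are bounded so branches stay
    inside the frame, remain longer than typical spur-pruning lengths,
    and do not collapse onto each other.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    segments = []

    def grow(p0, angle, length, width, level):
        p1 = (p0[0] + length * np.sin(angle), p0[1] - length * np.cos(angle))
        p1 = (float(np.clip(p1[0], 8, w - 8)), float(np.clip(p1[1], 8, h - 8)))
        segments.append((p0, p1, width))
        if level >= depth or rng.uniform() > branch_prob:
            return
        spread = rng.uniform(0.45, 0.8)
        child_len = length * rng.uniform(0.55, 0.7)
        if child_len < 18:
            return
        grow(p1, angle - spread, child_len, max(width * 0.85, 2.5), level + 1)
        grow(p1, angle + spread, child_len, max(width * 0.85, 2.5), level + 1)

    root = (w / 2.0 + rng.uniform(-10, 10), h - 10.0)
    grow(root, rng.uniform(-0.25, 0.25), h * 0.38, 5.0, 0)
    return TubuleTreeSpec(segments=tuple(segments), shape=shape,
                          noise_sigma=noise_sigma, seed=seed)


# ---------------------------------------------------------------------------
# division angles


def generate_division_angles(n: int, distribution=("uniform",), seed: int = 0) -> np.ndarray:
    """Sample division angles in degrees, folded into [0, 90].

    ``distribution`` is ``("uniform",)`` for U(0, 90) or
    ``("vonmises", mu_deg, kappa)`` for a concentrated distribution
    around ``mu_deg`` (von Mises on the doubled angle, then folded).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    kind = distribution[0]
    if kind == "uniform":
        return rng.uniform(0.0, 90.0, size=n)
    if kind == "vonmises":
        _, mu, kappa = distribution
        raw = np.degrees(rng.vonmises(np.radians(2.0 * mu), kappa, size=n)) / 2.0
        folded = np.abs(raw) % 180.0
        return np.where(folded > 90.0, 180.0 - folded, folded)
    raise ValueError(f"unknown angle distribution {kind!r}")
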