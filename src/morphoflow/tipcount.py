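"""Branching-tip quantification by skeleton endpoint counting.

Pipeline: maximum intensity projection (3D input), rolling-ball
background subtraction, Gaussian blur, threshold, small-component
removal, morphological thinning to a 1-px skeleton, iterative spur
pruning, then an endpoint census — every skeleton pixel with exactly
one 8-connected skeleton neighbour counts as one tip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology, restoration

__all__ = ["TipCountParams", "SkeletonResult", "mip", "count_tips"]


@dataclass(frozen=True)
class TipCountParams:
    """Knobs of the tip-counting pipeline.

    ``threshold`` is ``("otsu",)`` or ``("fixed", value)``.
    ``min_component_area`` of ``None`` keeps only the largest
    foreground component (the tree is a single connected structure);
    a number keeps every component at least that large.
    ``spur_prune_length = 0`` disables pruning.
    ``background_radius = None`` skips background subtraction.
    """

    background_radius: float | None = 50.0
    blur_sigma: float = 2.0
    threshold: tuple = ("otsu",)
    min_component_area: float | None = None
    spur_prune_length: int = 5

    def __post_init__(self) -> None:
        if self.background_radius is not None and self.background_radius <= 0:
            raise ValueError("background_radius must be > 0 (or None to skip)")
        if self.blur_sigma < 0 or self.spur_prune_length < 0:
            raise ValueError("lengths must be >= 0")
        kind = self.threshold[0]
        if kind == "otsu":
            if len(self.threshold) != 1:
                raise ValueError("otsu threshold takes no value")
        elif kind == "fixed":
            if len(self.threshold) != 2:
                raise ValueError("fixed threshold is ('fixed', value)")
        else:
            raise ValueError(f"unknown threshold method {kind!r}")


@dataclass
class SkeletonResult:
    """Skeleton raster with its endpoint and branch-point census."""

    skeleton: np.ndarray  # bool (H, W)
    endpoints: np.ndarray  # (n, 2) as (y, x)
    branch_points: np.ndarray  # (m, 2) as (y, x)
    tip_count: int
    warnings: list[str]

    def __post_init__(self) -> None:
        if self.tip_count != len(self.endpoints):
            raise ValueError("tip count must equal the endpoint census")


_NEIGHBOUR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def _neighbour_counts(skel: np.ndarray) -> np.ndarray:
    return ndimage.convolve(skel.astype(np.uint8), _NEIGHBOUR_KERNEL,
                            mode="constant", cval=0)


def mip(stack: np.ndarray) -> np.ndarray:
    """Maximum intensity projection over z; identity (with a warning) on 2D."""
    arr = np.asarray(stack)
    if arr.ndim == 2:
        warnings.warn("input is already 2D; returning it unchanged", stacklevel=2)
        return arr
    if arr.ndim != 3:
        raise ValueError("mip expects a 2D image or a 3D (z, y, x) volume")
    return arr.max(axis=0)


def _prune_spurs(skel: np.ndarray, max_len: int) -> np.ndarray:
    """Iteratively remove terminal branches shorter than ``max_len`` px.

    From each endpoint the skeleton is walked until a branch point
    (>= 3 neighbours) is hit; if the walk is shorter than ``max_len``
    the walked pixels are deleted.  Branches ending in another endpoint
    (an isolated arc) are never pruned — both of its ends are real.
    """
    skel = skel.copy()
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    while True:
        counts = _neighbour_counts(skel)
        endpoints = np.argwhere(skel & (counts == 1))
        removed_any = False
        for y0, x0 in endpoints:
            if not skel[y0, x0]:
                continue
            path = [(y0, x0)]
            prev = None
            reached_branch = False
            while len(path) <= max_len:
                y, x = path[-1]
                nbrs = [(y + dy, x + dx) for dy, dx in offsets
                        if 0 <= y + dy < skel.shape[0] and 0 <= x + dx < skel.shape[1]
                        and skel[y + dy, x + dx] and (y + dy, x + dx) != prev]
                if len(nbrs) != 1:
                    reached_branch = len(nbrs) > 1
                    break
                ny, nx_ = nbrs[0]
                if counts[ny, nx_] >= 3:
                    reached_branch = True
                    break
                prev = (y, x)
                path.append((ny, nx_))
            if reached_branch and len(path) < max_len:
                for y, x in path:
                    skel[y, x] = False
                removed_any = True
        if not removed_any:
            return skel


def count_tips(image: np.ndarray, params: TipCountParams | None = None) -> SkeletonResult:
    """Run the full tip-counting pipeline on a 2D image or 3D volume."""
    params = params or TipCountParams()
    arr = np.asarray(image, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("empty image")
    if not np.isfinite(arr).all():
        raise ValueError("image contains non-finite pixels")
    warn: list[str] = []
    if arr.ndim == 3:
        arr = arr.max(axis=0)
    elif arr.ndim != 2:
        raise ValueError("expected a 2D image or 3D volume")

    if params.background_radius is not None:
        arr = arr - restoration.rolling_ball(arr, radius=params.background_radius)
    if params.blur_sigma > 0:
        arr = ndimage.gaussian_filter(arr, params.blur_sigma)

    if params.threshold[0] == "otsu":
        if np.ptp(arr) == 0:
            thresh = np.inf  # flat image: nothing is foreground
        else:
            thresh = filters.threshold_otsu(arr)
    else:
        thresh = params.threshold[1]
    mask = arr > thresh

    if mask.any():
        if params.min_component_area is None:
            labels = measure.label(mask, connectivity=2)
            largest = max(measure.regionprops(labels), key=lambda r: r.area)
            mask = labels == largest.label
        else:
            mask = morphology.remove_small_objects(
                mask, min_size=int(params.min_component_area), connectivity=2
            )

    if not mask.any():
        warn.append("all-background after threshold; tip count is 0")
        warnings.warn(warn[-1], stacklevel=2)
        empty = np.zeros((0, 2), dtype=int)
        return SkeletonResult(skeleton=np.zeros_like(mask), endpoints=empty,
                              branch_points=empty, tip_count=0, warnings=warn)

    skel = morphology.skeletonize(mask)
    if params.spur_prune_length > 0:
        skel = _prune_spurs(skel, params.spur_prune_length)

    counts = _neighbour_counts(skel)
    endpoints = np.argwhere(skel & (counts == 1))
    branch_points = np.argwhere(skel & (counts >= 3))
    return SkeletonResult(skeleton=skel, endpoints=endpoints,
                          branch_points=branch_points,
                          tip_count=len(endpoints), warnings=warn)
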