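"""Vessel morphometry on maximum-intensity projections.

Branch points are skeleton junctions (>= 3 skeleton neighbors in
8-connectivity, adjacent junction pixels merged), sprouts are skeleton
end-branches whose protrusion beyond the parent vessel exceeds a strict
length threshold (default 8 um), and cell-to-vessel proximity is a
Euclidean distance transform sampled at thresholded cell pixels with
osseous regions excluded. Projected vessel crossings are counted as
branch points without superimposition correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import skeletonize

from .errors import SegmentationError, SpecValidationError

_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


@dataclass(frozen=True)
class ProjectionImage:
    """A single-channel projection with physical pixel size (um/pixel)."""

    image: np.ndarray
    pixel_size: float
    slices_projected: int = 1

    def __post_init__(self):
        object.__setattr__(self, "image", np.asarray(self.image, dtype=float))
        if self.image.ndim != 2:
            raise SpecValidationError("image", "projection must be 2D")
        if self.pixel_size <= 0:
            raise SpecValidationError("pixel_size", "must be > 0 um/pixel")


@dataclass(frozen=True)
class MorphometryConfig:
    vessel_threshold: float | str = "otsu"
    sprout_min_length: float = 8.0  # um, strict >
    min_object_area: float = 0.0  # um^2

    def __post_init__(self):
        if self.sprout_min_length <= 0:
            raise SpecValidationError("sprout_min_length", "must be > 0 um")


@dataclass
class MorphometryResult:
    branch_points: int
    vessel_area_fraction: float
    sprout_count: int
    sprout_lengths: list
    skeleton: np.ndarray
    warnings: list = field(default_factory=list)


@dataclass
class ProximityResult:
    """Nearest-vessel distances (um) per cell pixel, per vessel channel."""

    distances: dict  # channel -> 1D array of um
    bin_summary: dict  # channel -> {"below": n, "above": n} at bin_edge
    bin_edge: float = 40.0


def threshold_mask(
    image: np.ndarray,
    method: float | str = "otsu",
    roi: np.ndarray | None = None,
) -> np.ndarray:
    """Binary mask from Otsu (within ``roi`` if given) or a fixed value."""
    image = np.asarray(image, dtype=float)
    region = np.ones(image.shape, dtype=bool) if roi is None else np.asarray(roi, dtype=bool)
    if not region.any():
        raise SpecValidationError("roi", "ROI is empty")
    if isinstance(method, str):
        if method != "otsu":
            raise SpecValidationError("vessel_threshold", f"unknown method {method!r}")
        values = image[region]
        if np.ptp(values) == 0:
            raise SegmentationError("image is constant inside the ROI; cannot threshold")
        thr = float(threshold_otsu(values))
    else:
        thr = float(method)
    return (image > thr) & region


def _skeleton_neighbor_counts(skel: np.ndarray) -> np.ndarray:
    return ndimage.convolve(skel.astype(np.uint8), _NEIGHBOR_KERNEL, mode="constant")


def branch_point_map(skel: np.ndarray) -> np.ndarray:
    """Skeleton pixels with >= 3 skeleton neighbors (8-connectivity)."""
    return skel & (_skeleton_neighbor_counts(skel) >= 3)


def count_branch_points(
    projection: ProjectionImage,
    config: MorphometryConfig = MorphometryConfig(),
    regions=None,
) -> MorphometryResult:
    """Threshold, skeletonize and count merged skeleton junctions.

    Junction pixels that touch (8-connectivity) are merged into a single
    branch point. An empty vessel mask yields a zero-count result with a
    warning rather than an error.
    """
    roi = None
    if regions is not None:
        roi = regions.marrow_roi & ~regions.osseous_roi
    warnings = []
    try:
        mask = threshold_mask(projection.image, config.vessel_threshold, roi)
    except SegmentationError as exc:
        warnings.append(str(exc))
        mask = np.zeros(projection.image.shape, dtype=bool)
    if config.min_object_area > 0:
        min_px = int(round(config.min_object_area / projection.pixel_size**2))
        if min_px > 1:
            mask = _remove_small(mask, min_px)
    denom = int(roi.sum()) if roi is not None else mask.size
    area_fraction = float(mask.sum()) / denom if denom else 0.0
    if not mask.any():
        warnings.append("empty vessel mask: zero-count morphometry result")
        return MorphometryResult(0, 0.0, 0, [], np.zeros_like(mask), warnings)
    skel = skeletonize(mask)
    junctions = branch_point_map(skel)
    n_branch = int(label(junctions, connectivity=2).max())
    sprout_count, sprout_lengths = detect_sprouts(projection, config, mask=mask, skeleton=skel)
    return MorphometryResult(
        branch_points=n_branch,
        vessel_area_fraction=area_fraction,
        sprout_count=sprout_count,
        sprout_lengths=sprout_lengths,
        skeleton=skel,
        warnings=warnings,
    )


def _remove_small(mask, min_px):
    lab, n = ndimage.label(mask, structure=np.ones((3, 3)))
    sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = sizes >= min_px
    return keep[lab]


def _trace_end_branch(skel, junctions, start):
    """Walk the skeleton from an endpoint until a junction (or dead end).

    Returns (path length in pixels using 1/sqrt(2) steps, junction pixel
    or None).
    """
    visited = {start}
    length = 0.0
    current = start
    h, w = skel.shape
    while True:
        neighbors = []
        r, c = current
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and skel[rr, cc] and (rr, cc) not in visited:
                    neighbors.append((rr, cc))
        if not neighbors:
            return length, None
        # prefer stepping onto a junction to terminate the branch there
        for nxt in neighbors:
            if junctions[nxt]:
                step = np.hypot(nxt[0] - r, nxt[1] - c)
                return length + step, nxt
        if len(neighbors) > 1:
            # ambiguous continuation adjacent to a junction cluster
            nxt = neighbors[0]
        else:
            nxt = neighbors[0]
        length += np.hypot(nxt[0] - r, nxt[1] - c)
        visited.add(nxt)
        current = nxt


def detect_sprouts(
    projection: ProjectionImage,
    config: MorphometryConfig = MorphometryConfig(),
    mask: np.ndarray | None = None,
    skeleton: np.ndarray | None = None,
    border_margin_px: int = 3,
) -> tuple[int, list]:
    """Count skeleton end-branches protruding more than the threshold.

    Each skeleton endpoint is traced back to the nearest junction. The
    protrusion in um is the geodesic skeleton length, extended by the
    mask's distance transform at the tip (skeletonization prunes tip
    pixels) and shortened by the parent vessel half-width at the
    junction. Endpoints within ``border_margin_px`` of the image border
    are vessels truncated by the field of view, not sprouts. Only strict
    ``length > sprout_min_length`` counts.
    """
    if mask is None:
        mask = threshold_mask(projection.image, config.vessel_threshold)
    if not mask.any():
        raise SpecValidationError("mask", "vessel mask is empty")
    skel = skeletonize(mask) if skeleton is None else skeleton
    counts = _skeleton_neighbor_counts(skel)
    junctions = skel & (counts >= 3)
    endpoints = np.argwhere(skel & (counts == 1))
    edt = ndimage.distance_transform_edt(mask)
    h, w = mask.shape
    lengths = []
    for r, c in endpoints:
        if (
            r < border_margin_px
            or c < border_margin_px
            or r >= h - border_margin_px
            or c >= w - border_margin_px
        ):
            continue  # truncated by the field of view
        px_len, junction = _trace_end_branch(skel, junctions, (int(r), int(c)))
        if junction is None:
            continue  # isolated segment, not a protrusion from a vessel
        px_len += float(edt[int(r), int(c)])  # tip pixels lost to skeleton pruning
        protrusion = (px_len - float(edt[junction])) * projection.pixel_size
        if protrusion > config.sprout_min_length:
            lengths.append(float(protrusion))
    return len(lengths), sorted(lengths)


def proximity_distances(
    cell_mask: np.ndarray,
    vessel_masks: dict,
    regions=None,
    pixel_size: float = 1.0,
    bin_edge_um: float = 40.0,
) -> ProximityResult:
    """Distance from every cell pixel to the nearest pixel of each vessel mask.

    Euclidean distance transform of each vessel mask's complement,
    sampled at cell pixels outside the osseous ROI. Cells inside a vessel
    get distance 0. ``bin_summary`` counts cells below / at-or-above
    ``bin_edge_um``.
    """
    if pixel_size <= 0:
        raise SpecValidationError("pixel_size", "must be > 0 um/pixel")
    cell_mask = np.asarray(cell_mask, dtype=bool)
    keep = cell_mask.copy()
    if regions is not None:
        keep &= ~regions.osseous_roi
    cells = np.nonzero(keep)
    distances = {}
    bins = {}
    for name, vmask in vessel_masks.items():
        vmask = np.asarray(vmask, dtype=bool)
        if vmask.shape != cell_mask.shape:
            raise SpecValidationError(name, "vessel mask shape must match the cell channel")
        if not vmask.any():
            raise SpecValidationError(name, "vessel mask for this channel is empty")
        edt = ndimage.distance_transform_edt(~vmask, sampling=pixel_size)
        d = edt[cells]
        distances[name] = d
        bins[name] = {"below": int(np.sum(d < bin_edge_um)), "above": int(np.sum(d >= bin_edge_um))}
    return ProximityResult(distances=distances, bin_summary=bins, bin_edge=bin_edge_um)
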