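"""Intravital leakage quantification and target-to-background ratios.

Vascular leakiness is the I_out/I_in statistic: a vessel mask is
thresholded on the first frame after tracer injection, and the mean
albumin intensity outside the vasculature is ratioed against the mean
inside, per frame. Its slope over time (min^-1) is the leak rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import binary_dilation, remove_small_objects

from .errors import SegmentationError, SpecValidationError

_SECONDS_PER_MINUTE = 60.0


@dataclass(frozen=True)
class TimeLapseStack:
    """Single-plane fluorescence time-lapse.

    frames: (n_frames, H, W) intensities in a.u.; timestamps in seconds,
    strictly increasing; pixel_size in um/pixel.
    """

    frames: np.ndarray
    timestamps: np.ndarray
    pixel_size: float
    channel: str = "albumin"

    def __post_init__(self):
        object.__setattr__(self, "frames", np.asarray(self.frames, dtype=float))
        object.__setattr__(self, "timestamps", np.asarray(self.timestamps, dtype=float))
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise SpecValidationError("frames", "need a (n_frames>=2, H, W) stack")
        if self.timestamps.shape != (self.frames.shape[0],):
            raise SpecValidationError("timestamps", "one timestamp per frame required")
        if np.any(np.diff(self.timestamps) <= 0):
            raise SpecValidationError("timestamps", "must be strictly increasing")
        if self.pixel_size <= 0:
            raise SpecValidationError("pixel_size", "must be > 0 um/pixel")


@dataclass(frozen=True)
class RegionSet:
    """Marrow analysis ROI and osseous (background/exclusion) ROI."""

    marrow_roi: np.ndarray
    osseous_roi: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "marrow_roi", np.asarray(self.marrow_roi, dtype=bool))
        object.__setattr__(self, "osseous_roi", np.asarray(self.osseous_roi, dtype=bool))
        if self.marrow_roi.shape != self.osseous_roi.shape:
            raise SpecValidationError("osseous_roi", "shape must match marrow_roi")
        if np.any(self.marrow_roi & self.osseous_roi):
            raise SpecValidationError("marrow_roi", "marrow and osseous ROIs must be disjoint")


@dataclass(frozen=True)
class LeakageResult:
    vessel_mask: np.ndarray
    times: np.ndarray  # s, post-injection frames
    i_in: np.ndarray  # a.u.
    i_out: np.ndarray  # a.u.
    ratio: np.ndarray  # I_out / I_in
    leak_rate: float  # min^-1
    threshold: float


@dataclass(frozen=True)
class TBRResult:
    tbr: float
    target_mean: float
    background_mean: float
    projection_depth: int


def segment_vessels_first_frame(
    stack: TimeLapseStack,
    injection_frame: int,
    regions: RegionSet,
    threshold: float | None = None,
    min_object_px: int = 0,
) -> tuple[np.ndarray, float]:
    """Threshold the first post-injection frame into a vessel mask.

    Otsu's method inside the marrow ROI by default; ``threshold``
    overrides with a fixed value. Osseous pixels are always excluded,
    regardless of their intensity. Returns ``(mask, threshold_value)``.
    """
    if not (0 <= injection_frame < stack.frames.shape[0]):
        raise SpecValidationError("injection_frame", "outside the stack")
    if regions.marrow_roi.shape != stack.frames.shape[1:]:
        raise SpecValidationError("marrow_roi", "mask shape must match frames")
    if not regions.marrow_roi.any():
        raise SpecValidationError("marrow_roi", "marrow ROI is empty")
    frame = stack.frames[injection_frame]
    values = frame[regions.marrow_roi]
    if np.ptp(values) == 0:
        raise SegmentationError("first post-injection frame is flat inside the marrow ROI")
    thr = float(threshold) if threshold is not None else float(threshold_otsu(values))
    mask = (frame > thr) & regions.marrow_roi & ~regions.osseous_roi
    if min_object_px > 0:
        mask = remove_small_objects(mask, min_size=min_object_px)
    return mask, thr


def leakage_rate(
    stack: TimeLapseStack,
    vessel_mask: np.ndarray,
    regions: RegionSet,
    injection_frame: int,
    threshold: float = float("nan"),
    dilate_mask: bool = False,
) -> LeakageResult:
    """Compute I_out/I_in per post-injection frame and its OLS slope.

    i_in is the mean over mask∩marrow; i_out the mean over
    marrow∖(mask∪osseous). ``dilate_mask`` optionally grows the vessel
    mask by one pixel before defining the out-region (off by default).
    The leak rate is the ordinary-least-squares slope of the ratio
    against time, converted to min^-1.
    """
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    if vessel_mask.shape != stack.frames.shape[1:]:
        raise SpecValidationError("vessel_mask", "shape must match frames")
    in_region = vessel_mask & regions.marrow_roi
    if not in_region.any():
        raise SpecValidationError("vessel_mask", "vessel mask is empty inside the marrow ROI")
    out_mask_base = binary_dilation(vessel_mask) if dilate_mask else vessel_mask
    out_region = regions.marrow_roi & ~out_mask_base & ~regions.osseous_roi
    if not out_region.any():
        raise SegmentationError("out-region is empty: nothing outside the vasculature to measure")
    post = stack.frames[injection_frame:]
    if post.shape[0] < 2:
        raise SpecValidationError("injection_frame", "need >= 2 post-injection frames")
    times = stack.timestamps[injection_frame:]
    i_in = post[:, in_region].mean(axis=1)
    i_out = post[:, out_region].mean(axis=1)
    if np.any(i_in <= 0):
        raise SegmentationError("I_in is non-positive; ratio undefined")
    ratio = i_out / i_in
    t_min = (times - times[0]) / _SECONDS_PER_MINUTE
    slope, _ = np.polyfit(t_min, ratio, 1)
    return LeakageResult(
        vessel_mask=vessel_mask,
        times=times,
        i_in=i_in,
        i_out=i_out,
        ratio=ratio,
        leak_rate=float(slope),
        threshold=threshold,
    )


def analyze_leakage(
    stack: TimeLapseStack,
    regions: RegionSet,
    injection_frame: int,
    threshold: float | None = None,
    dilate_mask: bool = False,
) -> LeakageResult:
    """Segment on the first post-injection frame, then quantify leakage."""
    mask, thr = segment_vessels_first_frame(stack, injection_frame, regions, threshold=threshold)
    result = leakage_rate(stack, mask, regions, injection_frame, threshold=thr, dilate_mask=dilate_mask)
    return result


def max_intensity_projection(zstack: np.ndarray, projection_depth: int | None = None) -> np.ndarray:
    """MIP over the first ``projection_depth`` slices (all slices if None)."""
    zstack = np.asarray(zstack, dtype=float)
    if zstack.ndim != 3 or zstack.shape[0] < 1:
        raise SpecValidationError("zstack", "need a (n_slices>=1, H, W) stack")
    depth = zstack.shape[0] if projection_depth is None else int(projection_depth)
    if not (1 <= depth <= zstack.shape[0]):
        raise SpecValidationError("projection_depth", "must lie in [1, n_slices]")
    return zstack[:depth].max(axis=0)


def target_to_background(
    zstack: np.ndarray,
    regions: RegionSet,
    projection_depth: int | None = None,
) -> TBRResult:
    """TBR = mean(MIP over marrow ROI) / mean(MIP over osseous ROI)."""
    mip = max_intensity_projection(zstack, projection_depth)
    if mip.shape != regions.marrow_roi.shape:
        raise SpecValidationError("marrow_roi", "mask shape must match slices")
    if not regions.osseous_roi.any():
        raise SpecValidationError("osseous_roi", "background region is empty")
    target = float(mip[regions.marrow_roi].mean())
    background = float(mip[regions.osseous_roi].mean())
    if background <= 0:
        raise SegmentationError("background mean is non-positive; TBR undefined")
    depth = zstack.shape[0] if projection_depth is None else int(projection_depth)
    return TBRResult(
        tbr=target / background,
        target_mean=target,
        background_mean=background,
        projection_depth=depth,
    )
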