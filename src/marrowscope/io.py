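"""TIFF + JSON-sidecar input/output.

One sidecar dialect is used throughout: a multi-page TIFF (one page per
frame, flip angle, time point, slice or channel) accompanied by a JSON
file of the same stem carrying pixel size, timestamps, flip angles, TR,
relaxivity, seeds and ground truth where applicable. Masks are
single-page 8-bit TIFFs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .errors import SpecValidationError
from .leakage import RegionSet, TimeLapseStack
from .morphometry import ProjectionImage
from .relaxometry import DCESeries, VFASeries
from .velocimetry import Kymograph


def sidecar_path(tiff_path) -> Path:
    return Path(tiff_path).with_suffix(".json")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_stack(path, array, sidecar: dict | None = None):
    """Write a (pages, H, W) or (H, W) array as TIFF plus JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(array, dtype=np.float32)
    if arr.ndim >= 2:
        tifffile.imwrite(path, arr, photometric="minisblack")
    else:
        tifffile.imwrite(path, arr)
    if sidecar is not None:
        sidecar_path(path).write_text(json.dumps(_jsonable(sidecar), indent=2, sort_keys=True))


def write_mask(path, mask):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint8) * 255)


def load_mask(path) -> np.ndarray:
    return tifffile.imread(path) > 0


def read_sidecar(path) -> dict:
    sc = sidecar_path(path)
    if not sc.exists():
        return {}
    return json.loads(sc.read_text())


def _require(meta: dict, key: str, context: str):
    if key not in meta or meta[key] is None:
        raise SpecValidationError(key, f"required metadata missing for {context}")
    return meta[key]


def load_time_lapse(path, warn=None) -> tuple[TimeLapseStack, dict]:
    """Load a time-lapse TIFF; timestamps default to 1.2 s spacing with a warning."""
    frames = np.asarray(tifffile.imread(path), dtype=float)
    meta = read_sidecar(path)
    if frames.ndim == 2:
        raise SpecValidationError("frames", "time-lapse needs >= 2 pages")
    if "timestamps" in meta:
        timestamps = np.asarray(meta["timestamps"], dtype=float)
    else:
        timestamps = np.arange(frames.shape[0]) * 1.2
        if warn is not None:
            warn("timestamps missing from sidecar; defaulting to 1.2 s spacing")
    pixel_size = float(meta.get("pixel_size", 1.0))
    if "pixel_size" not in meta and warn is not None:
        warn("pixel_size missing from sidecar; defaulting to 1 um/pixel")
    stack = TimeLapseStack(frames=frames, timestamps=timestamps, pixel_size=pixel_size)
    return stack, meta


def load_kymograph(path) -> tuple[Kymograph, dict]:
    image = np.asarray(tifffile.imread(path), dtype=float)
    meta = read_sidecar(path)
    pixel_size = float(_require(meta, "pixel_size", "kymograph"))
    line_period = float(_require(meta, "line_period", "kymograph"))
    return Kymograph(image=image, pixel_size=pixel_size, line_period=line_period, metadata=meta), meta


def load_vfa(path) -> tuple[VFASeries, dict]:
    """Load a VFA TIFF (one page per flip angle) as ROI-mean signals."""
    pages = np.asarray(tifffile.imread(path), dtype=float)
    meta = read_sidecar(path)
    flip_angles = np.asarray(_require(meta, "flip_angles", "VFA series"), dtype=float)
    tr = float(_require(meta, "tr", "VFA series"))
    if pages.ndim == 1:
        signals = pages
    else:
        signals = pages.reshape(pages.shape[0], -1).mean(axis=1)
    return VFASeries(signals=signals, flip_angles=flip_angles, tr=tr), meta


def load_dce(path) -> tuple[DCESeries, dict]:
    """Load a dynamic TIFF (one page per time point) with blood ROI signals in the sidecar."""
    pages = np.asarray(tifffile.imread(path), dtype=float)
    meta = read_sidecar(path)
    times = np.asarray(_require(meta, "times", "DCE series"), dtype=float)
    blood = np.asarray(_require(meta, "blood_signals", "DCE series"), dtype=float)
    flip = float(_require(meta, "flip_angle_post", "DCE series"))
    tr = float(_require(meta, "tr", "DCE series"))
    if pages.ndim == 1:
        tissue = pages
    else:
        tissue = pages.reshape(pages.shape[0], -1).mean(axis=1)
    return DCESeries(tissue_signals=tissue, blood_signals=blood, times=times,
                     flip_angle_post=flip, tr=tr), meta


def load_dce_stacks(path):
    """Pixelwise variant: returns (dyn_stack, blood_signals, times, meta)."""
    pages = np.asarray(tifffile.imread(path), dtype=float)
    meta = read_sidecar(path)
    times = np.asarray(_require(meta, "times", "DCE series"), dtype=float)
    blood = np.asarray(_require(meta, "blood_signals", "DCE series"), dtype=float)
    return pages, blood, times, meta


def load_projection(path, channel: str | None = None) -> tuple[ProjectionImage, dict]:
    """Load a projection; for multi-channel TIFFs pick ``channel`` by sidecar name."""
    pages = np.asarray(tifffile.imread(path), dtype=float)
    meta = read_sidecar(path)
    pixel_size = float(_require(meta, "pixel_size", "projection"))
    if pages.ndim == 3:
        channels = meta.get("channels")
        if channel is None:
            raise SpecValidationError("channel", "multi-channel image: channel name required")
        if not channels or channel not in channels:
            raise SpecValidationError("channel", f"channel {channel!r} not found in sidecar")
        image = pages[list(channels).index(channel)]
    else:
        image = pages
    return ProjectionImage(image=image, pixel_size=pixel_size,
                           slices_projected=int(meta.get("slices_projected", 1))), meta


def load_regions(marrow_path=None, osseous_path=None, shape=None) -> RegionSet:
    """Build a RegionSet from mask files; missing masks default to full/empty."""
    if marrow_path is not None:
        marrow = load_mask(marrow_path)
        shape = marrow.shape
    elif shape is not None:
        marrow = np.ones(shape, dtype=bool)
    else:
        raise SpecValidationError("marrow_roi", "either a marrow mask or an image shape is required")
    osseous = load_mask(osseous_path) if osseous_path is not None else np.zeros(shape, dtype=bool)
    marrow = marrow & ~osseous
    return RegionSet(marrow_roi=marrow, osseous_roi=osseous)
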