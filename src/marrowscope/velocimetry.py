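"""Line-scan velocimetry.

Red blood cells appear as dark diagonal streaks in a kymograph of
repeated line scans through bright fluorescent plasma. The streak slope
(pixels of displacement per scanned line) encodes velocity. The dominant
orientation is found by maximizing the variance of the Radon transform
over an angle grid, refined by parabolic interpolation; the endothelial
function statistic is the velocity difference between a baseline and an
acetylcholine-stimulated scan of the same vessel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import radon

from .errors import SpecValidationError, UnresolvableVelocityError, VelocimetryError


@dataclass(frozen=True)
class Kymograph:
    """Line-scan image: rows are successive lines (time), columns position.

    pixel_size in um/pixel along the scan line; line_period in ms per line.
    """

    image: np.ndarray
    pixel_size: float
    line_period: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "image", np.asarray(self.image, dtype=float))
        if self.image.ndim != 2 or self.image.shape[0] < 2:
            raise SpecValidationError("image", "need a 2D kymograph with >= 2 lines")
        if self.pixel_size <= 0:
            raise SpecValidationError("pixel_size", "must be > 0 um/pixel")
        if self.line_period <= 0:
            raise SpecValidationError("line_period", "must be > 0 ms/line")


@dataclass(frozen=True)
class VelocityEstimate:
    velocity: float  # um/ms (== mm/s)
    streak_angle: float  # degrees from the time axis
    confidence: float  # in [0, 1]
    units: str = "um/ms"


@dataclass(frozen=True)
class DeltaVelocity:
    baseline: float
    stimulated: float
    delta: float
    units: str = "um/ms"


def _detrended(image: np.ndarray, streaks: str) -> np.ndarray:
    """Per-line median subtraction; flips sign so streaks are positive."""
    med = np.median(image, axis=1, keepdims=True)
    work = image - med
    if streaks == "dark":
        work = -work
    elif streaks != "bright":
        raise SpecValidationError("streaks", "must be 'dark' or 'bright'")
    return np.clip(work, 0.0, None)

def _angle_variance(work: np.ndarray, angles: np.ndarray) -> np.ndarray:
    sino = radon(work, theta=angles, circle=False, preserve_range=True)
    return sino.var(axis=0)


def estimate_velocity(
    k: Kymograph,
    streaks: str = "dark",
    angle_step: float = 0.25,
    max_abs_angle: float = 89.0,
) -> VelocityEstimate:
    """Estimate streak velocity from the dominant Radon orientation.

    The streak angle theta (degrees, measured from the time axis) maps to
    a displacement of tan(theta) pixels per line; velocity is
    tan(theta) * pixel_size / line_period, signed along the scan line.

    Raises
    ------
    VelocimetryError
        For a constant image.
    UnresolvableVelocityError
        When the orientation sits at the pixels-per-line asymptote
        (|theta| > ``max_abs_angle``): the cell outruns the line scan.
    """
    img = k.image
    if np.ptp(img) == 0:
        raise VelocimetryError("constant kymograph carries no streak orientation")
    work = _detrended(img, streaks)
    if not np.any(work > 0):
        raise VelocimetryError("kymograph has no contrast after detrending")

    coarse = np.arange(-88.0, 90.0, 2.0)
    var_coarse = _angle_variance(work, coarse)
    theta0 = coarse[int(np.argmax(var_coarse))]

    fine = np.arange(theta0 - 3.0, theta0 + 3.0 + 1e-9, angle_step)
    var_fine = _angle_variance(work, fine)
    i = int(np.argmax(var_fine))
    theta = float(fine[i])
    if 0 < i < fine.size - 1:
        y0, y1, y2 = var_fine[i - 1 : i + 2]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            theta += float(0.5 * (y0 - y2) / denom) * angle_step

    if abs(theta) > max_abs_angle:
        raise UnresolvableVelocityError(
            f"streak orientation {theta:.2f} deg is at the pixels-per-line asymptote"
        )

    all_var = np.concatenate([var_coarse, var_fine])
    peak = float(all_var.max())
    floor = float(np.median(all_var))
    confidence = 0.0 if peak <= 0 else float(np.clip((peak - floor) / peak, 0.0, 1.0))

    px_per_line = np.tan(np.deg2rad(theta))
    velocity = px_per_line * k.pixel_size / k.line_period
    return VelocityEstimate(velocity=float(velocity), streak_angle=theta, confidence=confidence)


def delta_velocity(baseline: VelocityEstimate, stimulated: VelocityEstimate) -> DeltaVelocity:
    """delta = stimulated - baseline; negative means impaired vasodilation."""
    if baseline.units != stimulated.units:
        raise SpecValidationError("units", "baseline and stimulated estimates use different units")
    return DeltaVelocity(
        baseline=baseline.velocity,
        stimulated=stimulated.velocity,
        delta=stimulated.velocity - baseline.velocity,
        units=baseline.units,
    )


def aggregate_vessels(velocities, deltas=None):
    """Unweighted per-animal mean over vessels.

    Returns a dict with mean velocity, mean delta (if given) and n.
    """
    velocities = [float(v) for v in velocities]
    if not velocities:
        raise SpecValidationError("velocities", "need >= 1 vessel")
    out = {"mean_velocity": float(np.mean(velocities)), "n_vessels": len(velocities)}
    if deltas is not None:
        deltas = [float(d) for d in deltas]
        if deltas:
            out["mean_delta"] = float(np.mean(deltas))
    return out
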