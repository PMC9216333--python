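"""Shared fixtures and independent oracles.

The oracle implementations here (grid search, centroid streak tracking,
brute-force nearest-pixel search) deliberately avoid the code paths they
check.
"""

import numpy as np
import pytest
from scipy.signal import find_peaks

from marrowscope.synthetic import (
    DCEPhantomSpec,
    KymographSpec,
    LeakagePhantomSpec,
    VesselPhantomSpec,
    VesselSegment,
)

FLIP_ANGLES = np.array([2.0, 6.0, 9.0, 15.0, 25.0, 50.0, 70.0])
TR_MS = 25.0


# ---------------------------------------------------------------------------
# phantom builders


@pytest.fixture
def leakage_base_spec():
    return VesselPhantomSpec(
        image_shape=(128, 128),
        pixel_size=1.0,
        vessel_segments=(
            VesselSegment(start=(40, 4), end=(40, 123), radius_um=4.0, intensity=1000.0),
            VesselSegment(start=(90, 4), end=(90, 123), radius_um=4.0, intensity=1000.0),
            VesselSegment(start=(8, 70), end=(120, 70), radius_um=4.0, intensity=1000.0),
        ),
        osseous_polygon=((0, 0), (0, 24), (24, 0)),
        background_intensity=100.0,
        noise_sd=0.0,
        seed=0,
    )


@pytest.fixture
def leakage_spec(leakage_base_spec):
    return LeakagePhantomSpec(
        base=leakage_base_spec,
        n_frames=25,
        frame_interval=1.2,
        inside_intensity=1000.0,
        outside_slope=10.0,
        injection_frame=0,
    )


@pytest.fixture
def healthy_dce_spec():
    return DCEPhantomSpec(seed=0)


def make_kymo_spec(**kwargs):
    defaults = dict(
        n_positions=256,
        n_lines=128,
        pixel_size=1.0,
        line_period=1.0,
        true_velocity=1.5,
        streak_density=8.0,
        streak_contrast=500.0,
        noise_sd=0.0,
        seed=0,
    )
    defaults.update(kwargs)
    return KymographSpec(**defaults)


# ---------------------------------------------------------------------------
# independent oracles


def vfa_grid_search_oracle(signals, flip_angles, tr_ms, r1_lo=0.25, r1_hi=4.0, step=1e-3):
    """Dense grid over R1 with S0 profiled out by linear least squares."""
    r1_grid = np.arange(r1_lo, r1_hi, step)
    e1 = np.exp(-(tr_ms / 1000.0) * r1_grid)[:, None]
    a = np.deg2rad(np.asarray(flip_angles))[None, :]
    f = np.sin(a) * (1 - e1) / (1 - e1 * np.cos(a))
    s = np.asarray(signals, dtype=float)[None, :]
    s0_hat = (f * s).sum(axis=1) / (f * f).sum(axis=1)
    resid = ((s0_hat[:, None] * f - s) ** 2).sum(axis=1)
    i = int(np.argmin(resid))
    return float(r1_grid[i]), float(s0_hat[i])


def centroid_tracking_velocity(kymo, min_track_lines=20, max_jump_px=4.0, max_rms_px=1.2):
    """Per-streak centroid tracking oracle.

    Detects dip minima per scan line (prominence-based on the smoothed,
    inverted line), links them across lines by nearest-neighbor
    continuity, fits a slope per sufficiently long and straight track,
    and returns the median track velocity in um/ms.
    """
    from scipy.ndimage import gaussian_filter1d

    img = kymo.image
    background = np.median(img)
    prominence = 0.35 * (background - img.min())
    tracks = []  # each: (lines list, positions list)
    active = []  # (last_line, last_pos, track_index)
    for j in range(img.shape[0]):
        inverted = gaussian_filter1d(background - img[j], 1.0)
        peaks, _ = find_peaks(inverted, prominence=prominence)
        # sub-pixel centroid over a +/-2 px window
        positions = []
        for p in peaks:
            lo, hi = max(0, p - 2), min(img.shape[1], p + 3)
            w = np.clip(inverted[lo:hi], 0, None)
            positions.append(float((np.arange(lo, hi) * w).sum() / w.sum()) if w.sum() else float(p))
        used = set()
        new_active = []
        for last_line, last_pos, ti in active:
            best, best_d = None, max_jump_px
            for i, pos in enumerate(positions):
                if i in used:
                    continue
                d = abs(pos - last_pos)
                if d < best_d:
                    best, best_d = i, d
            if best is not None:
                used.add(best)
                tracks[ti][0].append(j)
                tracks[ti][1].append(positions[best])
                new_active.append((j, positions[best], ti))
            elif j - last_line <= 2:
                new_active.append((last_line, last_pos, ti))
        for i, pos in enumerate(positions):
            if i not in used:
                tracks.append(([j], [pos]))
                new_active.append((j, pos, len(tracks) - 1))
        active = new_active
    slopes = []
    for lines, positions in tracks:
        if len(lines) >= min_track_lines:
            coef = np.polyfit(lines, positions, 1)
            rms = float(np.sqrt(np.mean((np.polyval(coef, lines) - positions) ** 2)))
            if rms <= max_rms_px:
                slopes.append(coef[0])
    if not slopes:
        raise RuntimeError("oracle found no usable streak tracks")
    return float(np.median(slopes)) * kymo.pixel_size / kymo.line_period


def brute_force_nearest_um(cell_coords, vessel_mask, pixel_size):
    """Exhaustive nearest-vessel-pixel search (center-to-center)."""
    vr, vc = np.nonzero(vessel_mask)
    out = []
    for r, c in cell_coords:
        out.append(float(np.min(np.hypot(vr - r, vc - c))) * pixel_size)
    return np.asarray(out)
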