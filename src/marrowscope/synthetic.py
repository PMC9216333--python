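"""Phantom generators with known ground truth.

Every generator is deterministic given its spec (seeds are mandatory
fields, never global state) and emits objects consumed directly by the
analysis modules: leakage time-lapse stacks, line-scan kymographs,
variable-flip-angle / dynamic post-contrast series, and multi-channel
morphometry scenes. Ground truth travels alongside each phantom so the
analysis chain can be validated by parameter recovery.

Vessels are rendered as anti-aliased capsules (constant-intensity core
with a one-pixel soft edge). Noise is additive Gaussian clipped at zero.
Osseous regions never receive vessel or leakage signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import LineString
from skimage.draw import polygon2mask

from .errors import SpecValidationError
from .leakage import RegionSet, TimeLapseStack
from .relaxometry import DCESeries, VFASeries, spgr_signal
from .velocimetry import Kymograph

#: Flip-angle schedule of the femoral DCE acquisition (degrees).
DEFAULT_FLIP_ANGLES_PRE = (2.0, 6.0, 9.0, 15.0, 25.0, 50.0, 70.0)
DEFAULT_FLIP_ANGLE_POST = 50.0
DEFAULT_TR_MS = 25.0


# ---------------------------------------------------------------------------
# vessel phantoms


@dataclass(frozen=True)
class VesselSegment:
    """A straight capsule: endpoints in (row, col) pixel coordinates."""

    start: tuple
    end: tuple
    radius_um: float
    intensity: float

    def __post_init__(self):
        if self.radius_um <= 0:
            raise SpecValidationError("radius_um", "vessel radius must be > 0 um")
        if self.intensity < 0:
            raise SpecValidationError("intensity", "vessel intensity must be >= 0")


@dataclass(frozen=True)
class VesselPhantomSpec:
    image_shape: tuple
    pixel_size: float  # um/pixel
    vessel_segments: tuple
    osseous_polygon: tuple = ()  # (row, col) vertices; empty = no osseous region
    background_intensity: float = 100.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.image_shape) != 2 or min(self.image_shape) < 4:
            raise SpecValidationError("image_shape", "need a 2D shape of at least 4x4 pixels")
        if self.pixel_size <= 0:
            raise SpecValidationError("pixel_size", "must be > 0 um/pixel")
        if self.noise_sd < 0:
            raise SpecValidationError("noise_sd", "must be >= 0")
        if self.background_intensity < 0:
            raise SpecValidationError("background_intensity", "must be >= 0")
        object.__setattr__(
            self, "vessel_segments", tuple(self.vessel_segments)
        )
        for seg in self.vessel_segments:
            if not isinstance(seg, VesselSegment):
                raise SpecValidationError("vessel_segments", "entries must be VesselSegment")


def _segment_distance_field(shape, seg: VesselSegment, pixel_size):
    """Per-pixel distance (px) from pixel centers to the segment."""
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    p = np.stack([rows, cols], axis=-1)
    a = np.asarray(seg.start, dtype=float)
    b = np.asarray(seg.end, dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return np.linalg.norm(p - a, axis=-1)
    t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
    closest = a + t[..., None] * ab
    return np.linalg.norm(p - closest, axis=-1)


def osseous_mask(spec: VesselPhantomSpec) -> np.ndarray:
    if not spec.osseous_polygon:
        return np.zeros(spec.image_shape, dtype=bool)
    return polygon2mask(spec.image_shape, np.asarray(spec.osseous_polygon, dtype=float))


def render_vessel_image(spec: VesselPhantomSpec):
    """Render the phantom; returns (image, vessel_mask, osseous_mask).

    Capsule cores carry the segment intensity; a one-pixel soft edge
    (linear ramp centered on the capsule boundary) anti-aliases the rim.
    The ground-truth mask is the hard capsule (distance <= radius). The
    osseous region is clamped to the background and excluded from the
    mask; noise is added last, Gaussian with sd ``noise_sd``, clipped at
    zero.
    """
    layer = np.zeros(spec.image_shape, dtype=float)
    mask = np.zeros(spec.image_shape, dtype=bool)
    for seg in spec.vessel_segments:
        dist = _segment_distance_field(spec.image_shape, seg, spec.pixel_size)
        radius_px = seg.radius_um / spec.pixel_size
        weight = np.clip(radius_px + 0.5 - dist, 0.0, 1.0)
        layer = np.maximum(layer, weight * seg.intensity)
        mask |= dist <= radius_px
    oss = osseous_mask(spec)
    image = np.maximum(layer, spec.background_intensity)
    image[oss] = spec.background_intensity
    mask &= ~oss
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        image = np.clip(image + rng.normal(0.0, spec.noise_sd, image.shape), 0.0, None)
    return image, mask, oss


# ---------------------------------------------------------------------------
# leakage time-lapse


@dataclass(frozen=True)
class LeakagePhantomSpec:
    """Albumin extravasation phantom.

    Defaults mirror the intravital acquisition: 25 frames at 1.2 s.
    Inside-vessel intensity is constant; the mean intensity outside the
    vessels rises linearly at ``outside_slope`` (a.u./s) after
    ``injection_frame``.
    """

    base: VesselPhantomSpec
    n_frames: int = 25
    frame_interval: float = 1.2  # s
    inside_intensity: float = 1000.0
    outside_slope: float = 0.0  # a.u./s
    injection_frame: int = 0

    def __post_init__(self):
        if self.n_frames < 2:
            raise SpecValidationError("n_frames", "need >= 2 frames")
        if self.frame_interval <= 0:
            raise SpecValidationError("frame_interval", "must be > 0 s")
        if self.outside_slope < 0:
            raise SpecValidationError("outside_slope", "must be >= 0 a.u./s")
        if self.inside_intensity <= 0:
            raise SpecValidationError("inside_intensity", "must be > 0 a.u.")
        if not (0 <= self.injection_frame < self.n_frames - 1):
            raise SpecValidationError(
                "injection_frame", "must leave >= 2 post-injection frames"
            )


def generate_leakage_stack(spec: LeakagePhantomSpec):
    """Generate a leakage time-lapse and its ground-truth vessel mask.

    Pixels inside the true mask hold exactly ``inside_intensity`` in
    every frame (the labeled plasma pool); non-osseous pixels outside it
    start at the background and, from the injection frame on, rise
    linearly at ``outside_slope``. Rendering inside the mask is hardened
    (no soft edge) so the closed-form I_out/I_in slope is exact.

    Returns (TimeLapseStack, vessel_mask, RegionSet).
    """
    base = spec.base
    _, mask, oss = render_vessel_image(replace(base, noise_sd=0.0))
    frames = np.empty((spec.n_frames,) + tuple(base.image_shape), dtype=float)
    t_inject = spec.injection_frame * spec.frame_interval
    outside = ~mask & ~oss
    for i in range(spec.n_frames):
        t = i * spec.frame_interval
        frame = np.full(base.image_shape, base.background_intensity, dtype=float)
        frame[mask] = spec.inside_intensity
        if i >= spec.injection_frame:
            frame[outside] += spec.outside_slope * (t - t_inject)
        frames[i] = frame
    if base.noise_sd > 0:
        rng = np.random.default_rng(base.seed)
        frames = np.clip(frames + rng.normal(0.0, base.noise_sd, frames.shape), 0.0, None)
    timestamps = np.arange(spec.n_frames) * spec.frame_interval
    stack = TimeLapseStack(frames=frames, timestamps=timestamps, pixel_size=base.pixel_size)
    regions = RegionSet(marrow_roi=~oss, osseous_roi=oss)
    return stack, mask, regions


# ---------------------------------------------------------------------------
# kymographs


@dataclass(frozen=True)
class KymographSpec:
    n_positions: int = 256
    n_lines: int = 128
    pixel_size: float = 1.0  # um/pixel
    line_period: float = 1.0  # ms/line
    true_velocity: float = 1.0  # um/ms
    streak_density: float = 8.0  # expected streaks per line
    streak_contrast: float = 500.0  # a.u. dip depth
    background_intensity: float = 1000.0
    streak_sigma_px: float = 1.2
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_lines < 2:
            raise SpecValidationError("n_lines", "need >= 2 scan lines")
        if self.n_positions < 4:
            raise SpecValidationError("n_positions", "need >= 4 positions per line")
        if self.pixel_size <= 0:
            raise SpecValidationError("pixel_size", "must be > 0 um/pixel")
        if self.line_period <= 0:
            raise SpecValidationError("line_period", "must be > 0 ms/line")
        if not np.isfinite(self.true_velocity):
            raise SpecValidationError("true_velocity", "must be finite")
        if self.streak_density < 0:
            raise SpecValidationError("streak_density", "must be >= 0")
        if self.noise_sd < 0:
            raise SpecValidationError("noise_sd", "must be >= 0")


def generate_kymograph(spec: KymographSpec) -> Kymograph:
    """Dark Gaussian-profile streaks advancing ``v * T / dx`` px per line.

    Streak entry positions are drawn uniformly over an extended range so
    the expected number of streaks crossing any one line equals
    ``streak_density``. A zero density yields a uniform bright image
    flagged with ``metadata['empty'] = True``.
    """
    rng = np.random.default_rng(spec.seed)
    v_px = spec.true_velocity * spec.line_period / spec.pixel_size  # px per line
    image = np.full((spec.n_lines, spec.n_positions), spec.background_intensity, dtype=float)
    span = abs(v_px) * (spec.n_lines - 1)
    x_lo = -span if v_px > 0 else 0.0
    x_hi = spec.n_positions + (span if v_px < 0 else 0.0)
    extent = x_hi - x_lo
    n_streaks = int(round(spec.streak_density * extent / spec.n_positions)) if spec.streak_density > 0 else 0
    lines = np.arange(spec.n_lines)[:, None]
    cols = np.arange(spec.n_positions)[None, :]
    x0s = np.sort(rng.uniform(x_lo, x_hi, size=n_streaks))
    for x0 in x0s:
        centers = x0 + v_px * lines  # (n_lines, 1)
        dip = spec.streak_contrast * np.exp(-((cols - centers) ** 2) / (2 * spec.streak_sigma_px**2))
        image -= dip
    image = np.clip(image, 0.0, None)
    if spec.noise_sd > 0:
        image = np.clip(image + rng.normal(0.0, spec.noise_sd, image.shape), 0.0, None)
    meta = {
        "true_velocity": spec.true_velocity,
        "true_px_per_line": v_px,
        "n_streaks": n_streaks,
        "streak_x0": x0s.tolist(),
        "empty": n_streaks == 0,
        "seed": spec.seed,
    }
    return Kymograph(image=image, pixel_size=spec.pixel_size, line_period=spec.line_period, metadata=meta)


# ---------------------------------------------------------------------------
# VFA / DCE series


@dataclass(frozen=True)
class DCEPhantomSpec:
    """Femoral DCE phantom with a two-parameter linear tissue model.

    Tissue concentration is C(t) = (fbv + ps * t) * C_blood(t); signals
    run through the spoiled gradient-echo model at the acquisition's
    flip-angle schedule. Healthy defaults carry the cohort truth
    fbv = 0.208 +/- 0.044 (between-phantom spread, truncated to (0, 1)).
    """

    true_fbv: float = 0.208
    true_ps: float = 0.004  # min^-1
    blood_concentration: float | tuple = 0.3  # mM; scalar = constant curve
    sample_times: tuple = tuple(float(t) for t in range(25, 250, 25))  # s
    flip_angles_pre: tuple = DEFAULT_FLIP_ANGLES_PRE
    flip_angle_post: float = DEFAULT_FLIP_ANGLE_POST
    tr: float = DEFAULT_TR_MS  # ms
    r1_pre: float = 1.0  # s^-1
    s0: float = 1000.0  # a.u.
    relaxivity: float = 145.0  # mM^-1 s^-1
    noise_sd: float = 0.0  # a.u.
    cohort_fbv_sd: float = 0.044
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.true_fbv < 1):
            raise SpecValidationError("true_fbv", "must lie in (0, 1)")
        if self.true_ps < 0:
            raise SpecValidationError("true_ps", "must be >= 0 min^-1")
        if self.relaxivity <= 0:
            raise SpecValidationError("relaxivity", "must be > 0 mM^-1 s^-1")
        t = np.asarray(self.sample_times, dtype=float)
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise SpecValidationError("sample_times", "must be strictly increasing, >= 2 points")
        angles = np.asarray(self.flip_angles_pre, dtype=float)
        if np.any((angles <= 0) | (angles > 90)) or not (0 < self.flip_angle_post <= 90):
            raise SpecValidationError("flip_angles_pre", "flip angles must lie in (0, 90] degrees")
        if self.r1_pre <= 0:
            raise SpecValidationError("r1_pre", "must be > 0 s^-1")
        if self.noise_sd < 0:
            raise SpecValidationError("noise_sd", "must be >= 0")
        if self.cohort_fbv_sd < 0:
            raise SpecValidationError("cohort_fbv_sd", "must be >= 0")


def _blood_curve(spec: DCEPhantomSpec) -> np.ndarray:
    t = np.asarray(spec.sample_times, dtype=float)
    if np.isscalar(spec.blood_concentration) or isinstance(spec.blood_concentration, float):
        return np.full(t.shape, float(spec.blood_concentration))
    curve = np.asarray(spec.blood_concentration, dtype=float)
    if curve.shape != t.shape:
        raise SpecValidationError("blood_concentration", "curve length must match sample_times")
    return curve


def generate_vfa_dce(spec: DCEPhantomSpec):
    """Generate one phantom's VFA and DCE series plus the truth record.

    Returns (VFASeries, DCESeries, truth) where truth holds the exact
    fbv, ps, r1_pre, s0 and the concentration curves used.
    """
    rng = np.random.default_rng(spec.seed)
    times = np.asarray(spec.sample_times, dtype=float)
    c_blood = _blood_curve(spec)
    c_tissue = (spec.true_fbv + spec.true_ps * times / 60.0) * c_blood
    r1_tissue = spec.r1_pre + spec.relaxivity * c_tissue
    r1_blood = spec.r1_pre + spec.relaxivity * c_blood
    vfa_signals = spgr_signal(spec.s0, spec.r1_pre, np.asarray(spec.flip_angles_pre), spec.tr)
    tissue = spgr_signal(spec.s0, r1_tissue, spec.flip_angle_post, spec.tr)
    blood = spgr_signal(spec.s0, r1_blood, spec.flip_angle_post, spec.tr)
    if spec.noise_sd > 0:
        vfa_signals = np.clip(vfa_signals + rng.normal(0, spec.noise_sd, vfa_signals.shape), 0, None)
        tissue = np.clip(tissue + rng.normal(0, spec.noise_sd, tissue.shape), 0, None)
        blood = np.clip(blood + rng.normal(0, spec.noise_sd, blood.shape), 0, None)
    vfa = VFASeries(signals=vfa_signals, flip_angles=np.asarray(spec.flip_angles_pre), tr=spec.tr)
    dce = DCESeries(
        tissue_signals=tissue,
        blood_signals=blood,
        times=times,
        flip_angle_post=spec.flip_angle_post,
        tr=spec.tr,
    )
    truth = {
        "fbv": spec.true_fbv,
        "ps": spec.true_ps,
        "r1_pre": spec.r1_pre,
        "s0": spec.s0,
        "relaxivity": spec.relaxivity,
        "c_blood": c_blood,
        "c_tissue": c_tissue,
        "seed": spec.seed,
    }
    return vfa, dce, truth


def generate_vfa_dce_cohort(spec: DCEPhantomSpec, n: int):
    """Cohort of ``n`` phantoms with per-phantom FBV ~ Normal(truth, sd).

    Draws are truncated to (0, 1) by redrawing; each phantom gets an
    independent child seed so the cohort is reproducible from
    ``spec.seed`` alone. Returns a list of (VFASeries, DCESeries, truth).
    """
    if n < 1:
        raise SpecValidationError("n", "cohort size must be >= 1")
    rng = np.random.default_rng(spec.seed)
    fbvs = []
    while len(fbvs) < n:
        draw = rng.normal(spec.true_fbv, spec.cohort_fbv_sd)
        if 0.0 < draw < 1.0:
            fbvs.append(float(draw))
    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    out = []
    for fbv, child in zip(fbvs, child_seeds):
        member = replace(spec, true_fbv=fbv, seed=int(child))
        out.append(generate_vfa_dce(member))
    return out


# ---------------------------------------------------------------------------
# morphometry scenes


@dataclass(frozen=True)
class Sprout:
    """A protrusion: attachment (row, col) on a vessel, polar direction."""

    attachment: tuple
    length_um: float
    angle_deg: float

    def __post_init__(self):
        if self.length_um <= 0:
            raise SpecValidationError("length_um", "sprout length must be > 0 um")


@dataclass
class MorphometryScene:
    vessel_image: np.ndarray
    cell_image: np.ndarray
    vessel_mask: np.ndarray
    osseous: np.ndarray
    pixel_size: float
    truth: dict = field(default_factory=dict)


def _analytic_branch_points(segments, merge_radius_px=2.0):
    """Count pairwise centerline crossings, merging nearby intersections."""
    points = []
    for i in range(len(segments)):
        for j in range(i + 1, len(segments)):
            a = LineString([segments[i].start, segments[i].end])
            b = LineString([segments[j].start, segments[j].end])
            inter = a.intersection(b)
            if inter.is_empty:
                continue
            geoms = getattr(inter, "geoms", [inter])
            for g in geoms:
                if g.geom_type == "Point":
                    points.append((g.x, g.y))
    merged = []
    for p in points:
        if all(np.hypot(p[0] - q[0], p[1] - q[1]) > merge_radius_px for q in merged):
            merged.append(p)
    return len(merged)


def generate_morphometry_scene(
    spec: VesselPhantomSpec,
    sprouts=(),
    cell_pixels=(),
    sprout_radius_um: float | None = None,
    cell_intensity: float = 500.0,
) -> MorphometryScene:
    """Render a two-channel scene with analytic ground truth.

    The vessel channel contains the spec's segments plus sprout capsules
    of the stated lengths growing outward from their attachment points;
    the cell channel holds the listed myeloid-like pixels. Ground truth
    records the analytic branch-point count (pairwise centerline
    crossings), the sprout lengths, and each cell pixel's brute-force
    distance to the nearest vessel pixel (um, osseous cells excluded).
    """
    base_img, base_mask, oss = render_vessel_image(spec)
    shape = spec.image_shape
    seg_list = list(spec.vessel_segments)
    sprout_lengths = []
    radius_um = sprout_radius_um if sprout_radius_um is not None else spec.pixel_size
    for s in sprouts:
        if not isinstance(s, Sprout):
            s = Sprout(*s)
        att = np.asarray(s.attachment, dtype=float)
        on_vessel = False
        for seg in spec.vessel_segments:
            d = _point_segment_distance(att, seg)
            if d <= seg.radius_um / spec.pixel_size + 0.5:
                on_vessel = True
                break
        if not on_vessel:
            raise SpecValidationError("sprouts", f"attachment {tuple(att)} is off any vessel")
        ang = np.deg2rad(s.angle_deg)
        direction = np.array([np.sin(ang), np.cos(ang)])
        tip = att + direction * (s.length_um / spec.pixel_size)
        seg_list.append(
            VesselSegment(start=tuple(att), end=tuple(tip), radius_um=radius_um,
                          intensity=spec.vessel_segments[0].intensity if spec.vessel_segments else 1000.0)
        )
        sprout_lengths.append(float(s.length_um))
    full_spec = replace(spec, vessel_segments=tuple(seg_list))
    vessel_img, vessel_mask, oss = render_vessel_image(full_spec)

    cell_img = np.zeros(shape, dtype=float)
    kept_cells = []
    for (r, c) in cell_pixels:
        if not (0 <= r < shape[0] and 0 <= c < shape[1]):
            raise SpecValidationError("cell_pixels", f"pixel {(r, c)} lies outside the image")
        cell_img[int(r), int(c)] = cell_intensity
        if not oss[int(r), int(c)]:
            kept_cells.append((int(r), int(c)))

    vr, vc = np.nonzero(vessel_mask)
    cell_distances = []
    for (r, c) in kept_cells:
        d = np.min(np.hypot(vr - r, vc - c)) * spec.pixel_size if vr.size else np.inf
        cell_distances.append(float(d))

    truth = {
        "branch_points": _analytic_branch_points(spec.vessel_segments),
        "sprout_lengths": sorted(sprout_lengths),
        "cell_pixels": kept_cells,
        "cell_distances": cell_distances,
    }
    return MorphometryScene(
        vessel_image=vessel_img,
        cell_image=cell_img,
        vessel_mask=vessel_mask,
        osseous=oss,
        pixel_size=spec.pixel_size,
        truth=truth,
    )


def _point_segment_distance(p, seg: VesselSegment) -> float:
    a = np.asarray(seg.start, dtype=float)
    b = np.asarray(seg.end, dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return float(np.linalg.norm(p - a))
    t = np.clip((p - a) @ ab / denom, 0.0, 1.0)
    return float(np.linalg.norm(p - (a + t * ab)))
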