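"""Macromolecular DCE-MRI chain.

Variable-flip-angle R1 estimation with the steady-state spoiled
gradient-echo (FLASH) signal model, inversion of post-contrast signals to
R1(t), relaxivity-based conversion to contrast-agent concentration,
blood-pool normalization, and the two-parameter linear model whose
intercept at the time of contrast administration is the fractional blood
volume (FBV) and whose slope is the permeability-surface-area product
(PS, reported in min^-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, SpecValidationError

#: Default contrast-agent relaxivity in mM^-1 s^-1.
DEFAULT_RELAXIVITY = 145.0

_SECONDS_PER_MINUTE = 60.0


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class VFASeries:
    """Spoiled gradient-echo signals acquired at several flip angles.

    Parameters
    ----------
    signals : array-like
        Magnitude signal per flip angle (a.u.). Either one scalar per
        angle or an ``(n_angles, ...)`` pixel array.
    flip_angles : array-like
        Excitation flip angles in degrees.
    tr : float
        Repetition time in milliseconds.
    """

    signals: np.ndarray
    flip_angles: np.ndarray
    tr: float

    def __post_init__(self):
        object.__setattr__(self, "signals", np.asarray(self.signals, dtype=float))
        object.__setattr__(self, "flip_angles", np.asarray(self.flip_angles, dtype=float))
        if self.tr <= 0:
            raise SpecValidationError("tr", "repetition time must be > 0 ms")
        if self.flip_angles.ndim != 1 or np.unique(self.flip_angles).size < 3:
            raise SpecValidationError("flip_angles", "need >= 3 distinct flip angles")
        if np.any((self.flip_angles <= 0) | (self.flip_angles > 90)):
            raise SpecValidationError("flip_angles", "flip angles must lie in (0, 90] degrees")
        if self.signals.shape[0] != self.flip_angles.size:
            raise SpecValidationError("signals", "first axis must match flip_angles")
        if np.any(self.signals < 0):
            raise SpecValidationError("signals", "signals must be >= 0")


@dataclass(frozen=True)
class R1Fit:
    """Result of a variable-flip-angle R1 fit."""

    r1: float  # s^-1
    s0: float  # a.u.
    residual_norm: float  # a.u.

    def __post_init__(self):
        if not (self.r1 > 0):
            raise SpecValidationError("r1", "fitted R1 must be > 0")
        if not (self.s0 > 0):
            raise SpecValidationError("s0", "fitted S0 must be > 0")


@dataclass(frozen=True)
class DCESeries:
    """Dynamic post-contrast signal series for a tissue ROI and blood pool.

    Times are seconds after contrast administration. ``blood_signals``
    comes from a blood-pool ROI (vena cava) and is used for
    normalization.
    """

    tissue_signals: np.ndarray
    blood_signals: np.ndarray
    times: np.ndarray
    flip_angle_post: float
    tr: float

    def __post_init__(self):
        object.__setattr__(self, "tissue_signals", np.asarray(self.tissue_signals, dtype=float))
        object.__setattr__(self, "blood_signals", np.asarray(self.blood_signals, dtype=float))
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if self.times.ndim != 1 or self.times.size < 2:
            raise SpecValidationError("times", "need >= 2 time points")
        if np.any(np.diff(self.times) <= 0):
            raise SpecValidationError("times", "times must be strictly increasing")
        if self.times[0] < 0:
            raise SpecValidationError("times", "times are offsets from injection, must be >= 0")
        if self.tissue_signals.shape[0] != self.times.size:
            raise SpecValidationError("tissue_signals", "length must match times")
        if self.blood_signals.shape != (self.times.size,):
            raise SpecValidationError("blood_signals", "length must match times")
        if not (0 < self.flip_angle_post <= 90):
            raise SpecValidationError("flip_angle_post", "must lie in (0, 90] degrees")
        if self.tr <= 0:
            raise SpecValidationError("tr", "repetition time must be > 0 ms")


@dataclass(frozen=True)
class ConcentrationCurve:
    """Tissue and blood contrast concentrations plus their ratio."""

    c_tissue: np.ndarray  # mM
    c_blood: np.ndarray  # mM
    normalized: np.ndarray  # dimensionless; NaN where c_blood <= 0
    relaxivity: float  # mM^-1 s^-1
    clamped_points: int = 0  # negative concentrations clipped to zero

    def __post_init__(self):
        if self.relaxivity <= 0:
            raise SpecValidationError("relaxivity", "must be > 0")


@dataclass(frozen=True)
class PermeabilityFit:
    """Two-parameter linear DCE model.

    ``fbv`` is the regression value extrapolated to the time of contrast
    administration (t = 0); ``ps`` is the slope expressed in min^-1
    regardless of the time unit of the input samples.
    """

    fbv: float
    ps: float  # min^-1
    r_squared: float
    n_points: int = 2
    dropped_points: int = 0


# ---------------------------------------------------------------------------
# signal model


def spgr_signal(s0, r1, flip_angle_deg, tr_ms):
    """Steady-state spoiled gradient-echo signal.

    S = s0 * sin(a) * (1 - E) / (1 - E cos(a)),  E = exp(-TR * R1).
    ``tr_ms`` is in milliseconds, ``r1`` in s^-1.
    """
    a = np.deg2rad(flip_angle_deg)
    e1 = np.exp(-(np.asarray(tr_ms) / 1000.0) * np.asarray(r1))
    return s0 * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))


def _despot1_init(signals, flip_angles, tr_ms):
    """Linearized (DESPOT1) initial guess: S/sin(a) = E * S/tan(a) + s0(1-E)."""
    a = np.deg2rad(flip_angles)
    y = signals / np.sin(a)
    x = signals / np.tan(a)
    slope, intercept = np.polyfit(x, y, 1)
    slope = min(max(slope, 1e-6), 1.0 - 1e-9)
    r1 = -np.log(slope) / (tr_ms / 1000.0)
    s0 = intercept / (1.0 - slope)
    if not np.isfinite(r1) or r1 <= 0:
        r1 = 1.0
    if not np.isfinite(s0) or s0 <= 0:
        s0 = float(np.max(signals)) or 1.0
    return float(r1), float(s0)


def fit_vfa_r1(series: VFASeries) -> R1Fit:
    """Fit (R1, S0) to variable-flip-angle signals by nonlinear least squares.

    Uses a linearized initialization followed by bounded
    Levenberg-Marquardt-style refinement; up to three perturbed restarts
    are attempted before giving up.

    Raises
    ------
    FitError
        If the signals are all zero, flat across flip angles, or no
        restart converges.
    """
    signals = np.asarray(series.signals, dtype=float)
    if signals.ndim != 1:
        raise SpecValidationError("signals", "fit_vfa_r1 expects one signal per flip angle")
    if not np.any(signals > 0):
        raise FitError("all-zero VFA signals: no R1 information")
    if np.ptp(signals) == 0:
        raise FitError(
            "VFA signals are constant across flip angles; the spoiled "
            "gradient-echo model cannot produce a flat response"
        )

    angles = series.flip_angles
    tr = series.tr

    def residuals(params):
        log_r1, log_s0 = params
        return spgr_signal(np.exp(log_s0), np.exp(log_r1), angles, tr) - signals

    r1_0, s0_0 = _despot1_init(signals, angles, tr)
    scale = float(np.max(signals))
    best = None
    rng_offsets = [(0.0, 0.0), (0.5, 0.0), (-0.5, 0.0), (0.0, 0.5)]
    for dr, ds in rng_offsets:
        x0 = np.array([np.log(r1_0) + dr, np.log(s0_0) + ds])
        try:
            sol = least_squares(residuals, x0, method="lm", max_nfev=500)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.cost < (1e-12 * scale) ** 2:
            break
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitError("VFA R1 fit did not converge after bounded restarts")
    r1 = float(np.exp(best.x[0]))
    s0 = float(np.exp(best.x[1]))
    resid = float(np.linalg.norm(residuals(best.x)))
    if resid > 0.5 * np.linalg.norm(signals):
        raise FitError(f"VFA R1 fit residual too large (|r| = {resid:.3g})")
    return R1Fit(r1=r1, s0=s0, residual_norm=resid)


def post_contrast_r1(signal_t, precontrast: R1Fit, flip_angle_deg: float, tr_ms: float):
    """Invert the spoiled gradient-echo model to R1(t) at one flip angle.

    Uses ``s0`` from the precontrast fit. Solving the signal equation for
    E = exp(-TR*R1) gives E = (s0 sin a - S) / (s0 sin a - S cos a).

    Raises
    ------
    FitError
        If the signal is non-positive (contrast cannot erase signal) or
        reaches/exceeds the saturation value ``s0 * sin(a)``.
    """
    s = np.asarray(signal_t, dtype=float)
    a = np.deg2rad(flip_angle_deg)
    sat = precontrast.s0 * np.sin(a)
    if np.any(s <= 0):
        raise FitError("post-contrast signal <= 0 is non-physical (R1 -> 0 limit)")
    if np.any(s >= sat):
        raise FitError(
            f"post-contrast signal exceeds the saturation signal s0*sin(a) = {sat:.6g}; "
            "non-physical input"
        )
    e1 = (sat - s) / (sat - s * np.cos(a))
    r1 = -np.log(e1) / (tr_ms / 1000.0)
    return r1 if r1.shape else float(r1)


def concentration_from_r1(r1_t, r1_pre, relaxivity=DEFAULT_RELAXIVITY):
    """Convert R1 change to concentration: C = (R1(t) - R1_pre) / relaxivity.

    Negative differences (noise) are clamped to 0 mM; the number of
    clamped points is returned alongside the concentrations.

    Returns
    -------
    (concentration_mM, n_clamped)
    """
    if relaxivity <= 0:
        raise SpecValidationError("relaxivity", "must be > 0")
    c = (np.asarray(r1_t, dtype=float) - r1_pre) / relaxivity
    n_clamped = int(np.sum(c < 0))
    c = np.clip(c, 0.0, None)
    return (c if c.shape else float(c)), n_clamped


def concentration_curve(
    dce: DCESeries,
    precontrast: R1Fit,
    relaxivity: float = DEFAULT_RELAXIVITY,
    blood_precontrast: R1Fit | None = None,
) -> ConcentrationCurve:
    """Run signal -> R1 -> concentration for tissue and blood series.

    ``blood_precontrast`` defaults to the tissue precontrast fit (same
    ROI-independent S0 and baseline R1), which is exact for phantoms and
    a documented approximation for acquired data.
    """
    blood_pre = blood_precontrast or precontrast
    r1_tissue = post_contrast_r1(dce.tissue_signals, precontrast, dce.flip_angle_post, dce.tr)
    r1_blood = post_contrast_r1(dce.blood_signals, blood_pre, dce.flip_angle_post, dce.tr)
    c_tissue, clamped_t = concentration_from_r1(r1_tissue, precontrast.r1, relaxivity)
    c_blood, clamped_b = concentration_from_r1(r1_blood, blood_pre.r1, relaxivity)
    normalized = np.full_like(np.asarray(c_tissue, dtype=float), np.nan)
    ok = np.asarray(c_blood) > 0
    normalized[ok] = np.asarray(c_tissue)[ok] / np.asarray(c_blood)[ok]
    return ConcentrationCurve(
        c_tissue=np.asarray(c_tissue),
        c_blood=np.asarray(c_blood),
        normalized=normalized,
        relaxivity=relaxivity,
        clamped_points=clamped_t + clamped_b,
    )


def fit_permeability(curve: ConcentrationCurve, times, time_unit: str = "s") -> PermeabilityFit:
    """Ordinary least squares of normalized concentration against time.

    The intercept extrapolated to t = 0 (time of contrast administration)
    is the fractional blood volume; the slope, converted to min^-1, is
    the permeability-surface-area product. Points where the blood
    concentration was non-positive (NaN in ``normalized``) are dropped,
    never imputed.
    """
    if time_unit not in ("s", "min"):
        raise SpecValidationError("time_unit", "must be 's' or 'min'")
    t = np.asarray(times, dtype=float)
    y = np.asarray(curve.normalized, dtype=float)
    if t.shape != y.shape:
        raise SpecValidationError("times", "length must match the normalized curve")
    ok = np.isfinite(y) & np.isfinite(t)
    n_dropped = int(y.size - ok.sum())
    t, y = t[ok], y[ok]
    if t.size < 2:
        raise FitError("need >= 2 finite normalized points for the linear fit")
    if np.ptp(t) == 0:
        raise FitError("all time points identical; slope undefined")
    t_min = t / _SECONDS_PER_MINUTE if time_unit == "s" else t
    slope, intercept = np.polyfit(t_min, y, 1)
    pred = slope * t_min + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return PermeabilityFit(
        fbv=float(intercept),
        ps=float(slope),
        r_squared=float(r2),
        n_points=int(t.size),
        dropped_points=n_dropped,
    )


def estimate_fbv_ps(
    vfa: VFASeries,
    dce: DCESeries,
    relaxivity: float = DEFAULT_RELAXIVITY,
    blood_vfa: VFASeries | None = None,
) -> PermeabilityFit:
    """Full scalar chain: VFA fit -> R1(t) -> concentration -> normalization -> OLS."""
    pre = fit_vfa_r1(vfa)
    blood_pre = fit_vfa_r1(blood_vfa) if blood_vfa is not None else None
    curve = concentration_curve(dce, pre, relaxivity=relaxivity, blood_precontrast=blood_pre)
    return fit_permeability(curve, dce.times, time_unit="s")


# ---------------------------------------------------------------------------
# pixelwise maps


@dataclass
class ParametricMaps:
    """Per-pixel FBV and PS maps plus mask-mean summaries."""

    fbv_map: np.ndarray
    ps_map: np.ndarray
    failed: np.ndarray  # bool; True where the per-pixel chain errored
    fbv_mean: float
    ps_mean: float
    n_failed: int = 0
    warnings: list = field(default_factory=list)


def parametric_map(
    vfa_stack: np.ndarray,
    dyn_stack: np.ndarray,
    blood_signals: np.ndarray,
    times: np.ndarray,
    flip_angles: np.ndarray,
    flip_angle_post: float,
    tr: float,
    mask: np.ndarray,
    relaxivity: float = DEFAULT_RELAXIVITY,
) -> ParametricMaps:
    """Apply the scalar DCE chain to every pixel inside ``mask``.

    ``vfa_stack`` has shape (n_angles, H, W) and ``dyn_stack``
    (n_times, H, W). Pixels whose fit fails are flagged, excluded from
    the mask means and counted; they do not abort the map.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vfa_stack.shape[1:] or mask.shape != dyn_stack.shape[1:]:
        raise SpecValidationError("mask", "mask shape must match image shape")
    if not mask.any():
        raise SpecValidationError("mask", "mask is empty")

    blood_pre_fit = None
    fbv_map = np.full(mask.shape, np.nan)
    ps_map = np.full(mask.shape, np.nan)
    failed = np.zeros(mask.shape, dtype=bool)
    for r, c in zip(*np.nonzero(mask)):
        try:
            vfa = VFASeries(signals=vfa_stack[:, r, c], flip_angles=flip_angles, tr=tr)
            dce = DCESeries(
                tissue_signals=dyn_stack[:, r, c],
                blood_signals=blood_signals,
                times=times,
                flip_angle_post=flip_angle_post,
                tr=tr,
            )
            pre = fit_vfa_r1(vfa)
            if blood_pre_fit is None:
                blood_pre_fit = pre  # blood series is global; reuse first pixel's S0 scale
            curve = concentration_curve(dce, pre, relaxivity=relaxivity)
            fit = fit_permeability(curve, dce.times, time_unit="s")
        except (FitError, SpecValidationError):
            failed[r, c] = True
            continue
        fbv_map[r, c] = fit.fbv
        ps_map[r, c] = fit.ps

    good = mask & ~failed
    if not good.any():
        raise FitError("every pixel inside the mask failed to fit")
    return ParametricMaps(
        fbv_map=fbv_map,
        ps_map=ps_map,
        failed=failed,
        fbv_mean=float(np.mean(fbv_map[good])),
        ps_mean=float(np.mean(ps_map[good])),
        n_failed=int(failed.sum()),
    )
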