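"""Monoexponential recovery fitting and the per-movie analysis pipeline.

The normalized post-bleach curve is fitted with ``F(t) = M * (1 - exp(-t/tau))``
by bounded nonlinear least squares (no offset term: normalization pins
``F(0) = 0``).  The mobile fraction is the fitted model evaluated at the last
recorded recovery time point, and the recovery half-time is read directly
from the data by linear interpolation to half of the tail-mean maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .curves import (
    RecoveryCurve,
    TimeSeries,
    correct_and_normalize,
    extract_series,
    fit_acquisition_decay,
)
from .io import ExperimentConfig, FrapMovie, NucleusMask
from .registration import register_stack
from .segmentation import BleachROI, detect_bleach_roi

__all__ = [
    "FitResult",
    "AnalysisResult",
    "PipelineError",
    "fit_recovery",
    "estimate_t_half",
    "analyze_movie",
]


@dataclass
class FitResult:
    """Recovery-fit summary for one nucleus."""

    plateau_M: float
    tau_s: float
    mobile_fraction: float
    t_half_s: float = np.nan
    rss: float = np.nan
    converged: bool = True
    qc_flags: set = field(default_factory=set)
    source_id: str = ""
    n_pre: int = 0
    n_post: int = 0


@dataclass
class AnalysisResult:
    """Everything produced by the per-movie pipeline."""

    fit: FitResult
    curve: RecoveryCurve
    roi: BleachROI
    drift: np.ndarray
    decay: object
    nucleus_series: TimeSeries


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and movie identifier."""

    def __init__(self, stage: str, source_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for {source_id!r}: {cause}")
        self.stage = stage
        self.source_id = source_id
        self.cause = cause


def _model(t: np.ndarray, m: float, tau: float) -> np.ndarray:
    return m * (1.0 - np.exp(-t / tau))


def fit_recovery(curve: RecoveryCurve, tail_fraction: float = 0.05) -> FitResult:
    """Fit ``M * (1 - exp(-t/tau))`` to the normalized post-bleach points.

    Init: M0 = mean of the final ``tail_fraction`` of points; tau0 = first
    time the data reaches ``(1 - 1/e) * M0`` (fallback T_last/3).  Bounds:
    M in [0, 1.5], tau in (0, 100*T_last].  The result is never clamped;
    out-of-[0, 1] mobile fractions are flagged in ``qc_flags``.
    """
    t = np.asarray(curve.post_times, dtype=np.float64)
    y = np.asarray(curve.post_normalized, dtype=np.float64)
    if len(y) < 20:
        raise ValueError("fit_recovery needs >= 20 post-bleach points")
    t_last = float(t[-1])
    n_tail = max(1, int(round(tail_fraction * len(y))))
    m0 = float(np.clip(np.mean(y[-n_tail:]), 0.0, 1.5))

    tau0 = t_last / 3.0
    target = (1.0 - np.exp(-1.0)) * m0
    if m0 > 0:
        reached = np.nonzero((y >= target) & (t > 0))[0]
        if reached.size:
            tau0 = float(t[reached[0]])
    tau_hi = 100.0 * t_last
    tau0 = float(np.clip(tau0, 1e-6, tau_hi))

    if np.all(y == 0):  # exact immobile curve
        return FitResult(
            plateau_M=0.0, tau_s=tau0, mobile_fraction=0.0, rss=0.0,
            converged=True, qc_flags=set(), source_id=curve.source_id,
            n_pre=curve.n_prebleach, n_post=len(y),
        )

    qc: set = set()
    converged = True
    try:
        popt, _ = curve_fit(
            _model,
            t,
            y,
            p0=(m0, tau0),
            bounds=([0.0, 1e-9], [1.5, tau_hi]),
            ftol=1e-14,
            xtol=1e-14,
            gtol=1e-14,
            maxfev=20000,
        )
        m_hat, tau_hat = float(popt[0]), float(popt[1])
    except RuntimeError:
        converged = False
        qc.add("fit_not_converged")
        m_hat, tau_hat = m0, tau0

    rss = float(np.sum((y - _model(t, m_hat, tau_hat)) ** 2))
    mobile = float(m_hat * (1.0 - np.exp(-t_last / tau_hat)))
    if not 0.0 <= mobile <= 1.0:
        qc.add("mobile_fraction_out_of_range")
    return FitResult(
        plateau_M=m_hat,
        tau_s=tau_hat,
        mobile_fraction=mobile,
        rss=rss,
        converged=converged,
        qc_flags=qc,
        source_id=curve.source_id,
        n_pre=curve.n_prebleach,
        n_post=len(y),
    )


def estimate_t_half(
    curve: RecoveryCurve, fit: FitResult | None = None, tail_fraction: float = 0.05
) -> float:
    """Recovery half-time read directly from the normalized data.

    The fluorescence maximum is the mean of the final ``tail_fraction`` of
    post-bleach points; t_half is the first time the data crosses half of it,
    linearly interpolated between the bracketing frames.  Returns NaN (and
    flags the fit, if given) when the curve never crosses half-maximum.
    """
    t = np.asarray(curve.post_times, dtype=np.float64)
    y = np.asarray(curve.post_normalized, dtype=np.float64)
    n_tail = max(1, int(round(tail_fraction * len(y))))
    ref_max = float(np.mean(y[-n_tail:]))
    half = ref_max / 2.0

    t_half = np.nan
    if ref_max > 0:
        above = np.nonzero(y >= half)[0]
        if above.size:
            i = int(above[0])
            if i == 0:
                t_half = float(t[0])
            else:
                frac = (half - y[i - 1]) / (y[i] - y[i - 1])
                t_half = float(t[i - 1] + frac * (t[i] - t[i - 1]))
    if np.isnan(t_half) and fit is not None:
        fit.qc_flags.add("t_half_undefined")
    return t_half


def analyze_movie(
    movie: FrapMovie,
    nucleus_mask: NucleusMask,
    config: ExperimentConfig | None = None,
) -> AnalysisResult:
    """Run the full per-movie pipeline in acquisition order.

    register -> detect bleach ROI -> extract ROI and nucleus series -> fit
    acquisition decay -> correct and normalize -> fit recovery -> half-time.
    Any stage error is re-raised as :class:`PipelineError` carrying the stage
    name and source id.  Deterministic: the same movie always yields the same
    result.
    """
    cfg = config or ExperimentConfig()
    sid = movie.source_id

    try:
        registered, drift = register_stack(movie, upsample=cfg.upsample)
    except Exception as exc:
        raise PipelineError("registration", sid, exc) from exc

    try:
        roi = detect_bleach_roi(
            registered,
            nucleus_mask,
            n_post_for_diff=cfg.n_post_for_diff,
            n_bins=cfg.otsu_bins,
            dilate=cfg.roi_dilate,
        )
    except Exception as exc:
        raise PipelineError("bleach_detection", sid, exc) from exc

    try:
        roi_series = extract_series(registered, roi.mask)
        nucleus_pixels = nucleus_mask.mask
        if cfg.decay_exclude_roi:
            nucleus_pixels = nucleus_pixels & ~roi.mask
        nucleus_series = extract_series(registered, nucleus_pixels)
    except Exception as exc:
        raise PipelineError("extraction", sid, exc) from exc

    try:
        decay = fit_acquisition_decay(nucleus_series)
    except Exception as exc:
        raise PipelineError("decay_fit", sid, exc) from exc

    try:
        curve = correct_and_normalize(roi_series, decay)
    except Exception as exc:
        raise PipelineError("normalization", sid, exc) from exc

    try:
        fit = fit_recovery(curve, tail_fraction=cfg.tail_fraction)
        fit.t_half_s = estimate_t_half(curve, fit, tail_fraction=cfg.tail_fraction)
    except Exception as exc:
        raise PipelineError("recovery_fit", sid, exc) from exc

    return AnalysisResult(
        fit=fit,
        curve=curve,
        roi=roi,
        drift=drift,
        decay=decay,
        nucleus_series=nucleus_series,
    )
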