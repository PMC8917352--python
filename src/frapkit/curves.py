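"""Intensity series extraction, acquisition-bleach correction and normalization.

Acquisition bleaching is estimated from the whole-nucleus mean of the
post-bleach frames as a monoexponential decay ``A * exp(-k * t)`` and divided
out of the ROI series on the shared time axis (pre-bleach frames carry
negative t).  Each corrected curve is then double-normalized to a pre-bleach
mean of 1 and an immediate post-bleach value of 0 so different acquisitions
are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .io import FrapMovie

__all__ = [
    "TimeSeries",
    "DecayFit",
    "RecoveryCurve",
    "extract_series",
    "fit_acquisition_decay",
    "correct_and_normalize",
]


@dataclass
class TimeSeries:
    """Per-frame mean intensity with t=0 at the first post-bleach frame."""

    times: np.ndarray
    values: np.ndarray
    n_prebleach: int
    source_id: str = ""

    @property
    def post_times(self) -> np.ndarray:
        return self.times[self.n_prebleach :]

    @property
    def post_values(self) -> np.ndarray:
        return self.values[self.n_prebleach :]


@dataclass
class DecayFit:
    """Monoexponential acquisition-bleach fit ``A * exp(-k * t)``, k >= 0."""

    amplitude: float
    rate: float  # per second
    rss: float


@dataclass
class RecoveryCurve:
    """A recovery curve through its raw -> corrected -> normalized states.

    Invariants by construction: the normalized pre-bleach mean is 1 and the
    normalized value at the first post-bleach frame is 0.
    """

    times: np.ndarray
    raw: np.ndarray
    corrected: np.ndarray
    normalized: np.ndarray
    n_prebleach: int
    source_id: str = ""

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.raw) == len(self.corrected) == len(self.normalized) == n):
            raise ValueError("times/raw/corrected/normalized must have equal lengths")

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def post_times(self) -> np.ndarray:
        return self.times[self.n_prebleach :]

    @property
    def post_normalized(self) -> np.ndarray:
        return self.normalized[self.n_prebleach :]


def extract_series(movie: FrapMovie, mask: np.ndarray) -> TimeSeries:
    """Arithmetic mean of the masked pixels in every frame."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != movie.shape:
        raise ValueError(f"mask shape {mask.shape} != frame shape {movie.shape}")
    if not mask.any():
        raise ValueError("mask is empty")
    values = movie.frames[:, mask].mean(axis=1)
    return TimeSeries(
        times=movie.times,
        values=values,
        n_prebleach=movie.n_prebleach,
        source_id=movie.source_id,
    )


def fit_acquisition_decay(series: TimeSeries) -> DecayFit:
    """Least-squares monoexponential fit to the post-bleach whole-nucleus means.

    Initialization: A0 = first post-bleach value; k0 from a log-linear
    regression of the positive values.  k is bounded >= 0.
    """
    t = np.asarray(series.post_times, dtype=np.float64)
    y = np.asarray(series.post_values, dtype=np.float64)
    if len(y) < 10:
        raise ValueError("fit_acquisition_decay needs >= 10 post-bleach points")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in decay series")

    if np.ptp(y) == 0:  # constant series: exact degenerate fit
        return DecayFit(amplitude=float(y[0]), rate=0.0, rss=0.0)

    a0 = y[0] if y[0] > 0 else max(y.max(), 1.0)
    pos = y > 0
    k0 = 0.0
    if pos.sum() >= 2 and np.ptp(t[pos]) > 0:
        slope = np.polyfit(t[pos], np.log(y[pos]), 1)[0]
        k0 = max(0.0, -slope)

    popt, _ = curve_fit(
        lambda tt, a, k: a * np.exp(-k * tt),
        t,
        y,
        p0=(a0, k0),
        bounds=([0.0, 0.0], [np.inf, np.inf]),
        ftol=1e-14,
        xtol=1e-14,
        gtol=1e-14,
        maxfev=10000,
    )
    a, k = float(popt[0]), float(popt[1])
    rss = float(np.sum((y - a * np.exp(-k * t)) ** 2))
    return DecayFit(amplitude=a, rate=k, rss=rss)


def correct_and_normalize(
    series: TimeSeries,
    decay: DecayFit,
    n_prebleach: int | None = None,
    min_relative_depth: float = 1e-6,
) -> RecoveryCurve:
    """Divide out the fitted acquisition decay, then double-normalize.

    corrected(t) = raw(t) / exp(-k*t) on the decay fit's clock (pre-bleach
    frames corrected at their negative t); normalized(t) =
    (corrected(t) - C0) / (C_pre - C0) with C_pre the corrected pre-bleach
    mean and C0 the corrected value at the single first post-bleach frame.

    Raises ``ValueError`` when C_pre and C0 coincide (no bleach depth).
    """
    if not np.isfinite(decay.rate):
        raise ValueError("decay rate must be finite")
    if n_prebleach is None:
        n_prebleach = series.n_prebleach
    times = np.asarray(series.times, dtype=np.float64)
    raw = np.asarray(series.values, dtype=np.float64)
    if decay.rate == 0.0:
        corrected = raw.copy()
    else:
        corrected = raw / np.exp(-decay.rate * times)

    c_pre = corrected[:n_prebleach].mean()
    c0 = corrected[n_prebleach]
    depth = c_pre - c0
    if abs(depth) <= min_relative_depth * max(abs(c_pre), abs(c0)):
        raise ValueError("no bleach detected in curve (C_pre = C0)")
    normalized = (corrected - c0) / depth
    return RecoveryCurve(
        times=times,
        raw=raw,
        corrected=corrected,
        normalized=normalized,
        n_prebleach=n_prebleach,
        source_id=series.source_id,
    )
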