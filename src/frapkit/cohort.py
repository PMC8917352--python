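"""Group-level summaries and tests over per-nucleus FRAP results.

Cohort curves are per-time-point mean +/- s.e.m. after truncating all repeats
to the shortest post-bleach length; group comparisons use the pooled-variance
Student's t-test (Welch available by flag).  The pixel-intensity distribution
comparison uses bin-width-20 densities and a Mann-Whitney U test with the
normal approximation (pixel samples are large).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .curves import RecoveryCurve

__all__ = [
    "CohortCurve",
    "GroupSummary",
    "mean_sem_curves",
    "summarize_group",
    "compare_groups",
    "intensity_density",
    "mann_whitney",
]


@dataclass
class CohortCurve:
    times: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: int


@dataclass
class GroupSummary:
    """Boxplot-style summary: median, IQR and 5th/95th percentile whiskers."""

    median: float
    q1: float
    q3: float
    p5: float
    p95: float
    n: int


def mean_sem_curves(curves: list[RecoveryCurve]) -> CohortCurve:
    """Per-time-point mean and s.e.m. of normalized curves.

    Curves must share the frame interval and pre-bleach count; all repeats are
    truncated to the shortest post-bleach length so n is constant per time
    point.
    """
    if len(curves) < 2:
        raise ValueError("mean_sem_curves needs >= 2 curves")
    dt = curves[0].frame_interval
    n_pre = curves[0].n_prebleach
    for c in curves[1:]:
        if not np.isclose(c.frame_interval, dt, rtol=1e-9):
            raise ValueError(
                f"mixed frame intervals: {c.frame_interval} vs {dt}"
            )
        if c.n_prebleach != n_pre:
            raise ValueError("curves must share n_prebleach")
    n_post = min(len(c.normalized) - c.n_prebleach for c in curves)
    length = n_pre + n_post
    data = np.stack([c.normalized[:length] for c in curves])
    mean = data.mean(axis=0)
    sem = data.std(axis=0, ddof=1) / np.sqrt(len(curves))
    return CohortCurve(
        times=curves[0].times[:length].copy(), mean=mean, sem=sem, n=len(curves)
    )


def summarize_group(values) -> GroupSummary:
    """Median, quartiles (linear interpolation) and 5th/95th percentiles."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 1:
        raise ValueError("summarize_group needs n >= 1")
    p5, q1, med, q3, p95 = np.percentile(values, [5, 25, 50, 75, 95])
    return GroupSummary(
        median=float(med), q1=float(q1), q3=float(q3), p5=float(p5), p95=float(p95),
        n=values.size,
    )


def compare_groups(a, b, equal_var: bool = True) -> tuple[float, float]:
    """Two-tailed independent two-sample t-test; pooled variance by default.

    Degenerate zero-variance inputs return (0, 1) for equal means and
    (+/-inf, 0) with a warning for unequal means.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("compare_groups needs n >= 2 per group")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)

    if equal_var:
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    else:
        se = np.sqrt(va / na + vb / nb)
        if se > 0:
            df = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )

    if se == 0:
        if ma == mb:
            return 0.0, 1.0
        warnings.warn("degenerate t-test: zero variance with unequal means", stacklevel=2)
        return float(np.sign(ma - mb) * np.inf), 0.0

    t = float((ma - mb) / se)
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, p


def intensity_density(
    samples: list[np.ndarray], bin_width: float = 20.0
) -> tuple[np.ndarray, np.ndarray]:
    """Average per-image histogram of pixel intensities.

    Counts in half-open bins of width ``bin_width`` are summed over all images
    of a condition and divided by the number of images.  Returns
    ``(bin_edges, density)``; ``density.sum() * len(samples)`` equals the
    total pixel count exactly.
    """
    if len(samples) == 0:
        raise ValueError("intensity_density needs >= 1 image sample")
    arrays = [np.asarray(s, dtype=np.float64).ravel() for s in samples]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty pixel sample")
    lo = np.floor(min(a.min() for a in arrays) / bin_width) * bin_width
    hi = max(a.max() for a in arrays)
    n_bins = int((hi - lo) // bin_width) + 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    total = np.zeros(n_bins)
    for a in arrays:
        counts, _ = np.histogram(a, bins=edges)
        total += counts
    return edges, total / len(arrays)


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U (midranks for ties) with a two-tailed normal-approximation p.

    Returns ``U = #{a_i > b_j} + ties/2`` so that ``U + U' = n_a * n_b``.
    The p-value uses the tie-corrected normal approximation with continuity
    correction.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    n1, n2 = a.size, b.size
    if n1 < 1 or n2 < 1:
        raise ValueError("mann_whitney needs n >= 1 per sample")
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)  # midranks
    r1 = ranks[:n1].sum()
    u = float(r1 - n1 * (n1 + 1) / 2.0)

    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    if sigma2 <= 0:
        return u, 1.0
    z = u - mu
    z -= 0.5 * np.sign(z)  # continuity correction
    z /= np.sqrt(sigma2)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return u, float(p)
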