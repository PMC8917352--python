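"""QC and cohort plotting (matplotlib, Agg backend)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cohort import CohortCurve
from .fitting import AnalysisResult

__all__ = ["plot_qc_panel", "plot_cohort_curves"]


def plot_qc_panel(result: AnalysisResult, path: str | Path) -> None:
    """Per-nucleus QC panel: normalized curve with fitted overlay, drift, ROI."""
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))

    curve, fit = result.curve, result.fit
    ax = axes[0]
    ax.plot(curve.times, curve.normalized, ".", ms=2, color="0.5", label="data")
    t = np.linspace(0, curve.post_times[-1], 200)
    ax.plot(
        t,
        fit.plateau_M * (1 - np.exp(-t / fit.tau_s)),
        "r-",
        label=f"fit: M={fit.plateau_M:.3f}, tau={fit.tau_s:.2f}s",
    )
    if np.isfinite(fit.t_half_s):
        ax.axvline(fit.t_half_s, color="b", ls="--", lw=0.8, label=f"t1/2={fit.t_half_s:.2f}s")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("normalized intensity")
    ax.legend(fontsize=7)
    ax.set_title(curve.source_id, fontsize=8)

    ax = axes[1]
    ax.plot(result.drift[:, 1], result.drift[:, 0], "-", lw=0.7)
    ax.set_xlabel("dx (px)")
    ax.set_ylabel("dy (px)")
    ax.set_title("estimated drift", fontsize=8)
    ax.set_aspect("equal", adjustable="datalim")

    ax = axes[2]
    ax.imshow(result.roi.mask, cmap="gray", interpolation="nearest")
    ax.plot(result.roi.centroid[1], result.roi.centroid[0], "r+")
    ax.set_title(f"bleach ROI ({result.roi.area} px)", fontsize=8)
    ax.axis("off")

    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_cohort_curves(groups: dict[str, CohortCurve], path: str | Path) -> None:
    """Mean +/- s.e.m. recovery curves for several conditions on one axis."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, cc in groups.items():
        ax.plot(cc.times, cc.mean, label=f"{name} (n={cc.n})")
        ax.fill_between(cc.times, cc.mean - cc.sem, cc.mean + cc.sem, alpha=0.3)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("mean normalized intensity")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
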