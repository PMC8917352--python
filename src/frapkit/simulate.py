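"""Synthetic FRAP movies with known ground truth.

A disk-shaped nucleus sits on a flat background; at the bleach frame the
signal inside a bleach disk is multiplied by ``1 - bleach_depth`` and then
recovers by single-exponential exchange of a mobile pool.  Optional layers on
top of the ideal signal: multiplicative per-frame acquisition bleaching,
cumulative lateral drift (applied as an exact Fourier phase shift), and
additive Gaussian noise clipped at zero.  Every simulated movie comes with a
:class:`GroundTruth` so downstream stages are testable without real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import FrapMovie
from .registration import fourier_translate

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "simulate_frap_movie",
    "roi_mean_closed_form",
    "simulate_cohort",
    "iter_cohort",
    "disk_mask",
]


def disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


@dataclass
class SimulationParams:
    """Parameters of one simulated FRAP acquisition.

    Defaults follow the acquisition protocol: 20 pre-bleach frames, 500
    recovery frames at 0.21 s/frame, 128x128 px geometry with a 40 px nucleus
    and a 6 px bleach spot.
    """

    image_size: tuple[int, int] = (128, 128)
    nucleus_center: tuple[float, float] = (64.0, 64.0)
    nucleus_radius: float = 40.0
    baseline_intensity: float = 1000.0
    background_intensity: float = 50.0
    n_prebleach: int = 20
    n_postbleach: int = 500
    frame_interval: float = 0.21
    bleach_center: tuple[float, float] = (64.0, 64.0)
    bleach_radius: float = 6.0
    bleach_depth: float = 0.9  # beta, fraction bleached in (0, 1]
    mobile_fraction: float = 0.3  # m in [0, 1]
    tau: float = 3.75  # recovery time constant, seconds
    acquisition_decay_rate: float = 0.0  # k, per-frame fraction >= 0
    drift_per_frame: tuple[float, float] | np.ndarray | None = None
    noise_sd: float = 0.0  # fraction of baseline, >= 0
    noise_model: str = "gaussian"  # "gaussian" | "poisson"
    bleach_edge_sigma: float = 0.0  # 0 = hard disk
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_prebleach < 1:
            raise ValueError("n_prebleach must be >= 1")
        if self.n_postbleach < 10:
            raise ValueError("n_postbleach must be >= 10")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        # beta = 0 is admitted as the degenerate "nothing bleached" control
        if not 0 <= self.bleach_depth <= 1:
            raise ValueError("bleach_depth must be in [0, 1]")
        if not 0 <= self.mobile_fraction <= 1:
            raise ValueError("mobile_fraction must be in [0, 1]")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.acquisition_decay_rate < 0:
            raise ValueError("acquisition_decay_rate must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.baseline_intensity <= 0 or self.background_intensity < 0:
            raise ValueError("intensities must be positive (baseline) / non-negative")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        d = np.hypot(
            self.bleach_center[0] - self.nucleus_center[0],
            self.bleach_center[1] - self.nucleus_center[1],
        )
        if d + self.bleach_radius > self.nucleus_radius:
            raise ValueError("bleach disk must lie fully inside the nucleus disk")

    @property
    def n_frames(self) -> int:
        return self.n_prebleach + self.n_postbleach

    def drift_trajectory(self) -> np.ndarray:
        """Cumulative (dy, dx) displacement of every frame; frame 0 is at (0, 0)."""
        n = self.n_frames
        if self.drift_per_frame is None:
            return np.zeros((n, 2))
        drift = np.asarray(self.drift_per_frame, dtype=np.float64)
        if drift.shape == (2,):
            return np.arange(n)[:, None] * drift[None, :]
        if drift.shape == (n, 2):
            return drift.copy()
        raise ValueError(
            f"drift_per_frame must be a (dy, dx) pair or an ({n}, 2) array of "
            f"cumulative displacements, got shape {drift.shape}"
        )


@dataclass
class GroundTruth:
    """Simulator parameters frozen next to the movie they generated."""

    m: float
    tau: float
    k: float
    beta: float
    drift: np.ndarray  # (n_frames, 2) cumulative displacement
    bleach_mask: np.ndarray  # true bleach disk, un-drifted scene coordinates
    nucleus_mask: np.ndarray
    frame_interval: float
    n_prebleach: int

    @property
    def expected_t_half(self) -> float:
        return self.tau * np.log(2.0)


def _bleach_weight(params: SimulationParams) -> np.ndarray:
    """Spatial weight in [0, 1]: 1 inside the bleach disk, optional Gaussian edge."""
    yy, xx = np.ogrid[: params.image_size[0], : params.image_size[1]]
    dist = np.hypot(yy - params.bleach_center[0], xx - params.bleach_center[1])
    if params.bleach_edge_sigma <= 0:
        return (dist <= params.bleach_radius).astype(np.float64)
    w = np.ones_like(dist)
    outside = dist > params.bleach_radius
    w[outside] = np.exp(
        -((dist[outside] - params.bleach_radius) ** 2)
        / (2 * params.bleach_edge_sigma**2)
    )
    return w


def simulate_frap_movie(params: SimulationParams) -> tuple[FrapMovie, GroundTruth]:
    """Render one FRAP movie and its ground truth.

    Post-bleach ROI mean follows
    ``S(t) = S_pre * [(1 - beta) + beta * m * (1 - exp(-t / tau))]`` with t
    measured from the first post-bleach frame, before the global per-frame
    acquisition decay ``exp(-k * f)`` (f counted from frame 0), drift and
    noise are applied.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size
    nucleus = disk_mask((h, w), params.nucleus_center, params.nucleus_radius)
    bleach_mask = disk_mask((h, w), params.bleach_center, params.bleach_radius)
    weight = _bleach_weight(params)

    base = np.full((h, w), params.background_intensity, dtype=np.float64)
    base[nucleus] = params.baseline_intensity

    traj = params.drift_trajectory()
    beta, m, tau = params.bleach_depth, params.mobile_fraction, params.tau
    k = params.acquisition_decay_rate

    frames = np.empty((params.n_frames, h, w), dtype=np.float64)
    for f in range(params.n_frames):
        if f < params.n_prebleach:
            frame = base.copy()
        else:
            t = (f - params.n_prebleach) * params.frame_interval
            recovery = (1 - beta) + beta * m * (1 - np.exp(-t / tau))
            # weight blends the bleach factor towards 1 outside the disk
            frame = base * (1 - weight * (1 - recovery))
        frame *= np.exp(-k * f)
        dy, dx = traj[f]
        if dy != 0 or dx != 0:
            frame = fourier_translate(frame, dy, dx)
        if params.noise_model == "poisson" and params.noise_sd > 0:
            frame = rng.poisson(np.clip(frame, 0, None)).astype(np.float64)
        elif params.noise_sd > 0:
            frame = frame + rng.normal(
                0.0, params.noise_sd * params.baseline_intensity, size=frame.shape
            )
        np.clip(frame, 0, None, out=frame)
        frames[f] = frame

    movie = FrapMovie(
        frames=frames,
        frame_interval=params.frame_interval,
        n_prebleach=params.n_prebleach,
        source_id=f"sim-seed{params.seed}",
    )
    truth = GroundTruth(
        m=m,
        tau=tau,
        k=k,
        beta=beta,
        drift=traj,
        bleach_mask=bleach_mask,
        nucleus_mask=nucleus,
        frame_interval=params.frame_interval,
        n_prebleach=params.n_prebleach,
    )
    return movie, truth


def roi_mean_closed_form(params: SimulationParams, t: float) -> float:
    """Analytic mean intensity inside the true bleach disk at post-bleach time t.

    ``t`` is seconds from the first post-bleach frame; the acquisition decay
    uses the (fractional) frame index ``f(t) = n_prebleach + t / frame_interval``,
    which coincides with the rendered frames on the acquisition grid.
    """
    if t < 0:
        raise ValueError("t must be >= 0 (post-bleach time)")
    beta, m, tau = params.bleach_depth, params.mobile_fraction, params.tau
    s_pre = params.baseline_intensity
    f = params.n_prebleach + t / params.frame_interval
    recovery = (1 - beta) + beta * m * (1 - np.exp(-t / tau))
    return float(s_pre * recovery * np.exp(-params.acquisition_decay_rate * f))


def iter_cohort(n: int, params: SimulationParams, seed: int | None = None):
    """Yield ``n`` independent (movie, truth) pairs, deterministic given seed.

    Sub-seeds are spawned from ``seed`` so each movie has an independent noise
    and drift realization while sharing the kinetic ground truth.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(seed if seed is not None else params.seed)
    for i, child in enumerate(ss.spawn(n)):
        sub_seed = int(child.generate_state(1)[0])
        p = replace(params, seed=sub_seed)
        movie, truth = simulate_frap_movie(p)
        movie.source_id = f"sim-{i:03d}-seed{sub_seed}"
        yield movie, truth


def simulate_cohort(
    n: int, params: SimulationParams, seed: int | None = None
) -> list[tuple[FrapMovie, GroundTruth]]:
    """Materialized list form of :func:`iter_cohort` (mind memory for large n)."""
    return list(iter_cohort(n, params, seed=seed))
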