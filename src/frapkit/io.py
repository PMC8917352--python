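"""Reading and writing of image stacks, masks, metadata and result tables.

Image stacks are multi-page grayscale TIFFs with a JSON sidecar carrying the
timing metadata (``frame_interval_s``, ``n_prebleach``).  Intensities are
processed as floating point throughout; no rescaling is applied on load.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, fields
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "FrapMovie",
    "NucleusMask",
    "ExperimentConfig",
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
    "write_results",
    "read_results",
    "load_experiment_config",
    "RESULT_COLUMNS",
]

#: Column order of the per-nucleus results table.
RESULT_COLUMNS = [
    "source_id",
    "mobile_fraction",
    "tau_s",
    "t_half_s",
    "plateau_M",
    "fit_rss",
    "n_pre",
    "n_post",
    "qc_flags",
]

MIN_NUCLEUS_PIXELS = 50


@dataclass
class FrapMovie:
    """A time-lapse stack with timing metadata and bleach-frame index.

    Parameters
    ----------
    frames
        3-D intensity array ``(time, y, x)``, non-negative.
    frame_interval
        Seconds between consecutive frames.
    n_prebleach
        Number of frames acquired before the bleach pulse.
    source_id
        Free-text identifier carried through to result tables.
    """

    frames: np.ndarray
    frame_interval: float
    n_prebleach: int
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a 3-D (time, y, x) array, got ndim={self.frames.ndim}"
            )
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if not (0 < self.n_prebleach < self.n_frames):
            raise ValueError(
                f"n_prebleach ({self.n_prebleach}) must be positive and smaller "
                f"than the total frame count ({self.n_frames})"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_postbleach(self) -> int:
        return self.n_frames - self.n_prebleach

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial shape (H, W) of a single frame."""
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds; t=0 at the first post-bleach frame."""
        return (np.arange(self.n_frames) - self.n_prebleach) * self.frame_interval


@dataclass
class NucleusMask:
    """Binary 2-D mask of the (manually segmented or simulated) nucleus."""

    mask: np.ndarray
    provenance: str = "manual"  # "manual" | "simulated"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("nucleus mask must be 2-D")
        if int(self.mask.sum()) < MIN_NUCLEUS_PIXELS:
            raise ValueError(
                f"nucleus mask must contain at least {MIN_NUCLEUS_PIXELS} pixels, "
                f"got {int(self.mask.sum())}"
            )

    def validate_against(self, movie: FrapMovie) -> None:
        if self.mask.shape != movie.shape:
            raise ValueError(
                f"nucleus mask shape {self.mask.shape} does not match "
                f"frame shape {movie.shape}"
            )


@dataclass
class ExperimentConfig:
    """Resolved analysis configuration with the protocol defaults."""

    frame_interval: float = 0.21
    n_prebleach: int = 20
    n_post_for_diff: int = 5
    upsample: int = 100
    tail_fraction: float = 0.05
    roi_dilate: int = 0
    decay_exclude_roi: bool = False
    fit_tol: float = 1e-12
    otsu_bins: int = 256

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        for name in ("n_prebleach", "n_post_for_diff", "upsample", "otsu_bins"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        if not 0 < self.tail_fraction <= 1:
            raise ValueError("tail_fraction must be in (0, 1]")
        if self.roi_dilate < 0:
            raise ValueError("roi_dilate must be >= 0")


def read_stack(path: str | Path, metadata_path: str | Path) -> FrapMovie:
    """Read a multi-page grayscale TIFF plus its JSON metadata sidecar.

    The sidecar must provide ``frame_interval_s`` and ``n_prebleach``.  Pixel
    values are cast to float64 unchanged.
    """
    frames = tifffile.imread(str(path))
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim == 4 or (frames.ndim == 3 and frames.shape[-1] in (3, 4)):
        raise ValueError(f"grayscale required: {path} looks like a color stack")
    if frames.ndim != 3:
        raise ValueError(f"expected a 3-D stack, got shape {frames.shape}")

    with open(metadata_path) as fh:
        meta = json.load(fh)
    for key in ("frame_interval_s", "n_prebleach"):
        if key not in meta:
            raise KeyError(f"metadata sidecar {metadata_path} is missing key {key!r}")

    n_prebleach = int(meta["n_prebleach"])
    if frames.shape[0] <= n_prebleach:
        raise ValueError(
            f"stack has {frames.shape[0]} frames but n_prebleach={n_prebleach}; "
            "post-bleach frames required"
        )
    return FrapMovie(
        frames=frames.astype(np.float64, copy=False),
        frame_interval=float(meta["frame_interval_s"]),
        n_prebleach=n_prebleach,
        source_id=str(meta.get("source_id", Path(path).stem)),
    )


def write_stack(
    movie: FrapMovie,
    path: str | Path,
    metadata_path: str | Path | None = None,
    extra_metadata: dict | None = None,
) -> None:
    """Write a movie as a multi-page TIFF with a JSON sidecar."""
    tifffile.imwrite(str(path), movie.frames, photometric="minisblack")
    if metadata_path is None:
        metadata_path = Path(path).with_suffix(".json")
    meta = {
        "frame_interval_s": movie.frame_interval,
        "n_prebleach": movie.n_prebleach,
        "source_id": movie.source_id,
    }
    if extra_metadata:
        meta.update(extra_metadata)
    with open(metadata_path, "w") as fh:
        json.dump(meta, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_mask(path: str | Path, provenance: str = "manual") -> NucleusMask:
    """Read a mask image (TIFF or PNG); nonzero pixels are True."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(str(path))
    else:
        arr = iio.imread(str(path))
    if arr.ndim == 3:  # collapse color channels
        arr = arr[..., 0]
    return NucleusMask(mask=np.asarray(arr) != 0, provenance=provenance)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    arr = (np.asarray(mask, dtype=bool).astype(np.uint8)) * 255
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), arr)
    else:
        iio.imwrite(str(path), arr)


def write_results(results: list, path: str | Path) -> pd.DataFrame:
    """Write one CSV row per nucleus in the documented column order.

    ``results`` is a list of :class:`frapkit.fitting.FitResult`.  Returns the
    DataFrame that was written.
    """
    rows = []
    for r in results:
        rows.append(
            {
                "source_id": r.source_id,
                "mobile_fraction": r.mobile_fraction,
                "tau_s": r.tau_s,
                "t_half_s": r.t_half_s,
                "plateau_M": r.plateau_M,
                "fit_rss": r.rss,
                "n_pre": r.n_pre,
                "n_post": r.n_post,
                "qc_flags": ";".join(sorted(r.qc_flags)),
            }
        )
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df.to_csv(path, index=False)
    return df


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False, na_values=[""]).reindex(
        columns=RESULT_COLUMNS
    )


def load_experiment_config(path: str | Path | None) -> ExperimentConfig:
    """Load a YAML/JSON config, applying defaults for absent keys.

    Unknown keys produce a warning, not a failure, so configs written for a
    newer version still load.
    """
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping, got {type(data).__name__}")
    known = {f.name for f in fields(ExperimentConfig)}
    unknown = set(data) - known
    if unknown:
        warnings.warn(f"ignoring unknown config keys: {sorted(unknown)}", stacklevel=2)
    cfg = ExperimentConfig(**{k: v for k, v in data.items() if k in known})
    return cfg
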