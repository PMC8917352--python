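"""Chromosome-scale enrichment statistics.

Two families of operations:

* Fixed-bin genomic signal tracks: z-score standardization against a set of
  background chromosomes, total-signal equalization on target chromosomes,
  and a 500 kb / 50 kb moving average for spreading profiles.
* Binned contact matrices: per-chromosome contact-decay curves P(s), unity
  normalization over 5 kb - 4 Mb, and the X/A ratio curve
  ``P(s, chrX) / mean_A P(s, chrA)``.

Coordinates are zero-based half-open.  Matrix balancing is out of scope:
contact matrices are taken as already-normalized counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BinnedTrack",
    "ContactMatrix",
    "DecayCurve",
    "zscore_standardize",
    "equalize_total",
    "sliding_mean",
    "contact_decay",
    "unity_normalize_decay",
    "xa_ratio",
    "simulate_contact_matrix",
    "read_bedgraph",
    "write_bedgraph",
    "read_contact_matrix",
    "write_contact_matrix",
    "read_dense_matrix",
]

UNITY_RANGE = (5_000, 4_000_000)
MAX_DECAY_DEPTH = 20_000_000


@dataclass
class BinnedTrack:
    """Fixed-bin genomic signal: one value per ``[start, start + bin_size)`` bin."""

    data: pd.DataFrame  # columns: chrom, start, value
    bin_size: int

    def __post_init__(self) -> None:
        required = {"chrom", "start", "value"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"track data needs columns {sorted(required)}")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.data["chrom"]))

    def chrom_values(self, chrom: str) -> np.ndarray:
        sub = self.data[self.data["chrom"] == chrom].sort_values("start")
        return sub["value"].to_numpy(dtype=np.float64)

    def with_values(self, values: np.ndarray) -> "BinnedTrack":
        df = self.data.copy()
        df["value"] = np.asarray(values, dtype=np.float64)
        return BinnedTrack(df, self.bin_size)


@dataclass
class ContactMatrix:
    """Per-chromosome symmetric binned contact counts."""

    matrices: dict[str, np.ndarray]
    bin_size: int = 5_000

    def __post_init__(self) -> None:
        for chrom, m in self.matrices.items():
            m = np.asarray(m, dtype=np.float64)
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise ValueError(f"{chrom}: contact matrix must be square")
            if not np.all(np.isfinite(m)):
                raise ValueError(f"{chrom}: contact matrix has non-finite entries")
            if not np.allclose(m, m.T, rtol=1e-8, atol=1e-8):
                raise ValueError(f"{chrom}: contact matrix is not symmetric")
            self.matrices[chrom] = m


@dataclass
class DecayCurve:
    """Average contact vs genomic separation; s strictly increasing."""

    s: np.ndarray
    p: np.ndarray
    chrom: str = ""

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=np.float64)
        self.p = np.asarray(self.p, dtype=np.float64)
        if len(self.s) != len(self.p):
            raise ValueError("s and p must have equal lengths")
        if np.any(np.diff(self.s) <= 0):
            raise ValueError("s must be strictly increasing")


# ---------------------------------------------------------------------------
# signal tracks


def zscore_standardize(track: BinnedTrack, background_chroms: set[str]) -> BinnedTrack:
    """z = (value - mu_bg) / sigma_bg genome-wide, with mu/sigma from the
    background chromosomes only (population s.d.).

    Raises ``ValueError`` for missing background chromosomes or a constant
    background (sigma = 0).
    """
    background_chroms = set(background_chroms)
    missing = background_chroms - set(track.chromosomes)
    if missing:
        raise ValueError(f"background chromosomes absent from track: {sorted(missing)}")
    bg = track.data.loc[
        track.data["chrom"].isin(background_chroms), "value"
    ].to_numpy(dtype=np.float64)
    if bg.size < 2:
        raise ValueError("need >= 2 background bins")
    mu = bg.mean()
    sigma = bg.std(ddof=0)
    if sigma == 0:
        raise ValueError("constant background: sigma is zero")
    return track.with_values((track.data["value"].to_numpy(np.float64) - mu) / sigma)


def equalize_total(track: BinnedTrack, target_chroms: set[str]) -> BinnedTrack:
    """Scale all values by one constant so the target chromosomes sum to 1."""
    target_chroms = set(target_chroms)
    missing = target_chroms - set(track.chromosomes)
    if missing:
        raise ValueError(f"target chromosomes absent from track: {sorted(missing)}")
    total = track.data.loc[track.data["chrom"].isin(target_chroms), "value"].sum()
    if total == 0:
        raise ValueError("zero total signal on target chromosomes")
    return track.with_values(track.data["value"].to_numpy(np.float64) / total)


def sliding_mean(
    track: BinnedTrack, window: int = 500_000, step: int = 50_000
) -> pd.DataFrame:
    """Moving average on a step grid; windows never span chromosomes.

    Trailing windows that would extend past the last bin are dropped.  Returns
    a DataFrame with columns chrom, start, end, value.
    """
    bs = track.bin_size
    if window < bs:
        raise ValueError("window must be >= bin size")
    if window % bs or step % bs:
        raise ValueError("window and step must be multiples of the bin size")
    wb, sb = window // bs, step // bs

    rows = []
    for chrom in track.chromosomes:
        sub = track.data[track.data["chrom"] == chrom].sort_values("start")
        starts = sub["start"].to_numpy(dtype=np.int64)
        values = sub["value"].to_numpy(dtype=np.float64)
        if np.any(np.diff(starts) != bs):
            raise ValueError(f"{chrom}: bins must be contiguous at bin_size={bs}")
        if len(values) < wb:
            continue  # window longer than the chromosome -> empty output
        csum = np.concatenate([[0.0], np.cumsum(values)])
        for i in range(0, len(values) - wb + 1, sb):
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(starts[i]),
                    "end": int(starts[i] + window),
                    "value": (csum[i + wb] - csum[i]) / wb,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


# ---------------------------------------------------------------------------
# contact matrices


def contact_decay(
    matrix: ContactMatrix, max_depth: int = MAX_DECAY_DEPTH
) -> dict[str, DecayCurve]:
    """Per-chromosome P(s): mean of entries at each off-diagonal distance.

    ``s = d * bin_size`` for diagonal offset d, up to ``max_depth``.
    """
    curves = {}
    for chrom, m in matrix.matrices.items():
        n = m.shape[0]
        d_max = min(n - 1, max_depth // matrix.bin_size)
        p = np.array([np.diagonal(m, d).mean() for d in range(d_max + 1)])
        s = np.arange(d_max + 1, dtype=np.float64) * matrix.bin_size
        curves[chrom] = DecayCurve(s=s, p=p, chrom=chrom)
    return curves


def unity_normalize_decay(
    curve: DecayCurve,
    s_min: int = UNITY_RANGE[0],
    s_max: int = UNITY_RANGE[1],
) -> DecayCurve:
    """Divide P(s) by its sum over ``s_min <= s <= s_max`` (which becomes 1)."""
    sel = (curve.s >= s_min) & (curve.s <= s_max)
    if not sel.any():
        raise ValueError(f"curve has no support in [{s_min}, {s_max}]")
    total = curve.p[sel].sum()
    if total == 0:
        raise ValueError("zero contact sum over the normalization range")
    return DecayCurve(s=curve.s.copy(), p=curve.p / total, chrom=curve.chrom)


def xa_ratio(
    decays: dict[str, DecayCurve], x_chrom: str, autosomes: list[str]
) -> DecayCurve:
    """ratio(s) = P(s, chrX) / unweighted mean over autosomes of P(s, chrA).

    Inputs should be unity-normalized curves on a shared s grid; the ratio is
    computed on the overlapping support and is NaN where the autosome mean is
    zero.
    """
    if x_chrom not in decays:
        raise ValueError(f"missing X chromosome curve {x_chrom!r}")
    missing = [c for c in autosomes if c not in decays]
    if missing:
        raise ValueError(f"missing autosome curves: {missing}")
    if not autosomes:
        raise ValueError("need at least one autosome")

    grid = decays[x_chrom].s
    for chrom in autosomes:
        grid = np.intersect1d(grid, decays[chrom].s)
    if grid.size == 0:
        raise ValueError("no overlapping s support between X and autosomes")

    def on_grid(curve: DecayCurve) -> np.ndarray:
        idx = np.searchsorted(curve.s, grid)
        return curve.p[idx]

    px = on_grid(decays[x_chrom])
    pa = np.mean([on_grid(decays[c]) for c in autosomes], axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pa != 0, px / pa, np.nan)
    return DecayCurve(s=grid, p=ratio, chrom=f"{x_chrom}/A")


def simulate_contact_matrix(
    n_bins: int,
    bin_size: int = 5_000,
    exponent: float = 1.5,
    x_band: tuple[int, int] = (50_000, 1_000_000),
    x_factor: float = 1.5,
    noise: bool = False,
    intensity: float = 1000.0,
    n_autosomes: int = 4,
    seed: int | None = None,
) -> tuple[ContactMatrix, dict]:
    """Power-law contact matrices with an X-specific enrichment band.

    Expected entries fall as ``intensity * d**-exponent`` with diagonal offset
    d (the d=0 diagonal is held at ``intensity``); on the X chromosome,
    entries whose separation lies in ``x_band`` are multiplied by
    ``x_factor``.  With ``noise=True`` entries are Poisson counts, symmetric
    by construction.  Autosomes are named I..n, the X chromosome "X".
    """
    if exponent <= 0:
        raise ValueError("exponent must be > 0")
    s1, s2 = x_band
    if s1 >= s2:
        raise ValueError("x_band must satisfy s1 < s2")
    rng = np.random.default_rng(seed)

    idx = np.arange(n_bins)
    dist = np.abs(idx[:, None] - idx[None, :])
    base = intensity * np.maximum(dist, 1).astype(np.float64) ** (-exponent)

    sep = dist * bin_size
    band = (sep >= s1) & (sep <= s2)
    x_expected = np.where(band, base * x_factor, base)

    names = ["I", "II", "III", "IV", "V"][:n_autosomes]
    matrices: dict[str, np.ndarray] = {}
    for name in names:
        matrices[name] = _realize(base, rng, noise)
    matrices["X"] = _realize(x_expected, rng, noise)

    truth = {
        "exponent": exponent,
        "x_factor": x_factor,
        "x_band": (s1, s2),
        "intensity": intensity,
        "autosomes": names,
        "x_chrom": "X",
    }
    return ContactMatrix(matrices=matrices, bin_size=bin_size), truth


def _realize(expected: np.ndarray, rng: np.random.Generator, noise: bool) -> np.ndarray:
    if not noise:
        return expected.copy()
    upper = rng.poisson(np.triu(expected)).astype(np.float64)
    return upper + np.triu(upper, 1).T


# ---------------------------------------------------------------------------
# text I/O (bedGraph; bin-table + triplet; dense TSV)


def read_bedgraph(path: str | Path) -> BinnedTrack:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "value"],
        comment="#",
        dtype={"chrom": str},
    )
    sizes = (df["end"] - df["start"]).unique()
    if len(sizes) != 1:
        raise ValueError(f"bedGraph bins are not a constant size: {sorted(sizes)}")
    return BinnedTrack(df[["chrom", "start", "value"]], bin_size=int(sizes[0]))


def write_bedgraph(track: BinnedTrack, path: str | Path) -> None:
    df = track.data.copy()
    df["end"] = df["start"] + track.bin_size
    df[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_contact_matrix(
    matrix: ContactMatrix, bins_path: str | Path, triplet_path: str | Path
) -> None:
    """Write a bin table (chrom, start, end, bin_id) and a triplet file."""
    bin_rows, trip_rows = [], []
    offset = 0
    for chrom, m in matrix.matrices.items():
        n = m.shape[0]
        for i in range(n):
            bin_rows.append(
                (chrom, i * matrix.bin_size, (i + 1) * matrix.bin_size, offset + i)
            )
        ii, jj = np.nonzero(np.triu(m))
        for i, j in zip(ii, jj):
            trip_rows.append((offset + i, offset + j, m[i, j]))
        offset += n
    pd.DataFrame(bin_rows, columns=["chrom", "start", "end", "bin_id"]).to_csv(
        bins_path, sep="\t", header=True, index=False
    )
    pd.DataFrame(trip_rows, columns=["bin1", "bin2", "count"]).to_csv(
        triplet_path, sep="\t", header=True, index=False
    )


def read_contact_matrix(bins_path: str | Path, triplet_path: str | Path) -> ContactMatrix:
    """Read a bin table + upper-triangle triplet file written by
    :func:`write_contact_matrix`.  Inter-chromosomal triplets are ignored."""
    bins = pd.read_csv(bins_path, sep="\t", dtype={"chrom": str})
    trips = pd.read_csv(triplet_path, sep="\t")
    sizes = (bins["end"] - bins["start"]).unique()
    if len(sizes) != 1:
        raise ValueError("bin table does not have a constant bin size")
    bin_size = int(sizes[0])

    chrom_of = bins.set_index("bin_id")["chrom"]
    local_of = bins.groupby("chrom", sort=False).cumcount()
    local_of.index = bins["bin_id"].to_numpy()

    matrices: dict[str, np.ndarray] = {
        chrom: np.zeros((count, count))
        for chrom, count in bins["chrom"].value_counts(sort=False).items()
    }
    for b1, b2, count in trips.itertuples(index=False):
        c1, c2 = chrom_of[b1], chrom_of[b2]
        if c1 != c2:
            continue
        i, j = int(local_of[b1]), int(local_of[b2])
        matrices[c1][i, j] = count
        matrices[c1][j, i] = count
    return ContactMatrix(matrices=matrices, bin_size=bin_size)


def read_dense_matrix(path: str | Path, chrom: str, bin_size: int) -> ContactMatrix:
    """Read a dense per-chromosome TSV of contact counts."""
    m = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=np.float64)
    return ContactMatrix(matrices={chrom: m}, bin_size=bin_size)
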