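"""Sub-pixel lateral drift correction by upsampled cross-correlation.

The shift between two frames is first estimated to integer precision from the
peak of the circular cross-correlation, then refined on an upsampled grid by
evaluating a matrix-multiply discrete Fourier transform only in a
1.5x1.5-pixel neighborhood of the peak, at resolution ``1/upsample``.
Translations are applied as Fourier phase shifts, so the correction is exact
for periodic images and preserves total intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

from .io import FrapMovie

__all__ = ["Shift", "estimate_shift", "apply_shift", "register_stack", "fourier_translate"]


@dataclass(frozen=True)
class Shift:
    """A signed, sub-pixel (dy, dx) translation plus a registration error metric."""

    dy: float
    dx: float
    peak_error: float = 0.0

    def __iter__(self):
        yield self.dy
        yield self.dx

    def __neg__(self) -> "Shift":
        return Shift(-self.dy, -self.dx, self.peak_error)


def _upsampled_dft(
    data: np.ndarray,
    region_size: tuple[int, int],
    upsample: int,
    offsets: tuple[float, float],
) -> np.ndarray:
    # Matrix-multiply DFT evaluated on a small upsampled output region only.
    out = data
    for n_items, size, offset in reversed(list(zip(data.shape, region_size, offsets))):
        kernel = (np.arange(size) - offset)[:, None] * np.fft.fftfreq(n_items, upsample)
        kernel = np.exp(-2j * np.pi * kernel)
        out = np.tensordot(kernel, out, axes=(1, -1))
    return out


def estimate_shift(reference: np.ndarray, moving: np.ndarray, upsample: int = 1) -> Shift:
    """Estimate the translation aligning ``moving`` onto ``reference``.

    Returns the shift that :func:`apply_shift` must receive to align ``moving``
    onto ``reference``: if ``moving`` is the reference scene translated by
    ``s``, the returned shift is ``-s``.

    Raises ``ValueError`` for constant images (no correlation peak) or
    mismatched shapes.
    """
    reference = np.asarray(reference, dtype=np.float64)
    moving = np.asarray(moving, dtype=np.float64)
    if reference.shape != moving.shape:
        raise ValueError(
            f"shape mismatch: reference {reference.shape} vs moving {moving.shape}"
        )
    if reference.ndim != 2:
        raise ValueError("estimate_shift expects 2-D images")
    if upsample < 1:
        raise ValueError("upsample must be >= 1")
    if reference.std() == 0 or moving.std() == 0:
        raise ValueError("all-constant image: no correlation peak")

    shape = np.array(reference.shape)
    f_ref = np.fft.fft2(reference)
    f_mov = np.fft.fft2(moving)
    # Peak of ifft2(F_ref * conj(F_mov)) sits at the shift aligning moving onto
    # reference (already in apply_shift's sign convention).
    product = f_ref * np.conj(f_mov)
    correlation = np.fft.ifft2(product)
    maxima = np.unravel_index(np.argmax(np.abs(correlation)), correlation.shape)
    shifts = np.array(maxima, dtype=np.float64)
    shifts[shifts > shape // 2] -= shape[shifts > shape // 2]

    cc_max = correlation[maxima]
    norm = np.sqrt(
        (np.abs(f_ref) ** 2).sum() * (np.abs(f_mov) ** 2).sum()
    ) / reference.size
    error = float(np.sqrt(max(0.0, 1.0 - (np.abs(cc_max) / norm) ** 2)))

    if upsample > 1:
        shifts = np.round(shifts * upsample) / upsample
        region = int(np.ceil(upsample * 1.5))
        dftshift = np.fix(region / 2.0)
        offsets = dftshift - shifts * upsample
        cc_ups = np.conj(
            _upsampled_dft(np.conj(product), (region, region), upsample, tuple(offsets))
        )
        ups_maxima = np.unravel_index(np.argmax(np.abs(cc_ups)), cc_ups.shape)
        shifts = shifts + (np.array(ups_maxima, dtype=np.float64) - dftshift) / upsample

    return Shift(dy=float(shifts[0]), dx=float(shifts[1]), peak_error=error)


def fourier_translate(image: np.ndarray, dy: float, dx: float) -> np.ndarray:
    """Translate ``image`` by (dy, dx) via a Fourier phase shift (periodic edges)."""
    image = np.asarray(image, dtype=np.float64)
    if dy == 0 and dx == 0:
        return image.copy()
    shifted = np.fft.ifft2(ndi.fourier_shift(np.fft.fft2(image), (dy, dx)))
    return shifted.real


def apply_shift(image: np.ndarray, shift: Shift | tuple[float, float]) -> np.ndarray:
    """Translate ``image`` by ``shift`` with periodic boundary handling.

    The Fourier shift leaves the DC term untouched, so total intensity is
    preserved to floating-point precision.
    """
    dy, dx = shift
    if not (np.isfinite(dy) and np.isfinite(dx)):
        raise ValueError("shift must be finite")
    return fourier_translate(image, dy, dx)


def register_stack(
    movie: FrapMovie, upsample: int = 100
) -> tuple[FrapMovie, np.ndarray]:
    """Register every frame of a movie to a high-SNR pre-bleach reference.

    The reference is the mean of the pre-bleach frames after aligning them to
    the first frame, so the registered coordinate system coincides with the
    scene at frame 0.  Returns the registered movie and the per-frame
    estimated drift trajectory, an ``(n_frames, 2)`` array of (dy, dx)
    displacements of each raw frame relative to the reference (the applied
    correction is the negative of each row).
    """
    if movie.n_frames < 2:
        raise ValueError("register_stack requires at least 2 frames")
    frames = movie.frames.astype(np.float64, copy=False)

    # Pass 1: align pre-bleach frames to frame 0, average into the reference.
    first = frames[0]
    aligned_pre = [first]
    for f in range(1, movie.n_prebleach):
        try:
            s = estimate_shift(first, frames[f], upsample=upsample)
        except ValueError as exc:
            raise ValueError(f"registration failed at frame {f}: {exc}") from exc
        aligned_pre.append(apply_shift(frames[f], s))
    reference = np.mean(aligned_pre, axis=0)

    # Pass 2: register all frames to the reference.
    registered = np.empty_like(frames)
    trajectory = np.zeros((movie.n_frames, 2), dtype=np.float64)
    for f in range(movie.n_frames):
        try:
            s = estimate_shift(reference, frames[f], upsample=upsample)
        except ValueError as exc:
            raise ValueError(f"registration failed at frame {f}: {exc}") from exc
        registered[f] = apply_shift(frames[f], s)
        trajectory[f] = (-s.dy, -s.dx)

    out = FrapMovie(
        frames=registered,
        frame_interval=movie.frame_interval,
        n_prebleach=movie.n_prebleach,
        source_id=movie.source_id,
    )
    return out, trajectory
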