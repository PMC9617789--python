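"""Centered, unitary 2-D FFT helpers.

Conventions used throughout the package:

* k-space is stored DC-centered: the DC coefficient sits at index
  ``N // 2`` (0-based) along each transformed axis.
* all transforms are unitary (``norm="ortho"``) so Parseval holds exactly,
  which the test-suite relies on.
* the last two axes of any array are (readout, phase-encode).
"""

from __future__ import annotations

import numpy as np

__all__ = ["fft2c", "ifft2c", "crop_center", "pad_center", "fourier_shift"]

_AXES = (-2, -1)


def fft2c(img: np.ndarray) -> np.ndarray:
    """Image -> DC-centered k-space, unitary."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(img, axes=_AXES), axes=_AXES, norm="ortho"),
        axes=_AXES,
    )


def ifft2c(ksp: np.ndarray) -> np.ndarray:
    """DC-centered k-space -> image, unitary."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(ksp, axes=_AXES), axes=_AXES, norm="ortho"),
        axes=_AXES,
    )


def crop_center(arr: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Crop the central ``shape`` region of the last two axes (DC-centered)."""
    nx, ny = arr.shape[-2:]
    cx, cy = shape
    if cx > nx or cy > ny:
        raise ValueError(f"crop {shape} larger than array {(nx, ny)}")
    x0 = nx // 2 - cx // 2
    y0 = ny // 2 - cy // 2
    return arr[..., x0 : x0 + cx, y0 : y0 + cy]


def pad_center(arr: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Zero-pad the last two axes to ``shape``, keeping DC centered."""
    nx, ny = arr.shape[-2:]
    px, py = shape
    if px < nx or py < ny:
        raise ValueError(f"pad target {shape} smaller than array {(nx, ny)}")
    out = np.zeros(arr.shape[:-2] + (px, py), dtype=arr.dtype)
    x0 = px // 2 - nx // 2
    y0 = py // 2 - ny // 2
    out[..., x0 : x0 + nx, y0 : y0 + ny] = arr
    return out


def fourier_shift(img: np.ndarray, shift: tuple[float, float]) -> np.ndarray:
    """Circular sub-pixel shift of the last two axes via the shift theorem."""
    nx, ny = img.shape[-2:]
    kx = np.fft.fftfreq(nx)[:, None]
    ky = np.fft.fftfreq(ny)[None, :]
    phase = np.exp(-2j * np.pi * (kx * shift[0] + ky * shift[1]))
    return np.fft.ifft2(np.fft.fft2(img, axes=_AXES) * phase, axes=_AXES)
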