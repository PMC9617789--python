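"""Image-quality metrics and temporal uptake-curve analysis."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import filtfilt, firwin
from skimage.metrics import structural_similarity

__all__ = ["psnr", "ssim", "UptakeCurve", "uptake_curve"]


def psnr(x: np.ndarray, ref: np.ndarray) -> float:
    """Peak SNR in dB on magnitude images: 20 log10(max|ref| / RMSE)."""
    x, ref = np.abs(np.asarray(x)), np.abs(np.asarray(ref))
    if x.shape != ref.shape:
        raise ValueError("shape mismatch")
    peak = ref.max()
    if peak == 0:
        raise ValueError("reference image is zero")
    rmse = np.sqrt(np.mean((x - ref) ** 2))
    if rmse == 0:
        return float("inf")
    return float(20 * np.log10(peak / rmse))


def ssim(x: np.ndarray, ref: np.ndarray, win_size: int = 7) -> float:
    """Windowed structural similarity on magnitude images, range set by ref."""
    x, ref = np.abs(np.asarray(x)), np.abs(np.asarray(ref))
    if x.shape != ref.shape:
        raise ValueError("shape mismatch")
    rng = float(max(x.max(), ref.max()))
    if rng == 0:
        raise ValueError("reference image is zero")
    return float(structural_similarity(x, ref, win_size=win_size, data_range=rng))


@dataclass
class UptakeCurve:
    raw: np.ndarray  # per-frame ROI mean of magnitude
    filtered: np.ndarray  # zero-phase low-pass, DC gain 1
    roi: np.ndarray
    cutoff: float


def uptake_curve(
    images: np.ndarray, roi: np.ndarray, filter_cutoff: float = 0.2, numtaps: int = 9
) -> UptakeCurve:
    """ROI-mean signal-intensity curve with zero-phase FIR low-pass.

    ``images``: (n_frames, nx, ny); ``roi``: (nx, ny) bool;
    ``filter_cutoff`` in cycles/frame (Nyquist = 0.5).
    """
    images = np.asarray(images)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != images.shape[-2:]:
        raise ValueError("ROI grid does not match images")
    if not roi.any():
        raise ValueError("empty ROI")
    raw = np.abs(images)[:, roi].mean(axis=1)
    nt = raw.size
    taps = min(numtaps, max(3, (nt // 3) * 2 - 1))
    if taps % 2 == 0:
        taps -= 1
    b = firwin(taps, filter_cutoff / 0.5)
    filtered = filtfilt(b, [1.0], raw, padlen=min(3 * taps, nt - 1))
    return UptakeCurve(raw=raw, filtered=filtered, roi=roi, cutoff=filter_cutoff)
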