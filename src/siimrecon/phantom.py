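"""Numerical dynamic perfusion phantom and acquisition simulator.

A parametric-ellipse torso with right-ventricle / left-ventricle blood pools
and a myocardial ring; tissue signal follows a gamma-variate bolus curve
with staggered arrival times (RV before LV before myocardium), emulating
first-pass contrast dynamics over ~40 frames.  Coil sensitivities are
smooth complex fields normalized to unit root-sum-of-squares, so exact
inverse-chain identities hold in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._fft import crop_center, fft2c
from .datamodel import AcquisitionProtocol, CalibrationScan, ImageSeries, KSpaceSMS
from .encoding import EncodingOperator, make_caipi_schedule, make_sampling_pattern

__all__ = ["PhantomConfig", "Phantom", "gamma_variate", "generate_phantom", "simulate_acquisition"]


def gamma_variate(t: np.ndarray, t0: float, alpha: float, beta: float) -> np.ndarray:
    """Gamma-variate bolus curve, normalized to peak 1 at ``t = t0 + alpha*beta``."""
    t = np.asarray(t, dtype=np.float64)
    tau = (t - t0) / beta
    out = np.zeros_like(tau)
    pos = tau > 0
    out[pos] = (tau[pos] / alpha) ** alpha * np.exp(alpha - tau[pos])
    return out


@dataclass
class TissueDynamics:
    baseline: float
    amplitude: float
    delay: float  # bolus arrival t0 in frames
    alpha: float = 3.0
    beta: float = 1.5


@dataclass
class PhantomConfig:
    matrix_size: tuple[int, int] = (96, 96)
    n_slices: int = 3
    n_frames: int = 40
    n_coils: int = 8
    rv: TissueDynamics = field(default_factory=lambda: TissueDynamics(0.35, 2.0, 2.0))
    lv: TissueDynamics = field(default_factory=lambda: TissueDynamics(0.35, 2.4, 5.0))
    myo: TissueDynamics = field(default_factory=lambda: TissueDynamics(0.30, 0.8, 9.0, 3.0, 2.5))
    body_baseline: float = 0.25
    texture: float = 0.15  # relative amplitude of smooth static tissue texture
    texture_scale: float = 3.0  # Gaussian smoothing length of the texture, px
    noise_sigma: float = 0.0
    coil_width_frac: float = 0.4  # Gaussian width of coil profiles / FOV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


@dataclass
class Phantom:
    """Ground truth: images, coil maps, ROI masks and uptake curves."""

    truth: ImageSeries  # (slice, frame, x, y), domain "coil-combined"
    maps: np.ndarray  # (slice, coil, x, y), sum_c |S|^2 = 1 everywhere
    rois: dict  # name -> bool (slice, x, y)
    curves: dict  # name -> (n_frames,) tissue signal magnitude
    config: PhantomConfig


def _ellipse(nx, ny, cx, cy, ax, ay):
    x = np.arange(nx)[:, None]
    y = np.arange(ny)[None, :]
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 <= 1.0


def _coil_maps(
    nx: int, ny: int, n_coils: int, width_frac: float, n_slices: int = 1
) -> np.ndarray:
    """Smooth complex profiles with genuine through-slice variation.

    Coil elements sit on a ring at three staggered z-rows (like a cardiac
    array); each excited slice sees a different subset strongly, which is
    what makes simultaneous-multislice separation well-posed.  Returns
    (n_slices, n_coils, nx, ny), normalized to unit RSS per slice.
    """
    x = np.arange(nx)[:, None] / nx - 0.5
    y = np.arange(ny)[None, :] / ny - 0.5
    z_slices = (
        np.linspace(-0.8, 0.8, n_slices) if n_slices > 1 else np.zeros(1)
    )
    maps = np.empty((n_slices, n_coils, nx, ny), dtype=np.complex128)
    for c in range(n_coils):
        th = 2 * np.pi * c / n_coils
        z_c = 0.8 * ((c % 3) - 1)
        d2 = (x - 0.55 * np.cos(th)) ** 2 + (y - 0.55 * np.sin(th)) ** 2
        mag_xy = np.exp(-d2 / (2 * width_frac**2)) + 0.02
        ph_xy = np.pi * (0.4 * (x * np.cos(th) + y * np.sin(th)) + 0.1 * c)
        for s, z_s in enumerate(z_slices):
            zfac = np.exp(-((z_s - z_c) ** 2) / (2 * 0.45**2))
            tilt = np.pi * 0.2 * z_s * (x * np.sin(th) - y * np.cos(th))
            maps[s, c] = (mag_xy * zfac + 0.01) * np.exp(1j * (ph_xy + tilt))
    rss = np.sqrt((np.abs(maps) ** 2).sum(axis=1, keepdims=True))
    return maps / rss


def generate_phantom(config: PhantomConfig) -> Phantom:
    """Deterministic (seeded) dynamic phantom with per-slice geometry."""
    nx, ny = config.matrix_size
    nt, ns = config.n_frames, config.n_slices
    t = np.arange(nt, dtype=np.float64)
    rng = np.random.default_rng(config.seed)

    curves = {
        "rv": config.rv.baseline
        + config.rv.amplitude * gamma_variate(t, config.rv.delay, config.rv.alpha, config.rv.beta),
        "lv": config.lv.baseline
        + config.lv.amplitude * gamma_variate(t, config.lv.delay, config.lv.alpha, config.lv.beta),
        "myo": config.myo.baseline
        + config.myo.amplitude
        * gamma_variate(t, config.myo.delay, config.myo.alpha, config.myo.beta),
        "body": np.full(nt, config.body_baseline),
    }

    m = min(nx, ny)
    data = np.empty((ns, nt, nx, ny), dtype=np.complex128)
    rois: dict[str, np.ndarray] = {
        k: np.zeros((ns, nx, ny), dtype=bool) for k in ("rv", "lv", "myo", "body")
    }
    # slow smooth background phase, shared across frames (static anatomy)
    xg = np.arange(nx)[:, None] / nx - 0.5
    yg = np.arange(ny)[None, :] / ny - 0.5
    for s in range(ns):
        dz = (s - (ns - 1) / 2) * 0.02 * m
        body = _ellipse(nx, ny, nx / 2, ny / 2, 0.42 * nx, 0.40 * ny)
        lv_c = (0.55 * nx + dz, 0.52 * ny)
        lv = _ellipse(nx, ny, *lv_c, 0.10 * m, 0.10 * m)
        epi = _ellipse(nx, ny, *lv_c, 0.17 * m, 0.17 * m)
        myo = epi & ~lv
        rv = _ellipse(nx, ny, 0.34 * nx + dz, 0.42 * ny, 0.09 * m, 0.13 * m) & ~epi
        rois["body"][s] = body & ~epi & ~rv
        rois["lv"][s], rois["rv"][s], rois["myo"][s] = lv, rv, myo
        phase = np.exp(1j * np.pi * (0.5 * xg + 0.3 * yg + 0.05 * s))
        # static smooth texture makes the k-space full-rank enough for
        # kernel calibration (pure ellipses are too low-dimensional)
        if config.texture > 0:
            from scipy.ndimage import gaussian_filter

            field = gaussian_filter(rng.normal(size=(nx, ny)), config.texture_scale)
            field /= max(field.std(), 1e-12)
            modulation = 1.0 + config.texture * field
        else:
            modulation = np.ones((nx, ny))
        for ti in range(nt):
            img = np.zeros((nx, ny))
            img[rois["body"][s]] = curves["body"][ti]
            img[rv] = curves["rv"][ti]
            img[lv] = curves["lv"][ti]
            img[myo] = curves["myo"][ti]
            data[s, ti] = img * modulation * phase
    all_maps = _coil_maps(nx, ny, config.n_coils, config.coil_width_frac, ns)
    truth = ImageSeries(data, domain="coil-combined")
    return Phantom(truth=truth, maps=all_maps, rois=rois, curves=curves, config=config)


def simulate_acquisition(
    phantom: Phantom,
    protocol: AcquisitionProtocol,
    seed: int = 0,
    calib_grid: tuple[int, int] | None = None,
    outer_volume_suppression: float | None = None,
) -> tuple[KSpaceSMS, CalibrationScan]:
    """Simulate the SMS-collapsed dynamic scan plus per-slice calibration.

    Per frame and SMS group the ground-truth slices are encoded with the
    full coil model, CAIPIRINHA schedule and undersampling mask; i.i.d.
    complex Gaussian noise (sigma from the phantom config) is added at
    sampled locations only.  The calibration scan is the central
    ``calib_grid`` k-space region of the pre-contrast (first-frame) object,
    acquired per slice without SMS, with the same noise level.

    ``outer_volume_suppression``: optional fraction of the phase-encode FOV
    outside of which signal is zeroed before encoding.
    """
    nx, ny = protocol.matrix_size
    if phantom.truth.data.shape[-2:] != (nx, ny):
        raise ValueError("phantom grid does not match protocol matrix size")
    if phantom.truth.data.shape[0] != protocol.n_slices:
        raise ValueError(
            f"phantom has {phantom.truth.data.shape[0]} slices, protocol needs "
            f"{protocol.n_slices}"
        )
    rng = np.random.default_rng(seed)
    pattern = make_sampling_pattern(protocol)
    caipi = make_caipi_schedule(protocol, pattern)
    sigma = phantom.config.noise_sigma

    truth = phantom.truth.data
    if outer_volume_suppression is not None:
        band = np.zeros(ny, dtype=bool)
        half = int(round(outer_volume_suppression * ny / 2))
        band[ny // 2 - half : ny // 2 + half] = True
        truth = truth * band[None, None, None, :]

    ksp = np.zeros(protocol.kspace_shape, dtype=np.complex128)
    sms = protocol.sms_factor
    for g in range(protocol.n_groups):
        slices = protocol.group_slices(g)
        op = EncodingOperator(phantom.maps[slices], pattern, caipi)
        for t in range(protocol.n_frames):
            y = op.forward(truth[slices, t])
            if sigma > 0:
                noise = rng.normal(scale=sigma / np.sqrt(2), size=(2,) + y.shape)
                y = y + (noise[0] + 1j * noise[1]) * pattern.mask
            ksp[t, g] = y

    if calib_grid is None:
        calib_grid = tuple(min(2 * c, n) for c, n in zip(protocol.calib_size, (nx, ny)))
    cal = np.empty((protocol.n_slices, protocol.n_coils) + tuple(calib_grid), np.complex128)
    for s in range(protocol.n_slices):
        full = fft2c(phantom.maps[s] * truth[s, 0][None])
        low = crop_center(full, calib_grid)
        if sigma > 0:
            noise = rng.normal(scale=sigma / np.sqrt(2), size=(2,) + low.shape)
            low = low + noise[0] + 1j * noise[1]
        cal[s] = low
    return KSpaceSMS(ksp, pattern_ref=pattern), CalibrationScan(cal)
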