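"""Multi-coil encoding operators.

Builds the conventional SENSE-style operator ``E`` (coil maps + masked
unitary Fourier transform), its intensity-informed variant ``H = E @ L``
where ``L`` is a diagonal per-pixel intensity map, and the simultaneous
multislice (SMS) extensions of both with CAIPIRINHA phase cycling.  Forward
and adjoint are exact adjoint pairs in double precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from ._fft import fft2c, ifft2c
from .datamodel import AcquisitionProtocol, ValidationError

__all__ = [
    "SamplingPattern",
    "CaipiSchedule",
    "IntensityMap",
    "EncodingOperator",
    "make_sampling_pattern",
    "acceleration_factor",
    "make_caipi_schedule",
    "make_operator",
]

# floor for inverting L, relative to the per-slice maximum
INTENSITY_FLOOR_FRAC = 1e-3


@dataclass(frozen=True)
class SamplingPattern:
    """Boolean sampling mask over the (readout, phase-encode) grid.

    Sampled phase-encode lines form an arithmetic progression with step
    ``in_plane_R`` restricted to the partial-Fourier window; the readout
    direction is always fully sampled.
    """

    mask: np.ndarray  # bool (nx, ny)
    in_plane_R: int
    partial_fourier: Fraction
    pe_offset: int
    pe_window_start: int  # first line of the partial-Fourier window

    @property
    def sampled_lines(self) -> np.ndarray:
        """Indices of sampled phase-encode lines, ascending."""
        return np.flatnonzero(self.mask[0])

    @property
    def n_sampled(self) -> int:
        return int(self.sampled_lines.size)


@dataclass(frozen=True)
class CaipiSchedule:
    """Per-slice CAIPIRINHA phase for each sampled phase-encode line.

    ``phases[i, j]`` is the phase (radians) applied to SMS band ``i`` on the
    j-th sampled line: ``2*pi * i * j * fov_shift_fraction`` (mod 2*pi).
    Convention: a positive phase slope displaces band i's aliased image by
    ``i * fov_shift_fraction`` of the aliased FOV along ``-y``.
    """

    phases: np.ndarray  # (sms_factor, n_sampled_lines)
    fov_shift_fraction: Fraction
    sampled_lines: np.ndarray

    @property
    def sms_factor(self) -> int:
        return self.phases.shape[0]

    def line_phase_grid(self, n_pe: int) -> np.ndarray:
        """Complex modulation per slice on the full PE grid (1 off-mask)."""
        grid = np.ones((self.sms_factor, n_pe), dtype=np.complex128)
        grid[:, self.sampled_lines] = np.exp(1j * self.phases)
        return grid


@dataclass
class IntensityMap:
    """Diagonal of the intensity operator ``L``: one nonnegative real image
    per slice and frame, plus the floor used when the diagonal is inverted."""

    values: np.ndarray  # (n_slices, n_frames, nx, ny) real >= 0
    floor_frac: float = INTENSITY_FLOOR_FRAC

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 4:
            raise ValidationError("intensity map must be (slice, frame, x, y)")
        if np.any(self.values < 0):
            raise ValidationError("intensity map entries must be nonnegative")

    def floored(self) -> np.ndarray:
        """Values with the per-slice/frame floor applied (strictly positive)."""
        peak = self.values.max(axis=(-2, -1), keepdims=True)
        peak = np.where(peak > 0, peak, 1.0)
        return np.maximum(self.values, self.floor_frac * peak)

    def frame(self, t: int, slices: np.ndarray) -> np.ndarray:
        """Floored (sms_factor, nx, ny) block for one frame; ``slices`` is
        ``protocol.group_slices(g)``."""
        return self.floored()[np.asarray(slices), t]


def make_sampling_pattern(
    protocol: AcquisitionProtocol, frame_index: int = 0, rotate_offset: bool = False
) -> SamplingPattern:
    """Uniform step-R mask inside the partial-Fourier window, no ACS block.

    The window keeps the DC-containing side: with partial Fourier ``pf`` the
    first ``(1 - pf) * n_pe`` lines are never acquired.  ``pe_offset`` is 0
    by default; with ``rotate_offset`` it cycles with ``frame_index``.
    """
    nx, ny = protocol.matrix_size
    R = protocol.in_plane_R
    if R > ny:
        raise ValueError(f"in-plane R={R} exceeds phase-encode count {ny}")
    start = int(round((1 - protocol.partial_fourier) * ny))
    offset = (frame_index % R) if rotate_offset else 0
    lines = np.arange(start + offset, ny, R)
    mask = np.zeros((nx, ny), dtype=bool)
    mask[:, lines] = True
    return SamplingPattern(
        mask=mask,
        in_plane_R=R,
        partial_fourier=protocol.partial_fourier,
        pe_offset=offset,
        pe_window_start=start,
    )


def acceleration_factor(pattern: SamplingPattern, sms_factor: int = 1) -> float:
    """Net acceleration: sms_factor * (total PE lines) / (sampled PE lines)."""
    n = pattern.n_sampled
    if n == 0:
        raise ValueError("empty sampling mask")
    return sms_factor * pattern.mask.shape[1] / n


def make_caipi_schedule(
    protocol: AcquisitionProtocol, pattern: SamplingPattern | None = None
) -> CaipiSchedule:
    """CAIPIRINHA phase cycling: band i, j-th sampled line gets phase
    ``2*pi * i * j * fov_shift_fraction``."""
    if pattern is None:
        pattern = make_sampling_pattern(protocol)
    shift = float(protocol.fov_shift_fraction)
    j = np.arange(pattern.n_sampled)
    i = np.arange(protocol.sms_factor)[:, None]
    phases = np.mod(2 * np.pi * shift * i * j, 2 * np.pi)
    return CaipiSchedule(
        phases=phases,
        fov_shift_fraction=protocol.fov_shift_fraction,
        sampled_lines=pattern.sampled_lines.copy(),
    )


class EncodingOperator:
    """Linear operator from a per-slice image stack to collapsed k-space.

    Forward (one SMS group, one frame), per coil c::

        y_c = mask * sum_i  P_i * F( S_c^{(i)} * L_i * x_i )

    with ``P_i`` the CAIPIRINHA per-line phase of band i, ``F`` the unitary
    centered 2-D FFT, ``S`` the coil maps and ``L`` the optional intensity
    map (``kind="siim"``).  ``adjoint`` is the exact Hermitian transpose.

    Shapes: x (sms, nx, ny) -> y (coils, nx, ny).
    """

    def __init__(
        self,
        maps: np.ndarray,
        pattern: SamplingPattern,
        caipi: CaipiSchedule | None = None,
        intensity: np.ndarray | None = None,
    ):
        maps = np.asarray(maps, dtype=np.complex128)
        if maps.ndim == 3:  # (coil, nx, ny) -> single slice
            maps = maps[None]
        if maps.ndim != 4:
            raise ValidationError("maps must be (sms, coil, nx, ny)")
        self.maps = maps
        self.n_sms, self.n_coils, self.nx, self.ny = maps.shape
        if pattern.mask.shape != (self.nx, self.ny):
            raise ValidationError("pattern grid does not match maps")
        self.pattern = pattern
        self.mask = pattern.mask
        if caipi is None and self.n_sms > 1:
            raise ValidationError("SMS operator requires a CAIPI schedule")
        self.caipi = caipi
        if caipi is not None:
            if caipi.sms_factor != self.n_sms:
                raise ValidationError("CAIPI schedule does not match SMS factor")
            self._pmod = caipi.line_phase_grid(self.ny)[:, None, None, :]
        else:
            self._pmod = np.ones((1, 1, 1, self.ny), dtype=np.complex128)
        if intensity is not None:
            intensity = np.asarray(intensity, dtype=np.float64)
            if intensity.shape != (self.n_sms, self.nx, self.ny):
                raise ValidationError("intensity map must be (sms, nx, ny)")
            if np.any(intensity < 0):
                raise ValidationError("intensity map entries must be nonnegative")
        self.intensity = intensity

    @property
    def kind(self) -> str:
        return "conventional" if self.intensity is None else "siim"

    @property
    def x_shape(self) -> tuple[int, int, int]:
        return (self.n_sms, self.nx, self.ny)

    @property
    def y_shape(self) -> tuple[int, int, int]:
        return (self.n_coils, self.nx, self.ny)

    def _check_x(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.complex128)
        if x.shape == (self.nx, self.ny) and self.n_sms == 1:
            x = x[None]
        if x.shape != self.x_shape:
            raise ValidationError(f"expected image {self.x_shape}, got {x.shape}")
        return x

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = self._check_x(x)
        if self.intensity is not None:
            x = self.intensity * x
        # (sms, coil, nx, ny): per-coil weighted slices
        weighted = self.maps * x[:, None]
        ksp = fft2c(weighted) * self._pmod
        return ksp.sum(axis=0) * self.mask

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=np.complex128)
        if y.shape != self.y_shape:
            raise ValidationError(f"expected k-space {self.y_shape}, got {y.shape}")
        ym = (y * self.mask)[None] * np.conj(self._pmod)
        imgs = ifft2c(ym)  # (sms, coil, nx, ny)
        x = (np.conj(self.maps) * imgs).sum(axis=1)
        if self.intensity is not None:
            x = self.intensity * x
        return x

    def normal(self, x: np.ndarray) -> np.ndarray:
        """adjoint(forward(x)) — Hermitian positive semidefinite."""
        return self.adjoint(self.forward(x))

    def with_mask(self, mask: np.ndarray) -> "EncodingOperator":
        """Same operator restricted to a different sampling mask (same grid).

        Used by self-supervised training to run data consistency on a
        sub-mask while keeping maps, CAIPI phases and intensity unchanged.
        """
        from dataclasses import replace

        pat = replace(self.pattern, mask=np.asarray(mask, dtype=bool))
        return EncodingOperator(self.maps, pat, self.caipi, self.intensity)


def make_operator(
    maps: np.ndarray,
    pattern: SamplingPattern,
    caipi: CaipiSchedule | None = None,
    intensity: np.ndarray | None = None,
    kind: str = "conventional",
) -> EncodingOperator:
    """Convenience constructor checking kind/intensity consistency."""
    if kind == "siim" and intensity is None:
        raise ValidationError("siim operator requires an intensity map")
    if kind == "conventional":
        intensity = None
    return EncodingOperator(maps, pattern, caipi, intensity)
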