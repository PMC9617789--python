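"""Shared data model for the reconstruction pipeline.

Array axis order is fixed package-wide:

* k-space: ``(frame, group, coil, readout, phase-encode)``
* images:  ``(slice, frame, x, y)`` with ``x`` = readout, ``y`` = phase-encode
* SMS groups are interleaved across the slice stack (as acquired): group
  ``g``, band ``i`` excites anatomical slice ``g + n_groups * i``, so the
  simultaneously excited slices are maximally separated in z.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np

__all__ = [
    "AcquisitionProtocol",
    "KSpaceSMS",
    "CalibrationScan",
    "ImageSeries",
    "ReconConfig",
    "ValidationError",
]


class ValidationError(ValueError):
    """An object violates one of its documented invariants."""


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Geometry and acceleration settings of one dynamic SMS acquisition."""

    matrix_size: tuple[int, int] = (160, 160)  # (readout, phase-encode)
    n_coils: int = 8
    sms_factor: int = 3
    n_groups: int = 3
    n_frames: int = 40
    in_plane_R: int = 4
    partial_fourier: Fraction = Fraction(6, 8)
    fov_shift_fraction: Fraction = Fraction(1, 3)
    calib_size: tuple[int, int] = (24, 24)

    def __post_init__(self) -> None:
        object.__setattr__(self, "partial_fourier", Fraction(self.partial_fourier))
        object.__setattr__(self, "fov_shift_fraction", Fraction(self.fov_shift_fraction))
        if self.in_plane_R < 1:
            raise ValidationError("in_plane_R must be >= 1")
        if not (Fraction(1, 2) <= self.partial_fourier <= 1):
            raise ValidationError("partial_fourier must lie in [1/2, 1]")
        shift = self.fov_shift_fraction * self.sms_factor
        if shift.denominator != 1:
            raise ValidationError(
                "fov_shift_fraction must be p / sms_factor for integer p"
            )
        if any(c > m for c, m in zip(self.calib_size, self.matrix_size)):
            raise ValidationError("calib_size must not exceed matrix_size")
        for name in ("n_coils", "sms_factor", "n_groups", "n_frames"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")

    @property
    def n_slices(self) -> int:
        return self.sms_factor * self.n_groups

    def group_slices(self, group: int) -> np.ndarray:
        """Anatomical slice indices excited by SMS group ``group``."""
        if not 0 <= group < self.n_groups:
            raise IndexError(f"group {group} out of range")
        return group + self.n_groups * np.arange(self.sms_factor)

    def slice_position(self, s: int) -> tuple[int, int]:
        """Inverse of ``group_slices``: slice -> (group, band)."""
        return s % self.n_groups, s // self.n_groups

    @property
    def kspace_shape(self) -> tuple[int, int, int, int, int]:
        nx, ny = self.matrix_size
        return (self.n_frames, self.n_groups, self.n_coils, nx, ny)

    def with_(self, **kw) -> "AcquisitionProtocol":
        return replace(self, **kw)


@dataclass
class KSpaceSMS:
    """Acquired multi-coil, SMS-collapsed, undersampled k-space.

    ``data`` has axes (frame, group, coil, readout, phase-encode); entries at
    unsampled locations are exactly zero.  ``pattern_ref`` links to the
    sampling pattern the data was acquired with.
    """

    data: np.ndarray
    pattern_ref: "object | None" = None  # SamplingPattern; avoids import cycle

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValidationError(
                f"k-space must be 5-D (frame, group, coil, kx, ky); got {self.data.ndim}-D"
            )
        if not np.iscomplexobj(self.data):
            self.data = self.data.astype(np.complex128)

    def validate_zeros(self) -> None:
        if self.pattern_ref is None:
            return
        off = ~self.pattern_ref.mask
        if np.any(self.data[..., off] != 0):
            raise ValidationError("nonzero k-space entries at unsampled locations")


@dataclass
class CalibrationScan:
    """Per-slice low-resolution multi-coil k-space, fully sampled on its grid.

    ``data`` axes: (slice, coil, kx, ky).  One entry per anatomical slice.
    """

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValidationError("calibration must be 4-D (slice, coil, kx, ky)")
        if not np.iscomplexobj(self.data):
            self.data = self.data.astype(np.complex128)

    @property
    def grid(self) -> tuple[int, int]:
        return self.data.shape[-2:]


_DOMAINS = ("siim", "restored", "coil-combined")


@dataclass
class ImageSeries:
    """Complex image stack (slice, frame, x, y) with a one-shot domain tag."""

    data: np.ndarray
    domain: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 4:
            raise ValidationError("image series must be 4-D (slice, frame, x, y)")
        if self.domain not in _DOMAINS:
            raise ValidationError(f"unknown domain tag {self.domain!r}")

    def retag(self, domain: str) -> "ImageSeries":
        """Return a new series in a different domain (tags are set once)."""
        return ImageSeries(self.data.copy(), domain)


_METHODS = ("ssg", "llr", "lps", "pgdl-conv", "pgdl-siim", "cg")


@dataclass
class ReconConfig:
    """Solver/regularization settings recorded in every output artifact."""

    method: str = "cg"
    cg_tol: float = 1e-8
    cg_max_iter: int = 50
    reg_weight: float = 0.01
    n_unrolls: int = 10
    cg_iters_df: int = 10
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValidationError(f"unknown method {self.method!r}")
        if self.cg_tol <= 0:
            raise ValidationError("cg_tol must be > 0")
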