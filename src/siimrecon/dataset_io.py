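"""HDF5 dataset layout: reader, writer, validator.

Layout (all arrays native complex128 unless noted)::

    /kspace        (frame, group, coil, kx, ky)
    /calibration   (slice, coil, kx, ky)
    /mask          uint8 (kx, ky)
    /caipi_phase   float64 radians (sms, n_sampled_lines)
    /derived/L     optional (slice, frame, kx, ky) float64
    /derived/maps  optional (slice, coil, kx, ky) complex

Root attributes: matrix_size, n_coils, sms_factor, n_groups, n_frames,
in_plane_R, partial_fourier (two ints), fov_shift (two ints), calib_size,
seed, plus pattern bookkeeping (pe_offset, pe_window_start).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from fractions import Fraction

import h5py
import numpy as np

from .datamodel import (
    AcquisitionProtocol,
    CalibrationScan,
    KSpaceSMS,
    ValidationError,
)
from .encoding import CaipiSchedule, SamplingPattern

__all__ = ["read_dataset", "write_dataset", "validate_dataset", "DatasetFormatError"]


class DatasetFormatError(IOError):
    """File does not conform to the dataset layout."""


_REQUIRED = ("kspace", "calibration", "mask", "caipi_phase")
_INT_ATTRS = (
    "n_coils",
    "sms_factor",
    "n_groups",
    "n_frames",
    "in_plane_R",
    "seed",
    "pe_offset",
    "pe_window_start",
)


def write_dataset(
    path: str,
    protocol: AcquisitionProtocol,
    kspace: KSpaceSMS,
    calib: CalibrationScan,
    pattern: SamplingPattern,
    caipi: CaipiSchedule,
    seed: int = 0,
    force: bool = False,
    derived: dict[str, np.ndarray] | None = None,
) -> str:
    if os.path.exists(path) and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    if kspace.data.shape != protocol.kspace_shape:
        raise ValidationError(
            f"k-space shape {kspace.data.shape} != protocol {protocol.kspace_shape}"
        )
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=kspace.data.astype(np.complex128))
        f.create_dataset("calibration", data=calib.data.astype(np.complex128))
        f.create_dataset("mask", data=pattern.mask.astype(np.uint8))
        f.create_dataset("caipi_phase", data=caipi.phases.astype(np.float64))
        f.create_dataset("sampled_lines", data=pattern.sampled_lines.astype(np.int64))
        a = f.attrs
        a["matrix_size"] = np.asarray(protocol.matrix_size, dtype=np.int64)
        a["calib_size"] = np.asarray(protocol.calib_size, dtype=np.int64)
        a["n_coils"] = int(protocol.n_coils)
        a["sms_factor"] = int(protocol.sms_factor)
        a["n_groups"] = int(protocol.n_groups)
        a["n_frames"] = int(protocol.n_frames)
        a["in_plane_R"] = int(protocol.in_plane_R)
        pf = Fraction(protocol.partial_fourier)
        a["partial_fourier"] = np.asarray([pf.numerator, pf.denominator], dtype=np.int64)
        fs = Fraction(protocol.fov_shift_fraction)
        a["fov_shift"] = np.asarray([fs.numerator, fs.denominator], dtype=np.int64)
        a["seed"] = int(seed)
        a["pe_offset"] = int(pattern.pe_offset)
        a["pe_window_start"] = int(pattern.pe_window_start)
        if derived:
            g = f.create_group("derived")
            for k, v in derived.items():
                g.create_dataset(k, data=v)
    return path


def read_dataset(
    path: str,
) -> tuple[AcquisitionProtocol, KSpaceSMS, CalibrationScan, SamplingPattern, CaipiSchedule]:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        for key in _REQUIRED:
            if key not in f:
                raise DatasetFormatError(f"missing dataset {key!r} in {path}")
        for key in ("matrix_size", "partial_fourier", "fov_shift") + _INT_ATTRS:
            if key not in f.attrs:
                raise DatasetFormatError(f"missing root attribute {key!r} in {path}")
        a = f.attrs
        protocol = AcquisitionProtocol(
            matrix_size=tuple(int(v) for v in a["matrix_size"]),
            n_coils=int(a["n_coils"]),
            sms_factor=int(a["sms_factor"]),
            n_groups=int(a["n_groups"]),
            n_frames=int(a["n_frames"]),
            in_plane_R=int(a["in_plane_R"]),
            partial_fourier=Fraction(*(int(v) for v in a["partial_fourier"])),
            fov_shift_fraction=Fraction(*(int(v) for v in a["fov_shift"])),
            calib_size=tuple(int(v) for v in a["calib_size"]),
        )
        ksp = f["kspace"][()]
        cal = f["calibration"][()]
        mask = f["mask"][()].astype(bool)
        phases = f["caipi_phase"][()]
        lines = f["sampled_lines"][()] if "sampled_lines" in f else np.flatnonzero(mask[0])
        pattern = SamplingPattern(
            mask=mask,
            in_plane_R=protocol.in_plane_R,
            partial_fourier=protocol.partial_fourier,
            pe_offset=int(a["pe_offset"]),
            pe_window_start=int(a["pe_window_start"]),
        )
        caipi = CaipiSchedule(
            phases=phases,
            fov_shift_fraction=protocol.fov_shift_fraction,
            sampled_lines=np.asarray(lines),
        )
    kspace = KSpaceSMS(ksp, pattern_ref=pattern)
    calib = CalibrationScan(cal)
    if kspace.data.shape != protocol.kspace_shape:
        raise ValidationError(
            f"k-space shape {kspace.data.shape} != protocol {protocol.kspace_shape}"
        )
    kspace.validate_zeros()
    return protocol, kspace, calib, pattern, caipi


@dataclass
class ValidationReport:
    problems: list[str] = field(default_factory=list)

    def add(self, msg: str) -> None:
        self.problems.append(msg)

    @property
    def ok(self) -> bool:
        return not self.problems

    def __iter__(self):
        return iter(self.problems)


def validate_dataset(
    protocol: AcquisitionProtocol,
    kspace: KSpaceSMS,
    calib: CalibrationScan,
    pattern: SamplingPattern,
) -> ValidationReport:
    """Report-only check of every cross-object invariant."""
    rep = ValidationReport()
    if kspace.data.shape != protocol.kspace_shape:
        rep.add(
            f"kspace shape {kspace.data.shape} does not match protocol "
            f"{protocol.kspace_shape}"
        )
    if pattern.mask.shape != protocol.matrix_size:
        rep.add("mask grid does not match matrix_size")
    else:
        off = ~pattern.mask
        if np.any(kspace.data[..., off] != 0):
            rep.add("nonzero k-space entries at unsampled locations")
        lines = pattern.sampled_lines
        if lines.size == 0:
            rep.add("sampling mask is empty")
        else:
            steps = np.diff(lines)
            if lines.size > 1 and not np.all(steps == pattern.in_plane_R):
                rep.add(
                    f"sampled lines spaced {sorted(set(int(s) for s in steps))}, "
                    f"inconsistent with in_plane_R={pattern.in_plane_R}"
                )
            ny = pattern.mask.shape[1]
            start = int(round((1 - float(protocol.partial_fourier)) * ny))
            if lines[0] < start:
                rep.add("sampled lines violate the partial-Fourier window")
        if not np.all(pattern.mask == pattern.mask[:1]):
            rep.add("mask varies along readout")
    if calib.data.shape[0] != protocol.n_slices:
        rep.add(
            f"calibration has {calib.data.shape[0]} slices, protocol expects "
            f"{protocol.n_slices}"
        )
    if calib.data.shape[1] != protocol.n_coils:
        rep.add("calibration coil count does not match protocol")
    if any(g < c for g, c in zip(calib.grid, protocol.calib_size)):
        rep.add(
            f"calibration grid {calib.grid} smaller than calib_size "
            f"{protocol.calib_size}"
        )
    return rep
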