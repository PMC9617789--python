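"""Coil-map estimation, slice separation, and intensity-map construction.

* ``espirit_maps``: eigenvalue-based sensitivity maps from a central
  calibration region.
* ``ssg_calibrate`` / ``ssg_apply``: split slice-GRAPPA kernels separating
  SMS-collapsed k-space into per-slice k-space with leakage blocking, plus
  in-plane GRAPPA kernels filling the uniform undersampling gaps (the gaps
  are filled after separation; partial-Fourier lines stay unacquired).
* ``make_intensity_map``: per-frame low-resolution intensity images from the
  central k-space region (Blackman-windowed, SENSE-1 combined, magnitude).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal.windows import blackman

from ._fft import crop_center, ifft2c, pad_center
from .datamodel import AcquisitionProtocol, CalibrationScan, ValidationError
from .encoding import IntensityMap, SamplingPattern, make_sampling_pattern

__all__ = [
    "CoilMaps",
    "GrappaKernels",
    "espirit_maps",
    "ssg_calibrate",
    "ssg_apply",
    "sense1_combine",
    "make_intensity_map",
]


@dataclass
class CoilMaps:
    """Complex sensitivities (slice, coil, x, y) with a support mask.

    Inside the support ``sum_c |S_c|^2 == 1``; outside all maps are zero.
    """

    values: np.ndarray
    support: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        self.support = np.asarray(self.support, dtype=bool)
        if self.values.ndim != 4:
            raise ValidationError("coil maps must be (slice, coil, x, y)")

    def group(self, slices: np.ndarray) -> np.ndarray:
        """Maps for one SMS group, given ``protocol.group_slices(g)``."""
        return self.values[np.asarray(slices)]


# ---------------------------------------------------------------------------
# ESPIRiT
# ---------------------------------------------------------------------------


def _calibration_matrix(calib: np.ndarray, k: int) -> np.ndarray:
    """Block-Hankel matrix: rows = sliding k x k multi-coil windows."""
    nc = calib.shape[0]
    win = sliding_window_view(calib, (k, k), axis=(1, 2))  # (nc, px, py, k, k)
    win = win.transpose(1, 2, 0, 3, 4)  # (px, py, nc, k, k)
    return win.reshape(-1, nc * k * k)


def espirit_maps(
    calib: CalibrationScan | np.ndarray,
    out_shape: tuple[int, int],
    kernel_size: int = 6,
    eig_threshold: float = 0.02,
    crop_threshold: float = 0.95,
    calib_size: tuple[int, int] = (24, 24),
) -> CoilMaps:
    """Per-pixel dominant eigenvector of the calibration-subspace operator.

    Maps are normalized to unit root-sum-of-squares on the support (pixels
    whose leading eigenvalue exceeds ``crop_threshold``) and phase-referenced
    so the first coil is real-positive.
    """
    data = calib.data if isinstance(calib, CalibrationScan) else np.asarray(calib)
    if data.ndim == 3:
        data = data[None]
    n_slices, nc = data.shape[:2]
    nx, ny = out_shape
    k = kernel_size
    csize = tuple(min(c, g) for c, g in zip(calib_size, data.shape[-2:]))
    if any(c < k for c in csize):
        raise ValueError(f"calibration region {csize} smaller than kernel {k}")
    values = np.zeros((n_slices, nc, nx, ny), dtype=np.complex128)
    support = np.zeros((n_slices, nx, ny), dtype=bool)
    for s in range(n_slices):
        region = crop_center(data[s], csize)
        if not np.any(region):
            raise ValueError(f"calibration for slice {s} is all zeros")
        A = _calibration_matrix(region, k)
        _, sv, vh = np.linalg.svd(A, full_matrices=False)
        n_keep = max(1, int(np.sum(sv >= eig_threshold * sv[0])))
        # row-space kernels, zero-padded and transformed so the per-pixel
        # subspace operator has eigenvalues in [0, 1]
        kernels = vh[:n_keep].reshape(n_keep, nc, k, k)
        padded = pad_center(kernels, (nx, ny))
        kerimg = ifft2c(padded) * (np.sqrt(nx * ny) / k)
        # per-pixel matrix G (nc, n_keep); dominant eigenvector of G G^H
        G = kerimg.transpose(2, 3, 1, 0)  # (nx, ny, nc, n_keep)
        M = G @ G.conj().transpose(0, 1, 3, 2)
        eigval, eigvec = np.linalg.eigh(M)
        lead_val = eigval[..., -1].real
        lead_vec = eigvec[..., -1]  # (nx, ny, nc)
        sup = lead_val >= crop_threshold
        vec = np.where(sup[..., None], lead_vec, 0.0)
        # unit RSS on support (eigh already returns unit vectors) and
        # coil-0 real-positive phase reference
        ref = vec[..., 0]
        phase = np.where(np.abs(ref) > 0, ref / np.where(np.abs(ref) > 0, np.abs(ref), 1), 1.0)
        vec = vec * np.conj(phase)[..., None]
        values[s] = vec.transpose(2, 0, 1)
        support[s] = sup
    return CoilMaps(values=values, support=support)


# ---------------------------------------------------------------------------
# split slice-GRAPPA + in-plane GRAPPA
# ---------------------------------------------------------------------------


@dataclass
class GrappaKernels:
    """Slice-separation and in-plane interpolation kernels for one protocol.

    ``ssg[g][i]``: weights (nc*kt*kt, nc) predicting the CAIPI-modulated
    k-space of band ``i`` of group ``g`` from the collapsed data, taps spaced
    ``in_plane_R`` along phase-encode.
    ``inplane[s][delta]``: weights (nc*kxt*4, nc) predicting a missing line
    at offset ``delta`` (mod R) for slice ``s``.
    """

    ssg: list
    inplane: list
    kernel_taps: int
    kx_taps_inplane: int
    protocol: AcquisitionProtocol

    @property
    def sms_factor(self) -> int:
        return self.protocol.sms_factor


def _caipi_ramp(
    slice_in_group: int, grid_ny: int, protocol: AcquisitionProtocol, pattern: SamplingPattern
) -> np.ndarray:
    """CAIPIRINHA modulation for band ``i`` as a linear phase over a
    DC-centered ky grid, consistent with the per-sampled-line schedule."""
    shift = float(protocol.fov_shift_fraction)
    ny = protocol.matrix_size[1]
    ky = np.arange(grid_ny) - grid_ny // 2 + ny // 2  # absolute full-grid index
    phi = 2 * np.pi * slice_in_group * shift * (ky - pattern.pe_window_start) / pattern.in_plane_R
    return np.exp(1j * phi)


def _patches(
    arr: np.ndarray, kt: int, dil_y: int, y_keep: np.ndarray | None = None
) -> tuple[np.ndarray, tuple[int, int], np.ndarray]:
    """Valid-position patches (n_pos, nc*kt*kt) with ky taps spaced dil_y.

    ``y_keep`` restricts the patch start positions along ky (the CAIPI phase
    pattern only repeats on the sampled-line lattice, so kernel fits must use
    positions aligned with it).
    """
    nc, px, py = arr.shape
    span_y = (kt - 1) * dil_y + 1
    win = sliding_window_view(arr, (kt, span_y), axis=(1, 2))[..., ::dil_y]
    # (nc, vx, vy, kt, kt) -> (vx, vy, nc*kt*kt)
    win = win.transpose(1, 2, 0, 3, 4)
    if y_keep is None:
        y_keep = np.arange(win.shape[1])
    win = win[:, y_keep]
    vx, vy = win.shape[:2]
    return win.reshape(vx * vy, -1), (vx, vy), np.asarray(y_keep)


def _ridge_lstsq(X: np.ndarray, T: np.ndarray, reg: float) -> np.ndarray:
    """Tikhonov-regularized least squares; ``reg`` is relative to the mean
    diagonal of X^H X (standard GRAPPA kernel conditioning)."""
    G = X.conj().T @ X
    lam = reg * np.trace(G).real / max(G.shape[0], 1)
    G += lam * np.eye(G.shape[0])
    return np.linalg.solve(G, X.conj().T @ T)


def ssg_calibrate(
    calib: CalibrationScan,
    protocol: AcquisitionProtocol,
    kernel_taps: int = 5,
    kx_taps_inplane: int = 5,
    pattern: SamplingPattern | None = None,
    reg: float = 1e-6,
) -> GrappaKernels:
    """Least-squares fit of split slice-GRAPPA and in-plane GRAPPA kernels.

    The split constraint is enforced by stacking one equation block per band:
    sources from band j alone must predict band i's modulated k-space when
    ``j == i`` and zero otherwise.
    """
    if pattern is None:
        pattern = make_sampling_pattern(protocol)
    data = calib.data
    if data.shape[0] != protocol.n_slices:
        raise ValidationError("calibration slice count does not match protocol")
    nc = protocol.n_coils
    sms, R, kt = protocol.sms_factor, protocol.in_plane_R, kernel_taps
    cx, cy = data.shape[-2:]
    span_y = (kt - 1) * R + 1
    if cx < kt or cy < span_y:
        raise ValueError(
            f"calibration grid {(cx, cy)} too small for {kt} taps at step {R}: "
            f"needs at least {(kt, span_y)}"
        )

    # the CAIPI modulation is a linear phase in ky, so the fit equations are
    # shift-covariant: every patch position contributes consistently
    cxo, cyo = kt // 2, (kt // 2) * R
    ssg_kernels = []
    for g in range(protocol.n_groups):
        mods = []
        for i in range(sms):
            ramp = _caipi_ramp(i, cy, protocol, pattern)
            mods.append(data[protocol.group_slices(g)[i]] * ramp[None, None, :])
        blocks, centers = [], []
        for j in range(sms):
            X, (vx, vy), kept = _patches(mods[j], kt, R)
            blocks.append(X)
            centers.append(
                [
                    m[:, cxo : cxo + vx, cyo + kept].transpose(1, 2, 0).reshape(-1, nc)
                    for m in mods
                ]
            )
        X = np.concatenate(blocks, axis=0)
        n_pos = blocks[0].shape[0]
        if X.shape[0] < X.shape[1]:
            raise ValueError(
                f"underdetermined slice-kernel fit: {X.shape[0]} equations for "
                f"{X.shape[1]} unknowns; enlarge the calibration region"
            )
        group_w = []
        for i in range(sms):
            T = np.concatenate(
                [centers[j][i] if j == i else np.zeros((n_pos, nc)) for j in range(sms)]
            )
            w = _ridge_lstsq(X, T, reg)
            group_w.append(w)
        ssg_kernels.append(group_w)

    inplane_kernels = []
    kxt = kx_taps_inplane
    hx = kxt // 2
    for s in range(protocol.n_slices):
        per_delta = {}
        if R > 1:
            g, i = protocol.slice_position(s)
            ramp = _caipi_ramp(i, cy, protocol, pattern)
            mod = data[s] * ramp[None, None, :]
            for delta in range(1, R):
                offs = np.array([-delta - R, -delta, R - delta, 2 * R - delta])
                y0, y1 = -offs.min(), cy - offs.max()
                x0, x1 = hx, cx - hx
                if y1 <= y0 or x1 <= x0:
                    raise ValueError("calibration grid too small for in-plane kernels")
                ys = np.arange(y0, y1)
                cols = []
                for dx in range(-hx, hx + 1):
                    for dy in offs:
                        cols.append(mod[:, x0 + dx : x1 + dx, :][:, :, ys + dy])
                X = np.stack(cols, axis=1).reshape(nc * kxt * 4, -1).T
                T = mod[:, x0:x1, :][:, :, ys].reshape(nc, -1).T
                if X.shape[0] < X.shape[1]:
                    raise ValueError(
                        f"underdetermined in-plane fit: {X.shape[0]} equations for "
                        f"{X.shape[1]} unknowns"
                    )
                w = _ridge_lstsq(X, T, reg)
                per_delta[delta] = w
        inplane_kernels.append(per_delta)

    return GrappaKernels(
        ssg=ssg_kernels,
        inplane=inplane_kernels,
        kernel_taps=kt,
        kx_taps_inplane=kxt,
        protocol=protocol,
    )


def _apply_compact_kernel(ys: np.ndarray, w: np.ndarray, kt: int) -> np.ndarray:
    """Apply a (nc*kt*kt, nc) kernel over a compact (nc, nx, n_lines) array
    with zero padding, returning predictions at every position."""
    nc, nx, nl = ys.shape
    h = kt // 2
    pad = np.pad(ys, ((0, 0), (h, h), (h, h)))
    win = sliding_window_view(pad, (kt, kt), axis=(1, 2)).transpose(1, 2, 0, 3, 4)
    X = win.reshape(nx * nl, -1)
    return (X @ w).T.reshape(nc, nx, nl)


def ssg_apply(
    kernels: GrappaKernels, kspace_frame: np.ndarray, group: int, pattern: SamplingPattern
) -> np.ndarray:
    """Separate one collapsed frame (coil, kx, ky) into per-band full k-space.

    Returns (sms, coil, kx, ky): slice-separated, in-plane gaps filled,
    CAIPI modulation removed.  Acquired collapsed entries are used as-is.
    """
    protocol = kernels.protocol
    nc = protocol.n_coils
    nx, ny = protocol.matrix_size
    y = np.asarray(kspace_frame, dtype=np.complex128)
    if y.shape != (nc, nx, ny):
        raise ValidationError(f"expected frame {(nc, nx, ny)}, got {y.shape}")
    lines = pattern.sampled_lines
    if lines.size == 0:
        raise ValueError("pattern has no sampled lines")
    R, sms = pattern.in_plane_R, protocol.sms_factor
    compact = y[:, :, lines]
    out = np.zeros((sms, nc, nx, ny), dtype=np.complex128)
    for i in range(sms):
        sep = _apply_compact_kernel(compact, kernels.ssg[group][i], kernels.kernel_taps)
        full = np.zeros((nc, nx, ny), dtype=np.complex128)
        full[:, :, lines] = sep
        s = group * sms + i
        if R > 1:
            full = _fill_inplane(full, kernels, s, pattern)
        ramp = _caipi_ramp(i, ny, protocol, pattern)
        out[i] = full * np.conj(ramp)[None, None, :]
    return out


def _fill_inplane(
    full: np.ndarray, kernels: GrappaKernels, s: int, pattern: SamplingPattern
) -> np.ndarray:
    nc, nx, ny = full.shape
    R = pattern.in_plane_R
    start = pattern.pe_window_start + pattern.pe_offset
    kxt = kernels.kx_taps_inplane
    hx = kxt // 2
    padx = np.pad(full, ((0, 0), (hx, hx), (R + 2 * R, R + 2 * R)))
    out = full.copy()
    for m in range(start, ny):
        delta = (m - start) % R
        if delta == 0:
            continue
        w = kernels.inplane[s][delta]
        offs = np.array([-delta - R, -delta, R - delta, 2 * R - delta])
        cols = []
        for dx in range(-hx, hx + 1):
            for dy in offs:
                cols.append(padx[:, hx + dx : hx + dx + nx, 3 * R + m + dy])
        X = np.stack(cols, axis=1).reshape(nc * kxt * 4, -1).T
        out[:, :, m] = (X @ w).T
    return out


# ---------------------------------------------------------------------------
# SENSE-1 combination and intensity maps
# ---------------------------------------------------------------------------


def sense1_combine(
    coil_images: np.ndarray, maps: np.ndarray, support: np.ndarray | None = None
) -> np.ndarray:
    """Unit-gain coil combination sum_c conj(S_c) m_c / sum_c |S_c|^2."""
    coil_images = np.asarray(coil_images)
    maps = np.asarray(maps)
    if coil_images.shape != maps.shape:
        raise ValidationError("coil images and maps must share a shape")
    denom = (np.abs(maps) ** 2).sum(axis=0)
    if support is None:
        support = denom > 1e-12
    num = (np.conj(maps) * coil_images).sum(axis=0)
    return np.where(support, num / np.maximum(denom, 1e-12), 0.0)


def make_intensity_map(
    kspace: np.ndarray,
    kernels: GrappaKernels,
    maps: CoilMaps,
    pattern: SamplingPattern,
    calib_size: tuple[int, int] | None = None,
    window: str = "blackman",
) -> IntensityMap:
    """Per-frame/slice low-resolution intensity images.

    Pipeline per frame and group: slice separation -> central
    ``calib_size`` crop -> separable Blackman window -> zero-pad to matrix
    size -> unitary inverse FFT -> SENSE-1 combine -> magnitude.

    ``kspace``: (frame, group, coil, kx, ky).
    """
    protocol = kernels.protocol
    if calib_size is None:
        calib_size = protocol.calib_size
    if not np.any(kspace):
        raise ValueError("all-zero k-space frame")
    nt, ng = kspace.shape[:2]
    nx, ny = protocol.matrix_size
    sms = protocol.sms_factor
    if window == "blackman":
        w2d = np.outer(blackman(calib_size[0]), blackman(calib_size[1]))
    elif window == "none":
        w2d = np.ones(calib_size)
    else:
        raise ValueError(f"unknown window {window!r}")
    L = np.zeros((protocol.n_slices, nt, nx, ny))
    for t in range(nt):
        for g in range(ng):
            sep = ssg_apply(kernels, kspace[t, g], g, pattern)
            low = crop_center(sep, calib_size) * w2d
            imgs = ifft2c(pad_center(low, (nx, ny)))
            for i in range(sms):
                s = int(protocol.group_slices(g)[i])
                comb = sense1_combine(imgs[i], maps.values[s], maps.support[s])
                L[s, t] = np.abs(comb)
    return IntensityMap(values=L)
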