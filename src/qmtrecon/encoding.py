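"""Undersampled multi-coil acquisition operator and data-consistency terms.

The forward model per measurement is ``d = U F C S(Q)``: voxelwise signal
model, coil weighting, orthonormal 2D Fourier transform over the in-plane
axes (slices along the last axis are fully sampled and processed as a
batch), and retention of the sampled phase-encode locations.  The DC
component sits at the grid center (fftshift convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal import (
    AcquisitionProtocol,
    FixedPoolConstants,
    MeasurementConstants,
    QMapVolume,
    measurement_constants,
    magnitude_and_partials,
    signal_magnitude_series,
)

__all__ = [
    "SamplingMask",
    "CoilSensitivities",
    "KSpaceData",
    "make_vd_gaussian_mask",
    "stack_measurement_masks",
    "fft2c",
    "ifft2c",
    "forward_encode",
    "adjoint_encode",
    "zero_fill_recon",
    "model_images",
    "data_consistency_value",
    "data_consistency_grad",
]


@dataclass
class SamplingMask:
    """Binary phase-encode sampling pattern with an exact sample budget.

    ``grid`` is 2D (one pattern shared by every measurement, the default)
    or 3D ``[meas, kx, ky]`` for per-measurement patterns.
    """

    grid: np.ndarray
    calibration_extent: tuple
    af_nominal: float
    seed: int

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.uint8)

    @property
    def per_measurement(self) -> bool:
        return self.grid.ndim == 3

    def broadcast_grid(self) -> np.ndarray:
        """Grid shaped for [meas, coil, kx, ky, z] broadcasting."""
        if self.per_measurement:
            return self.grid[:, None, :, :, None]
        return self.grid[None, None, :, :, None]

    @property
    def sampled_fraction(self) -> float:
        return float(self.grid.mean())

    @property
    def n_sampled(self) -> int:
        return int(self.grid.sum())


@dataclass
class CoilSensitivities:
    """Complex coil maps, normalized so Σ|C|² = 1 on the object support."""

    maps: np.ndarray
    support: np.ndarray

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=complex)
        self.support = np.asarray(self.support, dtype=bool)

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    @property
    def sos(self) -> np.ndarray:
        return np.sum(np.abs(self.maps) ** 2, axis=0)


@dataclass
class KSpaceData:
    """Measured (possibly undersampled) k-space: [meas, coil, kx, ky, z]."""

    data: np.ndarray
    mask: SamplingMask
    protocol: AcquisitionProtocol | None = None
    noise_sigma: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=complex)


class InvalidMaskConfigError(ValueError):
    pass


def _gaussian_density(shape, stds=None):
    grids = []
    for n, s in zip(shape, stds or [n / 6.0 for n in shape]):
        x = np.arange(n) - (n - 1) / 2.0
        grids.append(np.exp(-0.5 * (x / s) ** 2))
    if len(shape) == 1:
        return grids[0]
    return np.outer(grids[0], grids[1])


def make_vd_gaussian_mask(
    grid_shape,
    af: float,
    calibration_extent,
    seed: int = 0,
    dim: int = 2,
    axis: int = 0,
) -> SamplingMask:
    """Variable-density Gaussian sampling pattern with exact budget.

    ``dim=2`` draws individual phase-encode points on the 2D grid; ``dim=1``
    draws whole lines perpendicular to ``axis``.  A central calibration
    block (``dim=2``: ``calibration_extent`` can be an int or a pair;
    ``dim=1``: number of central lines) is always fully sampled.  The total
    number of sampled points equals ``round(N / af)`` exactly; the remaining
    budget is drawn without replacement with a center-peaked Gaussian
    density (per-axis std = extent/6).
    """
    if af < 1:
        raise InvalidMaskConfigError("acceleration factor must be >= 1")
    nx, ny = grid_shape
    rng = np.random.default_rng(seed)
    mask = np.zeros((nx, ny), dtype=np.uint8)
    if dim == 2:
        cal = (
            (int(calibration_extent),) * 2
            if np.isscalar(calibration_extent)
            else tuple(int(c) for c in calibration_extent)
        )
        if cal[0] > nx or cal[1] > ny:
            raise InvalidMaskConfigError("calibration block exceeds grid")
        budget = int(round(nx * ny / af))
        x0, y0 = (nx - cal[0]) // 2, (ny - cal[1]) // 2
        mask[x0 : x0 + cal[0], y0 : y0 + cal[1]] = 1
        n_cal = int(mask.sum())
        if budget < n_cal:
            raise InvalidMaskConfigError("calibration block larger than sample budget")
        dens = _gaussian_density((nx, ny))
        dens = dens.ravel().copy()
        dens[mask.ravel() > 0] = 0.0
        dens /= dens.sum()
        extra = rng.choice(nx * ny, size=budget - n_cal, replace=False, p=dens)
        flat = mask.ravel()
        flat[extra] = 1
        mask = flat.reshape(nx, ny)
        cal_extent = cal
    elif dim == 1:
        n_pe = grid_shape[axis]
        n_line = int(calibration_extent)
        if n_line > n_pe:
            raise InvalidMaskConfigError("calibration lines exceed grid")
        budget = int(round(n_pe / af))
        if budget < n_line:
            raise InvalidMaskConfigError("calibration lines exceed line budget")
        line_mask = np.zeros(n_pe, dtype=np.uint8)
        c0 = (n_pe - n_line) // 2
        line_mask[c0 : c0 + n_line] = 1
        dens = _gaussian_density((n_pe,))
        dens = dens.copy()
        dens[line_mask > 0] = 0.0
        dens /= dens.sum()
        extra = rng.choice(n_pe, size=budget - n_line, replace=False, p=dens)
        line_mask[extra] = 1
        mask = (
            np.broadcast_to(line_mask[:, None], (n_pe, grid_shape[1 - axis]))
            if axis == 0
            else np.broadcast_to(line_mask[None, :], (grid_shape[1 - axis], n_pe))
        ).copy()
        if axis == 1:
            mask = mask.reshape(grid_shape)
        cal_extent = (n_line,)
    else:
        raise InvalidMaskConfigError("dim must be 1 or 2")
    return SamplingMask(
        grid=mask, calibration_extent=cal_extent, af_nominal=af, seed=seed
    )


def stack_measurement_masks(masks) -> SamplingMask:
    """Combine per-measurement masks into one 3D-pattern SamplingMask."""
    masks = list(masks)
    grids = np.stack([m.grid for m in masks], axis=0)
    return SamplingMask(
        grid=grids,
        calibration_extent=masks[0].calibration_extent,
        af_nominal=masks[0].af_nominal,
        seed=masks[0].seed,
    )


# ---------------------------------------------------------------------------
# orthonormal centered FFT pair
# ---------------------------------------------------------------------------


def fft2c(x, axes=(-3, -2)):
    """Orthonormal centered 2D FFT over the in-plane axes."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def ifft2c(x, axes=(-3, -2)):
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def _check_shapes(W, C):
    if W.shape[1:] != C.shape[1:]:
        raise ValueError(
            f"spatial shape mismatch: images {W.shape[1:]} vs coils {C.shape[1:]}"
        )


def _maps_as(C: CoilSensitivities, dtype):
    if C.maps.dtype == dtype:
        return C.maps
    cached = getattr(C, "_maps_cast", None)
    if cached is None or cached.dtype != dtype:
        cached = C.maps.astype(dtype)
        C._maps_cast = cached
    return cached


def forward_encode(W, C: CoilSensitivities, mask: SamplingMask) -> np.ndarray:
    """``d[m, c] = mask ⊙ F(C_c ⊙ W_m)`` — shape (meas, coil, kx, ky, z).

    The complex precision of ``W`` is preserved (complex64 input stays
    complex64, anything else is done in complex128).
    """
    W = np.asarray(W)
    ct = np.complex64 if W.dtype == np.complex64 else np.complex128
    W = W.astype(ct, copy=False)
    _check_shapes(W, C.maps)
    maps = _maps_as(C, ct)
    coil_imgs = maps[None, :, :, :, :] * W[:, None, :, :, :]
    k = fft2c(coil_imgs, axes=(2, 3))
    return k * mask.broadcast_grid()


def adjoint_encode(d, C: CoilSensitivities, mask: SamplingMask) -> np.ndarray:
    """Exact adjoint of :func:`forward_encode` (conjugate coil combination)."""
    d = np.asarray(d)
    ct = np.complex64 if d.dtype == np.complex64 else np.complex128
    d = d.astype(ct, copy=False)
    maps = _maps_as(C, ct)
    k = d * mask.broadcast_grid()
    imgs = ifft2c(k, axes=(2, 3))
    return np.sum(np.conj(maps)[None] * imgs, axis=1)


def zero_fill_recon(d: KSpaceData | np.ndarray, C: CoilSensitivities, mask: SamplingMask):
    """Coil-combined inverse FFT of the zero-filled k-space.

    The adjoint is normalized by Σ|C|², guarded where the sensitivity norm
    vanishes (those voxels are returned as zero).
    """
    data = d.data if isinstance(d, KSpaceData) else np.asarray(d, dtype=complex)
    num = adjoint_encode(data, C, mask)
    sos = C.sos
    guard = sos > 1e-12
    out = np.zeros_like(num)
    out[:, guard] = num[:, guard] / sos[guard]
    return out


# ---------------------------------------------------------------------------
# data consistency
# ---------------------------------------------------------------------------


def model_images(
    Q: QMapVolume, mc: MeasurementConstants, clip_f: bool = True
) -> np.ndarray:
    """Weighted images S(Q): shape (meas,) + spatial, complex."""
    shape = Q.i0.shape
    bc = (slice(None),) + (None,) * len(shape)
    mags = signal_magnitude_series(
        (
            Q.i0[None],
            np.maximum(Q.t1f, 1e-4)[None],
            np.clip(Q.f, 1e-9, 1.0)[None] if clip_f else Q.f[None],
            Q.kf[None],
        ),
        MeasurementConstants(
            sin_a=mc.sin_a[bc],
            cos_a=mc.cos_a[bc],
            e1r=mc.e1r,
            ew=mc.ew[bc],
            ew0=mc.ew0[bc],
            phase=mc.phase[bc],
            tr=mc.tr,
        ),
    )
    return mags * np.exp(1j * mc.phase[bc])


def data_consistency_value(
    Q: QMapVolume,
    d,
    C: CoilSensitivities,
    mask: SamplingMask,
    protocol: AcquisitionProtocol,
    consts: FixedPoolConstants,
    mc: MeasurementConstants | None = None,
) -> float:
    """``g(Q) = ½ ‖d − U F C S(Q)‖²``."""
    data = d.data if isinstance(d, KSpaceData) else np.asarray(d, dtype=complex)
    if mc is None:
        mc = measurement_constants(protocol, consts)
    W = model_images(Q, mc)
    r = forward_encode(W, C, mask) - data
    return 0.5 * float(np.sum(np.abs(r) ** 2))


def data_consistency_grad(
    Q: QMapVolume,
    d,
    C: CoilSensitivities,
    mask: SamplingMask,
    protocol: AcquisitionProtocol,
    consts: FixedPoolConstants,
    mc: MeasurementConstants | None = None,
) -> np.ndarray:
    """Gradient of g w.r.t. the four maps, shape (4,) + spatial.

    Explicit chain: backproject the k-space residual through the adjoint
    encoding operator, then contract with the analytic signal Jacobian,
    ``∇g_i = Σ_m Re[conj(∂S_m/∂q_i) · (A^H r)_m]``.
    """
    data = d.data if isinstance(d, KSpaceData) else np.asarray(d, dtype=complex)
    if mc is None:
        mc = measurement_constants(protocol, consts)
    shape = Q.i0.shape
    bc = (slice(None),) + (None,) * len(shape)
    W = model_images(Q, mc)
    r = forward_encode(W, C, mask) - data
    b = adjoint_encode(r, C, mask)  # (meas,) + spatial
    _, parts = magnitude_and_partials(
        (
            Q.i0[None],
            np.maximum(Q.t1f, 1e-4)[None],
            np.clip(Q.f, 1e-9, 1.0)[None],
            Q.kf[None],
        ),
        MeasurementConstants(
            sin_a=mc.sin_a[bc],
            cos_a=mc.cos_a[bc],
            e1r=mc.e1r,
            ew=mc.ew[bc],
            ew0=mc.ew0[bc],
            phase=mc.phase[bc],
            tr=mc.tr,
        ),
    )
    phasor = np.exp(1j * mc.phase[bc])
    grads = []
    for p in parts:
        jac_m = np.broadcast_to(p, (len(mc.sin_a),) + shape) * phasor
        grads.append(np.sum(np.real(np.conj(jac_m) * b), axis=0))
    return np.stack(grads, axis=0)
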