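"""Seeded digital phantoms and simulated accelerated acquisitions.

The generators emulate the two study designs the reconstruction targets:

* a four-vial phantom — circular vials of increasing macromolecular
  fraction (agar-like concentration series plus a distinct fourth vial)
  immersed in a doped-water bath, scanned with the 10-measurement
  variable-flip-angle protocol (5/10/20/40/60° with and without
  saturation, TR 80 ms, Fermi pulse 8 ms / 9.128 μT / 4 kHz offset);
* a brain-like slab with white-matter-like (high f), gray-matter-like
  (low f) and fluid regions, for in-vivo-flavored tests.

Acquisitions are simulated through the same forward model the
reconstruction inverts: voxelwise signal model, smooth synthetic coil
maps, orthonormal FFT, variable-density undersampling, and complex
Gaussian noise added in k-space at the sampled locations only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import (
    CoilSensitivities,
    SamplingMask,
    forward_encode,
    make_vd_gaussian_mask,
    model_images,
)
from .io import ScanData
from .signal import (
    AcquisitionProtocol,
    FixedPoolConstants,
    QMapVolume,
    TissueParams,
    measurement_constants,
    phantom_protocol,
)

__all__ = [
    "PhantomSpec",
    "SimulatedDataset",
    "default_vial_spec",
    "make_vial_phantom",
    "make_brain_like_phantom",
    "simulate_coils",
    "sigma_for_snr",
    "simulate_acquisition",
    "simulate_vial_dataset",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and tissue assignment of a digital phantom.

    ``regions`` is a tuple of ``(cx, cy, radius, TissueParams)`` with
    positions/radii as fractions of the grid extent; regions must not
    overlap.  ``background`` fills the bath disc; outside the bath the
    object is empty (i0 = 0).
    """

    grid_shape: tuple = (64, 64, 2)
    regions: tuple = ()
    background: TissueParams = field(
        default_factory=lambda: TissueParams(1.0, 1.8, 0.02, 1.0)
    )
    bath_radius: float = 0.45
    noise_sigma: float = 0.0
    seed: int = 0


def default_vial_spec(grid_shape=(64, 64, 2), noise_sigma=0.0, seed=0) -> PhantomSpec:
    """Four vials of increasing macromolecular fraction in a water bath."""
    vials = (
        (-0.18, -0.18, 0.11, TissueParams(1.0, 2.0, 0.04, 1.0)),
        (0.18, -0.18, 0.11, TissueParams(1.0, 1.5, 0.08, 2.0)),
        (-0.18, 0.18, 0.11, TissueParams(1.0, 1.0, 0.16, 3.0)),
        (0.18, 0.18, 0.11, TissueParams(1.0, 0.8, 0.25, 4.0)),
    )
    return PhantomSpec(
        grid_shape=grid_shape, regions=vials, noise_sigma=noise_sigma, seed=seed
    )


def _disc(nx, ny, cx, cy, r):
    x = (np.arange(nx) - (nx - 1) / 2.0) / nx
    y = (np.arange(ny) - (ny - 1) / 2.0) / ny
    xx, yy = np.meshgrid(x, y, indexing="ij")
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r


def _paint(spec: PhantomSpec, masks_params) -> tuple[QMapVolume, np.ndarray]:
    nx, ny, nz = spec.grid_shape
    maps = np.zeros((4, nx, ny, nz))
    labels = np.zeros((nx, ny, nz), dtype=np.int16)
    for lab, (m2d, params) in enumerate(masks_params):
        m = np.repeat(m2d[:, :, None], nz, axis=2)
        for i, v in enumerate(params.as_array()):
            maps[i][m] = v
        if lab > 0:
            labels[m] = lab
    return QMapVolume.from_stack(maps), labels


def make_vial_phantom(spec: PhantomSpec | None = None):
    """Piecewise-constant truth maps and ROI labels for the vial phantom.

    Labels: 0 background/bath, 1..n vials in the order given (increasing f
    for the default spec).
    """
    spec = spec or default_vial_spec()
    nx, ny, _ = spec.grid_shape
    bath = _disc(nx, ny, 0.0, 0.0, spec.bath_radius)
    entries = [(bath, spec.background)]
    painted = np.zeros((nx, ny), dtype=bool)
    for cx, cy, r, params in spec.regions:
        m = _disc(nx, ny, cx, cy, r)
        if (m & painted).any():
            raise ValueError("phantom regions overlap")
        painted |= m
        entries.append((m, params))
    return _paint(spec, entries)


def make_brain_like_phantom(grid_shape=(64, 64, 2)):
    """Ellipse-based slab with WM-like, GM-like and fluid compartments.

    Labels: 1 white-matter-like, 2 gray-matter-like, 3 fluid.
    """
    nx, ny, nz = grid_shape
    x = (np.arange(nx) - (nx - 1) / 2.0) / nx
    y = (np.arange(ny) - (ny - 1) / 2.0) / ny
    xx, yy = np.meshgrid(x, y, indexing="ij")

    def ellipse(cx, cy, a, b):
        return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0

    head = ellipse(0, 0, 0.44, 0.38)
    wm = ellipse(0, 0, 0.30, 0.24)
    csf = ellipse(0, 0.02, 0.08, 0.05)
    gm = head & ~wm
    wm_only = wm & ~csf
    spec = PhantomSpec(grid_shape=grid_shape)
    entries = [
        (head, TissueParams(1.0, 1.4, 0.05, 2.0)),  # GM-like base fill
        (wm_only, TissueParams(0.95, 1.0, 0.14, 3.0)),
        (csf, TissueParams(1.05, 3.5, 0.005, 0.2)),
    ]
    qmaps, _ = _paint(spec, entries)
    labels = np.zeros((nx, ny), dtype=np.int16)
    labels[gm] = 2
    labels[wm_only] = 1
    labels[csf] = 3
    return qmaps, np.repeat(labels[:, :, None], nz, axis=2)


def simulate_coils(n_coils: int, grid_shape, seed: int = 0) -> CoilSensitivities:
    """Smooth synthetic coil maps, normalized to unit sum-of-squares.

    Magnitudes are Gaussian profiles centered on a ring around the FOV,
    phases low-order smooth ramps.  A single coil is the uniform map.
    """
    nx, ny, nz = grid_shape
    support = np.ones(grid_shape, dtype=bool)
    if n_coils == 1:
        return CoilSensitivities(np.ones((1,) + tuple(grid_shape), complex), support)
    rng = np.random.default_rng(seed)
    x = np.linspace(-0.5, 0.5, nx)
    y = np.linspace(-0.5, 0.5, ny)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    maps = np.zeros((n_coils, nx, ny, nz), dtype=complex)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils + rng.uniform(-0.2, 0.2)
        cx, cy = 0.55 * np.cos(ang), 0.55 * np.sin(ang)
        mag = np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2)) / (2 * 0.35**2))
        gx, gy = rng.uniform(-2.0, 2.0, size=2)
        phase = gx * xx + gy * yy + rng.uniform(0, 2 * np.pi)
        maps[c] = (mag * np.exp(1j * phase))[:, :, None]
    sos = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    maps /= sos[None]
    return CoilSensitivities(maps, support)


def sigma_for_snr(kspace_full: np.ndarray, snr_db: float) -> float:
    """Complex noise std giving the requested k-space SNR in dB
    (rms of the noiseless k-space over rms of the complex noise)."""
    rms = float(np.sqrt(np.mean(np.abs(kspace_full) ** 2)))
    return rms * 10.0 ** (-snr_db / 20.0)


@dataclass
class SimulatedDataset:
    """A complete simulated scan with its generating truth."""

    truth: QMapVolume
    truth_w: np.ndarray
    sens: CoilSensitivities
    mask: SamplingMask
    kspace: np.ndarray
    kspace_full: np.ndarray
    labels: np.ndarray
    protocol: AcquisitionProtocol
    consts: FixedPoolConstants
    noise_sigma: float
    provenance: dict

    @property
    def scan(self) -> ScanData:
        return ScanData(
            kspace=self.kspace,
            sens=self.sens,
            mask=self.mask,
            protocol=self.protocol,
            consts=self.consts,
            noise_sigma=self.noise_sigma,
            meta=dict(self.provenance),
        )

    @property
    def support(self) -> np.ndarray:
        return self.truth.i0 > 0


def simulate_acquisition(
    truth: QMapVolume,
    consts: FixedPoolConstants,
    protocol: AcquisitionProtocol,
    sens: CoilSensitivities,
    mask: SamplingMask,
    noise_sigma: float = 0.0,
    seed: int = 0,
    labels: np.ndarray | None = None,
    provenance: dict | None = None,
) -> SimulatedDataset:
    """Forward-simulate a scan from truth maps.

    The fully sampled k-space is kept noiseless; the undersampled data are
    ``mask ⊙ k_full`` plus complex Gaussian noise at the sampled points.
    """
    mc = measurement_constants(protocol, consts)
    W = model_images(truth, mc)
    nx, ny = W.shape[1:3]
    full_mask = SamplingMask(
        np.ones((nx, ny), np.uint8), (nx, ny), 1.0, seed=0
    )
    k_full = forward_encode(W, sens, full_mask)
    rng = np.random.default_rng(seed)
    m = mask.broadcast_grid()
    noise = np.zeros_like(k_full)
    if noise_sigma > 0:
        noise = (noise_sigma / np.sqrt(2.0)) * (
            rng.standard_normal(k_full.shape) + 1j * rng.standard_normal(k_full.shape)
        )
    k_us = (k_full + noise) * m
    if labels is None:
        labels = np.zeros(truth.i0.shape, dtype=np.int16)
    return SimulatedDataset(
        truth=truth,
        truth_w=W,
        sens=sens,
        mask=mask,
        kspace=k_us,
        kspace_full=k_full,
        labels=labels,
        protocol=protocol,
        consts=consts,
        noise_sigma=float(noise_sigma),
        provenance=dict(provenance or {}, seed=seed),
    )


def simulate_vial_dataset(
    seed: int = 0,
    grid_shape=(64, 64, 2),
    n_coils: int = 4,
    af: float = 4.0,
    calibration_lines: int = 12,
    snr_db: float | None = 30.0,
    protocol: AcquisitionProtocol | None = None,
    consts: FixedPoolConstants | None = None,
) -> SimulatedDataset:
    """The standard synthetic four-vial study: phantom, coils, 1D
    variable-density undersampling, and k-space noise at the given SNR."""
    protocol = protocol or phantom_protocol()
    consts = consts or FixedPoolConstants()
    truth, labels = make_vial_phantom(default_vial_spec(grid_shape, seed=seed))
    sens = simulate_coils(n_coils, grid_shape, seed=seed)
    mask = make_vd_gaussian_mask(
        grid_shape[:2], af, calibration_lines, seed=seed, dim=1, axis=0
    )
    mc = measurement_constants(protocol, consts)
    W = model_images(truth, mc)
    full_mask = SamplingMask(
        np.ones(grid_shape[:2], np.uint8), grid_shape[:2], 1.0, seed=0
    )
    k_full = forward_encode(W, sens, full_mask)
    sigma = sigma_for_snr(k_full, snr_db) if snr_db is not None else 0.0
    return simulate_acquisition(
        truth,
        consts,
        protocol,
        sens,
        mask,
        noise_sigma=sigma,
        seed=seed,
        labels=labels,
        provenance={
            "generator": "simulate_vial_dataset",
            "grid_shape": list(grid_shape),
            "n_coils": n_coils,
            "af": af,
            "calibration_lines": calibration_lines,
            "snr_db": snr_db,
        },
    )
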