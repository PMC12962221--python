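"""Bound-constrained voxel-wise nonlinear fitting of the signal model.

This is the reference pipeline: given (reconstructed) weighted-image
magnitudes per measurement, estimate the four tissue parameters per voxel by
nonlinear least squares, exactly as fully sampled reference maps are
produced.  Fitting operates on magnitudes because absolute image phase is
not modeled by the reconstruction references.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .signal import (
    DEFAULT_BOUNDS,
    AcquisitionProtocol,
    FixedPoolConstants,
    MeasurementConstants,
    QMapVolume,
    TissueParams,
    magnitude_and_partials,
    measurement_constants,
    signal_magnitude_series,
)

__all__ = ["FitResult", "fit_voxelwise", "fit_volume", "VoxelwiseFitter"]


class UnderdeterminedError(ValueError):
    """Fewer measurements than unknowns."""


@dataclass
class FitResult:
    params: TissueParams
    residual_norm: float
    converged: bool
    n_evaluations: int


def _default_init(weighted: np.ndarray) -> np.ndarray:
    return np.array([float(np.max(weighted)) * 2.0, 1.0, 0.1, 2.0])


def fit_voxelwise(
    weighted,
    consts: FixedPoolConstants,
    protocol: AcquisitionProtocol,
    bounds=DEFAULT_BOUNDS,
    init: TissueParams | None = None,
    mc: MeasurementConstants | None = None,
    n_starts: int = 1,
    rng: np.random.Generator | None = None,
) -> FitResult:
    """Fit (i0, t1f, f, kf) to observed magnitudes of one voxel.

    Minimizes the sum of squared residuals between the closed-form signal
    magnitudes and ``weighted`` under box bounds, via trust-region reflective
    least squares with the analytic Jacobian.  ``n_starts > 1`` adds
    randomized restarts and keeps the best minimizer.
    """
    weighted = np.asarray(weighted, dtype=float)
    if weighted.ndim != 1:
        raise ValueError("weighted must be a 1D vector of magnitudes")
    if len(weighted) < 4:
        raise UnderdeterminedError("need at least 4 measurements for 4 unknowns")
    if len(weighted) != protocol.n_measurements:
        raise ValueError("measurement count mismatch with protocol")
    if mc is None:
        mc = measurement_constants(protocol, consts)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    # keep f strictly positive inside the solver; the analytic Jacobian is
    # singular at f = 0 (projected back to the nominal bound afterwards)
    f_floor = max(lo[2], 1e-7)

    def resid(x):
        return signal_magnitude_series(tuple(x), mc) - weighted

    def jac(x):
        _, parts = magnitude_and_partials(tuple(x), mc)
        return np.stack(
            [np.broadcast_to(p, weighted.shape) for p in parts], axis=1
        )

    x0 = init.as_array() if init is not None else _default_init(weighted)
    starts = [x0]
    if n_starts > 1:
        rng = np.random.default_rng(0) if rng is None else rng
        for _ in range(n_starts - 1):
            starts.append(x0 * rng.uniform(0.5, 1.5, size=4))
    best = None
    nfev = 0
    for s in starts:
        s = np.clip(s, np.maximum(lo, [0, 1e-3, f_floor, 0]), np.minimum(hi, np.inf))
        s[2] = max(s[2], f_floor)
        sol = least_squares(
            resid,
            s,
            jac=jac,
            bounds=(np.array([lo[0], lo[1], f_floor, lo[3]]), hi),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
        nfev += sol.nfev
        if best is None or sol.cost < best.cost:
            best = sol
    x = best.x.copy()
    if x[2] <= f_floor * (1 + 1e-6) and lo[2] == 0.0:
        x[2] = 0.0
    params = TissueParams(*x)
    return FitResult(
        params=params,
        residual_norm=float(np.linalg.norm(resid(best.x))),
        converged=bool(best.success),
        n_evaluations=nfev,
    )


def fit_volume(
    weighted,
    mask,
    consts: FixedPoolConstants,
    protocol: AcquisitionProtocol,
    bounds=DEFAULT_BOUNDS,
    n_starts: int = 1,
) -> tuple[QMapVolume, np.ndarray]:
    """Per-voxel fit over a volume.

    ``weighted`` has shape ``(n_meas,) + spatial``; ``mask`` selects voxels
    to fit (others are zero).  Returns the maps and a boolean volume flagging
    voxels whose fit did not converge (failures never abort the volume).
    """
    weighted = np.abs(np.asarray(weighted))
    mask = np.asarray(mask, dtype=bool)
    spatial = weighted.shape[1:]
    if mask.shape != spatial:
        raise ValueError("mask shape mismatch")
    if not mask.any():
        z = np.zeros(spatial)
        return QMapVolume(z.copy(), z.copy(), z.copy(), z.copy()), np.zeros(
            spatial, dtype=bool
        )
    mc = measurement_constants(protocol, consts)
    maps = np.zeros((4,) + spatial)
    failed = np.zeros(spatial, dtype=bool)
    cache: dict[bytes, np.ndarray] = {}
    for idx in np.argwhere(mask):
        tidx = tuple(idx)
        y = weighted[(slice(None),) + tidx]
        key = y.tobytes()
        if key in cache:
            maps[(slice(None),) + tidx] = cache[key]
            continue
        try:
            res = fit_voxelwise(
                y, consts, protocol, bounds=bounds, mc=mc, n_starts=n_starts
            )
            vals = res.params.as_array()
            failed[tidx] = not res.converged
        except Exception:
            vals = np.zeros(4)
            failed[tidx] = True
        cache[key] = vals
        maps[(slice(None),) + tidx] = vals
    return QMapVolume.from_stack(maps), failed


class VoxelwiseFitter:
    """Estimator wrapper around :func:`fit_volume`.

    Parameters mirror the function; after :meth:`fit`, the maps are exposed
    as ``qmaps_`` and non-converged voxels as ``failed_``.
    """

    def __init__(
        self,
        consts: FixedPoolConstants | None = None,
        protocol: AcquisitionProtocol | None = None,
        bounds=DEFAULT_BOUNDS,
        n_starts: int = 1,
    ):
        self.consts = consts
        self.protocol = protocol
        self.bounds = bounds
        self.n_starts = n_starts

    def get_params(self, deep=True):
        return {
            "consts": self.consts,
            "protocol": self.protocol,
            "bounds": self.bounds,
            "n_starts": self.n_starts,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, weighted, mask=None):
        weighted = np.abs(np.asarray(weighted))
        if mask is None:
            mask = np.ones(weighted.shape[1:], dtype=bool)
        consts = self.consts or FixedPoolConstants()
        if self.protocol is None:
            raise ValueError("protocol must be provided")
        self.qmaps_, self.failed_ = fit_volume(
            weighted,
            mask,
            consts,
            self.protocol,
            bounds=self.bounds,
            n_starts=self.n_starts,
        )
        return self

    def transform(self, weighted=None):
        return self.qmaps_
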