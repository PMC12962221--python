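"""Implicit-neural-representation initialization of the quantitative maps.

Stage 1 of the reconstruction represents the complex weighted-image series
``W(x, y, z, t)`` as a coordinate network (3D spatial hash encoding plus a
1D contrast-index encoding, concatenated into a small MLP) and the four
quantitative maps ``Q(x, y, z)`` as a second coordinate network.  Both are
trained against the measured undersampled k-space:

* the image loss ``L1 = ‖d − U F C W‖² + λ·TV(W)`` de-aliases the weighted
  images directly;
* the model loss ``L2 = ‖W − S(Q)‖²`` distills the de-aliased images into
  quantitative maps through the signal model.  By default ``W`` enters L2 as
  a fixed target (stop-gradient), so L2 only shapes the map network.

The trained map network provides the initialization ``Q(0)`` for the
unrolled physics-reinforcement stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .encoding import CoilSensitivities, SamplingMask, adjoint_encode, forward_encode, zero_fill_recon
from .nn import (
    MLP,
    Adam,
    HashEncoding,
    HashEncodingConfig,
    Module,
    Tensor,
    concat,
    custom_op,
    stack,
)
from .signal import (
    MeasurementConstants,
    QMapVolume,
    _magnitude_expr,
    measurement_constants,
)

__all__ = [
    "INRConfig",
    "INRModel",
    "TrainingDivergedError",
    "coordinate_grid",
    "tv_norm",
    "sense_data_term",
    "signal_tensor",
    "loss_recon",
    "loss_model",
    "train_initialization",
]


class TrainingDivergedError(RuntimeError):
    def __init__(self, msg, trace=None):
        super().__init__(msg)
        self.trace = trace


def _tensor_exp(x):
    return x.exp() if hasattr(x, "exp") else np.exp(x)


@dataclass(frozen=True)
class INRConfig:
    """Hyperparameters of the initialization module.

    Physical output ranges: ``t1f = t1f_floor + t1f_scale·|o|`` [s],
    ``kf = kf_scale·|o|`` [1/s], ``f = f_eps + (1−2 f_eps)·σ(o)``; ``i0`` is
    ``|o|·i0_scale`` with the scale taken from the zero-filled images when
    not set explicitly.
    """

    spatial_w: HashEncodingConfig = field(
        default_factory=lambda: HashEncodingConfig(dimensionality=3)
    )
    temporal: HashEncodingConfig = field(
        default_factory=lambda: HashEncodingConfig(
            n_levels=4,
            features_per_level=2,
            table_size_log2=19,
            base_resolution=2,
            growth_factor=2.0,
            dimensionality=1,
        )
    )
    spatial_q: HashEncodingConfig = field(
        default_factory=lambda: HashEncodingConfig(dimensionality=3)
    )
    hidden: tuple = (64, 64, 64)
    i0_scale: float | None = None
    t1f_scale: float = 3.0
    t1f_floor: float = 0.05
    kf_scale: float = 10.0
    f_eps: float = 1e-3
    #: gain on the f-channel pre-sigmoid activation; compensates the
    #: sigmoid's small slope so the poorly conditioned f direction trains at
    #: a useful rate under the shared learning rate
    f_gain: float = 4.0
    lambda_tv: float = 0.01
    lr: float = 1e-3
    n_iters: int = 300
    l2_magnitude: bool = False
    l2_joint_gradient: bool = False


def coordinate_grid(shape) -> np.ndarray:
    """Normalized voxel coordinates in [0,1], shape (nvox, 3)."""
    axes = [
        np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.5]) for n in shape
    ]
    g = np.meshgrid(*axes, indexing="ij")
    return np.stack([a.ravel() for a in g], axis=1)


class INRModel(Module):
    """The three encodings and two MLPs, bound to a fixed voxel grid."""

    def __init__(
        self,
        spatial_shape,
        n_measurements: int,
        config: INRConfig,
        rng: np.random.Generator,
    ):
        self.config = config
        self.spatial_shape = tuple(spatial_shape)
        self.n_measurements = int(n_measurements)
        self.enc_w = HashEncoding(config.spatial_w, rng)
        self.enc_t = HashEncoding(config.temporal, rng)
        self.enc_q = HashEncoding(config.spatial_q, rng)
        n_sp = self.enc_w.n_features
        n_t = self.enc_t.n_features
        self.mlp_w = MLP(n_sp + n_t, config.hidden, 2, rng)
        self.mlp_q = MLP(self.enc_q.n_features, config.hidden, 4, rng)
        coords = coordinate_grid(self.spatial_shape)
        tcoords = np.linspace(0.0, 1.0, self.n_measurements)[:, None]
        self._interp_w = self.enc_w.build_interpolator(coords)
        self._interp_q = self.enc_q.build_interpolator(coords)
        self._interp_t = self.enc_t.build_interpolator(tcoords)
        self._nvox = coords.shape[0]
        self._ones = np.ones((self._nvox, 1), dtype=np.float32)

    # -- parameter groups (for freezing / counting) -----------------------
    def groups(self) -> dict:
        return {
            "spatial_w": self.enc_w,
            "temporal": self.enc_t,
            "spatial_q": self.enc_q,
            "mlp_w": self.mlp_w,
            "mlp_q": self.mlp_q,
        }

    # -- forward ----------------------------------------------------------
    def predict_weighted(self, t_interp=None) -> tuple[Tensor, Tensor]:
        """Complex weighted images as (real, imag), shape (n_meas,)+spatial."""
        sfeat = self.enc_w(self._interp_w)  # (nvox, Fs)
        tfeat = self.enc_t(t_interp if t_interp is not None else self._interp_t)
        rows_re, rows_im = [], []
        n_t = tfeat.shape[0]
        for m in range(n_t):
            trow = tfeat[m : m + 1] * self._ones  # broadcast to (nvox, Ft)
            out = self.mlp_w(concat([sfeat, trow], axis=1))
            rows_re.append(out[:, 0].reshape(*self.spatial_shape))
            rows_im.append(out[:, 1].reshape(*self.spatial_shape))
        return stack(rows_re, axis=0), stack(rows_im, axis=0)

    def predict_qmaps(self) -> dict:
        """Constrained map tensors, each with the spatial shape."""
        cfg = self.config
        feats = self.enc_q(self._interp_q)
        out = self.mlp_q(feats)  # (nvox, 4)
        i0s = 1.0 if cfg.i0_scale is None else cfg.i0_scale
        i0 = out[:, 0].abs() * i0s
        t1f = out[:, 1].abs() * cfg.t1f_scale + cfg.t1f_floor
        f = (out[:, 2] * cfg.f_gain).sigmoid() * (1.0 - 2.0 * cfg.f_eps) + cfg.f_eps
        kf = out[:, 3].abs() * cfg.kf_scale
        sh = self.spatial_shape
        return {
            "i0": i0.reshape(*sh),
            "t1f": t1f.reshape(*sh),
            "f": f.reshape(*sh),
            "kf": kf.reshape(*sh),
        }

    def qmaps_volume(self) -> QMapVolume:
        q = self.predict_qmaps()
        return QMapVolume(*(q[k].data.astype(float) for k in ("i0", "t1f", "f", "kf")))

    def synthesize_contrast(self, t_fractional: float) -> np.ndarray:
        """Decode an image at an arbitrary (possibly untrained) contrast
        coordinate in [0, 1]; returns a complex volume."""
        if not (0.0 <= t_fractional <= 1.0):
            raise ValueError("t_fractional must lie in [0, 1]")
        t_interp = self.enc_t.build_interpolator(np.array([[t_fractional]]))
        wre, wim = self.predict_weighted(t_interp=t_interp)
        return wre.data[0] + 1j * wim.data[0]


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def tv_norm(wre: Tensor, wim: Tensor | None = None) -> Tensor:
    """Anisotropic L1 total variation over the spatial axes (no wrap)."""
    total = None
    for w in (wre, wim):
        if w is None:
            continue
        nd = w.ndim
        for ax in range(1, nd):  # axis 0 is the measurement index
            n = w.shape[ax]
            if n < 2:
                continue
            sl_hi = tuple(
                slice(1, None) if a == ax else slice(None) for a in range(nd)
            )
            sl_lo = tuple(
                slice(None, -1) if a == ax else slice(None) for a in range(nd)
            )
            d = (w[sl_hi] - w[sl_lo]).abs().sum()
            total = d if total is None else total + d
    return total


def sense_data_term(
    wre: Tensor,
    wim: Tensor,
    d: np.ndarray,
    C: CoilSensitivities,
    mask: SamplingMask,
) -> Tensor:
    """``‖d − U F C W‖²`` as a scalar graph node."""
    W = wre.data + 1j * wim.data
    r = forward_encode(W, C, mask) - d

    # scalar kept in the graph's float dtype so backward stays single-precision
    val = np.asarray(np.sum(np.abs(r) ** 2), dtype=wre.data.dtype)
    b = 2.0 * adjoint_encode(r, C, mask)

    def backward(g):
        return (g * b.real, g * b.imag)

    return custom_op(val, (wre, wim), backward)


def _mc_broadcast(mc: MeasurementConstants, n_spatial_dims: int, dtype):
    """Per-measurement constants shaped for broadcasting, in the graph's
    floating dtype (so float32 training graphs stay float32)."""
    bshape = (-1,) + (1,) * n_spatial_dims
    return tuple(
        a.reshape(bshape).astype(dtype)
        for a in (mc.sin_a, mc.cos_a, mc.ew, mc.ew0, mc.phase)
    )


def signal_tensor(qmaps: dict, mc: MeasurementConstants) -> tuple[Tensor, Tensor]:
    """Model images S(Q) as (real, imag) tensors, (n_meas,) + spatial.

    The Bloch-Siegert phase is tissue-independent, so the complex signal is
    the real magnitude graph times a constant per-measurement phasor.
    """
    nd = qmaps["i0"].ndim
    dt = qmaps["i0"].dtype
    sin_a, cos_a, ew, ew0, phase = _mc_broadcast(mc, nd, dt)
    mag = _magnitude_expr(
        qmaps["i0"],
        qmaps["t1f"],
        qmaps["f"],
        qmaps["kf"],
        float(mc.tr),
        sin_a,
        cos_a,
        float(mc.e1r),
        ew,
        ew0,
        _tensor_exp,
    )
    return mag * np.cos(phase).astype(dt), mag * np.sin(phase).astype(dt)


def loss_recon(
    wre: Tensor,
    wim: Tensor,
    d,
    C: CoilSensitivities,
    mask: SamplingMask,
    lambda_tv: float,
) -> tuple[Tensor, float, float]:
    """L1 = data-consistency + λ·TV; returns (node, data part, tv part)."""
    data_term = sense_data_term(wre, wim, d, C, mask)
    if lambda_tv > 0:
        tv = tv_norm(wre, wim)
        return data_term + lambda_tv * tv, float(data_term.item()), float(tv.item())
    return data_term, float(data_term.item()), 0.0


def loss_model(
    wre,
    wim,
    qmaps: dict,
    mc: MeasurementConstants,
    magnitude: bool = False,
) -> Tensor:
    """L2 = ‖W − S(Q)‖² (complex by default, magnitudes optionally).

    ``wre``/``wim`` may be plain arrays (stop-gradient target, the default)
    or tensors (joint-gradient ablation).
    """
    sre, sim = signal_tensor(qmaps, mc)
    if magnitude:
        wr = wre.data if isinstance(wre, Tensor) else np.asarray(wre)
        wi = wim.data if isinstance(wim, Tensor) else np.asarray(wim)
        wmag = np.sqrt(wr * wr + wi * wi)
        smag = (sre * sre + sim * sim + 1e-20).sqrt()
        diff = smag - wmag
        return (diff * diff).sum()
    dre = sre - wre
    dim_ = sim - wim
    return (dre * dre).sum() + (dim_ * dim_).sum()


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def auto_i0_scale(d, C, mask) -> float:
    """Data-driven scale for the i0 output channel (99th percentile of the
    zero-filled magnitude, times a headroom factor)."""
    zf = zero_fill_recon(d, C, mask)
    p99 = float(np.percentile(np.abs(zf), 99))
    return max(6.0 * p99, 1e-6)


def train_initialization(
    scan,
    config: INRConfig | None = None,
    seed: int = 0,
    model: INRModel | None = None,
    callback=None,
):
    """Train the INR on one scan; returns (model, Q0, loss trace dict).

    ``scan`` needs attributes ``kspace`` (complex, [meas, coil, kx, ky, z]),
    ``sens`` (CoilSensitivities), ``mask`` (SamplingMask), ``protocol`` and
    ``consts``.  Passing an existing ``model`` warm-starts training (only
    its trainable parameters are optimized).
    """
    config = config or INRConfig()
    rng = np.random.default_rng(seed)
    d = np.asarray(scan.kspace).astype(np.complex64)
    C, mask = scan.sens, scan.mask
    if config.i0_scale is None:
        config = replace(config, i0_scale=auto_i0_scale(d, C, mask))
    spatial_shape = d.shape[2:]
    if model is None:
        model = INRModel(spatial_shape, d.shape[0], config, rng)
    # a warm-started model keeps its own output scaling (model.config);
    # the passed config still controls the loss and iteration settings
    mc = measurement_constants(scan.protocol, scan.consts)
    opt = Adam(model.trainable_parameters(), lr=config.lr)
    trace = {"total": [], "l1_data": [], "l1_tv": [], "l2": []}
    for it in range(config.n_iters):
        opt.zero_grad()
        wre, wim = model.predict_weighted()
        l1, l1_data, l1_tv = loss_recon(wre, wim, d, C, mask, config.lambda_tv)
        q = model.predict_qmaps()
        if config.l2_joint_gradient:
            l2 = loss_model(wre, wim, q, mc, magnitude=config.l2_magnitude)
        else:
            l2 = loss_model(wre.data, wim.data, q, mc, magnitude=config.l2_magnitude)
        total = l1 + l2
        val = float(total.item())
        if not np.isfinite(val):
            raise TrainingDivergedError(f"loss became non-finite at iter {it}", trace)
        trace["total"].append(val)
        trace["l1_data"].append(l1_data)
        trace["l1_tv"].append(l1_tv)
        trace["l2"].append(float(l2.item()))
        total.backward()
        opt.step()
        if callback is not None:
            callback(it, trace)
    return model, model.qmaps_volume(), trace
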