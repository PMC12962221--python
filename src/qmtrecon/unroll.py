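"""Unrolled proximal gradient descent with a learned proximal operator.

Stage 2 refines the INR initialization ``Q(0)`` by unrolling K phases of
proximal gradient descent on the data-consistency functional
``g(Q) = ½‖d − U F C S(Q)‖²``.  Each phase takes a gradient step per map,

    q̂_i = q_i − α_i ∇g(q_i),

followed by a learned regularization step: a shared 2D U-Net acting on the
four maps as channels (slices as batch elements), applied as a residual
correction and projected back to the physical bounds.  The whole unroll is
differentiable — gradients of the self-supervised loss flow through the
signal model, the acquisition operator, the CNN, and back into the INR.

Maps are normalized to comparable dynamic ranges inside the unroll
(``i0`` by its 99th percentile at initialization, ``t1f`` by 3 s, ``f`` by
1, ``kf`` by 10 s⁻¹), and per-map gradient magnitudes are equalized by
constants measured once at ``Q(0)``, making one step size scale work for
all four channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import (
    CoilSensitivities,
    SamplingMask,
    adjoint_encode,
    forward_encode,
)
from .inr import (
    INRModel,
    TrainingDivergedError,
    loss_model,
    loss_recon,
    sense_data_term,
    signal_tensor,
)
from .nn import Adam, Tensor, UNet, custom_op, stack
from .signal import (
    MeasurementConstants,
    QMapVolume,
    magnitude_and_partials,
    measurement_constants,
)

__all__ = [
    "UnrolledConfig",
    "ProxNetConfig",
    "MapNormalization",
    "ReconResult",
    "build_prox_net",
    "dc_backprojection",
    "gradient_step",
    "prox_step",
    "unroll_forward",
    "loss_unrolled",
    "train_joint",
]

PARAM_BOUNDS = np.array([[0.0, np.inf], [0.05, 10.0], [1e-3, 0.999], [0.0, 100.0]])


@dataclass(frozen=True)
class UnrolledConfig:
    n_phases: int = 4
    step_size_mode: str = "learnable"  # or "fixed"
    step_init: float = 0.1
    shared_cnn: bool = True

    def __post_init__(self):
        if self.n_phases < 0:
            raise ValueError("n_phases must be >= 0")
        if self.step_size_mode not in ("learnable", "fixed"):
            raise ValueError("step_size_mode must be 'learnable' or 'fixed'")


@dataclass(frozen=True)
class ProxNetConfig:
    """U-Net proximal operator: 4 map channels, 32 base features, and
    ``n_stages`` pooling stages (so ``n_stages + 1`` resolution levels)."""

    in_channels: int = 4
    out_channels: int = 4
    base_features: int = 32
    n_stages: int = 3


def build_prox_net(config: ProxNetConfig, rng: np.random.Generator) -> UNet:
    return UNet(
        in_channels=config.in_channels,
        out_channels=config.out_channels,
        base=config.base_features,
        depth=config.n_stages + 1,
        rng=rng,
    )


@dataclass
class MapNormalization:
    """Per-map scales and gradient equalizers used inside the unroll."""

    scales: np.ndarray  # (4,)
    grad_norm: np.ndarray  # (4,)

    @classmethod
    def from_initialization(cls, q0: QMapVolume, scan) -> "MapNormalization":
        """Scales from the initialization; one *global* step normalization.

        The step normalizer is a Lipschitz proxy: the largest (99th
        percentile over voxels) per-map diagonal curvature of g in
        normalized coordinates, ``λ = max_i p99(Σ_m (J_{m,i} s_i)²)``.
        A single λ for all maps keeps gradient steps stable — per-map
        equalization would take huge steps along the poorly conditioned
        (I0, f, kF) valley and overshoot it.
        """
        scales = np.array(
            [max(float(np.percentile(q0.i0, 99)), 1e-6), 3.0, 1.0, 10.0]
        )
        mc = measurement_constants(scan.protocol, scan.consts)
        shape = q0.i0.shape
        bc = (slice(None),) + (None,) * len(shape)
        _, parts = magnitude_and_partials(
            (
                q0.i0[None],
                np.maximum(q0.t1f, 1e-4)[None],
                np.clip(q0.f, 1e-9, 1.0)[None],
                q0.kf[None],
            ),
            MeasurementConstants(
                sin_a=mc.sin_a[bc], cos_a=mc.cos_a[bc], e1r=mc.e1r,
                ew=mc.ew[bc], ew0=mc.ew0[bc], phase=mc.phase[bc], tr=mc.tr,
            ),
        )
        curv = [
            float(
                np.percentile(
                    np.sum(np.broadcast_to(p, (len(mc.sin_a),) + shape) ** 2, axis=0)
                    * scales[i] ** 2,
                    99,
                )
            )
            for i, p in enumerate(parts)
        ]
        lam = max(max(curv), 1e-12)
        return cls(scales=scales, grad_norm=np.full(4, lam))

    @property
    def bounds_normalized(self) -> np.ndarray:
        return PARAM_BOUNDS / self.scales[:, None]


@dataclass
class ReconResult:
    """Output of a (two-stage) reconstruction run."""

    qmaps: QMapVolume
    q0: QMapVolume
    phases: list
    w0: np.ndarray
    traces: dict
    config: dict
    seed: int
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# differentiable building blocks
# ---------------------------------------------------------------------------


def dc_backprojection(
    sre: Tensor,
    sim: Tensor,
    d: np.ndarray,
    C: CoilSensitivities,
    mask: SamplingMask,
) -> Tensor:
    """``b = A^H (A S − d)`` as a graph node, stacked as (2,)+S.shape.

    The linear part ``A^H A`` is Hermitian, which is exactly the backward
    rule applied to the cotangent.
    """
    S = sre.data + 1j * sim.data
    r = forward_encode(S, C, mask) - d
    b = adjoint_encode(r, C, mask)
    out = np.stack([b.real, b.imag], axis=0)

    def backward(g):
        gc = g[0] + 1j * g[1]
        nb = adjoint_encode(forward_encode(gc, C, mask), C, mask)
        return (nb.real, nb.imag)

    return custom_op(out, (sre, sim), backward)


def _qdict_from_stack(qn: Tensor, scales: np.ndarray) -> dict:
    return {
        "i0": qn[0] * float(scales[0]),
        "t1f": qn[1] * float(scales[1]),
        "f": qn[2] * float(scales[2]),
        "kf": qn[3] * float(scales[3]),
    }


def gradient_step(
    qn: Tensor,
    alphas,
    scan_d: np.ndarray,
    C: CoilSensitivities,
    mask: SamplingMask,
    mc: MeasurementConstants,
    norm: MapNormalization,
) -> Tensor:
    """One data-consistency gradient step in normalized map space.

    ``qn``: (4,)+spatial normalized maps; ``alphas``: per-map step sizes
    (tensor (4,) or array).  Returns the intermediate maps q̂ (normalized).
    """
    q = _qdict_from_stack(qn, norm.scales)
    nd = q["i0"].ndim
    dt = q["i0"].dtype
    bshape = (-1,) + (1,) * nd
    sin_a = mc.sin_a.reshape(bshape).astype(dt)
    cos_p = np.cos(mc.phase.reshape(bshape)).astype(dt)
    sin_p = np.sin(mc.phase.reshape(bshape)).astype(dt)
    mag, parts = magnitude_and_partials(
        (q["i0"], q["t1f"], q["f"], q["kf"]),
        MeasurementConstants(
            sin_a=sin_a,
            cos_a=mc.cos_a.reshape(bshape).astype(dt),
            e1r=float(mc.e1r),
            ew=mc.ew.reshape(bshape).astype(dt),
            ew0=mc.ew0.reshape(bshape).astype(dt),
            phase=mc.phase.reshape(bshape).astype(dt),
            tr=float(mc.tr),
        ),
    )
    b = dc_backprojection(mag * cos_p, mag * sin_p, scan_d, C, mask)
    bre, bim = b[0], b[1]
    grads = []
    for i in range(4):
        jre = parts[i] * cos_p
        jim = parts[i] * sin_p
        gi = (jre * bre + jim * bim).sum(axis=0)
        grads.append(gi * float(norm.scales[i] / norm.grad_norm[i]))
    gradn = stack(grads, axis=0)
    if isinstance(alphas, Tensor):
        a = alphas.reshape((4,) + (1,) * nd)
    else:
        a = np.asarray(alphas, dtype=dt).reshape((4,) + (1,) * nd)
    return qn - a * gradn


def _project(qn: Tensor, norm: MapNormalization) -> Tensor:
    nb = norm.bounds_normalized
    # python-float bounds keep the graph in its own precision
    return stack(
        [qn[i].clip(float(nb[i, 0]), float(nb[i, 1])) for i in range(4)], axis=0
    )


def prox_step(qn_hat: Tensor, cnn: UNet, norm: MapNormalization) -> Tensor:
    """Learned proximal step: residual CNN correction + bound projection.

    Slices (last spatial axis) are batch elements; the four maps are the
    channel dimension (channels-last inside the CNN).
    """
    x = qn_hat.transpose(3, 1, 2, 0)  # (nz, nx, ny, 4)
    upd = cnn(x.astype(np.float32)).astype(qn_hat.dtype)
    y = (x + upd).transpose(3, 1, 2, 0)
    return _project(y, norm)


def unroll_forward(
    qn0: Tensor,
    scan,
    cnn: UNet,
    alphas_raw,
    config: UnrolledConfig,
    norm: MapNormalization,
    mc: MeasurementConstants | None = None,
) -> list:
    """Run K phases; returns the list of normalized phase outputs (tensors)."""
    if mc is None:
        mc = measurement_constants(scan.protocol, scan.consts)
    d = np.asarray(scan.kspace).astype(np.complex64)
    qn = qn0
    phases = []
    for k in range(config.n_phases):
        if config.step_size_mode == "learnable":
            a = alphas_raw[k].softplus()
        else:
            a = np.full(4, float(config.step_init), dtype=np.float32)
        q_hat = gradient_step(qn, a, d, scan.sens, scan.mask, mc, norm)
        qn = prox_step(q_hat, cnn, norm)
        phases.append(qn)
    return phases


def loss_unrolled(phases, scan, norm: MapNormalization, mc=None) -> Tensor:
    """L3 = Σ_k ‖d − U F C S(Q(k))‖²."""
    if mc is None:
        mc = measurement_constants(scan.protocol, scan.consts)
    d = np.asarray(scan.kspace).astype(np.complex64)
    nd = None
    total = None
    for qn in phases:
        q = _qdict_from_stack(qn, norm.scales)
        if nd is None:
            nd = q["i0"].ndim
        sre, sim = signal_tensor(q, mc)
        term = sense_data_term(sre, sim, d, scan.sens, scan.mask)
        total = term if total is None else total + term
    if total is None:
        total = Tensor(np.array(0.0))
    return total


def _init_step_raw(config: UnrolledConfig) -> Tensor:
    from .nn.layers import _PTensor

    raw0 = float(np.log(np.expm1(max(config.step_init, 1e-6))))
    t = _PTensor(np.full((config.n_phases, 4), raw0, dtype=np.float32), requires_grad=True)
    t._is_param = True
    return t


def train_joint(
    scan,
    model: INRModel,
    unroll_config: UnrolledConfig | None = None,
    prox_config: ProxNetConfig | None = None,
    n_iters: int = 300,
    lr: float = 1e-3,
    seed: int = 0,
    cnn: UNet | None = None,
    alphas_raw: Tensor | None = None,
    norm: MapNormalization | None = None,
    callback=None,
):
    """Jointly optimize INR, CNN and step sizes on L1 + L2 + L3.

    Returns ``(phases, cnn, alphas_raw, trace)`` where ``phases`` are the
    final normalized phase outputs (numpy copies are in the trace's last
    entry via :func:`reconstruct`-level code).
    """
    unroll_config = unroll_config or UnrolledConfig()
    prox_config = prox_config or ProxNetConfig()
    rng = np.random.default_rng(seed)
    if cnn is None:
        cnn = build_prox_net(prox_config, rng)
    if alphas_raw is None and unroll_config.step_size_mode == "learnable":
        alphas_raw = _init_step_raw(unroll_config)
    d = np.asarray(scan.kspace).astype(np.complex64)
    mc = measurement_constants(scan.protocol, scan.consts)
    q0 = model.qmaps_volume()
    if norm is None:
        norm = MapNormalization.from_initialization(q0, scan)
    params = list(model.trainable_parameters()) + list(cnn.trainable_parameters())
    if alphas_raw is not None and alphas_raw.requires_grad:
        params.append(alphas_raw)
    opt = Adam(params, lr=lr)
    trace = {"total": [], "l1": [], "l2": [], "l3": []}
    cfg = model.config
    phases = []
    for it in range(n_iters):
        opt.zero_grad()
        wre, wim = model.predict_weighted()
        l1, _, _ = loss_recon(wre, wim, d, scan.sens, scan.mask, cfg.lambda_tv)
        qdict = model.predict_qmaps()
        if cfg.l2_joint_gradient:
            l2 = loss_model(wre, wim, qdict, mc, magnitude=cfg.l2_magnitude)
        else:
            l2 = loss_model(wre.data, wim.data, qdict, mc, magnitude=cfg.l2_magnitude)
        qn0 = stack(
            [qdict[k] / norm.scales[i] for i, k in enumerate(("i0", "t1f", "f", "kf"))],
            axis=0,
        )
        qn0 = _project(qn0, norm)
        phases = unroll_forward(qn0, scan, cnn, alphas_raw, unroll_config, norm, mc)
        l3 = loss_unrolled(phases, scan, norm, mc)
        total = l1 + l2 + l3
        val = float(total.item())
        if not np.isfinite(val):
            raise TrainingDivergedError(f"joint loss non-finite at iter {it}", trace)
        trace["total"].append(val)
        trace["l1"].append(float(l1.item()))
        trace["l2"].append(float(l2.item()))
        trace["l3"].append(float(l3.item()))
        total.backward()
        opt.step()
        if callback is not None:
            callback(it, trace)
    return phases, cnn, alphas_raw, norm, trace
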