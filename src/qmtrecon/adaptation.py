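"""Rapid model adaptation across scans.

A scan-specific reconstruction retrains everything per scan.  When a scan
with the same protocol has already been reconstructed, most of what was
learned transfers: the temporal (contrast) encoding and both MLPs vary
little between subjects, and the convolutional proximal operator's features
are largely reusable.  Adaptation therefore

* transfers all learned weights as the starting point,
* freezes the temporal encoding and the MLPs (only the spatial hash tables
  retrain),
* replaces every convolution's full-weight update by a low-rank (LoRA)
  update ``W = W0 + β·A·B`` with frozen ``W0``, ``A`` (m×r) randomly
  initialized and ``B`` (r×l) zero — identity at initialization,
* and runs both stages for a fraction of the original iterations.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator

from .nn import Conv2d, LoRAConv2d, Module, UNet
from .recon import ReinforcedReconstructor

__all__ = [
    "LoRAConfig",
    "AdaptationPolicy",
    "freeze_shared_components",
    "lora_wrap",
    "count_trainable",
    "AdaptedReconstructor",
    "adapt_reconstruct",
]


@dataclass(frozen=True)
class LoRAConfig:
    rank: int = 8
    beta: float = 1.0
    target_layers: str = "all"  # every convolution, including first/last


@dataclass(frozen=True)
class AdaptationPolicy:
    freeze_temporal: bool = True
    freeze_mlp_w: bool = True
    freeze_mlp_q: bool = True
    lora: LoRAConfig = field(default_factory=LoRAConfig)
    iter_fraction: float = 0.2

    def __post_init__(self):
        if self.freeze_temporal and self.freeze_mlp_w and self.freeze_mlp_q:
            pass  # spatial tables always stay trainable


def freeze_shared_components(model, policy: AdaptationPolicy):
    """Mark the transferred INR groups non-trainable (in place)."""
    groups = model.groups()
    if policy.freeze_temporal:
        groups["temporal"].freeze()
    if policy.freeze_mlp_w:
        groups["mlp_w"].freeze()
    if policy.freeze_mlp_q:
        groups["mlp_q"].freeze()
    if not any(p.requires_grad for p in model.parameters()):
        raise ValueError("adaptation policy froze every parameter")
    return model


def lora_wrap(cnn: UNet, config: LoRAConfig, rng: np.random.Generator) -> UNet:
    """Replace each convolution by its LoRA-wrapped version (in place).

    The base kernels are frozen; only the low-rank factors train.  Output
    is bit-identical to the base network until the factors move.  Layers
    whose channel geometry cannot accommodate the requested rank (e.g. the
    4-channel output convolution) get the largest admissible rank
    ``min(m, l) - 1`` instead.
    """

    def make(conv: Conv2d) -> LoRAConv2d:
        cout, cin, kh, kw = conv.weight.shape
        r = min(config.rank, min(cout, cin * kh * kw) - 1)
        return LoRAConv2d(conv, max(1, r), config.beta, rng)

    def wrap(module: Module):
        for name, value in list(vars(module).items()):
            if isinstance(value, Conv2d):
                setattr(module, name, make(value))
            elif isinstance(value, Module):
                wrap(value)
            elif isinstance(value, list):
                for i, item in enumerate(value):
                    if isinstance(item, Conv2d):
                        value[i] = make(item)
                    elif isinstance(item, Module):
                        wrap(item)

    wrap(cnn)
    return cnn


def merge_lora(cnn: UNet) -> UNet:
    """Export a flattened network with LoRA updates folded into kernels."""
    merged = copy.deepcopy(cnn)

    def fold(module: Module):
        for name, value in list(vars(module).items()):
            if isinstance(value, LoRAConv2d):
                rng = np.random.default_rng(0)
                cout, cin, kh, kw = value._kshape
                conv = Conv2d(cin, cout, rng, kernel=kh, bias=value.bias is not None)
                conv.weight.data = value.merged_weight()
                if value.bias is not None:
                    conv.bias.data = value.bias.data.copy()
                setattr(module, name, conv)
            elif isinstance(value, Module):
                fold(value)
            elif isinstance(value, list):
                for i, item in enumerate(value):
                    if isinstance(item, LoRAConv2d):
                        rng = np.random.default_rng(0)
                        cout, cin, kh, kw = item._kshape
                        conv = Conv2d(cin, cout, rng, kernel=kh, bias=item.bias is not None)
                        conv.weight.data = item.merged_weight()
                        if item.bias is not None:
                            conv.bias.data = item.bias.data.copy()
                        value[i] = conv
                    elif isinstance(item, Module):
                        fold(item)

    fold(merged)
    return merged


def count_trainable(bundle: dict) -> dict:
    """Per-group (trainable, total) parameter counts plus a grand total."""
    out = {}
    tr_sum = tot_sum = 0
    for name, module in bundle.items():
        tr, tot = module.n_trainable(), module.n_parameters()
        out[name] = {"trainable": tr, "total": tot}
        tr_sum += tr
        tot_sum += tot
    out["total"] = {"trainable": tr_sum, "total": tot_sum}
    return out


class AdaptedReconstructor(BaseEstimator):
    """Two-stage reconstruction warm-started from a previously fitted
    :class:`~qmtrecon.recon.ReinforcedReconstructor`.

    ``prior`` must be a fitted reconstructor whose scan shared the protocol
    and grid shape; its weights are transferred, shared components frozen,
    and the CNN LoRA-wrapped.  Iteration counts default to
    ``iter_fraction`` of the prior's.
    """

    def __init__(
        self,
        prior: ReinforcedReconstructor = None,
        policy: AdaptationPolicy = None,
        n_iters_init: int | None = None,
        n_iters_joint: int | None = None,
        seed: int = 1,
    ):
        self.prior = prior
        self.policy = policy
        self.n_iters_init = n_iters_init
        self.n_iters_joint = n_iters_joint
        self.seed = seed

    def fit(self, X, y=None):
        scan = X
        if self.prior is None or not hasattr(self.prior, "model_"):
            raise ValueError("prior must be a fitted ReinforcedReconstructor")
        policy = self.policy or AdaptationPolicy()
        prior = self.prior
        rng = np.random.default_rng(self.seed)

        # transfer: same architecture bound to the new scan's grid
        model = copy.deepcopy(prior.model_)
        if model.spatial_shape != np.asarray(scan.kspace).shape[2:]:
            raise ValueError("adaptation requires a matching grid shape")
        freeze_shared_components(model, policy)
        cnn = lora_wrap(copy.deepcopy(prior.cnn_), policy.lora, rng)
        alphas = None
        if prior.alphas_ is not None:
            from .nn.layers import _PTensor

            alphas = _PTensor(prior.alphas_.data.copy(), requires_grad=True)
            alphas._is_param = True

        frac = policy.iter_fraction
        cfg = prior.result_.config
        n1 = self.n_iters_init or max(1, int(round(cfg["n_iters_init"] * frac)))
        n2 = self.n_iters_joint or max(1, int(round(cfg["n_iters_joint"] * frac)))
        inner = ReinforcedReconstructor(
            preset=cfg.get("preset", "desk"),
            n_iters_init=n1,
            n_iters_joint=n2,
            n_phases=cfg["n_phases"],
            lambda_tv=cfg["lambda_tv"],
            lr=cfg["lr"],
            seed=self.seed,
            inr_config=model.config,
        )
        inner.fit(scan, model=model, cnn=cnn, alphas_raw=alphas)
        self.model_ = inner.model_
        self.cnn_ = inner.cnn_
        self.alphas_ = inner.alphas_
        self.qmaps_ = inner.qmaps_
        self.q0_ = inner.q0_
        self.phases_ = inner.phases_
        self.result_ = inner.result_
        self.result_.provenance.update(
            {
                "adapted_from_seed": prior.seed,
                "frozen": [
                    g
                    for g, flag in (
                        ("temporal", policy.freeze_temporal),
                        ("mlp_w", policy.freeze_mlp_w),
                        ("mlp_q", policy.freeze_mlp_q),
                    )
                    if flag
                ],
                "lora_rank": policy.lora.rank,
            }
        )
        self.counts_ = count_trainable(
            dict(self.model_.groups(), cnn=self.cnn_)
        )
        return self

    def transform(self, X=None):
        return self.qmaps_


def adapt_reconstruct(scan, prior, policy: AdaptationPolicy | None = None, seed: int = 1):
    """Functional wrapper over :class:`AdaptedReconstructor`."""
    est = AdaptedReconstructor(prior=prior, policy=policy, seed=seed).fit(scan)
    return est.result_
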