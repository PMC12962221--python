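"""Scan-specific reconstruction estimators.

The two-stage method is exposed sklearn-style: construct an estimator with
hyperparameters, call ``fit(scan)`` on a :class:`~qmtrecon.io.ScanData`
(or any object with ``kspace``/``sens``/``mask``/``protocol``/``consts``),
and read the fitted attributes (``qmaps_``, ``q0_``, ``result_``).  Module
functions (:func:`reconstruct`) stay thin wrappers over the estimators.

Presets: ``"paper"`` runs 1500 + 1500 iterations on full-size grids;
``"desk"`` runs 300 + 300 on small synthetic grids and is the default for
every example and test in this package.
"""

from __future__ import annotations

from dataclasses import replace

from sklearn.base import BaseEstimator

from .inr import INRConfig, train_initialization
from .nn import stack
from .signal import QMapVolume, measurement_constants
from .unroll import (
    ProxNetConfig,
    ReconResult,
    UnrolledConfig,
    _project,
    train_joint,
    unroll_forward,
)

__all__ = ["PRESETS", "INRInitializer", "ReinforcedReconstructor", "reconstruct"]

PRESETS = {
    "paper": {"n_iters_init": 1500, "n_iters_joint": 1500, "table_size_log2": 19},
    "desk": {"n_iters_init": 300, "n_iters_joint": 300, "table_size_log2": 16},
}


def _default_inr_config(preset: str) -> INRConfig:
    """Preset-sized INR: full-size hash tables for "paper", smaller tables
    for the desk-scale grids (a 2^16 table is already collision-free over
    far more corners than a 64-voxel-per-axis grid touches)."""
    from .nn import HashEncodingConfig

    log2 = PRESETS[preset]["table_size_log2"]
    spatial = HashEncodingConfig(table_size_log2=log2, dimensionality=3)
    return INRConfig(spatial_w=spatial, spatial_q=spatial)


def _evaluate_unroll(model, scan, cnn, alphas_raw, unroll_config, norm, mc):
    """Forward pass with current weights; returns (q0, per-phase volumes)."""
    qdict = model.predict_qmaps()
    q0 = QMapVolume(*(qdict[k].data.astype(float) for k in ("i0", "t1f", "f", "kf")))
    qn0 = stack(
        [qdict[k] / norm.scales[i] for i, k in enumerate(("i0", "t1f", "f", "kf"))],
        axis=0,
    )
    qn0 = _project(qn0, norm)
    phases = unroll_forward(qn0, scan, cnn, alphas_raw, unroll_config, norm, mc)
    vols = [
        QMapVolume.from_stack(p.data * norm.scales[:, None, None, None])
        for p in phases
    ]
    return q0, vols


class INRInitializer(BaseEstimator):
    """Stage 1 only: fit the coordinate networks, expose Q(0).

    Fitted attributes: ``model_`` (the INR), ``qmaps_`` (Q(0)),
    ``w0_`` (complex de-aliased weighted images), ``trace_`` (losses).
    """

    def __init__(
        self,
        preset: str = "desk",
        n_iters: int | None = None,
        lambda_tv: float = 0.01,
        lr: float = 1e-3,
        seed: int = 0,
        inr_config: INRConfig | None = None,
    ):
        self.preset = preset
        self.n_iters = n_iters
        self.lambda_tv = lambda_tv
        self.lr = lr
        self.seed = seed
        self.inr_config = inr_config

    def _config(self) -> INRConfig:
        cfg = self.inr_config or _default_inr_config(self.preset)
        n = self.n_iters or PRESETS[self.preset]["n_iters_init"]
        return replace(cfg, n_iters=n, lambda_tv=self.lambda_tv, lr=self.lr)

    def fit(self, X, y=None):
        scan = X
        self.model_, self.qmaps_, self.trace_ = train_initialization(
            scan, self._config(), seed=self.seed
        )
        wre, wim = self.model_.predict_weighted()
        self.w0_ = wre.data + 1j * wim.data
        return self

    def transform(self, X=None):
        return self.qmaps_


class ReinforcedReconstructor(BaseEstimator):
    """Full two-stage reconstruction: INR initialization then K unrolled
    proximal-gradient phases with a learned proximal operator.

    Fitted attributes: ``qmaps_`` (final maps Q(K)), ``q0_`` (Q(0) after
    joint training), ``phases_`` (per-phase maps), ``result_``
    (:class:`~qmtrecon.unroll.ReconResult` with losses and provenance),
    plus the trained components ``model_``, ``cnn_``, ``alphas_``.
    """

    def __init__(
        self,
        preset: str = "desk",
        n_iters_init: int | None = None,
        n_iters_joint: int | None = None,
        n_phases: int = 4,
        lambda_tv: float = 0.01,
        lr: float = 1e-3,
        seed: int = 0,
        inr_config: INRConfig | None = None,
        unroll_config: UnrolledConfig | None = None,
        prox_config: ProxNetConfig | None = None,
    ):
        self.preset = preset
        self.n_iters_init = n_iters_init
        self.n_iters_joint = n_iters_joint
        self.n_phases = n_phases
        self.lambda_tv = lambda_tv
        self.lr = lr
        self.seed = seed
        self.inr_config = inr_config
        self.unroll_config = unroll_config
        self.prox_config = prox_config

    # -- internals --------------------------------------------------------
    def _configs(self):
        inr = self.inr_config or _default_inr_config(self.preset)
        n1 = self.n_iters_init or PRESETS[self.preset]["n_iters_init"]
        n2 = (
            self.n_iters_joint
            if self.n_iters_joint is not None
            else PRESETS[self.preset]["n_iters_joint"]
        )
        inr = replace(inr, n_iters=n1, lambda_tv=self.lambda_tv, lr=self.lr)
        unroll = self.unroll_config or UnrolledConfig()
        unroll = replace(unroll, n_phases=self.n_phases)
        prox = self.prox_config or ProxNetConfig()
        return inr, unroll, prox, n2

    def fit(self, X, y=None, model=None, cnn=None, alphas_raw=None):
        """Run both stages on scan ``X``.

        ``model``/``cnn``/``alphas_raw`` allow warm starts (used by the
        adaptation machinery); fresh components are built when omitted.
        """
        scan = X
        inr_cfg, unroll_cfg, prox_cfg, n_joint = self._configs()
        self.model_, q0_initial, trace1 = train_initialization(
            scan, inr_cfg, seed=self.seed, model=model
        )
        phases, self.cnn_, self.alphas_, self.norm_, trace2 = train_joint(
            scan,
            self.model_,
            unroll_config=unroll_cfg,
            prox_config=prox_cfg,
            n_iters=n_joint,
            lr=self.lr,
            seed=self.seed,
            cnn=cnn,
            alphas_raw=alphas_raw,
        )
        mc = measurement_constants(scan.protocol, scan.consts)
        if unroll_cfg.n_phases > 0 and n_joint >= 0:
            self.q0_, self.phases_ = _evaluate_unroll(
                self.model_, scan, self.cnn_, self.alphas_, unroll_cfg, self.norm_, mc
            )
            self.qmaps_ = self.phases_[-1]
        else:
            self.q0_ = self.model_.qmaps_volume()
            self.phases_ = []
            self.qmaps_ = self.q0_
        wre, wim = self.model_.predict_weighted()
        self.result_ = ReconResult(
            qmaps=self.qmaps_,
            q0=self.q0_,
            phases=self.phases_,
            w0=wre.data + 1j * wim.data,
            traces={"initialization": trace1, "joint": trace2},
            config={
                "preset": self.preset,
                "n_phases": unroll_cfg.n_phases,
                "n_iters_init": inr_cfg.n_iters,
                "n_iters_joint": n_joint,
                "lambda_tv": self.lambda_tv,
                "lr": self.lr,
                "step_size_mode": unroll_cfg.step_size_mode,
            },
            seed=self.seed,
            provenance={"warm_start": model is not None},
        )
        return self

    def transform(self, X=None):
        return self.qmaps_

    def save_checkpoint(self, path):
        """Archive all trained parameter groups (INR encodings and MLPs,
        proximal CNN, step sizes) plus the run configuration."""
        from .io import save_checkpoint

        extra = (
            {"step_sizes_raw": self.alphas_.data} if self.alphas_ is not None else None
        )
        return save_checkpoint(
            path,
            dict(self.model_.groups(), cnn=self.cnn_),
            config=self.result_.config,
            extra=extra,
        )


def reconstruct(scan, **kwargs) -> ReconResult:
    """Two-stage reconstruction of one scan; see
    :class:`ReinforcedReconstructor` for keyword arguments."""
    return ReinforcedReconstructor(**kwargs).fit(scan).result_
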