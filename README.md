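# qmtrecon

Self-supervised, scan-specific reconstruction of accelerated
multiparametric quantitative magnetization-transfer (qMT) MRI.

## The problem

Quantitative MT imaging estimates physical tissue parameters — the free
water pool's spin–lattice time T1F, the macromolecular proton fraction f,
and the exchange rate kF — from a series of spoiled gradient-echo
acquisitions in which an off-resonance saturation pulse induces
magnetization transfer (and a Bloch-Siegert phase) every TR. Mapping a
whole volume needs many weighted acquisitions, so k-space is undersampled
(AF 4–5) and the maps must be reconstructed from incomplete data:

    d = U F C S(Q),   Q = (I0, T1F, f, kF) per voxel,

where `S` is the two-pool steady-state signal model, `C` the coil maps,
`F` the Fourier transform and `U` the sampling mask. `qmtrecon`
reconstructs `Q` from a *single* scan with no external training data:

1. **Initialization** — the weighted images `W(x,y,z,t)` and the maps
   `Q(x,y,z)` are represented as coordinate networks (multiresolution
   hash encodings + small MLPs) trained with
   `L1 = ‖d − UFC W‖² + λ·TV(W)` and `L2 = ‖W − S(Q)‖²`;
2. **Physics reinforcement** — K = 4 unrolled proximal-gradient phases
   on `g(Q) = ½‖d − UFC S(Q)‖²`, with a shared U-Net as learned proximal
   operator, trained jointly with the networks above by
   `L1 + L2 + L3`, `L3 = Σ_k ‖d − UFC S(Q^{(k)})‖²`.

The package also provides the analytic signal model with a numerical
steady-state oracle, bound-constrained voxel-wise fitting (the reference
pipeline), synthetic phantoms and simulated acquisitions, LoRA-based
rapid adaptation of a trained model to a new scan, and the evaluation
suite (nRMSE, SSIM, ROI regression, Bland-Altman). Everything runs on
plain numpy/scipy, including a small reverse-mode autodiff engine for the
learned components. See `docs/methods.md` for the model and all
numerical choices.

## Worked example

```python
import numpy as np
from qmtrecon import (ReinforcedReconstructor, nrmse, roi_means,
                      roi_regression, simulate_vial_dataset)

# four-vial phantom (f = 0.04/0.08/0.16/0.25), 10-measurement protocol,
# 4 coils, 1D variable-density undersampling at AF 4, 30 dB k-space SNR
ds = simulate_vial_dataset(seed=0, grid_shape=(64, 64, 2), n_coils=4,
                           af=4.0, calibration_lines=12, snr_db=30.0)

rec = ReinforcedReconstructor(preset="desk", seed=0).fit(ds.scan)

est = roi_means(rec.qmaps_.f, ds.labels)
ref = roi_means(ds.truth.f, ds.labels)
ids = sorted(est)
print("vial-mean f:", [round(est[i], 3) for i in ids])
print("truth      :", [ref[i] for i in ids])
print("regression :", roi_regression([est[i] for i in ids],
                                     [ref[i] for i in ids]))
```

Output of this run (desk preset, ~10 min on one CPU core):

```
vial-mean f: [0.038, 0.081, 0.159, 0.257]
truth      : [0.04, 0.08, 0.16, 0.25]
regression : {'slope': 1.032, 'intercept': -0.003, 'r2': 0.9995}
```

The reconstructed macromolecular-fraction vial means track the generating
truth almost perfectly (T1F does too, R² = 0.99994); the exchange-rate
map kF is the hardest of the four — its vial means come out at
R² ≈ 0.98, which already beats a classical fully sampled voxel-wise fit
at this noise level (see `docs/methods.md` on identifiability).
`rec.q0_` holds the initialization-stage maps and `rec.result_.traces`
the loss curves.

A command-line interface covers the same workflow
(`qmtrecon simulate | mask | recon | adapt | fit | eval`); each command
writes a YAML manifest with the configuration and seeds of the run.

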