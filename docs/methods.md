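# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `qmtrecon`. It is the package's own account of what it
computes; every number quoted here is produced by the test suite or the
acceptance script, not asserted from elsewhere.

## The signal model

Tissue is a binary spin bath: a free water pool F holding a fraction
`1 − f` of the equilibrium magnetization and a restricted macromolecular
pool R holding `f`, exchanging longitudinal magnetization with
pseudo-first-order rates `kF = k·f` (F→R) and `kR = k·(1−f)` (R→F), where
`k` is the fundamental rate constant (equilibrium magnetization normalized
to 1, so `k = kF/f`). The acquisition is a spoiled gradient echo whose
every TR contains, in order: an excitation of flip angle α and width
τexc, an off-resonance saturation pulse (duration τBTS, peak amplitude
B1max, offset Δoff), acquisition, and recovery.

The per-TR cycle applied to the longitudinal magnetizations `(MzF, MzR)`
is:

1. excitation: `MzF ← MzF·cos α`, with on-resonance saturation of the
   restricted pool `MzR ← MzR·EW0`, `EW0 = exp(−⟨W(0)⟩ τexc)`;
2. off-resonance saturation: `MzR ← MzR·EW`, `EW = exp(−⟨W(Δ)⟩ τBTS)`;
   the transverse signal additionally acquires the Bloch-Siegert phase
   `φ = B1max²·K_BS`, which is tissue-independent;
3. decoupled spin-lattice relaxation of both pools over the full TR
   (factors `E1F = e^{−TR/T1F}`, `E1R = e^{−R1R·TR}`);
4. exchange over the full TR (propagator `Ek = e^{−k·TR}`, relaxing the
   pool imbalance toward the equilibrium split `(1−f, f)`).

The closed-form steady state of this cycle is

    S = I0 (1−f) sin α · (1 − E1F·A − E1R·B) / (1 − E1F·A·cos α − E1R·EW0·EW·C) · e^{iφ}

with

    A = 1 − f + f·Ek − Ek·E1R·EW·EW0
    B = f − f·Ek + Ek·EW·EW0
    C = f + Ek − f·Ek

This expression was derived symbolically (the fixed point of the cycle
above) and reduces exactly to the single-pool SPGR steady state at
`f = 0`. The companion numerical oracle `simulate_steady_state` iterates
the same cycle to its fixed point and agrees with the closed form to
machine precision; a `mode="coupled"` variant replaces steps 3–4 by the
exact matrix exponential of the joint relaxation–exchange generator and
differs from the split-operator closed form by ~0.5% at white-matter-like
parameters — that is the operator-splitting approximation inherent in the
analytic model, quantified but not used as the reference.

The mean saturation rate is `⟨W(Δ)⟩ = π·(1/τ)∫ω1²(t)dt·G_SL(Δ)` with the
super-Lorentzian lineshape

    G_SL(Δ) = ∫₀¹ √(2/π) · T2R/|3u²−1| · exp(−2(2πΔ·T2R/(3u²−1))²) du

evaluated by adaptive Gauss–Kronrod quadrature with an explicit break at
the integrable singularity `u = 1/√3` (relative tolerance 1e−10). The
lineshape diverges on resonance; the on-resonance value needed for the
excitation-saturation factor `EW0` is linearly extrapolated from the
values at 1 and 2 kHz (`G(0) ≈ 2G(1 kHz) − G(2 kHz)`), with a config
switch (`onres_policy="zero"`) that disables excitation saturation
entirely. The excitation is modeled as a hard pulse (`ω1 = α/τexc`).

Fixed restricted-pool constants default to `R1R = 1 s⁻¹`, `T2R = 10 μs` —
conventional white-matter qMT values; they are inputs, not estimates, and
matching any particular scanner study requires that study's constants.
The Fermi saturation pulse's flat-top half-width (0.4 τ) and transition
width (τ/50) are likewise configurable; exact shape parameters of
scanner implementations vary and are not standardized.

### Parameters and units

| parameter | meaning | unit | default bounds |
|---|---|---|---|
| I0 (=ρM0) | scaled equilibrium signal | a.u. | ≥ 0 |
| T1F | free-pool spin–lattice time | s | (0.05, 10] during recon, (0, 10] in fitting |
| f | macromolecular proton fraction | – | [0, 1] (recon keeps f in [1e−3, 0.999]) |
| kF | forward exchange rate | s⁻¹ | [0, 100] |

### Identifiability

The relative-scaled Jacobian of the 10-measurement phantom protocol has a
condition number of roughly 150–500 inside the vials (and worse in the
low-f bath): the data determine all four parameters, but there is a
shallow valley coupling (I0, f, kF). Second-order solvers (the
trust-region voxel-wise fitter) traverse it easily — noiseless recovery
is exact to <1% — while plain first-order descent moves along it slowly.
This is the central optimization difficulty of the self-supervised
reconstruction and the reason the learned unrolled stage matters.

The exchange rate kF is additionally noise-limited: on the standard
synthetic study (30 dB k-space SNR), a fully sampled voxel-wise ML fit —
the classical reference pipeline — returns vial-mean kF estimates biased
upward by factors of several (per-voxel kF is nearly flat in the
likelihood and rectifies noise), with a vial-mean regression R² of only
~0.59 against truth. The spatially regularized reconstruction does far
better (R² ≈ 0.96–0.98 against truth), but near-perfect kF linearity
against ground truth is not reachable at this noise level; phantom
agreement figures quoted for such methods typically compare two pipelines
that share the same fitting bias rather than the generating truth.

## Acquisition operator

Per measurement, `d = U F C S(Q)`: voxelwise signal model, coil
weighting, orthonormal centered 2D FFT over the in-plane axes (slices are
fully sampled along the readout-resolved axis and processed as a batch),
and masking. The adjoint is exact (dot-product test at 1e−10);
variable-density Gaussian masks have per-axis density std = extent/6,
always include the calibration block, and hit the budget `round(N/AF)`
exactly so nominal undersampling fractions are exact (25.0% at AF 4 with
the 176×48 grid, 20.0% at AF 5).

## Stage 1 — implicit-representation initialization

The weighted series `W(x,y,z,t)` is a coordinate network: a 3D
multiresolution hash encoding (defaults: 16 levels, 2 features/level,
growth 1.5 from base resolution 8; table 2^19 in the full-size preset,
2^16 in the desk preset where grids touch far fewer corners) concatenated
with a 1D contrast-index encoding (4 levels, direct indexing), feeding an
MLP with three 64-neuron ReLU hidden layers and a 2-channel (real,
imaginary) output. The maps `Q(x,y,z)` are a second 3D encoding + MLP
with four channels mapped to physical ranges: absolute value times a
scale for I0 (scale auto-set from the zero-filled images), T1F
(`0.05 + 3·|o|` s) and kF (`10·|o|` s⁻¹), and a sigmoid for f (restricted
to `[1e−3, 0.999]` so the exchange factor `e^{−kF·TR/f}` and its
derivatives stay finite in single precision). The f channel's
pre-sigmoid activation carries a gain of 4 (`INRConfig.f_gain`): with the
shared learning rate, a plain sigmoid moves the poorly conditioned f
direction an order of magnitude too slowly to converge within the desk
schedule, and the gain restores a useful effective rate (verified by an
isolated map-fitting experiment; without it f stalls near the sigmoid
midpoint).

Losses: `L1 = ‖d − U F C W‖² + λ·TV(W)` (anisotropic L1 total variation
on real and imaginary parts, λ = 0.01) and `L2 = ‖W − S(Q)‖²`, complex by
default with a magnitude option for data with unmodeled phase. `W` enters
L2 as a fixed target (stop-gradient) so L2 shapes only the map network; a
joint-gradient switch exists for ablation. Training uses Adam at the
method's fixed learning rate 1e−3. Because every query lies on a fixed
voxel/contrast grid, hash interpolation is precompiled into one sparse
matrix per level and a forward pass is a sparse-dense product.

## Stage 2 — unrolled physics reinforcement

K = 4 phases of proximal gradient descent on `g(Q) = ½‖d − UFC S(Q)‖²`
are unrolled; each phase takes a per-map gradient step with learnable
positive step size (softplus-parameterized) and applies a shared 2D
U-Net to the four maps (channels) over slices (batch), as a residual
correction followed by projection onto the physical bounds. Inside the
unroll, maps are normalized to comparable ranges (I0 by its 99th
percentile at initialization, T1F by 3 s, f by 1, kF by 10 s⁻¹), and
gradients are divided by a single Lipschitz-style constant
`λ = max_i p99(Σ_m (J_{m,i} s_i)²)` measured once at Q(0), so a step
size of order 1 is a classical stable gradient step. One global λ is
deliberate: equalizing gradient magnitudes per map (a Jacobi
preconditioner) takes enormous steps along the flat (I0, f, kF) valley
of g and destabilizes the unroll — this was measured, not conjectured.
The U-Net's output convolution is zero-initialized, so the residual
proximal operator is exactly the identity until training moves it;
without this the randomly initialized CNN freely perturbs the
data-consistency-flat directions that g cannot pull back.
The U-Net default follows the 4-level reading of the architecture
(3 pooling stages, widths 32→256, 3×3 kernels, instance norm, nearest
upsampling, ~1.9M parameters); a 4-stage variant (widths 32→512, ~7.9M
parameters, the full-size reference architecture) is one
config away (`ProxNetConfig(n_stages=4)`).

`∇g` is built from the analytic signal Jacobian (symbolically derived
from the same expression as the forward model, with common-subexpression
sharing) contracted with the backprojected residual `A^H(A S(Q) − d)`;
the whole unroll is part of the computation graph, so the joint loss
`L1 + L2 + L3` (with `L3 = Σ_k ‖d − UFC S(Q^{(k)})‖²` over all phases)
back-propagates through the CNN, the step sizes, the signal model and
into the coordinate networks. A reverse-mode evaluation of `∇g` agrees
with the explicit Jacobian-chain computation to 1e−6 relative (tested).

All learnable computation runs on a small reverse-mode autodiff engine
over numpy arrays written for this package (dense/conv/sparse-gather
primitives, Adam); convolutions use a channels-last shift-and-GEMM
scheme. Training graphs are kept in single precision; the oracle and
operator-test paths run in double precision.

## Rapid adaptation

For a new scan under the same protocol, all weights transfer; the
temporal encoding and both MLPs are frozen (bit-immutability is
asserted in tests), and every convolution is re-parameterized as
`W0 + β·A·B` with frozen base, `A (m×r)` from a scaled normal and
`B (r×l)` zero — exactly the identity at initialization. Defaults
`r = 8`, `β = 1`; layers whose geometry cannot accommodate r (the
4-channel in/out convolutions) receive the largest admissible rank
`min(m, l) − 1`. Both stages then run at a fraction (default 1/5) of the
original iterations.

## Synthetic data

The vial phantom places four circular vials (f = 0.04/0.08/0.16/0.25,
T1F = 2.0/1.5/1.0/0.8 s, kF = 1/2/3/4 s⁻¹, I0 = 1 — an agar-like
concentration series plus a distinct fourth vial) in a doped-water bath
(f = 0.02, T1F = 1.8 s, kF = 1 s⁻¹) on a 64×64×2 grid; the scan uses the
10-measurement protocol (5/10/20/40/60° with and without saturation,
TR 80 ms, TE 12 ms, Fermi 8 ms / 9.128 μT / 4 kHz), four synthetic coils
(Gaussian magnitude profiles on a ring, smooth phase, exact unit
sum-of-squares), 1D variable-density undersampling, and complex Gaussian
k-space noise at a stated SNR (30 dB default; `σ = rms(k)·10^{−SNR/20}`)
added at sampled locations only. A brain-like ellipse phantom provides
WM/GM/fluid-flavored regions for qualitative tests.

What the generator does **not** emulate: B0/B1 field inhomogeneity,
motion, partial-volume mixing, realistic coil geometry/noise correlation,
and anatomical structure. Passing the synthetic suites therefore
demonstrates the correctness and self-consistency of the implementation
under the model's own assumptions, not in vivo performance.

## Problem sizes and presets

The `"paper"` preset is the full-scale schedule (1500 + 1500
iterations, 2^19 hash tables). The `"desk"` preset — the default for all
examples, tests and the acceptance script — runs 300 + 300 iterations on
64×64×2 grids with 2^16 tables, chosen as the package's standard small
problem so that a complete two-stage study runs on one ordinary CPU
core. Property tests that need paired training runs use a 48×48×1 grid
at 150 + 150 iterations for the same reason.

## Known limitations

* Transverse relaxation (T2F), dipolar order / inhomogeneous MT, B1+ map
  estimation from the Bloch-Siegert phase, and non-Cartesian
  trajectories are out of scope; coil maps are inputs.
* The analytic steady state inherits the split-operator approximation
  (~0.5% vs the coupled two-pool propagator).
* Accuracy at desk scale is limited by first-order optimization of a
  stiff (I0, f, kF) coupling; see the acceptance results for what the
  desk schedule achieves.
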