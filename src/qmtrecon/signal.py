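"""Analytic steady-state signal model for the saturated two-pool SPGR sequence.

The acquisition interleaves a spoiled gradient-echo excitation with an
off-resonance saturation pulse applied every TR.  Tissue is modeled as a
binary spin bath: a free water pool F (fraction ``1-f`` of the equilibrium
magnetization) and a restricted macromolecular pool R (fraction ``f``),
exchanging longitudinal magnetization at pseudo-first-order rates ``kF``
(F→R) and ``kR`` (R→F), with ``kF = k·f`` and ``kR = k·(1-f)`` for a
fundamental rate constant ``k`` (equilibrium magnetization normalized to 1,
so ``k = kF/f = kR/(1-f)``).

Within each TR the model applies, in order:

1. excitation — the free longitudinal magnetization is scaled by ``cos α``
   while the on-resonance excitation pulse saturates the restricted pool by
   ``EW0 = exp(-⟨W(0)⟩ τexc)``;
2. off-resonance saturation — the restricted pool is scaled by
   ``EW = exp(-⟨W(Δ)⟩ τBTS)`` and the transverse signal acquires the
   Bloch-Siegert phase ``φ`` (quadratic in the pulse's peak B1);
3. decoupled spin-lattice relaxation of both pools over the full TR;
4. two-pool exchange over the full TR (propagator ``Ek = exp(-k·TR)``).

The steady state of this cycle has the closed form implemented in
:func:`bts_signal`; :func:`simulate_steady_state` provides an independent
numerical oracle that propagates the same cycle (and, optionally, the fully
coupled relaxation-exchange generator) to its fixed point.

The mean saturation rate of the restricted pool follows the super-Lorentzian
absorption lineshape :func:`superlorentzian_lineshape`, which diverges on
resonance; the on-resonance value needed for the excitation term is obtained
by linear extrapolation from the 1-2 kHz band (configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.integrate import quad

__all__ = [
    "GAMMA_H",
    "SaturationPulse",
    "AcquisitionProtocol",
    "FixedPoolConstants",
    "TissueParams",
    "QMapVolume",
    "fermi_pulse",
    "in_vivo_protocol",
    "phantom_protocol",
    "superlorentzian_lineshape",
    "lineshape_at_zero",
    "mean_saturation_rate",
    "bloch_siegert_phase",
    "MeasurementConstants",
    "measurement_constants",
    "bts_signal",
    "bts_signal_series",
    "signal_magnitude_series",
    "simulate_steady_state",
    "signal_jacobian",
]

#: proton gyromagnetic ratio, rad s^-1 T^-1
GAMMA_H = 2.6752218744e8

_U_SING = 1.0 / np.sqrt(3.0)


class InvalidParameterError(ValueError):
    """A physical parameter violates its documented bounds."""


class ConvergenceError(RuntimeError):
    """Iterative steady-state propagation failed to converge."""

    def __init__(self, msg, last=None):
        super().__init__(msg)
        self.last = last


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SaturationPulse:
    """Off-resonance saturation pulse description.

    Parameters are stored in acquisition units: duration in seconds, peak
    amplitude in microtesla, offset in hertz.  ``envelope`` is the normalized
    amplitude modulation sampled on a uniform grid over ``[0, tau_bts]``.
    """

    shape_name: str = "fermi"
    tau_bts: float = 8e-3
    b1_max: float = 7.3
    envelope: tuple = ()
    delta_off: float = 4000.0

    def __post_init__(self):
        if self.tau_bts <= 0:
            raise InvalidParameterError("tau_bts must be positive")
        env = np.asarray(self.envelope, dtype=float)
        if env.size == 0:
            raise InvalidParameterError("pulse envelope must be non-empty")
        if env.min() < -1e-12 or env.max() > 1 + 1e-9:
            raise InvalidParameterError("envelope values must lie in [0, 1]")
        if abs(env.max() - 1.0) > 1e-9:
            raise InvalidParameterError("envelope must be normalized to peak 1")

    @property
    def env(self) -> np.ndarray:
        return np.asarray(self.envelope, dtype=float)

    @property
    def time_grid(self) -> np.ndarray:
        return np.linspace(0.0, self.tau_bts, len(self.envelope))


def fermi_pulse(
    tau_bts: float = 8e-3,
    b1_max: float = 7.3,
    delta_off: float = 4000.0,
    flat_half_width: float | None = None,
    transition_width: float | None = None,
    n_samples: int = 512,
) -> SaturationPulse:
    """Fermi-shaped saturation pulse.

    The envelope is ``1 / (1 + exp((|t - τ/2| - t0)/a))`` with flat-top
    half-width ``t0`` (default ``0.4 τ``) and transition width ``a``
    (default ``τ/50``), renormalized to peak amplitude 1.
    """
    t0 = 0.4 * tau_bts if flat_half_width is None else flat_half_width
    a = tau_bts / 50.0 if transition_width is None else transition_width
    t = np.linspace(0.0, tau_bts, n_samples)
    env = 1.0 / (1.0 + np.exp((np.abs(t - tau_bts / 2.0) - t0) / a))
    env = env / env.max()
    return SaturationPulse(
        shape_name="fermi",
        tau_bts=tau_bts,
        b1_max=b1_max,
        envelope=tuple(env),
        delta_off=delta_off,
    )


def constant_pulse(tau_bts=8e-3, b1_max=7.3, delta_off=4000.0, n_samples=64):
    """Rectangular saturation pulse (mostly useful for analytic checks)."""
    return SaturationPulse(
        shape_name="const",
        tau_bts=tau_bts,
        b1_max=b1_max,
        envelope=tuple(np.ones(n_samples)),
        delta_off=delta_off,
    )


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Sequence description: ordered measurements plus shared timing.

    ``measurements`` is a tuple of ``(flip_angle_deg, saturation_on)``.
    """

    measurements: tuple
    tr: float
    te: float
    tau_exc: float = 500e-6
    pulse: SaturationPulse = field(default_factory=fermi_pulse)
    gamma: float = GAMMA_H

    def __post_init__(self):
        if len(self.measurements) < 2:
            raise InvalidParameterError("protocol needs at least 2 measurements")
        if not (self.tr > self.te > 0):
            raise InvalidParameterError("require tr > te > 0")
        for a, _ in self.measurements:
            if not (0.0 < a <= 180.0):
                raise InvalidParameterError(f"flip angle {a} outside (0, 180] deg")

    @property
    def n_measurements(self) -> int:
        return len(self.measurements)

    @property
    def flip_angles_deg(self) -> np.ndarray:
        return np.array([a for a, _ in self.measurements], dtype=float)

    @property
    def saturation_on(self) -> np.ndarray:
        return np.array([s for _, s in self.measurements], dtype=bool)


def _paired_measurements(flips_deg) -> tuple:
    """Saturation-off block then saturation-on block, flip angles ascending."""
    flips = sorted(flips_deg)
    return tuple((a, False) for a in flips) + tuple((a, True) for a in flips)


def in_vivo_protocol() -> AcquisitionProtocol:
    """Brain protocol: 4 flip angles x {saturation off, on}, TR 40 ms."""
    return AcquisitionProtocol(
        measurements=_paired_measurements([5, 10, 20, 40]),
        tr=40e-3,
        te=12e-3,
        tau_exc=500e-6,
        pulse=fermi_pulse(8e-3, 7.3, 4000.0),
    )


def phantom_protocol() -> AcquisitionProtocol:
    """Vial-phantom protocol: 5 flip angles x {saturation off, on}, TR 80 ms."""
    return AcquisitionProtocol(
        measurements=_paired_measurements([5, 10, 20, 40, 60]),
        tr=80e-3,
        te=12e-3,
        tau_exc=500e-6,
        pulse=fermi_pulse(8e-3, 9.128, 4000.0),
    )


@dataclass(frozen=True)
class FixedPoolConstants:
    """Fixed restricted-pool constants.

    The restricted-pool rate ``R1R`` and transverse time ``T2R`` cannot be
    estimated from this acquisition and are held at conventional white-matter
    qMT values by default.  ``onres_policy`` selects how the (formally
    divergent) on-resonance lineshape value is obtained for the excitation
    saturation term: ``"extrapolate"`` (linear extrapolation from 1-2 kHz) or
    ``"zero"`` (no excitation saturation).
    """

    r1r: float = 1.0
    t2r: float = 10e-6
    onres_policy: str = "extrapolate"

    def __post_init__(self):
        if self.r1r <= 0 or self.t2r <= 0:
            raise InvalidParameterError("r1r and t2r must be positive")
        if self.onres_policy not in ("extrapolate", "zero"):
            raise InvalidParameterError("onres_policy must be 'extrapolate' or 'zero'")


#: default fitting bounds, order (i0, t1f, f, kf)
DEFAULT_BOUNDS = ((0.0, np.inf), (1e-3, 10.0), (0.0, 1.0), (0.0, 100.0))


@dataclass(frozen=True)
class TissueParams:
    """The four unknowns of a voxel: scaled equilibrium signal ``i0`` (=ρM0),
    free-pool T1 ``t1f`` [s], macromolecular proton fraction ``f`` and
    forward exchange rate ``kf`` [s^-1]."""

    i0: float
    t1f: float
    f: float
    kf: float

    def __post_init__(self):
        if self.i0 < 0 or self.t1f <= 0 or not (0 <= self.f <= 1) or self.kf < 0:
            raise InvalidParameterError(f"tissue parameters out of bounds: {self}")

    @property
    def k(self) -> float:
        """Fundamental exchange constant (0 when f = 0 by convention)."""
        return self.kf / self.f if self.f > 0 else 0.0

    @property
    def kr(self) -> float:
        """Reverse exchange rate kR = kF (1-f)/f (0 when f = 0)."""
        return self.kf * (1.0 - self.f) / self.f if self.f > 0 else 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.i0, self.t1f, self.f, self.kf], dtype=float)


PARAM_NAMES = ("i0", "t1f", "f", "kf")


@dataclass
class QMapVolume:
    """Stack of the four quantitative maps over a spatial grid."""

    i0: np.ndarray
    t1f: np.ndarray
    f: np.ndarray
    kf: np.ndarray

    def stack(self) -> np.ndarray:
        return np.stack([self.i0, self.t1f, self.f, self.kf], axis=0)

    @classmethod
    def from_stack(cls, arr) -> "QMapVolume":
        return cls(*(np.asarray(arr[i]) for i in range(4)))

    @property
    def shape(self):
        return self.i0.shape

    def __getitem__(self, name):
        return getattr(self, name)


# ---------------------------------------------------------------------------
# lineshape and saturation rates
# ---------------------------------------------------------------------------


def _gsl_integrand(u, delta, t2r):
    d = 3.0 * u * u - 1.0
    x = 2.0 * np.pi * delta * t2r / d
    return np.sqrt(2.0 / np.pi) * (t2r / np.abs(d)) * np.exp(-2.0 * x * x)


@lru_cache(maxsize=4096)
def _gsl_cached(delta: float, t2r: float) -> float:
    val, _ = quad(
        _gsl_integrand,
        0.0,
        1.0,
        args=(delta, t2r),
        points=[_U_SING],
        limit=200,
        epsabs=0.0,
        epsrel=1e-10,
    )
    return val


def superlorentzian_lineshape(delta, t2r: float):
    """Super-Lorentzian absorption lineshape G_SL(Δ) [s].

    Evaluated by adaptive quadrature with an explicit break at the integrable
    singularity ``u = 1/sqrt(3)``.  Even in Δ and strictly positive.  The
    offset must be bounded away from 0 (use :func:`lineshape_at_zero` for the
    extrapolated on-resonance value).
    """
    if t2r <= 0:
        raise InvalidParameterError("t2r must be positive")
    deltas = np.atleast_1d(np.asarray(delta, dtype=float))
    if np.any(np.abs(deltas) < 1.0):
        raise InvalidParameterError(
            "offset too close to resonance; the super-Lorentzian diverges at 0"
        )
    out = np.array([_gsl_cached(abs(float(d)), float(t2r)) for d in deltas])
    return out if np.ndim(delta) else float(out[0])


def lineshape_at_zero(t2r: float, policy: str = "extrapolate") -> float:
    """On-resonance lineshape value G_SL(0) by linear extrapolation.

    The lineshape is extrapolated linearly in Δ from its values at 1 and
    2 kHz, the standard workaround for the on-resonance divergence.  With
    ``policy="zero"`` the excitation causes no restricted-pool saturation.
    """
    if policy == "zero":
        return 0.0
    g1 = superlorentzian_lineshape(1000.0, t2r)
    g2 = superlorentzian_lineshape(2000.0, t2r)
    return 2.0 * g1 - g2


def mean_saturation_rate(
    pulse: SaturationPulse,
    delta: float,
    consts: FixedPoolConstants,
    gamma: float = GAMMA_H,
) -> float:
    """Mean restricted-pool saturation rate ⟨W(Δ)⟩ [s^-1].

    ``⟨W(Δ)⟩ = π (1/τ) ∫ ω1²(t) dt · G_SL(Δ)`` with
    ``ω1(t) = γ B1max envelope(t)`` (B1max in μT).
    """
    env = pulse.env
    if env.size == 0:
        raise InvalidParameterError("pulse envelope must be non-empty")
    w1 = gamma * pulse.b1_max * 1e-6 * env
    msq = np.trapezoid(w1 * w1, pulse.time_grid) / pulse.tau_bts
    if abs(delta) < 1.0:
        g = lineshape_at_zero(consts.t2r, consts.onres_policy)
    else:
        g = superlorentzian_lineshape(delta, consts.t2r)
    return float(np.pi * msq * g)


def excitation_saturation_rate(
    alpha_deg: float, tau_exc: float, consts: FixedPoolConstants
) -> float:
    """On-resonance saturation rate ⟨W(0)⟩ of a rectangular excitation pulse.

    The excitation is modeled as a hard pulse of constant amplitude
    ``ω1 = α / τexc``.
    """
    w1 = np.deg2rad(alpha_deg) / tau_exc
    g0 = lineshape_at_zero(consts.t2r, consts.onres_policy)
    return float(np.pi * w1 * w1 * g0)


def bloch_siegert_phase(pulse: SaturationPulse, gamma: float = GAMMA_H) -> float:
    """Bloch-Siegert phase of the saturation pulse [rad].

    ``φ = B1max² K_BS`` with ``K_BS = ∫ (γ envelope(t))² / (2·2πΔ) dt``
    (B1max in tesla inside the integral).  The sign follows the offset sign.
    """
    if pulse.delta_off == 0:
        raise InvalidParameterError("Bloch-Siegert phase undefined at zero offset")
    b1_t = pulse.b1_max * 1e-6
    env = pulse.env
    kbs = np.trapezoid((gamma * env) ** 2, pulse.time_grid) / (
        2.0 * 2.0 * np.pi * pulse.delta_off
    )
    return float(b1_t * b1_t * kbs)


# ---------------------------------------------------------------------------
# closed-form steady state
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MeasurementConstants:
    """Tissue-independent per-measurement factors of the signal model."""

    sin_a: np.ndarray
    cos_a: np.ndarray
    e1r: float
    ew: np.ndarray
    ew0: np.ndarray
    phase: np.ndarray
    tr: float


def measurement_constants(
    protocol: AcquisitionProtocol, consts: FixedPoolConstants
) -> MeasurementConstants:
    """Precompute saturation/excitation factors for every measurement."""
    alphas = protocol.flip_angles_deg
    sat = protocol.saturation_on
    w_off = mean_saturation_rate(
        protocol.pulse, protocol.pulse.delta_off, consts, protocol.gamma
    )
    ew_on = np.exp(-w_off * protocol.pulse.tau_bts)
    phi = bloch_siegert_phase(protocol.pulse, protocol.gamma)
    ew = np.where(sat, ew_on, 1.0)
    ew0 = np.array(
        [
            np.exp(-excitation_saturation_rate(a, protocol.tau_exc, consts) * protocol.tau_exc)
            for a in alphas
        ]
    )
    phase = np.where(sat, phi, 0.0)
    rad = np.deg2rad(alphas)
    return MeasurementConstants(
        sin_a=np.sin(rad),
        cos_a=np.cos(rad),
        e1r=float(np.exp(-consts.r1r * protocol.tr)),
        ew=ew,
        ew0=ew0,
        phase=phase,
        tr=protocol.tr,
    )


def _magnitude_expr(i0, t1f, f, kf, tr, sin_a, cos_a, e1r, ew, ew0, exp):
    """Steady-state signal magnitude; generic over the arithmetic backend.

    Valid for ``f > 0`` (the exchange propagator uses ``k = kf/f``); callers
    handle the single-pool limit ``f = 0`` separately.  ``exp`` is the
    exponential of the active backend (numpy / autodiff tensor / sympy).
    """
    e1f = exp(-tr / t1f)
    ek = exp(-(kf / f) * tr)
    ews = ew * ew0
    a_c = 1.0 - f + f * ek - ek * e1r * ews
    b_c = f - f * ek + ek * ews
    c_c = f + ek - f * ek
    num = 1.0 - e1f * a_c - e1r * b_c
    den = 1.0 - e1f * a_c * cos_a - e1r * ews * c_c
    return i0 * (1.0 - f) * sin_a * num / den


def _spgr_magnitude(i0, t1f, sin_a, cos_a, tr, exp=np.exp):
    e1f = exp(-tr / t1f)
    return i0 * sin_a * (1.0 - e1f) / (1.0 - e1f * cos_a)


def signal_magnitude_series(params, mc: MeasurementConstants, exp=np.exp):
    """Vector of signal magnitudes for all measurements.

    ``params`` may hold scalars or arrays (vectorized over voxels); arrays
    broadcast against the per-measurement constants, giving shape
    ``(n_meas,) + voxel_shape`` when evaluated with numpy.
    """
    i0, t1f, f, kf = params
    f_arr = np.asarray(f, dtype=float)
    if np.ndim(f_arr) == 0 and float(f_arr) == 0.0:
        return _spgr_magnitude(i0, t1f, mc.sin_a, mc.cos_a, mc.tr, exp)
    f_safe = np.clip(f, 1e-12, 1.0) if exp is np.exp else f
    return _magnitude_expr(
        i0, t1f, f_safe, kf, mc.tr, mc.sin_a, mc.cos_a, mc.e1r, mc.ew, mc.ew0, exp
    )


def bts_signal(
    params: TissueParams,
    consts: FixedPoolConstants,
    protocol: AcquisitionProtocol,
    measurement_index: int,
) -> complex:
    """Closed-form complex steady-state signal of one measurement."""
    return bts_signal_series(params, consts, protocol)[measurement_index]


def bts_signal_series(
    params: TissueParams,
    consts: FixedPoolConstants,
    protocol: AcquisitionProtocol,
    mc: MeasurementConstants | None = None,
) -> np.ndarray:
    """Closed-form complex steady-state signal for every measurement."""
    if mc is None:
        mc = measurement_constants(protocol, consts)
    mag = signal_magnitude_series(
        (params.i0, params.t1f, params.f, params.kf), mc
    )
    return mag * np.exp(1j * mc.phase)


# ---------------------------------------------------------------------------
# numerical steady-state oracle
# ---------------------------------------------------------------------------


def simulate_steady_state(
    params: TissueParams,
    consts: FixedPoolConstants,
    protocol: AcquisitionProtocol,
    measurement_index: int,
    n_reps: int = 10000,
    tol: float = 1e-12,
    mode: str = "split",
) -> complex:
    """Propagate the two-pool longitudinal magnetization to steady state.

    Starting from thermal equilibrium, repeats the per-TR cycle (excitation
    scaling + excitation saturation, off-resonance saturation, relaxation,
    exchange) until the pre-excitation free-pool magnetization changes by
    less than ``tol`` (relative) between periods, then returns the
    post-excitation transverse signal ``i0 · Mz,F · sinα · e^{iφ}``.

    ``mode="split"`` applies relaxation and exchange as sequential decoupled
    propagators over the full TR — the cycle whose fixed point the closed
    form is; ``mode="coupled"`` uses the exact matrix exponential of the
    joint relaxation-exchange generator, quantifying the splitting error.
    """
    if n_reps < 1:
        raise InvalidParameterError("n_reps must be >= 1")
    alpha_deg, sat_on = protocol.measurements[measurement_index]
    mc = measurement_constants(protocol, consts)
    ca = mc.cos_a[measurement_index]
    sa = mc.sin_a[measurement_index]
    ew = mc.ew[measurement_index]
    ew0 = mc.ew0[measurement_index]
    phase = mc.phase[measurement_index]
    f = params.f
    tr = protocol.tr
    e1f = np.exp(-tr / params.t1f)
    e1r = mc.e1r
    k = params.k  # fundamental rate x M0
    ek = np.exp(-k * tr)

    if mode == "coupled":
        from scipy.linalg import expm

        r1f = 1.0 / params.t1f
        kf_rate, kr_rate = params.kf, params.kr
        gen = np.array(
            [[-r1f - kf_rate, kr_rate], [kf_rate, -consts.r1r - kr_rate]]
        )
        prop = expm(gen * tr)
        eq = np.array([1.0 - f, f])
        drive = eq - prop @ eq  # affine part: M(TR) = prop M0 + (I - prop) Meq
    elif mode != "split":
        raise InvalidParameterError("mode must be 'split' or 'coupled'")

    m, n = 1.0 - f, f  # pre-excitation state, equilibrium start
    converged = False
    for _ in range(n_reps):
        m_prev = m
        # excitation + saturation events
        m_post, n_post = m * ca, n * ew0 * ew
        if mode == "split":
            # decoupled relaxation over TR
            m1 = (1.0 - f) * (1.0 - e1f) + m_post * e1f
            n1 = f * (1.0 - e1r) + n_post * e1r
            # exchange over TR
            tot = m1 + n1
            m = (1.0 - f) * tot + (m1 - (1.0 - f) * tot) * ek
            n = tot - m
        else:
            vec = prop @ np.array([m_post, n_post]) + drive
            m, n = vec
        if abs(m - m_prev) <= tol * max(abs(m), 1e-30):
            converged = True
            break
    if not converged and tol > 0 and n_reps > 1 and not np.isinf(tol):
        raise ConvergenceError(
            f"steady state not reached in {n_reps} periods", last=(m, n)
        )
    return params.i0 * m * sa * np.exp(1j * phase)


# ---------------------------------------------------------------------------
# analytic Jacobian (symbolically derived once, cached)
# ---------------------------------------------------------------------------


@lru_cache(maxsize=1)
def _jacobian_func():
    """Lambdified (magnitude, four partials) w.r.t. (i0, t1f, f, kf).

    Derived symbolically from the same expression used for evaluation, with
    common subexpressions shared across the five outputs, and emitted over a
    minimal namespace so the generated function accepts both numpy arrays
    and autodiff tensors.
    """
    import sympy as sp

    syms = sp.symbols("i0 t1f f kf tr sin_a cos_a e1r ew ew0", positive=True)
    i0, t1f, f, kf = syms[:4]
    expr = _magnitude_expr(*syms, sp.exp)

    def dispatch_exp(x):
        return x.exp() if hasattr(x, "exp") else np.exp(x)

    # note: keep the raw derivative structure — rewriting (e.g. together())
    # can flip exp(-x) factors into exp(+x) ratios that overflow numerically
    exprs = [expr] + [sp.diff(expr, v) for v in (i0, t1f, f, kf)]
    return sp.lambdify(syms, exprs, modules=[{"exp": dispatch_exp}], cse=True)


def magnitude_and_partials(params, mc: MeasurementConstants):
    """Magnitude and analytic partials, vectorized over measurements/voxels.

    Accepts numpy arrays or autodiff tensors for the four parameter entries;
    per-measurement constants broadcast along the leading axis.  Requires
    ``f > 0``.
    """
    i0, t1f, f, kf = params
    out = _jacobian_func()(
        i0, t1f, f, kf, mc.tr, mc.sin_a, mc.cos_a, mc.e1r, mc.ew, mc.ew0
    )
    return out[0], tuple(out[1:])


def signal_jacobian(
    params: TissueParams,
    consts: FixedPoolConstants,
    protocol: AcquisitionProtocol,
    mc: MeasurementConstants | None = None,
) -> np.ndarray:
    """Jacobian of the signal magnitudes, shape (n_meas, 4).

    Columns are ∂|S|/∂(i0, t1f, f, kf).  At the ``f = 0`` boundary the
    analytic expressions are singular; a flagged one-sided finite-difference
    fallback is used there.
    """
    if mc is None:
        mc = measurement_constants(protocol, consts)
    if params.f <= 0.0:
        warnings.warn(
            "f on its lower bound: using one-sided finite differences",
            RuntimeWarning,
            stacklevel=2,
        )
        return _fd_jacobian(params, mc)
    _, parts = magnitude_and_partials(
        (params.i0, params.t1f, params.f, params.kf), mc
    )
    return np.stack([np.broadcast_to(p, mc.sin_a.shape) for p in parts], axis=1)


def _fd_jacobian(params: TissueParams, mc: MeasurementConstants) -> np.ndarray:
    base = np.asarray(params.as_array(), dtype=float)
    scales = np.maximum(np.abs(base), np.array([1.0, 1.0, 0.1, 1.0]))
    out = np.zeros((len(mc.sin_a), 4))
    f0 = signal_magnitude_series(tuple(base), mc)
    for j in range(4):
        h = 1e-6 * scales[j]
        p = base.copy()
        p[j] += h
        out[:, j] = (signal_magnitude_series(tuple(p), mc) - f0) / h
    return out
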