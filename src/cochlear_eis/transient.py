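"""Transient spread-induced voltage prediction for the two-block R-CPE circuit.

For a unit current step into the circuit, each R || CPE block contributes

    f_block(t) = (t**p / Y) * E_{p, p+1}(-t**p / (Y*R))
               = R * (1 - E_{p, 1}(-t**p / (Y*R))),

and a bare CPE contributes the fractional ramp ``t**p / (Y * Gamma(p+1))``,
where ``E_{a,b}(z) = sum_l z**l / Gamma(a*l + b)`` is the Mittag-Leffler
function (the fractional-order generalisation of the exponential; for
``p = 1`` the block term reduces to the familiar ``R*(1 - exp(-t/(R*C)))``).

A charge-balanced biphasic pulse is a superposition of three delayed current
steps with weights ``(-1, +2, -1) * i_amp`` (cathodic-leading), so the
spread-induced voltage at the recording electrode is

    v(t) = -i_amp * [ f(t) - 2*f(t-T0)*u(t-T0) + f(t-2*T0)*u(t-2*T0) ],

with ``f`` the summed step kernel of both blocks.  Arbitrary piecewise-
constant stimuli follow by the same superposition.

The module also provides an independent numerical inverse Laplace transform
(de Hoog quotient-difference method by default, fixed Talbot as an
alternative) used to cross-check the closed form against I(s)*Z(s).

Mittag-Leffler evaluation strategy (z <= 0, 0 < alpha <= 1): the power
series is used while its floating-point cancellation error stays below
~1e-12; the algebraic asymptotic expansion ``-sum_l z**-l / Gamma(b - a*l)``
takes over at large ``|z|``; in the intermediate band where neither reaches
the target, the global spectral (inversion-integral) representation is
integrated by adaptive quadrature.  ``alpha = 1`` reduces to exponentials.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import integrate
from scipy.special import gamma as _gamma_fn
from scipy.special import gammaln, hyp1f1, rgamma

from .circuit import BlockVariant, TransimpedanceModel, transimpedance
from .stimulus import (
    BiphasicPulse,
    PiecewiseConstantStimulus,
    pulse_laplace,
    stimulus_to_step_superposition,
)

__all__ = [
    "Provenance",
    "VoltageWaveform",
    "MLArgs",
    "mittag_leffler",
    "step_response",
    "pulse_response",
    "arbitrary_response",
    "default_grid",
    "rms_error",
    "numeric_ilt",
    "ILTConvergenceError",
    "transimpedance_laplace",
    "voltage_laplace",
    "pulse_response_numeric",
]


# --------------------------------------------------------------------------
# Waveform container
# --------------------------------------------------------------------------


class Provenance(str, enum.Enum):
    SIMULATED_CLOSED_FORM = "simulated_closed_form"
    SIMULATED_NUMERIC_ILT = "simulated_numeric_ilt"
    MEASURED = "measured"


@dataclass(frozen=True)
class VoltageWaveform:
    """Uniformly sampled voltage trace (times in s, voltages in V)."""

    times: np.ndarray
    voltages: np.ndarray
    provenance: Provenance = Provenance.SIMULATED_CLOSED_FORM

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        volts = np.asarray(self.voltages, dtype=float)
        if times.ndim != 1 or times.size < 2:
            raise ValueError("waveform needs at least two samples")
        if volts.shape != times.shape:
            raise ValueError("times and voltages must have equal length")
        dt = np.diff(times)
        if np.any(dt <= 0.0):
            raise ValueError("times must be strictly increasing")
        if np.max(np.abs(dt - dt.mean())) > 1e-9 * dt.mean():
            raise ValueError("time grid must be uniform")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "voltages", volts)
        object.__setattr__(self, "provenance", Provenance(self.provenance))

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


# --------------------------------------------------------------------------
# Mittag-Leffler function
# --------------------------------------------------------------------------

_ML_TOL = 1e-12  # per-route acceptance threshold; final target 1e-10 absolute


@dataclass(frozen=True)
class MLArgs:
    """Arguments of E_{alpha,beta}(z) as used here: alpha in (0,1], beta > 0, z <= 0."""

    alpha: float
    beta: float
    z: float

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha}")
        if not (self.beta > 0.0):
            raise ValueError(f"beta must be positive, got {self.beta}")
        if not (self.z <= 0.0 and np.isfinite(self.z)):
            raise ValueError(f"z must be finite and <= 0, got {self.z}")

    def evaluate(self) -> float:
        return mittag_leffler(self.alpha, self.beta, self.z)


def _ml_series(alpha: float, beta: float, z: float, max_terms: int = 420):
    """Power series with a cancellation-error estimate; returns (value, err)."""
    ls = np.arange(max_terms)
    with np.errstate(divide="ignore", over="ignore"):
        log_mag = ls * np.log(abs(z)) - gammaln(alpha * ls + beta)
        mags = np.exp(log_mag)
    if not np.all(np.isfinite(mags)):
        return 0.0, np.inf
    # truncate where the (eventually decreasing) terms fall below the noise floor
    peak = int(np.argmax(mags))
    tail = np.nonzero((mags < 1e-18) & (ls > peak))[0]
    stop = int(tail[0]) if tail.size else max_terms - 1
    signs = np.where(ls % 2 == 0, 1.0, -1.0)  # z <= 0
    value = float(np.sum(signs[: stop + 1] * mags[: stop + 1]))
    err = 2e-16 * float(np.max(mags[: stop + 1])) + float(mags[stop])
    if stop == max_terms - 1 and mags[stop] > 1e-18:
        err = np.inf  # did not converge within the term budget
    return value, err


def _ml_asymptotic(alpha: float, beta: float, z: float, max_terms: int = 200):
    """Algebraic expansion -sum_{l>=1} z**-l / Gamma(beta - alpha*l); (value, err).

    The divergent tail is truncated where a smooth magnitude envelope
    |z|**-l * Gamma(1 + alpha*l - beta) / pi (the reflection-formula bound on
    the coefficients) reaches its minimum; the omitted-term envelope value is
    the error estimate.  Coefficients landing within 1e-8 of a Gamma pole are
    treated as zero, with their envelope bound folded into the estimate,
    because the reflection sine factor makes both the true value and its
    floating-point evaluation unreliable there.
    """
    if abs(z) <= 1.0:
        return 0.0, np.inf
    log_az = np.log(abs(z))
    total = 0.0
    err = 0.0
    max_mag = 0.0
    prev_env = np.inf
    for l in range(1, max_terms + 1):
        x = beta - alpha * l
        inv_pow = np.exp(-l * log_az)
        if x > 0.5:
            env = inv_pow * abs(rgamma(x))
        else:
            env = inv_pow * np.exp(gammaln(1.0 - x)) / np.pi
        if env >= prev_env:  # divergence onset: stop, charge the omitted term
            err += env
            break
        prev_env = env
        if x <= 0.5 and abs(x - round(x)) < 1e-8:
            err += env * np.pi * 1e-8  # |sin| bound near the pole
            continue
        sign = 1.0 if l % 2 == 0 else -1.0  # (1/z)**l with z < 0
        term = -sign * inv_pow * rgamma(x)
        total += term
        max_mag = max(max_mag, abs(term))
    else:
        err += prev_env
    err += 2e-16 * max_mag
    return total, err


def _ml_integral(alpha: float, beta: float, z: float) -> float:
    """Spectral (inversion-integral) representation, valid for 0<alpha<1, z<0, beta<=1.

    E_{a,b}(-x) = (1/pi) * int_0^inf exp(-u) * u**(a-b)
                  * [u**a*sin(pi*(1-b)) + x*sin(pi*(1-b+a))]
                  / (u**(2a) + 2*u**a*x*cos(pi*a) + x**2) du
    """
    x = -z
    sa, sb = np.sin(np.pi * (1.0 - beta + alpha)), np.sin(np.pi * (1.0 - beta))
    ca = np.cos(np.pi * alpha)

    def integrand(u: float) -> float:
        ua = u**alpha
        denom = ua * ua + 2.0 * ua * x * ca + x * x
        return np.exp(-u) * u ** (alpha - beta) * (ua * sb + x * sa) / denom

    u_star = x ** (1.0 / alpha)  # location of the denominator minimum
    cut = max(40.0, 2.0 * u_star) if u_star < 1e3 else 40.0
    pts = [u_star] if 0.0 < u_star < cut else None
    # full_output=1 suppresses round-off warnings from the u**(alpha-beta)
    # endpoint singularity; the returned estimate is still at target accuracy
    head = integrate.quad(
        integrand, 0.0, cut, points=pts, limit=400, epsabs=1e-14, epsrel=1e-13,
        full_output=1,
    )[0]
    tail = integrate.quad(
        integrand, cut, np.inf, limit=200, epsabs=1e-14, epsrel=1e-13, full_output=1
    )[0]
    return (head + tail) / np.pi


def _ml_scalar(alpha: float, beta: float, z: float) -> float:
    if z == 0.0:
        return float(rgamma(beta))
    if alpha == 1.0:
        if beta == 1.0:
            return float(np.exp(z))
        if beta == 2.0:
            return float(np.expm1(z) / z)
        return float(hyp1f1(1.0, beta, z) * rgamma(beta))
    v_s, e_s = _ml_series(alpha, beta, z)
    if e_s <= _ML_TOL:
        return v_s
    v_a, e_a = _ml_asymptotic(alpha, beta, z)
    if e_a <= _ML_TOL:
        return v_a
    # intermediate band: integrate the spectral representation, reducing beta
    # through E_{a,b}(z) = (E_{a,b-a}(z) - 1/Gamma(b-a)) / z until b <= 1.
    b, shifts = beta, []
    while b > 1.0:
        shifts.append(b - alpha)
        b -= alpha
    val = _ml_integral(alpha, b, z)
    for bb in reversed(shifts):
        val = (val - float(rgamma(bb))) / z
    return val


def mittag_leffler(alpha: float, beta: float, z) -> np.ndarray | float:
    """E_{alpha,beta}(z) for alpha in (0,1], beta > 0, real z <= 0 (scalar or array)."""
    MLArgs(alpha=float(alpha), beta=float(beta), z=float(np.min(z)) if np.ndim(z) else float(z))
    if np.ndim(z):
        zz = np.asarray(z, dtype=float)
        if np.any(zz > 0.0):
            raise ValueError("z must be <= 0")
        out = np.array([_ml_scalar(float(alpha), float(beta), float(v)) for v in zz.ravel()])
        return out.reshape(zz.shape)
    return _ml_scalar(float(alpha), float(beta), float(z))


# --------------------------------------------------------------------------
# Step / pulse / arbitrary responses (closed form)
# --------------------------------------------------------------------------


def _rcpe_step_kernel(R: float, Y: float, p: float, t_pos: np.ndarray) -> np.ndarray:
    """(t**p / Y) * E_{p,p+1}(-t**p/(Y*R)); tends to R as t -> infinity."""
    tp = t_pos**p
    z = -tp / (Y * R)
    return tp / Y * mittag_leffler(p, p + 1.0, z)


def _bare_cpe_step_kernel(Y: float, p: float, t_pos: np.ndarray) -> np.ndarray:
    """Fractional ramp t**p / (Y * Gamma(p+1)) of a bare CPE."""
    return t_pos**p / (Y * _gamma_fn(p + 1.0))


def step_response(model: TransimpedanceModel, t) -> np.ndarray | float:
    """Voltage per amp of unit current step (ohm); zero for t < 0 by causality."""
    tt = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros_like(tt)
    pos = tt > 0.0
    if np.any(pos):
        tp = tt[pos]
        b1 = model.block1
        if model.variant is BlockVariant.BARE_CPE1:
            f1 = _bare_cpe_step_kernel(b1.cpe.Y, b1.cpe.p, tp)
        else:
            f1 = _rcpe_step_kernel(b1.R, b1.cpe.Y, b1.cpe.p, tp)
        b2 = model.block2
        f2 = _rcpe_step_kernel(b2.R, b2.cpe.Y, b2.cpe.p, tp)
        out[pos] = f1 + f2
    return out if np.ndim(t) else float(out[0])


def default_grid(pulse: BiphasicPulse, points_per_phase: int = 64, horizon: float = 3.0):
    """Uniform grid over [0, horizon*T0] with >= points_per_phase samples per phase."""
    t0 = pulse.phase_duration
    n = int(round(horizon * points_per_phase))
    return np.linspace(0.0, horizon * t0, n + 1)


def _shifted_kernel_sum(
    model: TransimpedanceModel,
    steps: Sequence[tuple[float, float]],
    grid: np.ndarray,
) -> np.ndarray:
    """sum_i a_i * f(t - d_i) on a uniform grid, reusing f when delays are grid-aligned."""
    dt = grid[1] - grid[0]
    offsets = [d / dt for d, _ in steps]
    aligned = all(abs(o - round(o)) < 1e-9 for o in offsets)
    v = np.zeros_like(grid)
    if aligned:
        f = np.asarray(step_response(model, grid))
        for (d, a), o in zip(steps, offsets):
            k = int(round(o))
            if k < grid.size:
                v[k:] += a * f[: grid.size - k]
            elif k == 0:
                v += a * f
    else:
        for d, a in steps:
            v += a * np.asarray(step_response(model, grid - d))
    return v


def pulse_response(
    model: TransimpedanceModel,
    pulse: BiphasicPulse,
    grid: np.ndarray | None = None,
    points_per_phase: int = 64,
) -> VoltageWaveform:
    """Closed-form spread-induced voltage under a charge-balanced biphasic pulse."""
    if grid is None:
        grid = default_grid(pulse, points_per_phase=points_per_phase)
    grid = np.asarray(grid, dtype=float)
    t0 = pulse.phase_duration
    if grid[0] > 0.0 or grid[-1] < 2.0 * t0:
        raise ValueError("grid must cover the pulse support [0, 2*T0]")
    s = pulse.leading_sign * pulse.amplitude
    steps = [(0.0, s), (t0, -2.0 * s), (2.0 * t0, s)]
    v = _shifted_kernel_sum(model, steps, grid)
    return VoltageWaveform(times=grid, voltages=v, provenance=Provenance.SIMULATED_CLOSED_FORM)


def arbitrary_response(
    model: TransimpedanceModel,
    stim: PiecewiseConstantStimulus,
    grid: np.ndarray,
) -> VoltageWaveform:
    """Spread-induced voltage under any piecewise-constant stimulus (step superposition)."""
    grid = np.asarray(grid, dtype=float)
    bp = stim.breakpoints
    if grid[0] > bp[0] or grid[-1] < bp[-1]:
        raise ValueError("grid must cover the stimulus support")
    steps = stimulus_to_step_superposition(stim)
    v = _shifted_kernel_sum(model, steps, grid)
    return VoltageWaveform(times=grid, voltages=v, provenance=Provenance.SIMULATED_CLOSED_FORM)


def rms_error(
    sim: VoltageWaveform,
    ref: VoltageWaveform,
    window: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """(RMS error in volts, RMS error / max |ref| over the analysis window).

    The grids must match; the window defaults to the full common grid.
    """
    if sim.times.shape != ref.times.shape or not np.allclose(
        sim.times, ref.times, rtol=1e-12, atol=0.0
    ):
        raise ValueError("waveforms must share an identical time grid")
    mask = np.ones(sim.times.size, dtype=bool)
    if window is not None:
        lo, hi = window
        mask = (sim.times >= lo) & (sim.times <= hi)
        if not np.any(mask):
            raise ValueError("analysis window contains no samples")
    diff = sim.voltages[mask] - ref.voltages[mask]
    rms = float(np.sqrt(np.mean(diff**2)))
    peak = float(np.max(np.abs(ref.voltages[mask])))
    rel = rms / peak if peak > 0.0 else (0.0 if rms == 0.0 else np.inf)
    return rms, rel


# --------------------------------------------------------------------------
# Numerical inverse Laplace transform (independent oracle)
# --------------------------------------------------------------------------


class ILTConvergenceError(RuntimeError):
    """Raised when the inversion series fails to produce finite values."""


def _ilt_dehoog(F: Callable, t: np.ndarray, M: int = 40, tol: float = 1e-14) -> np.ndarray:
    """de Hoog, Knight & Stokes quotient-difference accelerated Fourier inversion.

    Evaluates F on the abscissae s_k = gamma + i*pi*k/T (T = 2t per time point)
    and sums the half-period Fourier series accelerated by the quotient-
    difference continued fraction with the analytic remainder term.
    """
    nt = t.size
    T = 2.0 * t
    g = -np.log(tol) / (2.0 * T)
    k = np.arange(2 * M + 1)
    s = g[:, None] + 1j * np.pi * k[None, :] / T[:, None]
    fp = np.asarray(F(s.ravel()), dtype=complex).reshape(nt, 2 * M + 1)

    d = np.empty((nt, 2 * M + 1), dtype=complex)
    d[:, 0] = 0.5 * fp[:, 0]
    tiny = 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        # quotient-difference (rhombus) recurrence on the series coefficients
        denom0 = np.concatenate([0.5 * fp[:, :1], fp[:, 1:-1]], axis=1)
        q_cur = fp[:, 1:] / np.where(denom0 == 0, tiny, denom0)
        e_prev = np.zeros((nt, 2 * M + 1), dtype=complex)
        for r in range(1, M + 1):
            d[:, 2 * r - 1] = -q_cur[:, 0]
            le = 2 * (M - r) + 1
            e_cur = e_prev[:, 1 : le + 1] + q_cur[:, 1 : le + 1] - q_cur[:, :le]
            d[:, 2 * r] = -e_cur[:, 0]
            if r < M:
                lq = 2 * (M - r)
                denom = np.where(e_cur[:, :lq] == 0, tiny, e_cur[:, :lq])
                q_cur = q_cur[:, 1 : lq + 1] * e_cur[:, 1 : lq + 1] / denom
                e_prev = e_cur

        # continued fraction A/B at z = exp(i*pi*t/T) = i, improved remainder
        z = 1j
        A_prev = np.zeros(nt, dtype=complex)
        B_prev = np.ones(nt, dtype=complex)
        A = d[:, 0].copy()
        B = np.ones(nt, dtype=complex)
        for n in range(1, 2 * M):
            A, A_prev = A + d[:, n] * z * A_prev, A
            B, B_prev = B + d[:, n] * z * B_prev, B
        brem = 0.5 * (1.0 + z * (d[:, 2 * M - 1] - d[:, 2 * M]))
        rem = brem * (np.sqrt(1.0 + d[:, 2 * M] * z / brem) - 1.0)
        Af = A + rem * A_prev
        Bf = B + rem * B_prev
        out = np.exp(g * t) / T * np.real(Af / Bf)
    return out


def _ilt_talbot(F: Callable, t: np.ndarray, M: int = 28) -> np.ndarray:
    """Abate-Valko fixed-Talbot inversion (deformed Bromwich contour)."""
    out = np.empty_like(t)
    k = np.arange(1, M)
    th = k * np.pi / M
    cot = np.cos(th) / np.sin(th)
    sigma = th + (th * cot - 1.0) * cot
    for i, ti in enumerate(t):
        r = 2.0 * M / (5.0 * ti)
        s = r * th * (cot + 1j)
        vals = np.exp(ti * s) * np.asarray(F(s), dtype=complex) * (1.0 + 1j * sigma)
        out[i] = r / M * (0.5 * float(np.real(F(np.array([r + 0j]))[0])) * np.exp(r * ti) + np.sum(np.real(vals)))
    return out


def numeric_ilt(
    laplace_fn: Callable,
    t,
    method: str = "dehoog",
    **options,
) -> np.ndarray | float:
    """Numerically invert ``laplace_fn`` (vectorised over complex s) at times t > 0."""
    tt = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(tt <= 0.0):
        raise ValueError("numeric inversion requires t > 0")
    if method == "dehoog":
        out = _ilt_dehoog(laplace_fn, tt, **options)
    elif method == "talbot":
        out = _ilt_talbot(laplace_fn, tt, **options)
    else:
        raise ValueError(f"unknown inversion method {method!r}")
    if not np.all(np.isfinite(out)):
        raise ILTConvergenceError("inverse Laplace series did not converge to finite values")
    return out if np.ndim(t) else float(out[0])


def transimpedance_laplace(model: TransimpedanceModel) -> Callable:
    """Z(s) as a vectorised function of complex s (the circuit in the Laplace domain)."""

    def Z(s):
        ss = np.asarray(s, dtype=complex)
        b1, b2 = model.block1, model.block2
        zc1 = 1.0 / (b1.cpe.Y * ss**b1.cpe.p)
        if model.variant is BlockVariant.BARE_CPE1:
            z1 = zc1
        else:
            z1 = b1.R * zc1 / (b1.R + zc1)
        zc2 = 1.0 / (b2.cpe.Y * ss**b2.cpe.p)
        z2 = b2.R * zc2 / (b2.R + zc2)
        return z1 + z2

    return Z


def voltage_laplace(model: TransimpedanceModel, pulse: BiphasicPulse) -> Callable:
    """V(s) = I(s) * Z(s) for the biphasic pulse — the quantity the oracle inverts."""
    Z = transimpedance_laplace(model)

    def V(s):
        return pulse_laplace(pulse, s) * Z(s)

    return V


def pulse_response_numeric(
    model: TransimpedanceModel,
    pulse: BiphasicPulse,
    grid: np.ndarray,
    method: str = "dehoog",
    **options,
) -> VoltageWaveform:
    """Invert V(s) = I(s)*Z(s) numerically — the independent check on the closed form.

    The pulse transform factors as (delta-train delay operators) x (1/s), so by
    the Laplace time-shift theorem the inversion reduces exactly to delayed
    superpositions of the numerically inverted step kernel Z(s)/s.  Inverting
    the kernel rather than the full product keeps the contour method accurate
    at the switch instants, where v(t) has vertical-tangent t**p cusps that
    degrade a direct inversion of the product algebraically.
    """
    grid = np.asarray(grid, dtype=float)
    t0 = pulse.phase_duration
    Z = transimpedance_laplace(model)

    def kernel(s):
        return Z(s) / s

    s_amp = pulse.leading_sign * pulse.amplitude
    v = np.zeros_like(grid)
    for delay, a in ((0.0, s_amp), (t0, -2.0 * s_amp), (2.0 * t0, s_amp)):
        tau = grid - delay
        mask = tau > 0.0
        if np.any(mask):
            v[mask] += a * numeric_ilt(kernel, tau[mask], method=method, **options)
    return VoltageWaveform(times=grid, voltages=v, provenance=Provenance.SIMULATED_NUMERIC_ILT)
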