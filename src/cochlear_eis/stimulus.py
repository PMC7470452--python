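"""Charge-balanced biphasic pulses and general piecewise-constant stimuli.

The clinical stimulus is a symmetric biphasic square pulse: a cathodic
(negative) phase of duration ``T0`` immediately followed by an anodic phase
of the same duration and amplitude, so the delivered charge over ``[0, 2*T0]``
is exactly zero.  Its Laplace transform is

    I(s) = -(i_amp / s) * (1 - 2*exp(-s*T0) + exp(-2*s*T0))
         = -(i_amp / s) * (1 - exp(-s*T0))**2            (cathodic-leading)

Any piecewise-constant stimulus decomposes into a superposition of delayed
current steps, which is how the transient solver generalises the closed-form
pulse response to arbitrary pulse trains (linearity of the circuit).

Convention: segments are left-closed/right-open, so the sampled value at a
breakpoint is the level that starts there.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "Polarity",
    "BiphasicPulse",
    "PiecewiseConstantStimulus",
    "pulse_current",
    "pulse_laplace",
    "stimulus_to_step_superposition",
]


class Polarity(str, enum.Enum):
    CATHODIC_LEADING = "cathodic_leading"
    ANODIC_LEADING = "anodic_leading"


@dataclass(frozen=True)
class BiphasicPulse:
    """Symmetric charge-balanced square pulse: amplitude (A), phase duration T0 (s)."""

    amplitude: float
    phase_duration: float
    polarity: Polarity = Polarity.CATHODIC_LEADING

    def __post_init__(self) -> None:
        if not (self.amplitude > 0.0 and np.isfinite(self.amplitude)):
            raise ValueError(f"pulse amplitude must be positive, got {self.amplitude}")
        if not (self.phase_duration > 0.0 and np.isfinite(self.phase_duration)):
            raise ValueError(f"phase duration must be positive, got {self.phase_duration}")

    @property
    def leading_sign(self) -> float:
        """Sign of the first phase: -1 for cathodic-leading."""
        return -1.0 if self.polarity is Polarity.CATHODIC_LEADING else 1.0

    def to_piecewise(self) -> "PiecewiseConstantStimulus":
        s, a, t0 = self.leading_sign, self.amplitude, self.phase_duration
        return PiecewiseConstantStimulus(
            breakpoints=(0.0, t0, 2.0 * t0), levels=(s * a, -s * a)
        )


def pulse_current(pulse: BiphasicPulse, t) -> np.ndarray | float:
    """Instantaneous current (A) of the pulse at time(s) ``t`` (s)."""
    tt = np.asarray(t, dtype=float)
    t0 = pulse.phase_duration
    s = pulse.leading_sign * pulse.amplitude
    out = np.where(
        (tt >= 0.0) & (tt < t0), s, np.where((tt >= t0) & (tt < 2.0 * t0), -s, 0.0)
    )
    return out if np.ndim(t) else float(out)


def pulse_laplace(pulse: BiphasicPulse, s) -> np.ndarray | complex:
    """Laplace transform of the pulse current.

    At ``s = 0`` the charge-balanced limit 0 is returned (the transform at the
    origin equals the total delivered charge).
    """
    ss = np.asarray(s, dtype=complex)
    t0 = pulse.phase_duration
    sign = pulse.leading_sign * pulse.amplitude
    with np.errstate(divide="ignore", invalid="ignore"):
        val = sign / ss * (1.0 - np.exp(-ss * t0)) ** 2
    val = np.where(ss == 0.0, 0.0 + 0.0j, val)
    return val if np.ndim(s) else complex(val)


@dataclass(frozen=True)
class PiecewiseConstantStimulus:
    """Current that is constant on ``[breakpoints[i], breakpoints[i+1])`` and zero outside.

    ``len(levels) == len(breakpoints) - 1``; breakpoints strictly increasing.
    """

    breakpoints: tuple
    levels: tuple

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        lv = np.asarray(self.levels, dtype=float)
        if bp.ndim != 1 or bp.size < 2:
            raise ValueError("need at least two breakpoints")
        if lv.size != bp.size - 1:
            raise ValueError("levels must have one fewer entry than breakpoints")
        if not np.all(np.diff(bp) > 0.0):
            raise ValueError("breakpoints must be strictly increasing")
        if not np.all(np.isfinite(bp)) or not np.all(np.isfinite(lv)):
            raise ValueError("breakpoints and levels must be finite")
        object.__setattr__(self, "breakpoints", tuple(bp.tolist()))
        object.__setattr__(self, "levels", tuple(lv.tolist()))

    def current(self, t) -> np.ndarray | float:
        tt = np.asarray(t, dtype=float)
        bp = np.asarray(self.breakpoints)
        lv = np.concatenate([[0.0], np.asarray(self.levels), [0.0]])
        idx = np.searchsorted(bp, tt, side="right")
        out = lv[idx]
        out = np.where(tt < bp[0], 0.0, out)
        return out if np.ndim(t) else float(out)

    @property
    def charge(self) -> float:
        """Total delivered charge (A*s)."""
        bp = np.asarray(self.breakpoints)
        return float(np.sum(np.asarray(self.levels) * np.diff(bp)))

    def laplace(self, s) -> np.ndarray | complex:
        """Laplace transform; at s=0 returns the total charge (the analytic limit)."""
        steps = stimulus_to_step_superposition(self)
        ss = np.asarray(s, dtype=complex)
        with np.errstate(divide="ignore", invalid="ignore"):
            val = sum(a * np.exp(-ss * d) for d, a in steps) / ss
        val = np.where(ss == 0.0, self.charge + 0.0j, val)
        return val if np.ndim(s) else complex(val)


def stimulus_to_step_superposition(
    stim: PiecewiseConstantStimulus,
) -> list[tuple[float, float]]:
    """Minimal list of (delay, step amplitude) whose summed unit steps equal the stimulus.

    A cathodic-leading biphasic pulse yields the familiar three-step train
    ``(-i, +2i, -i)`` at delays ``(0, T0, 2*T0)``.
    """
    bp = np.asarray(stim.breakpoints)
    lv = np.concatenate([[0.0], np.asarray(stim.levels), [0.0]])
    jumps = np.diff(lv)
    return [(float(t), float(a)) for t, a in zip(bp, jumps) if a != 0.0]
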