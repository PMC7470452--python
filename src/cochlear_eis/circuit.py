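"""Lumped two-block R-CPE transimpedance model.

The cochlear transimpedance between a stimulating electrode *j* and a
recording electrode *k* is modelled as two blocks in series:

* block 1 — the common return path (cochlea -> temporal bone -> extracochlear
  ground), shared by all electrode pairs and hence spread-independent;
* block 2 — the intracochlear conduction path, which depends on the
  stimulating/recording electrode locations and carries the spread
  information.

Each block combines a resistor with a constant phase element (CPE), the
standard non-ideal capacitor of tissue impedance:

    Z_CPE(omega) = 1 / (Y * (i*omega)**p),

where ``Y`` is the admittance magnitude at 1 rad/s (units S*s^p) and
``p`` in [0, 1] sets the constant phase theta = -90*p degrees.  ``p = 1``
is an ideal capacitor, ``p = 0`` a resistor.

Two circuit variants are supported.  ``PARALLEL_RCPE1`` places R1 in
parallel with CPE1 (the layout used for spectrum fitting); ``BARE_CPE1``
drops R1 so block 1 is a bare CPE in series (the layout whose pulse
response has a simple closed form).  Block 2 is always R2 || CPE2.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "BlockVariant",
    "CPEParams",
    "RCPEBlock",
    "TransimpedanceModel",
    "ElectrodePairKey",
    "cpe_impedance",
    "block_impedance",
    "transimpedance",
    "bode",
    "nyquist",
]

TWO_PI = 2.0 * np.pi


class BlockVariant(str, enum.Enum):
    """How block 1 enters the series circuit."""

    BARE_CPE1 = "bare_cpe1"
    PARALLEL_RCPE1 = "parallel_rcpe1"


@dataclass(frozen=True)
class CPEParams:
    """Constant phase element: Y (S*s^p, admittance magnitude at 1 rad/s), p in [0, 1]."""

    Y: float
    p: float

    def __post_init__(self) -> None:
        if not (self.Y > 0.0 and np.isfinite(self.Y)):
            raise ValueError(f"CPE admittance magnitude must be positive, got Y={self.Y}")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"CPE exponent must lie in [0, 1], got p={self.p}")

    @property
    def theta_deg(self) -> float:
        """Constant phase in degrees, theta = -90*p."""
        return -90.0 * self.p


@dataclass(frozen=True)
class RCPEBlock:
    """Resistor in parallel with a CPE; ``R=None`` marks a bare CPE (R absent/infinite)."""

    cpe: CPEParams
    R: float | None = None

    def __post_init__(self) -> None:
        if self.R is not None and not (self.R > 0.0 and np.isfinite(self.R)):
            raise ValueError(f"Block resistance must be positive or None, got R={self.R}")

    @property
    def is_bare(self) -> bool:
        return self.R is None


@dataclass(frozen=True)
class TransimpedanceModel:
    """Series combination of the common-path block (1) and intracochlear block (2)."""

    block1: RCPEBlock
    block2: RCPEBlock
    variant: BlockVariant = BlockVariant.PARALLEL_RCPE1

    def __post_init__(self) -> None:
        if self.block2.is_bare:
            raise ValueError("block 2 requires a finite parallel resistance R2")
        if self.variant is BlockVariant.PARALLEL_RCPE1 and self.block1.is_bare:
            raise ValueError("PARALLEL_RCPE1 variant requires a finite R1")

    @classmethod
    def from_values(
        cls,
        *,
        Y1: float,
        p1: float,
        R2: float,
        Y2: float,
        p2: float,
        R1: float | None = None,
        variant: BlockVariant | str = BlockVariant.PARALLEL_RCPE1,
    ) -> "TransimpedanceModel":
        variant = BlockVariant(variant)
        return cls(
            block1=RCPEBlock(cpe=CPEParams(Y=Y1, p=p1), R=R1),
            block2=RCPEBlock(cpe=CPEParams(Y=Y2, p=p2), R=R2),
            variant=variant,
        )

    # Convenience accessors used throughout fitting/reporting.
    @property
    def R1(self) -> float | None:
        return self.block1.R

    @property
    def Y1(self) -> float:
        return self.block1.cpe.Y

    @property
    def p1(self) -> float:
        return self.block1.cpe.p

    @property
    def R2(self) -> float:
        assert self.block2.R is not None
        return self.block2.R

    @property
    def Y2(self) -> float:
        return self.block2.cpe.Y

    @property
    def p2(self) -> float:
        return self.block2.cpe.p


@dataclass(frozen=True, order=True)
class ElectrodePairKey:
    """Stimulating (j) and recording (k) electrode indices on a 16-contact array."""

    stim: int
    rec: int

    def __post_init__(self) -> None:
        for name, idx in (("stim", self.stim), ("rec", self.rec)):
            if not (isinstance(idx, (int, np.integer)) and 1 <= idx <= 16):
                raise ValueError(f"{name} electrode index must be an integer in 1..16, got {idx}")
        if self.stim == self.rec:
            raise ValueError("stimulating and recording electrodes must differ")


def _as_omega(omega) -> np.ndarray:
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0.0) or not np.all(np.isfinite(omega)):
        raise ValueError("angular frequency must be positive and finite")
    return omega


def cpe_impedance(cpe: CPEParams, omega) -> np.ndarray | complex:
    """Z_CPE = 1/(Y*(i*omega)^p) on the principal branch; phase is -90*p deg at every omega."""
    w = _as_omega(omega)
    z = 1.0 / (cpe.Y * (1j * w) ** cpe.p)
    return z if np.ndim(omega) else complex(z)


def block_impedance(block: RCPEBlock, omega) -> np.ndarray | complex:
    """Impedance of R || CPE (or the bare CPE when R is absent)."""
    zc = cpe_impedance(block.cpe, omega)
    if block.is_bare:
        return zc
    z = block.R * zc / (block.R + zc)
    return z if np.ndim(omega) else complex(z)


def transimpedance(model: TransimpedanceModel, omega) -> np.ndarray | complex:
    """Series impedance of both blocks; block 1 enters per the model variant."""
    if model.variant is BlockVariant.BARE_CPE1:
        z1 = cpe_impedance(model.block1.cpe, omega)
    else:
        z1 = block_impedance(model.block1, omega)
    z = z1 + block_impedance(model.block2, omega)
    return z if np.ndim(omega) else complex(z)


def bode(model: TransimpedanceModel, frequencies_hz: Sequence[float]):
    """Magnitude (ohm) and phase (deg) of the transimpedance at the given frequencies (Hz)."""
    f = np.asarray(frequencies_hz, dtype=float)
    z = transimpedance(model, TWO_PI * f)
    return np.abs(z), np.degrees(np.angle(z))


def nyquist(model: TransimpedanceModel, frequencies_hz: Sequence[float]):
    """(Re Z, -Im Z) pairs, the standard EIS complex-plane representation."""
    f = np.asarray(frequencies_hz, dtype=float)
    z = transimpedance(model, TWO_PI * f)
    return np.real(z), -np.imag(z)
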