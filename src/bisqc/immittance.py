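"""Spectral immittance components.

Immittance covers both the impedance plane Z = R + jX and the admittance
plane Y = G + jB, related by Z * Y = 1.  Six magnitudes are used by the
feature set: R, X, G, B, |Z| and the impedance phase angle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cole import ComplexSpectrum

__all__ = ["ImmittanceSet", "to_admittance", "components"]


@dataclass(frozen=True)
class ImmittanceSet:
    """The six spectral magnitudes of one measurement on a shared grid.

    Fields: resistance ``r`` and reactance ``x`` (ohm), conductance ``g``
    and susceptance ``b`` (siemens), impedance modulus ``zmod`` (ohm) and
    phase ``zang`` (radians, atan2 convention).
    """

    omega: np.ndarray
    r: np.ndarray
    x: np.ndarray
    g: np.ndarray
    b: np.ndarray
    zmod: np.ndarray
    zang: np.ndarray

    def magnitude(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def __len__(self) -> int:
        return int(np.asarray(self.omega).size)


def to_admittance(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Conductance and susceptance of a complex impedance vector.

    G = R/(R^2+X^2), B = -X/(R^2+X^2) — i.e. the real and imaginary parts
    of Y = 1/Z.

    Raises
    ------
    ValueError
        If any element of ``z`` is exactly zero (index reported).
    """
    z = np.asarray(z, dtype=complex)
    zero = np.flatnonzero(z == 0)
    if zero.size:
        raise ValueError(f"zero impedance at index {int(zero[0])}: admittance undefined")
    y = 1.0 / z
    return y.real, y.imag


def components(spectrum: ComplexSpectrum) -> ImmittanceSet:
    """All six immittance magnitudes of a measured spectrum."""
    z = spectrum.z
    g, b = to_admittance(z)
    return ImmittanceSet(
        omega=spectrum.omega,
        r=z.real,
        x=z.imag,
        g=g,
        b=b,
        zmod=np.abs(z),
        zang=np.arctan2(z.imag, z.real),
    )
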