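"""Jones-vector representation of a transverse vector optical field.

A monochromatic paraxial field is described by two co-registered complex
amplitude maps, one per orthogonal linear polarization component (x and y).
Intensity at the camera plane (no analyzer) is ``|ex|^2 + |ey|^2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["JonesField"]


@dataclass
class JonesField:
    """Two orthogonal complex polarization components on a square pixel grid."""

    ex: np.ndarray  # complex, (H, W)
    ey: np.ndarray  # complex, (H, W)

    def __post_init__(self) -> None:
        self.ex = np.asarray(self.ex, dtype=np.complex128)
        self.ey = np.asarray(self.ey, dtype=np.complex128)
        if self.ex.shape != self.ey.shape or self.ex.ndim != 2:
            raise ValueError("ex and ey must be 2-D arrays of identical shape")
        if not (np.all(np.isfinite(self.ex.view(float))) and np.all(np.isfinite(self.ey.view(float)))):
            raise ValueError("field components must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.ex.shape

    @property
    def power(self) -> float:
        """Total power summed over pixels and both polarization components."""
        return float(np.sum(np.abs(self.ex) ** 2) + np.sum(np.abs(self.ey) ** 2))

    @property
    def intensity(self) -> np.ndarray:
        """Analyzer-free camera intensity |ex|^2 + |ey|^2."""
        return np.abs(self.ex) ** 2 + np.abs(self.ey) ** 2

    def __add__(self, other: "JonesField") -> "JonesField":
        return JonesField(self.ex + other.ex, self.ey + other.ey)

    def __mul__(self, c: complex) -> "JonesField":
        return JonesField(self.ex * c, self.ey * c)

    __rmul__ = __mul__
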