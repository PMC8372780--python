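"""Physical constants for the 15N-1H spin pair.

All quantities are SI: rad s^-1 T^-1 for gyromagnetic ratios, metres for
the bond length.  The CSA is stored as a dimensionless fraction (ppm/1e6)
that multiplies the 15N Larmor frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace


@dataclass(frozen=True)
class PhysicalConstants:
    """Spin-pair constants and the derived interaction prefactors.

    The dipolar prefactor is ``d_NH = (mu0/4pi) * hbar * gamma_H * gamma_N
    / r_NH**3`` and the CSA prefactor is ``c_NH = delta_sigma * |omega_N| /
    sqrt(3)``.  Defaults: r_NH = 1.02 Angstrom, delta_sigma = -172 ppm,
    CODATA-consistent gyromagnetic ratios.
    """

    gamma_H: float = 2.6752218744e8
    gamma_N: float = -2.7126e7
    r_NH: float = 1.02e-10
    delta_sigma: float = -172.0e-6
    mu0_over_4pi: float = 1.0e-7
    hbar: float = 1.054571817e-34

    def __post_init__(self) -> None:
        if not (self.gamma_N < 0.0 < self.gamma_H):
            raise ValueError("require gamma_N < 0 < gamma_H")
        if self.r_NH <= 0:
            raise ValueError("r_NH must be positive")

    @property
    def d_NH(self) -> float:
        """Dipolar coupling prefactor (rad/s); negative for 15N-1H."""
        return (
            self.mu0_over_4pi * self.hbar * self.gamma_H * self.gamma_N
            / self.r_NH**3
        )

    def omega_H(self, field_MHz: float) -> float:
        """1H Larmor frequency (rad/s) at the given 1H field in MHz."""
        if field_MHz <= 0:
            raise ValueError("field_MHz must be positive")
        return 2.0 * math.pi * field_MHz * 1.0e6

    def omega_N(self, field_MHz: float) -> float:
        """Magnitude of the 15N Larmor frequency (rad/s)."""
        return abs(self.omega_H(field_MHz) * self.gamma_N / self.gamma_H)

    def c_NH(self, field_MHz: float) -> float:
        """CSA prefactor (rad/s) at the given field."""
        return self.delta_sigma * self.omega_N(field_MHz) / math.sqrt(3.0)

    def with_overrides(self, **kwargs: float) -> "PhysicalConstants":
        return replace(self, **kwargs)


DEFAULT_CONSTANTS = PhysicalConstants()
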