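"""Spectrometer context: field-dependent constants of the ¹⁵N relaxation analysis.

The dipolar (``d``) and CSA (``c``) interaction constants are derived
deterministically from the field strength, the gyromagnetic ratios, the N–H
bond length and the ¹⁵N chemical shift anisotropy:

    d = μ₀ h γ_H γ_N ⟨r_NH⁻³⟩ / (8π²)
    c = ω_N Δσ / √3

Both enter the relaxation expressions only as d² and c², so their signs are
immaterial; the *signed* γ ratio is exposed separately for the NOE and the
cross-relaxation rate σ, where the sign does matter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .constants import GAMMA_H, GAMMA_N, MU_0, PLANCK_H


@dataclass(frozen=True)
class SpectrometerContext:
    """Field-dependent constants for amide ¹⁵N relaxation.

    Parameters
    ----------
    proton_frequency_mhz:
        ¹H Larmor frequency in MHz (e.g. 800 for an 18.8 T magnet).
    gamma_H, gamma_N:
        Signed gyromagnetic ratios, rad s⁻¹ T⁻¹.  γ_N is negative.
    r_NH:
        Amide N–H bond length in Å.
    delta_sigma:
        ¹⁵N chemical shift anisotropy Δσ = σ∥ − σ⊥ in ppm (−160 by default).
    """

    proton_frequency_mhz: float = 800.0
    gamma_H: float = GAMMA_H
    gamma_N: float = GAMMA_N
    r_NH: float = 1.02
    delta_sigma: float = -160.0

    # derived, filled in __post_init__
    omega_H: float = field(init=False, repr=False)
    omega_N: float = field(init=False, repr=False)
    d: float = field(init=False, repr=False)
    c: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.proton_frequency_mhz <= 0:
            raise ValueError("proton_frequency_mhz must be positive")
        if self.r_NH <= 0:
            raise ValueError("r_NH must be positive")
        omega_H = 2.0 * math.pi * self.proton_frequency_mhz * 1e6
        # magnitude convention for the frequency axis; signs live in gamma_ratio
        omega_N = abs(self.gamma_N / self.gamma_H) * omega_H
        r_m = self.r_NH * 1e-10
        d = MU_0 * PLANCK_H * abs(self.gamma_H * self.gamma_N) / (8.0 * math.pi**2) * r_m**-3
        c = omega_N * abs(self.delta_sigma) * 1e-6 / math.sqrt(3.0)
        object.__setattr__(self, "omega_H", omega_H)
        object.__setattr__(self, "omega_N", omega_N)
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "c", c)

    @property
    def gamma_ratio(self) -> float:
        """Signed γ_N/γ_H (≈ −0.1014); used in σ and the NOE."""
        return self.gamma_N / self.gamma_H

    @property
    def denominator(self) -> float:
        """3d² + 4c², the shared denominator of the J(0)/J(ω_N) mapping."""
        return 3.0 * self.d**2 + 4.0 * self.c**2


__all__ = ["SpectrometerContext"]
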