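"""Model-free spectral density and forward relaxation rates.

This module is the ground-truth engine of the synthetic-data generator: a
Lipari–Szabo spectral density parameterised by an order parameter S², an
overall tumbling time τc and an internal correlation time τe, and the
standard dipolar + CSA expressions that turn it into (R1, R2, NOE) at a
given field.  It is *not* used to fit experimental data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .context import SpectrometerContext


@dataclass(frozen=True)
class ModelFreeParams:
    """Lipari–Szabo parameters for one residue.

    S2 is dimensionless in [0, 1]; tau_c is the overall correlation time in
    ns; tau_e the internal correlation time in ps; Rex a chemical-exchange
    contribution to R2 in s⁻¹ (enters R2 additively and nothing else).
    """

    residue_id: int = 0
    S2: float = 1.0
    tau_c: float = 10.0
    tau_e: float = 0.0
    Rex: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.S2 <= 1.0:
            raise ValueError(f"S2 must be in [0, 1], got {self.S2}")
        if self.tau_c <= 0:
            raise ValueError(f"tau_c must be positive, got {self.tau_c}")
        if self.tau_e < 0:
            raise ValueError(f"tau_e must be non-negative, got {self.tau_e}")
        if self.Rex < 0:
            raise ValueError(f"Rex must be non-negative, got {self.Rex}")


class RelaxationRates(NamedTuple):
    R1: float
    R2: float
    NOE: float


def model_free_J(params: ModelFreeParams, omega: float | np.ndarray) -> float | np.ndarray:
    """Lipari–Szabo spectral density J(ω) in s/rad.

    J(ω) = (2/5) [ S² τc / (1 + (ω τc)²) + (1 − S²) τ / (1 + (ω τ)²) ]
    with 1/τ = 1/τc + 1/τe.  ``omega`` is angular frequency in rad/s.
    """
    tau_c = params.tau_c * 1e-9
    tau_e = params.tau_e * 1e-12
    w2 = np.square(omega)
    j = params.S2 * tau_c / (1.0 + w2 * tau_c**2)
    if params.S2 < 1.0 and tau_e > 0.0:
        tau = 1.0 / (1.0 / tau_c + 1.0 / tau_e)
        j = j + (1.0 - params.S2) * tau / (1.0 + w2 * tau**2)
    return 0.4 * j


def forward_relaxation(params: ModelFreeParams, ctx: SpectrometerContext) -> RelaxationRates:
    """Forward-simulate (R1, R2, NOE) for an amide ¹⁵N at the given field.

    Standard dipolar + CSA expressions; Rex is added to R2 only.  The NOE
    uses the signed γ_H/γ_N ratio, so protein-regime tumbling gives NOE < 1
    and the extreme-narrowing limit approaches 1 + γ_H/(2γ_N) < 0.

    The combination frequencies honour the sign of the ¹⁵N Larmor
    frequency (ω_N = γ_N·B₀ < 0): the "sum" frequency ω_H + ω_N has
    magnitude ≈ 0.9 ω_H and the "difference" ≈ 1.1 ω_H.  This ordering is
    what makes the cross-relaxation combination (6J(ω_H+ω_N) − J(ω_H−ω_N))/5
    a probe of J near 0.87 ω_H.
    """
    wH, wN = ctx.omega_H, ctx.omega_N
    d2, c2 = ctx.d**2, ctx.c**2

    def J(w: float) -> float:
        return float(model_free_J(params, w))

    j0, jn, jh = J(0.0), J(wN), J(wH)
    # signed omega_N < 0: |wH + omega_N| = wH - wN, |wH - omega_N| = wH + wN
    j_sum, j_diff = J(wH - wN), J(wH + wN)

    R1 = d2 / 4.0 * (j_diff + 3.0 * jn + 6.0 * j_sum) + c2 * jn
    R2 = (
        d2 / 8.0 * (4.0 * j0 + j_diff + 3.0 * jn + 6.0 * jh + 6.0 * j_sum)
        + c2 / 6.0 * (4.0 * j0 + 3.0 * jn)
        + params.Rex
    )
    NOE = 1.0 + d2 / (4.0 * R1) * (ctx.gamma_H / ctx.gamma_N) * (6.0 * j_sum - j_diff)
    return RelaxationRates(R1=R1, R2=R2, NOE=NOE)


__all__ = ["ModelFreeParams", "RelaxationRates", "model_free_J", "forward_relaxation"]
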