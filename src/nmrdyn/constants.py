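"""Physical constants used throughout the relaxation analysis.

Gyromagnetic ratios are kept *signed*: the negative sign of the ¹⁵N ratio
matters for the heteronuclear NOE and for the sign convention of the
¹H–¹⁵N cross-relaxation rate σ.
"""

import math

from scipy.constants import h as PLANCK_H  # J s

#: Vacuum permeability, N A⁻², at its classical defined value 4π×10⁻⁷ —
#: the convention of the relaxation literature (differs from the measured
#: CODATA value only at the 1e-10 level).
MU_0: float = 4.0e-7 * math.pi

#: ¹H gyromagnetic ratio, rad s⁻¹ T⁻¹ (CODATA).
GAMMA_H: float = 2.6752218744e8

#: ¹⁵N gyromagnetic ratio, rad s⁻¹ T⁻¹ — signed (negative).
GAMMA_N: float = -2.7126e7

__all__ = ["PLANCK_H", "MU_0", "GAMMA_H", "GAMMA_N"]
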