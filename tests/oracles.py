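"""Independent brute-force oracles for the test suite.

These deliberately reimplement the physics and geometry from scratch,
with their own literal constants and no imports from the package's
computational code paths, so the package can be checked against them.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize

# literal constants, written out independently of nmrdyn.constants
_MU0 = 4.0e-7 * math.pi  # classical vacuum permeability, N A^-2
_H = 6.62607015e-34
_GH = 2.6752218744e8
_GN = -2.7126e7


def oracle_J(S2: float, tau_c_ns: float, tau_e_ps: float, omega: float) -> float:
    """Direct evaluation of the two-timescale Lorentzian spectral density."""
    tc = tau_c_ns * 1e-9
    te = tau_e_ps * 1e-12
    term = S2 * tc / (1.0 + (omega * tc) ** 2)
    if te > 0.0:
        tau = 1.0 / (1.0 / tc + 1.0 / te)
        term += (1.0 - S2) * tau / (1.0 + (omega * tau) ** 2)
    return (2.0 / 5.0) * term


def oracle_constants(field_mhz: float, r_nh_A: float = 1.02, dsigma_ppm: float = -160.0):
    """(omega_H, omega_N_signed, d, c) computed from scratch."""
    wh = 2.0 * math.pi * field_mhz * 1e6
    wn = (_GN / _GH) * wh  # signed, negative
    d = _MU0 * _H * _GH * abs(_GN) / (8.0 * math.pi**2) * (r_nh_A * 1e-10) ** -3
    c = abs(wn) * abs(dsigma_ppm) * 1e-6 / math.sqrt(3.0)
    return wh, wn, d, c


def oracle_rates(
    S2: float,
    tau_c_ns: float,
    tau_e_ps: float,
    rex: float,
    field_mhz: float = 800.0,
) -> tuple[float, float, float]:
    """Brute-force (R1, R2, NOE) from the dipolar + CSA expressions.

    The signed ¹⁵N Larmor frequency enters the combination frequencies
    directly: J is evaluated at |omega_H + omega_N| and |omega_H − omega_N|
    with omega_N negative.
    """
    wh, wn, d, c = oracle_constants(field_mhz)

    def J(w):
        return oracle_J(S2, tau_c_ns, tau_e_ps, abs(w))

    d2, c2 = d * d, c * c
    j_sum = J(wh + wn)   # |0.9 wh|
    j_diff = J(wh - wn)  # |1.1 wh|
    r1 = d2 / 4.0 * (j_diff + 3.0 * J(wn) + 6.0 * j_sum) + c2 * J(wn)
    r2 = (
        d2 / 8.0 * (4.0 * J(0) + j_diff + 3.0 * J(wn) + 6.0 * J(wh) + 6.0 * j_sum)
        + c2 / 6.0 * (4.0 * J(0) + 3.0 * J(wn))
        + rex
    )
    noe = 1.0 + d2 / (4.0 * r1) * (_GH / _GN) * (6.0 * j_sum - j_diff)
    return r1, r2, noe


def oracle_cross_relaxation(S2, tau_c_ns, tau_e_ps, field_mhz=800.0) -> float:
    """Directly computed σ = (d²/4)[6J(|ω_H+ω_N|) − J(|ω_H−ω_N|)]."""
    wh, wn, d, _ = oracle_constants(field_mhz)

    def J(w):
        return oracle_J(S2, tau_c_ns, tau_e_ps, abs(w))

    return d * d / 4.0 * (6.0 * J(wh + wn) - J(wh - wn))


# ---------------------------------------------------------------------------
# rigid-body superposition by brute-force rotation search


def _rotvec_to_matrix(v: np.ndarray) -> np.ndarray:
    angle = np.linalg.norm(v)
    if angle < 1e-12:
        return np.eye(3)
    axis = v / angle
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


def oracle_min_rmsd(mobile: np.ndarray, reference: np.ndarray, seed: int = 0) -> float:
    """Minimum superposition RMSD via random rotation search plus local refinement.

    Independent of the Kabsch solution: samples many random rotations
    (translation resolved exactly by centroid matching for each) and
    polishes the best candidates with a derivative-free simplex search
    over the rotation vector.
    """
    rng = np.random.default_rng(seed)
    P = mobile - mobile.mean(axis=0)
    Q = reference - reference.mean(axis=0)

    def rmsd_of(v):
        R = _rotvec_to_matrix(np.asarray(v))
        return float(np.sqrt(np.mean(np.sum((P @ R.T - Q) ** 2, axis=1))))

    candidates = rng.normal(size=(4000, 3)) * rng.uniform(0, math.pi, size=(4000, 1))
    scores = [rmsd_of(v) for v in candidates]
    best = np.argsort(scores)[:5]
    out = min(scores)
    for i in best:
        res = minimize(rmsd_of, candidates[i], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000})
        out = min(out, float(res.fun))
    return out


def oracle_rmsd_from_mean_no_motion(coords: np.ndarray) -> np.ndarray:
    """Per-model RMSD to the plain coordinate mean, with no superposition.

    Valid as a reference when the models carry no rigid-body motion
    (scatter-only ensembles built directly on a common frame).
    """
    mean = coords.mean(axis=0)
    return np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=1))
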