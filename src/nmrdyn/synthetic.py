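"""Synthetic-data generators for every stage of the pipeline.

Raw NMR peak heights, melt curves and per-residue rates behind published
dynamics studies are rarely deposited; these generators produce each
input the analysis consumes from known ground-truth parameters, so every
downstream stage has a self-checking parameter-recovery test:

* exponential decay series and paired XNOE heights from model-free
  (S², τc, τe, Rex) ground truth at a stated field, with Gaussian
  intensity noise and duplicate spectra for error estimation;
* Boltzmann-sigmoid melt curves;
* paired HSQC peak lists with planted shift perturbations and height
  attenuations;
* small multi-model coordinate ensembles with controlled scatter and
  random rigid-body motion per model.

All generators are bit-for-bit reproducible under a NoiseSpec seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .context import SpectrometerContext
from .ensemble import Ensemble
from .modelfree import ModelFreeParams, RelaxationRates, forward_relaxation, model_free_J
from .peaklist import PeakList
from .relaxation import T1_DELAYS_S, T2_DELAYS_S, RelaxationSeries
from .thermal import MeltCurve, boltzmann

__all__ = [
    "NoiseSpec",
    "ModelFreeParams",
    "model_free_J",
    "forward_relaxation",
    "simulate_decay_series",
    "simulate_xnoe_measurement",
    "simulate_melt_curve",
    "simulate_titration_peaklists",
    "simulate_ensemble",
    "simulate_relaxation_experiment",
    "make_template_ensemble",
    "DEFAULT_MELT_GRID",
]

#: Default melt temperature grid: 25–99 °C ramp at 0.5 °C sampling.
DEFAULT_MELT_GRID = np.arange(25.0, 99.0 + 1e-9, 0.5)


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian intensity noise as a fraction of a reference peak height."""

    intensity_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intensity_sd < 0:
            raise ValueError("intensity_sd must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def simulate_decay_series(
    rate: float,
    I0: float,
    delays: Sequence[float] | np.ndarray = T1_DELAYS_S,
    noise: NoiseSpec = NoiseSpec(0.0),
    residue_id: int = 1,
    replicate_id: int = 0,
    rng: np.random.Generator | None = None,
) -> RelaxationSeries:
    """Noisy single-exponential decay I(t) = I0·exp(−rate·t) on a delay grid.

    Noise is Gaussian with sd = intensity_sd·I0.  Pass ``rng`` to draw from
    a caller-managed stream (several series per seed); otherwise the
    NoiseSpec seed starts a fresh one.
    """
    delays = np.asarray(delays, dtype=float)
    if delays.size == 0:
        raise ValueError("delays must be non-empty")
    if np.any(delays < 0):
        raise ValueError("delays must be non-negative")
    if rng is None:
        rng = noise.rng()
    ideal = I0 * np.exp(-rate * delays)
    noisy = ideal + rng.normal(0.0, noise.intensity_sd * I0, size=delays.size)
    return RelaxationSeries(residue_id, delays, noisy, replicate_id=replicate_id)


def simulate_xnoe_measurement(
    noe_true: float,
    I_ref: float = 100.0,
    noise: NoiseSpec = NoiseSpec(0.0),
    n_duplicates: int = 1,
    rng: np.random.Generator | None = None,
) -> list[tuple[float, float]]:
    """Paired (saturated, unsaturated) peak heights for one residue.

    Unsaturated heights scatter about I_ref and saturated about
    noe_true·I_ref, both with sd = intensity_sd·I_ref; duplicates share
    the truth and differ only in noise.
    """
    if n_duplicates < 1:
        raise ValueError("n_duplicates must be >= 1")
    if rng is None:
        rng = noise.rng()
    sd = noise.intensity_sd * I_ref
    out = []
    for _ in range(n_duplicates):
        sat = noe_true * I_ref + rng.normal(0.0, sd)
        unsat = I_ref + rng.normal(0.0, sd)
        out.append((float(sat), float(unsat)))
    return out


def simulate_melt_curve(
    Tm: float,
    slope: float = 1.5,
    baselines: tuple[float, float] = (0.0, 1.0),
    T_grid: np.ndarray = DEFAULT_MELT_GRID,
    noise: NoiseSpec = NoiseSpec(0.0),
    replicate_id: int = 0,
    construct: str = "",
    rng: np.random.Generator | None = None,
) -> MeltCurve:
    """Boltzmann-sigmoid melt curve with Gaussian fluorescence noise.

    Noise sd is intensity_sd × the transition amplitude (high − low
    baseline).  A Tm outside the temperature grid warns but still
    generates (the fit may be attempted regardless).
    """
    import warnings

    T_grid = np.asarray(T_grid, dtype=float)
    if slope <= 0:
        raise ValueError("slope must be positive")
    if not T_grid.min() <= Tm <= T_grid.max():
        warnings.warn(f"Tm {Tm} lies outside the temperature grid", stacklevel=2)
    if rng is None:
        rng = noise.rng()
    low, high = baselines
    F = boltzmann(T_grid, low, high, Tm, slope)
    F = F + rng.normal(0.0, noise.intensity_sd * abs(high - low), size=T_grid.size)
    return MeltCurve(T_grid, F, replicate_id=replicate_id, construct=construct)


def simulate_titration_peaklists(
    base: PeakList,
    shifted_residues: Mapping[int, tuple[float, float]] | None = None,
    attenuated_residues: Mapping[int, float] | None = None,
    noise: NoiseSpec = NoiseSpec(0.0),
    shift_noise_H: float = 0.0,
    shift_noise_N: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[PeakList, PeakList]:
    """(free, bound) HSQC peak lists for a single-point titration.

    ``shifted_residues`` maps residue → (ΔδH, ΔδN) in ppm applied in the
    bound list; ``attenuated_residues`` maps residue → bound/free height
    ratio.  Heights get Gaussian noise of sd intensity_sd × the median
    base height; peak positions in *both* lists get Gaussian jitter of sd
    ``shift_noise_H``/``shift_noise_N`` ppm (per spectrum), emulating the
    position uncertainty of peak picking.  Unlisted residues are unchanged
    up to noise.
    """
    shifted_residues = dict(shifted_residues or {})
    attenuated_residues = dict(attenuated_residues or {})
    known = set(base.data["residue"])
    for mapping in (shifted_residues, attenuated_residues):
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"residues not in base peak list: {sorted(unknown)}")
    if rng is None:
        rng = noise.rng()

    free = base.data.copy()
    bound = base.data.copy()
    for res, (d_h, d_n) in shifted_residues.items():
        sel = bound["residue"] == res
        bound.loc[sel, "w_H"] += d_h
        bound.loc[sel, "w_N"] += d_n
    for res, ratio in attenuated_residues.items():
        bound.loc[bound["residue"] == res, "height"] *= ratio

    ref_height = float(np.nanmedian(base.data["height"])) if base.data["height"].notna().any() else 0.0
    for df in (free, bound):
        n = len(df)
        df["w_H"] += rng.normal(0.0, shift_noise_H, size=n) if shift_noise_H > 0 else 0.0
        df["w_N"] += rng.normal(0.0, shift_noise_N, size=n) if shift_noise_N > 0 else 0.0
        if noise.intensity_sd > 0 and ref_height > 0:
            df["height"] += rng.normal(0.0, noise.intensity_sd * ref_height, size=n)
    return PeakList(free), PeakList(bound)


def simulate_ensemble(
    template: Ensemble,
    n_models: int,
    coord_sd: float,
    noise: NoiseSpec = NoiseSpec(0.0),
    max_rotation_deg: float = 180.0,
    max_translation: float = 10.0,
    rng: np.random.Generator | None = None,
) -> Ensemble:
    """Ensemble of ``n_models`` copies of a single-model template.

    Each model is the template plus isotropic Gaussian displacement of sd
    ``coord_sd`` Å per atom coordinate, followed by a random rigid-body
    rotation and translation (so downstream superposition is exercised).
    """
    if template.n_models != 1:
        raise ValueError("template must contain exactly one model")
    if n_models < 2:
        raise ValueError("n_models must be >= 2")
    if rng is None:
        rng = noise.rng()
    base = template.coords[0]
    models = []
    for _ in range(n_models):
        coords = base + rng.normal(0.0, coord_sd, size=base.shape)
        R = _random_rotation(rng, max_rotation_deg)
        t = rng.uniform(-max_translation, max_translation, size=3)
        models.append(coords @ R.T + t)
    return Ensemble(template.atoms.copy(), np.array(models))


def _random_rotation(rng: np.random.Generator, max_deg: float) -> np.ndarray:
    """Uniform random axis, angle uniform in [0, max_deg]; Rodrigues' formula."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = math.radians(rng.uniform(0.0, max_deg))
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


def make_template_ensemble(n_residues: int = 30, chain: str = "A") -> Ensemble:
    """Single-model synthetic template: an idealised α-helical backbone.

    N, CA, C and O atoms (plus CB except for glycine-free poly-Ala this is
    always present) are placed on a helical curve with ~3.8 Å Cα spacing —
    plausible geometry for exercising superposition and RMSD code, not a
    stereochemically exact structure.
    """
    rows, coords = [], []
    rise, turn, radius = 1.5, math.radians(100.0), 2.3
    offsets = {"N": (-0.7, -0.6, -0.5), "CA": (0.0, 0.0, 0.0), "C": (0.8, 0.5, 0.4),
               "O": (0.9, 1.2, 1.1), "CB": (-0.5, 1.3, -0.6)}
    for i in range(n_residues):
        theta = i * turn
        ca = np.array([radius * math.cos(theta), radius * math.sin(theta), rise * i])
        for name, off in offsets.items():
            rows.append(
                {"chain": chain, "residue": i + 1, "res_name": "ALA",
                 "atom_name": name, "element": name[0]}
            )
            coords.append(ca + np.array(off))
    atoms = pd.DataFrame(rows)
    return Ensemble(atoms, np.array(coords)[None, :, :])


def simulate_relaxation_experiment(
    params_list: Sequence[ModelFreeParams],
    ctx: SpectrometerContext,
    noise: NoiseSpec = NoiseSpec(0.01),
    I0: float = 100.0,
    t1_delays: np.ndarray = T1_DELAYS_S,
    t2_delays: np.ndarray = T2_DELAYS_S,
    n_duplicates: int = 2,
) -> dict:
    """Full synthetic relaxation dataset from per-residue model-free truth.

    Returns a dict with per-residue ground-truth rates, T1/T2 decay series
    (with a duplicate replicate for noise estimation) and XNOE height
    pairs — everything the rate-fitting stage consumes.
    """
    rng = noise.rng()
    truth: dict[int, RelaxationRates] = {}
    t1_series: list[RelaxationSeries] = []
    t2_series: list[RelaxationSeries] = []
    xnoe_pairs: dict[int, list[tuple[float, float]]] = {}
    for params in params_list:
        rates = forward_relaxation(params, ctx)
        truth[params.residue_id] = rates
        for rep in range(n_duplicates):
            t1_series.append(
                simulate_decay_series(rates.R1, I0, t1_delays, noise,
                                      residue_id=params.residue_id, replicate_id=rep, rng=rng)
            )
            t2_series.append(
                simulate_decay_series(rates.R2, I0, t2_delays, noise,
                                      residue_id=params.residue_id, replicate_id=rep, rng=rng)
            )
        xnoe_pairs[params.residue_id] = simulate_xnoe_measurement(
            rates.NOE, I0, noise, n_duplicates=n_duplicates, rng=rng
        )
    return {"truth": truth, "t1": t1_series, "t2": t2_series, "xnoe": xnoe_pairs}


def write_delay_series_csv(series: Sequence[RelaxationSeries], path) -> None:
    """Write delay series as CSV (residue, delay_s, intensity, replicate)."""
    frames = [
        pd.DataFrame(
            {"residue": s.residue_id, "delay_s": s.delays, "intensity": s.intensities,
             "replicate": s.replicate_id}
        )
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
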