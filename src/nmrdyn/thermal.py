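"""Thermal shift assay analysis: Boltzmann sigmoid Tm fitting and ΔTm.

A dye-reported melt curve is truncated to its transition window (SYPRO
Orange fluorescence decays after the unfolding peak), fitted with the
Boltzmann equation

    F(T) = LL + (UL − LL) / (1 + exp((Tm − T)/a)),

replicate Tm values are aggregated (mean ± sd across the three repeats a
typical assay runs), and construct stabilities are compared as ΔTm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lmfit import Model


@dataclass
class MeltCurve:
    """Fluorescence vs temperature for one well."""

    temperatures: np.ndarray
    fluorescence: np.ndarray
    replicate_id: int = 0
    construct: str = ""

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures.shape != self.fluorescence.shape:
            raise ValueError("temperatures and fluorescence must have the same length")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")


@dataclass
class BoltzmannFit:
    """Fitted Boltzmann sigmoid for one melt curve (or a replicate aggregate)."""

    Tm: float = math.nan
    slope: float = math.nan
    baseline_low: float = math.nan
    baseline_high: float = math.nan
    Tm_error: float = math.nan
    fit_window: tuple[float, float] = (math.nan, math.nan)
    construct: str = ""
    n_replicates: int = 1
    ok: bool = True
    message: str = ""


def boltzmann(T: np.ndarray, LL: float, UL: float, Tm: float, a: float) -> np.ndarray:
    """Boltzmann sigmoid; Tm is the midpoint (and inflection), a the width in °C."""
    return LL + (UL - LL) / (1.0 + np.exp((Tm - T) / a))


def truncate_transition(curve: MeltCurve) -> tuple[MeltCurve | None, tuple[float, float], str]:
    """Restrict a melt curve to its transition window.

    Keeps the points from the global fluorescence minimum preceding the
    rise through the global maximum, discarding the post-peak dye-release
    decay.  Returns (curve, window, message); curve is None for flat or
    monotonically decreasing data with no detectable rise.
    """
    if curve.temperatures.size < 10:
        raise ValueError("at least 10 points are required to locate the transition")
    F = curve.fluorescence
    i_max = int(np.argmax(F))
    i_min = int(np.argmin(F[: i_max + 1]))
    if i_max <= i_min or F[i_max] <= F[i_min]:
        return None, (math.nan, math.nan), "no rising transition found"
    window = (float(curve.temperatures[i_min]), float(curve.temperatures[i_max]))
    truncated = MeltCurve(
        curve.temperatures[i_min : i_max + 1],
        F[i_min : i_max + 1],
        replicate_id=curve.replicate_id,
        construct=curve.construct,
    )
    return truncated, window, ""


def fit_boltzmann(curve: MeltCurve, truncate: bool = True) -> BoltzmannFit:
    """Least-squares Boltzmann fit of one melt curve.

    The initial Tm is placed at the steepest observed rise (maximum first
    difference of F over T); failures (no transition, non-convergence, Tm
    outside the fit window) come back as flagged records, not exceptions.
    """
    window = (float(curve.temperatures[0]), float(curve.temperatures[-1]))
    fit_curve = curve
    if truncate:
        fit_curve, window, msg = truncate_transition(curve)
        if fit_curve is None:
            return BoltzmannFit(construct=curve.construct, ok=False, message=msg)
    T, F = fit_curve.temperatures, fit_curve.fluorescence
    dF = np.diff(F) / np.diff(T)
    tm0 = float(T[int(np.argmax(dF))])
    model = Model(boltzmann)
    params = model.make_params(LL=float(F.min()), UL=float(F.max()), Tm=tm0, a=1.5)
    params["a"].set(min=1e-3)
    try:
        result = model.fit(F, params, T=T)
    except Exception as exc:  # lmfit can raise on degenerate data
        return BoltzmannFit(construct=curve.construct, ok=False, message=str(exc))
    if not result.success:
        return BoltzmannFit(construct=curve.construct, ok=False, message="fit did not converge")
    p = result.params
    tm = float(p["Tm"].value)
    if not window[0] <= tm <= window[1]:
        return BoltzmannFit(
            construct=curve.construct, ok=False, message=f"Tm {tm:.2f} outside fit window"
        )
    return BoltzmannFit(
        Tm=tm,
        slope=float(p["a"].value),
        baseline_low=float(p["LL"].value),
        baseline_high=float(p["UL"].value),
        fit_window=window,
        construct=curve.construct,
    )


def aggregate_replicates(fits: Sequence[BoltzmannFit], use_sem: bool = False) -> BoltzmannFit:
    """Aggregate replicate fits of one construct: Tm = mean, Tm_error = sd.

    ``use_sem`` reports the standard error of the mean instead of the sd.
    A single accepted replicate passes through with Tm_error left NaN.
    """
    accepted = [f for f in fits if f.ok]
    if not accepted:
        raise ValueError("no accepted fits to aggregate")
    constructs = {f.construct for f in accepted}
    if len(constructs) > 1:
        raise ValueError(f"fits span multiple constructs: {sorted(constructs)}")
    if len(accepted) == 1:
        return replace(accepted[0], message="single replicate; Tm_error undefined")
    tms = np.array([f.Tm for f in accepted])
    err = float(np.std(tms, ddof=1))
    if use_sem:
        err /= math.sqrt(len(tms))
    return BoltzmannFit(
        Tm=float(tms.mean()),
        slope=float(np.mean([f.slope for f in accepted])),
        baseline_low=float(np.mean([f.baseline_low for f in accepted])),
        baseline_high=float(np.mean([f.baseline_high for f in accepted])),
        Tm_error=err,
        fit_window=accepted[0].fit_window,
        construct=accepted[0].construct,
        n_replicates=len(accepted),
    )


def delta_tm(fit_a: BoltzmannFit, fit_b: BoltzmannFit) -> tuple[float, float]:
    """ΔTm = Tm(a) − Tm(b) in °C, with error √(e_a² + e_b²)."""
    delta = fit_a.Tm - fit_b.Tm
    ea = fit_a.Tm_error if math.isfinite(fit_a.Tm_error) else 0.0
    eb = fit_b.Tm_error if math.isfinite(fit_b.Tm_error) else 0.0
    return delta, math.hypot(ea, eb)


# ---------------------------------------------------------------------------
# tabular I/O

def read_melt_curves_csv(path: str | Path) -> list[MeltCurve]:
    """Read melt curves from CSV (temperature_C, fluorescence, replicate, construct)."""
    df = pd.read_csv(path)
    if "construct" not in df.columns:
        df["construct"] = ""
    if "replicate" not in df.columns:
        df["replicate"] = 0
    curves = []
    for (construct, rep), grp in df.groupby(["construct", "replicate"], sort=True):
        grp = grp.sort_values("temperature_C")
        curves.append(
            MeltCurve(
                grp["temperature_C"].to_numpy(),
                grp["fluorescence"].to_numpy(),
                replicate_id=int(rep),
                construct=str(construct),
            )
        )
    return curves


def write_melt_curves_csv(curves: Iterable[MeltCurve], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "temperature_C": c.temperatures,
                "fluorescence": c.fluorescence,
                "replicate": c.replicate_id,
                "construct": c.construct,
            }
        )
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def fit_constructs(curves: Iterable[MeltCurve], use_sem: bool = False) -> dict[str, BoltzmannFit]:
    """Fit every curve and aggregate replicates per construct label."""
    by_construct: dict[str, list[BoltzmannFit]] = {}
    for curve in curves:
        by_construct.setdefault(curve.construct, []).append(fit_boltzmann(curve))
    out = {}
    for construct, fits in by_construct.items():
        out[construct] = aggregate_replicates(fits, use_sem=use_sem)
    return out


__all__ = [
    "MeltCurve",
    "BoltzmannFit",
    "boltzmann",
    "truncate_transition",
    "fit_boltzmann",
    "aggregate_replicates",
    "delta_tm",
    "read_melt_curves_csv",
    "write_melt_curves_csv",
    "fit_constructs",
]
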