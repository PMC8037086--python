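"""Estimate R1, R2 and heteronuclear NOE (XNOE) from peak-intensity data.

R1/R2 come from two-parameter single-exponential fits I(t) = I0·exp(−R·t)
to peak heights measured at a series of relaxation delays; their errors
from Monte-Carlo refits of noise-perturbed best-fit curves.  XNOE is the
ratio of saturated to unsaturated peak heights, with errors propagated
from duplicate-spectrum noise estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

#: Default relaxation delay grids (s): the full-length-construct experiment grids.
T1_DELAYS_S = np.array([10, 20, 60, 100, 160, 320, 640, 1280, 1800, 2560]) * 1e-3
T2_DELAYS_S = np.array([10, 30, 50, 70, 90, 110, 130, 150]) * 1e-3
#: Delay grids (s) used for the isolated single-domain constructs.
T1_DELAYS_DOMAIN_S = np.array([10, 40, 80, 160, 320, 640, 1280, 2560]) * 1e-3
T2_DELAYS_DOMAIN_S = np.array([10, 30, 70, 90, 110, 150, 190, 210]) * 1e-3


@dataclass
class RelaxationSeries:
    """One residue's peak intensities across relaxation delays."""

    residue_id: int
    delays: np.ndarray
    intensities: np.ndarray
    replicate_id: int = 0

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.delays.shape != self.intensities.shape:
            raise ValueError("delays and intensities must have the same length")
        if np.any(self.delays < 0):
            raise ValueError("delays must be non-negative")


@dataclass
class RateEstimate:
    """Fitted decay rate (R1 or R2) for one residue."""

    residue_id: int
    rate: float = math.nan
    rate_error: float = 0.0
    I0: float = math.nan
    fit_rss: float = math.nan
    ok: bool = True
    message: str = ""


@dataclass
class XnoeEstimate:
    """Heteronuclear NOE (saturated/unsaturated height ratio) for one residue."""

    residue_id: int
    noe: float = math.nan
    noe_error: float = 0.0
    ok: bool = True
    message: str = ""


def _decay(t: np.ndarray, I0: float, rate: float) -> np.ndarray:
    return I0 * np.exp(-rate * t)


def _decay_jac(t: np.ndarray, I0: float, rate: float) -> np.ndarray:
    e = np.exp(-rate * t)
    return np.column_stack([e, -I0 * t * e])


def _log_linear_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Initial (I0, rate) from a straight-line fit of ln I vs t."""
    mask = y > 0
    if mask.sum() >= 2:
        slope, intercept = np.polyfit(t[mask], np.log(y[mask]), 1)
        rate = -slope
        if rate > 0:
            return math.exp(intercept), rate
    # crude fallback: decay over the observed span
    span = t.max() - t.min() if t.max() > t.min() else 1.0
    return float(np.max(np.abs(y))) or 1.0, 1.0 / span


def fit_exponential(series: RelaxationSeries) -> RateEstimate:
    """Least-squares fit of I(t) = I0·exp(−rate·t).

    Degenerate data (all intensities equal) and non-physical optima
    (rate ≤ 0, non-convergence) return a flagged failure record rather
    than raising; fewer than 4 points is a validation error.
    """
    t, y = series.delays, series.intensities
    if np.all(y == y[0]):
        return RateEstimate(series.residue_id, ok=False, message="degenerate: constant intensities")
    if t.size < 4:
        raise ValueError("at least 4 points are required for exponential fitting")
    I0_0, rate_0 = _log_linear_guess(t, y)
    try:
        popt, _ = curve_fit(_decay, t, y, p0=[I0_0, rate_0], jac=_decay_jac,
                            maxfev=20000, ftol=1e-14, xtol=1e-14, gtol=1e-14)
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        return RateEstimate(series.residue_id, ok=False, message=f"no convergence: {exc}")
    I0, rate = float(popt[0]), float(popt[1])
    if rate <= 0 or not math.isfinite(rate):
        return RateEstimate(series.residue_id, ok=False, message=f"non-physical rate {rate:g}")
    rss = float(np.sum((y - _decay(t, I0, rate)) ** 2))
    return RateEstimate(series.residue_id, rate=rate, I0=I0, fit_rss=rss)


def mc_error(
    series: RelaxationSeries,
    fit: RateEstimate,
    noise_sd: float,
    n_mc: int = 500,
    seed: int = 0,
) -> RateEstimate:
    """Monte-Carlo rate error: sd of rates refit to noise-perturbed best-fit curves.

    Each of the ``n_mc`` synthetic datasets is the best-fit curve evaluated
    on the measured delay grid plus Gaussian noise of standard deviation
    ``noise_sd``; the reported error is the sd (ddof=1) of the refitted rates.
    """
    if not fit.ok:
        raise ValueError("mc_error requires a successful fit")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if n_mc < 100:
        raise ValueError("n_mc must be >= 100")
    rng = np.random.default_rng(seed)
    t = series.delays
    ideal = _decay(t, fit.I0, fit.rate)
    rates = np.empty(n_mc)
    rates.fill(np.nan)
    for k in range(n_mc):
        y = ideal + rng.normal(0.0, noise_sd, size=t.size)
        try:
            popt, _ = curve_fit(_decay, t, y, p0=[fit.I0, fit.rate], maxfev=5000)
            rates[k] = popt[1]
        except RuntimeError:
            continue
    rates = rates[np.isfinite(rates)]
    if rates.size < 2:
        return replace(fit, ok=False, message="Monte-Carlo refits failed")
    return replace(fit, rate_error=float(np.std(rates, ddof=1)))


def estimate_noise_from_duplicates(
    series_a: RelaxationSeries | Sequence[RelaxationSeries],
    series_b: RelaxationSeries | Sequence[RelaxationSeries] = None,
) -> float:
    """Peak-height noise sd from duplicate measurements.

    For paired duplicates the estimate is sd(paired differences)/√2; lists
    of pairs are pooled before taking the sd.  Delay grids must match.
    """
    if isinstance(series_a, RelaxationSeries):
        pairs = [(series_a, series_b)]
    else:
        pairs = list(zip(series_a, series_b))
    diffs = []
    for a, b in pairs:
        if a.delays.shape != b.delays.shape or not np.allclose(a.delays, b.delays):
            raise ValueError("duplicate series must share the same delay grid")
        diffs.append(a.intensities - b.intensities)
    d = np.concatenate(diffs)
    if np.allclose(d, 0.0):
        return 0.0
    return float(np.std(d, ddof=1) / math.sqrt(2.0))


def compute_xnoe(
    sat_heights: Mapping[int, float],
    unsat_heights: Mapping[int, float],
    duplicates: tuple[Mapping[int, float], Mapping[int, float]] | None = None,
) -> list[XnoeEstimate]:
    """Per-residue NOE = saturated/unsaturated height ratio with propagated error.

    ``duplicates`` is an optional second (saturated, unsaturated) pair from
    duplicate spectra; the pooled duplicate differences give the height sd,
    which is pushed through first-order error propagation of the ratio.
    Heights are averaged over duplicates before taking the ratio.
    """
    if set(sat_heights) != set(unsat_heights):
        raise ValueError("saturated and unsaturated residue sets must match")
    residues = sorted(sat_heights)

    sat = {r: float(sat_heights[r]) for r in residues}
    unsat = {r: float(unsat_heights[r]) for r in residues}
    height_sd = 0.0
    if duplicates is not None:
        sat2, unsat2 = duplicates
        if set(sat2) != set(residues) or set(unsat2) != set(residues):
            raise ValueError("duplicate residue sets must match the primary spectra")
        d = np.array(
            [sat[r] - sat2[r] for r in residues] + [unsat[r] - unsat2[r] for r in residues]
        )
        height_sd = 0.0 if np.allclose(d, 0) else float(np.std(d, ddof=1) / math.sqrt(2.0))
        sat = {r: 0.5 * (sat[r] + sat2[r]) for r in residues}
        unsat = {r: 0.5 * (unsat[r] + unsat2[r]) for r in residues}

    out = []
    for r in residues:
        if unsat[r] <= 0:
            out.append(XnoeEstimate(r, ok=False, message="non-positive unsaturated height"))
            continue
        noe = sat[r] / unsat[r]
        err = 0.0
        if height_sd > 0 and sat[r] != 0:
            err = abs(noe) * math.hypot(height_sd / sat[r], height_sd / unsat[r])
        out.append(XnoeEstimate(r, noe=noe, noe_error=err))
    return out


# ---------------------------------------------------------------------------
# tabular I/O

def read_delay_series_csv(path: str | Path) -> list[RelaxationSeries]:
    """Read a delay-series table (residue, delay_s, intensity, replicate)."""
    df = pd.read_csv(path)
    out = []
    for (res, rep), grp in df.groupby(["residue", "replicate"], sort=True):
        out.append(
            RelaxationSeries(
                residue_id=int(res),
                delays=grp["delay_s"].to_numpy(),
                intensities=grp["intensity"].to_numpy(),
                replicate_id=int(rep),
            )
        )
    return out


def write_rates_csv(
    path: str | Path,
    r1: Iterable[RateEstimate] = (),
    r2: Iterable[RateEstimate] = (),
    xnoe: Iterable[XnoeEstimate] = (),
) -> pd.DataFrame:
    """Merge R1/R2/NOE estimates into one per-residue table and write CSV."""
    frames = []
    for name, ests in (("R1", r1), ("R2", r2)):
        rows = [
            {"residue": e.residue_id, name: e.rate, f"{name}_err": e.rate_error}
            for e in ests
            if e.ok
        ]
        if rows:
            frames.append(pd.DataFrame(rows).set_index("residue"))
    rows = [
        {"residue": e.residue_id, "NOE": e.noe, "NOE_err": e.noe_error} for e in xnoe if e.ok
    ]
    if rows:
        frames.append(pd.DataFrame(rows).set_index("residue"))
    if not frames:
        raise ValueError("no successful estimates to write")
    df = pd.concat(frames, axis=1).sort_index()
    df.to_csv(path, index_label="residue")
    return df.reset_index()


__all__ = [
    "RelaxationSeries",
    "RateEstimate",
    "XnoeEstimate",
    "fit_exponential",
    "mc_error",
    "estimate_noise_from_duplicates",
    "compute_xnoe",
    "read_delay_series_csv",
    "write_rates_csv",
    "T1_DELAYS_S",
    "T2_DELAYS_S",
    "T1_DELAYS_DOMAIN_S",
    "T2_DELAYS_DOMAIN_S",
]
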