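"""Melt-curve analysis: -dF/dT derivative traces, peak calling, gene detection.

A SYBR melt curve is a fluorescence-vs-temperature trace; amplicons appear as
sigmoidal drops whose midpoint is the melting temperature (Tm).  Genotyping
reads the negative first derivative: each amplicon gives a -dF/dT peak at its
Tm.  A gene is called present when a peak falls within a Tm tolerance window
of the gene's expected Tm; GAPDH serves as the amplification control and a
GAPDH-negative sample is reported "no result" rather than scored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

from .config import SEX_PANEL, ConfigError

__all__ = [
    "MeltPeak",
    "LocusDetection",
    "negative_derivative",
    "call_peaks",
    "detect_gene",
    "call_plate",
]


@dataclass(frozen=True)
class MeltPeak:
    """A -dF/dT local maximum: location (Tm), height and prominence."""
    tm: float
    height: float
    prominence: float


@dataclass(frozen=True)
class LocusDetection:
    """Present/absent call for one gene in one sample."""
    embryo_id: str
    gene: str
    detected: bool
    tm_observed: Optional[float]
    qc_pass: bool = True


def _validate_grid(temps: np.ndarray, fluor: np.ndarray) -> None:
    if temps.ndim != 1 or fluor.ndim != 1 or temps.size != fluor.size:
        raise ValueError("temperature and fluorescence must be 1-D and equal length")
    if temps.size < 2 or np.any(np.diff(temps) <= 0):
        raise ValueError("temperature grid must be strictly increasing")


def negative_derivative(temps, fluor, smooth_window: int = 7) -> np.ndarray:
    """Smoothed -dF/dT on the input grid.

    Uses quadratic Savitzky-Golay smoothing-differentiation over
    ``smooth_window`` points (odd, >= 1); endpoint windows are handled by
    one-sided polynomial fits.  Windows too short for a quadratic fit, or
    non-uniform grids, fall back to central finite differences.
    """
    temps = np.asarray(temps, dtype=float)
    fluor = np.asarray(fluor, dtype=float)
    _validate_grid(temps, fluor)
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError(f"smooth_window must be odd and >= 1, got {smooth_window}")
    if smooth_window >= temps.size:
        raise ValueError("smooth_window must be smaller than the grid length")

    steps = np.diff(temps)
    uniform = np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9)
    if smooth_window >= 5 and uniform:
        deriv = savgol_filter(fluor, smooth_window, polyorder=2, deriv=1,
                              delta=steps[0], mode="interp")
    else:
        deriv = np.gradient(fluor, temps)
    return -deriv


def call_peaks(temps, deriv, min_height: float = 0.0,
               min_prominence: float = 0.0) -> List[MeltPeak]:
    """Local maxima of a -dF/dT trace above height and prominence thresholds.

    Returns peaks in ascending Tm order.
    """
    temps = np.asarray(temps, dtype=float)
    deriv = np.asarray(deriv, dtype=float)
    if min_height < 0 or min_prominence < 0:
        raise ValueError("thresholds must be >= 0")
    idx, props = find_peaks(deriv, height=min_height,
                            prominence=max(min_prominence, 1e-12))
    return [MeltPeak(tm=float(temps[i]),
                     height=float(props["peak_heights"][j]),
                     prominence=float(props["prominences"][j]))
            for j, i in enumerate(idx)]


def detect_gene(temps, fluor, embryo_id: str, gene: str,
                expected_tm: Optional[float], tol: float = 1.5,
                min_height: float = 0.0, min_prominence: float = 0.0,
                smooth_window: int = 7, qc_pass: bool = True) -> LocusDetection:
    """Call one gene present/absent from its melt curve.

    The gene is detected iff some -dF/dT peak lies within ``tol`` of the
    gene's expected Tm; off-target products outside the window are ignored.
    ``tm_observed`` is the nearest matching peak.
    """
    if expected_tm is None:
        raise ConfigError(f"no expected Tm configured for gene {gene!r}")
    deriv = negative_derivative(temps, fluor, smooth_window)
    peaks = call_peaks(temps, deriv, min_height, min_prominence)
    matches = [p for p in peaks if abs(p.tm - expected_tm) <= tol]
    if matches:
        best = min(matches, key=lambda p: abs(p.tm - expected_tm))
        return LocusDetection(embryo_id, gene, True, best.tm, qc_pass)
    return LocusDetection(embryo_id, gene, False, None, qc_pass)


def call_plate(curves: pd.DataFrame, expected_tm: Dict[str, float],
               tol: float = 1.5, min_peak_frac: float = 0.05,
               smooth_window: int = 7,
               genes: Sequence[str] = SEX_PANEL) -> pd.DataFrame:
    """Score every (embryo, gene) melt curve on a plate.

    ``curves`` is long-format ``(embryo_id, gene, temperature_c,
    fluorescence)``.  The peak-height threshold is ``min_peak_frac`` times the
    plate-wide maximum -dF/dT, so an empty plate cannot self-calibrate to
    noise.  Samples whose GAPDH curve shows no peak get ``qc_pass = False``
    (no amplification control -> "no result" downstream).

    Returns ``(embryo_id, gene, detected, tm_observed, qc_pass)``.
    """
    missing = [g for g in genes if g not in expected_tm]
    if missing:
        raise ConfigError(f"no expected Tm configured for genes: {missing}")

    derivs = {}
    plate_max = 0.0
    for (embryo, gene), grp in curves.groupby(["embryo_id", "gene"], sort=False):
        t = grp["temperature_c"].to_numpy()
        d = negative_derivative(t, grp["fluorescence"].to_numpy(), smooth_window)
        derivs[(embryo, gene)] = (t, d)
        plate_max = max(plate_max, float(d.max(initial=0.0)))
    min_height = min_peak_frac * plate_max

    rows = []
    embryos = curves["embryo_id"].drop_duplicates().tolist()
    gapdh_ok = {}
    for embryo in embryos:
        key = (embryo, "GAPDH")
        if key in derivs:
            t, d = derivs[key]
            peaks = call_peaks(t, d, min_height)
            gapdh_ok[embryo] = any(abs(p.tm - expected_tm["GAPDH"]) <= tol
                                   for p in peaks)
        else:
            gapdh_ok[embryo] = True  # no control well on this plate layout
    for embryo in embryos:
        for gene in genes:
            key = (embryo, gene)
            if key not in derivs:
                continue
            t, d = derivs[key]
            peaks = call_peaks(t, d, min_height)
            matches = [p for p in peaks if abs(p.tm - expected_tm[gene]) <= tol]
            best = (min(matches, key=lambda p: abs(p.tm - expected_tm[gene]))
                    if matches else None)
            rows.append({
                "embryo_id": embryo,
                "gene": gene,
                "detected": best is not None,
                "tm_observed": best.tm if best else np.nan,
                "qc_pass": gapdh_ok[embryo],
            })
    return pd.DataFrame(rows, columns=["embryo_id", "gene", "detected",
                                       "tm_observed", "qc_pass"])
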