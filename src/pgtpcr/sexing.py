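"""Embryo sex calling by Y-marker detection and amelogenin fragment analysis.

Two independent procedures are implemented:

* **GSD index** — the combined call from melt-curve detection of the Y-linked
  markers SRY (single copy) and DYS14 (multicopy, within TSPY).  Any Y-marker
  signal suggests a male embryo; a logistic regression of CGH sex on the two
  detection indicators supplies per-category male probabilities.  In *index*
  mode a DYS14-only sample is called male; in *clinical* mode it is left
  unclassified (DYS14 false alleles are too common to act on alone).
* **Amelogenin (AMEL)** — fragment-length typing of the AMELX (104 bp) /
  AMELY (110 bp) amplicons.  Three rules are scored per sample: AMELY peak
  presence, AMELY peak height above a cutoff, and the X/Y height ratio below
  a cutoff.

Both report "no result"/"qc_fail" rather than "female" when the
amplification control is missing: absence of signal in a failed sample is
not evidence of absence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import AmelModelParams, CallerCutoffs
from . import refdata

__all__ = [
    "GsdResult",
    "CategoryLogisticFit",
    "AmelPeakSet",
    "AmelResult",
    "fit_category_logistic",
    "reference_fit",
    "gsd_classify",
    "call_sex_gsd",
    "extract_amel_peaks",
    "amel_classify",
    "call_sex_amel",
]

GSD_CATEGORIES = ("neither", "dys14_only", "sry_only", "both")


def _category(sry: bool, dys14: bool) -> str:
    if sry and dys14:
        return "both"
    if sry:
        return "sry_only"
    if dys14:
        return "dys14_only"
    return "neither"


# ---------------------------------------------------------------------------
# Logistic regression of sex on SRY/DYS14 detection indicators
# ---------------------------------------------------------------------------

@dataclass
class CategoryLogisticFit:
    """Fitted P(male) per detection category with per-marker odds ratios.

    With all three observed categories the two-indicator model is saturated,
    so fitted probabilities equal the empirical male proportions.  The
    ``sry_only`` category is never observed in the reference cohort; its
    probability is a model extrapolation and flagged as such.
    """

    p_male: Dict[str, float]
    coefficients: Dict[str, float]
    odds_ratios: Dict[str, Tuple[float, float, float]]  # OR, lo95, hi95
    converged: bool = True
    separation: bool = False
    extrapolated: Tuple[str, ...] = ("sry_only",)
    method: str = "irls"


def fit_category_logistic(counts: pd.DataFrame,
                          tol: float = 1e-8) -> CategoryLogisticFit:
    """Fit logistic regression of male status on SRY/DYS14 indicators.

    ``counts`` needs columns ``sry``, ``dys14`` (booleans) and ``n_male``,
    ``n_female`` per category.  Fitting is IRLS via a binomial GLM.  With
    fewer than two categories containing both outcomes the model falls back
    to empirical proportions (with a warning); complete separation is
    reported as an infinite odds ratio with ``separation=True``.
    """
    counts = counts.copy()
    for col in ("sry", "dys14", "n_male", "n_female"):
        if col not in counts.columns:
            raise ValueError(f"counts table missing column {col!r}")
    counts["n"] = counts["n_male"] + counts["n_female"]
    counts = counts[counts["n"] > 0]
    if counts.empty:
        raise ValueError("counts table has no observations")

    informative = int(((counts["n_male"] > 0) & (counts["n_female"] > 0)).sum())
    empirical = {
        _category(bool(r.sry), bool(r.dys14)): r.n_male / r.n
        for r in counts.itertuples()
    }

    if informative < 2 or len(counts) < 2:
        warnings.warn("too few informative detection categories; "
                      "reporting empirical proportions", stacklevel=2)
        return CategoryLogisticFit(
            p_male=empirical, coefficients={},
            odds_ratios={}, converged=True, separation=False,
            extrapolated=tuple(c for c in GSD_CATEGORIES if c not in empirical),
            method="empirical",
        )

    endog = counts[["n_male", "n_female"]].to_numpy(float)
    exog = sm.add_constant(
        counts[["sry", "dys14"]].astype(float).to_numpy(), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separation warnings handled below
        model = sm.GLM(endog, exog, family=sm.families.Binomial())
        res = model.fit(tol=tol, maxiter=200)

    names = ["const", "sry", "dys14"]
    coef = dict(zip(names, res.params))
    separation = bool(np.any(np.abs(res.params) > 15) or not np.all(np.isfinite(res.bse)))
    ors: Dict[str, Tuple[float, float, float]] = {}
    for i, name in enumerate(names[1:], start=1):
        b, se = res.params[i], res.bse[i]
        if not np.isfinite(se) or abs(b) > 15:
            ors[name] = (float("inf"), float("nan"), float("nan"))
        else:
            ors[name] = (float(np.exp(b)),
                         float(np.exp(b - 1.96 * se)),
                         float(np.exp(b + 1.96 * se)))

    def predict(sry: float, dys14: float) -> float:
        eta = coef["const"] + coef["sry"] * sry + coef["dys14"] * dys14
        return float(1.0 / (1.0 + np.exp(-eta)))

    p_male = {
        "neither": predict(0, 0),
        "dys14_only": predict(0, 1),
        "sry_only": predict(1, 0),
        "both": predict(1, 1),
    }
    return CategoryLogisticFit(
        p_male=p_male, coefficients=coef, odds_ratios=ors,
        converged=bool(res.converged), separation=separation,
        extrapolated=tuple(c for c in GSD_CATEGORIES if c not in empirical),
    )


def reference_fit() -> CategoryLogisticFit:
    """Logistic fit on the reference validation-cohort category counts."""
    return fit_category_logistic(refdata.GSD_CATEGORY_COUNTS)


# ---------------------------------------------------------------------------
# GSD index classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GsdResult:
    embryo_id: str
    category: str        # neither | dys14_only | sry_only | both | qc_fail
    call: str            # female | male | unclassified | no_result
    p_male: float


def gsd_classify(embryo_id: str, sry_detected: Optional[bool],
                 dys14_detected: Optional[bool], gapdh_detected: bool,
                 mode: str = "index",
                 fit: Optional[CategoryLogisticFit] = None) -> GsdResult:
    """Sex call from the SRY/DYS14 detection pair.

    A pure function of the two booleans (plus the GAPDH QC gate): any
    Y-marker signal means male under the index, "neither" means female, and
    DYS14-only is left unclassified in clinical mode.  ``p_male`` is looked
    up from the category logistic fit (reference-cohort fit by default).
    """
    if mode not in ("index", "clinical"):
        raise ValueError(f"mode must be 'index' or 'clinical', got {mode!r}")
    if not gapdh_detected:
        return GsdResult(embryo_id, "qc_fail", "no_result", float("nan"))
    if sry_detected is None or dys14_detected is None:
        raise ValueError(f"missing SRY or DYS14 record for {embryo_id!r}")
    fit = reference_fit() if fit is None else fit
    category = _category(bool(sry_detected), bool(dys14_detected))
    p_male = fit.p_male.get(category, float("nan"))
    if category == "neither":
        call = "female"
    elif category == "both":
        call = "male"
    else:  # single-marker categories
        call = "male" if mode == "index" else "unclassified"
    return GsdResult(embryo_id, category, call, p_male)


def call_sex_gsd(detections: pd.DataFrame, mode: str = "index",
                 fit: Optional[CategoryLogisticFit] = None) -> pd.DataFrame:
    """Classify every embryo in a wide detection table.

    ``detections`` needs boolean columns ``SRY``, ``DYS14`` and ``GAPDH``
    (GAPDH doubles as the QC gate).  Returns
    ``(embryo_id, category, call, p_male)``.
    """
    for col in ("SRY", "DYS14", "GAPDH"):
        if col not in detections.columns:
            raise ValueError(f"detections table missing column {col!r}")
    fit = reference_fit() if fit is None else fit
    rows = [gsd_classify(r.embryo_id, bool(r.SRY), bool(r.DYS14),
                         bool(r.GAPDH), mode, fit)
            for r in detections.itertuples()]
    return pd.DataFrame([r.__dict__ for r in rows])


# ---------------------------------------------------------------------------
# Amelogenin fragment analysis
# ---------------------------------------------------------------------------

@dataclass
class AmelPeakSet:
    """Per-sample fragment peaks with derived AMELX/AMELY heights and ratio.

    ``amelx_height``/``amely_height`` are the tallest peaks within the size
    tolerance of 104/110 bp (0 when absent); ``ratio`` is X over Y with the
    configured noise floor as denominator when AMELY is missing, so female
    ratios are large but finite.
    """

    embryo_id: str
    peaks: List[Tuple[float, float]] = field(default_factory=list)
    amelx_height: float = 0.0
    amely_height: float = 0.0
    ratio: float = 0.0


@dataclass(frozen=True)
class AmelResult:
    embryo_id: str
    call_by_presence: str  # male | female | qc_fail
    call_by_height: str    # male | female | qc_fail
    call_by_ratio: str     # male | female | qc_fail
    amelx_height: float
    amely_height: float
    ratio: float


def extract_amel_peaks(embryo_id: str,
                       peaks: Sequence[Tuple[float, float]],
                       size_x: float = 104.0, size_y: float = 110.0,
                       size_tol: float = 1.0,
                       noise_floor: float = 1.0) -> AmelPeakSet:
    """Reduce a raw peak list to AMELX/AMELY heights and the X/Y ratio."""
    clean: List[Tuple[float, float]] = []
    bad: List[int] = []
    for i, peak in enumerate(peaks):
        try:
            size, height = float(peak[0]), float(peak[1])
        except (TypeError, ValueError, IndexError):
            bad.append(i)
            continue
        if not np.isfinite(size) or not np.isfinite(height) or height < 0:
            bad.append(i)
            continue
        clean.append((size, height))
    if bad:
        raise ValueError(f"malformed peak records for {embryo_id!r} at rows {bad}")

    def tallest(target: float) -> float:
        hits = [h for s, h in clean if abs(s - target) <= size_tol]
        return max(hits) if hits else 0.0

    x, y = tallest(size_x), tallest(size_y)
    return AmelPeakSet(embryo_id=embryo_id, peaks=clean,
                       amelx_height=x, amely_height=y,
                       ratio=x / max(y, noise_floor))


def amel_classify(peakset: AmelPeakSet,
                  cutoffs: Optional[CallerCutoffs] = None) -> AmelResult:
    """Score the three amelogenin sex rules for one sample.

    * presence: any AMELY peak => male;
    * height: AMELY height strictly above ``cutoffs.amely_height`` => male
      (a boundary tie is female);
    * ratio: X/Y ratio <= ``cutoffs.xy_ratio`` => male.

    A sample with no AMELX peak failed amplification and is ``qc_fail`` under
    all three rules — not female.
    """
    cutoffs = cutoffs or CallerCutoffs()
    if peakset.amelx_height <= 0:
        return AmelResult(peakset.embryo_id, "qc_fail", "qc_fail", "qc_fail",
                          0.0, peakset.amely_height, peakset.ratio)
    by_presence = "male" if peakset.amely_height > 0 else "female"
    by_height = "male" if peakset.amely_height > cutoffs.amely_height else "female"
    by_ratio = "male" if peakset.ratio <= cutoffs.xy_ratio else "female"
    return AmelResult(peakset.embryo_id, by_presence, by_height, by_ratio,
                      peakset.amelx_height, peakset.amely_height, peakset.ratio)


def call_sex_amel(peak_table: pd.DataFrame,
                  params: Optional[AmelModelParams] = None,
                  cutoffs: Optional[CallerCutoffs] = None) -> pd.DataFrame:
    """Classify every sample in a long fragment-analysis peak table.

    ``peak_table`` is ``(embryo_id, size_bp, height_rfu)``.  Returns one row
    per embryo with the three calls and the derived heights/ratio.
    """
    params = params or AmelModelParams()
    cutoffs = cutoffs or CallerCutoffs()
    for col in ("embryo_id", "size_bp", "height_rfu"):
        if col not in peak_table.columns:
            raise ValueError(f"peak table missing column {col!r}")
    rows = []
    for embryo, grp in peak_table.groupby("embryo_id", sort=False):
        ps = extract_amel_peaks(
            embryo, list(zip(grp["size_bp"], grp["height_rfu"])),
            size_x=params.size_x, size_y=params.size_y,
            size_tol=cutoffs.size_tol_bp, noise_floor=params.noise_floor)
        rows.append(amel_classify(ps, cutoffs).__dict__)
    return pd.DataFrame(rows)
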