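"""Delta-Ct trisomy 18/21 calling with standard-curve QC and Ct exclusion.

Each sample is run as a three-point dilution series (3.75, 7.5, 15 ng WGA)
for the chromosome-21 target TTC3, the chromosome-18 target RPL17 and the
copy-neutral reference HSDB.  The Ct-vs-log10(mass) slope of each gene must
fall in the -3.3 +/- 0.4 acceptance band (comparable amplification
efficiency); the analysis value is the 15 ng Ct.  A chromosome gain adds
template for its target only, lowering the target's delta-Ct
(Ct_target - Ct_HSDB), so the calls are

* trisomy 21 positive  iff  delta-Ct(TTC3)  <= 3.85 cycles,
* trisomy 18 positive  iff  delta-Ct(RPL17) <= 0.985 cycles,

with a raw target Ct above 30 (too little template to quantify) or a failed
standard curve downgrading that gene's call to "excluded" — an uncallable
sample, never a forced negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .config import CT_TARGETS, CallerCutoffs

__all__ = [
    "StandardCurveQC",
    "TrisomyCall",
    "standard_curve_qc",
    "delta_ct",
    "call_trisomy",
    "call_trisomy_cohort",
]

ANALYSIS_MASS_NG = 15.0
TARGET_CUTOFF_ATTR = {"TTC3": "ttc3_delta_ct", "RPL17": "rpl17_delta_ct"}
TARGET_CALL = {"TTC3": "t21", "RPL17": "t18"}


@dataclass(frozen=True)
class StandardCurveQC:
    gene: str
    slope: float       # cycles per log10(ng)
    passed: bool


@dataclass
class TrisomyCall:
    embryo_id: str
    delta_ct_ttc3: float
    delta_ct_rpl17: float
    call_t21: str      # positive | negative | excluded
    call_t18: str
    reason: str = ""


def _panel_ct(panel: pd.DataFrame, gene: str, mass: float) -> float:
    sel = panel[(panel["gene"] == gene)
                & (np.isclose(panel["input_ng"].astype(float), mass))]
    if sel.empty:
        return float("nan")
    return float(sel["ct"].iloc[-1])


def standard_curve_qc(panel: pd.DataFrame, gene: str,
                      cutoffs: Optional[CallerCutoffs] = None) -> StandardCurveQC:
    """OLS slope of Ct on log10(input mass) and its acceptance-band verdict.

    ``panel`` is long-format ``(gene, input_ng, ct)`` for one sample; at
    least two masses are required.
    """
    cutoffs = cutoffs or CallerCutoffs()
    sel = panel[panel["gene"] == gene]
    masses = sel["input_ng"].to_numpy(float)
    cts = sel["ct"].to_numpy(float)
    keep = np.isfinite(masses) & np.isfinite(cts)
    masses, cts = masses[keep], cts[keep]
    if np.unique(masses).size < 2:
        raise ValueError(f"standard curve for {gene!r} needs Ct at >= 2 masses")
    slope = float(np.polyfit(np.log10(masses), cts, 1)[0])
    passed = abs(slope - cutoffs.qc_slope_center) <= cutoffs.qc_slope_tol
    return StandardCurveQC(gene=gene, slope=slope, passed=bool(passed))


def delta_ct(panel: pd.DataFrame, target: str,
             reference: str = "HSDB",
             mass: float = ANALYSIS_MASS_NG) -> float:
    """Ct_target - Ct_reference at the analysis mass (15 ng by default)."""
    ct_t = _panel_ct(panel, target, mass)
    ct_r = _panel_ct(panel, reference, mass)
    if not np.isfinite(ct_r):
        raise ValueError(f"missing reference ({reference}) Ct at {mass} ng")
    if not np.isfinite(ct_t):
        raise ValueError(f"missing {target} Ct at {mass} ng")
    return ct_t - ct_r


def call_trisomy(panel: pd.DataFrame, embryo_id: str = "",
                 cutoffs: Optional[CallerCutoffs] = None,
                 qc: Optional[Dict[str, StandardCurveQC]] = None,
                 scale: str = "delta_ct") -> TrisomyCall:
    """Score one sample's Ct panel for trisomy 18 and 21.

    ``scale`` selects whether the cutoffs compare target-minus-reference
    delta-Ct (default) or the raw target Ct at the analysis mass.  Exclusion
    (raw target Ct > ``cutoffs.exclusion_ct``, or failed standard-curve QC
    for the target or reference gene) is always decided on raw Ct.  A
    both-positive sample keeps both flags set; double aneuploidy is not
    adjudicated here.
    """
    cutoffs = cutoffs or CallerCutoffs()
    if scale not in ("delta_ct", "raw_ct"):
        raise ValueError(f"scale must be 'delta_ct' or 'raw_ct', got {scale!r}")
    qc = qc or {}
    reasons = []
    values: Dict[str, float] = {}
    calls: Dict[str, str] = {}
    ref_qc = qc.get("HSDB")
    for target in CT_TARGETS:
        raw = _panel_ct(panel, target, ANALYSIS_MASS_NG)
        try:
            d = delta_ct(panel, target)
        except ValueError:
            d = float("nan")
        values[target] = d if scale == "delta_ct" else raw
        gene_qc = qc.get(target)
        if not np.isfinite(raw) or not np.isfinite(values[target]):
            calls[target] = "excluded"
            reasons.append(f"{target}: missing Ct")
        elif raw > cutoffs.exclusion_ct:
            calls[target] = "excluded"
            reasons.append(f"{target}: raw Ct {raw:.2f} > {cutoffs.exclusion_ct:g}")
        elif (gene_qc is not None and not gene_qc.passed) or \
             (ref_qc is not None and not ref_qc.passed):
            calls[target] = "excluded"
            failed = target if (gene_qc and not gene_qc.passed) else "HSDB"
            reasons.append(f"{target}: standard-curve QC failed ({failed})")
        else:
            cut = getattr(cutoffs, TARGET_CUTOFF_ATTR[target])
            # "<= cutoff => positive", with a guard so a value equal to the
            # cutoff up to float rounding stays on the positive side
            calls[target] = "positive" if values[target] <= cut + 1e-9 else "negative"
    return TrisomyCall(
        embryo_id=embryo_id,
        delta_ct_ttc3=values["TTC3"],
        delta_ct_rpl17=values["RPL17"],
        call_t21=calls["TTC3"],
        call_t18=calls["RPL17"],
        reason="; ".join(reasons),
    )


def call_trisomy_cohort(ct_table: pd.DataFrame,
                        cutoffs: Optional[CallerCutoffs] = None,
                        scale: str = "delta_ct",
                        run_qc: bool = True) -> pd.DataFrame:
    """Call every embryo in a long Ct table.

    ``ct_table`` is ``(embryo_id, gene, input_ng, ct)``.  Returns one row per
    embryo with delta-Ct values, per-gene standard-curve slopes, both calls
    and an exclusion reason.
    """
    cutoffs = cutoffs or CallerCutoffs()
    rows = []
    for embryo, panel in ct_table.groupby("embryo_id", sort=False):
        qc: Dict[str, StandardCurveQC] = {}
        if run_qc:
            for gene in ("TTC3", "RPL17", "HSDB"):
                try:
                    qc[gene] = standard_curve_qc(panel, gene, cutoffs)
                except ValueError:
                    pass  # single-mass panel: no slope QC possible
        call = call_trisomy(panel, embryo, cutoffs, qc, scale)
        rows.append({
            "embryo_id": embryo,
            "delta_ct_ttc3": call.delta_ct_ttc3,
            "delta_ct_rpl17": call.delta_ct_rpl17,
            "slope_ttc3": qc["TTC3"].slope if "TTC3" in qc else np.nan,
            "slope_rpl17": qc["RPL17"].slope if "RPL17" in qc else np.nan,
            "slope_hsdb": qc["HSDB"].slope if "HSDB" in qc else np.nan,
            "call_t21": call.call_t21,
            "call_t18": call.call_t18,
            "reason": call.reason,
        })
    return pd.DataFrame(rows)
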