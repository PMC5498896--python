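"""Diagnostic-test evaluation statistics, implemented from first principles.

Confusion matrices against a reference standard (CGH), accuracy, sensitivity
and specificity, the Youden index J = sens + spec - 1 with an optimal-cutoff
search, Cohen's chance-corrected kappa, the odds ratio with a Woolf
(log-method) 95% CI, the Mann-Whitney AUC with the Hanley-McNeil standard
error, and single-cell WGA error rates (allele drop-out, false alleles).

Conventions:

* ADO = misses / carriers.  FA is reported two ways: ``fa`` divides spurious
  detections by *all* analyzed samples (the convention of the reference
  study's printed rates) and ``fa_conditional`` divides by non-carriers (the
  per-sample false-allele probability a generative model controls).
* Cutoff searches scan midpoints between adjacent distinct scores; ties are
  broken toward higher sensitivity, then toward the lower cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "ConfusionMatrix",
    "ErrorRates",
    "DiagnosticSummary",
    "confusion",
    "accuracy_kappa",
    "sensitivity_specificity",
    "youden_from_cm",
    "odds_ratio",
    "roc_auc",
    "youden_optimal_cutoff",
    "ado_fa_rates",
    "summarize",
]

EXCLUDED_CALLS = frozenset({"unclassified", "no_result", "excluded", "qc_fail"})


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 cross-tabulation of calls against truth for one positive class."""

    tp: int
    fp: int
    fn: int
    tn: int
    n_excluded: int = 0
    excluded_counts: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix cells must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def transpose(self) -> "ConfusionMatrix":
        return ConfusionMatrix(tp=self.tp, fp=self.fn, fn=self.fp, tn=self.tn)

    def swap_positive(self) -> "ConfusionMatrix":
        """Relabel the positive class on both margins (OR is invariant)."""
        return ConfusionMatrix(tp=self.tn, fp=self.fn, fn=self.fp, tn=self.tp)

    def flip_calls(self) -> "ConfusionMatrix":
        """Invert the test's polarity only; this maps OR to 1/OR."""
        return ConfusionMatrix(tp=self.fn, fp=self.tn, fn=self.tp, tn=self.fp)


def confusion(truth: Sequence, calls: Sequence, positive_class) -> ConfusionMatrix:
    """Cross-tabulate calls against truth labels.

    Calls in ``{unclassified, no_result, excluded, qc_fail}`` are tallied
    separately (``n_excluded``) and left out of the matrix.  Truth labels
    must be binary against ``positive_class``.
    """
    truth = list(truth)
    calls = list(calls)
    if len(truth) != len(calls):
        raise ValueError(f"length mismatch: {len(truth)} truths vs {len(calls)} calls")
    tp = fp = fn = tn = 0
    excluded: Dict[str, int] = {}
    for t, c in zip(truth, calls):
        if c in EXCLUDED_CALLS or (isinstance(c, float) and math.isnan(c)):
            key = str(c)
            excluded[key] = excluded.get(key, 0) + 1
            continue
        t_pos = t == positive_class
        c_pos = c == positive_class
        if c_pos and t_pos:
            tp += 1
        elif c_pos:
            fp += 1
        elif t_pos:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn,
                           n_excluded=sum(excluded.values()),
                           excluded_counts=excluded)


def accuracy_kappa(cm: ConfusionMatrix) -> Tuple[float, float]:
    """Overall accuracy and Cohen's kappa.

    kappa = (p_o - p_e) / (1 - p_e) with expected agreement p_e from the
    marginal products.  Degenerate marginals (p_e = 1) yield NaN kappa.
    """
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = (cm.tp + cm.tn) / n
    p_e = ((cm.tp + cm.fn) * (cm.tp + cm.fp)
           + (cm.tn + cm.fp) * (cm.tn + cm.fn)) / n ** 2
    if abs(1.0 - p_e) < 1e-15:
        return p_o, float("nan")
    return p_o, (p_o - p_e) / (1.0 - p_e)


def sensitivity_specificity(cm: ConfusionMatrix) -> Tuple[float, float]:
    sens = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) else float("nan")
    spec = cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) else float("nan")
    return sens, spec


def youden_from_cm(cm: ConfusionMatrix) -> float:
    sens, spec = sensitivity_specificity(cm)
    return sens + spec - 1.0


def odds_ratio(cm: ConfusionMatrix, correction: bool = True
               ) -> Tuple[float, Tuple[float, float], float]:
    """Odds ratio with Woolf 95% CI and a Wald p-value.

    OR = (tn * tp) / (fp * fn): concordant over discordant cell products.
    With any zero cell the Haldane-Anscombe +0.5 correction is applied when
    ``correction`` is enabled, otherwise a zero cell raises.
    """
    cells = [cm.tn, cm.fp, cm.tp, cm.fn]
    if min(cells) == 0:
        if not correction:
            raise ValueError("zero cell in confusion matrix; enable the "
                             "Haldane-Anscombe correction")
        cells = [c + 0.5 for c in cells]
    tn, fp, tp, fn = cells
    or_ = (tn * tp) / (fp * fn)
    se = math.sqrt(sum(1.0 / c for c in cells))
    lo = math.exp(math.log(or_) - 1.96 * se)
    hi = math.exp(math.log(or_) + 1.96 * se)
    z = math.log(or_) / se
    p = 2.0 * float(norm.sf(abs(z)))
    return or_, (lo, hi), p


def _oriented_scores(scores, labels, positive_class, positive_low: bool
                     ) -> Tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    is_pos = np.asarray([l == positive_class for l in labels])
    if is_pos.all() or (~is_pos).all():
        raise ValueError("both classes must be present")
    if scores.size != is_pos.size:
        raise ValueError("scores and labels must have equal length")
    return (-scores if positive_low else scores), is_pos


def roc_auc(scores, labels, positive_class=True, positive_low: bool = False
            ) -> Tuple[float, Tuple[float, float], float]:
    """Mann-Whitney AUC with Hanley-McNeil 95% CI and p-value against 0.5.

    ``positive_low=True`` declares that low scores indicate the positive
    class (as for delta-Ct, where trisomy lowers the value).  Ties contribute
    1/2 via midranks.  The p-value is a normal approximation using the
    Hanley-McNeil SE at the observed AUC (Wald-type).
    """
    s, is_pos = _oriented_scores(scores, labels, positive_class, positive_low)
    n_pos, n_neg = int(is_pos.sum()), int((~is_pos).sum())
    ranks = rankdata(s)  # midranks handle ties
    u = ranks[is_pos].sum() - n_pos * (n_pos + 1) / 2.0
    auc = u / (n_pos * n_neg)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc ** 2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc ** 2)
           + (n_neg - 1) * (q2 - auc ** 2)) / (n_pos * n_neg)
    se = math.sqrt(max(var, 0.0))
    lo, hi = auc - 1.96 * se, auc + 1.96 * se
    if se > 0:
        p = 2.0 * float(norm.sf(abs(auc - 0.5) / se))
    else:
        p = 0.0 if auc != 0.5 else 1.0
    return float(auc), (lo, hi), p


def youden_optimal_cutoff(scores, labels, positive_class=True,
                          positive_low: bool = False
                          ) -> Tuple[float, float, float, float]:
    """Cutoff maximizing J over midpoints between adjacent distinct scores.

    Classification is "positive iff score <= cutoff" when ``positive_low``
    and ">=" otherwise.  Ties in J are broken toward higher sensitivity,
    then toward the lower cutoff.  Returns (cutoff, J, sens, spec) with the
    cutoff on the original score scale.
    """
    s, is_pos = _oriented_scores(scores, labels, positive_class, positive_low)
    distinct = np.unique(s)
    # candidate thresholds: midpoints, plus outer guards so "all positive" /
    # "all negative" are reachable
    mids = (distinct[:-1] + distinct[1:]) / 2.0 if distinct.size > 1 else np.array([])
    candidates = np.concatenate(([distinct[0] - 1.0], mids, [distinct[-1] + 1.0]))
    n_pos, n_neg = is_pos.sum(), (~is_pos).sum()
    best = None
    for c in candidates:
        pred_pos = s >= c  # oriented scale: high = positive
        sens = float((pred_pos & is_pos).sum() / n_pos)
        spec = float((~pred_pos & ~is_pos).sum() / n_neg)
        j = sens + spec - 1.0
        # tie-breaks: larger J, then larger sens, then lower original cutoff
        orig = -c if positive_low else c
        key = (round(j, 12), round(sens, 12), -orig)
        if best is None or key > best[0]:
            best = (key, orig, j, sens, spec)
    _, cutoff, j, sens, spec = best
    return float(cutoff), float(j), float(sens), float(spec)


@dataclass(frozen=True)
class ErrorRates:
    """Per-locus ADO/FA estimates with their counts."""

    locus: str
    ado: float               # misses / carriers (NaN if no carriers)
    fa: float                # spurious detections / all analyzed samples
    fa_conditional: float    # spurious detections / non-carriers
    n_carriers: int
    n_noncarriers: int
    n_analyzed: int
    ado_defined: bool = True


def ado_fa_rates(detections: pd.DataFrame, truth: pd.DataFrame,
                 locus: str) -> ErrorRates:
    """Estimate ADO and FA for one locus from detections plus known truth.

    Carrier status: Y-linked loci are carried iff the sample has
    ``y_copies >= 1`` or the Y-fragment translocation flag; all other loci
    are carried by everyone.  Samples flagged as failed WGA are excluded
    from the analysis (they carry no information about locus-level errors).
    """
    from .simulate import y_material_present  # local import, no cycle at load

    if locus not in detections.columns:
        raise ValueError(f"no detection column for locus {locus!r}")
    merged = truth.merge(detections[["embryo_id", locus]], on="embryo_id")
    if "wga_failed" in merged.columns:
        merged = merged[~merged["wga_failed"].astype(bool)]
    det = merged[locus].astype(bool).to_numpy()
    if locus in ("SRY", "DYS14", "AMELY"):
        carrier = y_material_present(merged).to_numpy()
    else:
        carrier = np.ones(len(merged), dtype=bool)
    n_car, n_non = int(carrier.sum()), int((~carrier).sum())
    n_all = len(merged)
    misses = int((carrier & ~det).sum())
    spurious = int((~carrier & det).sum())
    ado = misses / n_car if n_car else float("nan")
    return ErrorRates(
        locus=locus,
        ado=ado,
        fa=spurious / n_all if n_all else float("nan"),
        fa_conditional=spurious / n_non if n_non else 0.0,
        n_carriers=n_car, n_noncarriers=n_non, n_analyzed=n_all,
        ado_defined=bool(n_car),
    )


@dataclass
class DiagnosticSummary:
    """All concordance statistics for one method against the reference."""

    method: str
    cm: ConfusionMatrix
    accuracy: float
    sensitivity: float
    specificity: float
    youden_j: float
    kappa: float
    odds_ratio: float
    or_ci: Tuple[float, float]
    or_p: float
    auc: Optional[float] = None
    auc_ci: Optional[Tuple[float, float]] = None
    auc_p: Optional[float] = None

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "tp": self.cm.tp, "fp": self.cm.fp,
            "fn": self.cm.fn, "tn": self.cm.tn,
            "n_excluded": self.cm.n_excluded,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "youden_j": self.youden_j,
            "kappa": self.kappa,
            "odds_ratio": self.odds_ratio,
            "or_ci_low": self.or_ci[0], "or_ci_high": self.or_ci[1],
            "or_p": self.or_p,
        }
        if self.auc is not None:
            d.update(auc=self.auc, auc_ci_low=self.auc_ci[0],
                     auc_ci_high=self.auc_ci[1], auc_p=self.auc_p)
        return d


def summarize(truth: Sequence, calls: Sequence, positive_class,
              method: str = "", scores=None,
              positive_low: bool = False) -> DiagnosticSummary:
    """Full concordance summary; AUC included when scores are supplied."""
    cm = confusion(truth, calls, positive_class)
    acc, kap = accuracy_kappa(cm)
    sens, spec = sensitivity_specificity(cm)
    or_, ci, p = odds_ratio(cm)
    auc = auc_ci = auc_p = None
    if scores is not None:
        labels = list(truth)
        auc, auc_ci, auc_p = roc_auc(scores, labels, positive_class,
                                     positive_low)
    return DiagnosticSummary(
        method=method, cm=cm, accuracy=acc, sensitivity=sens,
        specificity=spec, youden_j=sens + spec - 1.0, kappa=kap,
        odds_ratio=or_, or_ci=ci, or_p=p,
        auc=auc, auc_ci=auc_ci, auc_p=auc_p,
    )
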