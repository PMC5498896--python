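"""Reference-cohort count tables from the original clinical validation study.

These are the printed contingency tables and group summaries of the
CGH-verified embryo cohort the assay design was validated on: 204 embryos
scored by the SRY/DYS14 melt-curve index, 128 by amelogenin fragment
analysis, and a 43-embryo quantitative subset for trisomy 18/21.  They serve
as fixed inputs for recomputing the published concordance statistics; nothing
here is produced by this package's simulator.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "GSD_CATEGORY_COUNTS",
    "SEX_CM_SRY",
    "SEX_CM_GSD",
    "TRISOMY_CM_T21",
    "TRISOMY_CM_T18",
    "ADO_FA_COUNTS",
    "CT_GROUPS",
]

#: Sexing detection categories (positive class: male), reconstructed from the
#: published two-row contingency table plus the reported 14 DYS14-only
#: samples of which 6 were female.  Columns: SRY detected, DYS14 detected,
#: number of males, number of females.
GSD_CATEGORY_COUNTS = pd.DataFrame(
    [
        {"sry": False, "dys14": False, "n_male": 5, "n_female": 101},
        {"sry": False, "dys14": True, "n_male": 8, "n_female": 6},
        {"sry": True, "dys14": True, "n_male": 83, "n_female": 1},
    ]
)

#: SRY-alone sexing vs CGH: (tp, fn, tn, fp) with "male" positive.
SEX_CM_SRY = dict(tp=83, fn=13, tn=107, fp=1)
#: Combined SRY/DYS14 index vs CGH.
SEX_CM_GSD = dict(tp=91, fn=5, tn=101, fp=7)

#: TTC3 delta-Ct trisomy-21 call at cutoff 3.85 vs CGH (3 trisomy-18 embryos
#: with raw Ct > 30 excluded, leaving 13 T21 positives and 27 negatives).
TRISOMY_CM_T21 = dict(tp=12, fn=1, tn=26, fp=1)
#: RPL17 delta-Ct trisomy-18 call at cutoff 0.985 vs CGH (9 positives,
#: 34 pooled euploid + T21 negatives).
TRISOMY_CM_T18 = dict(tp=8, fn=1, tn=31, fp=3)

#: Raw ADO/FA counts: (events, denominator).  ADO denominators are carriers
#: (males); FA denominators are all analyzed samples of that assay arm.
ADO_FA_COUNTS = {
    "SRY": {"ado": (13, 96), "fa": (1, 204)},
    "DYS14": {"ado": (5, 96), "fa": (7, 204)},
    "AMELY": {"ado": (1, 50), "fa": (8, 128)},
}

#: Per-gene delta-Ct group summaries: (n, mean, sd) cycles.
CT_GROUPS = {
    "TTC3": {
        "normal": (21, 4.77, 0.56),
        "trisomy18": (6, 4.81, 1.49),
        "trisomy21": (13, 3.39, 0.99),
    },
    "RPL17": {
        "normal": (21, 2.19, 0.80),
        "trisomy18": (9, 0.53, 0.53),
        "trisomy21": (13, 1.77, 0.87),
    },
}
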