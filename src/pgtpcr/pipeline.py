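"""End-to-end orchestration: simulate -> call -> evaluate.

``run_pipeline`` chains the simulator, the melt-curve caller, both sex
callers and the trisomy caller, writes every intermediate table as CSV/TSV,
evaluates each method against the simulated truth and writes a JSON summary
plus a log recording the seed, a config hash and package versions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__, diagnostics, io, melt, sexing, simulate, trisomy
from .config import SEX_PANEL, PipelineConfig

__all__ = ["run_pipeline", "evaluate_calls"]

log = logging.getLogger("pgtpcr")

ALL_STAGES = ("simulate", "melt-call", "sex-call", "trisomy-call", "evaluate")


def evaluate_calls(truth: pd.DataFrame, gsd_calls: Optional[pd.DataFrame],
                   amel_calls: Optional[pd.DataFrame],
                   trisomy_calls: Optional[pd.DataFrame],
                   detections: Optional[pd.DataFrame] = None,
                   pool_specificity: bool = True) -> dict:
    """Concordance of every caller with the simulated/CGH truth labels.

    Returns a JSON-ready dict of DiagnosticSummary fields per method, plus
    per-locus ADO/FA estimates when a detection table is supplied.  With
    ``pool_specificity`` the trisomy negatives pool euploid and
    other-trisomy embryos (otherwise euploid only).
    """
    report: dict = {}
    truth = truth.set_index("embryo_id", drop=False)

    if gsd_calls is not None and len(gsd_calls):
        t = truth.loc[gsd_calls["embryo_id"], "sex"].tolist()
        report["gsd"] = diagnostics.summarize(
            t, gsd_calls["call"].tolist(), "male", method="gsd").to_dict()

    if amel_calls is not None and len(amel_calls):
        t = truth.loc[amel_calls["embryo_id"], "sex"].tolist()
        for rule in ("presence", "height", "ratio"):
            calls = amel_calls[f"call_by_{rule}"].tolist()
            scores = None
            positive_low = False
            if rule == "height":
                scores, positive_low = amel_calls["amely_height"], False
            elif rule == "ratio":
                scores, positive_low = amel_calls["ratio"], True
            try:
                report[f"amel_{rule}"] = diagnostics.summarize(
                    t, calls, "male", method=f"amel_{rule}",
                    scores=None if scores is None else scores.to_numpy(),
                    positive_low=positive_low).to_dict()
            except ValueError:
                log.warning("amel_%s: degenerate labels, summary skipped", rule)

    if trisomy_calls is not None and len(trisomy_calls):
        t_df = truth.loc[trisomy_calls["embryo_id"]]
        for target, call_col, score_col, chrom in (
                ("t21", "call_t21", "delta_ct_ttc3", "chr21_copies"),
                ("t18", "call_t18", "delta_ct_rpl17", "chr18_copies")):
            is_tri = (t_df[chrom] >= 3).to_numpy()
            other = "chr18_copies" if chrom == "chr21_copies" else "chr21_copies"
            keep = np.ones(len(t_df), bool) if pool_specificity else \
                (is_tri | (t_df[other].to_numpy() < 3))
            labels = np.where(is_tri, "positive", "negative")[keep]
            calls = trisomy_calls[call_col].to_numpy()[keep]
            scores = trisomy_calls[score_col].to_numpy()[keep]
            called = ~pd.Series(calls).isin(diagnostics.EXCLUDED_CALLS).to_numpy()
            try:
                summary = diagnostics.summarize(
                    labels.tolist(), calls.tolist(), "positive", method=target)
            except ValueError:
                log.warning("%s: degenerate labels, summary skipped", target)
                continue
            # AUC on the called subset only (exclusions carry no score)
            keep_auc = called & np.isfinite(scores)
            try:
                auc, ci, p = diagnostics.roc_auc(
                    scores[keep_auc], labels[keep_auc].tolist(), "positive",
                    positive_low=True)
                summary.auc, summary.auc_ci, summary.auc_p = auc, ci, p
            except ValueError:
                pass
            report[target] = summary.to_dict()

    if detections is not None:
        rates = {}
        for locus in ("SRY", "DYS14", "AMELY"):
            r = diagnostics.ado_fa_rates(detections, truth.reset_index(drop=True),
                                         locus)
            rates[locus] = {"ado": r.ado, "fa": r.fa,
                            "fa_conditional": r.fa_conditional,
                            "n_carriers": r.n_carriers,
                            "n_analyzed": r.n_analyzed}
        report["error_rates"] = rates
    return report


def run_pipeline(config: PipelineConfig, out_dir,
                 stages: Sequence[str] = ALL_STAGES,
                 seed: Optional[int] = None) -> dict:
    """Execute the pipeline stages, writing all artifacts under ``out_dir``.

    Returns the evaluation report dict (also written to ``summary.json``).
    A stage failure propagates after earlier outputs are on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.cohort.seed if seed is None else seed
    cfg_yaml = config.to_yaml()
    cfg_hash = hashlib.sha256(cfg_yaml.encode()).hexdigest()[:16]
    log.info("pgtpcr %s | seed=%d | config sha256:%s", __version__, seed, cfg_hash)
    (out / "run.log").write_text(
        f"pgtpcr={__version__}\nnumpy={np.__version__}\npandas={pd.__version__}\n"
        f"seed={seed}\nconfig_sha256={cfg_hash}\n")
    (out / "config.yaml").write_text(cfg_yaml)

    sim = None
    if "simulate" in stages:
        sim = simulate.simulate_cohort(config, seed=seed)
        io.write_table(sim["truth"], out / "truth.csv")
        io.write_table(sim["detections"], out / "detections.csv")
        io.write_table(sim["melt"], out / "melt_curves.csv")
        io.write_table(sim["peaks"], out / "peaks.tsv", sep="\t")
        io.write_table(sim["ct"], out / "ct.csv")
    else:
        sim = {
            "truth": io.read_truth(out / "truth.csv"),
            "melt": io.read_melt(out / "melt_curves.csv"),
            "peaks": io.read_peaks(out / "peaks.tsv"),
            "ct": io.read_ct(out / "ct.csv"),
        }

    melt_calls = None
    if "melt-call" in stages:
        melt_calls = melt.call_plate(
            sim["melt"], config.melt.tm, tol=config.cutoffs.tm_tol_c,
            min_peak_frac=config.cutoffs.min_peak_frac, genes=SEX_PANEL)
        io.write_table(melt_calls, out / "melt_calls.csv")

    gsd_calls = amel_calls = None
    if "sex-call" in stages and melt_calls is not None:
        wide = io.detections_wide(melt_calls)
        gsd_calls = sexing.call_sex_gsd(wide, mode=config.gsd_mode)
        io.write_table(gsd_calls, out / "sex_gsd.csv")
        amel_calls = sexing.call_sex_amel(sim["peaks"], config.amel,
                                          config.cutoffs)
        io.write_table(amel_calls, out / "sex_amel.csv")

    tri_calls = None
    if "trisomy-call" in stages:
        tri_calls = trisomy.call_trisomy_cohort(
            sim["ct"], config.cutoffs, scale=config.trisomy_scale)
        io.write_table(tri_calls, out / "trisomy_calls.csv")

    report: dict = {}
    if "evaluate" in stages:
        report = evaluate_calls(
            sim["truth"], gsd_calls, amel_calls, tri_calls,
            detections=sim.get("detections"),
            pool_specificity=config.pool_specificity)
        report["seed"] = seed
        report["config_sha256"] = cfg_hash
        (out / "summary.json").write_text(json.dumps(report, indent=2,
                                                     default=float))
    return report
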