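"""Synthetic single-cell WGA embryo cohorts for the genotyping pipeline.

Generates ground-truth karyotypes and simulates the three assays performed on
whole-genome-amplified biopsies: present/absent locus detections under
per-locus allele-drop-out (ADO) and false-allele (FA) error rates, SYBR melt
curves, amelogenin electropherogram peak tables, and quantitative Ct panels
with copy-number-dependent delta-Ct and standard-curve dilution series.

All outputs are pandas DataFrames in the long/tidy layouts that the IO module
writes and the callers read, so every downstream stage is testable without
instrument data.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence, Set

import numpy as np
import pandas as pd

from .config import (
    CT_GENES,
    LOCI,
    MASSES_NG,
    SEX_PANEL,
    Y_LOCI,
    AmelModelParams,
    CohortConfig,
    ConfigError,
    CtModelParams,
    ErrorModel,
    MeltModelParams,
)

__all__ = [
    "simulate_karyotypes",
    "y_material_present",
    "simulate_locus_detections",
    "simulate_ct_panel",
    "simulate_melt_curve",
    "simulate_melt_plate",
    "simulate_electropherogram",
    "simulate_cohort",
]

TRUTH_COLUMNS = [
    "embryo_id", "sex", "x_copies", "y_copies", "chr18_copies",
    "chr21_copies", "xx_male_translocation", "wga_failed",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_karyotypes(config: CohortConfig,
                        rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Draw a cohort of embryo karyotypes.

    Sex, trisomy status, Y-loss (in males), Y-fragment translocation (in
    females) and WGA failure are drawn independently per embryo.  ``sex``
    records the CGH label; Y-linked locus presence follows ``y_copies`` and
    ``xx_male_translocation``, not ``sex``.
    """
    rng = _rng(config.seed if rng is None else rng)
    n = config.n_embryos
    male = rng.random(n) < config.p_male
    # one draw decides euploid / T18 / T21 so the two trisomies are exclusive
    u = rng.random(n)
    t18 = u < config.p_trisomy18
    t21 = (~t18) & (u < config.p_trisomy18 + config.p_trisomy21)
    y_loss = male & (rng.random(n) < config.p_y_loss_in_males)
    y_frag = (~male) & (rng.random(n) < config.p_y_fragment_in_females)
    wga_failed = rng.random(n) < config.p_wga_failure

    return pd.DataFrame({
        "embryo_id": [f"E{i + 1:05d}" for i in range(n)],
        "sex": np.where(male, "male", "female"),
        "x_copies": np.where(male, 1, 2),
        "y_copies": np.where(male & ~y_loss, 1, 0),
        "chr18_copies": np.where(t18, 3, 2),
        "chr21_copies": np.where(t21, 3, 2),
        "xx_male_translocation": y_frag,
        "wga_failed": wga_failed,
    })


def y_material_present(truth: pd.DataFrame) -> pd.Series:
    """True where the sample genuinely carries Y-linked template."""
    return (truth["y_copies"] >= 1) | truth["xx_male_translocation"].astype(bool)


def simulate_locus_detections(truth: pd.DataFrame, errors: ErrorModel,
                              seed=None,
                              loci: Sequence[str] = LOCI) -> pd.DataFrame:
    """Simulate present/absent detections for each embryo and locus.

    Present loci are detected with probability ``1 - ado[locus]``; absent loci
    with probability ``fa[locus]``.  GAPDH and AMELX are present in every
    sample; the Y-linked loci are present iff the sample carries Y material.
    A failed WGA yields no detection at any locus.

    Returns a wide boolean table indexed like ``truth`` with one column per
    locus plus ``embryo_id``.
    """
    rng = _rng(seed)
    known = set(errors.ado) & set(errors.fa)
    unknown = [l for l in loci if l not in known]
    if unknown:
        raise ConfigError(f"no error rates configured for loci: {unknown}")

    n = len(truth)
    carrier_y = y_material_present(truth).to_numpy()
    ok = ~truth["wga_failed"].to_numpy(dtype=bool)
    out = pd.DataFrame({"embryo_id": truth["embryo_id"].to_numpy()})
    for locus in loci:
        present = carrier_y if locus in Y_LOCI else np.ones(n, dtype=bool)
        p_detect = np.where(present, 1.0 - errors.ado[locus], errors.fa[locus])
        out[locus] = ok & (rng.random(n) < p_detect)
    return out


def simulate_ct_panel(truth: pd.DataFrame, params: CtModelParams,
                      masses: Iterable[float] = MASSES_NG,
                      seed=None) -> pd.DataFrame:
    """Simulate the TTC3/RPL17/HSDB standard-curve Ct panel.

    One Ct per embryo x gene x input mass, long format
    ``(embryo_id, gene, input_ng, ct)``.  See :class:`CtModelParams` for the
    generative model; the trisomic delta-Ct shift at the analysis mass is
    ``gamma_s * log2(copies/2)`` cycles, exactly ``log2(3/2)`` when
    ``gamma = 1`` and all noise is off.
    """
    rng = _rng(seed)
    masses = [float(m) for m in masses]
    if any(m <= 0 for m in masses):
        raise ConfigError(f"input masses must be positive, got {masses}")

    n = len(truth)
    copies = {
        "TTC3": truth["chr21_copies"].to_numpy(float),
        "RPL17": truth["chr18_copies"].to_numpy(float),
        "HSDB": np.full(n, 2.0),  # copy-neutral reference
    }
    b_sample = rng.normal(0.0, params.sigma_sample, size=n)

    frames = []
    for gene in CT_GENES:
        gamma_s = rng.normal(params.gamma[gene], params.gamma_sd[gene], size=n)
        eta = rng.normal(0.0, params.sigma_gene[gene], size=n)
        slope = rng.normal(params.standard_slope, params.slope_sd, size=n)
        ct15 = (params.base_ct + params.mu[gene]
                - gamma_s * np.log2(copies[gene] / 2.0)
                + b_sample + eta)
        for mass in masses:
            eps = rng.normal(0.0, params.sigma_tech, size=n)
            ct = ct15 + slope * np.log10(mass / 15.0) + eps
            frames.append(pd.DataFrame({
                "embryo_id": truth["embryo_id"].to_numpy(),
                "gene": gene,
                "input_ng": mass,
                "ct": np.clip(ct, 1e-6, params.max_ct),
            }))
    return (pd.concat(frames, ignore_index=True)
            .sort_values(["embryo_id", "gene", "input_ng"], kind="stable")
            .reset_index(drop=True))


def simulate_melt_curve(amplicons_present: Set[str], params: MeltModelParams,
                        seed=None) -> pd.DataFrame:
    """Render one fluorescence-vs-temperature trace.

    Each present amplicon contributes a logistic melt transition centred at
    its configured Tm; a linear baseline and Gaussian noise are added.
    Returns ``(temperature_c, fluorescence)``.
    """
    rng = _rng(seed)
    unknown = set(amplicons_present) - set(params.tm)
    if unknown:
        raise ConfigError(f"no Tm configured for amplicons: {sorted(unknown)}")
    temps = params.grid()
    if temps.size == 0:
        raise ConfigError("empty temperature grid")
    fluor = params.baseline_intercept + params.baseline_slope * temps
    for amp in amplicons_present:
        x = (temps - params.tm[amp]) / params.transition_width
        fluor = fluor + params.amplitude / (1.0 + np.exp(x))
    if params.noise_sd > 0:
        fluor = fluor + rng.normal(0.0, params.noise_sd, size=temps.size)
    return pd.DataFrame({"temperature_c": temps, "fluorescence": fluor})


def simulate_melt_plate(detections: pd.DataFrame, params: MeltModelParams,
                        seed=None,
                        genes: Sequence[str] = SEX_PANEL) -> pd.DataFrame:
    """Render one single-plex melt curve per embryo and sex-panel gene.

    The amplicon is present in a well iff the detection table says that locus
    was detected, so ADO/FA propagate into the traces.  Long format
    ``(embryo_id, gene, temperature_c, fluorescence)``.
    """
    rng = _rng(seed)
    frames = []
    for _, row in detections.iterrows():
        for gene in genes:
            present = {gene} if bool(row[gene]) else set()
            curve = simulate_melt_curve(present, params, rng)
            curve.insert(0, "gene", gene)
            curve.insert(0, "embryo_id", row["embryo_id"])
            frames.append(curve)
    return pd.concat(frames, ignore_index=True)


def simulate_electropherogram(truth: pd.DataFrame, detections: pd.DataFrame,
                              params: AmelModelParams, seed=None) -> pd.DataFrame:
    """Simulate the amelogenin fragment-analysis peak table.

    AMELX (104 bp) appears whenever the sample amplified and AMELX was
    detected; AMELY (110 bp) follows the detection table so ADO/FA propagate.
    Genuine AMELY peaks (samples with Y material) draw lognormal heights from
    ``height_log_mean``; false-allele peaks from the lower artifact
    distribution.  Sizes get Gaussian jitter.  Long format
    ``(embryo_id, size_bp, height_rfu)``.
    """
    rng = _rng(seed)
    merged = truth.merge(detections, on="embryo_id", suffixes=("", "_det"))
    carrier = y_material_present(merged).to_numpy()
    rows = []
    for i, row in merged.iterrows():
        if row["wga_failed"]:
            continue
        if bool(row["AMELX"]):
            h = float(np.exp(rng.normal(params.height_log_mean["AMELX"],
                                        params.height_log_sd)))
            s = float(params.size_x + rng.normal(0.0, params.size_jitter_sd))
            rows.append((row["embryo_id"], s, h))
        if bool(row["AMELY"]):
            if carrier[i]:
                h = float(np.exp(rng.normal(params.height_log_mean["AMELY"],
                                            params.height_log_sd)))
            else:
                h = float(np.exp(rng.normal(params.fa_height_log_mean,
                                            params.fa_height_log_sd)))
            s = float(params.size_y + rng.normal(0.0, params.size_jitter_sd))
            rows.append((row["embryo_id"], s, h))
    return pd.DataFrame(rows, columns=["embryo_id", "size_bp", "height_rfu"])


def simulate_cohort(config, seed=None) -> dict:
    """Run the full simulator: truth, detections, melt plate, peaks, Ct panel.

    ``config`` is a :class:`~pgtpcr.config.PipelineConfig`; ``seed`` overrides
    ``config.cohort.seed`` when given.  Returns a dict of DataFrames keyed
    ``truth``, ``detections``, ``melt``, ``peaks``, ``ct``.
    """
    rng = _rng(config.cohort.seed if seed is None else seed)
    truth = simulate_karyotypes(config.cohort, rng)
    detections = simulate_locus_detections(truth, config.errors, rng)
    melt = simulate_melt_plate(detections, config.melt, rng)
    peaks = simulate_electropherogram(truth, detections, config.amel, rng)
    ct = simulate_ct_panel(truth, config.ct, MASSES_NG, rng)
    return {"truth": truth, "detections": detections, "melt": melt,
            "peaks": peaks, "ct": ct}
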