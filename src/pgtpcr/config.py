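"""Parameter containers and defaults for the preimplantation-genotyping pipeline.

Every tunable quantity of the simulator and the three callers lives in one of
the dataclasses below and is aggregated into :class:`PipelineConfig`, which
round-trips losslessly through YAML.  Defaults encode the study conditions of
the clinical validation cohort this pipeline models: 328 sexed embryos
(146 male), a 43-embryo quantitative subset (21 euploid / 9 trisomy 18 /
13 trisomy 21), per-locus allele-drop-out (ADO) and false-allele (FA) rates
for the Y markers, and delta-Ct group means/SDs for the trisomy assay.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import asdict, dataclass, field
from typing import Dict, Tuple

import yaml

__all__ = [
    "ConfigError",
    "CohortConfig",
    "ErrorModel",
    "CtModelParams",
    "MeltModelParams",
    "AmelModelParams",
    "CallerCutoffs",
    "PipelineConfig",
    "LOCI",
    "Y_LOCI",
    "SEX_PANEL",
    "CT_GENES",
    "CT_TARGETS",
    "MASSES_NG",
    "LOG2_TRISOMIC_RATIO",
    "Y_LOSS_RATE_CONTINGENCY",
    "Y_LOSS_RATE_NARRATIVE",
]


class ConfigError(ValueError):
    """Raised for invalid parameter values or malformed configuration files."""


#: Loci simulated as present/absent detections.
LOCI: Tuple[str, ...] = ("GAPDH", "SRY", "DYS14", "AMELX", "AMELY")
#: Y-linked loci: present iff the sample carries Y material.
Y_LOCI: Tuple[str, ...] = ("SRY", "DYS14", "AMELY")
#: Genes assayed by melt-curve analysis for sex determination.
SEX_PANEL: Tuple[str, ...] = ("GAPDH", "SRY", "DYS14")
#: Genes of the quantitative trisomy panel (HSDB is the endogenous reference).
CT_GENES: Tuple[str, ...] = ("TTC3", "RPL17", "HSDB")
CT_TARGETS: Tuple[str, ...] = ("TTC3", "RPL17")
#: WGA input masses (ng) of the per-sample standard curve; 15 ng is the
#: analysis point.
MASSES_NG: Tuple[float, ...] = (3.75, 7.5, 15.0)

#: log2(3/2): the ideal delta-Ct shift of one extra chromosome copy.
LOG2_TRISOMIC_RATIO: float = math.log2(1.5)

#: Fraction of males whose sample carries no detectable Y material, as implied
#: by the sexing contingency table (5 of 96 males negative for both markers).
Y_LOSS_RATE_CONTINGENCY: float = 5 / 96
#: Alternative preset from the cohort narrative ("eleven male embryos ...
#: negative for both markers"); the two counts disagree in the source report
#: and both are exposed.
Y_LOSS_RATE_NARRATIVE: float = 11 / 96


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ConfigError(f"{name} must be a probability in [0, 1], got {p!r}")


@dataclass
class CohortConfig:
    """Cohort composition: sample size, sex ratio, trisomy prevalences.

    ``p_y_loss_in_males`` models males whose biopsy lost the Y chromosome
    (CGH still labels them male); ``p_y_fragment_in_females`` models females
    carrying translocated Y material (XX-male-like), which makes the Y loci
    genuinely present despite the female CGH label.
    """

    n_embryos: int = 328
    p_male: float = 146 / 328
    p_trisomy18: float = 9 / 43
    p_trisomy21: float = 13 / 43
    p_y_loss_in_males: float = Y_LOSS_RATE_CONTINGENCY
    p_y_fragment_in_females: float = 3 / 108
    p_wga_failure: float = 6 / 342
    seed: int = 2017

    def __post_init__(self) -> None:
        if self.n_embryos < 0:
            raise ConfigError(f"n_embryos must be >= 0, got {self.n_embryos}")
        for name in ("p_male", "p_trisomy18", "p_trisomy21",
                     "p_y_loss_in_males", "p_y_fragment_in_females",
                     "p_wga_failure"):
            _check_prob(name, getattr(self, name))
        if self.p_trisomy18 + self.p_trisomy21 > 1.0 + 1e-12:
            raise ConfigError("p_trisomy18 + p_trisomy21 must not exceed 1")


@dataclass
class ErrorModel:
    """Per-locus ADO and FA probabilities.

    ``ado[locus]`` is the probability that a truly present locus is not
    detected; ``fa[locus]`` the probability that an absent locus yields a
    spurious detection (per non-carrier sample).  GAPDH is present in every
    sample, so its "ADO" is the per-sample amplification-control failure rate.
    """

    ado: Dict[str, float] = field(default_factory=lambda: {
        "GAPDH": 8 / 342,
        "SRY": 0.135,
        "DYS14": 0.052,
        "AMELX": 0.0,
        "AMELY": 0.020,
    })
    fa: Dict[str, float] = field(default_factory=lambda: {
        "GAPDH": 0.0,
        "SRY": 0.005,
        "DYS14": 0.034,
        "AMELX": 0.0,
        "AMELY": 0.063,
    })

    def __post_init__(self) -> None:
        for table, label in ((self.ado, "ado"), (self.fa, "fa")):
            for locus, p in table.items():
                _check_prob(f"{label}[{locus}]", p)

    def loci(self) -> Tuple[str, ...]:
        return tuple(self.ado)


@dataclass
class CtModelParams:
    """Generative model for the quantitative (Ct) trisomy panel.

    Per sample and gene, the Ct at the 15 ng analysis mass is

    ``Ct = base_ct + mu_g - gamma_s * log2(copies/2) + b_sample + eta_g + eps``

    where ``mu_g`` is the gene's diploid delta-Ct offset versus the HSDB
    reference, ``gamma_s ~ N(gamma_g, gamma_sd_g)`` is a per-sample WGA
    distortion factor (``gamma = 1`` is the ideal dosage response; observed
    trisomic shifts of 1.4-1.7 cycles instead of 0.585 imply gamma well above
    1), ``b_sample ~ N(0, sigma_sample)`` is a whole-sample WGA offset that
    cancels in delta-Ct, ``eta_g ~ N(0, sigma_gene[g])`` is locus-specific
    amplification-representation noise, and ``eps ~ N(0, sigma_tech)`` is
    technical replicate noise.  Other masses follow the standard curve
    ``Ct(m) = Ct(15) + slope * log10(m/15)`` with a per-sample/gene slope
    drawn around ``standard_slope`` (= -1/log10(1+efficiency)).

    Defaults are calibrated so diploid delta-Ct is N(4.77, 0.56) for TTC3 and
    N(2.19, 0.80) for RPL17, and trisomy-21 TTC3 delta-Ct is N(3.39, 0.99).
    """

    mu: Dict[str, float] = field(default_factory=lambda: {
        "TTC3": 4.77, "RPL17": 2.19, "HSDB": 0.0,
    })
    gamma: Dict[str, float] = field(default_factory=lambda: {
        "TTC3": 1.38 / LOG2_TRISOMIC_RATIO,   # ~2.359
        "RPL17": 1.66 / LOG2_TRISOMIC_RATIO,  # ~2.838
        "HSDB": 1.0,
    })
    gamma_sd: Dict[str, float] = field(default_factory=lambda: {
        # sqrt(0.99^2 - 0.56^2) / log2(1.5): inflates the T21 group SD from
        # the diploid 0.56 to the observed 0.99.  The T18 RPL17 group SD
        # (0.53) is *below* the diploid 0.80, which no extra heterogeneity
        # can produce, hence 0 for RPL17 (means only are calibrated there).
        "TTC3": math.sqrt(0.99 ** 2 - 0.56 ** 2) / LOG2_TRISOMIC_RATIO,
        "RPL17": 0.0,
        "HSDB": 0.0,
    })
    sigma_gene: Dict[str, float] = field(default_factory=lambda: {
        # Calibrated so Var(delta-Ct) = sigma_gene[g]^2 + sigma_gene[HSDB]^2
        # + 2*sigma_tech^2 equals 0.56^2 (TTC3) and 0.80^2 (RPL17).
        "TTC3": math.sqrt(0.56 ** 2 - 0.10 ** 2 - 2 * 0.05 ** 2),
        "RPL17": math.sqrt(0.80 ** 2 - 0.10 ** 2 - 2 * 0.05 ** 2),
        "HSDB": 0.10,
    })
    sigma_sample: float = 1.2
    # Replicate noise and per-sample slope jitter are kept small enough that
    # the 3-point OLS slope (SE ~ sigma_tech / 0.426 per decade) stays inside
    # the -3.3 +/- 0.4 acceptance band for nearly all samples, matching a QC
    # rule that real runs are expected to pass.
    sigma_tech: float = 0.05
    efficiency: float = 1.0
    slope_sd: float = 0.05
    base_ct: float = 23.5
    max_ct: float = 45.0

    def __post_init__(self) -> None:
        if not (0.0 < self.efficiency <= 1.0):
            raise ConfigError(f"efficiency must be in (0, 1], got {self.efficiency}")
        for name in ("sigma_sample", "sigma_tech", "slope_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for g, v in self.gamma.items():
            if v <= 0:
                raise ConfigError(f"gamma[{g}] must be > 0, got {v}")
        for table in (self.gamma_sd, self.sigma_gene):
            for g, v in table.items():
                if v < 0:
                    raise ConfigError(f"SD for {g} must be >= 0, got {v}")

    @property
    def standard_slope(self) -> float:
        """Expected Ct-vs-log10(mass) slope; -3.32 at 100% efficiency."""
        return -1.0 / math.log10(1.0 + self.efficiency)


@dataclass
class MeltModelParams:
    """Generative model for SYBR melt curves.

    Fluorescence is a sum of logistic melt transitions (one per present
    amplicon, centred at its Tm) on a linear baseline plus Gaussian noise:
    ``F(T) = sum_a A / (1 + exp((T - Tm_a)/w)) + b0 + b1*T + eps``.
    The -dF/dT trace then peaks at each Tm with height A/(4w).
    """

    tm: Dict[str, float] = field(default_factory=lambda: {
        "GAPDH": 81.5, "SRY": 84.0, "DYS14": 78.5,
        "TTC3": 79.0, "RPL17": 82.5, "HSDB": 83.0,
    })
    transition_width: float = 0.5
    amplitude: float = 800.0
    baseline_intercept: float = 2000.0
    baseline_slope: float = -2.0
    noise_sd: float = 3.0
    t_min: float = 60.0
    t_max: float = 95.0
    t_step: float = 0.2

    def __post_init__(self) -> None:
        if self.transition_width <= 0:
            raise ConfigError("transition_width must be > 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not (self.t_min < self.t_max) or self.t_step <= 0:
            raise ConfigError("temperature grid must be ascending with positive step")
        for amp, tm in self.tm.items():
            if not (self.t_min <= tm <= self.t_max):
                raise ConfigError(f"tm[{amp}]={tm} outside grid [{self.t_min}, {self.t_max}]")

    def grid(self):
        import numpy as np

        n = int(round((self.t_max - self.t_min) / self.t_step)) + 1
        return self.t_min + self.t_step * np.arange(n)


@dataclass
class AmelModelParams:
    """Generative model for amelogenin fragment-analysis peak tables.

    AMELX amplifies at 104 bp, AMELY at 110 bp (6 bp intron-1 insertion).
    Peak heights are lognormal; spurious (false-allele) AMELY peaks draw from
    a lower lognormal, reflecting the weak artifact signals that motivate a
    height cutoff on top of mere peak presence.
    """

    size_x: float = 104.0
    size_y: float = 110.0
    height_log_mean: Dict[str, float] = field(default_factory=lambda: {
        "AMELX": math.log(300.0), "AMELY": math.log(150.0),
    })
    height_log_sd: float = 0.6
    fa_height_log_mean: float = math.log(8.0)
    fa_height_log_sd: float = 0.8
    noise_floor: float = 1.0
    size_jitter_sd: float = 0.15

    def __post_init__(self) -> None:
        if abs((self.size_y - self.size_x) - 6.0) > 1e-9:
            raise ConfigError("AMELY amplicon must be 6 bp longer than AMELX")
        if self.height_log_sd < 0 or self.fa_height_log_sd < 0 or self.size_jitter_sd < 0:
            raise ConfigError("SDs must be >= 0")
        if self.noise_floor <= 0:
            raise ConfigError("noise_floor must be > 0")


@dataclass
class CallerCutoffs:
    """Published decision thresholds and QC bands for the three callers."""

    amely_height: float = 23.5     # RFU; AMELY peak height > cutoff => male
    xy_ratio: float = 21.8         # X/Y height ratio <= cutoff => male
    ttc3_delta_ct: float = 3.85    # delta-Ct <= cutoff => trisomy 21
    rpl17_delta_ct: float = 0.985  # delta-Ct <= cutoff => trisomy 18
    exclusion_ct: float = 30.0     # raw target Ct above this => excluded
    qc_slope_center: float = -3.3  # standard-curve slope acceptance band
    qc_slope_tol: float = 0.4
    size_tol_bp: float = 1.0       # fragment-size match window for 104/110 bp
    tm_tol_c: float = 1.5          # Tm match window for melt peak -> gene
    min_peak_frac: float = 0.05    # peak height floor, fraction of plate max

    def __post_init__(self) -> None:
        if self.qc_slope_tol < 0 or self.size_tol_bp < 0 or self.tm_tol_c < 0:
            raise ConfigError("tolerances must be >= 0")
        if not (0 <= self.min_peak_frac <= 1):
            raise ConfigError("min_peak_frac must be in [0, 1]")


@dataclass
class PipelineConfig:
    """Aggregate configuration for the full simulate-call-evaluate pipeline."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    errors: ErrorModel = field(default_factory=ErrorModel)
    ct: CtModelParams = field(default_factory=CtModelParams)
    melt: MeltModelParams = field(default_factory=MeltModelParams)
    amel: AmelModelParams = field(default_factory=AmelModelParams)
    cutoffs: CallerCutoffs = field(default_factory=CallerCutoffs)
    #: "index": DYS14-only samples are called male; "clinical": unclassified.
    gsd_mode: str = "index"
    #: Pool euploid + other-trisomy embryos as negatives for specificity.
    pool_specificity: bool = True
    #: "delta_ct": trisomy cutoffs compare target-minus-reference delta-Ct
    #: (default); "raw_ct": compare raw target Ct at the analysis mass.
    trisomy_scale: str = "delta_ct"

    def __post_init__(self) -> None:
        if self.gsd_mode not in ("index", "clinical"):
            raise ConfigError(f"gsd_mode must be 'index' or 'clinical', got {self.gsd_mode!r}")
        if self.trisomy_scale not in ("delta_ct", "raw_ct"):
            raise ConfigError("trisomy_scale must be 'delta_ct' or 'raw_ct'")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        try:
            return cls(
                cohort=CohortConfig(**d.pop("cohort", {})),
                errors=ErrorModel(**d.pop("errors", {})),
                ct=CtModelParams(**d.pop("ct", {})),
                melt=MeltModelParams(**d.pop("melt", {})),
                amel=AmelModelParams(**d.pop("amel", {})),
                cutoffs=CallerCutoffs(**d.pop("cutoffs", {})),
                **d,
            )
        except TypeError as exc:  # unknown key
            raise ConfigError(str(exc)) from exc

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(_io.StringIO(text))
        if not isinstance(data, dict):
            raise ConfigError("configuration file must contain a mapping")
        return cls.from_dict(data)

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_yaml())

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_yaml(fh.read())
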