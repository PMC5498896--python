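"""Simulator contracts: determinism, degenerate limits, calibrated moments."""

import math

import numpy as np
import pandas as pd
import pytest

from pgtpcr import simulate
from pgtpcr.config import (
    LOG2_TRISOMIC_RATIO,
    AmelModelParams,
    CohortConfig,
    ConfigError,
    CtModelParams,
    ErrorModel,
    MeltModelParams,
    PipelineConfig,
)


class TestKaryotypes:
    def test_degenerate_probabilities(self):
        all_male = simulate.simulate_karyotypes(CohortConfig(n_embryos=10, p_male=1.0))
        assert (all_male["sex"] == "male").all()
        assert (all_male["y_copies"] >= 0).all()
        all_female = simulate.simulate_karyotypes(CohortConfig(n_embryos=10, p_male=0.0))
        assert (all_female["sex"] == "female").all()
        assert (all_female["y_copies"] == 0).all()

    def test_same_seed_reproduces_sequence(self):
        cfg = CohortConfig(n_embryos=500, seed=7)
        a = simulate.simulate_karyotypes(cfg)
        b = simulate.simulate_karyotypes(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_male_fraction_matches_cohort_prevalence(self):
        p = 146 / 328
        n = 100_000
        truth = simulate.simulate_karyotypes(CohortConfig(n_embryos=n, p_male=p, seed=1))
        se = math.sqrt(p * (1 - p) / n)
        assert abs((truth["sex"] == "male").mean() - p) < 3 * se

    def test_trisomies_are_exclusive(self):
        truth = simulate.simulate_karyotypes(
            CohortConfig(n_embryos=5000, p_trisomy18=0.4, p_trisomy21=0.5, seed=3))
        both = (truth["chr18_copies"] >= 3) & (truth["chr21_copies"] >= 3)
        assert not both.any()

    def test_invalid_probability_rejected(self):
        with pytest.raises(ConfigError):
            CohortConfig(p_male=1.5)
        with pytest.raises(ConfigError):
            CohortConfig(p_trisomy18=0.7, p_trisomy21=0.7)


class TestLocusDetections:
    def test_no_noise_detection_equals_presence(self, noise_free_config):
        cfg = noise_free_config
        truth = simulate.simulate_karyotypes(cfg.cohort)
        det = simulate.simulate_locus_detections(truth, cfg.errors, seed=1)
        carrier = simulate.y_material_present(truth)
        for locus in ("SRY", "DYS14", "AMELY"):
            assert (det[locus] == carrier).all()
        assert det["GAPDH"].all() and det["AMELX"].all()

    def test_sry_dropout_rate_recovered(self):
        truth = simulate.simulate_karyotypes(
            CohortConfig(n_embryos=10_000, p_male=1.0, p_y_loss_in_males=0.0,
                         p_wga_failure=0.0, seed=11))
        det = simulate.simulate_locus_detections(truth, ErrorModel(), seed=12)
        miss = 1.0 - det["SRY"].mean()
        se = math.sqrt(0.135 * 0.865 / 10_000)
        assert abs(miss - 0.135) < 3 * se

    def test_certain_false_allele_hits_every_noncarrier(self):
        truth = simulate.simulate_karyotypes(
            CohortConfig(n_embryos=200, p_male=0.0, p_y_fragment_in_females=0.0,
                         p_wga_failure=0.0, seed=2))
        errors = ErrorModel()
        errors.fa["SRY"] = 1.0
        det = simulate.simulate_locus_detections(truth, errors, seed=3)
        assert det["SRY"].all()

    def test_unknown_locus_raises(self):
        truth = simulate.simulate_karyotypes(CohortConfig(n_embryos=5))
        with pytest.raises(ConfigError, match="NOT_A_LOCUS"):
            simulate.simulate_locus_detections(truth, ErrorModel(), seed=1,
                                               loci=("NOT_A_LOCUS",))

    def test_wga_failure_blanks_all_loci(self):
        truth = simulate.simulate_karyotypes(
            CohortConfig(n_embryos=300, p_wga_failure=1.0, seed=4))
        det = simulate.simulate_locus_detections(truth, ErrorModel(), seed=5)
        assert not det[list(ErrorModel().ado)].to_numpy().any()


def _quiet_ct_params(**kw) -> CtModelParams:
    p = CtModelParams(**kw)
    p.sigma_sample = 0.0
    p.sigma_tech = 0.0
    p.slope_sd = 0.0
    p.gamma_sd = {g: 0.0 for g in p.gamma_sd}
    p.sigma_gene = {g: 0.0 for g in p.sigma_gene}
    return p


class TestCtPanel:
    def test_ideal_wga_trisomic_shift_is_log2_three_halves(self):
        truth = pd.DataFrame({
            "embryo_id": ["dip", "tri"], "sex": ["female", "female"],
            "x_copies": [2, 2], "y_copies": [0, 0],
            "chr18_copies": [2, 2], "chr21_copies": [2, 3],
            "xx_male_translocation": [False, False], "wga_failed": [False, False],
        })
        params = _quiet_ct_params()
        params.gamma = {g: 1.0 for g in params.gamma}
        ct = simulate.simulate_ct_panel(truth, params, seed=1)
        pivot = ct[ct["input_ng"] == 15.0].pivot(index="embryo_id",
                                                 columns="gene", values="ct")
        delta = pivot["TTC3"] - pivot["HSDB"]
        assert delta["dip"] - delta["tri"] == pytest.approx(LOG2_TRISOMIC_RATIO, abs=1e-12)

    def test_group_means_match_study_calibration(self):
        cfg = PipelineConfig()
        truth = simulate.simulate_karyotypes(CohortConfig(n_embryos=10_000, seed=21))
        ct = simulate.simulate_ct_panel(truth, cfg.ct, seed=22)
        pivot = ct[ct["input_ng"] == 15.0].pivot(index="embryo_id",
                                                 columns="gene", values="ct")
        pivot = pivot.loc[truth["embryo_id"]]
        d_ttc3 = (pivot["TTC3"] - pivot["HSDB"]).to_numpy()
        d_rpl17 = (pivot["RPL17"] - pivot["HSDB"]).to_numpy()
        t21 = (truth["chr21_copies"] >= 3).to_numpy()
        t18 = (truth["chr18_copies"] >= 3).to_numpy()
        checks = [  # (observed sample, expected mean, expected sd)
            (d_ttc3[~t21], 4.77, 0.56),
            (d_ttc3[t21], 3.39, 0.99),
            (d_rpl17[~t18], 2.19, 0.80),
            (d_rpl17[t18], 0.53, 0.80),  # model keeps diploid spread for RPL17
        ]
        for sample, mean, sd in checks:
            se = sd / math.sqrt(sample.size)
            assert abs(sample.mean() - mean) < 3 * se

    def test_noise_free_standard_curve_slope_exact(self):
        truth = simulate.simulate_karyotypes(CohortConfig(n_embryos=3, seed=5))
        params = _quiet_ct_params()
        ct = simulate.simulate_ct_panel(truth, params, seed=6)
        for _, panel in ct.groupby("embryo_id"):
            sel = panel[panel["gene"] == "TTC3"]
            slope = np.polyfit(np.log10(sel["input_ng"]), sel["ct"], 1)[0]
            assert slope == pytest.approx(params.standard_slope, abs=1e-9)

    def test_ct_strictly_decreases_with_mass(self):
        truth = simulate.simulate_karyotypes(CohortConfig(n_embryos=20, seed=7))
        params = CtModelParams()
        params.sigma_tech = 0.0
        ct = simulate.simulate_ct_panel(truth, params, seed=8)
        for (_, _), grp in ct.groupby(["embryo_id", "gene"]):
            ordered = grp.sort_values("input_ng")["ct"].to_numpy()
            assert np.all(np.diff(ordered) < 0)

    def test_sample_offset_cancels_in_delta_ct(self):
        # with only the whole-sample offset active, delta-Ct is exactly mu_g
        truth = simulate.simulate_karyotypes(
            CohortConfig(n_embryos=50, p_trisomy18=0, p_trisomy21=0, seed=9))
        params = _quiet_ct_params()
        params.sigma_sample = 3.0
        ct = simulate.simulate_ct_panel(truth, params, seed=10)
        pivot = ct[ct["input_ng"] == 15.0].pivot(index="embryo_id",
                                                 columns="gene", values="ct")
        assert np.allclose(pivot["TTC3"] - pivot["HSDB"], params.mu["TTC3"])
        assert np.allclose(pivot["RPL17"] - pivot["HSDB"], params.mu["RPL17"])

    def test_nonpositive_mass_rejected(self):
        truth = simulate.simulate_karyotypes(CohortConfig(n_embryos=2))
        with pytest.raises(ConfigError):
            simulate.simulate_ct_panel(truth, CtModelParams(), masses=[0.0, 15.0])


class TestMeltCurves:
    def test_baseline_only_derivative_is_constant(self):
        params = MeltModelParams(noise_sd=0.0)
        curve = simulate.simulate_melt_curve(set(), params, seed=1)
        deriv = -np.gradient(curve["fluorescence"], curve["temperature_c"])
        assert np.allclose(deriv, -params.baseline_slope)

    def test_single_amplicon_peak_at_its_tm(self):
        params = MeltModelParams(noise_sd=0.0)
        params.tm["SRY"] = 84.0
        curve = simulate.simulate_melt_curve({"SRY"}, params, seed=1)
        deriv = -np.gradient(curve["fluorescence"], curve["temperature_c"])
        tm_hat = curve["temperature_c"].iloc[int(np.argmax(deriv))]
        assert abs(tm_hat - 84.0) <= params.t_step

    def test_two_amplicons_give_two_resolvable_peaks(self):
        from scipy.signal import find_peaks

        params = MeltModelParams(noise_sd=0.0, transition_width=0.8)
        params.tm["A"], params.tm["B"] = 78.0, 82.0
        curve = simulate.simulate_melt_curve({"A", "B"}, params, seed=1)
        deriv = -np.gradient(curve["fluorescence"], curve["temperature_c"])
        idx, _ = find_peaks(deriv, height=0.25 * deriv.max())
        assert len(idx) == 2

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigError):
            MeltModelParams(t_min=95.0, t_max=60.0)


class TestElectropherogram:
    def _cohort(self, n, p_male, seed, **err):
        truth = simulate.simulate_karyotypes(
            CohortConfig(n_embryos=n, p_male=p_male, p_y_loss_in_males=0.0,
                         p_y_fragment_in_females=0.0, p_wga_failure=0.0,
                         seed=seed))
        errors = ErrorModel()
        for locus, (ado, fa) in err.items():
            errors.ado[locus], errors.fa[locus] = ado, fa
        det = simulate.simulate_locus_detections(truth, errors, seed=seed + 1)
        return truth, det

    def test_female_without_fa_has_no_y_peak(self):
        truth, det = self._cohort(100, 0.0, 31, AMELY=(0.0, 0.0))
        peaks = simulate.simulate_electropherogram(truth, det, AmelModelParams(),
                                                   seed=32)
        assert not ((peaks["size_bp"] - 110).abs() <= 1.0).any()

    def test_male_has_both_fragments(self):
        truth, det = self._cohort(50, 1.0, 33, AMELY=(0.0, 0.0))
        peaks = simulate.simulate_electropherogram(truth, det, AmelModelParams(),
                                                   seed=34)
        for _, grp in peaks.groupby("embryo_id"):
            sizes = grp["size_bp"].to_numpy()
            assert ((np.abs(sizes - 104) <= 1.0).any()
                    and (np.abs(sizes - 110) <= 1.0).any())

    def test_male_y_height_median_is_lognormal_median(self):
        params = AmelModelParams()
        truth, det = self._cohort(10_000, 1.0, 35, AMELY=(0.0, 0.0))
        peaks = simulate.simulate_electropherogram(truth, det, params, seed=36)
        y = peaks[(peaks["size_bp"] - 110).abs() <= 1.0]["height_rfu"].to_numpy()
        # median test: share below exp(mu) is Binomial(n, 1/2)
        frac_below = (y < math.exp(params.height_log_mean["AMELY"])).mean()
        assert abs(frac_below - 0.5) < 3 * math.sqrt(0.25 / y.size)


def test_cohort_simulation_is_byte_deterministic(tmp_path):
    cfg = PipelineConfig()
    cfg.cohort = CohortConfig(n_embryos=40, seed=77)
    out = []
    for tag in ("a", "b"):
        sim = simulate.simulate_cohort(cfg, seed=123)
        path = tmp_path / f"{tag}.csv"
        sim["ct"].to_csv(path, index=False)
        sim["peaks"].to_csv(path.with_suffix(".tsv"), sep="\t", index=False)
        out.append(path.read_text() + path.with_suffix(".tsv").read_text())
    assert out[0] == out[1]
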