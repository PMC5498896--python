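# Methods

This note documents the models behind `pgtpcr`: what the synthetic cohort
generator emulates, how the callers decide, how every default was chosen,
and what the tests do and do not demonstrate about real embryo data.

## Cohort model

Each simulated embryo draws, independently: sex (P(male) = 146/328, the
validation cohort's prevalence), trisomy status (one draw making T18 and
T21 exclusive; defaults 9/43 and 13/43, the quantitative subset's
prevalences), and three complications that make sex calling non-trivial:

- **Y loss in males** (`p_y_loss_in_males`, default 5/96): the biopsy
  carries no Y material although CGH labelled the embryo male. The default
  is the rate implied by the sexing contingency table (5 of 96 males
  negative for both markers); the cohort narrative elsewhere suggests 11
  such males, and `Y_LOSS_RATE_NARRATIVE` exposes that alternative — the
  two counts cannot both be right, and the generator does not adjudicate.
- **Y fragment in females** (`p_y_fragment_in_females`, default 3/108):
  translocated Y material (XX-male-like) makes the Y loci genuinely
  present despite the female label. The default makes the expected female
  miscall rate (FA plus Y-material) match the observed 7/108.
- **WGA failure** (`p_wga_failure`, default 6/342): all loci blank;
  combined with the GAPDH control failure rate (8/342, modelled as the
  GAPDH "ADO") this reproduces the 14/342 samples lost to "no result".

`sex` always records the reference (CGH) label; locus presence follows
`y_copies` and the translocation flag. This separation is what lets the
error-rate estimators distinguish biological discordance from assay error.

## Detection error model

Present loci are detected with probability 1 − ADO, absent loci with
probability FA, independently per locus. Defaults are the validation
cohort's embryo rates: SRY 13.5%/0.5%, DYS14 5.2%/3.4%, AMELY 2.0%/6.3%.
DYS14's lower dropout (multicopy template) is represented only through its
rate, not by explicit copy counting.

One convention matters. The printed FA rates divide spurious detections by
**all** analyzed samples (1/204, 7/204, 8/128), while a generative FA
parameter is naturally a **per-non-carrier** probability. Both cannot equal
the same number, so `diagnostics.ado_fa_rates` reports both: `fa`
(all-sample denominator, matching the printed rates) and `fa_conditional`
(non-carrier denominator, the estimand the generator controls and the one
used for parameter-recovery tests). The original per-heterozygote
definitions of ADO/FA in the population-genetics literature differ again;
they are not used here.

With these defaults the expected end-to-end GSD-index accuracy is ≈ 93.8%
(male errors: Y-loss plus joint SRY∧DYS14 dropout ≈ 5.7%; female errors:
Y-fragments plus any-marker FA ≈ 6.6%), consistent with the reported 94.1%.

## Melt curves

Fluorescence is a sum of logistic transitions on a linear baseline:
F(T) = Σ_a A/(1 + exp((T − Tm_a)/w)) + b₀ + b₁T + ε. This form is chosen
because its −dF/dT peak is analytic: height A/(4w) at exactly Tm, which
makes the derivative-and-peak-calling pipeline checkable in closed form.
Defaults: grid 60–95 °C in 0.2 °C steps, width 0.5 °C, amplitude 800 RFU,
baseline slope −2 RFU/°C, noise 3 RFU. Amplicon Tm values are deployment
configuration (the instrument's theoretical Tm per amplicon); the defaults
(DYS14 78.5, GAPDH 81.5, SRY 84.0 °C, …) are merely well-separated
plausible values.

Analysis uses quadratic Savitzky–Golay smoothing-differentiation (default
window 7 points; endpoints by one-sided fits) rather than raw finite
differences, mirroring instrument software and stabilising peak calling
under noise. Note the window biases a logistic peak height low by
O(w²·F‴): ~3.6% at window 7 and grid 0.2 °C, ~1.8% at window 5 — peak
*location* is unaffected, which is what detection uses. Peaks are scipy
`find_peaks` local maxima filtered by height and standard topographic
prominence; a gene is detected iff a peak lies within ±1.5 °C of its
expected Tm (default tolerance; the height floor defaults to 5% of the
plate-wide maximum −dF/dT so a plate cannot calibrate its threshold to
noise). GAPDH-negative samples are "no result", never "female".

## Amelogenin electropherograms

Peak heights are lognormal (medians: AMELX 300, AMELY 150 RFU, log-SD
0.6). False-allele AMELY peaks draw from a lower artifact distribution
(median 8 RFU, log-SD 0.8) — this is what gives the height cutoff (23.5
RFU) its discriminating power over mere presence, as observed in the
validation data where 8 female embryos showed an AMELY peak. Sizes jitter
by 0.15 bp around 104/110; matching uses a ±1 bp window. The X/Y ratio
uses a 1 RFU denominator floor when AMELY is absent, so female ratios are
large but finite. Boundary conventions (documented and tested): height
strictly ">" for male, ratio "≤" for male. No stutter or pull-up artifacts
are modelled.

## Ct panel

Per sample and gene:

    Ct(15 ng) = base + μ_g − γ_s·log₂(copies/2) + b_sample + η_g + ε
    Ct(m)     = Ct(15) + slope_s·log₁₀(m/15)

- μ_g is the diploid ΔCt offset versus HSDB: 4.77 (TTC3), 2.19 (RPL17).
- γ_s ~ N(γ_g, γ_sd): per-sample WGA dosage distortion. γ = 1 is the ideal
  response (shift log₂(3/2) ≈ 0.585); the calibrated γ are 2.36 (TTC3) and
  2.84 (RPL17), reproducing the observed 1.38/1.66-cycle trisomic shifts.
  γ_sd(TTC3) = 1.395 inflates the T21 group SD from the diploid 0.56 to
  the observed 0.99 — heterogeneous WGA distortion (and, biologically,
  mosaicism) is the only mechanism in the model that can widen the
  trisomy group without widening the diploid group. The T18 RPL17 SD
  (0.53) is *smaller* than the diploid 0.80, which no added heterogeneity
  can produce; γ_sd(RPL17) = 0 and only the means are calibrated there.
- b_sample ~ N(0, 1.2) is the whole-sample WGA offset; it cancels exactly
  in ΔCt (tested) but drives the raw-Ct exclusion rule: with base = 23.5
  the raw TTC3 Ct exceeds 30 for ≈ 9% of diploid samples, the same order
  as the validation subset's 3/43 exclusions.
- η_g (per-gene representation noise) is calibrated so diploid ΔCt SDs are
  exactly 0.56 (TTC3) and 0.80 (RPL17); technical noise ε (SD 0.05) and
  slope jitter (SD 0.05 around −1/log₁₀2 ≈ −3.32) are kept small enough
  that the 3-point OLS slope passes the −3.3 ± 0.4 QC band for nearly all
  samples — a 3-point slope estimate has SE ≈ σ_tech/0.426 per decade, so
  replicate noise above ~0.15 cycles would fail a QC rule that real runs
  are expected to pass.

**Scale interpretation.** The published group values (4.77 ± 0.56 etc.)
are treated as ΔCt versus HSDB, not raw Ct: raw single-cell WGA Cts near
4.8 are implausible and the decision cutoffs (3.85, 0.985) live on the
same scale. The alternative raw-Ct reading is available via
`PipelineConfig.trisomy_scale = "raw_ct"`. The Ct > 30 exclusion always
applies to raw target Ct.

**Operating points.** Because each group's ΔCt is Gaussian by
construction, the population sensitivity/specificity at the published
cutoffs follow in closed form: Φ((3.85−3.39)/0.99) ≈ 0.68 and
Φ((4.77−3.85)/0.56) ≈ 0.95 for TTC3. The validation study's in-sample
92.3%/96.3% came from 13 + 27 embryos with the cutoff Youden-optimised on
those same embryos; no generative model matching the reported group means
and SDs can reproduce that sensitivity out of sample (with mean shift 1.38
and at least diploid noise, sensitivity is bounded by Φ(0.46/0.56) ≈
0.79). The tests therefore check the simulator against the closed-form
operating points and reserve exact reproduction for the count-level
statistics (J = 0.886/0.801, accuracies 95.0%/90.7%), which are arithmetic
identities of the published confusion matrices. The AUC — insensitive to
cutoff choice — *is* reproducible: the binormal value
Φ(1.38/√(0.56² + 0.99²)) ≈ 0.888 matches the reported 0.89, and the
acceptance script re-derives it by simulation at the study's group sizes.

## Statistics

All evaluation statistics are computed from first principles and
cross-checked in tests against independent oracles (O(n²) all-pairs AUC,
direct proportion/contingency recomputation, scikit-learn):

- κ = (p_o − p_e)/(1 − p_e), p_e from marginal products.
- OR = (tn·tp)/(fp·fn) with Woolf log-method CI,
  exp(ln OR ± 1.96·√Σ1/cell); Haldane–Anscombe +0.5 on zero cells
  (flagged). Reported p-values are Wald-type; the validation report's
  "p < 0.001" entries name no test.
- AUC by the Mann–Whitney U identity with midrank tie handling; SE by
  Hanley–McNeil; p against 0.5 by normal approximation at the observed
  AUC.
- Youden-optimal cutoffs scan midpoints between adjacent distinct scores
  (stable under score perturbation, unlike observed-score grids); ties
  break toward higher sensitivity, then the lower cutoff.
- The category logistic regression is a binomial GLM (IRLS) on the SRY and
  DYS14 indicators; with all three observed categories it is saturated, so
  fitted probabilities equal empirical proportions (57.1% = 8/14, 98.8% =
  83/84, and 4.7% = 5/106 for the neither category — the summary-level
  report rounds this last one to 4.4%, which the fit does not force). The
  never-observed SRY-only category's probability (≈ 0.76) is an
  extrapolation and flagged as such.
- Trisomy specificity pools euploid and other-trisomy embryos as negatives
  (the published 26/27 and 31/34 denominators imply pooling);
  `pool_specificity=False` restricts to euploids.

## What passing tests do and do not show

The simulator reproduces the *marginal* behaviour the validation cohort
reports: prevalences, per-locus error rates, group means/SDs, exclusion
rates. It does not model correlated dropout across loci (sample-quality
effects beyond whole-sample failure), mosaicism fractions, stutter/pull-up,
inter-plate drift, or CGH's own 2–9% error rate (truth labels are taken as
exact). Agreement between callers and simulated truth therefore validates
the *decision logic and statistics*, not the wet-lab performance of the
assays on new embryos. Problem sizes in the test suite (5 000–10 000
simulated embryos for rate recovery; 200 replicates for the AUC) were
chosen so that 3-SE binomial bands are a few times tighter than the
effects being checked.

## Known limitations

- Single-gene wells only; overlapping melt transitions are not
  deconvolved.
- Sex-chromosome disorders (Klinefelter, Turner, XYY, XXX) are outside the
  callers' reach — the assays are qualitative by design.
- No aneuploidies other than 18/21; no chromosome-wide CGH simulation.
- The RPL17 trisomy-group variance and the T21/RPL17 group mean (1.77 vs
  diploid 2.19) are not matched by the generative model; only the
  calibrated means listed above are.
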