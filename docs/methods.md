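# Methods

`liverquant` re-implements, as a tested pipeline, the multiparametric MRI
quantification used to monitor liver regeneration in mice after partial
hepatectomy: voxel-wise T1 and T2 relaxometry, two-point diffusion (ADC) and
magnetization-transfer-ratio (MTR) mapping, Rician noise handling, ROI
statistics, slice-summation volumetry, and the longitudinal cohort
statistics. Because no per-animal data are deposited with the study it
emulates, a synthetic layer — a digital liver phantom and a cohort generator
parameterized by the published group trajectories — drives every stage.

## Signal models and quantification

**T1 (inversion-recovery trueFISP).** The transient signal after inversion is

    S(TI) = S0 · (1 − INV · exp(−TI / T1*))

with `S0` the steady-state signal, `INV > 1` the inversion ratio and `T1*`
the apparent relaxation time. The true T1 follows from the Schmitt
correction `T1 = T1* · cos(α/2) · (INV − 1)` with α the flip angle (60° in
the default protocol). The printed form of this correction is typographically
ambiguous (`cos α2` could be read as `cos(α)/2`); we use `cos(α/2)`, the
standard trueFISP effective-flip-angle convention. Exported magnitude images
lose signal polarity, so the fitter models `|S(TI)|` directly rather than
assuming phase-restored data (whether the original analysis restored polarity
is unstated; magnitude fitting is the assumption-free choice). Per-voxel
fits use Levenberg–Marquardt with deterministic starts: `INV₀ = 2`,
`T1*₀ = TI_min/ln 2` from the minimum-magnitude sample (which approximates
the zero crossing `TI₀ = T1* ln INV`), and `S0₀` from the longest-TI signal.
Voxels with `INV ≤ 1`, T1 outside (1, 10000) ms, or a failed fit are masked.

**T2 (multi-echo RARE).** `S(TE) = S0 · exp(−TE/T2) + N`, with `N` an
additive floor absorbing the residual magnitude-noise level. The fit is the
bounded trust-region variant of Levenberg–Marquardt with `S0 ≥ 0`,
T2 ∈ (1, 500) ms, initialized by log-linear regression after subtracting the
minimum signal as the floor estimate. When the background noise level σ is
known (it always is in the pipeline, from the air ROI), the voxel signals
are first corrected by squared subtraction, `Ŝ = √(max(S² − σ², 0))`, and
the residual floor is constrained to `|N| ≤ σ`. This choice matters at the
protocol's five echoes: Monte-Carlo simulation shows the unconstrained
three-parameter fit has ≈5.5% median T2 error at image SNR 50 (driven by a
strong N/T2 anticorrelation), while a one-sided `N ≥ 0` constraint halves
the spread but adds a ≈−2% truncation bias; the symmetric band removes the
excursions on both sides, giving ≈4% median error with <0.1% bias. Voxels
with T2 outside (1, 500) ms are masked.

**ADC (two b-values).** `ADC = ln(S(b₀)/S(b))/b` with b = 800 s/mm². The
high-b image sits at low SNR, where the Rician magnitude bias inflates
`S(b)` and deflates ADC; both images are therefore bias-corrected by squared
subtraction with the background σ before the ratio (toggle `noise_sigma`,
on by default in the pipeline). Voxels with non-positive signals or
attenuation reversal (`S(b) > S(b₀)`, i.e. a negative ADC) are masked.

**MTR.** `MTR = 100 · (M0 − Msat)/M0` percent from the spoiled gradient-echo
pair without/with the MT pre-pulse; voxels with `M0 ≤ 0` or MTR outside
[−10, 100]% are masked.

The plausibility gates (T1, T2, ADC, MTR ranges above) sit roughly an order
of magnitude beyond physiological liver values; they reject only outright
fit failures, never plausible tissue. Non-converged or gated voxels carry a
NaN sentinel internally and are excluded from every derived map and ROI
statistic; exporters replace the sentinel (−1) so no NaN reaches a file.

## Noise model

Magnitude MR images carry Rician noise: `|S + n_re + i·n_im|` with
independent zero-mean Gaussians of SD σ. In pure background the magnitude is
Rayleigh distributed with mean `σ·√(π/2)`; `estimate_background_noise`
inverts this from a rectangular air ROI in the upper-left image corner.
`correct_rician_bias` implements the squared-subtraction correction
`√(max(S² − N², 0))`, clamped at zero.

## Digital phantom and simulated cohort

The phantom is a deliberately schematic 2-D axial slice: an elliptical liver
whose voxel count is matched to a requested volume (exact to one voxel), with
seeded circular vessel cross-sections carrying distinct parameters (long T1,
high ADC, near-zero MTR) so that ROI placement must avoid them. Defaults:
48×48 grid at 0.234×0.234×1.5 mm (the relaxometry protocol's voxel
geometry), 56 mm³ liver (≈650 parenchyma voxels), three vessels of radius 2
voxels. Anatomical realism is out of scope — no registration is performed
downstream, so only the statistical structure (tissue contrast, vessels,
background) matters.

Acquisition simulation applies the forward model of the requested contrast
voxel-wise and then Rician noise. The default protocols reproduce the
study's sequences: 60 inversion times from 90 ms in 144 ms steps (flip 60°,
4 averages); echo times {11, 33, 55, 77, 99} ms (2 averages; of the
protocol's seven repetition times only the longest, 4000 ms, is simulated —
the echo-decay model carries no TR term, and how the other TRs entered the
original fit is unstated); b ∈ {0, 800} s/mm² (8 averages); MT off/on
(8 averages). Averages are applied as complex averaging, i.e. the effective
noise SD is σ/√AVG; a stated SNR is realised per series as the parenchyma
signal of the *first acquired volume* divided by the per-excitation σ — the
conventional image-SNR reference.

The cohort generator draws per-animal trajectories for the four surgical
groups — conventional 70% resection (cPH, n=8), extended 86% resection
(ePH, n=7), the fatal post-hepatectomy liver-failure subgroup (PLF, n=4) and
SHAM surgery (n=3) — over post-operative days 0, 1, 2, 3, 5, 7. Group means
and SDs default to the published summary trajectories of relative liver
volume, T1, T2, ADC and MTR. Each animal deviates from its group mean by
one standard-normal intercept per parameter, scaled by the per-cell SD, so
an animal sits consistently above or below its group across days; since only
mean±SD per cell is published, no further day-to-day covariance is imposed
(a documented simplification — real repeated measures are likely more
strongly autocorrelated, so passing tests say nothing about within-animal
dynamics). Censoring reproduces the published tables exactly: PLF records
end after day 3 (two deaths on day 2, two on day 3, implemented as record
truncation, not survival modeling), and one ePH animal misses the T2
measurement from day 5 on. All randomness flows from a single seed;
identical seeds give bit-identical tables.

What the generator does *not* emulate: respiratory-motion or triggering
jitter, B0/B1 inhomogeneity, partial-volume effects at the liver boundary,
inter-sequence misregistration, and any histological correlate. Recovery
results on the phantom therefore bound only the estimator's statistical
behaviour, not these systematic effects.

## ROI statistics and volumetry

Three circular ROIs are placed automatically in the largest vessel-free
parenchyma region (greedy selection on the Euclidean distance transform,
deterministic), standing in for the study's three manually drawn polygons
"avoiding large vessel structures". A voxel belongs to a polygon iff its
centre lies inside (even-odd rule, boundary centres included; polygons are
normalized to counter-clockwise orientation so the rule is independent of
vertex ordering). The reported statistic is the mean of the three ROI means
and their SD — whether the original aggregate was a mean of ROI means or a
voxel-pooled mean is unstated; mean-of-means is the default here.

Liver volume is the slice-summation rule: voxel count × voxel area × slice
thickness (0.117×0.117 mm² × 0.234 mm in the volumetric protocol), and
relative volume is percent of the pre-operative (day 0) value.

## Cohort statistics

Group summaries report n, mean and SD (n−1 denominator) per
(group, day, parameter) cell, leaving censored cells absent. Percent changes
against baseline are computed on group means (this choice, rather than
averaging per-animal changes, reproduces all nine printed integer percent
figures) and rounded half-up to integers. One printed figure — the ADC
decrease of the extended-resection group on day 1 — is not derivable from
the published group means (they give 32%, the text prints 21%) and is
excluded from the pass/fail fixture.

The two-way (group × day) fixed-effects ANOVA runs on available cells of the
unbalanced, censored design: main effects are Type-II model comparisons
(group adjusted for day and vice versa), the interaction is tested against
the additive model, with rank-based degrees of freedom so empty cells need
no imputation. Pairwise group contrasts at each day use the pooled residual
mean square of the full model; the Bonferroni family is all per-day pairwise
contrasts computed for one parameter (the original family is unstated; this
is the most conservative reading consistent with per-day significance
statements). Behavioural properties — null calibration of the omnibus test
at 5% and power under a 3-SD offset — are tested rather than any specific
p-value, since the original software's sum-of-squares convention is unknown.

Pearson correlations pool (animal, day) pairs of a parameter against
relative volume within a group, with two-sided p from the t-distribution
(n−2 df). The logistic-regression layer fits death-by-PLF against the four
MR parameters of all extended-resection animals on a given day (maximum
likelihood, predictors standardized internally for conditioning), reporting
coefficients, the likelihood-ratio omnibus test, and Nagelkerke
R² = (1 − (L0/L1)^(2/n))/(1 − L0^(2/n)); complete separation is flagged, not
fatal. The study's animal-level statistics (e.g. r = −0.81 for T1 vs volume
after extended resection, omnibus p = 0.292, R² = 0.528) cannot be
reproduced without the per-animal data; the package instead verifies its
statistics against closed-form oracles and simulation calibration, and the
simulated cohorts yield correlations of the same sign and magnitude.

## Numerical choices and problem sizes

Levenberg–Marquardt is capped at 200 iterations (×4 function evaluations)
with relative tolerance 1e-8; non-converged voxels are masked rather than
reported. All grids are row-major with 0-based indices; NIfTI affines are
carried through untouched; times are ms, b-values s/mm², ADC mm²/s
internally (reported as 10⁻³ mm²/s), MTR percent.

The end-to-end pipeline fits, by default, only the voxels inside the three
ROIs (`fit_scope="roi"`); the full liver mask is available via
`fit_scope="liver"`. Default problem sizes — a 48×48 phantom, ≈650
parenchyma voxels for recovery studies, 22 animals × up to 6 days, 1000
replicates for null calibration — were chosen so a complete verification run
finishes in minutes on one CPU while keeping ≥500 voxels per recovery
statistic and Monte-Carlo error well below the tolerances tested.

Reproduction of the group means by the full pipeline is judged per cell by
the z-score of the recovered group mean against the published mean, with
SE = published SD/√n. With ~100 populated cells and per-cell z approximately
standard normal, requiring every cell within 2 SE would fail almost surely
by chance alone; the pipeline therefore asserts ≥90% of cells within 2 SE
and none beyond 4 SE — the calibration property a correctly unbiased
pipeline should satisfy.

## Known limitations

- Single-slice 2-D phantoms; multi-slice mapping is supported by the data
  model but not exercised by the default pipeline.
- No IVIM/multi-compartment diffusion, no T2*, no quantitative (two-pool)
  MT, no B1 correction — matching the scope of the emulated analysis.
- The T2 protocol's seven TR values are reduced to the longest TR.
- The ANOVA is fixed-effects on available cells; repeated-measures
  covariance is ignored (as in the emulated analysis).
- Logistic regression on 11 animals with 4 predictors is fragile by nature;
  separation is flagged rather than resolved (no penalized inference).
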