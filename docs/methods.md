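# Methods

## Problem setting

Resting-state fMRI analyses censor motion-corrupted frames and exclude
participants left with too little clean data. Because in-scanner motion is
correlated with participant characteristics — especially in children — the
resulting list-wise deletion is missing-at-random at best and plausibly
missing-not-at-random. `scrubaudit` implements the full audit chain for
this problem: framewise displacement (FD) and censoring, multi-condition
inclusion flags, logistic exclusion-bias models, excess-missingness
trajectories, and QC-FC distance-dependence diagnostics, exercised on a
synthetic cohort whose motion and connectivity structure encode the
assumptions under audit.

## Motion QC

**Framewise displacement.** FD(t) is the sum of absolute backward
differences of the six rigid-body realignment parameters, with the three
rotations converted to arc length on a sphere of radius `head_radius_mm`
(default 50 mm, configurable). FD(0) := 0 — the first frame has no
predecessor; keeping it in the series (rather than dropping it) keeps frame
counts aligned between FD series, censor masks, and time series.

**Respiratory filtering.** Breathing-induced apparent motion concentrates
in a narrow band (default stopband 0.31–0.43 Hz, inside the Nyquist range
of TR = 0.8 s sampling). A zero-phase order-2 Butterworth band-stop
(`scipy.signal.sosfiltfilt`, so 4th-order magnitude response) is applied,
by default to the six parameter series before differencing; a `fd_series`
mode filters the FD trace directly (with negative excursions clipped at
zero) for pipelines that postprocess FD itself. Measured response at
TR = 0.8 s: a 0.35 Hz sinusoid is attenuated to ~6% of its amplitude,
0.05 Hz content and DC pass within 0.1%. The filter is *not* numerically
idempotent: the residual after one pass lives at the transition-band edges,
and a second pass changes broadband input by roughly 7–10% RMS (passband
content changes by <1%). Sharper designs trade this against worse ringing
at the stopband center, so the order-2 design is kept. Series shorter than
30 frames are rejected (edge-padding warm-up).

**Censoring.** Two passes: (1) censor every frame with filtered FD strictly
above the threshold (a tie is kept — the rule is "exceeding"); (2) censor
every maximal run of still-kept frames of length ≤ `min_island` (default 5)
that is flanked by censored frames. Runs touching the start or end of an
acquisition are treated as flanked by default
(`censor_boundary_islands=True`) — the conservative convention — with the
alternative available as a switch, since consortium practice is not
documented either way. Runs are censored independently; no cross-run
difference contributes to FD.

**Inclusion rule.** A participant is excluded at a threshold when the total
retained frames across runs is strictly below `min_retained_frames`
(default 375 = 5 minutes at TR 0.8 s; 374 excluded, 375 included).

**Mean FD.** Downstream analyses summarize each subject by mean *filtered*
FD over all frames of all runs (pre-censoring). Whether consortium
pipelines use filtered or unfiltered, all-frame or retained-frame means is
not documented; both choices are switches, and the defaults are stated
here once and used everywhere.

## Inclusion conditions

Eight pathways are assembled into a subjects × conditions boolean table:
`T` (pre-tabulated visual-inspection flag), `C` (pre-motion preprocessing
failure), five scrubbing thresholds 0.5/0.4/0.3/0.2/0.1 mm (each ORed with
`C`, since a preprocessing failure never reaches motion correction), and
`R` (segmentation failure OR fewer than 375 frames at the 0.2 mm
threshold). In simulation, `T` and `C` and the segmentation flag are
Bernoulli draws from logistic models with configurable covariate and site
effects; what "failed visual inspection" means operationally is not public,
so the simulated `T` is a declared abstraction. Percentages are reported to
one decimal with the full cohort as denominator.

## Bias analysis

- FD–covariate association: Pearson r (continuous covariates) within each
  threshold condition's included sample, p-values from the corresponding
  bivariate linear model; categorical covariates via OLS of mean FD
  z-scored within the analysis sample on treatment-coded levels, so each
  β is an SD-unit shift against the reference level, with the omnibus F.
- Exclusion models: logistic regression via statsmodels, bivariate (one
  covariate per model; 136 models for 17 covariates × 8 conditions) and
  adjusted (all covariates in a single step, optionally plus site and/or
  scanner factors). ORs are exponentiated coefficients with Wald CIs
  (default 90%, configurable); the Wald construction makes "CI excludes 1"
  and "p < 1 − level" agree by construction. Complete separation and
  non-convergence produce flagged rows, never silent estimates; a
  single-class outcome or rank-deficient design is an error (aliased
  columns listed). Unobserved category levels are dropped per model;
  an absent reference level is an error. Complete-case handling per model.
- Bonferroni: within-family correction `min(1, p × family size)` for the
  two declared families — neighborhood (ADI, COI) and general cognitive
  ability (WISC matrix reasoning, NIHTB total, NIHTB crystallized). The
  flanker score measures inhibitory control and stands alone. No other
  correction is applied.
- Excess missingness: per condition and subgroup, the subgroup exclusion
  percentage minus the whole-sample percentage (percentage points), plotted
  against the whole-sample percentage. The excess is identically zero at 0%
  and 100% overall exclusion, so any covariate-linked bias must peak at an
  interior amount of data loss. Default subgroups are ±1.5 SD cuts on
  motion-loaded continuous covariates plus a categorical example;
  configurable via `GroupSpec`.

## QC-FC diagnostics

Connectivity is the Pearson correlation over retained frames (≥ 3
required), optionally Fisher-z transformed (|r| clipped at 1 − 1e−7);
zero-variance ROIs flag their edges undefined rather than dropping them.
QC-FC is the across-subject correlation between each edge and subject mean
FD; subjects with an undefined edge are dropped for that edge only, with
counts recorded. The distance summary is OLS of QC-FC on raw inter-ROI
Euclidean distances — bins (equal-count, median QC-FC) are presentation
only — with a Wald CI at 99% by default. Connectivity enters as Fisher z by
default and mean FD as the all-frame filtered mean; both are switches,
since the convention is not standardized. For censored conditions the
QC-FC sample is the condition's included subjects (a fully scrubbed subject
has no connectivity estimate).

## Synthetic cohort

The generator is the package's study-condition definition; its defaults are
chosen once, from the acquisition design and published cohort-level rates,
and are not tuned per analysis.

**Covariates.** A 17-dimensional Gaussian copula: continuous covariates are
standardized latent normals; categorical ones cut their latent at quantiles
of fixed marginal frequencies. The correlation matrix encodes correlated
disadvantage (income/education/opportunity move together, deprivation
opposes them, cognition correlates with SES, puberty with age, BMI weakly
with SES); the p/internalizing/externalizing factor scores are mutually
orthogonal, mirroring their bifactor construction, and independent of the
rest. These copula correlations are stated placeholders for a US pediatric
cohort — plausible structure, not estimates of any particular study — and
that is their documented status.

**Motion.** Six parameter series per run: AR(1) noise (φ = 0.4, innovation
SD 0.015 mm for translations and 0.015/50 rad for rotations, per-subject
lognormal scale factor with σ = 0.3), a respiratory sinusoid (0.35 Hz,
0.04 mm, on the y/z translations with random phase), and single-frame
displacement spikes. A latent motion propensity λ = Σ effects·z +
N(0, 1.3²) raises the per-frame spike probability through a logistic link
(base rate 0.04); spike magnitude is 0.1 mm + Exp(0.35 mm) on a random
translation axis, so FD exceedances occur at graded rates across all five
thresholds. Default covariate effects follow the motion literature's signs
(BMI +0.30, age −0.12, total cognition −0.15, opportunity −0.12,
deprivation +0.10, p-factor +0.08, male sex +0.20 on the log scale).
The noise scales were set so that the default attrition profile matches the
published cohort the simulator emulates (~19% pre-motion, ~27% cumulative
by 0.2 mm, ~55% at 0.1 mm), and the resulting mean filtered FD (~0.15 mm)
is realistic for 9–10-year-olds.

**Pre-motion flags.** `preqc_fail` (base rate 0.19), `t_fail` (0.043) and
`seg_fail` (0.05) are logistic draws with configurable covariate effects;
site is assigned uniformly or assorted with a configured covariate, with
optional per-site log-odds offsets on `preqc_fail` (the lever used for the
site-confounding sensitivity analysis); scanner is a deterministic function
of site.

**Connectivity artifact.** ROI time series are latent network signal (five
shared components plus white noise) plus a motion-locked artifact: at frame
t, δ · max(FD_unfiltered(t) − floor, 0) · L w(t), where L is the Cholesky
factor of the kernel exp(−d/λ_d) over ROI centroid distances (λ_d = 60 mm)
and w(t) is white. The per-edge artifact covariance is therefore
δ²·mean(carrier²)·exp(−d/λ_d): positive, decaying with distance, scaled
across subjects by their high-motion frame burden, and carried almost
entirely by frames above the 0.15 mm floor — which is what lets frame
censoring remove it. The literal alternative (a subject-constant artifact
spread uniformly over time) was rejected because censoring could never
attenuate it, contradicting the phenomenon the diagnostic exists to show.

**What the simulator does not emulate.** No volumetric images, no spatial
smoothness or parcellation structure, no scan-to-scan propensity drift, no
nuisance-regression residual structure, no missing covariate values by
default, and the categorical copula is a single-latent cut (no interaction
structure). Passing tests therefore demonstrate that the *pipeline* behaves
correctly under the stated generative assumptions — not that any particular
real cohort shows these effect sizes.

## Numerical and design choices

- Seeds: one `numpy` Generator per cohort, seeded from the config; fixed
  operation order makes cohorts bit-identical across runs. The acceptance
  script derives all child seeds from its `--seed`.
- FD ties at the threshold are kept; `fd[0] = 0`; filtered FD may be
  negative before clipping only in `fd_series` mode (clipped, frame 0
  re-zeroed).
- The excess-missingness endpoints (0%/100%) return exactly 0 by
  definition, not by floating-point accident.
- Odds ratios are clipped to the exp(±700) representable range before
  exponentiation; near-separation fits at tiny n surface as flagged rows
  or wide CIs rather than exceptions.
- The inverted-U trajectory is a property of cohorts whose motion effects
  are strong enough for the high-risk subgroup to saturate before the
  strictest threshold (effects around 1.2 log-units for a +1.5 SD
  subgroup); under the default, weaker effect sizes the peak can sit at
  the strictest condition because exclusion there (~55%) is still in the
  steep part of the propensity distribution. The end-to-end checks
  construct the strongly graded case explicitly.
- Problem sizes in the test and acceptance runs (cohorts of 120–3000
  subjects, 4–60 ROIs, 50-seed replications) were chosen as the smallest
  sizes at which the audited effects are comfortably resolved.

## Known limitations

- Wald CIs only (profile likelihood not implemented); at small n with rare
  conditions the Wald interval is approximate, which the coverage check
  quantifies.
- The respiratory filter's non-idempotence is inherent to the narrow-band
  IIR design (documented above).
- The brute-force censoring oracle lives in the test suite; the production
  implementation is vectorised but per-run (a pure-Python loop over runs),
  adequate up to a few thousand subjects, not optimized for consortium
  scale.
- Real cohort inputs are supported through the documented TSV/CSV formats,
  but no BIDS discovery or confounds-file dialect detection is attempted
  beyond the declared schema.
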