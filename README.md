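# scrubaudit

Motion quality control in resting-state fMRI removes data, and it does not
remove it at random. Frames corrupted by head motion are censored
("scrubbed"), and participants left with too little clean data are dropped
from analysis — but motion tracks age, body mass, socioeconomic context,
cognition, and psychopathology, so list-wise deletion quietly reshapes the
sample along exactly the variables developmental researchers care about.
`scrubaudit` is a library for quantifying that trade-off. It is aimed at
neuroimaging methodologists and analysts of large pediatric cohorts who
want to audit, before modelling, who their QC pipeline throws away and what
the censoring buys in artifact control.

The package provides, as importable building blocks:

- **Synthetic cohorts** (`generate_cohort`): 17 covariates with a
  correlated-disadvantage dependence structure, per-run six-parameter
  rigid-body motion traces (AR(1) noise + respiratory oscillation +
  covariate-graded displacement spikes), ROI geometry, and ROI time series
  carrying a motion-locked, distance-decaying connectivity artifact.
- **Motion QC** (`compute_fd`, `filter_respiratory`, `build_censor_mask`,
  `flag_motion_exclusion`): framewise displacement by the Power convention,

  FD(t) = |Δdx| + |Δdy| + |Δdz| + r·(|Δα| + |Δβ| + |Δγ|),  r = 50 mm,

  zero-phase band-stop filtering of the respiratory band (0.31–0.43 Hz),
  two-pass censoring (FD > threshold, then every island of ≤ 5 contiguous
  kept frames), and the inclusion rule: fewer than 375 retained frames
  (5 min at TR = 0.8 s) across runs ⇒ excluded.
- **Inclusion conditions** (`assemble_conditions`): the eight pathways a
  participant can drop out — pre-tabulated visual QC (T), pre-motion
  preprocessing (C), scrubbing at 0.5/0.4/0.3/0.2/0.1 mm, and the
  recommended flag (R) — as a subjects × conditions exclusion table.
- **Bias analysis** (`fit_bivariate_exclusion`, `fit_adjusted_exclusion`,
  `correlate_fd_continuous`, `contrast_fd_categorical`,
  `excess_missingness_trajectory`): logistic odds of exclusion per covariate
  and condition, OR = exp(β) with 90% Wald CIs, Bonferroni families for
  neighborhood and cognition measures, FD–covariate correlations and
  contrasts, and each subgroup's exclusion excess over the sample average.
- **QC-FC diagnostics** (`compute_connectivity`, `compute_qcfc`,
  `qcfc_distance_summary`): per-edge correlation across subjects between
  connectivity and mean FD, regressed on inter-ROI Euclidean distance with
  a 99% CI on the slope — the standard residual-motion-artifact check.

A thin `scrubaudit` CLI (`simulate`, `fd`, `censor`, `conditions`, `bias`,
`qcfc`, `audit`) wraps the library; `audit` runs the whole chain from a
YAML config in one deterministic invocation. The `examples/` directory
holds one short narrative script per capability.

## Worked example

```python
import scrubaudit as sa

cohort = sa.generate_cohort(
    sa.CohortConfig(n_subjects=400, n_rois=10, seed=7, make_timeseries=False)
)
qc = sa.run_motion_qc(cohort)
table = sa.assemble_conditions(cohort.records, qc.retention)
print(sa.condition_summary(table).to_string(index=False))
```

prints

```
condition  n_excluded  pct_excluded  n_included
        T          26           6.5         374
        C          78          19.5         322
      0.5          82          20.5         318
      0.4          82          20.5         318
      0.3          89          22.2         311
        R          46          11.5         354
      0.2         102          25.5         298
      0.1         209          52.2         191
```

Roughly a fifth of the cohort is lost before any motion thresholding (C),
attrition grows monotonically as the scrubbing threshold tightens, and the
0.1 mm condition halves the sample. Fitting the bivariate exclusion models
on such a cohort (`examples/03_exclusion_bias_tables.py`) gives, at the
0.2 mm condition, OR = 1.37 [1.24, 1.50] per SD of BMI and OR = 0.72
[0.65, 0.79] per SD of neighborhood opportunity: exclusion odds are graded
in the covariates, i.e. the missingness is not completely at random. The
QC-FC example (`examples/05_qcfc_distance.py`) shows the other side of the
ledger: the uncensored QC-FC/distance slope is −0.0049 per mm (99% CI
excluding zero), collapsing to −0.0004 after scrubbing at 0.2 mm — the
censored frames carried the artifact.

## Layout

```
src/scrubaudit/   cohort.py motion.py pipeline.py conditions.py
                  bias.py qcfc.py io.py audit.py cli.py
tests/            unit, property and end-to-end suites
examples/         one narrative script per capability
docs/methods.md   model, assumptions, parameter choices, limitations
```
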