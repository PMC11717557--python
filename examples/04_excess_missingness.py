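"""The excess-missingness trajectory: how subgroup bias evolves as QC
tightens.

For each condition, a subgroup's exclusion percentage minus the
whole-sample percentage (percentage points). Zero means exclusion hits the
subgroup at the sample-average rate; the excess is exactly zero when
nobody or everybody is excluded, so it must peak somewhere in between.
"""

import scrubaudit as sa

cohort = sa.generate_cohort(
    sa.CohortConfig(
        n_subjects=1200, n_rois=4, seed=5,
        covariate_effects={"bmi_z": 1.2}, preqc_fail_effects={},
        make_timeseries=False,
    )
)
qc = sa.run_motion_qc(cohort)
table = sa.assemble_conditions(cohort.records, qc.retention)

traj = sa.excess_missingness_trajectory(
    cohort.records, table,
    group_specs=[sa.GroupSpec("BMI z >= 1.5", "bmi_z", lo=1.5)],
    conditions=("C", "0.5", "0.4", "0.3", "0.2", "0.1"),
)
print(traj[["condition_id", "pct_data_excluded", "group_pct_excluded",
            "excess_missingness"]].to_string(index=False, float_format="%.1f"))
print(
    "\nReading the curve left to right (more data excluded): the high-BMI "
    "group is excluded at an ever-higher excess rate through the liberal "
    "thresholds, peaks before the strictest condition, then declines at "
    "0.1 mm — once most high-motion subjects are already gone, further "
    "tightening removes everyone at more similar rates."
)
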