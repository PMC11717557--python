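"""Who gets excluded? Bivariate and adjusted odds-ratio tables.

Fits one logistic model per covariate x condition (unconditional effects)
and one all-covariate model per condition, reporting odds ratios with 90%
Wald intervals, Bonferroni-corrected within the neighborhood and cognition
families.
"""

import pandas as pd

import scrubaudit as sa

pd.set_option("display.width", 120)

cohort = sa.generate_cohort(
    sa.CohortConfig(n_subjects=1500, n_rois=4, seed=11, make_timeseries=False)
)
qc = sa.run_motion_qc(cohort)
table = sa.assemble_conditions(cohort.records, qc.retention)

bivariate = sa.apply_bonferroni(sa.fit_bivariate_exclusion(cohort.records, table))
show = bivariate[
    (bivariate["condition_id"] == "0.2")
    & bivariate["covariate"].isin(["bmi_z", "age", "nihtb_total", "coi", "p_factor"])
][["covariate", "odds_ratio", "ci_low", "ci_high", "p_value", "p_corrected"]]
print("bivariate odds of exclusion at the 0.2 mm condition:")
print(show.to_string(index=False, float_format="%.3f"))
print(
    "\nAn odds ratio above 1 means a one-SD increase in the covariate raises "
    "the odds of being excluded; BMI and psychopathology load positively, "
    "age, cognition and neighborhood opportunity protectively — exclusion "
    "is not missing completely at random."
)

adjusted = sa.fit_adjusted_exclusion(cohort.records, table, conditions=("0.2",))
show = adjusted[adjusted["covariate"].isin(["bmi_z", "age", "nihtb_total", "coi"])]
print("\nsame covariates, adjusted model (all 17 entered in a single step):")
print(
    show[["covariate", "odds_ratio", "ci_low", "ci_high", "p_value"]]
    .to_string(index=False, float_format="%.3f")
)
print(
    "\nAdjusted estimates shrink where covariates share variance (the "
    "correlated-disadvantage block), but the gradient survives adjustment."
)
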