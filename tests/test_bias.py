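"""Covariate-motion correlations, contrasts, exclusion odds ratios,
Bonferroni families, and the excess-missingness trajectory."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import scrubaudit as sa
from scrubaudit.bias import GroupSpec
from scrubaudit.cohort import CATEGORY_LEVELS


def _full_table(subject_ids, excluded_ids, conditions=("C",)):
    tab = pd.DataFrame(index=pd.Index(subject_ids, name="subject_id"))
    for cond in conditions:
        tab[cond] = [s in excluded_ids for s in subject_ids]
    return tab


def _direct_logistic_records(rng, n, log_or, base_logit=-1.1):
    """Exclusion generated straight from the logistic model on one
    standardized covariate (the estimator's own generating process)."""
    x = rng.standard_normal(n)
    y = rng.random(n) < expit(base_logit + log_or * x)
    records = pd.DataFrame({"subject_id": [f"s{i}" for i in range(n)], "x": x})
    table = pd.DataFrame({"C": y}, index=pd.Index(records["subject_id"], name="subject_id"))
    return records, table


class TestCorrelateContinuous:
    def test_covariate_equal_to_fd_gives_r_of_one(self, small_cohort, small_qc, small_table):
        records = small_cohort.records.copy()
        fd = small_qc.mean_fd_filtered
        records["bmi_z"] = fd.reindex(records["subject_id"]).to_numpy()
        res = sa.correlate_fd_continuous(
            records, fd, small_table, conditions=("0.5",), covariates=("bmi_z",)
        )
        assert res["estimate"].iloc[0] == pytest.approx(1.0)

    def test_zero_variance_flagged_undefined_not_zero(self, small_cohort, small_qc, small_table):
        records = small_cohort.records.copy()
        records["age"] = 0.0
        res = sa.correlate_fd_continuous(
            records, small_qc.mean_fd_filtered, small_table,
            conditions=("0.5",), covariates=("age",),
        )
        assert bool(res["undefined"].iloc[0])
        assert np.isnan(res["estimate"].iloc[0])

    def test_independent_covariate_correlation_is_small(self):
        cfg = sa.CohortConfig(
            n_subjects=2000, n_rois=4, seed=77,
            covariate_effects={}, preqc_fail_effects={}, make_timeseries=False,
        )
        cohort = sa.generate_cohort(cfg)
        qc = sa.run_motion_qc(cohort)
        table = sa.assemble_conditions(cohort.records, qc.retention)
        res = sa.correlate_fd_continuous(
            cohort.records, qc.mean_fd_filtered, table, conditions=("0.5",)
        )
        assert (res["estimate"].abs() < 0.05).all()


class TestContrastCategorical:
    def _records_with_fd_shift(self, n=400, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        sex = np.where(rng.random(n) < 0.5, "M", "F")
        fd = rng.normal(0.12, 0.03, size=n)
        fd[sex == "M"] += shift * fd.std(ddof=0)
        records = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "sex": pd.Categorical(sex, categories=CATEGORY_LEVELS["sex"]),
            }
        )
        mean_fd = pd.Series(fd, index=records["subject_id"])
        table = _full_table(records["subject_id"], set(), conditions=("0.5",))
        return records, mean_fd, table

    def test_one_sd_group_shift_recovers_beta_near_one(self):
        records, fd, table = self._records_with_fd_shift(shift=1.0, seed=4)
        res = sa.contrast_fd_categorical(
            records, fd, table, conditions=("0.5",), covariates=("sex",)
        )
        beta = res.loc[res["contrast_label"] == "M vs F", "estimate"].iloc[0]
        assert beta == pytest.approx(1.0, abs=0.15)

    def test_null_shift_gives_small_beta(self):
        records, fd, table = self._records_with_fd_shift(shift=0.0, seed=5)
        res = sa.contrast_fd_categorical(
            records, fd, table, conditions=("0.5",), covariates=("sex",)
        )
        assert abs(res["estimate"].iloc[0]) < 0.25
        assert res["omnibus_f_p"].iloc[0] > 0.01

    def test_single_level_covariate_is_an_error(self):
        records, fd, table = self._records_with_fd_shift()
        records["sex"] = pd.Categorical(["F"] * len(records),
                                        categories=CATEGORY_LEVELS["sex"])
        with pytest.raises(ValueError, match="single level"):
            sa.contrast_fd_categorical(
                records, fd, table, conditions=("0.5",), covariates=("sex",)
            )

    def test_absent_reference_level_is_an_error(self):
        records, fd, table = self._records_with_fd_shift()
        # two observed income levels, but the reference level never occurs
        records["income_level"] = pd.Categorical(
            np.where(np.arange(len(records)) % 2 == 0, "<$25k", ">$200k"),
            categories=CATEGORY_LEVELS["income_level"],
        )
        with pytest.raises(ValueError, match="reference level"):
            sa.contrast_fd_categorical(
                records, fd, table, conditions=("0.5",),
                covariates=("income_level",),
            )


class TestBivariateExclusion:
    def test_known_log_odds_effect_recovered(self):
        rng = np.random.default_rng(11)
        ors = []
        for _ in range(10):
            records, table = _direct_logistic_records(rng, 4000, np.log(1.5))
            res = sa.fit_bivariate_exclusion(records, table, covariates=("x",))
            ors.append(res["odds_ratio"].iloc[0])
        assert 1.35 < np.median(ors) < 1.65

    def test_wald_ci_and_p_value_agree_about_one(self):
        rng = np.random.default_rng(12)
        records, table = _direct_logistic_records(rng, 1500, 0.25)
        res = sa.fit_bivariate_exclusion(records, table, ci_level=0.90,
                                         covariates=("x",))
        row = res.iloc[0]
        excludes_one = row["ci_low"] > 1.0 or row["ci_high"] < 1.0
        assert excludes_one == (row["p_value"] < 0.10)
        assert row["ci_low"] <= row["odds_ratio"] <= row["ci_high"]

    def test_intercept_only_model_returns_exact_odds(self):
        sids = [f"s{i}" for i in range(400)]
        table = _full_table(sids, set(sids[:100]))  # exactly 25% excluded
        records = pd.DataFrame({"subject_id": sids})
        res = sa.fit_adjusted_exclusion(records, table, covariates=())
        odds = res.loc[res["covariate"] == "Intercept", "odds_ratio"].iloc[0]
        assert odds == pytest.approx(1.0 / 3.0, rel=1e-4)

    def test_single_class_outcome_names_condition(self):
        sids = [f"s{i}" for i in range(50)]
        records = pd.DataFrame({"subject_id": sids, "x": np.arange(50.0)})
        table = _full_table(sids, set())
        with pytest.raises(ValueError, match="'C'"):
            sa.fit_bivariate_exclusion(records, table, covariates=("x",))

    def test_complete_separation_is_flagged_not_estimated(self):
        sids = [f"s{i}" for i in range(60)]
        x = np.arange(60.0)
        records = pd.DataFrame({"subject_id": sids, "x": x})
        table = _full_table(sids, {f"s{i}" for i in range(30, 60)})
        res = sa.fit_bivariate_exclusion(records, table, covariates=("x",))
        assert (res["flag"] == "separation").all()
        assert res["odds_ratio"].isna().all()

    def test_categorical_covariate_expands_to_reference_coded_terms(
        self, small_cohort, small_table
    ):
        res = sa.fit_bivariate_exclusion(
            small_cohort.records, small_table,
            covariates=("trauma_count",), conditions=("0.1",),
        )
        assert set(res["contrast_label"]) == {"1 vs 0", "2+ vs 0"}


class TestAdjustedExclusion:
    def test_confounded_covariate_attenuates_toward_one(self):
        rng = np.random.default_rng(21)
        n = 6000
        a = rng.standard_normal(n)
        b = 0.6 * a + np.sqrt(1 - 0.36) * rng.standard_normal(n)
        y = rng.random(n) < expit(-1.1 + 0.8 * a)  # effect on A only
        records = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(n)], "a": a, "b": b}
        )
        table = pd.DataFrame({"C": y}, index=pd.Index(records["subject_id"],
                                                      name="subject_id"))
        biv = sa.fit_bivariate_exclusion(records, table, covariates=("a", "b"))
        adj = sa.fit_adjusted_exclusion(records, table, covariates=("a", "b"))
        or_b_biv = biv.loc[biv["covariate"] == "b", "odds_ratio"].iloc[0]
        or_b_adj = adj.loc[adj["covariate"] == "b", "odds_ratio"].iloc[0]
        assert or_b_biv > 1.15  # confounding leaks through marginally
        assert abs(np.log(or_b_adj)) < abs(np.log(or_b_biv))
        assert or_b_adj == pytest.approx(1.0, abs=0.12)

    def test_rank_deficient_design_lists_aliased_terms(self):
        rng = np.random.default_rng(22)
        n = 200
        a = rng.standard_normal(n)
        records = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(n)], "a": a, "b": 2.0 * a}
        )
        y = rng.random(n) < 0.3
        table = pd.DataFrame({"C": y}, index=pd.Index(records["subject_id"],
                                                      name="subject_id"))
        with pytest.raises(ValueError, match="rank deficient"):
            sa.fit_adjusted_exclusion(records, table, covariates=("a", "b"))

    def test_site_control_attenuates_site_driven_covariate(self):
        cfg = sa.CohortConfig(
            n_subjects=2500, n_rois=4, seed=7,
            covariate_effects={}, preqc_fail_effects={},
            site_assortment_covariate="coi", site_assortment_strength=1.0,
            site_preqc_effects=(1.2, 0.4, -0.4, -1.2),
            make_timeseries=False,
        )
        cohort = sa.generate_cohort(cfg)
        qc = sa.run_motion_qc(cohort)
        table = sa.assemble_conditions(cohort.records, qc.retention)
        no_site = sa.fit_adjusted_exclusion(cohort.records, table, conditions=("C",))
        with_site = sa.fit_adjusted_exclusion(
            cohort.records, table, conditions=("C",), include_site=True
        )
        a = no_site.loc[no_site["covariate"] == "coi", "odds_ratio"].iloc[0]
        b = with_site.loc[with_site["covariate"] == "coi", "odds_ratio"].iloc[0]
        assert abs(np.log(b)) < abs(np.log(a))


class TestBonferroni:
    def _results(self, rows):
        return pd.DataFrame(
            [
                {"covariate": cov, "condition_id": "C", "p_value": p}
                for cov, p in rows
            ]
        )

    def test_family_of_two_doubles_p(self):
        res = sa.apply_bonferroni(self._results([("adi", 0.03)]))
        assert res["p_corrected"].iloc[0] == pytest.approx(0.06)

    def test_correction_caps_at_one(self):
        res = sa.apply_bonferroni(self._results([("nihtb_total", 0.5)]))
        assert res["p_corrected"].iloc[0] == 1.0

    def test_unfamilied_covariate_unchanged(self):
        res = sa.apply_bonferroni(self._results([("bmi_z", 0.04)]))
        assert res["p_corrected"].iloc[0] == pytest.approx(0.04)
        assert pd.isna(res["corrected_family"].iloc[0])

    def test_unknown_family_member_rejected(self):
        with pytest.raises(ValueError, match="unknown covariate"):
            sa.apply_bonferroni(
                self._results([("adi", 0.1)]), families={"f": ("nope",)}
            )

    def test_covariate_in_two_families_rejected(self):
        with pytest.raises(ValueError, match="families"):
            sa.apply_bonferroni(
                self._results([("adi", 0.1)]),
                families={"f1": ("adi",), "f2": ("adi", "coi")},
            )


class TestTrajectory:
    def _records(self, n=100):
        rng = np.random.default_rng(31)
        return pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "bmi_z": rng.standard_normal(n),
            }
        )

    def test_excess_is_exactly_zero_at_empty_and_full_exclusion(self):
        records = self._records()
        sids = list(records["subject_id"])
        table = _full_table(sids, set(), conditions=("none",))
        table["all"] = True
        traj = sa.excess_missingness_trajectory(
            records, table, group_specs=[GroupSpec("hi", "bmi_z", lo=0.0)]
        )
        assert (traj["excess_missingness"] == 0.0).all()

    def test_toy_group_rate_arithmetic(self):
        records = self._records(100)
        records["bmi_z"] = np.where(np.arange(100) < 50, 2.0, -2.0)
        # group (first 50): 15 excluded (30%); overall: 20 excluded (20%)
        excluded = {f"s{i}" for i in range(15)} | {f"s{i}" for i in range(50, 55)}
        table = _full_table(list(records["subject_id"]), excluded)
        traj = sa.excess_missingness_trajectory(
            records, table, group_specs=[GroupSpec("hi", "bmi_z", lo=1.5)]
        )
        assert traj["excess_missingness"].iloc[0] == pytest.approx(10.0)

    def test_empty_group_warns_and_is_omitted(self):
        records = self._records()
        table = _full_table(list(records["subject_id"]), {"s0"})
        with pytest.warns(UserWarning, match="empty"):
            traj = sa.excess_missingness_trajectory(
                records, table, group_specs=[GroupSpec("none", "bmi_z", lo=99.0)]
            )
        assert len(traj) == 0

    def test_rows_ordered_by_percent_excluded(self, small_cohort, small_table):
        traj = sa.excess_missingness_trajectory(small_cohort.records, small_table)
        for _, g in traj.groupby("group"):
            assert g["pct_data_excluded"].is_monotonic_increasing


class TestMissingnessReport:
    def test_counts_injected_missingness(self, small_cohort):
        records = small_cohort.records.copy()
        records.loc[records.index[:8], "coi"] = np.nan
        rep = sa.covariate_missingness(records).set_index("covariate")
        assert rep.loc["coi", "n_missing"] == 8
        assert rep.loc["adi", "n_missing"] == 0
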