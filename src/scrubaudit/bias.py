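"""Covariate-motion and covariate-exclusion association analyses.

Quantifies how participant characteristics relate to (a) in-scanner motion
and (b) the odds of being excluded under each QC condition:

* Pearson correlations of continuous covariates with subject mean FD within
  each motion-threshold condition's included sample;
* categorical contrasts from bivariate linear models of standardized mean
  FD (per-level standardized betas plus the omnibus F test);
* bivariate logistic models of exclusion (one covariate per model, per
  condition) and fully adjusted models (all 17 covariates in a single
  step, optionally plus site and scanner), reporting odds ratios with Wald
  confidence intervals (default 90%);
* Bonferroni correction within declared covariate families;
* the excess-missingness trajectory: each subgroup's exclusion percentage
  minus the whole-sample percentage, traced across conditions ordered by
  the amount of data excluded.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .cohort import (
    ANALYSIS_COVARIATES,
    CATEGORICAL_COVARIATES,
    CONTINUOUS_COVARIATES,
    REFERENCE_LEVELS,
)
from .conditions import THRESHOLD_CONDITIONS

__all__ = [
    "GroupSpec",
    "DEFAULT_BONFERRONI_FAMILIES",
    "DEFAULT_GROUP_SPECS",
    "correlate_fd_continuous",
    "contrast_fd_categorical",
    "fit_bivariate_exclusion",
    "fit_adjusted_exclusion",
    "apply_bonferroni",
    "excess_missingness_trajectory",
    "covariate_missingness",
]

#: multiple-comparison families: neighborhood characteristics and general
#: cognitive ability (the inhibitory-control flanker score stands alone)
DEFAULT_BONFERRONI_FAMILIES: dict[str, tuple[str, ...]] = {
    "neighborhood": ("adi", "coi"),
    "cognitive": ("wisc_matrix", "nihtb_total", "nihtb_crystallized"),
}

_TERM_LEVEL_RE = re.compile(r"\[T\.(.+)\]$")


def _drop_unused_levels(df: pd.DataFrame, covariates) -> pd.DataFrame:
    """Unobserved category levels would inject all-zero design columns, so
    they are dropped per model; an absent reference level is an error."""
    df = df.copy()
    for cov in covariates:
        if cov in CATEGORICAL_COVARIATES and cov in df.columns:
            col = df[cov]
            if not isinstance(col.dtype, pd.CategoricalDtype):
                col = pd.Categorical(col)
                df[cov] = col
            df[cov] = df[cov].cat.remove_unused_categories()
            ref = REFERENCE_LEVELS[cov]
            if ref not in df[cov].cat.categories:
                raise ValueError(
                    f"reference level {ref!r} of {cov!r} is absent from the "
                    "analysis sample"
                )
    return df


def _cat_formula_term(cov: str) -> str:
    ref = REFERENCE_LEVELS[cov].replace("'", "\\'")
    return f"C({cov}, Treatment('{ref}'))"


def _term_label(term: str, cov: str) -> tuple[str, str | None]:
    """Map a patsy design-matrix column name to (covariate, contrast)."""
    m = _TERM_LEVEL_RE.search(term)
    if m is None:
        return cov, None
    ref = REFERENCE_LEVELS.get(cov)
    return cov, f"{m.group(1)} vs {ref}" if ref else f"{m.group(1)}"


# ---------------------------------------------------------------------------
# FD - covariate association (continuous / categorical)


def correlate_fd_continuous(
    records: pd.DataFrame,
    mean_fd: pd.Series,
    table: pd.DataFrame,
    conditions: Sequence[str] = THRESHOLD_CONDITIONS,
    include_all_subjects: bool = False,
    covariates: Sequence[str] = CONTINUOUS_COVARIATES,
) -> pd.DataFrame:
    """Pearson r between each continuous covariate and subject mean FD.

    By default the correlation is computed within each condition's included
    sample; ``include_all_subjects`` computes it over everyone with FD.
    Zero-variance inputs yield a flagged undefined row, never a silent 0.
    """
    fd = mean_fd.reindex(records["subject_id"]).to_numpy()
    rows = []
    for cond in conditions:
        if include_all_subjects:
            in_sample = np.ones(len(records), dtype=bool)
        else:
            in_sample = ~table[cond].reindex(records["subject_id"]).to_numpy()
        for cov in covariates:
            x = records[cov].to_numpy(dtype=float)
            ok = in_sample & np.isfinite(x) & np.isfinite(fd)
            n = int(ok.sum())
            undefined = n < 3 or np.var(x[ok]) == 0 or np.var(fd[ok]) == 0
            if undefined:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(x[ok], fd[ok])
            rows.append(
                {
                    "covariate": cov,
                    "condition_id": cond,
                    "statistic_type": "pearson_r",
                    "contrast_label": None,
                    "estimate": r,
                    "p_value": p,
                    "n": n,
                    "undefined": undefined,
                }
            )
    return pd.DataFrame(rows)


def contrast_fd_categorical(
    records: pd.DataFrame,
    mean_fd: pd.Series,
    table: pd.DataFrame,
    conditions: Sequence[str] = THRESHOLD_CONDITIONS,
    include_all_subjects: bool = False,
    covariates: Sequence[str] = CATEGORICAL_COVARIATES,
) -> pd.DataFrame:
    """Per-level standardized betas from bivariate linear models of mean FD.

    Mean FD is z-scored within the analysis sample, so each treatment-coded
    beta is the level's FD shift from the reference level in SD units.  The
    omnibus F p-value of each model is attached to every one of its rows.
    """
    fd = mean_fd.reindex(records["subject_id"]).to_numpy()
    rows = []
    for cond in conditions:
        if include_all_subjects:
            in_sample = np.ones(len(records), dtype=bool)
        else:
            in_sample = ~table[cond].reindex(records["subject_id"]).to_numpy()
        sub = records.loc[in_sample].copy()
        fd_s = fd[in_sample]
        if np.std(fd_s) == 0:
            raise ValueError(f"mean FD has zero variance in condition {cond}")
        sub["fd_z"] = (fd_s - fd_s.mean()) / fd_s.std(ddof=0)
        for cov in covariates:
            observed = sub[cov].astype(object).dropna().unique()
            if len(observed) < 2:
                raise ValueError(
                    f"covariate {cov!r} has a single level in condition {cond}; "
                    "a contrast needs at least two"
                )
            if REFERENCE_LEVELS[cov] not in set(observed):
                raise ValueError(
                    f"reference level {REFERENCE_LEVELS[cov]!r} of {cov!r} is "
                    f"absent in condition {cond}"
                )
            data = _drop_unused_levels(sub, (cov,))
            model = smf.ols(f"fd_z ~ {_cat_formula_term(cov)}", data=data).fit()
            for term, beta in model.params.items():
                if term == "Intercept":
                    continue
                _, contrast = _term_label(term, cov)
                rows.append(
                    {
                        "covariate": cov,
                        "condition_id": cond,
                        "statistic_type": "standardized_beta",
                        "contrast_label": contrast,
                        "estimate": beta,
                        "p_value": model.pvalues[term],
                        "omnibus_f_p": model.f_pvalue,
                        "n": int(model.nobs),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# logistic exclusion models


def _collect_or_rows(
    result,
    cov_of_term: Mapping[str, str] | str,
    condition: str,
    ci_level: float,
    adjusted: bool,
    flag: str | None = None,
) -> list[dict]:
    conf = result.conf_int(alpha=1.0 - ci_level)
    rows = []
    np_exp = lambda v: float(np.exp(np.clip(v, -700, 700)))  # noqa: E731
    for term in result.params.index:
        if isinstance(cov_of_term, str):
            cov = cov_of_term
        else:
            cov = cov_of_term.get(term, term)
        if term == "Intercept":
            covariate, contrast = "Intercept", None
        else:
            covariate, contrast = _term_label(term, cov)
        rows.append(
            {
                "covariate": covariate,
                "contrast_label": contrast,
                "condition_id": condition,
                "odds_ratio": np_exp(result.params[term]),
                "ci_low": np_exp(conf.loc[term, 0]),
                "ci_high": np_exp(conf.loc[term, 1]),
                "ci_level": ci_level,
                "p_value": float(result.pvalues[term]),
                "adjusted": adjusted,
                "n": int(result.nobs),
                "flag": flag,
            }
        )
    return rows


def _flagged_rows(cov: str, condition: str, ci_level: float, adjusted: bool,
                  flag: str, n: int) -> list[dict]:
    return [
        {
            "covariate": cov,
            "contrast_label": None,
            "condition_id": condition,
            "odds_ratio": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "ci_level": ci_level,
            "p_value": np.nan,
            "adjusted": adjusted,
            "n": n,
            "flag": flag,
        }
    ]


def _fit_logit(formula: str, data: pd.DataFrame):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.logit(formula, data=data)
        result = model.fit(disp=0, maxiter=200)
    if not result.mle_retvals.get("converged", False) or not np.isfinite(
        result.bse
    ).all():
        raise PerfectSeparationError("non-converged or unstable fit")
    return result


def fit_bivariate_exclusion(
    records: pd.DataFrame,
    table: pd.DataFrame,
    ci_level: float = 0.90,
    covariates: Sequence[str] = ANALYSIS_COVARIATES,
    conditions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One logistic model per covariate x condition (unconditional effects).

    Categorical covariates expand to treatment-coded terms against their
    reference levels.  Complete separation or non-convergence yields a
    flagged row with no estimate.  A condition with a single outcome class
    is an error naming that condition.
    """
    conditions = list(table.columns) if conditions is None else list(conditions)
    rows: list[dict] = []
    excluded = table.reindex(records["subject_id"])
    for cond in conditions:
        y = excluded[cond].astype(int).to_numpy()
        if len(np.unique(y)) < 2:
            raise ValueError(
                f"condition {cond!r} has a single outcome class; the exclusion "
                "model is undefined"
            )
        for cov in covariates:
            df = pd.DataFrame({cov: records[cov].to_numpy(), "excluded": y}).dropna()
            df = _drop_unused_levels(df, (cov,))
            term = (
                _cat_formula_term(cov) if cov in CATEGORICAL_COVARIATES else cov
            )
            try:
                result = _fit_logit(f"excluded ~ {term}", df)
            except (PerfectSeparationError, np.linalg.LinAlgError):
                rows.extend(
                    _flagged_rows(cov, cond, ci_level, False, "separation", len(df))
                )
                continue
            rows.extend(_collect_or_rows(result, cov, cond, ci_level, False))
    out = pd.DataFrame(rows)
    return out[out["covariate"] != "Intercept"].reset_index(drop=True)


def fit_adjusted_exclusion(
    records: pd.DataFrame,
    table: pd.DataFrame,
    ci_level: float = 0.90,
    include_site: bool = False,
    include_scanner: bool = False,
    covariates: Sequence[str] = ANALYSIS_COVARIATES,
    conditions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One logistic model per condition with all covariates entered in a
    single step (optionally plus site and scanner factors).

    Complete-case across all predictors; a rank-deficient design raises an
    error listing the aliased columns.
    """
    conditions = list(table.columns) if conditions is None else list(conditions)
    terms = [
        _cat_formula_term(c) if c in CATEGORICAL_COVARIATES else c
        for c in covariates
    ]
    cov_of_prefix = {
        (_cat_formula_term(c) if c in CATEGORICAL_COVARIATES else c): c
        for c in covariates
    }
    if include_site:
        terms.append("C(site)")
        cov_of_prefix["C(site)"] = "site"
    if include_scanner:
        terms.append("C(scanner)")
        cov_of_prefix["C(scanner)"] = "scanner"
    formula_rhs = " + ".join(terms) if terms else "1"

    use_cols = list(covariates) + (["site"] if include_site else []) + (
        ["scanner"] if include_scanner else []
    )
    base = records[["subject_id"] + use_cols].dropna()
    base = _drop_unused_levels(base, covariates)
    excluded = table.reindex(base["subject_id"])

    rows: list[dict] = []
    for cond in conditions:
        df = base.copy()
        df["excluded"] = excluded[cond].astype(int).to_numpy()
        if df["excluded"].nunique() < 2:
            raise ValueError(
                f"condition {cond!r} has a single outcome class; the exclusion "
                "model is undefined"
            )
        model = smf.logit(f"excluded ~ {formula_rhs}", data=df)
        exog = model.exog
        rank = np.linalg.matrix_rank(exog)
        if rank < exog.shape[1]:
            _, r = np.linalg.qr(exog)
            diag = np.abs(np.diag(r))
            aliased = [
                model.exog_names[j]
                for j in range(len(diag))
                if diag[j] < 1e-8 * diag.max()
            ]
            raise ValueError(
                f"design matrix for condition {cond!r} is rank deficient; "
                f"aliased terms: {aliased}"
            )
        term_cov = {}
        for name in model.exog_names:
            for prefix, cov in cov_of_prefix.items():
                if name.startswith(prefix):
                    term_cov[name] = cov
                    break
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = model.fit(disp=0, maxiter=200)
            if not result.mle_retvals.get("converged", False):
                raise PerfectSeparationError("non-converged")
        except (PerfectSeparationError, np.linalg.LinAlgError):
            rows.extend(
                _flagged_rows("<all>", cond, ci_level, True, "separation", len(df))
            )
            continue
        rows.extend(_collect_or_rows(result, term_cov, cond, ci_level, True))
    return pd.DataFrame(rows)


def apply_bonferroni(
    results: pd.DataFrame,
    families: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Bonferroni-correct p-values within covariate families.

    Within each family the corrected p is ``min(1, p * family_size)``;
    covariates outside every family pass through unchanged.  A covariate in
    more than one family, or a family naming an unknown covariate, is an
    error.
    """
    families = DEFAULT_BONFERRONI_FAMILIES if families is None else families
    seen: dict[str, str] = {}
    for fam, covs in families.items():
        for cov in covs:
            if cov not in ANALYSIS_COVARIATES and cov not in set(
                results["covariate"]
            ):
                raise ValueError(f"family {fam!r} names unknown covariate {cov!r}")
            if cov in seen:
                raise ValueError(
                    f"covariate {cov!r} appears in families {seen[cov]!r} and {fam!r}"
                )
            seen[cov] = fam
    out = results.copy()
    out["corrected_family"] = out["covariate"].map(seen)
    size_of_family = {fam: len(covs) for fam, covs in families.items()}
    factor = out["corrected_family"].map(size_of_family).fillna(1).astype(float)
    out["p_corrected"] = np.minimum(1.0, out["p_value"] * factor)
    return out


# ---------------------------------------------------------------------------
# excess missingness


@dataclass(frozen=True)
class GroupSpec:
    """A subgroup definition for the excess-missingness trajectory.

    Either a categorical ``level`` of ``column``, or a one- or two-sided
    cut on a continuous ``column`` (``lo <= x`` and/or ``x <= hi``).
    """

    name: str
    column: str
    level: str | None = None
    lo: float | None = None
    hi: float | None = None

    def member_mask(self, records: pd.DataFrame) -> np.ndarray:
        if self.level is not None:
            return (records[self.column].astype(object) == self.level).to_numpy()
        x = records[self.column].to_numpy(dtype=float)
        mask = np.isfinite(x)
        if self.lo is not None:
            mask &= x >= self.lo
        if self.hi is not None:
            mask &= x <= self.hi
        return mask


#: illustrative high-risk subgroups (|z| >= 1.5 cuts on motion-loaded
#: covariates plus a categorical example)
DEFAULT_GROUP_SPECS = (
    GroupSpec("BMI z >= 1.5", "bmi_z", lo=1.5),
    GroupSpec("NIHTB total <= -1.5", "nihtb_total", hi=-1.5),
    GroupSpec("p-factor >= 1.5", "p_factor", lo=1.5),
    GroupSpec("Black", "race_ethnicity", level="Black"),
)


def excess_missingness_trajectory(
    records: pd.DataFrame,
    table: pd.DataFrame,
    group_specs: Sequence[GroupSpec] = DEFAULT_GROUP_SPECS,
    conditions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Subgroup exclusion rate minus the whole-sample rate, per condition.

    x is the overall percentage of the sample excluded under the condition;
    y (``excess_missingness``) is the subgroup's percentage minus the
    overall percentage, in percentage points.  At 0% or 100% overall
    exclusion the excess is exactly 0.  Rows are ordered by x within each
    group.  Empty groups are dropped with a warning.
    """
    conditions = list(table.columns) if conditions is None else list(conditions)
    excluded = table.reindex(records["subject_id"])
    n = len(records)
    rows = []
    for spec in group_specs:
        mask = spec.member_mask(records)
        if mask.sum() == 0:
            warnings.warn(f"group {spec.name!r} is empty; omitted", stacklevel=2)
            continue
        for cond in conditions:
            y = excluded[cond].astype(bool).to_numpy()
            overall = 100.0 * y.mean()
            if overall == 0.0 or overall == 100.0:
                excess = 0.0
            else:
                excess = 100.0 * y[mask].mean() - overall
            rows.append(
                {
                    "group": spec.name,
                    "condition_id": cond,
                    "pct_data_excluded": overall,
                    "group_pct_excluded": 100.0 * y[mask].mean(),
                    "excess_missingness": excess,
                    "n_group": int(mask.sum()),
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(["group", "pct_data_excluded"]).reset_index(drop=True)
    return out


def covariate_missingness(records: pd.DataFrame) -> pd.DataFrame:
    """Per-covariate missing-value counts and percentages."""
    n = len(records)
    rows = []
    for cov in ANALYSIS_COVARIATES:
        miss = int(records[cov].isna().sum())
        rows.append(
            {
                "covariate": cov,
                "n_missing": miss,
                "pct_missing": round(100.0 * miss / n, 2) if n else 0.0,
            }
        )
    return pd.DataFrame(rows)
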