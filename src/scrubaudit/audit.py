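"""End-to-end audit pipeline.

One call simulates (or accepts) a cohort, runs motion QC, assembles the
eight inclusion conditions, fits the correlation/contrast/odds-ratio table
analogs, traces excess missingness, computes QC-FC distance diagnostics at
each scrubbing threshold, and writes every artifact as tidy CSV/JSON under
a single output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bias import (
    apply_bonferroni,
    contrast_fd_categorical,
    correlate_fd_continuous,
    excess_missingness_trajectory,
    fit_adjusted_exclusion,
    fit_bivariate_exclusion,
)
from .cohort import Cohort, generate_cohort
from .conditions import assemble_conditions, condition_overlap, condition_summary
from .io import RunConfig, config_hash
from .pipeline import THRESHOLDS_MM, run_motion_qc
from .qcfc import compute_connectivity, compute_qcfc, qcfc_distance_summary

__all__ = ["run_audit"]

log = logging.getLogger("scrubaudit")


def _qcfc_for_masks(cohort, keep, mean_fd, fisher_z, subject_mask=None):
    """QC-FC edges for one censoring condition.

    ``subject_mask`` restricts to the subjects still available in that
    condition (connectivity is undefined for a fully scrubbed subject).
    """
    idx = np.arange(len(cohort.subject_ids))
    if subject_mask is not None:
        idx = idx[np.asarray(subject_mask, dtype=bool)]
    mats = [
        compute_connectivity(
            cohort.timeseries[i],
            None if keep is None else keep[i],
            fisher_z=fisher_z,
            subject_id=cohort.subject_ids[i],
        )
        for i in idx
    ]
    return compute_qcfc(
        mats, mean_fd.to_numpy()[idx], cohort.geometry
    )


def run_audit(
    config: RunConfig,
    out_dir: str | Path,
    seed: int | None = None,
    cohort: Cohort | None = None,
) -> dict:
    """Run the full exclusion-bias audit; returns the run summary dict.

    ``seed`` overrides the cohort config seed.  All outputs land inside
    ``out_dir``; nothing is written elsewhere.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort_cfg = config.cohort
    if seed is not None:
        cohort_cfg = dataclasses.replace(cohort_cfg, seed=seed)
        config = dataclasses.replace(config, cohort=cohort_cfg)
    if cohort is None:
        log.info("simulating cohort: n=%d seed=%d", cohort_cfg.n_subjects, cohort_cfg.seed)
        cohort = generate_cohort(cohort_cfg)

    qc = run_motion_qc(cohort, config.censor)
    table = assemble_conditions(
        cohort.records, qc.retention, config.censor.min_retained_frames
    )

    table.astype(int).reset_index().to_csv(out / "exclusion_table.csv", index=False)
    summary = condition_summary(table)
    summary.to_csv(out / "condition_summary.csv", index=False)
    condition_overlap(table).to_csv(out / "condition_overlap.csv", index=False)
    qc.retention.to_csv(out / "retention.csv", index=False)
    for _, row in summary.iterrows():
        log.info(
            "condition %s: %d excluded (%.1f%%)",
            row["condition"], row["n_excluded"], row["pct_excluded"],
        )

    mean_fd = qc.mean_fd_filtered
    correlate_fd_continuous(cohort.records, mean_fd, table).to_csv(
        out / "table2_correlations.csv", index=False
    )
    contrast_fd_categorical(cohort.records, mean_fd, table).to_csv(
        out / "table3_contrasts.csv", index=False
    )
    bivariate = apply_bonferroni(
        fit_bivariate_exclusion(cohort.records, table, ci_level=config.ci_level)
    )
    bivariate.to_csv(out / "table4_bivariate_or.csv", index=False)
    adjusted = apply_bonferroni(
        fit_adjusted_exclusion(
            cohort.records,
            table,
            ci_level=config.ci_level,
            include_site=config.include_site,
            include_scanner=config.include_scanner,
        )
    )
    adjusted.to_csv(out / "table5_adjusted_or.csv", index=False)
    excess_missingness_trajectory(cohort.records, table).to_csv(
        out / "fig5_trajectory.csv", index=False
    )

    qcfc_summaries = {}
    if cohort.timeseries is not None:
        edge_frames = []
        retained_wide = qc.retention.pivot(
            index="subject_id", columns="threshold_mm", values="n_retained"
        ).loc[cohort.subject_ids]
        for label, keep in [("none", None)] + [
            (f"{thr}", qc.keep_masks[thr]) for thr in THRESHOLDS_MM
        ]:
            if keep is None:
                available = None
            else:
                thr = float(label)
                available = (
                    retained_wide[thr] >= config.censor.min_retained_frames
                ).to_numpy()
            edges = _qcfc_for_masks(
                cohort, keep, mean_fd, config.qcfc_fisher_z, available
            )
            s = qcfc_distance_summary(edges, ci_level=config.qcfc_ci_level)
            qcfc_summaries[label] = {
                "slope": s.slope,
                "intercept": s.intercept,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "ci_level": s.ci_level,
                "n_edges": s.n_edges,
            }
            edges.insert(0, "condition_id", label)
            edge_frames.append(edges)
            binned = s.binned_medians.copy()
            binned.insert(0, "condition_id", label)
            qcfc_summaries[label]["binned"] = binned.to_dict("records")
        pd.concat(edge_frames, ignore_index=True).to_csv(
            out / "qcfc_edges.csv", index=False
        )
        pd.concat(
            [
                pd.DataFrame(v["binned"]).assign(condition_id=k)
                for k, v in qcfc_summaries.items()
            ],
            ignore_index=True,
        ).to_csv(out / "qcfc_binned.csv", index=False)
        (out / "qcfc_summary.json").write_text(
            json.dumps(
                {k: {kk: vv for kk, vv in v.items() if kk != "binned"}
                 for k, v in qcfc_summaries.items()},
                indent=2,
                sort_keys=True,
            )
        )

    run_summary = {
        "seed": cohort.config.seed,
        "config_hash": config_hash(config),
        "scrubaudit_version": __version__,
        "python_version": platform.python_version(),
        "numpy_version": np.__version__,
        "n_subjects": cohort.config.n_subjects,
        "conditions": {
            row["condition"]: {
                "n_excluded": int(row["n_excluded"]),
                "pct_excluded": float(row["pct_excluded"]),
            }
            for _, row in summary.iterrows()
        },
    }
    (out / "run_summary.json").write_text(
        json.dumps(run_summary, indent=2, sort_keys=True)
    )
    return run_summary
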