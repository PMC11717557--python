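"""QC-FC distance-dependence: what scrubbing buys.

Correlates each ROI-pair's connectivity with subject mean FD across the
cohort and regresses those QC-FC values on inter-ROI distance. The
simulated artifact is motion-locked and decays with distance, so the
uncensored slope is reliably negative; scrubbing at 0.2 mm removes the
high-motion frames that carry it and flattens the slope.
"""

import numpy as np

import scrubaudit as sa

cohort = sa.generate_cohort(sa.CohortConfig(n_subjects=250, n_rois=40, seed=9))
qc = sa.run_motion_qc(cohort)
fd = qc.mean_fd_filtered.to_numpy()
wide = qc.retention.pivot(
    index="subject_id", columns="threshold_mm", values="n_retained"
).loc[cohort.subject_ids]

for label, thr in (("no censoring", None), ("scrubbed at 0.2 mm", 0.2)):
    if thr is None:
        idx = np.arange(cohort.config.n_subjects)
        keep = None
    else:
        idx = np.flatnonzero((wide[thr] >= 375).to_numpy())
        keep = qc.keep_masks[thr]
    mats = [
        sa.compute_connectivity(
            cohort.timeseries[i], None if keep is None else keep[i], fisher_z=True
        )
        for i in idx
    ]
    edges = sa.compute_qcfc(mats, fd[idx], cohort.geometry)
    s = sa.qcfc_distance_summary(edges, ci_level=0.99)
    print(
        f"{label:20s} n={len(idx):3d} subjects  mean QC-FC "
        f"{edges['qcfc_r'].mean():+.3f}  slope {s.slope:+.5f}/mm  "
        f"99% CI [{s.ci_low:+.5f}, {s.ci_high:+.5f}]"
    )

print(
    "\nA slope whose CI excludes zero says connectivity is conflated with "
    "motion in a distance-dependent way; after scrubbing the slope collapses "
    "toward zero — the artifact lived in the censored frames."
)
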