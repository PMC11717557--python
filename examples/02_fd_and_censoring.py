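"""Framewise displacement and segment-aware censoring on one motion run.

Shows the per-run pipeline: band-stop the respiratory frequency band out of
the six rigid-body parameters, difference them into FD, censor frames above
the threshold plus short surviving islands, and apply the 375-frame
(5-minute) inclusion rule.
"""

import scrubaudit as sa

cohort = sa.generate_cohort(sa.CohortConfig(n_subjects=1, n_rois=4, seed=3,
                                            make_timeseries=False))
config = sa.CensorConfig(threshold_mm=0.2)

masks = []
for run in range(1, cohort.config.n_runs + 1):
    trace = cohort.motion_trace(0, run)
    filtered = sa.filter_respiratory(trace, config)
    fd = sa.compute_fd(filtered, config.head_radius_mm, filtered=True)
    mask = sa.build_censor_mask(fd, config)
    masks.append(mask)
    n_over = int((fd.fd > config.threshold_mm).sum())
    print(
        f"run {run}: mean FD {fd.fd.mean():.3f} mm, "
        f"{n_over} frames over {config.threshold_mm} mm, "
        f"{mask.keep.size - mask.n_retained} censored after the "
        f"{config.min_island}-frame island rule, {mask.n_retained} retained"
    )

excluded = sa.flag_motion_exclusion(masks, config)
total = sum(m.n_retained for m in masks)
print(
    f"\ntotal retained: {total} frames; subject is "
    f"{'EXCLUDED' if excluded else 'included'} at this threshold "
    f"(rule: fewer than {config.min_retained_frames} retained frames "
    "means exclusion)"
)
print(
    "Censored frames outnumber threshold crossings because every island of "
    "five or fewer kept frames between censored frames is removed too."
)
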