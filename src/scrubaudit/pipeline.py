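"""Vectorised motion-QC pipeline over a whole cohort.

Glue between the single-run primitives in :mod:`scrubaudit.motion` and the
cohort-level analyses: computes filtered and unfiltered FD for every run,
censor masks and retained-frame counts at each scrubbing threshold, and
per-subject mean FD summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort
from .motion import CensorConfig, bandstop_filter, censor_from_fd, fd_from_params

__all__ = ["MotionQCResult", "run_motion_qc", "THRESHOLDS_MM"]

#: the study's motion-scrubbing threshold grid, liberal to strict
THRESHOLDS_MM = (0.5, 0.4, 0.3, 0.2, 0.1)


@dataclass
class MotionQCResult:
    """Cohort-level motion QC summary.

    ``fd_filtered``/``fd_unfiltered`` have shape (n_subjects, n_runs,
    frames_per_run).  ``retention`` is tidy: one row per subject x
    threshold with the total retained frame count and the exclusion flag.
    ``keep_masks`` maps threshold -> boolean (n_subjects, total_frames)
    arrays (runs concatenated, censored independently per run).
    """

    fd_filtered: np.ndarray
    fd_unfiltered: np.ndarray
    retention: pd.DataFrame
    keep_masks: dict[float, np.ndarray]
    mean_fd_filtered: pd.Series
    mean_fd_unfiltered: pd.Series


def run_motion_qc(
    cohort: Cohort,
    config: CensorConfig | None = None,
    thresholds: Sequence[float] = THRESHOLDS_MM,
) -> MotionQCResult:
    """Filter respiration, compute FD, censor, and tally retention.

    ``config.threshold_mm`` is ignored; censoring is evaluated at each value
    in ``thresholds`` with the remaining settings taken from ``config``.
    Mean FD summaries average the per-frame FD over all frames of all runs
    (pre-censoring), the default convention for downstream analyses.
    """
    if config is None:
        config = CensorConfig(threshold_mm=thresholds[0])
    cfg = cohort.config
    n, R, T = cfg.n_subjects, cfg.n_runs, cfg.frames_per_run

    fd_unf = fd_from_params(cohort.motion, config.head_radius_mm)

    if config.filter_target == "motion_parameters":
        filtered_params = bandstop_filter(
            cohort.motion,
            cfg.tr_seconds,
            config.respiratory_stopband_hz,
            axis=2,
        )
        fd_filt = fd_from_params(filtered_params, config.head_radius_mm)
    else:  # filter the FD series directly
        fd_filt = bandstop_filter(
            fd_unf, cfg.tr_seconds, config.respiratory_stopband_hz, axis=2
        )
        fd_filt = np.clip(fd_filt, 0.0, None)
        fd_filt[..., 0] = 0.0

    subject_ids = cohort.subject_ids
    keep_masks: dict[float, np.ndarray] = {}
    rows = []
    for thr in thresholds:
        thr_cfg = CensorConfig(
            threshold_mm=thr,
            min_island=config.min_island,
            min_retained_frames=config.min_retained_frames,
            head_radius_mm=config.head_radius_mm,
            respiratory_stopband_hz=config.respiratory_stopband_hz,
            filter_target=config.filter_target,
            censor_boundary_islands=config.censor_boundary_islands,
        )
        keep = np.empty((n, R * T), dtype=bool)
        for i in range(n):
            for r in range(R):
                keep[i, r * T : (r + 1) * T] = censor_from_fd(fd_filt[i, r], thr_cfg)
        keep_masks[thr] = keep
        retained = keep.sum(axis=1)
        for i in range(n):
            rows.append(
                {
                    "subject_id": subject_ids[i],
                    "threshold_mm": thr,
                    "n_retained": int(retained[i]),
                    "excluded": bool(retained[i] < config.min_retained_frames),
                }
            )
    retention = pd.DataFrame(rows)

    mean_filt = pd.Series(
        fd_filt.reshape(n, -1).mean(axis=1), index=subject_ids, name="mean_fd"
    )
    mean_unf = pd.Series(
        fd_unf.reshape(n, -1).mean(axis=1), index=subject_ids, name="mean_fd_unfiltered"
    )
    return MotionQCResult(
        fd_filtered=fd_filt,
        fd_unfiltered=fd_unf,
        retention=retention,
        keep_masks=keep_masks,
        mean_fd_filtered=mean_filt,
        mean_fd_unfiltered=mean_unf,
    )
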