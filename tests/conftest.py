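import numpy as np
import pytest

import scrubaudit as sa


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort with default (study-condition) parameters."""
    cfg = sa.CohortConfig(n_subjects=80, n_rois=12, seed=101)
    return sa.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_qc(small_cohort):
    return sa.run_motion_qc(small_cohort)


@pytest.fixture(scope="session")
def small_table(small_cohort, small_qc):
    return sa.assemble_conditions(small_cohort.records, small_qc.retention)


def brute_force_keep(fd, threshold, min_island, censor_boundaries):
    """Independent segment-enumeration implementation of the censoring rule.

    Walks the series, enumerates every maximal run of sub-threshold frames,
    and censors runs of length <= min_island that are flanked by censored
    frames (boundary runs flanked on one side only follow the
    ``censor_boundaries`` convention).
    """
    fd = list(fd)
    n = len(fd)
    keep = [fd[i] <= threshold for i in range(n)]
    out = list(keep)
    i = 0
    while i < n:
        if not keep[i]:
            i += 1
            continue
        j = i
        while j < n and keep[j]:
            j += 1
        length = j - i
        interior = i > 0 and j < n
        if length <= min_island and (interior or censor_boundaries):
            for t in range(i, j):
                out[t] = False
        i = j
    return np.array(out, dtype=bool)
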