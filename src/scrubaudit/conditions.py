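"""Assembly of the eight inclusion/exclusion conditions.

The audit compares eight ways a participant can drop out of a resting-state
analysis sample:

* ``T`` -- absent from the pre-tabulated release (visual-inspection
  failures; simulated as an independent low-rate flag);
* ``C`` -- excluded during community-collection preprocessing, before any
  motion correction (the pre-motion QC failure flag);
* ``0.5``/``0.4``/``0.3``/``0.2``/``0.1`` -- entered preprocessing but
  retained fewer than the minimum number of frames after scrubbing at the
  named FD threshold (these build on ``C``: a pre-motion failure is
  excluded at every threshold);
* ``R`` -- the consortium-recommended flag: failed segmentation and/or
  lacks the minimum retained frames at the 0.2 mm threshold.

The pivot object is a complete subjects x conditions boolean table.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .pipeline import THRESHOLDS_MM

__all__ = [
    "CONDITION_ORDER",
    "THRESHOLD_CONDITIONS",
    "assemble_conditions",
    "condition_summary",
    "condition_overlap",
]

#: presentation order of the eight conditions
CONDITION_ORDER = ("T", "C", "0.5", "0.4", "0.3", "R", "0.2", "0.1")

#: the five motion-threshold conditions, liberal to strict
THRESHOLD_CONDITIONS = tuple(f"{t}" for t in THRESHOLDS_MM)


def _retention_wide(retention: pd.DataFrame, subject_ids: pd.Series) -> pd.DataFrame:
    wide = retention.pivot(
        index="subject_id", columns="threshold_mm", values="n_retained"
    )
    missing_subjects = set(subject_ids) - set(wide.index)
    missing_thresholds = [t for t in THRESHOLDS_MM if t not in wide.columns]
    if missing_thresholds:
        raise ValueError(
            f"retention lacks thresholds {missing_thresholds}; all of "
            f"{list(THRESHOLDS_MM)} are required"
        )
    if missing_subjects or wide.loc[list(subject_ids)].isna().any().any():
        incomplete = sorted(missing_subjects) or sorted(
            wide.index[wide.isna().any(axis=1)]
        )
        raise ValueError(
            f"retention is missing entries for subjects: {incomplete[:10]}"
            + ("..." if len(incomplete) > 10 else "")
        )
    return wide.loc[list(subject_ids)]


def assemble_conditions(
    records: pd.DataFrame,
    retention: pd.DataFrame,
    min_retained_frames: int = 375,
) -> pd.DataFrame:
    """Build the subjects x conditions exclusion table.

    ``records`` must carry ``subject_id``, ``preqc_fail`` and the simulated
    pathway flags ``t_fail`` and ``seg_fail``; ``retention`` is the tidy
    per-subject per-threshold retained-frame table from
    :func:`scrubaudit.pipeline.run_motion_qc`.

    Returns a boolean DataFrame indexed by subject_id with one column per
    condition in :data:`CONDITION_ORDER` (True = excluded).
    """
    for col in ("subject_id", "preqc_fail", "t_fail", "seg_fail"):
        if col not in records.columns:
            raise ValueError(f"records lacks required column {col!r}")
    wide = _retention_wide(retention, records["subject_id"])

    preqc = records.set_index("subject_id")["preqc_fail"].astype(bool)
    preqc = preqc.loc[wide.index]
    table = pd.DataFrame(index=wide.index)
    table["T"] = records.set_index("subject_id")["t_fail"].astype(bool).loc[wide.index]
    table["C"] = preqc
    for thr in THRESHOLDS_MM:
        low_data = wide[thr] < min_retained_frames
        table[f"{thr}"] = preqc | low_data
    seg = records.set_index("subject_id")["seg_fail"].astype(bool).loc[wide.index]
    table["R"] = seg | (wide[0.2] < min_retained_frames)
    return table[list(CONDITION_ORDER)]


def condition_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-condition exclusion counts and percentages (denominator: full
    cohort; percentages reported to one decimal)."""
    if table.isna().any().any():
        raise ValueError("exclusion table has missing cells")
    n = len(table)
    rows = []
    for cond in table.columns:
        n_excl = int(table[cond].sum())
        rows.append(
            {
                "condition": cond,
                "n_excluded": n_excl,
                "pct_excluded": round(100.0 * n_excl / n, 1),
                "n_included": n - n_excl,
            }
        )
    return pd.DataFrame(rows)


def condition_overlap(
    table: pd.DataFrame, pairs: Sequence[tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Pairwise non-overlap counts: subjects excluded in A but not in B.

    Defaults to all ordered pairs of the table's conditions.
    """
    conds = list(table.columns)
    if pairs is None:
        pairs = [(a, b) for a in conds for b in conds if a != b]
    rows = []
    for a, b in pairs:
        if a not in conds or b not in conds:
            raise ValueError(f"unknown condition in pair ({a!r}, {b!r})")
        count = int((table[a] & ~table[b]).sum())
        rows.append({"condition_a": a, "condition_b": b, "excluded_a_not_b": count})
    return pd.DataFrame(rows)
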