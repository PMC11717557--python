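"""QC-FC distance-dependence diagnostics.

For each unordered ROI pair, connectivity (Pearson r over retained frames,
optionally Fisher z) is correlated across subjects with each subject's mean
FD; these "QC-FC" values are regressed on the Euclidean distance between
the ROI centroids.  A nonzero slope indicates that connectivity estimates
remain conflated with motion: uncensored data from a cohort with
motion-locked artifact shows a sloped QC-FC/distance relation, and
effective scrubbing flattens it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ConnectivityMatrix",
    "QCFCSummary",
    "compute_connectivity",
    "compute_qcfc",
    "qcfc_distance_summary",
]

#: minimum retained frames for a defined connectivity estimate
MIN_FRAMES_FOR_CONNECTIVITY = 3

#: |r| clip applied before the Fisher transform
_FISHER_CLIP = 1.0 - 1e-7


@dataclass
class ConnectivityMatrix:
    """Symmetric k x k edge matrix for one subject.

    ``fisher_z`` records whether values are arctanh-transformed; undefined
    edges (zero-variance ROI over retained frames) are NaN.
    """

    subject_id: str
    values: np.ndarray
    fisher_z: bool = False

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class QCFCSummary:
    """OLS fit of QC-FC on inter-ROI distance, with presentation bins."""

    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    ci_level: float
    n_edges: int
    binned_medians: pd.DataFrame  # columns: bin_center_mm, median_qcfc, n_edges


def compute_connectivity(
    timeseries: np.ndarray,
    keep: np.ndarray | None = None,
    fisher_z: bool = False,
    subject_id: str = "",
) -> ConnectivityMatrix:
    """Pairwise Pearson correlation over retained frames only.

    ``timeseries`` is (n_frames, n_rois); ``keep`` is a boolean frame mask
    of the same length (None keeps everything).  ROIs with zero variance
    over retained frames produce NaN on all their edges (flagged, not
    silently dropped); the diagonal stays 1 / arctanh-clipped 1.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("timeseries must be (n_frames, n_rois)")
    if keep is not None:
        keep = np.asarray(keep, dtype=bool)
        if keep.shape[0] != ts.shape[0]:
            raise ValueError(
                f"mask length {keep.shape[0]} does not match time-series "
                f"length {ts.shape[0]}"
            )
        ts = ts[keep]
    if ts.shape[0] < MIN_FRAMES_FOR_CONNECTIVITY:
        raise ValueError(
            f"only {ts.shape[0]} retained frames; at least "
            f"{MIN_FRAMES_FOR_CONNECTIVITY} are required for connectivity"
        )
    sd = ts.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(ts.T)
    dead = sd == 0
    if dead.any():
        r[dead, :] = np.nan
        r[:, dead] = np.nan
    np.fill_diagonal(r, 1.0)
    if fisher_z:
        r = np.arctanh(np.clip(r, -_FISHER_CLIP, _FISHER_CLIP))
    return ConnectivityMatrix(subject_id=subject_id, values=r, fisher_z=fisher_z)


def compute_qcfc(
    matrices: Sequence[ConnectivityMatrix],
    mean_fd: Sequence[float],
    geometry: pd.DataFrame,
) -> pd.DataFrame:
    """Per-edge correlation, across subjects, of edge value with mean FD.

    Returns one row per unordered ROI pair with columns roi_a, roi_b,
    distance_mm, qcfc_r, n_subjects, undefined.  Subjects with an undefined
    edge are dropped for that edge only, with the per-edge count recorded;
    an edge constant across subjects is flagged undefined.
    """
    if len(matrices) < 3:
        raise ValueError("QC-FC needs at least 3 subjects")
    fd = np.asarray(mean_fd, dtype=float)
    if len(fd) != len(matrices):
        raise ValueError("mean_fd length does not match number of matrices")
    if np.nanstd(fd) == 0:
        raise ValueError("mean FD is constant across subjects; QC-FC undefined")

    k = matrices[0].n_rois
    iu, ju = np.triu_indices(k, 1)
    edges = np.stack([m.values[iu, ju] for m in matrices])  # (n_subj, n_edges)

    xyz = geometry[["x", "y", "z"]].to_numpy()
    dist = np.linalg.norm(xyz[iu] - xyz[ju], axis=1)
    roi_ids = geometry["roi_id"].to_numpy()

    n_edges = edges.shape[1]
    qc = np.full(n_edges, np.nan)
    n_used = np.zeros(n_edges, dtype=int)
    valid = np.isfinite(edges)
    for e in range(n_edges):
        ok = valid[:, e] & np.isfinite(fd)
        n_used[e] = int(ok.sum())
        if n_used[e] < 3:
            continue
        v = edges[ok, e]
        f = fd[ok]
        if v.std() == 0 or f.std() == 0:
            continue
        qc[e] = np.corrcoef(v, f)[0, 1]
    return pd.DataFrame(
        {
            "roi_a": roi_ids[iu],
            "roi_b": roi_ids[ju],
            "distance_mm": dist,
            "qcfc_r": qc,
            "n_subjects": n_used,
            "undefined": ~np.isfinite(qc),
        }
    )


def qcfc_distance_summary(
    edges: pd.DataFrame,
    ci_level: float = 0.99,
    n_bins: int = 10,
) -> QCFCSummary:
    """OLS of QC-FC on raw edge distances; bins are presentation only.

    The slope is the change in QC-FC per mm with a Wald CI at ``ci_level``
    (default 99%).  Equal-count distance bins carry median QC-FC for
    plotting.
    """
    ok = edges.loc[~edges["undefined"].astype(bool)]
    if len(ok) < 2:
        raise ValueError("fewer than 2 defined edges; no distance fit possible")
    d = ok["distance_mm"].to_numpy()
    if len(np.unique(d)) < 2:
        raise ValueError("need at least 2 distinct distances")
    y = ok["qcfc_r"].to_numpy()
    X = sm.add_constant(d)
    fit = sm.OLS(y, X).fit()
    conf = fit.conf_int(alpha=1.0 - ci_level)
    slope = float(fit.params[1])

    n_bins = max(1, min(n_bins, len(ok)))
    quantiles = np.quantile(d, np.linspace(0, 1, n_bins + 1))
    quantiles[-1] += 1e-9
    which = np.clip(np.searchsorted(quantiles, d, side="right") - 1, 0, n_bins - 1)
    binned = pd.DataFrame(
        {
            "bin_center_mm": [d[which == b].mean() if (which == b).any() else np.nan
                              for b in range(n_bins)],
            "median_qcfc": [np.median(y[which == b]) if (which == b).any() else np.nan
                            for b in range(n_bins)],
            "n_edges": [int((which == b).sum()) for b in range(n_bins)],
        }
    ).dropna()

    return QCFCSummary(
        slope=slope,
        intercept=float(fit.params[0]),
        ci_low=float(conf[1, 0]),
        ci_high=float(conf[1, 1]),
        ci_level=ci_level,
        n_edges=int(len(ok)),
        binned_medians=binned.reset_index(drop=True),
    )
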