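"""Framewise displacement, respiratory filtering, and frame censoring.

This module implements the motion side of a volume-censoring ("scrubbing")
quality-control pipeline for resting-state fMRI:

* framewise displacement (FD) from six rigid-body realignment parameters,
  using the Power convention: the sum of absolute backward differences of
  the three translations (mm) plus the three rotations converted to arc
  length on a sphere of configurable head radius (default 50 mm);
* a zero-phase Butterworth band-stop filter that removes factitious
  respiratory motion (default stopband 0.31-0.43 Hz) from either the
  motion parameters (default) or the FD series itself;
* two-pass censor masks: frames whose (filtered) FD strictly exceeds the
  threshold are censored, then any surviving island of no more than
  ``min_island`` contiguous kept frames is censored as well;
* the participant-level inclusion rule: a subject is excluded at a given
  threshold when fewer than ``min_retained_frames`` frames (default 375,
  i.e. five minutes at TR = 0.8 s) survive censoring across all runs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from typing import Iterable

from scipy import signal

__all__ = [
    "PARAM_COLUMNS",
    "MotionTrace",
    "FDSeries",
    "CensorConfig",
    "CensorMask",
    "compute_fd",
    "fd_from_params",
    "bandstop_filter",
    "filter_respiratory",
    "filter_fd_series",
    "build_censor_mask",
    "censor_from_fd",
    "flag_motion_exclusion",
    "min_frames_for_duration",
]

#: column order of a rigid-body motion parameter table
PARAM_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")

#: minimum series length accepted by the zero-phase band-stop filter
#: (covers the sosfiltfilt edge padding of the default second-order design)
FILTER_WARMUP_FRAMES = 30


@dataclass(frozen=True)
class MotionTrace:
    """One run of rigid-body motion parameters.

    ``params`` has shape ``(n_frames, 6)`` ordered as :data:`PARAM_COLUMNS`
    (translations in mm, rotations in radians).
    """

    subject_id: str
    run_index: int
    params: np.ndarray
    tr_seconds: float = 0.8

    def __post_init__(self) -> None:
        p = np.asarray(self.params, dtype=float)
        if p.ndim != 2 or p.shape[1] != 6:
            raise ValueError(
                f"motion parameters must be (n_frames, 6); got shape {p.shape}"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        object.__setattr__(self, "params", p)

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]


@dataclass(frozen=True)
class FDSeries:
    """Framewise displacement for one run; ``fd[0] == 0`` by convention."""

    subject_id: str
    run_index: int
    fd: np.ndarray
    filtered: bool = False

    def __post_init__(self) -> None:
        fd = np.asarray(self.fd, dtype=float)
        if fd.ndim != 1:
            raise ValueError("fd must be one-dimensional")
        object.__setattr__(self, "fd", fd)


@dataclass(frozen=True)
class CensorConfig:
    """Parameters of the censoring and inclusion rules.

    ``threshold_mm`` is the FD scrubbing threshold (the study grid is
    0.5/0.4/0.3/0.2/0.1 mm but any positive value is accepted).
    ``censor_boundary_islands`` controls the boundary convention: when True
    (default), short kept runs at the start or end of a run are treated as
    flanked and censored; when False they are preserved.
    """

    threshold_mm: float
    min_island: int = 5
    min_retained_frames: int = 375
    head_radius_mm: float = 50.0
    respiratory_stopband_hz: tuple[float, float] = (0.31, 0.43)
    filter_target: str = "motion_parameters"  # or "fd_series"
    censor_boundary_islands: bool = True

    def __post_init__(self) -> None:
        if not self.threshold_mm > 0:
            raise ValueError("threshold_mm must be positive")
        if self.min_island < 0:
            raise ValueError("min_island must be nonnegative")
        if self.min_retained_frames < 0:
            raise ValueError("min_retained_frames must be nonnegative")
        if not self.head_radius_mm > 0:
            raise ValueError("head_radius_mm must be positive")
        lo, hi = self.respiratory_stopband_hz
        if not (0 < lo < hi):
            raise ValueError("respiratory_stopband_hz must satisfy 0 < low < high")
        if self.filter_target not in ("motion_parameters", "fd_series"):
            raise ValueError(
                "filter_target must be 'motion_parameters' or 'fd_series'"
            )


@dataclass(frozen=True)
class CensorMask:
    """Per-frame keep/censor decisions for one run at one threshold."""

    subject_id: str
    run_index: int
    keep: np.ndarray
    threshold_mm: float

    def __post_init__(self) -> None:
        keep = np.asarray(self.keep, dtype=bool)
        object.__setattr__(self, "keep", keep)

    @property
    def n_retained(self) -> int:
        return int(self.keep.sum())


def min_frames_for_duration(minutes: float, tr_seconds: float) -> int:
    """Number of frames needed to cover ``minutes`` of data at the given TR.

    Five minutes at TR = 0.8 s gives the conventional 375-frame inclusion
    minimum.
    """
    if minutes <= 0 or tr_seconds <= 0:
        raise ValueError("minutes and tr_seconds must be positive")
    return int(np.ceil(minutes * 60.0 / tr_seconds))


# ---------------------------------------------------------------------------
# framewise displacement


def fd_from_params(params: np.ndarray, head_radius_mm: float = 50.0) -> np.ndarray:
    """Vectorised FD: ``params`` has shape ``(..., n_frames, 6)``.

    Returns an array of shape ``(..., n_frames)`` with the leading frame of
    each series set to zero (no predecessor).
    """
    if head_radius_mm <= 0:
        raise ValueError("head_radius_mm must be positive")
    p = np.asarray(params, dtype=float)
    if p.shape[-1] != 6:
        raise ValueError("last axis of params must have length 6")
    diffs = np.abs(np.diff(p, axis=-2))
    fd = diffs[..., :3].sum(axis=-1) + head_radius_mm * diffs[..., 3:].sum(axis=-1)
    pad = np.zeros(fd.shape[:-1] + (1,), dtype=float)
    return np.concatenate([pad, fd], axis=-1)


def compute_fd(
    trace: MotionTrace, head_radius_mm: float = 50.0, filtered: bool = False
) -> FDSeries:
    """FD of a single run, flagging any non-finite parameter by frame."""
    bad = ~np.isfinite(trace.params)
    if bad.any():
        frame = int(np.argwhere(bad)[0, 0])
        raise ValueError(
            f"non-finite motion parameter at frame {frame} "
            f"(subject {trace.subject_id}, run {trace.run_index})"
        )
    fd = fd_from_params(trace.params, head_radius_mm)
    return FDSeries(trace.subject_id, trace.run_index, fd, filtered=filtered)


# ---------------------------------------------------------------------------
# respiratory band-stop filtering


def _bandstop_sos(tr_seconds: float, stopband_hz: tuple[float, float], order: int = 2):
    fs = 1.0 / tr_seconds
    lo, hi = stopband_hz
    nyq = fs / 2.0
    if hi >= nyq:
        raise ValueError(
            f"stopband upper edge {hi} Hz is at or above the Nyquist frequency "
            f"{nyq:.4g} Hz implied by TR = {tr_seconds} s; the sampling rate must "
            "exceed twice the stopband"
        )
    return signal.butter(order, [lo, hi], btype="bandstop", fs=fs, output="sos")


def bandstop_filter(
    series: np.ndarray,
    tr_seconds: float,
    stopband_hz: tuple[float, float] = (0.31, 0.43),
    axis: int = -1,
    order: int = 2,
) -> np.ndarray:
    """Zero-phase Butterworth band-stop along ``axis`` (default order 2,
    applied forward and backward, so 4th-order magnitude response)."""
    x = np.asarray(series, dtype=float)
    if x.shape[axis] < FILTER_WARMUP_FRAMES:
        raise ValueError(
            f"series of length {x.shape[axis]} is shorter than the filter "
            f"warm-up length ({FILTER_WARMUP_FRAMES} frames)"
        )
    sos = _bandstop_sos(tr_seconds, stopband_hz, order=order)
    return signal.sosfiltfilt(sos, x, axis=axis)


def filter_respiratory(trace: MotionTrace, config: CensorConfig) -> MotionTrace:
    """Remove the respiratory band from all six motion parameter series."""
    filtered = bandstop_filter(
        trace.params, trace.tr_seconds, config.respiratory_stopband_hz, axis=0
    )
    return replace(trace, params=filtered)


def filter_fd_series(fd: FDSeries, tr_seconds: float, config: CensorConfig) -> FDSeries:
    """Band-stop the FD series directly (the literal reading of "filtered
    from FD values"); negative excursions introduced by filtering are
    clipped at zero to preserve FD nonnegativity."""
    out = bandstop_filter(fd.fd, tr_seconds, config.respiratory_stopband_hz)
    out = np.clip(out, 0.0, None)
    out[0] = 0.0
    return FDSeries(fd.subject_id, fd.run_index, out, filtered=True)


# ---------------------------------------------------------------------------
# censoring


def _remove_short_islands(
    keep: np.ndarray, min_island: int, censor_boundaries: bool
) -> np.ndarray:
    """Censor every maximal run of kept frames of length <= min_island that
    is flanked by censored frames (boundary runs count as flanked when
    ``censor_boundaries``)."""
    k = keep.copy()
    n = k.size
    if n == 0:
        return k
    ik = k.astype(np.int8)
    starts = np.flatnonzero(np.diff(np.concatenate(([0], ik))) == 1)
    ends = np.flatnonzero(np.diff(np.concatenate((ik, [0]))) == -1)
    for s, e in zip(starts, ends):
        length = e - s + 1
        if length > min_island:
            continue
        interior = s > 0 and e < n - 1
        if interior or censor_boundaries:
            k[s : e + 1] = False
    return k


def censor_from_fd(fd: np.ndarray, config: CensorConfig) -> np.ndarray:
    """Boolean keep vector for one FD series (two-pass rule)."""
    fd = np.asarray(fd, dtype=float)
    if not np.isfinite(fd).all():
        raise ValueError("FD series contains non-finite values")
    keep = fd <= config.threshold_mm  # strict ">" censors; ties are kept
    return _remove_short_islands(
        keep, config.min_island, config.censor_boundary_islands
    )


def build_censor_mask(fd: FDSeries, config: CensorConfig) -> CensorMask:
    keep = censor_from_fd(fd.fd, config)
    return CensorMask(fd.subject_id, fd.run_index, keep, config.threshold_mm)


def flag_motion_exclusion(
    masks: Iterable[CensorMask], config: CensorConfig
) -> bool:
    """True when the subject is excluded: total retained frames across runs
    is strictly below ``min_retained_frames``."""
    masks = list(masks)
    if not masks:
        raise ValueError("no censor masks supplied")
    thresholds = {m.threshold_mm for m in masks}
    if len(thresholds) != 1:
        raise ValueError(
            f"masks mix thresholds {sorted(thresholds)}; exclusion is defined "
            "per threshold"
        )
    if thresholds != {config.threshold_mm}:
        raise ValueError(
            f"mask threshold {thresholds.pop()} does not match config "
            f"threshold {config.threshold_mm}"
        )
    total = sum(m.n_retained for m in masks)
    return total < config.min_retained_frames
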