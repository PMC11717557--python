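"""File formats, configuration, and cohort (de)serialisation.

Formats are plain text:

* covariates: CSV with a header, one row per subject, columns named exactly
  as the subject-record fields;
* motion: per-run TSV named ``sub-<id>_run-<k>_motion.tsv`` with header
  ``trans_x trans_y trans_z rot_x rot_y rot_z`` (mm, mm, mm, rad, rad, rad);
* ROI centroids: TSV ``roi_id x y z`` (mm);
* ROI time series: TSV, frames x ROIs, header = roi ids;
* a JSON manifest recording files and the generating seed.

Readers validate headers case-sensitively and report malformed cells with
file, line and column; unknown extra covariate columns are accepted with a
warning and preserved.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    ANALYSIS_COVARIATES,
    CATEGORICAL_COVARIATES,
    CATEGORY_LEVELS,
    Cohort,
    CohortConfig,
)
from .motion import PARAM_COLUMNS, CensorConfig, MotionTrace

__all__ = [
    "RunConfig",
    "write_cohort",
    "read_cohort",
    "read_motion_tsv",
    "write_motion_tsv",
    "read_covariates_csv",
    "write_covariates_csv",
    "read_centroids_tsv",
    "write_centroids_tsv",
    "read_timeseries_tsv",
    "write_timeseries_tsv",
    "config_hash",
]

_RECORD_COLUMNS = (
    ("subject_id",)
    + ANALYSIS_COVARIATES
    + ("site", "scanner", "preqc_fail", "t_fail", "seg_fail")
)


# ---------------------------------------------------------------------------
# run configuration


@dataclass(frozen=True)
class RunConfig:
    """Everything an end-to-end audit run needs, serialisable to YAML."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    censor: CensorConfig = field(default_factory=lambda: CensorConfig(threshold_mm=0.5))
    ci_level: float = 0.90
    qcfc_ci_level: float = 0.99
    qcfc_fisher_z: bool = True
    include_site: bool = False
    include_scanner: bool = False
    output_dir: str | None = None
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort.to_dict(),
            "censor": dataclasses.asdict(self.censor),
            "analysis": {
                "ci_level": self.ci_level,
                "qcfc_ci_level": self.qcfc_ci_level,
                "qcfc_fisher_z": self.qcfc_fisher_z,
                "include_site": self.include_site,
                "include_scanner": self.include_scanner,
            },
            "output_dir": self.output_dir,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        cohort_kwargs = dict(d.get("cohort", {}))
        if "site_preqc_effects" in cohort_kwargs and cohort_kwargs[
            "site_preqc_effects"
        ] is not None:
            cohort_kwargs["site_preqc_effects"] = tuple(
                cohort_kwargs["site_preqc_effects"]
            )
        censor_kwargs = dict(d.get("censor", {}))
        if "respiratory_stopband_hz" in censor_kwargs:
            censor_kwargs["respiratory_stopband_hz"] = tuple(
                censor_kwargs["respiratory_stopband_hz"]
            )
        analysis = dict(d.get("analysis", {}))
        return cls(
            cohort=CohortConfig(**cohort_kwargs),
            censor=CensorConfig(**censor_kwargs) if censor_kwargs else CensorConfig(
                threshold_mm=0.5
            ),
            ci_level=analysis.get("ci_level", 0.90),
            qcfc_ci_level=analysis.get("qcfc_ci_level", 0.99),
            qcfc_fisher_z=analysis.get("qcfc_fisher_z", True),
            include_site=analysis.get("include_site", False),
            include_scanner=analysis.get("include_scanner", False),
            output_dir=d.get("output_dir"),
            log_level=d.get("log_level", "INFO"),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        return cls.from_dict(yaml.safe_load(text) or {})


def config_hash(config: RunConfig | CohortConfig) -> str:
    """Stable short hash of a configuration, recorded in run outputs."""
    d = config.to_dict()
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# low-level readers / writers


def _require_nonempty(path: Path) -> None:
    if not path.exists():
        raise FileNotFoundError(f"{path} does not exist")
    if path.stat().st_size == 0:
        raise ValueError(f"{path} is empty")


def write_motion_tsv(trace: MotionTrace, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(trace.params, columns=list(PARAM_COLUMNS))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_motion_tsv(
    path: str | Path,
    subject_id: str | None = None,
    run_index: int | None = None,
    tr_seconds: float = 0.8,
) -> MotionTrace:
    """Read one run of motion parameters; identity defaults to the
    ``sub-<id>_run-<k>_motion.tsv`` file-name pattern when not supplied."""
    path = Path(path)
    _require_nonempty(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PARAM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in PARAM_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # 1-based, after header
            raise ValueError(
                f"{path}: non-numeric value in column {col!r} at line {line}"
            )
        df[col] = coerced
    if df[list(PARAM_COLUMNS)].isna().any().any():
        raise ValueError(f"{path}: missing numeric values")
    if subject_id is None or run_index is None:
        stem = path.name
        if stem.startswith("sub-") and "_run-" in stem:
            subject_id = subject_id or stem.split("_run-")[0][len("sub-"):]
            run_index = run_index or int(
                stem.split("_run-")[1].split("_")[0]
            )
        else:
            subject_id = subject_id or path.stem
            run_index = run_index or 1
    return MotionTrace(
        subject_id=subject_id,
        run_index=run_index,
        params=df[list(PARAM_COLUMNS)].to_numpy(),
        tr_seconds=tr_seconds,
    )


def write_covariates_csv(records: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    records.to_csv(path, index=False)
    return path


def read_covariates_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    _require_nonempty(path)
    df = pd.read_csv(path)
    missing = [c for c in _RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing covariate columns {missing}")
    extra = [c for c in df.columns if c not in _RECORD_COLUMNS]
    if extra:
        warnings.warn(
            f"{path}: unknown extra columns {extra} accepted and preserved",
            stacklevel=2,
        )
    for col in CATEGORICAL_COVARIATES:
        df[col] = pd.Categorical(df[col], categories=CATEGORY_LEVELS[col])
    for col in ("preqc_fail", "t_fail", "seg_fail"):
        df[col] = df[col].astype(bool)
    df["subject_id"] = df["subject_id"].astype(str)
    return df


def write_centroids_tsv(geometry: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    geometry.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_centroids_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    _require_nonempty(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("roi_id", "x", "y", "z") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("x", "y", "z"):
        if not np.isfinite(df[col].to_numpy(dtype=float)).all():
            raise ValueError(f"{path}: non-finite coordinate in column {col!r}")
    return df


def write_timeseries_tsv(
    ts: np.ndarray, roi_ids: list[str], path: str | Path
) -> Path:
    path = Path(path)
    pd.DataFrame(ts, columns=roi_ids).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
    return path


def read_timeseries_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    path = Path(path)
    _require_nonempty(path)
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=float), list(df.columns)


# ---------------------------------------------------------------------------
# whole-cohort round trip


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict:
    """Write a cohort to ``out_dir`` and return the manifest (also written
    as manifest.json)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    cov_path = out / "covariates.csv"
    write_covariates_csv(cohort.records, cov_path)
    files.append(cov_path.name)

    motion_dir = out / "motion"
    motion_dir.mkdir(exist_ok=True)
    for trace in cohort.iter_motion_traces():
        p = motion_dir / f"sub-{trace.subject_id}_run-{trace.run_index}_motion.tsv"
        write_motion_tsv(trace, p)
        files.append(f"motion/{p.name}")

    cent_path = out / "roi_centroids.tsv"
    write_centroids_tsv(cohort.geometry, cent_path)
    files.append(cent_path.name)

    if cohort.timeseries is not None:
        ts_dir = out / "timeseries"
        ts_dir.mkdir(exist_ok=True)
        roi_ids = list(cohort.geometry["roi_id"])
        for i, sid in enumerate(cohort.subject_ids):
            p = ts_dir / f"sub-{sid}_timeseries.tsv"
            write_timeseries_tsv(cohort.timeseries[i], roi_ids, p)
            files.append(f"timeseries/{p.name}")

    manifest = {
        "seed": cohort.config.seed,
        "n_subjects": cohort.config.n_subjects,
        "n_runs": cohort.config.n_runs,
        "frames_per_run": cohort.config.frames_per_run,
        "config": cohort.config.to_dict(),
        "config_hash": config_hash(cohort.config),
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def read_cohort(in_dir: str | Path) -> Cohort:
    """Reconstruct a cohort written by :func:`write_cohort`."""
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    cfg_kwargs = dict(manifest["config"])
    if cfg_kwargs.get("site_preqc_effects") is not None:
        cfg_kwargs["site_preqc_effects"] = tuple(cfg_kwargs["site_preqc_effects"])
    config = CohortConfig(**cfg_kwargs)

    records = read_covariates_csv(src / "covariates.csv")
    geometry = read_centroids_tsv(src / "roi_centroids.tsv")

    n, R, T = config.n_subjects, config.n_runs, config.frames_per_run
    motion = np.empty((n, R, T, 6))
    for i, sid in enumerate(records["subject_id"]):
        for r in range(1, R + 1):
            trace = read_motion_tsv(
                src / "motion" / f"sub-{sid}_run-{r}_motion.tsv",
                tr_seconds=config.tr_seconds,
            )
            if trace.n_frames != T:
                raise ValueError(
                    f"run sub-{sid} run {r} has {trace.n_frames} frames; "
                    f"expected {T}"
                )
            motion[i, r - 1] = trace.params

    timeseries = None
    ts_dir = src / "timeseries"
    if ts_dir.exists():
        timeseries = np.empty((n, R * T, config.n_rois))
        for i, sid in enumerate(records["subject_id"]):
            ts, _ = read_timeseries_tsv(ts_dir / f"sub-{sid}_timeseries.tsv")
            timeseries[i] = ts

    return Cohort(
        config=config,
        records=records,
        motion=motion,
        geometry=geometry,
        timeseries=timeseries,
    )
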