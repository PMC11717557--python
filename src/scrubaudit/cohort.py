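"""Synthetic cohort generator.

Emulates the data structure of a large pediatric resting-state fMRI study:
a participant covariate table (17 analysis covariates plus site, scanner and
a pre-motion QC failure flag), per-run rigid-body motion parameter traces,
ROI centroid geometry, and ROI time series carrying a configurable
distance-dependent motion artifact.

The generative model is deliberately the simplest structure that produces
the three phenomena the downstream audit measures:

* covariate-graded exclusion -- a latent motion propensity is a linear
  function of configured (standardized) covariates and raises the per-frame
  probability of a high-motion spike through a logistic link;
* respiratory contamination of FD -- a sinusoid at a configurable breathing
  frequency is added to the translation parameters;
* distance-dependent QC-FC -- a motion-locked shared signal component with
  spatially correlated ROI loadings (covariance exp(-d/lambda_d)) is added
  to the ROI time series, scaled by each frame's motion excess, so that
  high-motion subjects acquire spatially structured spurious connectivity
  which frame censoring can remove.

All randomness flows from a single ``numpy`` generator seeded from the
config, so identical configs produce bit-identical cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .motion import MotionTrace, fd_from_params

__all__ = [
    "CohortConfig",
    "Cohort",
    "generate_cohort",
    "CONTINUOUS_COVARIATES",
    "CATEGORICAL_COVARIATES",
    "ANALYSIS_COVARIATES",
    "CATEGORY_LEVELS",
    "REFERENCE_LEVELS",
]

# ---------------------------------------------------------------------------
# covariate schema

CONTINUOUS_COVARIATES = (
    "adi",
    "coi",
    "nihtb_flanker",
    "nihtb_crystallized",
    "nihtb_total",
    "wisc_matrix",
    "p_factor",
    "internalizing",
    "externalizing",
    "age",
    "bmi_z",
)

CATEGORICAL_COVARIATES = (
    "sex",
    "income_level",
    "parent_education",
    "race_ethnicity",
    "trauma_count",
    "puberty",
)

#: the 17 analysis covariates
ANALYSIS_COVARIATES = CONTINUOUS_COVARIATES + CATEGORICAL_COVARIATES

CATEGORY_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("F", "M"),
    "income_level": (
        "<$25k",
        "$25-50k",
        "$50-75k",
        "$75-100k",
        "$100-200k",
        ">$200k",
    ),
    "parent_education": ("<HS", "HS", "some college", "college", "graduate"),
    "race_ethnicity": ("White", "Black", "Hispanic", "Asian", "Other"),
    "trauma_count": ("0", "1", "2+"),
    "puberty": ("pre", "early", "mid", "late", "post"),
}

#: reference levels used by all downstream regression contrasts
REFERENCE_LEVELS: dict[str, str] = {
    "sex": "F",
    "income_level": "$100-200k",
    "parent_education": "college",
    "race_ethnicity": "White",
    "trauma_count": "0",
    "puberty": "pre",
}

#: marginal level frequencies (placeholders for a US pediatric cohort; they
#: are configuration, not estimates of any particular study sample)
_CATEGORY_FREQS: dict[str, tuple[float, ...]] = {
    "sex": (0.48, 0.52),
    "income_level": (0.16, 0.13, 0.13, 0.14, 0.30, 0.14),
    "parent_education": (0.05, 0.09, 0.26, 0.26, 0.34),
    "race_ethnicity": (0.52, 0.15, 0.20, 0.02, 0.11),
    "trauma_count": (0.60, 0.25, 0.15),
    "puberty": (0.50, 0.30, 0.15, 0.04, 0.01),
}

_SCANNERS = ("SIEMENS", "GE", "PHILIPS")

# default motion-propensity effects (log-scale per SD of the covariate's
# latent); signs follow the motion-covariate associations the audit expects
# to detect (higher BMI, deprivation and psychopathology -> more motion;
# older age, opportunity and cognition -> less)
_DEFAULT_MOTION_EFFECTS: dict[str, float] = {
    "bmi_z": 0.30,
    "age": -0.12,
    "nihtb_total": -0.15,
    "coi": -0.12,
    "adi": 0.10,
    "p_factor": 0.08,
    "sex": 0.20,
}

_DEFAULT_PREQC_EFFECTS: dict[str, float] = {
    "coi": -0.25,
    "nihtb_total": -0.20,
    "bmi_z": 0.10,
}


def _default_latent_correlation() -> tuple[list[str], np.ndarray]:
    """Correlation matrix of the latent Gaussian copula.

    Encodes correlated-disadvantage structure: SES variables move together,
    cognition correlates with SES, puberty with age, BMI weakly with SES.
    The p/INT/EXT factor scores are mutually orthogonal by construction and
    kept independent of the rest.
    """
    names = list(ANALYSIS_COVARIATES)
    k = len(names)
    r = np.eye(k)

    def set_r(a: str, b: str, v: float) -> None:
        i, j = names.index(a), names.index(b)
        r[i, j] = r[j, i] = v

    # socioeconomic block (adi is deprivation: high = worse)
    set_r("adi", "coi", -0.55)
    set_r("adi", "income_level", -0.45)
    set_r("coi", "income_level", 0.45)
    set_r("adi", "parent_education", -0.35)
    set_r("coi", "parent_education", 0.40)
    set_r("income_level", "parent_education", 0.50)
    set_r("race_ethnicity", "adi", 0.30)
    set_r("race_ethnicity", "coi", -0.30)
    set_r("race_ethnicity", "income_level", -0.30)
    set_r("race_ethnicity", "parent_education", -0.25)
    set_r("trauma_count", "income_level", -0.20)
    set_r("trauma_count", "adi", 0.15)
    # cognition block
    for a in ("nihtb_flanker", "nihtb_crystallized", "nihtb_total", "wisc_matrix"):
        for b in ("nihtb_flanker", "nihtb_crystallized", "nihtb_total", "wisc_matrix"):
            if a != b:
                set_r(a, b, 0.45)
        set_r(a, "income_level", 0.25)
        set_r(a, "parent_education", 0.25)
        set_r(a, "coi", 0.20)
        set_r(a, "adi", -0.20)
    set_r("nihtb_crystallized", "nihtb_total", 0.65)
    # development
    set_r("puberty", "age", 0.35)
    set_r("puberty", "sex", -0.15)
    set_r("bmi_z", "income_level", -0.15)
    set_r("bmi_z", "coi", -0.10)

    # project to the nearest positive-definite correlation matrix
    w, v = np.linalg.eigh(r)
    w = np.clip(w, 1e-6, None)
    r = v @ np.diag(w) @ v.T
    d = np.sqrt(np.diag(r))
    r = r / np.outer(d, d)
    return names, r


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of the simulated cohort.

    The acquisition constants default to the study design being emulated:
    four five-minute runs of 375 frames at TR = 0.8 s.
    """

    n_subjects: int = 500
    n_runs: int = 4
    frames_per_run: int = 375
    tr_seconds: float = 0.8
    n_rois: int = 60
    seed: int = 0
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MOTION_EFFECTS)
    )
    spike_base_rate: float = 0.04
    respiratory_freq_hz: float = 0.35
    respiratory_amp_mm: float = 0.04
    artifact_strength: float = 3.0
    artifact_distance_decay: float = 60.0
    preqc_fail_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PREQC_EFFECTS)
    )
    preqc_base_rate: float = 0.19
    # motion noise model
    param_noise_mm: float = 0.015
    param_noise_ar1: float = 0.4
    subject_scale_sd: float = 0.30
    propensity_noise_sd: float = 1.3
    spike_magnitude_min_mm: float = 0.10
    spike_magnitude_scale_mm: float = 0.35
    artifact_fd_floor_mm: float = 0.15
    head_radius_mm: float = 50.0
    # independent pathway flags
    t_fail_rate: float = 0.043
    t_fail_effects: Mapping[str, float] = field(default_factory=dict)
    seg_fail_rate: float = 0.05
    seg_fail_effects: Mapping[str, float] = field(default_factory=dict)
    # site structure
    n_sites: int = 4
    site_preqc_effects: Sequence[float] | None = None
    site_assortment_covariate: str | None = None
    site_assortment_strength: float = 0.0
    make_timeseries: bool = True

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_runs", "frames_per_run", "n_rois", "n_sites"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValueError(f"{name} must be a positive integer; got {v!r}")
        for name in (
            "tr_seconds",
            "respiratory_freq_hz",
            "artifact_distance_decay",
            "param_noise_mm",
            "spike_magnitude_scale_mm",
            "head_radius_mm",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("spike_base_rate", "preqc_base_rate", "t_fail_rate", "seg_fail_rate"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1); got {v!r}")
        for name in (
            "respiratory_amp_mm",
            "subject_scale_sd",
            "propensity_noise_sd",
            "spike_magnitude_min_mm",
            "artifact_fd_floor_mm",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not (0 <= self.param_noise_ar1 < 1):
            raise ValueError("param_noise_ar1 must be in [0, 1)")
        for mapping_name in ("covariate_effects", "preqc_fail_effects",
                             "t_fail_effects", "seg_fail_effects"):
            for key in getattr(self, mapping_name):
                if key not in ANALYSIS_COVARIATES:
                    raise ValueError(
                        f"{mapping_name} names unknown covariate {key!r}"
                    )
        if self.site_preqc_effects is not None and len(self.site_preqc_effects) != self.n_sites:
            raise ValueError("site_preqc_effects must have one entry per site")
        if (
            self.site_assortment_covariate is not None
            and self.site_assortment_covariate not in ANALYSIS_COVARIATES
        ):
            raise ValueError(
                f"site_assortment_covariate names unknown covariate "
                f"{self.site_assortment_covariate!r}"
            )

    @property
    def frames_per_subject(self) -> int:
        return self.n_runs * self.frames_per_run

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariate_effects"] = dict(self.covariate_effects)
        d["preqc_fail_effects"] = dict(self.preqc_fail_effects)
        d["t_fail_effects"] = dict(self.t_fail_effects)
        d["seg_fail_effects"] = dict(self.seg_fail_effects)
        if self.site_preqc_effects is not None:
            d["site_preqc_effects"] = list(self.site_preqc_effects)
        return d


# ---------------------------------------------------------------------------
# cohort container


@dataclass
class Cohort:
    """In-memory simulated cohort.

    ``motion`` has shape ``(n_subjects, n_runs, frames_per_run, 6)``;
    ``timeseries`` has shape ``(n_subjects, total_frames, n_rois)`` or is
    None when time-series synthesis was disabled.
    """

    config: CohortConfig
    records: pd.DataFrame
    motion: np.ndarray
    geometry: pd.DataFrame
    timeseries: np.ndarray | None

    @property
    def subject_ids(self) -> list[str]:
        return list(self.records["subject_id"])

    def motion_trace(self, subject_index: int, run_index: int) -> MotionTrace:
        """Run index is 1-based, matching file naming."""
        return MotionTrace(
            subject_id=self.records["subject_id"].iloc[subject_index],
            run_index=run_index,
            params=self.motion[subject_index, run_index - 1],
            tr_seconds=self.config.tr_seconds,
        )

    def iter_motion_traces(self) -> Iterator[MotionTrace]:
        for i in range(self.config.n_subjects):
            for r in range(1, self.config.n_runs + 1):
                yield self.motion_trace(i, r)

    def roi_distances(self) -> np.ndarray:
        xyz = self.geometry[["x", "y", "z"]].to_numpy()
        return np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)


# ---------------------------------------------------------------------------
# generation


def _ar1(innovations: np.ndarray, phi: float, axis: int = -1) -> np.ndarray:
    from scipy.signal import lfilter

    return lfilter([1.0], [1.0, -phi], innovations, axis=axis)


def _bernoulli_from_latents(
    rng: np.random.Generator,
    latents: pd.DataFrame,
    base_rate: float,
    effects: Mapping[str, float],
    offset: np.ndarray | None = None,
) -> np.ndarray:
    eta = np.full(len(latents), logit(base_rate))
    for name, beta in effects.items():
        eta = eta + beta * latents[name].to_numpy()
    if offset is not None:
        eta = eta + offset
    return rng.random(len(latents)) < expit(eta)


def _generate_covariates(
    rng: np.random.Generator, config: CohortConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Returns (records, latents); latents are the standardized Gaussian
    scores underlying every covariate (categorical ones included)."""
    names, corr = _default_latent_correlation()
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((config.n_subjects, len(names))) @ chol.T
    latents = pd.DataFrame(z, columns=names)

    records = pd.DataFrame(
        {"subject_id": [f"S{i:05d}" for i in range(config.n_subjects)]}
    )
    for name in CONTINUOUS_COVARIATES:
        records[name] = latents[name]
    for name in CATEGORICAL_COVARIATES:
        freqs = np.asarray(_CATEGORY_FREQS[name])
        cuts = np.concatenate(([-np.inf], _norm_ppf(np.cumsum(freqs)[:-1]), [np.inf]))
        idx = np.searchsorted(cuts, latents[name], side="right") - 1
        levels = CATEGORY_LEVELS[name]
        records[name] = pd.Categorical(
            [levels[i] for i in idx], categories=levels
        )

    # site assignment, optionally assorted with a covariate
    if config.site_assortment_covariate is not None:
        s_lat = (
            config.site_assortment_strength
            * latents[config.site_assortment_covariate].to_numpy()
            + rng.standard_normal(config.n_subjects)
        )
        qs = np.quantile(s_lat, np.linspace(0, 1, config.n_sites + 1)[1:-1])
        site_idx = np.searchsorted(qs, s_lat, side="right")
    else:
        site_idx = rng.integers(0, config.n_sites, size=config.n_subjects)
    records["site"] = pd.Categorical(
        [f"site{j:02d}" for j in site_idx],
        categories=[f"site{j:02d}" for j in range(config.n_sites)],
    )
    records["scanner"] = pd.Categorical(
        [_SCANNERS[j % len(_SCANNERS)] for j in site_idx], categories=_SCANNERS
    )

    site_offset = None
    if config.site_preqc_effects is not None:
        site_offset = np.asarray(config.site_preqc_effects)[site_idx]
    records["preqc_fail"] = _bernoulli_from_latents(
        rng, latents, config.preqc_base_rate, config.preqc_fail_effects, site_offset
    )
    records["t_fail"] = _bernoulli_from_latents(
        rng, latents, config.t_fail_rate, config.t_fail_effects
    )
    records["seg_fail"] = _bernoulli_from_latents(
        rng, latents, config.seg_fail_rate, config.seg_fail_effects
    )
    return records, latents


def _norm_ppf(q: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    return norm.ppf(q)


def _generate_motion(
    rng: np.random.Generator, config: CohortConfig, latents: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Returns (params, spike_prob): params (n, R, T, 6), spike_prob (n,)."""
    n, R, T = config.n_subjects, config.n_runs, config.frames_per_run

    lam = np.zeros(n)
    for name, beta in config.covariate_effects.items():
        lam = lam + beta * latents[name].to_numpy()
    lam = lam + config.propensity_noise_sd * rng.standard_normal(n)
    spike_prob = expit(logit(config.spike_base_rate) + lam)

    scale = np.exp(config.subject_scale_sd * rng.standard_normal(n))
    sd = np.empty(6)
    sd[:3] = config.param_noise_mm
    sd[3:] = config.param_noise_mm / config.head_radius_mm

    innov = rng.standard_normal((n, R, T, 6))
    innov *= sd
    innov *= scale[:, None, None, None]
    params = _ar1(innov, config.param_noise_ar1, axis=2)

    # respiratory oscillation on the translations (dominant on y/z, as for
    # pseudomotion from breathing-induced field shifts)
    t = np.arange(T) * config.tr_seconds
    phase = rng.uniform(0, 2 * np.pi, size=(n, R))
    amp = config.respiratory_amp_mm * np.exp(
        0.2 * rng.standard_normal(n)
    )
    osc = np.sin(
        2 * np.pi * config.respiratory_freq_hz * t[None, None, :] + phase[:, :, None]
    )
    params[..., 1] += amp[:, None, None] * osc
    params[..., 2] += 0.5 * amp[:, None, None] * osc

    # transient displacement spikes on a random translation parameter
    spikes = rng.random((n, R, T)) < spike_prob[:, None, None]
    where = np.argwhere(spikes)
    if where.size:
        mags = config.spike_magnitude_min_mm + rng.exponential(
            config.spike_magnitude_scale_mm, size=len(where)
        )
        signs = rng.choice([-1.0, 1.0], size=len(where))
        axes = rng.integers(0, 3, size=len(where))
        params[where[:, 0], where[:, 1], where[:, 2], axes] += mags * signs
    return params, spike_prob


def _generate_timeseries(
    rng: np.random.Generator,
    config: CohortConfig,
    geometry: pd.DataFrame,
    fd_unfiltered: np.ndarray,
) -> np.ndarray:
    """ROI signal = latent network signal + motion-locked spatially
    structured artifact.  ``fd_unfiltered`` is (n, total_frames)."""
    n, k = config.n_subjects, config.n_rois
    F = config.frames_per_subject
    n_networks = 5

    xyz = geometry[["x", "y", "z"]].to_numpy()
    dist = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    kern = np.exp(-dist / config.artifact_distance_decay)
    loadings = np.linalg.cholesky(kern + 1e-8 * np.eye(k))

    network_loadings = 0.5 * rng.standard_normal((k, n_networks))
    ts = np.empty((n, F, k))
    carrier = np.clip(fd_unfiltered - config.artifact_fd_floor_mm, 0.0, None)
    for i in range(n):
        h = rng.standard_normal((F, n_networks))
        sig = h @ network_loadings.T + rng.standard_normal((F, k))
        if config.artifact_strength != 0.0:
            w = rng.standard_normal((F, k))
            sig += (
                config.artifact_strength
                * carrier[i][:, None]
                * (w @ loadings.T)
            )
        ts[i] = sig
    return ts


def _generate_geometry(rng: np.random.Generator, config: CohortConfig) -> pd.DataFrame:
    # centroids in a brain-sized box (mm); resample until all pairwise
    # distances are strictly positive
    while True:
        xyz = rng.uniform(-70, 70, size=(config.n_rois, 3))
        d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
        if (d[np.triu_indices(config.n_rois, 1)] > 1e-6).all():
            break
    return pd.DataFrame(
        {
            "roi_id": [f"roi{j:03d}" for j in range(config.n_rois)],
            "x": xyz[:, 0],
            "y": xyz[:, 1],
            "z": xyz[:, 2],
        }
    )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a complete cohort (records, motion, geometry, time series).

    Deterministic in ``config.seed``; two calls with equal configs return
    bit-identical arrays.
    """
    rng = np.random.default_rng(config.seed)
    records, latents = _generate_covariates(rng, config)
    geometry = _generate_geometry(rng, config)
    params, _ = _generate_motion(rng, config, latents)

    timeseries = None
    if config.make_timeseries:
        fd = fd_from_params(params, config.head_radius_mm)
        fd_flat = fd.reshape(config.n_subjects, config.frames_per_subject)
        timeseries = _generate_timeseries(rng, config, geometry, fd_flat)

    return Cohort(
        config=config,
        records=records,
        motion=params,
        geometry=geometry,
        timeseries=timeseries,
    )
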