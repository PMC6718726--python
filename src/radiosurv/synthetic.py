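"""Phantom mpMRI studies and feature-level cohorts with survival linked to texture.

The generator builds what the downstream analysis assumes and nothing more: a
brain ellipsoid carrying four channels with distinct baselines, three nested
tumor sub-regions (edema / core / enhancing) with per-region contrast, a
checkerboard texture of configurable amplitude (giving analytically
predictable co-occurrence contrast), additive Gaussian noise, and overall
survival drawn from an exponential proportional-hazards model whose log-hazard
is a linear combination of designated generating parameters.  Ages are
truncated-normal; resection status is GTR/STR/MISSING with a configurable
missing fraction.

Every generator is a pure function of its config and seed.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES
from .io_preprocess import (GTR, MISSING, STR_STATUS, CHANNELS, LABEL_ED,
                            LABEL_ET, LABEL_NCR_NET, MriStudy)

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """A generator config violates its invariants."""


# ---------------------------------------------------------------- configs


@dataclasses.dataclass
class PhantomConfig:
    """Geometry, contrast and noise of one phantom study."""

    grid_shape: tuple[int, int, int] = (64, 64, 48)
    voxel_mm: float = 1.0
    brain_radius_mm: tuple[float, float, float] = (28.0, 28.0, 20.0)
    wt_radius_mm: float = 16.0
    tc_radius_mm: float = 10.0
    at_radius_mm: float = 6.0
    #: checkerboard amplitude per sub-region, grey units
    texture_contrast: float = 30.0
    texture_period: int = 4
    #: mean in-brain intensity per channel
    channel_baselines: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"t1": 120.0, "t1gd": 110.0, "t2": 100.0, "flair": 90.0})
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.at_radius_mm <= self.tc_radius_mm <= self.wt_radius_mm):
            raise ConfigurationError(
                "radii must satisfy 0 < at <= tc <= wt "
                f"(got at={self.at_radius_mm}, tc={self.tc_radius_mm}, wt={self.wt_radius_mm})")
        half_extent = min(self.grid_shape) * self.voxel_mm / 2.0
        if self.wt_radius_mm >= half_extent:
            raise ConfigurationError(
                f"wt radius {self.wt_radius_mm} mm does not fit half the grid extent "
                f"({half_extent} mm)")
        if set(self.channel_baselines) != set(CHANNELS):
            raise ConfigurationError(f"channel_baselines must cover {CHANNELS}")


@dataclasses.dataclass
class CohortConfig:
    """Population-level structure of a synthetic cohort.

    ``effect_features`` name generating parameters (feature-level cohorts: any
    column name; imaging cohorts: phantom parameters such as
    ``texture_contrast`` or ``wt_radius_mm``); ``effect_sizes`` are their
    log-hazard coefficients per standard deviation.  Defaults mirror the study
    conditions: n=163 patients, ~49% missing resection status, ages ~N(60, 12^2)
    truncated to [18, 90], and a baseline median survival of 362 days.
    """

    n_patients: int = 163
    effect_features: tuple[str, ...] = ("texture_contrast", "wt_radius_mm")
    effect_sizes: tuple[float, ...] = (0.5, 0.5)
    baseline_median_os_days: float = 362.0
    age_mean: float = 60.0
    age_sd: float = 12.0
    missing_resection_frac: float = 0.49
    gtr_frac_known: float = 59.0 / 83.0  # GTR share among known statuses
    censoring_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 3:
            raise ConfigurationError("need n_patients >= 3 to form three survival groups")
        if not 0.0 <= self.missing_resection_frac <= 1.0:
            raise ConfigurationError("missing_resection_frac must lie in [0, 1]")
        if len(self.effect_features) != len(self.effect_sizes):
            raise ConfigurationError("effect_features and effect_sizes lengths differ")
        if len(set(self.effect_features)) != len(self.effect_features):
            raise ConfigurationError("duplicate effect feature names")


# ---------------------------------------------------------------- phantom study


def _ellipsoid(shape: Sequence[int], center: Sequence[float],
               radii: Sequence[float]) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return d <= 1.0


def _checkerboard(shape: Sequence[int], period: int) -> np.ndarray:
    """+1/-1 3-D checkerboard with the given cell period (voxels)."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    parity = sum(g // period for g in grids) % 2
    return np.where(parity == 0, 1.0, -1.0)


#: per-channel additive contrast of each tumor sub-region (grey units); makes
#: the region each pairing reads brightest on its paired channel
_REGION_CONTRAST = {
    "flair": {"ed": 60.0, "core": 40.0, "at": 40.0},
    "t2": {"ed": 25.0, "core": 55.0, "at": 45.0},
    "t1gd": {"ed": 10.0, "core": 20.0, "at": 70.0},
    "t1": {"ed": -15.0, "core": -25.0, "at": -10.0},
}


def generate_phantom_study(config: PhantomConfig,
                           patient_id: str = "phantom") -> MriStudy:
    """Generate one phantom study: four channels plus a nested label volume.

    Identical config and seed reproduce identical voxel data.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.grid_shape)
    center = tuple((s - 1) / 2.0 for s in shape)
    vox = config.voxel_mm

    brain = _ellipsoid(shape, center, tuple(r / vox for r in config.brain_radius_mm))
    # tumor offset from brain center so the phantom is not trivially symmetric
    t_center = tuple(c + o for c, o in zip(center, (4.0, -3.0, 2.0)))
    wt = _ellipsoid(shape, t_center, (config.wt_radius_mm / vox,) * 3) & brain
    tc = _ellipsoid(shape, t_center, (config.tc_radius_mm / vox,) * 3) & brain
    at = _ellipsoid(shape, t_center, (config.at_radius_mm / vox,) * 3) & brain

    labels = np.zeros(shape, dtype=np.int16)
    labels[wt] = LABEL_ED
    labels[tc] = LABEL_NCR_NET
    labels[at] = LABEL_ET

    board = _checkerboard(shape, config.texture_period)
    channels: dict[str, np.ndarray] = {}
    for ch in CHANNELS:
        vol = np.zeros(shape, dtype=np.float64)
        vol[brain] = config.channel_baselines[ch]
        rc = _REGION_CONTRAST[ch]
        vol[wt & ~tc] += rc["ed"]
        vol[tc & ~at] += rc["core"]
        vol[at] += rc["at"]
        vol[wt] += config.texture_contrast * board[wt]
        if config.noise_sd > 0:
            vol[brain] += rng.normal(0.0, config.noise_sd, int(brain.sum()))
        vol[brain] = np.clip(vol[brain], 1.0, None)  # keep brain support nonzero
        vol[~brain] = 0.0
        channels[ch] = vol
    return MriStudy(patient_id=patient_id, channels=channels, labels=labels,
                    voxel_mm=(vox, vox, vox))


# ---------------------------------------------------------------- survival model


def _sample_survival(rng: np.random.Generator, latent: pd.DataFrame,
                     config: CohortConfig) -> np.ndarray:
    """Exponential proportional-hazards survival times in days.

    hazard_i = (ln 2 / baseline_median) * exp(sum_j beta_j z_ij) with z the
    cohort-standardized generating features; one rate parameter, so the
    baseline median survival is ``baseline_median_os_days`` when all effects
    vanish.
    """
    n = len(latent)
    lp = np.zeros(n)
    for name, beta in zip(config.effect_features, config.effect_sizes):
        col = latent[name].to_numpy(dtype=float)
        sd = col.std()
        z = (col - col.mean()) / sd if sd > 0 else np.zeros(n)
        lp += beta * z
    base_rate = np.log(2.0) / config.baseline_median_os_days
    os_days = rng.exponential(1.0 / (base_rate * np.exp(lp)))
    return np.maximum(os_days, 1.0)


def _clinical_table(rng: np.random.Generator, patient_ids: Sequence[str],
                    os_days: np.ndarray, config: CohortConfig) -> pd.DataFrame:
    n = len(patient_ids)
    ages = rng.normal(config.age_mean, config.age_sd, n)
    # truncated normal by redraw
    for _ in range(100):
        bad = (ages < 18.0) | (ages > 90.0)
        if not bad.any():
            break
        ages[bad] = rng.normal(config.age_mean, config.age_sd, int(bad.sum()))
    ages = np.clip(ages, 18.0, 90.0)
    u = rng.random(n)
    status = np.where(
        u < config.missing_resection_frac, MISSING,
        np.where(rng.random(n) < config.gtr_frac_known, GTR, STR_STATUS))
    event = np.ones(n, dtype=int)
    if config.censoring_frac > 0:
        cens = rng.random(n) < config.censoring_frac
        os_days = np.where(cens, os_days * rng.random(n), os_days)
        event = (~cens).astype(int)
    return pd.DataFrame({
        "patient_id": list(patient_ids),
        "age_years": ages,
        "os_days": np.maximum(os_days, 1.0),
        "resection_status": status,
        "event": event,
    })


# ---------------------------------------------------------------- cohorts

#: per-patient phantom parameter variation (lognormal sd on radii, normal on texture)
_RADIUS_LOG_SD = 0.15
_TEXTURE_SD = 10.0


def generate_cohort(config: CohortConfig,
                    phantom: PhantomConfig | None = None
                    ) -> tuple[list[MriStudy], pd.DataFrame, pd.DataFrame]:
    """Generate an imaging cohort: studies, clinical table, latent parameters.

    Per-patient phantom geometry and texture are drawn around the template
    ``phantom`` config; survival hazard follows the configured linear model on
    the latent generating parameters.  Returns ``(studies, clinical, latent)``
    — the latent table holds the true generating values the hazard was linked
    to, for parameter-recovery checks.
    """
    if phantom is None:
        phantom = PhantomConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    ids = [f"SYN{i:04d}" for i in range(1, n + 1)]

    wt = phantom.wt_radius_mm * np.exp(rng.normal(0, _RADIUS_LOG_SD, n))
    half_extent = min(phantom.grid_shape) * phantom.voxel_mm / 2.0
    wt = np.clip(wt, 4.0, half_extent - 1.0)
    tc = wt * np.clip(phantom.tc_radius_mm / phantom.wt_radius_mm
                      * np.exp(rng.normal(0, _RADIUS_LOG_SD, n)), 0.1, 1.0)
    at = tc * np.clip(phantom.at_radius_mm / phantom.tc_radius_mm
                      * np.exp(rng.normal(0, _RADIUS_LOG_SD, n)), 0.1, 1.0)
    texture = np.clip(rng.normal(phantom.texture_contrast, _TEXTURE_SD, n), 0.0, None)
    latent = pd.DataFrame({
        "patient_id": ids,
        "wt_radius_mm": wt,
        "tc_radius_mm": tc,
        "at_radius_mm": at,
        "texture_contrast": texture,
    }).set_index("patient_id")

    unknown = set(config.effect_features) - set(latent.columns)
    if unknown:
        raise ConfigurationError(f"unknown effect feature(s) for imaging cohort: {sorted(unknown)}")

    studies = []
    for i, pid in enumerate(ids):
        cfg = dataclasses.replace(
            phantom,
            wt_radius_mm=float(wt[i]), tc_radius_mm=float(tc[i]),
            at_radius_mm=float(at[i]), texture_contrast=float(texture[i]),
            seed=int(rng.integers(0, 2 ** 31 - 1)))
        studies.append(generate_phantom_study(cfg, patient_id=pid))

    os_days = _sample_survival(rng, latent, config)
    clinical = _clinical_table(rng, ids, os_days, config)
    return studies, clinical, latent.reset_index()


def generate_feature_cohort(config: CohortConfig, p_features: int = 147,
                            n_constant_decoys: int = 0, noise_sd: float = 1.0
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature-level cohort: an n x p feature table plus the clinical table.

    A fast path for exercising selection, signature and classifier stages
    without imaging.  Columns are standard-normal decoys named after the
    canonical catalogue; effect columns (named in the config) carry the
    survival signal.  Effect names not in the canonical list replace the
    leading decoy names.  ``n_constant_decoys`` appends zero-variance columns
    (for filter tests).
    """
    if p_features < len(config.effect_features):
        raise ConfigurationError("p_features smaller than the number of effect features")
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    ids = [f"SYN{i:04d}" for i in range(1, n + 1)]

    names = list(FEATURE_NAMES[:p_features])
    if p_features > len(FEATURE_NAMES):
        names += [f"Synthetic_Extra_Noise_F{i}" for i in range(len(FEATURE_NAMES) + 1,
                                                               p_features + 1)]
    slot = 0
    for eff in config.effect_features:
        if eff not in names:
            names[slot] = eff
            slot += 1
    if len(set(names)) != len(names):
        raise ConfigurationError("duplicate column names after effect renaming")

    X = rng.normal(0.0, noise_sd, (n, len(names)))
    table = pd.DataFrame(X, columns=names, index=pd.Index(ids, name="patient_id"))
    for i in range(n_constant_decoys):
        table[f"Synthetic_Const_Decoy_F{p_features + i + 1}"] = 1.0

    os_days = _sample_survival(rng, table, config)
    clinical = _clinical_table(rng, ids, os_days, config)
    return table, clinical
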