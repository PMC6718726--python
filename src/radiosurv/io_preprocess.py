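"""Study IO, tumor-mask decoding, intensity standardization, cohort split, survival classes.

Volumes are four co-registered, skull-stripped 3-D MRI channels (T1, T1-Gd, T2,
T2-FLAIR) plus an integer label volume using the BRATS post-2017 convention
(0 background, 1 necrosis/non-enhancing core, 2 edema, 4 enhancing tumor).
Intensities are standardized per channel to 8 bits over the brain's mu +/- 3 sigma
range before any feature is computed.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------- constants

CHANNELS: tuple[str, ...] = ("t1", "t1gd", "t2", "flair")
#: reference channel whose nonzero support defines the brain mask
REFERENCE_CHANNEL = "t1"

LABEL_BACKGROUND = 0
LABEL_NCR_NET = 1  # necrosis + non-enhancing solid core
LABEL_ED = 2       # peritumoral edema
LABEL_ET = 4       # enhancing tumor
VALID_LABELS = frozenset({LABEL_BACKGROUND, LABEL_NCR_NET, LABEL_ED, LABEL_ET})

#: days per month used to convert overall survival to the class thresholds
#: (Julian year / 12; the threshold definitions are stated in months only)
DAYS_PER_MONTH = 30.4375
SHORT_MAX_MONTHS = 10.0
LONG_MIN_MONTHS = 15.0

SHORT, MEDIUM, LONG = "SHORT", "MEDIUM", "LONG"
SURVIVAL_CLASSES = (SHORT, MEDIUM, LONG)
GTR, STR_STATUS, MISSING = "GTR", "STR", "MISSING"
RESECTION_CATEGORIES = (GTR, STR_STATUS, MISSING)

CLINICAL_COLUMNS = ("patient_id", "age_years", "os_days", "resection_status")


class FormatError(ValueError):
    """Input files or arrays violate the declared study format."""


class EmptyTumorError(ValueError):
    """Label volume contains no tumor voxels (empty whole tumor)."""


class DegenerateVolumeError(ValueError):
    """Intensity volume has zero variance over the brain mask."""


# ---------------------------------------------------------------- domain types


@dataclasses.dataclass
class MriStudy:
    """One patient's four channel volumes plus the tumor label volume."""

    patient_id: str
    channels: dict[str, np.ndarray]
    labels: np.ndarray
    voxel_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        missing = [c for c in CHANNELS if c not in self.channels]
        if missing:
            raise FormatError(f"missing channel(s): {', '.join(missing)}")
        shapes = {c: v.shape for c, v in self.channels.items()}
        shapes["labels"] = self.labels.shape
        if len(set(shapes.values())) != 1:
            raise FormatError(f"inconsistent volume shapes: {shapes}")
        found = set(np.unique(self.labels).tolist())
        if not found <= VALID_LABELS:
            raise FormatError(
                f"unknown label value(s) {sorted(found - VALID_LABELS)}; "
                f"expected subset of {sorted(VALID_LABELS)}"
            )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape


@dataclasses.dataclass
class TumorMasks:
    """Nested boolean tumor sub-region masks plus the brain support mask.

    whole tumor (wt) = edema + core; tumor core (tc) = necrosis/non-enhancing
    + enhancing; active tumor (at) = enhancing only.  at <= tc <= wt <= brain.
    """

    wt: np.ndarray
    tc: np.ndarray
    at: np.ndarray
    brain: np.ndarray

    def __post_init__(self) -> None:
        if not self.wt.any():
            raise EmptyTumorError("whole-tumor mask is empty")
        if np.any(self.at & ~self.tc) or np.any(self.tc & ~self.wt):
            raise FormatError("tumor masks are not nested (AT <= TC <= WT violated)")


# ---------------------------------------------------------------- reading/writing


def read_study(
    paths: Mapping[str, str | Path],
    patient_id: str | None = None,
    legacy_labels: bool = False,
) -> MriStudy:
    """Load one study from NIfTI files.

    ``paths`` maps each channel name (t1, t1gd, t2, flair) and ``"seg"`` to a
    file path.  ``legacy_labels`` maps the pre-2017 BRATS dialect {0,1,2,3,4}
    onto the current one (3 -> 1).
    """
    missing = [k for k in (*CHANNELS, "seg") if k not in paths]
    if missing:
        raise FormatError(f"missing channel(s): {', '.join(missing)}")
    volumes: dict[str, np.ndarray] = {}
    spacing: tuple[float, float, float] | None = None
    for key in (*CHANNELS, "seg"):
        img = nib.load(str(paths[key]))
        data = np.asarray(img.dataobj)
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        if spacing is None:
            spacing = zooms
        elif not np.allclose(zooms, spacing):
            raise FormatError(f"voxel spacing of {key} {zooms} differs from {spacing}")
        volumes[key] = data
    labels = np.rint(volumes.pop("seg")).astype(np.int16)
    if legacy_labels:
        labels[labels == 3] = LABEL_NCR_NET
    if patient_id is None:
        patient_id = Path(str(paths["seg"])).name.split("_")[0]
    return MriStudy(patient_id=patient_id, channels=volumes, labels=labels,
                    voxel_mm=spacing or (1.0, 1.0, 1.0))


def write_study(study: MriStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write a study as ``<id>_<channel>.nii.gz`` files; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*study.voxel_mm, 1.0])
    paths: dict[str, Path] = {}
    for key in CHANNELS:
        p = out / f"{study.patient_id}_{key}.nii.gz"
        nib.save(nib.Nifti1Image(study.channels[key].astype(np.float32), affine), p)
        paths[key] = p
    p = out / f"{study.patient_id}_seg.nii.gz"
    nib.save(nib.Nifti1Image(study.labels.astype(np.int16), affine), p)
    paths["seg"] = p
    return paths


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read the clinical CSV (patient_id, age_years, os_days, resection_status)."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"clinical table missing column(s): {sorted(missing)}")
    bad = set(df["resection_status"].unique()) - set(RESECTION_CATEGORIES)
    if bad:
        raise FormatError(f"unknown resection status value(s): {sorted(bad)}")
    if (df["os_days"] <= 0).any():
        raise FormatError("os_days must be positive")
    return df


# ---------------------------------------------------------------- mask decoding


def decode_masks(labels: np.ndarray, reference: np.ndarray | None = None) -> TumorMasks:
    """Decode nested WT/TC/AT masks from a BRATS label volume.

    WT = {1,2,4}, TC = {1,4}, AT = {4}.  ``reference`` is the intensity volume
    whose nonzero support defines the brain mask; when omitted the brain is
    taken as the full grid.
    """
    found = set(np.unique(labels).tolist())
    if not found <= VALID_LABELS:
        raise FormatError(f"unknown label value(s) {sorted(found - VALID_LABELS)}")
    at = labels == LABEL_ET
    tc = at | (labels == LABEL_NCR_NET)
    wt = tc | (labels == LABEL_ED)
    if not wt.any():
        raise EmptyTumorError("label volume contains no tumor voxels")
    if reference is not None:
        brain = np.asarray(reference) > 0
        brain |= wt  # tumor voxels are brain by definition
    else:
        brain = np.ones(labels.shape, dtype=bool)
    return TumorMasks(wt=wt, tc=tc, at=at, brain=brain)


def study_masks(study: MriStudy) -> TumorMasks:
    """Decode masks for a study, using the reference channel for brain support."""
    return decode_masks(study.labels, reference=study.channels[REFERENCE_CHANNEL])


# ---------------------------------------------------------------- normalization


def normalize_mu3sigma(volume: np.ndarray, brain: np.ndarray) -> np.ndarray:
    """Standardize an intensity volume to 8 bits over the brain's mu +/- 3 sigma.

    mu and sigma (population denominator) are computed over brain voxels; values
    are clipped to [mu - 3 sigma, mu + 3 sigma], mapped affinely onto [0, 255]
    and rounded half-up.  The result is invariant to positive affine intensity
    transforms of the input (a*V + b, a > 0), which is the point of the scheme:
    scanner-dependent gain and offset drop out.
    """
    volume = np.asarray(volume, dtype=np.float64)
    brain = np.asarray(brain, dtype=bool)
    if not brain.any():
        raise DegenerateVolumeError("brain mask is empty")
    vals = volume[brain]
    mu = vals.mean()
    sigma = vals.std()  # population (n-denominator)
    if sigma == 0:
        raise DegenerateVolumeError("zero intensity variance over the brain mask")
    lo, hi = mu - 3.0 * sigma, mu + 3.0 * sigma
    scaled = (np.clip(volume, lo, hi) - lo) / (hi - lo) * 255.0
    return np.floor(scaled + 0.5).astype(np.uint8)  # round half-up


def normalize_study(study: MriStudy, masks: TumorMasks | None = None) -> MriStudy:
    """Return a copy of the study with every channel mu+/-3sigma standardized.

    Each channel is normalized against its own brain statistics.
    """
    if masks is None:
        masks = study_masks(study)
    channels = {c: normalize_mu3sigma(v, masks.brain) for c, v in study.channels.items()}
    return MriStudy(patient_id=study.patient_id, channels=channels,
                    labels=study.labels.copy(), voxel_mm=study.voxel_mm)


# ---------------------------------------------------------------- split & classes


def sort_for_split(records: pd.DataFrame) -> pd.DataFrame:
    """Stable sort by (os_days, patient_id) — the ordering the 1-in-3 split expects."""
    return records.sort_values(["os_days", "patient_id"], kind="stable").reset_index(drop=True)


def split_discovery_validation(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic 1-in-3 cohort split on survival-sorted records.

    With records sorted ascending by overall survival, every third one (1-based
    rank divisible by 3) goes to validation and the rest to discovery, so the
    full range of survival times appears in both cohorts.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records to split")
    os_days = records["os_days"].to_numpy()
    if np.any(np.diff(os_days) < 0):
        raise ValueError("records must be sorted ascending by os_days (see sort_for_split)")
    rank = np.arange(1, len(records) + 1)
    validation = records.iloc[rank % 3 == 0].reset_index(drop=True)
    discovery = records.iloc[rank % 3 != 0].reset_index(drop=True)
    return discovery, validation


def survival_class(os_days: float, days_per_month: float = DAYS_PER_MONTH) -> str:
    """Assign SHORT (<10 months), MEDIUM (10-15 months, inclusive) or LONG (>15)."""
    if not np.isfinite(os_days) or os_days <= 0:
        raise ValueError(f"os_days must be positive and finite, got {os_days}")
    months = os_days / days_per_month
    if months < SHORT_MAX_MONTHS:
        return SHORT
    if months <= LONG_MIN_MONTHS:
        return MEDIUM
    return LONG


def survival_classes(os_days, days_per_month: float = DAYS_PER_MONTH) -> np.ndarray:
    """Vectorized :func:`survival_class`."""
    return np.array([survival_class(d, days_per_month) for d in np.asarray(os_days, dtype=float)])
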