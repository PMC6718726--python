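"""The 147-feature radiomics catalogue over three tumor sub-region / modality pairings.

Per pairing — whole tumor on T2-FLAIR, active tumor on T1-Gd, tumor core on T2
— 48 features are computed on the axial slice with the largest in-slice tumor
area: 14 geometry/shape, 14 first-order intensity, 14 GLCM texture, 3 HOG and
3 LBP summaries.  Three joint volume ratios (AT/WT, TC/WT, AT/TC) complete the
catalogue.  Features are named ``Modality_Region_FeatureName_F<index>`` with a
fixed documented order, e.g. ``T2_TC_SumHOG_F139``.

All texture features operate on 8-bit standardized intensities (see
:mod:`radiosurv.io_preprocess`).  Empty sub-regions produce the policy value 0
for their whole block, recorded in the extraction QC log, so the cohort feature
matrix stays rectangular.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from skimage.feature import hog as sk_hog
from skimage.measure import regionprops

from .io_preprocess import MriStudy, TumorMasks, study_masks

logger = logging.getLogger(__name__)

EMPTY_REGION_VALUE = 0.0

# ------------------------------------------------------------- catalogue order

#: (modality label, region label, channel key, mask attribute), block order fixed
PAIRINGS: tuple[tuple[str, str, str, str], ...] = (
    ("T2-FLAIR", "WT", "flair", "wt"),
    ("T1-Gd", "AT", "t1gd", "at"),
    ("T2", "TC", "t2", "tc"),
)

SHAPE_NAMES = (
    "TumorVolume", "BrainVolume", "TumorToBrainVolumeRatio",
    "ConvexArea", "FilledArea", "TumorArea", "BrainArea",
    "TumorToBrainAreaRatio", "Eccentricity", "Orientation",
    "EquivalentDiameter", "Solidity", "Extent", "Perimeter",
)
INTENSITY_NAMES = (
    "MinimumIntensity", "MaximumIntensity", "MedianIntensity", "MeanIntensity",
    "Range", "Variance", "Moment2nd", "Moment3rd", "Entropy", "Kurtosis",
    "RMS", "Skewness", "StdDev", "MeanAbsoluteDeviation",
)
GLCM_NAMES = (
    "Contrast", "Correlation", "Energy", "Homogeneity",
    "SumVariance", "SumAverage", "MeanVariance", "MeanAutocorrelation",
    "Entropy", "SumEntropy2", "DifferenceEntropy2",
    "SumVariance2", "DifferenceVariance2", "GLCMRange",
)
HOG_NAMES = ("SumHOG", "MedianHOG", "StdHOG")
LBP_NAMES = ("SumLBP", "MeanLBP", "StdLBP")
BLOCK_NAMES: tuple[str, ...] = (*SHAPE_NAMES, *INTENSITY_NAMES, *GLCM_NAMES,
                                *HOG_NAMES, *LBP_NAMES)
JOINT_NAMES = ("ATtoWTVolumeRatio", "TCtoWTVolumeRatio", "ATtoTCVolumeRatio")

N_PER_BLOCK = len(BLOCK_NAMES)          # 48
N_FEATURES = N_PER_BLOCK * len(PAIRINGS) + len(JOINT_NAMES)  # 147


def feature_names() -> list[str]:
    """The full ordered 147-name catalogue, ``Modality_Region_FeatureName_F<i>``."""
    names: list[str] = []
    idx = 1
    for modality, region, _, _ in PAIRINGS:
        for base in BLOCK_NAMES:
            names.append(f"{modality}_{region}_{base}_F{idx}")
            idx += 1
    for base in JOINT_NAMES:
        names.append(f"mpMRI_Joint_{base}_F{idx}")
        idx += 1
    return names


FEATURE_NAMES: tuple[str, ...] = tuple(feature_names())


def write_feature_manifest(path: str | Path) -> None:
    """Write the machine-readable feature-order manifest as JSON."""
    manifest = {
        "n_features": N_FEATURES,
        "per_block": N_PER_BLOCK,
        "pairings": [{"modality": m, "region": r} for m, r, _, _ in PAIRINGS],
        "names": list(FEATURE_NAMES),
    }
    Path(path).write_text(json.dumps(manifest, indent=1))


# ------------------------------------------------------------- ROI machinery


@dataclasses.dataclass
class RoiPatch:
    """A 2-D grey-level patch cropped to the tight bounding box of its mask."""

    image2d: np.ndarray
    mask2d: np.ndarray
    plane: str = "axial"
    slice_index: int = 0
    bounding_box: tuple[int, int, int, int] = (0, 0, 0, 0)

    def __post_init__(self) -> None:
        if self.image2d.shape != self.mask2d.shape:
            raise ValueError("image and mask shapes differ")
        if not self.mask2d.any():
            raise EmptyRegionError("ROI mask is empty")


class EmptyRegionError(ValueError):
    """A requested tumor sub-region contains no voxels."""


class DegenerateTextureError(ValueError):
    """No valid in-mask pixel pair exists for co-occurrence counting."""


def select_slice(mask3d: np.ndarray) -> tuple[str, int]:
    """Pick the axial (transverse) slice with the largest in-slice mask area.

    Ties break to the lowest slice index.  The third array axis is axial.
    """
    mask3d = np.asarray(mask3d, dtype=bool)
    if not mask3d.any():
        raise EmptyRegionError("cannot select a slice from an empty mask")
    areas = mask3d.sum(axis=(0, 1))
    return "axial", int(np.argmax(areas))


def crop_roi(image2d: np.ndarray, mask2d: np.ndarray,
             slice_index: int = 0) -> RoiPatch:
    """Crop image and mask to the tight bounding box of the mask.

    Pixels outside the mask are retained in the image but flagged false in the
    mask, so texture operators can decide per-pixel membership.
    """
    mask2d = np.asarray(mask2d, dtype=bool)
    if not mask2d.any():
        raise EmptyRegionError("cannot crop an empty mask")
    rows = np.flatnonzero(mask2d.any(axis=1))
    cols = np.flatnonzero(mask2d.any(axis=0))
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    return RoiPatch(
        image2d=np.asarray(image2d)[r0:r1, c0:c1],
        mask2d=mask2d[r0:r1, c0:c1],
        slice_index=slice_index,
        bounding_box=(r0, c0, r1, c1),
    )


# ------------------------------------------------------------- shape features


def shape_features(mask3d: np.ndarray, brain3d: np.ndarray, slice_index: int,
                   voxel_mm: Sequence[float]) -> dict[str, float]:
    """14 geometry descriptors: 3-D volumes plus 2-D slice descriptors.

    Volumes are voxel counts times voxel volume (mm^3); areas and the six
    regionprops descriptors are computed on the selected axial slice.  The
    orientation is the major-axis angle in degrees in (-90, 90].
    """
    mask3d = np.asarray(mask3d, dtype=bool)
    brain3d = np.asarray(brain3d, dtype=bool)
    if not mask3d.any():
        raise EmptyRegionError("empty region mask")
    voxel_mm = tuple(float(v) for v in voxel_mm)
    voxvol = float(np.prod(voxel_mm))
    pix_mm = voxel_mm[0]  # in-plane spacing (isotropic input assumed)
    pixarea = voxel_mm[0] * voxel_mm[1]

    tumor_vol = mask3d.sum() * voxvol
    brain_vol = brain3d.sum() * voxvol

    mask2d = mask3d[:, :, slice_index]
    brain2d = brain3d[:, :, slice_index]
    # all in-mask pixels form one region regardless of connectivity
    rp = regionprops(mask2d.astype(np.uint8))[0]
    brain_area = brain2d.sum() * pixarea
    return {
        "TumorVolume": tumor_vol,
        "BrainVolume": brain_vol,
        "TumorToBrainVolumeRatio": tumor_vol / brain_vol if brain_vol else EMPTY_REGION_VALUE,
        "ConvexArea": float(rp.area_convex) * pixarea,
        "FilledArea": float(rp.area_filled) * pixarea,
        "TumorArea": float(rp.area) * pixarea,
        "BrainArea": brain_area,
        "TumorToBrainAreaRatio": float(rp.area) * pixarea / brain_area if brain_area else EMPTY_REGION_VALUE,
        "Eccentricity": float(rp.eccentricity),
        "Orientation": float(np.degrees(rp.orientation)),
        "EquivalentDiameter": float(rp.equivalent_diameter_area) * pix_mm,
        "Solidity": float(rp.solidity),
        "Extent": float(rp.extent),
        "Perimeter": float(rp.perimeter) * pix_mm,
    }


def joint_shape_features(masks: TumorMasks) -> dict[str, float]:
    """Joint volume ratios AT/WT, TC/WT, AT/TC across the nested sub-regions."""
    n_wt = int(masks.wt.sum())
    n_tc = int(masks.tc.sum())
    n_at = int(masks.at.sum())
    if n_wt == 0:
        raise EmptyRegionError("whole tumor empty")
    return {
        "ATtoWTVolumeRatio": n_at / n_wt,
        "TCtoWTVolumeRatio": n_tc / n_wt,
        "ATtoTCVolumeRatio": n_at / n_tc if n_tc else EMPTY_REGION_VALUE,
    }


# ------------------------------------------------------------- intensity


def intensity_features(values: np.ndarray) -> dict[str, float]:
    """14 first-order statistics of the in-mask grey levels.

    Entropy uses the 256-bin normalized histogram, in bits.  Moments are
    central population moments; variance and SD use the n-1 denominator;
    kurtosis is non-excess.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise EmptyRegionError("no intensity values")
    hist = np.bincount(np.clip(x.astype(np.int64), 0, 255), minlength=256)
    p = hist / hist.sum()
    p = p[p > 0]
    entropy = float(-(p * np.log2(p)).sum())
    mu = float(x.mean())
    var1 = float(x.var(ddof=1)) if x.size > 1 else 0.0
    centered = x - mu
    return {
        "MinimumIntensity": float(x.min()),
        "MaximumIntensity": float(x.max()),
        "MedianIntensity": float(np.median(x)),
        "MeanIntensity": mu,
        "Range": float(x.max() - x.min()),
        "Variance": var1,
        "Moment2nd": float((centered ** 2).mean()),
        "Moment3rd": float((centered ** 3).mean()),
        "Entropy": entropy,
        "Kurtosis": float(sps.kurtosis(x, fisher=False)) if np.ptp(x) > 0 else 0.0,
        "RMS": float(np.sqrt((x ** 2).mean())),
        "Skewness": float(sps.skew(x)) if np.ptp(x) > 0 else 0.0,
        "StdDev": float(np.sqrt(var1)),
        "MeanAbsoluteDeviation": float(np.abs(centered).mean()),
    }


# ------------------------------------------------------------- GLCM


@dataclasses.dataclass
class GlcmSpec:
    """Quantization and displacement spec for co-occurrence counting.

    ``levels`` grey levels by uniform binning of [0, 255]; offsets are
    (delta_row, delta_col) displacements; matrices are symmetrized and
    normalized to sum 1 by default.
    """

    levels: int = 8
    offsets: tuple[tuple[int, int], ...] = ((0, 1),)
    symmetric: bool = True
    normalized: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("need at least 2 grey levels")
        if not self.offsets:
            raise ValueError("need at least one offset")


OFFSET_0DEG = (0, 1)
OFFSET_45DEG = (-1, 1)


def quantize(image2d: np.ndarray, levels: int) -> np.ndarray:
    """Uniformly bin 8-bit grey values into ``levels`` levels (0..levels-1)."""
    img = np.asarray(image2d, dtype=np.float64)
    q = np.floor(img / 256.0 * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def glcm_matrix(patch: RoiPatch, spec: GlcmSpec = GlcmSpec()) -> np.ndarray:
    """Masked grey-level co-occurrence matrix.

    Counts ordered pairs (p, p+offset) with both pixels inside the mask,
    accumulated over all offsets in the spec.  Hand-rolled because the usual
    array implementations have no mask support.
    """
    q = quantize(patch.image2d, spec.levels)
    m = patch.mask2d
    H, W = q.shape
    counts = np.zeros((spec.levels, spec.levels), dtype=np.float64)
    for dr, dc in spec.offsets:
        i0, i1 = max(0, -dr), H - max(0, dr)
        j0, j1 = max(0, -dc), W - max(0, dc)
        if i0 >= i1 or j0 >= j1:
            continue
        a = q[i0:i1, j0:j1]
        b = q[i0 + dr:i1 + dr, j0 + dc:j1 + dc]
        valid = m[i0:i1, j0:j1] & m[i0 + dr:i1 + dr, j0 + dc:j1 + dc]
        np.add.at(counts, (a[valid], b[valid]), 1.0)
    if counts.sum() == 0:
        raise DegenerateTextureError("no valid in-mask pixel pair for any offset")
    if spec.symmetric:
        counts = counts + counts.T
    if spec.normalized:
        counts = counts / counts.sum()
    return counts


def _haralick(P: np.ndarray) -> dict[str, float]:
    """Textbook Haralick statistics of one normalized co-occurrence matrix."""
    L = P.shape[0]
    i = np.arange(L, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mx, my = (i * px).sum(), (i * py).sum()
    sx = np.sqrt(((i - mx) ** 2 * px).sum())
    sy = np.sqrt(((i - my) ** 2 * py).sum())

    # sum (k = i+j) and difference (k = |i-j|) distributions
    ks = np.arange(2 * L - 1, dtype=np.float64)
    p_sum = np.zeros(2 * L - 1)
    np.add.at(p_sum, (ii + jj).astype(int), P)
    kd = np.arange(L, dtype=np.float64)
    p_diff = np.zeros(L)
    np.add.at(p_diff, np.abs(ii - jj).astype(int), P)

    sum_avg = (ks * p_sum).sum()
    diff_avg = (kd * p_diff).sum()
    nz = P[P > 0]
    nzs = p_sum[p_sum > 0]
    nzd = p_diff[p_diff > 0]
    grand_mean = (ii * P).sum()  # mean of i under P (symmetric: == mean of j)
    if sx > 0 and sy > 0:
        correlation = float((((ii - mx) * (jj - my)) * P).sum() / (sx * sy))
    else:
        correlation = 0.0
    return {
        "Contrast": float(((ii - jj) ** 2 * P).sum()),
        "Correlation": correlation,
        "Energy": float((P ** 2).sum()),
        "Homogeneity": float((P / (1.0 + np.abs(ii - jj))).sum()),
        "SumVariance": float(((ks - sum_avg) ** 2 * p_sum).sum()),
        "SumAverage": float(sum_avg),
        "MeanVariance": float(((ii - grand_mean) ** 2 * P).sum()),
        "MeanAutocorrelation": float((ii * jj * P).sum()),
        "Entropy": float(-(nz * np.log2(nz)).sum()),
        "SumEntropy": float(-(nzs * np.log2(nzs)).sum()),
        "DifferenceEntropy": float(-(nzd * np.log2(nzd)).sum()),
        "SumVariance2_": float(((ks - sum_avg) ** 2 * p_sum).sum()),
        "DifferenceVariance": float(((kd - diff_avg) ** 2 * p_diff).sum()),
    }


def glcm_features(patch: RoiPatch, levels: int = 8,
                  accumulate_offsets: bool = True) -> dict[str, float]:
    """The 14 GLCM texture statistics.

    The first nine use the 0-degree matrix (offset (0,1)); the four "...2"
    statistics (sum entropy, difference entropy, sum variance, difference
    variance) use a single matrix accumulated over the 0- and 45-degree
    offsets, making them less sensitive to texture orientation; the 14th is
    the range (max - min) over the other 13.  With
    ``accumulate_offsets=False`` the "...2" statistics are instead the mean of
    the two single-offset values.
    """
    base = _haralick(glcm_matrix(patch, GlcmSpec(levels=levels, offsets=(OFFSET_0DEG,))))
    if accumulate_offsets:
        acc = _haralick(glcm_matrix(
            patch, GlcmSpec(levels=levels, offsets=(OFFSET_0DEG, OFFSET_45DEG))))
        two = acc
    else:
        h45 = _haralick(glcm_matrix(patch, GlcmSpec(levels=levels, offsets=(OFFSET_45DEG,))))
        two = {k: 0.5 * (base[k] + h45[k]) for k in base}
    out = {
        "Contrast": base["Contrast"],
        "Correlation": base["Correlation"],
        "Energy": base["Energy"],
        "Homogeneity": base["Homogeneity"],
        "SumVariance": base["SumVariance"],
        "SumAverage": base["SumAverage"],
        "MeanVariance": base["MeanVariance"],
        "MeanAutocorrelation": base["MeanAutocorrelation"],
        "Entropy": base["Entropy"],
        "SumEntropy2": two["SumEntropy"],
        "DifferenceEntropy2": two["DifferenceEntropy"],
        "SumVariance2": two["SumVariance2_"],
        "DifferenceVariance2": two["DifferenceVariance"],
    }
    vals = list(out.values())
    out["GLCMRange"] = float(max(vals) - min(vals))
    return out


# ------------------------------------------------------------- HOG / LBP

HOG_ORIENTATIONS = 9
HOG_CELL = (8, 8)
HOG_BLOCK = (2, 2)
_HOG_MIN = HOG_CELL[0] * HOG_BLOCK[0]  # minimum side for one block


def _pad_to(img: np.ndarray, min_shape: tuple[int, int]) -> np.ndarray:
    pr = max(0, min_shape[0] - img.shape[0])
    pc = max(0, min_shape[1] - img.shape[1])
    if pr or pc:
        img = np.pad(img, ((0, pr), (0, pc)))
    return img


def hog_descriptor(patch: RoiPatch) -> np.ndarray:
    """Oriented-gradient descriptor of the masked patch (background zeroed).

    9 orientation bins, 8x8-pixel cells, 2x2-cell blocks; patches smaller than
    one block are zero-padded to 16x16.
    """
    img = np.where(patch.mask2d, patch.image2d, 0).astype(np.float64)
    img = _pad_to(img, (_HOG_MIN, _HOG_MIN))
    return sk_hog(img, orientations=HOG_ORIENTATIONS, pixels_per_cell=HOG_CELL,
                  cells_per_block=HOG_BLOCK, feature_vector=True)


def hog_features(patch: RoiPatch) -> dict[str, float]:
    """Sum, median and standard deviation of the HOG descriptor vector."""
    d = hog_descriptor(patch)
    return {"SumHOG": float(d.sum()), "MedianHOG": float(np.median(d)),
            "StdHOG": float(d.std())}


LBP_POINTS = 8
LBP_RADIUS = 1
LBP_BINS = 59  # non-rotation-invariant uniform patterns, P=8

#: exact unit-circle sample offsets (delta_row, delta_col), counterclockwise
#: from the right-hand neighbor; diagonals at exactly +/- sqrt(1/2)
_LBP_S = np.sqrt(0.5)
LBP_OFFSETS: tuple[tuple[float, float], ...] = (
    (0.0, 1.0), (-_LBP_S, _LBP_S), (-1.0, 0.0), (-_LBP_S, -_LBP_S),
    (0.0, -1.0), (_LBP_S, -_LBP_S), (1.0, 0.0), (_LBP_S, _LBP_S),
)


def _uniform_lut() -> np.ndarray:
    """Map 8-bit LBP codes to bins: 58 uniform patterns (sorted), 58 = non-uniform."""
    lut = np.full(256, LBP_BINS - 1, dtype=np.int64)
    uniform = [code for code in range(256)
               if sum(((code >> i) & 1) != ((code >> ((i + 1) % 8)) & 1)
                      for i in range(8)) <= 2]
    for rank, code in enumerate(sorted(uniform)):
        lut[code] = rank
    return lut


_LBP_LUT = _uniform_lut()


def lbp_codes(image2d: np.ndarray) -> np.ndarray:
    """Uniform local-binary-pattern bin per pixel, 8 neighbors at radius 1.

    Each of the 8 unit-circle samples is bilinearly interpolated (exact
    geometry: axial neighbors are the pixels themselves, diagonal samples sit
    at +/- sqrt(1/2)); a sample at or above the center sets its bit, with the
    difference taken against the center so exact ties are exact zeros.  The
    image is edge-replicated by one pixel so border pixels see real
    neighbors.  Patterns with more than two 0/1 transitions share the
    non-uniform bin (index 58); the 58 uniform patterns occupy bins 0-57 in
    sorted code order.
    """
    # pad by 2: the zero-weight far corner of an integer-offset sample still
    # needs a valid slice
    pf = np.pad(np.asarray(image2d, dtype=np.float64), 2, mode="edge")
    H, W = pf.shape
    center = pf[2:-2, 2:-2]

    def sh(dr: int, dc: int) -> np.ndarray:
        return pf[2 + dr:H - 2 + dr, 2 + dc:W - 2 + dc]

    code = np.zeros(center.shape, dtype=np.int64)
    for bit, (a, b) in enumerate(LBP_OFFSETS):
        ra, rb = int(np.floor(a)), int(np.floor(b))
        fa, fb = a - ra, b - rb
        diff = ((1 - fa) * (1 - fb) * (sh(ra, rb) - center)
                + (1 - fa) * fb * (sh(ra, rb + 1) - center)
                + fa * (1 - fb) * (sh(ra + 1, rb) - center)
                + fa * fb * (sh(ra + 1, rb + 1) - center))
        code |= (diff >= 0).astype(np.int64) << bit
    return _LBP_LUT[code]


def lbp_histogram(patch: RoiPatch) -> np.ndarray:
    """Normalized 59-bin uniform LBP histogram over in-mask pixels.

    Codes are computed on the raw patch (background pixels serve as
    neighbors) but only in-mask pixels contribute to the histogram; patches
    smaller than 3x3 are zero-padded first.
    """
    img = np.rint(np.asarray(patch.image2d, dtype=np.float64))
    mask = patch.mask2d
    if img.shape[0] < 3 or img.shape[1] < 3:
        img = _pad_to(img, (3, 3))
        mask = _pad_to(mask.astype(np.uint8), (3, 3)).astype(bool)
    codes = lbp_codes(img)
    hist = np.bincount(codes[mask], minlength=LBP_BINS).astype(np.float64)
    return hist / hist.sum()


def lbp_features(patch: RoiPatch) -> dict[str, float]:
    """Sum, mean and standard deviation of the normalized LBP histogram."""
    h = lbp_histogram(patch)
    return {"SumLBP": float(h.sum()), "MeanLBP": float(h.mean()),
            "StdLBP": float(h.std())}


# ------------------------------------------------------------- full vector


def _region_block(study: MriStudy, masks: TumorMasks, channel: str,
                  mask3d: np.ndarray, qc: list[str], tag: str) -> dict[str, float]:
    """The 48 features of one (region, modality) pairing, with empty-region policy."""
    if not mask3d.any():
        qc.append(f"{tag}: empty region — whole block set to {EMPTY_REGION_VALUE}")
        return {name: EMPTY_REGION_VALUE for name in BLOCK_NAMES}
    _, k = select_slice(mask3d)
    image = np.asarray(study.channels[channel], dtype=np.float64)
    patch = crop_roi(image[:, :, k], mask3d[:, :, k], slice_index=k)
    out: dict[str, float] = {}
    out.update(shape_features(mask3d, masks.brain, k, study.voxel_mm))
    out.update(intensity_features(patch.image2d[patch.mask2d]))
    try:
        out.update(glcm_features(patch))
    except DegenerateTextureError:
        qc.append(f"{tag}: degenerate texture — GLCM block set to {EMPTY_REGION_VALUE}")
        out.update({name: EMPTY_REGION_VALUE for name in GLCM_NAMES})
    out.update(hog_features(patch))
    out.update(lbp_features(patch))
    return out


def extract_all(study: MriStudy, masks: TumorMasks | None = None,
                qc: list[str] | None = None) -> pd.Series:
    """Extract the full ordered 147-feature vector for one normalized study.

    ``study`` must already be intensity-standardized (see
    :func:`radiosurv.io_preprocess.normalize_study`).  ``qc``, when given, is
    appended with a line per empty or degenerate region.  Deterministic and
    seed-free.
    """
    if masks is None:
        masks = study_masks(study)
    if qc is None:
        qc = []
    values: list[float] = []
    for modality, region, channel, attr in PAIRINGS:
        block = _region_block(study, masks, channel, getattr(masks, attr),
                              qc, f"{study.patient_id}/{modality}_{region}")
        values.extend(block[name] for name in BLOCK_NAMES)
    joint = joint_shape_features(masks)
    if not masks.at.any() or not masks.tc.any():
        qc.append(f"{study.patient_id}/joint: empty sub-region in volume ratios")
    values.extend(joint[name] for name in JOINT_NAMES)
    for line in qc:
        logger.warning("QC: %s", line)
    return pd.Series(values, index=list(FEATURE_NAMES), name=study.patient_id)


def extract_cohort(studies: Iterable[MriStudy]) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Feature table (patients x 147) plus the per-patient QC log."""
    rows, qc_log = [], {}
    for study in studies:
        qc: list[str] = []
        rows.append(extract_all(study, qc=qc))
        if qc:
            qc_log[study.patient_id] = qc
    table = pd.DataFrame(rows)
    table.index.name = "patient_id"
    return table, qc_log
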