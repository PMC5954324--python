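"""Region-of-interest statistics on MWF maps and inter-rater reliability.

Implements the ROI arm of the mapping pipeline: lesion masks are subtracted
from the normal-appearing-white-matter (NAWM) mask so the two regions never
overlap, per-ROI mean MWF and volume are extracted, and the lesion/NAWM MWF
ratio summarises the degree of myelin disruption within lesions (values
near 1 mean lesion myelin close to the subject's own NAWM).  Inter-rater
agreement of manual lesion delineation is quantified with the two-way
random-effects, single-measures, absolute-agreement intraclass correlation
ICC(2,1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ROIMask",
    "ROIStats",
    "ICCResult",
    "subtract_mask",
    "roi_stats",
    "mwf_ratio",
    "icc_two_way_random",
]


@dataclass(frozen=True)
class ROIMask:
    """Binary 3D region mask in register with companion maps.

    Nonzero values other than 1 (e.g. 0/255 masks from segmentation tools)
    are coerced to 1 with a warning.
    """

    values: np.ndarray
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0)
    label: str = "other"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ValueError("mask must be a 3D volume")
        if any(d <= 0 for d in self.voxel_dims):
            raise ValueError("voxel_dims must be positive")
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            warnings.warn(
                f"mask '{self.label}' has values {uniq[:5]}...; coercing nonzero to 1",
                stacklevel=3,
            )
        object.__setattr__(self, "values", (arr != 0).astype(np.uint8))

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_dims))


@dataclass(frozen=True)
class ROIStats:
    """Mean/SE of MWF over one ROI plus its voxel count and volume."""

    mean_mwf: float
    se_mwf: float
    n_voxels: int
    volume_mm3: float
    label: str = "other"


@dataclass(frozen=True)
class ICCResult:
    """Intraclass correlation with its ANOVA F statistic."""

    icc: float
    f_statistic: float
    model: str = "ICC(2,1) two-way random, absolute agreement"
    df1: int = 0
    df2: int = 0


def subtract_mask(nawm: ROIMask, lesion: ROIMask) -> ROIMask:
    """NAWM mask with all lesion voxels removed.

    Output voxel is 1 iff it is in the NAWM mask and not in the lesion
    mask, guaranteeing the two ROIs are disjoint.
    """
    if nawm.values.shape != lesion.values.shape:
        raise ValueError(
            f"mask shapes differ: {nawm.values.shape} vs {lesion.values.shape}"
        )
    if not np.allclose(nawm.voxel_dims, lesion.voxel_dims):
        raise ValueError("masks have different voxel dimensions")
    out = nawm.values * (1 - lesion.values)
    return ROIMask(values=out, voxel_dims=nawm.voxel_dims, label=nawm.label)


def roi_stats(mwf_map: np.ndarray, mask: ROIMask) -> ROIStats:
    """Mean and standard error of defined MWF values under a mask.

    NaN map voxels (undefined fits, out-of-brain) are excluded from the
    mean but the reported volume counts every mask voxel.  An ROI with no
    defined voxels raises rather than silently returning zero.
    """
    arr = np.asarray(mwf_map, dtype=float)
    if arr.shape != mask.values.shape:
        raise ValueError(
            f"map shape {arr.shape} does not match mask {mask.values.shape}"
        )
    vals = arr[mask.values != 0]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"ROI '{mask.label}' contains no defined map voxels")
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
    return ROIStats(
        mean_mwf=mean,
        se_mwf=se,
        n_voxels=mask.n_voxels,
        volume_mm3=mask.n_voxels * mask.voxel_volume_mm3,
        label=mask.label,
    )


def mwf_ratio(lesion_stats: ROIStats, nawm_stats: ROIStats) -> float:
    """Lesion mean MWF divided by NAWM mean MWF.

    Values closer to 1 indicate less myelin disruption inside lesions
    relative to the subject's own normal-appearing white matter.
    """
    if not np.isfinite(nawm_stats.mean_mwf) or nawm_stats.mean_mwf <= 0:
        raise ValueError(
            f"NAWM mean MWF must be > 0 to form a ratio, got {nawm_stats.mean_mwf}"
        )
    return lesion_stats.mean_mwf / nawm_stats.mean_mwf


def icc_two_way_random(ratings: np.ndarray) -> ICCResult:
    """ICC(2,1): single measures, absolute agreement, two-way random model.

    Parameters
    ----------
    ratings
        n_targets x k_raters table with no missing cells (here: lesion
        volume or mean lesion MWF per subject, one column per rater).

    Notes
    -----
    From the two-way ANOVA mean squares (MS_R between targets, MS_C between
    raters, MS_E residual)::

        ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

    and the reliability F statistic is ``MS_R / MS_E`` with degrees of
    freedom (n-1, (n-1)(k-1)).  Absolute agreement penalises a constant
    offset between raters, unlike a consistency ICC.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2D n_targets x k_raters table")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 targets and 2 raters")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings table has missing cells")
    if np.ptp(x) == 0:
        raise ValueError("ratings are constant; ICC is undefined")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)

    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols

    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))

    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom == 0:
        raise ValueError("degenerate variance decomposition; ICC is undefined")
    icc = (ms_r - ms_e) / denom
    f_stat = np.inf if ms_e == 0 else ms_r / ms_e
    return ICCResult(
        icc=float(icc),
        f_statistic=float(f_stat),
        df1=n - 1,
        df2=(n - 1) * (k - 1),
    )
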