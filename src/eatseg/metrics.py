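"""Segmentation evaluation metrics and statistical comparison machinery.

Four metrics compare a manual mask S_M with an automatic mask S_A:

* DSC  = 2|S_M ∩ S_A| / (|S_M| + |S_A|)            (overlap accuracy)
* MSD  = symmetric mean contour-to-contour distance in mm (propinquity)
* RSE  = 100·| |S_M| − |S_A| | / |S_M|              (% area error)
* PPV  = |S_M ∩ S_A| / |S_A|                        (over-segmentation)

Contours are boundary pixels: mask pixels with at least one 8-connected
neighbor (or the image border) in the complement; distances are Euclidean
center-to-center in millimetres, honoring anisotropic spacing.

Empty-mask conventions: both masks empty → DSC 1 and RSE 0 (perfect
agreement on absence); one empty → DSC 0; MSD and PPV (and RSE when the
manual mask is empty) are *flagged missing* as NaN — never coerced to 0 or
infinity — so degenerate frames cannot silently skew cohort means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .dataio import EAT, HV, PAT, LabelStack

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class BinaryMask:
    """A single-label 2D mask with physical pixel spacing (row_mm, col_mm)."""

    mask: np.ndarray
    pixel_spacing: tuple[float, float]
    label: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")
        sr, sc = self.pixel_spacing
        if not (sr > 0 and sc > 0):
            raise ValueError("pixel spacing must be positive")
        self.pixel_spacing = (float(sr), float(sc))

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def area_mm2(self) -> float:
        return self.n_pixels * self.pixel_spacing[0] * self.pixel_spacing[1]


def _check_pair(manual: BinaryMask, auto: BinaryMask) -> None:
    if manual.mask.shape != auto.mask.shape:
        raise ValueError(
            f"grid mismatch: manual {manual.mask.shape} vs auto "
            f"{auto.mask.shape}"
        )


def dsc(manual: BinaryMask, auto: BinaryMask) -> float:
    """Dice similarity coefficient; 1.0 when both masks are empty."""
    _check_pair(manual, auto)
    n_m, n_a = manual.n_pixels, auto.n_pixels
    if n_m + n_a == 0:
        return 1.0
    inter = int(np.count_nonzero(manual.mask & auto.mask))
    return 2.0 * inter / (n_m + n_a)


def contour_pixels(mask: np.ndarray) -> np.ndarray:
    """(k, 2) row/col indices of boundary pixels (8-connectivity; the image
    border counts as complement)."""
    mask = np.asarray(mask, dtype=bool)
    interior = ndimage.binary_erosion(mask, structure=_EIGHT, border_value=0)
    return np.argwhere(mask & ~interior)


def msd(manual: BinaryMask, auto: BinaryMask) -> float:
    """Symmetric mean surface distance in mm; NaN if either mask is empty."""
    _check_pair(manual, auto)
    if manual.n_pixels == 0 or auto.n_pixels == 0:
        return math.nan
    spacing = np.asarray(manual.pixel_spacing)
    c_m = contour_pixels(manual.mask) * spacing
    c_a = contour_pixels(auto.mask) * spacing
    d_m = cKDTree(c_a).query(c_m)[0]
    d_a = cKDTree(c_m).query(c_a)[0]
    return float((d_m.sum() + d_a.sum()) / (len(c_m) + len(c_a)))


def rse(manual: BinaryMask, auto: BinaryMask) -> float:
    """Absolute relative surface error in percent; NaN if manual is empty."""
    _check_pair(manual, auto)
    a_m = manual.area_mm2
    if a_m == 0:
        return 0.0 if auto.n_pixels == 0 else math.nan
    return 100.0 * abs(a_m - auto.area_mm2) / a_m


def ppv(manual: BinaryMask, auto: BinaryMask) -> float:
    """Positive predictive value; NaN if the automatic mask is empty."""
    _check_pair(manual, auto)
    n_a = auto.n_pixels
    if n_a == 0:
        return math.nan
    inter = int(np.count_nonzero(manual.mask & auto.mask))
    return inter / n_a


# ---------------------------------------------------------------------------
# per-subject evaluation
# ---------------------------------------------------------------------------

#: evaluated labels: EAT, PAT, merged pericardial fat, heart ventricles
EVAL_LABELS: dict[str, tuple[int, ...]] = {
    "EAT": (EAT,),
    "PAT": (PAT,),
    "EAT+PAT": (EAT, PAT),
    "HV": (HV,),
}


@dataclass
class MetricRow:
    subject_id: str
    frame_role: str        # systole / diastole / other
    frame_index: int
    label: str
    dsc: float
    msd_mm: float
    rse_percent: float
    ppv: float
    manual_area_cm2: float
    auto_area_cm2: float
    comparator: str = ""   # intra / inter / unet / fcnb


def evaluate_subject(
    manual: LabelStack,
    auto: LabelStack,
    pixel_spacing: tuple[float, float],
    frames: dict[str, int],
    subject_id: str = "",
    comparator: str = "",
) -> list[MetricRow]:
    """All four metrics for EAT, PAT, EAT+PAT and HV at designated frames.

    ``frames`` maps frame roles (``{"systole": i, "diastole": j}``) to frame
    indices; both roles are required.
    """
    for role in ("systole", "diastole"):
        if role not in frames:
            raise ValueError(f"missing frame designation for {role!r}")
    if manual.masks.shape != auto.masks.shape:
        raise ValueError("manual and automatic label stacks differ in shape")
    rows = []
    for role, t in frames.items():
        for name, codes in EVAL_LABELS.items():
            m = BinaryMask(manual.mask_of(t, codes), pixel_spacing, name)
            a = BinaryMask(auto.mask_of(t, codes), pixel_spacing, name)
            rows.append(
                MetricRow(
                    subject_id=subject_id,
                    frame_role=role,
                    frame_index=int(t),
                    label=name,
                    dsc=dsc(m, a),
                    msd_mm=msd(m, a),
                    rse_percent=rse(m, a),
                    ppv=ppv(m, a),
                    manual_area_cm2=m.area_mm2 / 100.0,
                    auto_area_cm2=a.area_mm2 / 100.0,
                    comparator=comparator,
                )
            )
    return rows


def rows_to_frame(rows: Sequence[MetricRow]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in rows])


# ---------------------------------------------------------------------------
# statistical comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """Shapiro–Wilk normality per side plus a Wilcoxon location test.

    No multiple-testing correction is applied; p-values are raw.
    """

    test_name: str
    statistic: float
    p_value: float
    shapiro_p_a: float
    shapiro_p_b: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int
    paired: bool
    note: str = ""


def _shapiro_p(values: np.ndarray) -> float:
    if np.ptp(values) == 0:
        return math.nan  # degenerate: constant sample
    return float(stats.shapiro(values).pvalue)


def compare_distributions(
    values_a: Sequence[float],
    values_b: Sequence[float],
    paired: bool = False,
    subjects_a: Sequence[str] | None = None,
    subjects_b: Sequence[str] | None = None,
) -> ComparisonReport:
    """Compare two metric distributions.

    Normality is assessed per side with Shapiro–Wilk; the location test is a
    two-sided Wilcoxon signed-rank test when ``paired`` (requiring matched
    subjects when subject ids are supplied) and a Wilcoxon rank-sum test
    otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 observations per side")
    if paired:
        if subjects_a is not None or subjects_b is not None:
            if subjects_a is None or subjects_b is None:
                raise ValueError("paired comparison needs both subject lists")
            if list(subjects_a) != list(subjects_b):
                if sorted(subjects_a) != sorted(subjects_b):
                    raise ValueError(
                        "paired comparison requires matched subject sets"
                    )
                order = {s: i for i, s in enumerate(subjects_b)}
                b = b[[order[s] for s in subjects_a]]
        if len(a) != len(b):
            raise ValueError("paired samples must have equal length")
        diffs = a - b
        if np.all(diffs == 0):
            return ComparisonReport(
                test_name="wilcoxon_signed_rank",
                statistic=math.nan,
                p_value=1.0,
                shapiro_p_a=_shapiro_p(a),
                shapiro_p_b=_shapiro_p(b),
                median_a=float(np.median(a)),
                median_b=float(np.median(b)),
                n_a=len(a),
                n_b=len(b),
                paired=True,
                note="all paired differences are zero; reported as "
                     "no difference",
            )
        res = stats.wilcoxon(a, b, alternative="two-sided")
        name = "wilcoxon_signed_rank"
    else:
        res = stats.ranksums(a, b, alternative="two-sided")
        name = "wilcoxon_rank_sum"
    return ComparisonReport(
        test_name=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        shapiro_p_a=_shapiro_p(a),
        shapiro_p_b=_shapiro_p(b),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        n_a=len(a),
        n_b=len(b),
        paired=paired,
    )
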