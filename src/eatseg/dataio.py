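"""I/O and data preparation for 4-chamber cine series.

Cine series and per-frame label stacks are stored as NIfTI volumes shaped
(H, W, 1, T).  Label codes: 0 background, 1 EAT (epicardial adipose tissue),
2 PAT (paracardial adipose tissue), 3 HV (heart ventricles = ventricular
muscle + blood pools).

This module covers reading/writing subjects, per-series [0, 1] intensity
normalisation, fitting images to the fixed network grid (centered pad/crop
with an invertible placement record), building 3-frame training windows with
cyclic temporal indexing, stratified fold splitting, and bias-field
correction (external N4 via SimpleITK, or a self-contained polynomial
surrogate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

BACKGROUND, EAT, PAT, HV = 0, 1, 2, 3
LABEL_NAMES = {BACKGROUND: "background", EAT: "EAT", PAT: "PAT", HV: "HV"}
VALID_CODES = frozenset(LABEL_NAMES)

#: fixed spatial grid the networks are trained on (rows, cols)
DEFAULT_GRID = (256, 192)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CineSeries:
    """One subject's 2D+t cine stack.

    frames : (T, H, W) float array, one image per cardiac phase.
    pixel_spacing : (row_mm, col_mm) in-plane spacing.
    """

    frames: np.ndarray
    pixel_spacing: tuple[float, float]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (T, H, W)")
        if self.frames.shape[0] < 3:
            raise ValueError("a cine series needs at least 3 frames")
        sr, sc = self.pixel_spacing
        if not (sr > 0 and sc > 0):
            raise ValueError("pixel spacing must be positive")
        self.pixel_spacing = (float(sr), float(sc))

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class LabelStack:
    """Per-frame integer masks aligned with a :class:`CineSeries`."""

    masks: np.ndarray

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks)
        if self.masks.ndim != 3:
            raise ValueError("masks must be (T, H, W)")
        if not np.issubdtype(self.masks.dtype, np.integer):
            self.masks = self.masks.astype(np.int16)
        validate_label_codes(self.masks)

    @property
    def n_frames(self) -> int:
        return self.masks.shape[0]

    def mask_of(self, frame: int, code: int | Sequence[int]) -> np.ndarray:
        codes = (code,) if np.isscalar(code) else tuple(code)
        return np.isin(self.masks[frame], codes)


def validate_label_codes(masks: np.ndarray) -> None:
    """Raise naming the offending code and frame on any unknown label."""
    for t in range(masks.shape[0]):
        bad = np.setdiff1d(np.unique(masks[t]), sorted(VALID_CODES))
        if bad.size:
            raise ValueError(
                f"unknown label code {int(bad[0])} in frame {t}; "
                f"valid codes are {sorted(VALID_CODES)}"
            )


@dataclass
class MultiFrameSample:
    """A 3-frame window (t-1, t, t+1) with the central frame's labels."""

    window: np.ndarray  # (3, H, W)
    target: np.ndarray  # (H, W) int
    subject_id: str
    frame_index: int

    def __post_init__(self) -> None:
        if self.window.shape[0] != 3:
            raise ValueError("window must hold exactly 3 frames")
        if self.window.shape[1:] != self.target.shape:
            raise ValueError("window and target grids differ")


@dataclass
class FoldSplit:
    """Five stratified subject subsets; one is the test set, the other four
    rotate as validation in a 4-fold cross-validation."""

    subsets: list[list[str]]
    test_subset: int = 0
    train_val_assignments: list[tuple[list[str], list[str]]] = field(
        default_factory=list
    )

    @property
    def test_subjects(self) -> list[str]:
        return self.subsets[self.test_subset]


@dataclass(frozen=True)
class Placement:
    """Record of a pad/crop so metrics can be mapped back to native space."""

    original_shape: tuple[int, int]
    target_shape: tuple[int, int]
    pad_before: tuple[int, int]   # zeros added before (rows, cols); 0 if cropped
    crop_before: tuple[int, int]  # rows/cols removed before; 0 if padded


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _to_nifti_array(stack: np.ndarray) -> np.ndarray:
    # (T, H, W) -> (H, W, 1, T)
    return np.transpose(stack, (1, 2, 0))[:, :, None, :]


def _from_nifti_array(data: np.ndarray) -> np.ndarray:
    if data.ndim == 4 and data.shape[2] == 1:
        data = data[:, :, 0, :]
    elif data.ndim != 3:
        raise ValueError(f"expected (H, W, 1, T) or (H, W, T) volume, got {data.shape}")
    return np.transpose(data, (2, 0, 1))


def write_subject(
    out_dir: str | Path,
    subject_id: str,
    series: CineSeries,
    labels: LabelStack,
) -> tuple[Path, Path]:
    """Write ``<id>_cine.nii.gz`` and ``<id>_labels.nii.gz``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sr, sc = series.pixel_spacing
    affine = np.diag([sr, sc, 1.0, 1.0])
    cine_path = out_dir / f"{subject_id}_cine.nii.gz"
    lab_path = out_dir / f"{subject_id}_labels.nii.gz"
    img = nib.Nifti1Image(
        _to_nifti_array(series.frames).astype(np.float32), affine
    )
    img.header.set_zooms((sr, sc, 1.0, 1.0))
    nib.save(img, cine_path)
    lab = nib.Nifti1Image(
        _to_nifti_array(labels.masks).astype(np.uint8), affine
    )
    lab.header.set_zooms((sr, sc, 1.0, 1.0))
    nib.save(lab, lab_path)
    return cine_path, lab_path


def read_subject(
    cine_path: str | Path,
    labels_path: str | Path | None = None,
    manifest_row: pd.Series | dict | None = None,
) -> tuple[CineSeries, LabelStack | None]:
    """Load a subject's cine (and optionally labels) from NIfTI.

    Pixel spacing comes from the NIfTI header; the manifest row (if given)
    supplies the subject id and may override the spacing.
    """
    cine_path = Path(cine_path)
    img = nib.load(cine_path)
    frames = _from_nifti_array(np.asarray(img.dataobj, dtype=np.float64))
    zooms = img.header.get_zooms()
    spacing = (float(zooms[0]), float(zooms[1]))
    subject_id = cine_path.name.replace("_cine.nii.gz", "").replace(".nii.gz", "")
    if manifest_row is not None:
        row = dict(manifest_row)
        subject_id = str(row.get("subject_id", subject_id))
        if "pixel_spacing_mm" in row and row["pixel_spacing_mm"]:
            s = float(row["pixel_spacing_mm"])
            spacing = (s, s)
    series = CineSeries(frames, spacing, subject_id)

    labels = None
    if labels_path is not None:
        lab_img = nib.load(Path(labels_path))
        data = np.asarray(lab_img.dataobj)
        if not np.allclose(data, np.round(data)):
            raise ValueError("label volume holds non-integer values")
        masks = _from_nifti_array(np.round(data).astype(np.int16))
        if masks.shape != frames.shape:
            raise ValueError(
                f"label grid {masks.shape} does not match cine grid {frames.shape}"
            )
        labels = LabelStack(masks)
    return series, labels


# ---------------------------------------------------------------------------
# normalisation, grid fitting, windows
# ---------------------------------------------------------------------------

def normalize_intensity(series: CineSeries) -> CineSeries:
    """Map the whole series affinely to [0, 1].

    One affine map per series (not per frame) so relative intensity changes
    across the cardiac cycle stay meaningful for the multi-frame input.
    """
    lo = float(series.frames.min())
    hi = float(series.frames.max())
    if hi == lo:
        raise ValueError("cannot normalize a constant series")
    frames = (series.frames - lo) / (hi - lo)
    return CineSeries(frames, series.pixel_spacing, series.subject_id)


def fit_to_grid(
    array: np.ndarray, target_shape: tuple[int, int] = DEFAULT_GRID
) -> tuple[np.ndarray, Placement]:
    """Center-pad (zeros) or center-crop a 2D array to ``target_shape``.

    Each axis is handled independently; the returned :class:`Placement`
    allows exact inversion wherever content was not cropped away.
    """
    array = np.asarray(array)
    if array.ndim != 2:
        raise ValueError("fit_to_grid expects a 2D array")
    pad_before = [0, 0]
    crop_before = [0, 0]
    out = array
    for axis in (0, 1):
        n = out.shape[axis]
        m = target_shape[axis]
        if n < m:
            before = (m - n) // 2
            pad_before[axis] = before
            pad = [(0, 0), (0, 0)]
            pad[axis] = (before, m - n - before)
            out = np.pad(out, pad, mode="constant")
        elif n > m:
            before = (n - m) // 2
            crop_before[axis] = before
            sl = [slice(None), slice(None)]
            sl[axis] = slice(before, before + m)
            out = out[tuple(sl)]
    placement = Placement(
        original_shape=array.shape,
        target_shape=tuple(target_shape),
        pad_before=tuple(pad_before),
        crop_before=tuple(crop_before),
    )
    return out, placement


def invert_fit(fitted: np.ndarray, placement: Placement) -> np.ndarray:
    """Map a grid-fitted array back to native space (zeros where cropped)."""
    if fitted.shape != placement.target_shape:
        raise ValueError("array does not match the placement's target shape")
    out = np.zeros(placement.original_shape, dtype=fitted.dtype)
    src = [slice(None)] * 2
    dst = [slice(None)] * 2
    for axis in (0, 1):
        n = placement.original_shape[axis]
        m = placement.target_shape[axis]
        if n < m:
            src[axis] = slice(placement.pad_before[axis],
                              placement.pad_before[axis] + n)
            dst[axis] = slice(0, n)
        elif n > m:
            src[axis] = slice(0, m)
            dst[axis] = slice(placement.crop_before[axis],
                              placement.crop_before[axis] + m)
    out[tuple(dst)] = fitted[tuple(src)]
    return out


def extract_windows(
    series: CineSeries, labels: LabelStack
) -> list[MultiFrameSample]:
    """One 3-frame sample per frame, with cyclic temporal indexing.

    Retrospectively gated cine is periodic, so frame 0's window is
    (T-1, 0, 1) and frame T-1's is (T-2, T-1, 0); every frame appears as the
    central (target) frame exactly once.
    """
    if labels.n_frames != series.n_frames:
        raise ValueError("series and labels disagree on frame count")
    T = series.n_frames
    if T < 3:
        raise ValueError("need at least 3 frames to build windows")
    samples = []
    for t in range(T):
        idx = [(t - 1) % T, t, (t + 1) % T]
        samples.append(
            MultiFrameSample(
                window=series.frames[idx].copy(),
                target=labels.masks[t].copy(),
                subject_id=series.subject_id,
                frame_index=t,
            )
        )
    return samples


# ---------------------------------------------------------------------------
# fold splitting
# ---------------------------------------------------------------------------

def split_folds(
    manifest: pd.DataFrame,
    seed: int,
    n_subsets: int = 5,
    test_subset: int = 0,
) -> FoldSplit:
    """Stratified split into ``n_subsets`` disjoint subject subsets.

    Subjects of each group are shuffled (seeded) and dealt so every subset's
    group counts are within one of exact proportionality (largest-remainder
    with subset-size balancing).  One subset is held out as test; the other
    four rotate as (train=3 subsets, validation=1) pairs.
    """
    if not {"subject_id", "group"}.issubset(manifest.columns):
        raise ValueError("manifest needs 'subject_id' and 'group' columns")
    rng = np.random.default_rng(seed)
    subsets: list[list[str]] = [[] for _ in range(n_subsets)]
    totals = np.zeros(n_subsets, dtype=int)
    # deterministic group order: sorted
    for group in sorted(manifest["group"].unique()):
        ids = sorted(manifest.loc[manifest["group"] == group, "subject_id"])
        if len(ids) < n_subsets:
            warnings.warn(
                f"group '{group}' has only {len(ids)} subjects; it cannot "
                f"appear in every one of the {n_subsets} subsets",
                stacklevel=2,
            )
        ids = [ids[i] for i in rng.permutation(len(ids))]
        base, extra = divmod(len(ids), n_subsets)
        counts = np.full(n_subsets, base)
        # give remainders to the currently smallest subsets (stable order)
        order = np.argsort(totals, kind="stable")
        counts[order[:extra]] += 1
        pos = 0
        for s in range(n_subsets):
            subsets[s].extend(ids[pos:pos + counts[s]])
            pos += counts[s]
        totals += counts
    rotations = [s for s in range(n_subsets) if s != test_subset]
    assignments = []
    for val in rotations:
        train = [sid for s in rotations if s != val for sid in subsets[s]]
        assignments.append((train, list(subsets[val])))
    return FoldSplit(subsets=subsets, test_subset=test_subset,
                     train_val_assignments=assignments)


# ---------------------------------------------------------------------------
# bias-field correction
# ---------------------------------------------------------------------------

def _poly2_design(shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    y, x = np.meshgrid(
        np.linspace(-1.0, 1.0, h), np.linspace(-1.0, 1.0, w), indexing="ij"
    )
    return np.stack(
        [np.ones_like(x), x, y, x * y, x**2, y**2], axis=-1
    ).reshape(-1, 6)


def fit_polynomial_surface(image: np.ndarray) -> np.ndarray:
    """Least-squares 2nd-order polynomial surface fitted to ``image``."""
    design = _poly2_design(image.shape)
    coef, *_ = np.linalg.lstsq(design, image.ravel(), rcond=None)
    return (design @ coef).reshape(image.shape)


def bias_correct(series: CineSeries, method: str = "polynomial_surrogate") -> CineSeries:
    """Remove smooth multiplicative intensity inhomogeneity.

    ``polynomial_surrogate`` divides every frame by a least-squares
    2nd-order polynomial surface fitted to the temporal-mean image
    (normalised to unit mean) — the canonical low-frequency bias model.
    ``external_n4`` delegates to SimpleITK's N4 on the temporal mean and
    applies the recovered field to all frames.  ``none`` passes through.
    """
    if method == "none":
        return CineSeries(series.frames.copy(), series.pixel_spacing,
                          series.subject_id)
    mean_img = series.frames.mean(axis=0)
    if method == "polynomial_surrogate":
        surface = fit_polynomial_surface(mean_img)
        surface = surface / surface.mean()
        surface = np.clip(surface, 0.05, None)
        frames = series.frames / surface[None]
        return CineSeries(frames, series.pixel_spacing, series.subject_id)
    if method == "external_n4":
        try:
            import SimpleITK as sitk
        except ImportError as exc:  # pragma: no cover - environment dependent
            raise RuntimeError(
                "external_n4 requires SimpleITK; use method="
                "'polynomial_surrogate' instead"
            ) from exc
        img = sitk.GetImageFromArray(mean_img.astype(np.float64))
        mask = sitk.GetImageFromArray(
            np.ones_like(mean_img, dtype=np.uint8)
        )
        corrected = sitk.N4BiasFieldCorrection(img, mask)
        corr = np.clip(sitk.GetArrayFromImage(corrected), 1e-9, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            field = np.where(corr > 0, mean_img / corr, 1.0)
        field = np.clip(field / field.mean(), 0.05, None)
        frames = series.frames / field[None]
        return CineSeries(frames, series.pixel_spacing, series.subject_id)
    raise ValueError(
        f"unknown method {method!r}; expected 'external_n4', "
        "'polynomial_surrogate' or 'none'"
    )
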