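"""On-the-fly geometric augmentation of 3-frame training samples.

Rotation angles and isotropic scale factors are drawn from clipped normal
distributions spanning -30°..30° and 0.4..1.6 respectively.  Each transform
is applied about the grid center, identically to the three window frames
(bilinear interpolation) and to the target label map (nearest neighbor, so
label codes are preserved).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .dataio import MultiFrameSample


@dataclass
class AugmentConfig:
    """Clipped-normal rotation/scaling augmentation.

    Only the clip range is physically prescribed; the normal widths are set
    so the clips truncate a small (~4.6%) fraction of draws, spanning the
    range without being uniform.  Rotation and scaling are each applied
    independently with ``probability_apply``.
    """

    rotation_mean: float = 0.0
    rotation_sd: float = 15.0          # degrees
    rotation_clip: float = 30.0        # |angle| <= clip
    scale_mean: float = 1.0
    scale_sd: float = 0.3
    scale_clip: tuple[float, float] = (0.4, 1.6)
    probability_apply: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rotation_sd < 0 or self.scale_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0.0 <= self.probability_apply <= 1.0:
            raise ValueError("probability_apply must be in [0, 1]")
        lo, hi = self.scale_clip
        if not lo <= self.scale_mean <= hi:
            raise ValueError("scale_mean must lie inside scale_clip")


def sample_transform(
    config: AugmentConfig, rng: np.random.Generator
) -> tuple[float, float]:
    """Draw one (angle_degrees, scale) pair.

    Each component is applied with probability ``probability_apply``
    (identity otherwise); applied components are normal draws clipped to the
    configured range.
    """
    angle = 0.0
    scale = 1.0
    if rng.random() < config.probability_apply:
        angle = float(
            np.clip(
                rng.normal(config.rotation_mean, config.rotation_sd)
                if config.rotation_sd > 0
                else config.rotation_mean,
                -config.rotation_clip,
                config.rotation_clip,
            )
        )
    if rng.random() < config.probability_apply:
        scale = float(
            np.clip(
                rng.normal(config.scale_mean, config.scale_sd)
                if config.scale_sd > 0
                else config.scale_mean,
                config.scale_clip[0],
                config.scale_clip[1],
            )
        )
    return angle, scale


def _affine_matrix(angle_deg: float, scale: float) -> np.ndarray:
    """Output-to-input coordinate map for rotation+scaling about the center."""
    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    # snap the ~1e-16 residue of quarter turns to zero: scipy's constant
    # mode would otherwise treat on-lattice points as (barely) out of field
    if abs(c) < 1e-12:
        c = 0.0
    if abs(s) < 1e-12:
        s = 0.0
    rot = np.array([[c, -s], [s, c]])
    return rot.T / scale  # inverse of scale * rot


def _transform_2d(
    array: np.ndarray, matrix: np.ndarray, order: int
) -> np.ndarray:
    center = (np.asarray(array.shape) - 1) / 2.0
    offset = center - matrix @ center
    return ndimage.affine_transform(
        array, matrix, offset=offset, order=order,
        mode="constant", cval=0.0, prefilter=(order > 1),
    )


def apply_transform(
    sample: MultiFrameSample, angle: float, scale: float
) -> MultiFrameSample:
    """Rotate by ``angle`` degrees and scale by ``scale`` about the grid
    center; window frames bilinear, target nearest-neighbor; out-of-field
    pixels are zero (= background)."""
    if angle == 0.0 and scale == 1.0:
        return MultiFrameSample(
            window=sample.window.copy(),
            target=sample.target.copy(),
            subject_id=sample.subject_id,
            frame_index=sample.frame_index,
        )
    matrix = _affine_matrix(angle, scale)
    window = np.stack(
        [_transform_2d(f, matrix, order=1) for f in sample.window]
    )
    target = _transform_2d(sample.target, matrix, order=0)
    return MultiFrameSample(
        window=window,
        target=target.astype(sample.target.dtype),
        subject_id=sample.subject_id,
        frame_index=sample.frame_index,
    )


def augment_sample(
    sample: MultiFrameSample, config: AugmentConfig, rng: np.random.Generator
) -> MultiFrameSample:
    """Draw a transform and apply it (single entry point for training)."""
    angle, scale = sample_transform(config, rng)
    return apply_transform(sample, angle, scale)
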