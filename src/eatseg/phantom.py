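"""Synthetic 4-chamber cine phantom with ground-truth EAT/PAT/HV labels.

The phantom reduces the 4-chamber view to the features an EAT segmentation
network must exploit, at desk scale:

* a bright blood pool inside a dark myocardial ring (labelled together as
  HV, mirroring how ventricles are annotated as one class),
* a thin, bright epicardial fat (EAT) layer attached to the outer
  myocardial boundary, with a per-angle thickness profile that may vanish
  on arcs (sparse fat isles),
* a thin dark pericardial fascia gap (~2 mm, the same order as the pixel
  size) separating EAT from bright paracardial fat (PAT) blobs,
* cardiac contraction: the ventricular radius follows a cosine cycle
  (diastole at frame 0); EAT rides rigidly on the myocardial boundary while
  each PAT blob follows only a fraction (``motion_coupling``) of the local
  myocardial displacement,
* partial-volume mixing at tissue boundaries (area-weighted sub-pixel
  intensities), a smooth multiplicative second-order polynomial bias field,
  and Gaussian noise.  Labels are rendered noise-free at pixel centers.

``sample_cohort`` draws a cohort of healthy / obese / type-2 diabetic
subjects whose latent total EAT volume (cm^3, never rendered — the phantom
is a single slice) drives the EAT thickness profile, so the 4-chamber EAT
area correlates with volume by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import BACKGROUND, EAT, HV, PAT, CineSeries, LabelStack, write_subject

GROUPS = ("healthy", "obese", "diabetic")

#: lognormal medians (cm^3) and log-sd of latent total EAT volume per group,
#: chosen so a 100-subject cohort spans roughly 30-380 cm^3
GROUP_VOLUME_MEDIANS = {"healthy": 70.0, "obese": 90.0, "diabetic": 110.0}
GROUP_VOLUME_SIGMAS = {"healthy": 0.30, "obese": 0.35, "diabetic": 0.45}

#: 4Ch EAT area (cm^2) produced by a subject of 100 cm^3 latent volume
AREA_PER_100CM3 = 2.2

DEFAULT_INTENSITIES = {
    "background": 0.05,
    "myocardium": 0.30,
    "blood": 0.85,
    "fat": 1.00,
    "fascia": 0.20,
}

_N_PROFILE = 720  # angular samples of the EAT thickness profile


def default_thickness_profile(
    peak_mm: float = 5.3, main_angle: float = math.pi / 4
) -> np.ndarray:
    """Asymmetric EAT thickness profile: one broad patch plus a small isle.

    Thickness is zero on roughly a third of the circumference, producing the
    sparse fat isles that make thin-EAT subjects hard to segment.  The
    asymmetry also gives the EAT mass a net centroid, so cardiac contraction
    visibly displaces it (more than the loosely coupled PAT blobs).
    """
    theta = np.linspace(0.0, 2.0 * math.pi, _N_PROFILE, endpoint=False)
    main = np.maximum(0.0, np.cos(theta - main_angle)) ** 1.5
    isle_angle = main_angle + 2.0
    d = np.angle(np.exp(1j * (theta - isle_angle)))
    isle = 0.35 * np.maximum(0.0, np.cos(4.0 * d))
    return peak_mm * np.maximum(main, isle)


@dataclass
class PhantomParams:
    """Full geometric + signal description of one synthetic cine series."""

    grid_height: int = 64
    grid_width: int = 64
    pixel_spacing: float = 1.5           # mm/pixel, isotropic in-plane
    n_frames: int = 25
    heart_center: tuple[float, float] | None = None   # (row, col) pixels
    ventricle_radius_diastole: float = 14.5           # mm
    myocardium_thickness: float = 4.0                 # mm
    contraction_fraction: float = 0.25
    eat_thickness_profile: np.ndarray = field(
        default_factory=default_thickness_profile
    )
    pericardial_gap: float = 2.0                      # mm (fascia thickness)
    pat_blobs: list[tuple[tuple[float, float], float, float]] = field(
        default_factory=list
    )  # ((row_px, col_px), radius_mm, motion_coupling)
    intensity_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITIES)
    )
    noise_sigma: float = 0.03
    bias_field_amplitude: float = 0.10
    seed: int = 0
    supersample: int = 3   # odd sub-pixel factor for partial-volume rendering

    def __post_init__(self) -> None:
        self.eat_thickness_profile = np.asarray(
            self.eat_thickness_profile, dtype=float
        )
        if self.heart_center is None:
            self.heart_center = (
                (self.grid_height - 1) / 2.0,
                (self.grid_width - 1) / 2.0,
            )
        if np.any(self.eat_thickness_profile < 0):
            raise ValueError("eat_thickness_profile must be >= 0 everywhere")
        if not self.pericardial_gap > 0:
            raise ValueError("pericardial_gap must be > 0")
        if not 0 <= self.contraction_fraction < 1:
            raise ValueError("contraction_fraction must be in [0, 1)")
        if self.n_frames < 3:
            raise ValueError("n_frames must be >= 3")
        if not self.pixel_spacing > 0:
            raise ValueError("pixel_spacing must be > 0")
        if self.supersample % 2 != 1 or self.supersample < 1:
            raise ValueError("supersample must be a positive odd integer")
        im = self.intensity_means
        if not im["fat"] > im["myocardium"]:
            raise ValueError("fat intensity mean must exceed myocardium mean")


@dataclass
class PhantomSubject:
    subject_id: str
    group: str
    params: PhantomParams
    true_eat_volume: float          # cm^3, latent
    series: CineSeries
    labels: LabelStack
    systole_frame: int
    diastole_frame: int
    eat_area_cm2: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _thickness_at(profile: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Periodic linear interpolation of the per-angle thickness profile."""
    n = profile.size
    pos = (theta % (2.0 * math.pi)) / (2.0 * math.pi) * n
    i0 = np.floor(pos).astype(int) % n
    i1 = (i0 + 1) % n
    w = pos - np.floor(pos)
    return profile[i0] * (1.0 - w) + profile[i1] * w


def _contraction(params: PhantomParams, t: int) -> float:
    phase = 2.0 * math.pi * t / params.n_frames
    return params.contraction_fraction * (1.0 - math.cos(phase)) / 2.0


def _radii(params: PhantomParams, t: int) -> tuple[float, float]:
    """(ventricular blood radius, outer myocardial radius) in mm at frame t."""
    r_v = params.ventricle_radius_diastole * (1.0 - _contraction(params, t))
    return r_v, r_v + params.myocardium_thickness


def _boundary_distance_mm(params: PhantomParams, direction: np.ndarray) -> float:
    """Distance (mm) from the heart center to the grid border along a ray."""
    cr, cc = params.heart_center
    sp = params.pixel_spacing
    limits = []
    for comp, lo, hi in ((direction[0], -cr, params.grid_height - 1 - cr),
                         (direction[1], -cc, params.grid_width - 1 - cc)):
        if abs(comp) > 1e-12:
            bound = hi if comp > 0 else lo
            limits.append(bound * sp / comp)
    return min(limits) if limits else math.inf


def _validate_geometry(params: PhantomParams) -> None:
    sp = params.pixel_spacing
    cr, cc = params.heart_center
    avail = min(cr, params.grid_height - 1 - cr,
                cc, params.grid_width - 1 - cc) * sp
    r_m0 = params.ventricle_radius_diastole + params.myocardium_thickness
    if r_m0 > avail:
        raise ValueError(
            "ventricle_radius_diastole (+ myocardium_thickness) pushes the "
            f"heart outside the grid: needs {r_m0:.1f} mm, only {avail:.1f} "
            "mm available"
        )
    if r_m0 + float(params.eat_thickness_profile.max(initial=0.0)) > avail:
        raise ValueError(
            "eat_thickness_profile pushes the epicardial fat outside the grid"
        )
    if r_m0 + float(params.eat_thickness_profile.max(initial=0.0)) \
            + params.pericardial_gap > avail:
        raise ValueError(
            "pericardial_gap pushes the pericardium outside the grid"
        )
    for (brow, bcol), radius, _ in params.pat_blobs:
        offset = np.array([(brow - cr) * sp, (bcol - cc) * sp])
        dist = float(np.hypot(*offset))
        if dist < 1e-9:
            raise ValueError("pat_blobs: blob centered on the heart center")
        ray = offset / dist
        if dist + radius > _boundary_distance_mm(params, ray):
            raise ValueError(
                f"pat_blobs: blob at ({brow:.1f}, {bcol:.1f}) px with radius "
                f"{radius:.1f} mm lies outside the grid"
            )


def _bias_field(params: PhantomParams, shape: tuple[int, int]) -> np.ndarray:
    """Smooth multiplicative field 1 + b(x, y), |b| <= amplitude."""
    if params.bias_field_amplitude == 0:
        return np.ones(shape)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(params.seed), 0xB1A5])
    )
    coef = rng.uniform(-1.0, 1.0, size=5)
    h, w = shape
    y, x = np.meshgrid(np.linspace(-1, 1, h), np.linspace(-1, 1, w),
                       indexing="ij")
    b = (coef[0] * x + coef[1] * y + coef[2] * x * y
         + coef[3] * x**2 + coef[4] * y**2)
    peak = np.abs(b).max()
    if peak > 0:
        b *= params.bias_field_amplitude / peak
    return 1.0 + b


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _classify(params: PhantomParams, R: np.ndarray, TH: np.ndarray,
              t: int) -> np.ndarray:
    """Tissue class map on arbitrary (R, theta) sample points at frame t.

    Codes: 0 background, 1 EAT, 2 PAT, 3 HV, 4 fascia (pericardial gap;
    labelled background in the exported masks but rendered at its own
    intensity).
    """
    r_v, r_m = _radii(params, t)
    eat_th = _thickness_at(params.eat_thickness_profile, TH)
    r_eat_outer = r_m + eat_th
    r_gap_outer = r_eat_outer + params.pericardial_gap

    cls = np.zeros(R.shape, dtype=np.int8)
    cls[R < r_gap_outer] = 4
    cls[(R >= r_m) & (R < r_eat_outer)] = EAT
    cls[R < r_m] = HV

    # PAT blobs ride with a fraction of the local myocardial displacement
    r_m0 = params.ventricle_radius_diastole + params.myocardium_thickness
    dr = r_m - r_m0  # negative during contraction
    sp = params.pixel_spacing
    cr, cc = params.heart_center
    outside_gap = R >= r_gap_outer
    for (brow, bcol), radius, coupling in params.pat_blobs:
        offset = np.array([(brow - cr) * sp, (bcol - cc) * sp])
        dist = float(np.hypot(*offset))
        unit = offset / dist
        center_t = offset + coupling * dr * unit  # mm, rel. heart center
        y = R * np.cos(TH)  # note: TH measured from +row axis; see below
        x = R * np.sin(TH)
        d2 = (y - center_t[0]) ** 2 + (x - center_t[1]) ** 2
        cls[(d2 < radius**2) & outside_gap] = PAT
    return cls


_CLASS_TISSUE = {
    BACKGROUND: "background",
    EAT: "fat",
    PAT: "fat",
    HV: None,  # blood vs myocardium resolved separately
    4: "fascia",
}


def render_cine(
    params: PhantomParams,
) -> tuple[CineSeries, LabelStack, int, int]:
    """Render a cine series plus noise-free labels from phantom parameters.

    Returns ``(series, labels, systole_frame, diastole_frame)``.  Images are
    tissue means with sub-pixel partial-volume mixing, multiplied by a
    smooth polynomial bias field and degraded with Gaussian noise; labels
    classify pixel centers.
    """
    _validate_geometry(params)
    H, W = params.grid_height, params.grid_width
    ss = params.supersample
    sp = params.pixel_spacing
    cr, cc = params.heart_center

    sub = (np.arange(H * ss) + 0.5) / ss - 0.5
    rows_mm = (sub - cr) * sp
    sub_w = (np.arange(W * ss) + 0.5) / ss - 0.5
    cols_mm = (sub_w - cc) * sp
    Y, X = np.meshgrid(rows_mm, cols_mm, indexing="ij")
    R = np.hypot(Y, X)
    TH = np.arctan2(X, Y)  # angle from +row axis, consistent with _classify

    im = params.intensity_means
    means = np.empty(5)
    means[BACKGROUND] = im["background"]
    means[EAT] = im["fat"]
    means[PAT] = im["fat"]
    means[HV] = 0.0  # placeholder, handled below
    means[4] = im["fascia"]

    bias = _bias_field(params, (H, W))
    rng = np.random.default_rng(
        np.random.SeedSequence([int(params.seed), 0x4E01])
    )

    frames = np.empty((params.n_frames, H, W))
    masks = np.empty((params.n_frames, H, W), dtype=np.int16)
    radii = np.empty(params.n_frames)
    center = ss // 2
    for t in range(params.n_frames):
        r_v, r_m = _radii(params, t)
        radii[t] = r_v
        cls = _classify(params, R, TH, t)
        intensity = means[cls]
        hv = cls == HV
        intensity[hv] = np.where(R[hv] < r_v, im["blood"], im["myocardium"])
        native = intensity.reshape(H, ss, W, ss).mean(axis=(1, 3))
        native = native * bias
        native += rng.normal(0.0, params.noise_sigma, size=(H, W))
        frames[t] = native
        lab = cls[center::ss, center::ss].astype(np.int16)
        lab[lab == 4] = BACKGROUND
        masks[t] = lab

    systole = int(np.argmin(radii))
    diastole = int(np.argmax(radii))
    series = CineSeries(frames, (sp, sp))
    return series, LabelStack(masks), systole, diastole


def eat_coverage_area_cm2(params: PhantomParams, frame: int,
                          supersample: int | None = None) -> float:
    """EAT area at one frame from sub-pixel coverage (partial-volume aware).

    Measured on a finer sub-grid than the rendering itself (default 9×9
    sub-cells per pixel) so cohort manifests record areas far below the
    whole-pixel quantum — a strictly monotone volume→area link must not be
    flattened into ties by rasterization.
    """
    H, W = params.grid_height, params.grid_width
    ss = supersample if supersample is not None else max(params.supersample, 9)
    sp = params.pixel_spacing
    cr, cc = params.heart_center
    sub = (np.arange(H * ss) + 0.5) / ss - 0.5
    rows_mm = (sub - cr) * sp
    sub_w = (np.arange(W * ss) + 0.5) / ss - 0.5
    cols_mm = (sub_w - cc) * sp
    Y, X = np.meshgrid(rows_mm, cols_mm, indexing="ij")
    cls = _classify(params, np.hypot(Y, X), np.arctan2(X, Y), frame)
    n_sub = float(np.count_nonzero(cls == EAT))
    return n_sub * (sp / ss) ** 2 / 100.0


def analytic_eat_area_cm2(params: PhantomParams, frame: int = 0) -> float:
    """Closed-form EAT area at a frame: integral of t(θ)·(r_m + t(θ)/2) dθ."""
    _, r_m = _radii(params, frame)
    prof = params.eat_thickness_profile
    dtheta = 2.0 * math.pi / prof.size
    return float(np.sum(prof * (r_m + prof / 2.0)) * dtheta / 100.0)


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

def _saturate_area(area_cm2: float, knee: float = 7.0,
                   ceiling: float = 8.0) -> float:
    """Strictly monotone soft cap keeping EAT areas inside safe geometry.

    Identity below the knee; smooth exponential saturation toward the
    ceiling above it.  Strict monotonicity matters: the noiseless
    volume→area link must never create ties.
    """
    if area_cm2 <= knee:
        return float(area_cm2)
    return float(knee + (ceiling - knee)
                 * (1.0 - math.exp(-(area_cm2 - knee) / (ceiling - knee))))


def _largest_remainder_counts(n: int, proportions: np.ndarray) -> np.ndarray:
    quotas = np.asarray(proportions, dtype=float) * n
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def _solve_thickness_scale(target_area_cm2: float, r_m: float,
                           shape: np.ndarray) -> float:
    """Peak thickness s (mm) so that area(s·shape) equals the target.

    area(s) = s·I1·r_m + s²·I2/2 with I1 = ∫shape dθ, I2 = ∫shape² dθ.
    """
    dtheta = 2.0 * math.pi / shape.size
    i1 = float(np.sum(shape) * dtheta)
    i2 = float(np.sum(shape**2) * dtheta)
    a_mm2 = target_area_cm2 * 100.0
    disc = (i1 * r_m) ** 2 + 2.0 * i2 * a_mm2
    return (-i1 * r_m + math.sqrt(disc)) / i2


def sample_cohort(
    n_subjects: int,
    group_proportions: tuple[float, float, float] = (0.21, 0.12, 0.67),
    burden_to_area_noise: float = 0.33,
    seed: int = 0,
    grid_shape: tuple[int, int] = (64, 64),
    spacing_range: tuple[float, float] = (1.3, 1.8),
    n_frames: int = 25,
) -> list[PhantomSubject]:
    """Draw a reproducible cohort of phantom subjects.

    ``group_proportions`` orders (healthy, obese, diabetic) and is resolved
    to integer counts by largest remainder.  Each subject's latent EAT
    volume is lognormal within its group; the EAT thickness profile is
    scaled so the analytic 4-chamber EAT area equals
    ``AREA_PER_100CM3 · (volume/100) · (1 + ε)`` with
    ``ε ~ N(0, burden_to_area_noise)``, making area increase monotonically
    with volume when the noise is zero.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    props = np.asarray(group_proportions, dtype=float)
    if props.min() < 0 or not math.isclose(props.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("group_proportions must be nonnegative and sum to 1")
    counts = _largest_remainder_counts(n_subjects, props)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0]))
    base_shape = default_thickness_profile(peak_mm=1.0)

    subjects: list[PhantomSubject] = []
    idx = 0
    for group, count in zip(GROUPS, counts):
        med = GROUP_VOLUME_MEDIANS[group]
        sig = GROUP_VOLUME_SIGMAS[group]
        for _ in range(count):
            volume = float(med * np.exp(sig * rng.standard_normal()))
            eps = burden_to_area_noise * rng.standard_normal()
            link = max(0.2, 1.0 + eps)
            target_area = _saturate_area(
                AREA_PER_100CM3 * (volume / 100.0) * link
            )
            spacing = float(rng.uniform(*spacing_range))
            sub_seed = int(rng.integers(0, 2**31 - 1))

            r_m0 = 14.5 + 4.0
            s = _solve_thickness_scale(target_area, r_m0, base_shape)
            profile = s * base_shape

            blob_r = float(min(3.0 + 0.3 * s, 7.0))
            blobs = []
            cr = (grid_shape[0] - 1) / 2.0
            cc = (grid_shape[1] - 1) / 2.0
            for angle, coupling in ((3 * math.pi / 4, 0.1),
                                    (7 * math.pi / 4, 0.25)):
                # clearance must respect the thickest EAT anywhere under the
                # blob's angular span, or the pericardial gap clips the blob
                span = np.linspace(angle - 0.4, angle + 0.4, 33)
                th_here = float(_thickness_at(profile, span).max())
                center_r = r_m0 + th_here + 2.0 + blob_r + 1.0
                brow = cr + center_r * math.cos(angle) / spacing
                bcol = cc + center_r * math.sin(angle) / spacing
                blobs.append(((float(brow), float(bcol)), blob_r, coupling))

            params = PhantomParams(
                grid_height=grid_shape[0],
                grid_width=grid_shape[1],
                pixel_spacing=spacing,
                n_frames=n_frames,
                ventricle_radius_diastole=14.5,
                myocardium_thickness=4.0,
                contraction_fraction=0.25,
                eat_thickness_profile=profile,
                pericardial_gap=2.0,
                pat_blobs=blobs,
                noise_sigma=0.03,
                bias_field_amplitude=0.10,
                seed=sub_seed,
            )
            subject_id = f"sub-{idx:03d}"
            series, labels, sys_f, dia_f = render_cine(params)
            series.subject_id = subject_id
            subjects.append(
                PhantomSubject(
                    subject_id=subject_id,
                    group=group,
                    params=params,
                    true_eat_volume=volume,
                    series=series,
                    labels=labels,
                    systole_frame=sys_f,
                    diastole_frame=dia_f,
                    eat_area_cm2={
                        "diastole": eat_coverage_area_cm2(params, dia_f),
                        "systole": eat_coverage_area_cm2(params, sys_f),
                    },
                )
            )
            idx += 1
    return subjects


def cohort_manifest(subjects: list[PhantomSubject]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "group": [s.group for s in subjects],
            "pixel_spacing_mm": [s.params.pixel_spacing for s in subjects],
            "true_eat_volume_cm3": [s.true_eat_volume for s in subjects],
            "systole_frame": [s.systole_frame for s in subjects],
            "diastole_frame": [s.diastole_frame for s in subjects],
            "eat_area_dia_cm2": [s.eat_area_cm2.get("diastole") for s in subjects],
            "eat_area_sys_cm2": [s.eat_area_cm2.get("systole") for s in subjects],
        }
    )


def write_cohort(subjects: list[PhantomSubject], out_dir: str | Path) -> Path:
    """Write `<id>_cine.nii.gz`, `<id>_labels.nii.gz` and manifest.csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for s in subjects:
        write_subject(out_dir, s.subject_id, s.series, s.labels)
    manifest = cohort_manifest(subjects)
    path = out_dir / "manifest.csv"
    manifest.to_csv(path, index=False)
    return path
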