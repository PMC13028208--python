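"""Synthetic L3-level CT phantom cohorts for segmentation-pipeline validation.

Real external-validation scans for L3 muscle segmentation are clinical data
and generally not redistributable.  This module builds a schematic stand-in:
an axial slice at the level of the third lumbar vertebra composed of
ellipse-based tissue compartments — the six trunk muscle groups scored in
body-composition studies (psoas major, quadratus lumborum, erector spinae,
abdominal wall, rectus abdominis, diaphragm), subcutaneous/visceral adipose
tissue, vertebral bone, optional arms alongside the body, and non-muscle
soft-tissue organs.  Each compartment is filled with Hounsfield-unit values
drawn from a configurable tissue band, so that HU-threshold post-processing
behaves as it does on real CT.

On top of the reference segmentation the module simulates a *model* mask with
the error structure typical of a network trained on coarser annotations:
an adipose/fascia fringe hugging the muscle boundary, inclusion of arm
muscles when the arms are positioned alongside the body, sporadic non-muscle
anatomy blobs, and boundary jitter.  Fringe and jitter magnitudes can be
coupled to BMI (lower BMI -> larger errors), reproducing the direction of
the association reported for underweight subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "Region",
    "SubjectRecord",
    "CTSlice",
    "LabeledPhantom",
    "ErrorProfile",
    "CovariateConfig",
    "GeometryConfig",
    "generate_cohort",
    "generate_phantom",
    "simulate_model_mask",
    "TRUNK_MUSCLE_LABELS",
]

CANCER_TYPES = ("melanoma", "lung", "esophageal", "hnc")
BMI_REFERENCE = 26.0  # population mean BMI used as the coupling anchor
HU_MIN, HU_MAX = -1024.0, 3071.0

# Probability that an eligible boundary-layer pixel flips under unit jitter.
# Outward flips (over-inclusion) are twice as likely as inward flips: model
# errors on real scans are predominantly false positives.
JITTER_ADD_P = 0.3
JITTER_REMOVE_P = 0.15


class Region(IntEnum):
    """Integer codes of the phantom label map."""

    BACKGROUND = 0
    PSOAS_MAJOR = 1
    QUADRATUS_LUMBORUM = 2
    ERECTOR_SPINAE = 3
    ABDOMINAL_WALL = 4
    RECTUS_ABDOMINIS = 5
    DIAPHRAGM = 6
    ADIPOSE = 7
    BONE = 8
    ARM_MUSCLE = 9
    OTHER_ORGAN = 10


TRUNK_MUSCLE_LABELS = (
    Region.PSOAS_MAJOR,
    Region.QUADRATUS_LUMBORUM,
    Region.ERECTOR_SPINAE,
    Region.ABDOMINAL_WALL,
    Region.RECTUS_ABDOMINIS,
    Region.DIAPHRAGM,
)


@dataclass(frozen=True)
class SubjectRecord:
    """Covariates of one synthetic subject."""

    subject_id: str
    age: int  # years
    sex: str  # "male" | "female"
    bmi: float  # kg/m^2
    cancer_type: str
    cancer_grade: int  # 1..4
    cci: int  # Charlson Comorbidity Index, 1..4
    arm_position: str  # "up" | "down"
    iv_contrast: bool

    def __post_init__(self) -> None:
        if self.age < 18:
            raise ValueError(f"age must be >= 18, got {self.age}")
        if self.bmi <= 0:
            raise ValueError(f"bmi must be positive, got {self.bmi}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.cancer_type not in CANCER_TYPES:
            raise ValueError(f"unknown cancer_type {self.cancer_type!r}")
        if self.cancer_grade not in (1, 2, 3, 4):
            raise ValueError(f"cancer_grade must be 1..4, got {self.cancer_grade}")
        if self.cci not in (1, 2, 3, 4):
            raise ValueError(f"cci must be 1..4, got {self.cci}")
        if self.arm_position not in ("up", "down"):
            raise ValueError(f"arm_position must be 'up' or 'down'")


@dataclass
class CTSlice:
    """Single axial CT slice: HU grid plus physical pixel spacing.

    Parameters
    ----------
    hu
        2-D array of Hounsfield units.
    pixel_spacing
        (row, col) spacing in millimetres per pixel.
    """

    hu: np.ndarray
    pixel_spacing: tuple[float, float]

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=np.float32)
        if self.hu.ndim != 2:
            raise ValueError("hu must be a 2-D grid")
        r, c = self.pixel_spacing
        if r <= 0 or c <= 0:
            raise ValueError(f"pixel_spacing must be positive, got {self.pixel_spacing}")
        if self.hu.min() < HU_MIN or self.hu.max() > HU_MAX:
            raise ValueError("hu values outside plausible CT range [-1024, 3071]")

    @property
    def pixel_area_cm2(self) -> float:
        """Area of one pixel in cm^2 (mm spacing product / 100)."""
        return self.pixel_spacing[0] * self.pixel_spacing[1] / 100.0


@dataclass
class LabeledPhantom:
    """A CT slice with its reference muscle mask and full region-label map."""

    slice: CTSlice
    reference_mask: np.ndarray  # bool, union of the six trunk muscle groups
    region_labels: np.ndarray  # uint8, Region codes
    subject: SubjectRecord
    config: "GeometryConfig"


@dataclass(frozen=True)
class ErrorProfile:
    """Error structure injected into the simulated model mask.

    fringe_width
        Width (pixels) of the adipose/fascia fringe dilated onto the muscle
        boundary; scaled up at low BMI when ``bmi_coupling`` > 0.
    fringe_hu_band
        (low, high) HU assigned to fringe pixels; must sit below the muscle
        HU band so that thresholding can remove the fringe.
    include_arms
        Whether arm muscles (when present, arms-down subjects) are wrongly
        included in the model mask.
    nonmuscle_blob_rate
        Expected number (Poisson) of non-muscle anatomy blobs per slice.
    boundary_jitter
        RMS-like magnitude (pixels) of random boundary flips.
    bmi_coupling
        Dimensionless slope: effective fringe/jitter scale is
        ``1 + bmi_coupling * (26 - bmi) / 26`` (floored at 0), so lower BMI
        means larger errors.
    """

    fringe_width: float = 2.0
    fringe_hu_band: tuple[float, float] = (-80.0, -30.0)
    include_arms: bool = True
    nonmuscle_blob_rate: float = 1.0
    boundary_jitter: float = 1.0
    bmi_coupling: float = 1.0
    blob_radius: float = 3.0

    def __post_init__(self) -> None:
        lo, hi = self.fringe_hu_band
        if not lo < hi:
            raise ValueError("fringe_hu_band must satisfy low < high")
        if self.fringe_width < 0 or self.nonmuscle_blob_rate < 0 or self.boundary_jitter < 0:
            raise ValueError("error magnitudes must be non-negative")

    @classmethod
    def zero(cls) -> "ErrorProfile":
        """Profile injecting no error: model mask equals the reference."""
        return cls(
            fringe_width=0.0,
            include_arms=False,
            nonmuscle_blob_rate=0.0,
            boundary_jitter=0.0,
            bmi_coupling=0.0,
        )

    def coupling_scale(self, bmi: float) -> float:
        """Multiplier applied to fringe width and jitter for a given BMI."""
        return max(0.0, 1.0 + self.bmi_coupling * (BMI_REFERENCE - bmi) / BMI_REFERENCE)


# ---------------------------------------------------------------------------
# Cohort covariates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CovariateConfig:
    """Marginal distributions of the synthetic cohort covariates.

    Defaults approximate the published validation population: mean (SD) age
    65 (11) years, 73% male, mean (SD) BMI 26 (5) kg/m^2, and cancer-type
    frequencies matching the reported counts (melanoma 69, lung 56,
    esophageal 41, head-and-neck 23 of 189).
    """

    age_mean: float = 65.0
    age_sd: float = 11.0
    male_fraction: float = 0.73
    bmi_mean: float = 26.0
    bmi_sd: float = 5.0
    bmi_range: tuple[float, float] = (14.0, 45.0)
    cancer_type_weights: tuple[float, ...] = (69 / 189, 56 / 189, 41 / 189, 23 / 189)
    cancer_grade_weights: tuple[float, ...] = (0.2, 0.3, 0.3, 0.2)
    cci_weights: tuple[float, ...] = (0.3, 0.3, 0.25, 0.15)
    arm_down_fraction: float = 0.25
    iv_contrast_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("cancer_type_weights", "cancer_grade_weights", "cci_weights"):
            w = np.asarray(getattr(self, name), dtype=float)
            if w.size != 4 or np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-8):
                raise ValueError(f"{name} must be 4 non-negative weights summing to 1")
        for name in ("male_fraction", "arm_down_fraction", "iv_contrast_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def generate_cohort(
    n: int,
    config: CovariateConfig | None = None,
    seed: int = 0,
) -> list[SubjectRecord]:
    """Draw ``n`` subject records from the configured covariate marginals.

    Deterministic for a fixed ``(n, config, seed)``.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    cfg = config or CovariateConfig()
    rng = np.random.default_rng(seed)

    age = np.clip(np.rint(rng.normal(cfg.age_mean, cfg.age_sd, n)), 18, 100).astype(int)
    sex = np.where(rng.random(n) < cfg.male_fraction, "male", "female")
    bmi = np.clip(rng.normal(cfg.bmi_mean, cfg.bmi_sd, n), *cfg.bmi_range)
    ctype = rng.choice(CANCER_TYPES, size=n, p=cfg.cancer_type_weights)
    grade = rng.choice([1, 2, 3, 4], size=n, p=cfg.cancer_grade_weights)
    cci = rng.choice([1, 2, 3, 4], size=n, p=cfg.cci_weights)
    arm = np.where(rng.random(n) < cfg.arm_down_fraction, "down", "up")
    contrast = rng.random(n) < cfg.iv_contrast_fraction

    return [
        SubjectRecord(
            subject_id=f"S{i:04d}",
            age=int(age[i]),
            sex=str(sex[i]),
            bmi=float(np.round(bmi[i], 2)),
            cancer_type=str(ctype[i]),
            cancer_grade=int(grade[i]),
            cci=int(cci[i]),
            arm_position=str(arm[i]),
            iv_contrast=bool(contrast[i]),
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Phantom geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeometryConfig:
    """Phantom grid, tissue HU bands and compartment scaling.

    The grid default (256x256 at 1.5 mm isotropic) gives a 38.4 cm field of
    view and realistic trunk-muscle areas (~140 cm^2 at the default muscle
    scale).  Tissue HU bands default to muscle [+20, +70], adipose/fascia
    [-120, -30] and bone [+200, +1200]; the adipose/muscle gap straddles the
    threshold-sweep range so that a data-driven HU cut is recoverable.

    ``muscle_bmi_slope`` and ``body_bmi_slope`` couple compartment size to
    BMI (muscle area and body girth both increase with BMI); setting both to
    zero decouples geometry from the covariates entirely.
    """

    shape: tuple[int, int] = (256, 256)
    pixel_spacing: tuple[float, float] = (1.5, 1.5)
    muscle_hu_band: tuple[float, float] = (20.0, 70.0)
    adipose_hu_band: tuple[float, float] = (-120.0, -30.0)
    bone_hu_band: tuple[float, float] = (200.0, 1200.0)
    organ_hu_band: tuple[float, float] = (25.0, 65.0)
    background_hu: float = -1000.0
    muscle_scale: float = 1.35
    muscle_bmi_slope: float = 0.02  # per kg/m^2 around BMI 26
    body_bmi_slope: float = 0.01
    body_radii: tuple[float, float] = (68.0, 85.0)  # (row, col) semi-axes
    fat_rim: float = 12.0  # subcutaneous fat thickness outside the wall
    arm_radius: float = 13.0
    arm_muscle_radius: float = 7.0
    arm_gap: float = 4.0


def _ellipse(yy: np.ndarray, xx: np.ndarray, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def generate_phantom(
    subject: SubjectRecord,
    config: GeometryConfig | None = None,
    seed: int = 0,
) -> LabeledPhantom:
    """Build the labeled L3 phantom slice for one subject.

    The six trunk muscle compartments are placed so that neighbouring groups
    are within the density-clustering reach of each other (they form a single
    trunk cluster), while arm muscles — drawn only for arms-down subjects —
    sit well outside that reach, laterally separated by the subcutaneous fat
    rim and an air gap.
    """
    cfg = config or GeometryConfig()
    rng = np.random.default_rng(seed)
    h, w = cfg.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0

    # BMI-dependent scales: s multiplies muscle areas, bf the body outline.
    s = cfg.muscle_scale * float(np.clip(1.0 + cfg.muscle_bmi_slope * (subject.bmi - BMI_REFERENCE), 0.6, 1.5))
    bf = float(np.clip(1.0 + cfg.body_bmi_slope * (subject.bmi - BMI_REFERENCE), 0.85, 1.12))
    q = np.sqrt(s)  # linear muscle-dimension factor (area ~ s)

    body_ry, body_rx = cfg.body_radii[0] * bf, cfg.body_radii[1] * bf
    arms = subject.arm_position == "down"
    lateral_extent = body_rx + (cfg.arm_gap + 2 * cfg.arm_radius if arms else 0.0)
    if body_ry + 2 > cy or lateral_extent + 2 > cx:
        raise ValueError(
            f"grid {cfg.shape} too small for body radii {(body_ry, body_rx)}"
            + (" with arms" if arms else "")
        )

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    labels = np.zeros((h, w), dtype=np.uint8)

    def paint(mask: np.ndarray, region: Region) -> None:
        labels[mask] = region

    def ell(dy: float, dx: float, ry: float, rx: float) -> np.ndarray:
        return _ellipse(yy, xx, cy + dy * bf, cx + dx * bf, ry, rx)

    # Body outline filled with adipose; organs/bone/muscles painted on top.
    paint(ell(0, 0, body_ry, body_rx), Region.ADIPOSE)

    # Non-muscle soft tissue: bowel loop (anterior) and two kidneys flanking
    # the quadratus lumborum; placed adjacent to muscle so that erroneous
    # blobs there can survive central-cluster selection.
    paint(ell(-10, 0, 7, 10), Region.OTHER_ORGAN)
    for side in (-1, 1):
        paint(ell(22, side * 52, 7, 9), Region.OTHER_ORGAN)

    # Vertebral body.
    paint(ell(28, 0, 11, 11), Region.BONE)

    # Abdominal wall: elliptical ring 12 px inside the body outline.
    wall_ry_o, wall_rx_o = body_ry - cfg.fat_rim, body_rx - cfg.fat_rim
    thick = 8.0 * q
    wall = _ellipse(yy, xx, cy, cx, wall_ry_o, wall_rx_o) & ~_ellipse(
        yy, xx, cy, cx, wall_ry_o - thick, wall_rx_o - thick
    )
    paint(wall & (labels == Region.ADIPOSE), Region.ABDOMINAL_WALL)

    # Paired and midline compartments (base offsets in pixels at bf = 1).
    for side in (-1, 1):
        paint(ell(-47, side * 13, 5 * q, 12 * q), Region.RECTUS_ABDOMINIS)
        paint(ell(48, side * 17, 10 * q, 14 * q), Region.ERECTOR_SPINAE)
        paint(ell(27, side * 35, 6 * q, 10 * q), Region.QUADRATUS_LUMBORUM)
        paint(ell(18, side * 20, 12 * q, 9 * q), Region.PSOAS_MAJOR)
        paint(ell(6, side * 10, 4 * q, 6 * q), Region.DIAPHRAGM)

    if arms:
        arm_cx = body_rx + cfg.arm_gap + cfg.arm_radius
        for side in (-1, 1):
            arm = _ellipse(yy, xx, cy, cx + side * arm_cx, cfg.arm_radius, cfg.arm_radius)
            paint(arm, Region.ADIPOSE)
            core = _ellipse(yy, xx, cy, cx + side * arm_cx, cfg.arm_muscle_radius, cfg.arm_muscle_radius)
            paint(core, Region.ARM_MUSCLE)

    # HU synthesis: uniform texture within each tissue band.
    hu = np.full((h, w), cfg.background_hu, dtype=np.float32)
    bands = {
        Region.ADIPOSE: cfg.adipose_hu_band,
        Region.BONE: cfg.bone_hu_band,
        Region.OTHER_ORGAN: cfg.organ_hu_band,
        Region.ARM_MUSCLE: cfg.muscle_hu_band,
    }
    for region in TRUNK_MUSCLE_LABELS:
        bands[region] = cfg.muscle_hu_band
    for region, (lo, hi) in bands.items():
        m = labels == region
        hu[m] = rng.uniform(lo, hi, int(m.sum())).astype(np.float32)

    reference = np.isin(labels, TRUNK_MUSCLE_LABELS)
    return LabeledPhantom(
        slice=CTSlice(hu=hu, pixel_spacing=cfg.pixel_spacing),
        reference_mask=reference,
        region_labels=labels,
        subject=subject,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Model-mask simulation
# ---------------------------------------------------------------------------


def simulate_model_mask(
    phantom: LabeledPhantom,
    profile: ErrorProfile,
    seed: int = 0,
) -> np.ndarray:
    """Simulate a raw model mask with the configured error structure.

    The returned mask is the reference plus (i) an adipose/fascia fringe of
    width ``fringe_width`` (BMI-scaled) restricted to adipose-labeled pixels,
    (ii) arm muscles when ``include_arms`` and arms are present, (iii) a
    Poisson number of small blobs on non-muscle organ tissue, with boundary
    jitter applied last.  Fringe pixels have their HU re-painted into the
    phantom slice from ``fringe_hu_band`` (fascia-like attenuation), so the
    slice and mask stay consistent for downstream HU thresholding.  With the
    zero profile the output equals the reference exactly.
    """
    ref = phantom.reference_mask
    labels = phantom.region_labels
    if ref.shape != labels.shape:
        raise ValueError("phantom mask/label shape mismatch")
    lo, hi = profile.fringe_hu_band
    if hi >= phantom.config.muscle_hu_band[0] and profile.fringe_width > 0:
        raise ValueError("fringe_hu_band must lie below the muscle HU band")

    rng = np.random.default_rng(seed)
    mask = ref.copy()
    scale = profile.coupling_scale(phantom.subject.bmi)

    # (i) adipose/fascia fringe hugging the reference boundary
    w_eff = profile.fringe_width * scale
    if w_eff > 0:
        d_out = ndimage.distance_transform_edt(~ref)
        fringe = (~ref) & (d_out <= w_eff) & (labels == Region.ADIPOSE)
        mask |= fringe
        phantom.slice.hu[fringe] = rng.uniform(lo, hi, int(fringe.sum())).astype(np.float32)

    # (ii) arm-muscle inclusion
    if profile.include_arms:
        mask |= labels == Region.ARM_MUSCLE

    # (iii) non-muscle anatomy blobs on organ tissue
    n_blobs = int(rng.poisson(profile.nonmuscle_blob_rate))
    organ = np.argwhere(labels == Region.OTHER_ORGAN)
    if n_blobs > 0 and len(organ) > 0:
        yy, xx = np.mgrid[0 : ref.shape[0], 0 : ref.shape[1]].astype(float)
        centers = organ[rng.integers(0, len(organ), n_blobs)]
        for by, bx in centers:
            blob = ((yy - by) ** 2 + (xx - bx) ** 2 <= profile.blob_radius**2) & (
                labels == Region.OTHER_ORGAN
            )
            mask |= blob

    # (iv) boundary jitter: flip pixels layer by layer around the reference
    # boundary; layer d flips with probability p * clip(j-d+1, 0, 1) so the
    # expected flipped area varies continuously with j.
    j = profile.boundary_jitter * scale
    if j > 0:
        d_in = ndimage.distance_transform_edt(ref)
        d_out = ndimage.distance_transform_edt(~ref)
        layer_in = np.ceil(d_in)
        layer_out = np.ceil(d_out)
        u = rng.random(ref.shape)
        p_in = JITTER_REMOVE_P * np.clip(j - (layer_in - 1), 0.0, 1.0)
        remove = ref & (d_in > 0) & (u < p_in)
        p_out = JITTER_ADD_P * np.clip(j - (layer_out - 1), 0.0, 1.0)
        add = (~ref) & (labels == Region.ADIPOSE) & (u < p_out)
        mask = (mask & ~remove) | add

    return mask
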