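"""Synthetic two-channel tumor phantom generator.

Each subject carries an enhancing tumor in channel 1 (ellipsoid with optional
boundary spiculation and class-specific intratumoral texture) and an edema-like
region in channel 2 whose voxel volume is tied to channel 1 through a ratio
``r`` drawn independently of the class label, so that region volume confounds
neither grade.  A weak grade-dependent intensity gradient can be planted in
channel 2.

Randomness: one :class:`numpy.random.Generator` drives a whole cohort.  All
stochastic fields are drawn unconditionally and scaled by their (possibly
zero) amplitudes, so two subjects generated from identical generator states
with different grade labels but equal effect sizes are voxel-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .imgio import Volume3D, compute_r_ratio, write_volume

__all__ = [
    "LOCATIONS",
    "PhantomConfig",
    "Subject",
    "InvalidConfigError",
    "PhantomGenerationError",
    "sample_r_ratio",
    "generate_subject",
    "generate_subjects",
    "generate_cohort",
    "tumor_texture_sd",
    "surface_to_volume_ratio",
]

LOCATIONS = (
    "anterior_middle_fossa",
    "convexity",
    "falx_parasagittal",
    "posterior_fossa",
    "lateral_ventricle",
)
GRADES = ("I", "II")


class InvalidConfigError(ValueError):
    pass


class PhantomGenerationError(RuntimeError):
    pass


@dataclass
class PhantomConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the clinical cohort regime this generator emulates:
    class balance 55:41, location weights 43:20:18:13:2, and a truncated-normal
    volume-ratio distribution with mean 0.83, SD 0.50 on [0.07, 3.19].
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: float = 1.0
    tumor_radius_range_mm: tuple[float, float] = (4.0, 8.0)
    grade1_heterogeneity: float = 0.12
    grade2_heterogeneity: float = 0.45
    grade2_spiculation: float = 0.35
    flair_signal_weight: float = 0.08
    r_mean: float = 0.83
    r_sd: float = 0.50
    r_min: float = 0.07
    r_max: float = 3.19
    noise_sd: float = 0.05
    class_probs: tuple[float, float] = (55 / 96, 41 / 96)
    location_probs: tuple[float, ...] = (43 / 96, 20 / 96, 18 / 96, 13 / 96, 2 / 96)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        scalars = (
            self.spacing_mm,
            *self.tumor_radius_range_mm,
            self.grade1_heterogeneity,
            self.grade2_heterogeneity,
            self.grade2_spiculation,
            self.flair_signal_weight,
            self.r_mean,
            self.r_sd,
            self.r_min,
            self.r_max,
            self.noise_sd,
        )
        if not all(math.isfinite(v) for v in scalars):
            raise InvalidConfigError("phantom config contains non-finite parameters")
        if len(self.grid_shape) != 3 or any(int(s) < 8 for s in self.grid_shape):
            raise InvalidConfigError(f"grid_shape must be 3 axes of >= 8 voxels, got {self.grid_shape}")
        if self.spacing_mm <= 0:
            raise InvalidConfigError("spacing_mm must be positive")
        if self.grade2_heterogeneity < self.grade1_heterogeneity:
            raise InvalidConfigError("grade2_heterogeneity must be >= grade1_heterogeneity")
        if not (0 < self.r_min < self.r_max):
            raise InvalidConfigError("require 0 < r_min < r_max")
        if not (self.r_min <= self.r_mean <= self.r_max):
            raise InvalidConfigError("require r_min <= r_mean <= r_max")
        if self.r_sd < 0 or self.noise_sd < 0:
            raise InvalidConfigError("standard deviations must be nonnegative")
        lo, hi = self.tumor_radius_range_mm
        if not (0 < lo <= hi):
            raise InvalidConfigError("tumor_radius_range_mm must satisfy 0 < min <= max")
        for name, probs, k in (
            ("class_probs", self.class_probs, 2),
            ("location_probs", self.location_probs, len(LOCATIONS)),
        ):
            if len(probs) != k:
                raise InvalidConfigError(f"{name} must have {k} entries")
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise InvalidConfigError(f"{name} must be nonnegative and sum to 1")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PhantomConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise InvalidConfigError(f"unknown phantom config keys: {sorted(unknown)}")
        kwargs = dict(mapping)
        for key in ("grid_shape", "tumor_radius_range_mm", "class_probs", "location_probs"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class Subject:
    """One synthetic subject: two channels, two masks, grade, location, R."""

    subject_id: str
    t1ce: Volume3D
    flair: Volume3D
    t1ce_mask: Volume3D
    flair_mask: Volume3D
    grade: str
    location: str
    r_ratio: float

    def validate(self) -> None:
        if self.grade not in GRADES:
            raise ValueError(f"grade must be in {GRADES}")
        for m in (self.t1ce_mask, self.flair_mask):
            arr = np.asarray(m.values)
            if not arr.any():
                raise ValueError("mask is empty")
            if (
                arr[0].any() or arr[-1].any()
                or arr[:, 0].any() or arr[:, -1].any()
                or arr[:, :, 0].any() or arr[:, :, -1].any()
            ):
                raise ValueError("mask touches the grid boundary")
        if self.r_ratio <= 1.0:
            t1 = np.asarray(self.t1ce_mask.values) > 0
            fl = np.asarray(self.flair_mask.values) > 0
            if np.any(t1 & ~fl):
                raise ValueError("t1ce mask must be contained in flair mask when R <= 1")
        derived = compute_r_ratio(self.t1ce_mask, self.flair_mask)
        if abs(derived - self.r_ratio) > 0.05 * self.r_ratio:
            raise ValueError(
                f"mask-derived R {derived:.4f} deviates >5% from stored {self.r_ratio:.4f}"
            )


def sample_r_ratio(config: PhantomConfig, rng: np.random.Generator) -> float:
    """Draw R from Normal(r_mean, r_sd) truncated by rejection to [r_min, r_max]."""
    config.validate()
    if config.r_sd == 0:
        return float(config.r_mean)
    for _ in range(100_000):
        r = rng.normal(config.r_mean, config.r_sd)
        if config.r_min <= r <= config.r_max:
            return float(r)
    raise PhantomGenerationError("rejection sampling of R did not terminate")


def _smooth_unit_field(rng: np.random.Generator, shape, sigma: float = 2.0) -> np.ndarray:
    """Smooth random field normalized to zero mean and unit SD."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    return (f - f.mean()) / (f.std() + 1e-12)


def _pick_extremal_voxels(
    dist: np.ndarray,
    candidates: np.ndarray,
    count: int,
    rng: np.random.Generator,
    smallest: bool,
) -> np.ndarray:
    """Boolean mask selecting ``count`` candidate voxels with the smallest
    (or largest) distance; ties broken by a random key so the target voxel
    count is hit exactly."""
    flat_idx = np.flatnonzero(candidates)
    key = dist.ravel()[flat_idx]
    if not smallest:
        key = -key
    tiebreak = rng.random(flat_idx.size)
    order = np.lexsort((tiebreak, key))
    chosen = flat_idx[order[:count]]
    out = np.zeros(dist.size, dtype=bool)
    out[chosen] = True
    return out.reshape(dist.shape)


def generate_subject(
    config: PhantomConfig,
    grade: str,
    rng: np.random.Generator,
    subject_id: str = "subject",
) -> Subject:
    """Generate one two-channel subject of the requested grade.

    Channel-1 tumor: randomly placed ellipsoid, level-set boundary perturbation
    (amplitude ``grade2_spiculation`` for Grade II, 0 for Grade I) and additive
    intratumoral Gaussian texture with the class SD.  Channel-2 region: the
    tumor mask dilated (or eroded, for R > 1) voxel-exactly to volume
    V_T1CE / R via a distance-transform threshold with random tie trimming.
    Masks are derived before noise is added.
    """
    if grade not in GRADES:
        raise ValueError(f"grade must be in {GRADES}, got {grade!r}")
    config.validate()
    shape = tuple(int(s) for s in config.grid_shape)
    spacing = config.spacing_mm
    affine = np.diag([spacing, spacing, spacing, 1.0])
    coords = np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")

    # R is drawn once, before placement, so retries cannot bias its distribution
    r = sample_r_ratio(config, rng)
    lo_mm, hi_mm = config.tumor_radius_range_mm
    shrink = 1.0
    last_err = "no attempt"
    for _ in range(8):
        mean_radius_mm = rng.uniform(lo_mm, hi_mm) * shrink
        radii_vox = (mean_radius_mm / spacing) * (1.0 + rng.uniform(-0.25, 0.25, size=3))
        radii_vox = np.maximum(radii_vox, 1.5)
        # center drawn in the middle band of the grid so the halo has room
        center = np.array([rng.uniform(0.32 * s, 0.68 * s) for s in shape])
        q = sum(((c - mu) / r) ** 2 for c, mu, r in zip(coords, center, radii_vox))
        level = 1.0 - np.sqrt(q)
        perturb = _smooth_unit_field(rng, shape, sigma=1.0)
        spic_amp = config.grade2_spiculation if grade == "II" else 0.0
        tumor = level + 0.3 * spic_amp * perturb > 0.0
        # keep the component containing (or nearest) the center
        lab, nlab = ndimage.label(tumor)
        if nlab > 1:
            counts = np.bincount(lab.ravel())
            counts[0] = 0
            tumor = lab == int(np.argmax(counts))

        n_tumor = int(tumor.sum())
        interior = np.ones(shape, dtype=bool)
        interior[0], interior[-1] = False, False
        interior[:, 0], interior[:, -1] = False, False
        interior[:, :, 0], interior[:, :, -1] = False, False

        if n_tumor < 8 or np.any(tumor & ~interior):
            shrink *= 0.8
            last_err = "tumor empty or touching the grid boundary"
            continue

        target_flair = max(1, int(round(n_tumor / r)))
        if target_flair >= n_tumor:
            extra = target_flair - n_tumor
            candidates = interior & ~tumor
            if extra > int(candidates.sum()):
                shrink *= 0.8
                last_err = "edema halo does not fit in the grid"
                continue
            dist_out = ndimage.distance_transform_edt(~tumor)
            halo = _pick_extremal_voxels(dist_out, candidates, extra, rng, smallest=True)
            flair_region = tumor | halo
        else:
            dist_in = ndimage.distance_transform_edt(tumor)
            flair_region = _pick_extremal_voxels(dist_in, tumor, target_flair, rng, smallest=False)
        break
    else:
        raise PhantomGenerationError(
            f"could not place subject {subject_id!r} after bounded retries: {last_err}"
        )

    het = config.grade2_heterogeneity if grade == "II" else config.grade1_heterogeneity
    t1_texture = rng.standard_normal(shape)
    flair_texture = rng.standard_normal(shape)
    noise1 = rng.standard_normal(shape)
    noise2 = rng.standard_normal(shape)
    location = LOCATIONS[rng.choice(len(LOCATIONS), p=np.asarray(config.location_probs))]

    t1_vals = tumor * (1.0 + het * t1_texture)
    # weak grade-dependent radial gradient inside the channel-2 region
    radial = np.sqrt(sum((c - mu) ** 2 for c, mu in zip(coords, center)))
    rmax = max(float(radial[flair_region].max()), 1e-9)
    grad_field = 1.0 - radial / rmax
    g2 = 1.0 if grade == "II" else 0.0
    fl_vals = flair_region * (0.7 + 0.1 * flair_texture + config.flair_signal_weight * g2 * grad_field)
    t1_vals = t1_vals + config.noise_sd * noise1
    fl_vals = fl_vals + config.noise_sd * noise2

    subject = Subject(
        subject_id=subject_id,
        t1ce=Volume3D(t1_vals, affine.copy(), "T1CE"),
        flair=Volume3D(fl_vals, affine.copy(), "FLAIR"),
        t1ce_mask=Volume3D(tumor.astype(np.uint8), affine.copy(), "MASK"),
        flair_mask=Volume3D(flair_region.astype(np.uint8), affine.copy(), "MASK"),
        grade=grade,
        location=location,
        r_ratio=float(r),
    )
    subject.validate()
    return subject


def _draw_grades(
    config: PhantomConfig,
    n: int,
    rng: np.random.Generator,
    counts: tuple[int, int] | None,
) -> list[str]:
    if counts is not None:
        n1, n2 = counts
        if n1 + n2 != n:
            raise InvalidConfigError(f"fixed counts {counts} do not sum to n={n}")
        grades = ["I"] * n1 + ["II"] * n2
        rng.shuffle(grades)
        return grades
    picks = rng.choice(2, size=n, p=np.asarray(config.class_probs))
    return [GRADES[int(p)] for p in picks]


def generate_subjects(
    config: PhantomConfig,
    n: int,
    counts: tuple[int, int] | None = None,
    rng: np.random.Generator | None = None,
) -> list[Subject]:
    """Generate ``n`` in-memory subjects; grades follow ``class_probs`` unless
    fixed ``counts`` (n_grade1, n_grade2) are requested."""
    if n < 2:
        raise InvalidConfigError(f"cohort size must be >= 2, got {n}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    grades = _draw_grades(config, n, rng, counts)
    width = max(3, len(str(n - 1)))
    return [
        generate_subject(config, grade, rng, subject_id=f"s{idx:0{width}d}")
        for idx, grade in enumerate(grades)
    ]


def generate_cohort(
    config: PhantomConfig,
    n: int,
    out_dir,
    counts: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Generate ``n`` subjects, write NIfTI volumes plus a CSV manifest to
    ``out_dir`` and return the manifest.  Deterministic given the config seed."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    subjects = generate_subjects(config, n, counts=counts)
    rows = []
    for s in subjects:
        paths = {
            "t1ce_path": out_dir / f"{s.subject_id}_t1ce.nii.gz",
            "flair_path": out_dir / f"{s.subject_id}_flair.nii.gz",
            "t1ce_mask_path": out_dir / f"{s.subject_id}_t1ce_mask.nii.gz",
            "flair_mask_path": out_dir / f"{s.subject_id}_flair_mask.nii.gz",
        }
        write_volume(s.t1ce, paths["t1ce_path"])
        write_volume(s.flair, paths["flair_path"])
        write_volume(s.t1ce_mask, paths["t1ce_mask_path"])
        write_volume(s.flair_mask, paths["flair_mask_path"])
        rows.append(
            {
                "subject_id": s.subject_id,
                "grade": s.grade,
                "location": s.location,
                "r_ratio": f"{s.r_ratio:.6f}",
                **{k: str(v) for k, v in paths.items()},
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def tumor_texture_sd(subject: Subject) -> float:
    """Intratumoral intensity SD in channel 1 (a handcrafted grade feature)."""
    mask = np.asarray(subject.t1ce_mask.values) > 0
    return float(np.asarray(subject.t1ce.values)[mask].std())


def surface_to_volume_ratio(mask: Volume3D) -> float:
    """Exposed 6-neighbour face count divided by voxel count of a mask."""
    arr = np.asarray(mask.values) > 0
    n = int(arr.sum())
    if n == 0:
        raise ValueError("mask is empty")
    padded = np.pad(arr, 1)
    core = (slice(1, -1),) * 3
    faces = 0
    for axis in range(3):
        for shift in (1, -1):
            neighbour = np.roll(padded, shift, axis=axis)[core]
            faces += int(np.sum(arr & ~neighbour))
    return faces / n
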