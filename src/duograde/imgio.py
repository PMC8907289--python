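"""Volume I/O and the image preprocessing chain.

Covers reading/writing NIfTI volumes, resampling onto a reference grid or to
an isotropic spacing, tumor-volume / volume-ratio computation, fixed-shape ROI
extraction around a mask, and z-score intensity normalization.

Conventions
-----------
* Voxel indexing is 0-based; crop windows are half-open ``[origin, origin + shape)``.
* Crop windows align their center ``(shape - 1) / 2`` with the mask centroid,
  rounding the origin to the nearest voxel with ties toward the lower index.
* Voxels falling outside the source field of view after resampling are filled
  with 0 (the post-normalization background value).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume3D",
    "RoiTensor",
    "VolumeError",
    "VolumeFormatError",
    "UndefinedRatioError",
    "read_volume",
    "write_volume",
    "resample_to_reference",
    "resample_isotropic",
    "mask_volume_mm3",
    "compute_r_ratio",
    "crop_to_roi",
    "normalize_intensity",
    "subject_to_roi",
]

CHANNEL_ROLES = ("T1CE", "FLAIR", "MASK")


class VolumeError(ValueError):
    """Invalid volume contents or metadata."""


class VolumeFormatError(VolumeError):
    """File could not be parsed as a 3-D NIfTI volume."""


class UndefinedRatioError(VolumeError):
    """Volume ratio undefined (empty denominator mask)."""


@dataclass
class Volume3D:
    """A 3-D scalar grid with a grid-index -> world-mm affine.

    ``channel_role`` is one of ``{"T1CE", "FLAIR", "MASK"}``; MASK volumes are
    validated to contain only {0, 1}.
    """

    values: np.ndarray
    affine: np.ndarray
    channel_role: str = "T1CE"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise VolumeFormatError(
                f"expected a 3-D payload, got {self.values.ndim}-D"
            )
        if self.affine.shape != (4, 4):
            raise VolumeError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise VolumeError("affine is not invertible")
        if np.any(self.spacing <= 0):
            raise VolumeError(f"spacing must be strictly positive, got {self.spacing}")
        if self.channel_role not in CHANNEL_ROLES:
            raise VolumeError(
                f"channel_role must be one of {CHANNEL_ROLES}, got {self.channel_role!r}"
            )
        if self.channel_role == "MASK":
            uniq = np.unique(self.values)
            if not np.isin(uniq, (0, 1)).all():
                raise VolumeError(
                    f"MASK volume must contain only {{0, 1}}, found values {uniq[:8]}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        # product of column norms: exact for orthogonal direction matrices
        return float(np.prod(self.spacing))

    def same_grid(self, other: "Volume3D", tol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=tol
        )


@dataclass
class RoiTensor:
    """Fixed-shape two-channel 3-D crop centered on a tumor mask."""

    values: np.ndarray  # (2, *shape)
    source_subject: str
    crop_origin: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 4 or self.values.shape[0] != 2:
            raise VolumeError(
                f"RoiTensor values must have shape (2, d, h, w), got {self.values.shape}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape[1:]  # type: ignore[return-value]


def read_volume(path, channel_role: str = "T1CE") -> Volume3D:
    """Read a NIfTI file into a :class:`Volume3D`.

    Raises :class:`VolumeFormatError` for malformed files or non-3-D payloads.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeFormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeFormatError(
            f"{path}: expected a 3-D payload, got {data.ndim}-D with shape {data.shape}"
        )
    return Volume3D(values=data, affine=np.asarray(img.affine), channel_role=channel_role)


def write_volume(vol: Volume3D, path) -> None:
    """Write a volume to NIfTI; round-trip preserves values bit-exactly."""
    data = vol.values
    if vol.channel_role == "MASK":
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, vol.affine), str(path))


def _interp_order(vol: Volume3D, interp: str | None) -> int:
    if interp is None:
        interp = "nearest" if vol.channel_role == "MASK" else "trilinear"
    if interp == "nearest":
        return 0
    if interp == "trilinear":
        return 1
    raise ValueError(f"interp must be 'trilinear' or 'nearest', got {interp!r}")


def _fov_overlaps(moving: Volume3D, reference: Volume3D) -> bool:
    # Map the reference grid's corner voxel centers into moving index space
    # and test the bounding boxes for intersection.
    t = np.linalg.inv(moving.affine) @ reference.affine
    corners = np.array(
        [
            [i, j, k, 1.0]
            for i in (0, reference.shape[0] - 1)
            for j in (0, reference.shape[1] - 1)
            for k in (0, reference.shape[2] - 1)
        ]
    ).T
    mapped = (t @ corners)[:3]
    lo, hi = mapped.min(axis=1), mapped.max(axis=1)
    mshape = np.array(moving.shape)
    return bool(np.all(hi >= -0.5) and np.all(lo <= mshape - 0.5))


def resample_to_reference(
    moving: Volume3D, reference: Volume3D, interp: str | None = None
) -> Volume3D:
    """Resample ``moving`` onto the grid and affine of ``reference``.

    Interpolation happens in world space; voxels that map outside the moving
    volume are filled with 0.  Masks default to nearest-neighbour.  If the two
    fields of view do not overlap, a warning is emitted and an all-fill volume
    is returned.
    """
    order = _interp_order(moving, interp)
    if not _fov_overlaps(moving, reference):
        warnings.warn(
            "moving and reference fields of view do not overlap; output is all fill",
            stacklevel=2,
        )
    t = np.linalg.inv(moving.affine) @ reference.affine
    out = ndimage.affine_transform(
        np.asarray(moving.values, dtype=float),
        matrix=t[:3, :3],
        offset=t[:3, 3],
        output_shape=reference.shape,
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    if moving.channel_role == "MASK":
        out = (out > 0.5).astype(np.uint8)
    return Volume3D(values=out, affine=reference.affine.copy(), channel_role=moving.channel_role)


def resample_isotropic(
    vol: Volume3D, target_mm: float = 1.0, interp: str | None = None
) -> Volume3D:
    """Resample to isotropic ``target_mm`` spacing, preserving world extent
    to within one voxel per axis."""
    if target_mm <= 0:
        raise ValueError(f"target_mm must be > 0, got {target_mm}")
    spacing = vol.spacing
    if np.allclose(spacing, target_mm, atol=1e-9):
        return Volume3D(vol.values.copy(), vol.affine.copy(), vol.channel_role)
    direction = vol.affine[:3, :3] / spacing[np.newaxis, :]
    new_affine = np.eye(4)
    new_affine[:3, :3] = direction * target_mm
    new_affine[:3, 3] = vol.affine[:3, 3]
    new_shape = tuple(
        max(1, int(np.rint(n * s / target_mm))) for n, s in zip(vol.shape, spacing)
    )
    ref = Volume3D(np.zeros(new_shape), new_affine, "T1CE")
    return resample_to_reference(vol, ref, interp)


def mask_volume_mm3(mask: Volume3D) -> float:
    """Mask volume in mm^3: (number of 1-voxels) x (voxel volume)."""
    if mask.channel_role != "MASK":
        raise VolumeError("mask_volume_mm3 requires a MASK-role volume")
    return float(np.count_nonzero(mask.values)) * mask.voxel_volume_mm3


def compute_r_ratio(t1ce_mask: Volume3D, flair_mask: Volume3D) -> float:
    """R = V_T1CE / V_T2FLAIR from the two tumor masks."""
    v_flair = mask_volume_mm3(flair_mask)
    if v_flair == 0:
        raise UndefinedRatioError("FLAIR mask is empty; R is undefined")
    v_t1 = mask_volume_mm3(t1ce_mask)
    if v_t1 == 0:
        raise UndefinedRatioError("T1-CE mask is empty; R is undefined")
    return v_t1 / v_flair


def crop_to_roi(
    t1ce: Volume3D,
    flair: Volume3D,
    mask: Volume3D,
    target_shape: tuple[int, int, int],
    source_subject: str = "",
) -> RoiTensor:
    """Crop both channels with one window of ``target_shape`` centered on the
    mask centroid; borders are zero-padded."""
    if not (t1ce.same_grid(flair) and t1ce.same_grid(mask)):
        raise VolumeError("crop_to_roi requires all volumes on one grid")
    idx = np.nonzero(np.asarray(mask.values))
    if idx[0].size == 0:
        raise VolumeError("mask is empty")
    centroid = np.array([c.mean() for c in idx])
    target = np.asarray(target_shape, dtype=int)
    # align window center (target-1)/2 with the centroid; ties toward lower index
    origin = np.ceil(centroid - (target - 1) / 2.0 - 0.5).astype(int)
    out = np.zeros((2, *target), dtype=float)
    src_shape = np.array(t1ce.shape)
    src_lo = np.maximum(origin, 0)
    src_hi = np.minimum(origin + target, src_shape)
    if np.any(src_lo >= src_hi):
        raise VolumeError("crop window does not intersect the source grid")
    dst_lo = src_lo - origin
    dst_hi = dst_lo + (src_hi - src_lo)
    s_src = tuple(slice(int(a), int(b)) for a, b in zip(src_lo, src_hi))
    s_dst = tuple(slice(int(a), int(b)) for a, b in zip(dst_lo, dst_hi))
    out[(0, *s_dst)] = np.asarray(t1ce.values, dtype=float)[s_src]
    out[(1, *s_dst)] = np.asarray(flair.values, dtype=float)[s_src]
    return RoiTensor(values=out, source_subject=source_subject, crop_origin=tuple(int(o) for o in origin))


def normalize_intensity(vol: Volume3D, mask: Volume3D | None = None) -> Volume3D:
    """Z-score the volume over its support voxels (mean 0, SD 1).

    Support is the nonzero set of ``mask`` when given, else of the volume
    itself.  Non-support voxels are set to 0; a constant volume maps to all
    zeros.
    """
    values = np.asarray(vol.values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise VolumeError("normalize_intensity requires finite values")
    support = (np.asarray(mask.values) > 0) if mask is not None else (values != 0)
    out = np.zeros_like(values)
    if not support.any():
        return Volume3D(out, vol.affine.copy(), vol.channel_role)
    sub = values[support]
    mu = sub.mean()
    sd = sub.std()
    if sd < 1e-12:
        return Volume3D(out, vol.affine.copy(), vol.channel_role)
    out[support] = (sub - mu) / sd
    return Volume3D(out, vol.affine.copy(), vol.channel_role)


def subject_to_roi(subject, target_shape, masked: bool = False) -> RoiTensor:
    """Preprocess one subject into a network-ready ROI tensor.

    The crop window is centered on the union of the two tumor masks; each
    channel is then z-scored over its in-crop support.  With ``masked=True``
    each channel is multiplied by its own mask before normalization
    (context-free variant).
    """
    t1ce, flair = subject.t1ce, subject.flair
    if masked:
        t1ce = Volume3D(
            np.asarray(t1ce.values, dtype=float) * (np.asarray(subject.t1ce_mask.values) > 0),
            t1ce.affine.copy(),
            t1ce.channel_role,
        )
        flair = Volume3D(
            np.asarray(flair.values, dtype=float) * (np.asarray(subject.flair_mask.values) > 0),
            flair.affine.copy(),
            flair.channel_role,
        )
    union = (
        (np.asarray(subject.t1ce_mask.values) > 0)
        | (np.asarray(subject.flair_mask.values) > 0)
    ).astype(np.uint8)
    union_mask = Volume3D(union, subject.t1ce_mask.affine.copy(), "MASK")
    roi = crop_to_roi(t1ce, flair, union_mask, target_shape, source_subject=subject.subject_id)
    out = np.empty_like(roi.values)
    for c in range(2):
        ch = Volume3D(roi.values[c], np.eye(4), "T1CE")
        out[c] = normalize_intensity(ch).values
    return RoiTensor(values=out, source_subject=roi.source_subject, crop_origin=roi.crop_origin)
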