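"""Volume containers and I/O.

All in-memory volumes use the axes convention ``(slice, row, column)`` with
0-based indices; ``spacing`` is given in the same axis order, in millimetres.
Every image operation in the package works on these containers, and after
ingestion every channel of a patient case lives on the T2WI grid.

Voxels that are masked out of a derived map carry the missing sentinel
(IEEE NaN) and are excluded from all statistics downstream.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import nibabel as nib
import SimpleITK as sitk
from scipy import ndimage

#: Sentinel for "no value here" in derived maps (outside-mask voxels).
MISSING = np.nan

MASK_LABELS = ("PZ", "reference_tissue", "rater1", "rater2", "cancer", "noncancer")


class VolumeIOError(IOError):
    """Unreadable or malformed image file."""


class DimensionalityError(ValueError):
    """Image on disk is not a 3-D scalar volume."""


class GridMismatchError(ValueError):
    """Two objects that must share a voxel grid do not."""


@dataclass
class VoxelVolume:
    """A 3-D scalar grid with voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (n_slices, n_rows, n_cols)
        Float intensities; arbitrary units for signal channels, mm^2/s for
        diffusivities.  NaN marks masked-out voxels.
    spacing : tuple of float
        Voxel edge lengths (mm) in (slice, row, column) order.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3-D volume, got {self.data.ndim}-D"
            )
        if min(self.data.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "VoxelVolume":
        return VoxelVolume(self.data.copy(), self.spacing)

    def same_grid(self, other: "VoxelVolume | ROIMask") -> bool:
        return self.shape == other.shape and np.allclose(
            self.spacing, other.spacing, rtol=1e-6
        )


@dataclass
class ROIMask:
    """A binary mask aligned to a :class:`VoxelVolume` grid."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    label: str = "PZ"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise DimensionalityError("mask must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.label not in MASK_LABELS:
            raise ValueError(f"unknown mask label {self.label!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_cc(self) -> float:
        """Mask volume in cubic centimetres."""
        return self.voxel_count * float(np.prod(self.spacing)) / 1000.0

    def check_companion(self, vol: "VoxelVolume | ROIMask") -> None:
        if self.shape != vol.shape:
            raise GridMismatchError(
                f"mask shape {self.shape} != companion shape {vol.shape}"
            )

    def copy(self) -> "ROIMask":
        return ROIMask(self.data.copy(), self.spacing, self.label)


@dataclass
class DtiEigenvalues:
    """Sorted diffusion-tensor eigenvalue volumes (lambda1 >= lambda2 >= lambda3).

    On construction the three volumes are sorted voxelwise in descending
    order and negative values are clamped to zero; ``n_clamped`` counts the
    clamped voxels so ingest problems stay visible.
    """

    lambda1: VoxelVolume
    lambda2: VoxelVolume
    lambda3: VoxelVolume
    n_clamped: int = field(default=0, init=False)

    def __post_init__(self) -> None:
        if not (
            self.lambda1.same_grid(self.lambda2)
            and self.lambda1.same_grid(self.lambda3)
        ):
            raise GridMismatchError("eigenvalue volumes must share one grid")
        stack = np.stack(
            [self.lambda1.data, self.lambda2.data, self.lambda3.data], axis=0
        )
        finite = np.isfinite(stack)
        self.n_clamped = int((stack[finite] < 0).sum())
        stack = np.where(finite & (stack < 0), 0.0, stack)
        stack = -np.sort(-stack, axis=0)  # descending along the triplet axis
        sp = self.lambda1.spacing
        self.lambda1 = VoxelVolume(stack[0], sp)
        self.lambda2 = VoxelVolume(stack[1], sp)
        self.lambda3 = VoxelVolume(stack[2], sp)

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.lambda1.spacing

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.lambda1.shape


@dataclass
class PatientCase:
    """One subject: co-registered channels plus masks, all on the T2WI grid."""

    patient_id: str
    t2w: VoxelVolume
    dwi_highb: VoxelVolume
    adc: VoxelVolume
    eigenvalues: DtiEigenvalues
    pz: ROIMask
    reference_tissue: ROIMask
    rater_masks: list[tuple[ROIMask, ROIMask]] = field(default_factory=list)

    def __post_init__(self) -> None:
        grid = self.t2w
        for name in ("dwi_highb", "adc"):
            if not grid.same_grid(getattr(self, name)):
                raise GridMismatchError(f"{name} not on the T2WI grid")
        if self.eigenvalues.shape != grid.shape:
            raise GridMismatchError("eigenvalues not on the T2WI grid")
        for m in (self.pz, self.reference_tissue):
            m.check_companion(grid)
        for r1, r2 in self.rater_masks:
            r1.check_companion(grid)
            r2.check_companion(grid)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _infer_format(path: str) -> str:
    p = str(path).lower()
    if p.endswith((".nii", ".nii.gz")):
        return "nifti"
    if p.endswith(".nrrd"):
        return "nrrd"
    raise VolumeIOError(f"cannot infer image format from {path!r}")


def read_volume(path: str, format: str | None = None) -> VoxelVolume:
    """Read a 3-D volume from NIfTI-1 or NRRD.

    The on-disk (x, y, z) axes map to the in-memory (column, row, slice)
    axes, so ``data[s, r, c]`` indexes slice ``s``.  Spacing comes from the
    file header.
    """
    fmt = format or _infer_format(path)
    if not os.path.exists(path):
        raise VolumeIOError(f"no such file: {path}")
    if fmt == "nifti":
        try:
            img = nib.load(path)
            arr = np.asanyarray(img.dataobj)
        except Exception as exc:  # pragma: no cover - nibabel message varies
            raise VolumeIOError(f"could not read NIfTI file {path}: {exc}") from exc
        arr = np.squeeze(arr) if arr.ndim > 3 and all(
            d == 1 for d in arr.shape[3:]
        ) else arr
        if arr.ndim != 3:
            raise DimensionalityError(
                f"{path}: expected 3-D image, got shape {arr.shape}"
            )
        zooms = img.header.get_zooms()[:3]
        return VoxelVolume(np.ascontiguousarray(arr.T, dtype=np.float64),
                           (zooms[2], zooms[1], zooms[0]))
    if fmt == "nrrd":
        try:
            img = sitk.ReadImage(str(path))
        except Exception as exc:
            raise VolumeIOError(f"could not read NRRD file {path}: {exc}") from exc
        if img.GetDimension() != 3:
            raise DimensionalityError(
                f"{path}: expected 3-D image, got {img.GetDimension()}-D"
            )
        arr = sitk.GetArrayFromImage(img)  # (z, y, x) == (slice, row, col)
        sp = img.GetSpacing()  # (x, y, z)
        return VoxelVolume(arr.astype(np.float64), (sp[2], sp[1], sp[0]))
    raise ValueError(f"unknown format {fmt!r}")


def write_volume(vol: VoxelVolume, path: str, format: str | None = None) -> None:
    """Write a volume to NIfTI-1 or NRRD, inverting :func:`read_volume`."""
    fmt = format or _infer_format(path)
    ds, dr, dc = vol.spacing
    if fmt == "nifti":
        affine = np.diag([dc, dr, ds, 1.0])
        img = nib.Nifti1Image(np.ascontiguousarray(vol.data.T), affine)
        img.header.set_zooms((dc, dr, ds))
        nib.save(img, path)
        return
    if fmt == "nrrd":
        img = sitk.GetImageFromArray(vol.data)
        img.SetSpacing((dc, dr, ds))
        sitk.WriteImage(img, str(path))
        return
    raise ValueError(f"unknown format {fmt!r}")


def read_mask(path: str, label: str, format: str | None = None) -> ROIMask:
    """Read a 0/1 volume as a binary mask (nonzero -> True)."""
    vol = read_volume(path, format)
    return ROIMask(vol.data > 0.5, vol.spacing, label)


def write_mask(mask: ROIMask, path: str, format: str | None = None) -> None:
    write_volume(VoxelVolume(mask.data.astype(np.float64), mask.spacing), path, format)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_to_grid(
    src: VoxelVolume, target: VoxelVolume, method: str = "trilinear"
) -> VoxelVolume:
    """Resample ``src`` onto ``target``'s grid.

    The two grids are assumed co-registered with a shared world origin at
    the centre of voxel (0, 0, 0); resampling only changes grid density,
    never pose.  ``method`` is ``"trilinear"`` for images or ``"nearest"``
    for label-like data.  Values outside the source extent replicate the
    nearest edge voxel.
    """
    if method not in ("nearest", "trilinear"):
        raise ValueError(f"method must be 'nearest' or 'trilinear', got {method!r}")
    if src.data.dtype == bool:
        raise ValueError("resample boolean masks via resample_mask")
    if src.same_grid(target):
        return src.copy()
    coords = np.meshgrid(
        *[
            np.arange(n) * target.spacing[a] / src.spacing[a]
            for a, n in enumerate(target.shape)
        ],
        indexing="ij",
    )
    order = 0 if method == "nearest" else 1
    out = ndimage.map_coordinates(
        src.data, np.stack(coords), order=order, mode="nearest"
    )
    return VoxelVolume(out, target.spacing)


def resample_mask(mask: ROIMask, target: VoxelVolume, method: str = "nearest") -> ROIMask:
    """Resample a binary mask with nearest-neighbour interpolation only."""
    if method != "nearest":
        raise ValueError("masks must be resampled with method='nearest'")
    vol = VoxelVolume(mask.data.astype(np.float64), mask.spacing)
    out = resample_to_grid(vol, target, "nearest")
    return ROIMask(out.data > 0.5, target.spacing, mask.label)
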