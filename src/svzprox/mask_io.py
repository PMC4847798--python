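"""NIfTI mask volumes: reading, writing, and grid-compatibility checks.

All geometry in this package is computed on :class:`MaskVolume` objects —
integer-labeled 3-D arrays with a voxel-index → world-millimetre affine.
Voxel indices are 0-based; world coordinates are millimetres in the RAS
convention implied by the affine. Masks are treated as sets of voxel
*centers*; no sub-voxel surface is reconstructed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "MaskVolume",
    "MaskIOError",
    "EmptyMaskError",
    "LabelError",
    "GridMismatchError",
    "read_mask",
    "write_mask",
    "validate_pair",
]


class MaskIOError(ValueError):
    """A mask file could not be read or does not describe a valid volume."""


class EmptyMaskError(MaskIOError):
    """A mask has no foreground voxels."""


class LabelError(MaskIOError):
    """A mask contains label values outside the expected set."""


class GridMismatchError(ValueError):
    """Two masks do not live on the same voxel grid."""


@dataclass(frozen=True)
class MaskVolume:
    """A 3-D binary or integer-labeled volume with world-space metadata.

    Parameters
    ----------
    data
        3-D integer array; 0 is background, positive values are labels.
        A binary mask is the special case ``labels == {1}``.
    affine
        4x4 invertible matrix mapping homogeneous voxel indices ``(i,j,k,1)``
        to world millimetres.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise MaskIOError(f"mask must be 3-D, got shape {data.shape}")
        if not np.issubdtype(data.dtype, np.integer):
            if not np.allclose(data, np.round(data)):
                raise MaskIOError("mask values must be integers")
            data = np.round(data).astype(np.int16)
        if data.min() < 0:
            raise MaskIOError("mask values must be non-negative")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise MaskIOError("affine must be 4x4")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise MaskIOError("affine is not invertible")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", affine)
        if np.any(self.spacing <= 0):
            raise MaskIOError(f"voxel spacing must be positive, got {self.spacing}")

    # -- grid metadata -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing in mm along each index axis (affine column norms)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def labels(self) -> set[int]:
        vals = np.unique(self.data)
        return {int(v) for v in vals if v > 0}

    @property
    def is_binary(self) -> bool:
        return self.labels <= {1}

    # -- foreground access ---------------------------------------------

    @property
    def foreground_count(self) -> int:
        return int(np.count_nonzero(self.data))

    def foreground_indices(self) -> np.ndarray:
        """(n, 3) int array of foreground voxel indices, C-order sorted."""
        return np.argwhere(self.data > 0)

    def world_coordinates(self, indices: np.ndarray | None = None) -> np.ndarray:
        """World-mm coordinates of voxel centers.

        With no argument, returns coordinates of all foreground voxels.
        """
        if indices is None:
            indices = self.foreground_indices()
        indices = np.atleast_2d(np.asarray(indices, dtype=float))
        return indices @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Nearest voxel index for each world-mm point (may be out of bounds)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        inv = np.linalg.inv(self.affine)
        ijk = points @ inv[:3, :3].T + inv[:3, 3]
        return np.round(ijk).astype(int)

    def binarized(self) -> "MaskVolume":
        return MaskVolume((self.data > 0).astype(np.uint8), self.affine)


def read_mask(path: str | os.PathLike, expected_labels: set[int] | None = None) -> MaskVolume:
    """Read a NIfTI mask and validate its label content.

    Parameters
    ----------
    path
        ``.nii`` or ``.nii.gz`` file.
    expected_labels
        ``None`` or ``{1}`` selects binary mode: any strictly positive value
        is foreground (tolerant to 1-vs-255 dialects). Otherwise values must
        lie in ``expected_labels | {0}``.

    Raises
    ------
    FileNotFoundError, MaskIOError, EmptyMaskError, LabelError
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = nib.load(path)
        arr = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises a zoo of header errors
        raise MaskIOError(f"cannot read NIfTI volume {path!r}: {exc}") from exc
    arr = np.squeeze(arr)
    if arr.ndim != 3:
        raise MaskIOError(f"{path!r}: expected a 3-D volume, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise MaskIOError(f"{path!r}: non-finite voxel values")
    if expected_labels is None or expected_labels == {1}:
        if arr.min() < 0:
            raise LabelError(f"{path!r}: negative values in a binary mask")
        data = (arr > 0).astype(np.uint8)
    else:
        if not np.allclose(arr, np.round(arr)):
            raise LabelError(f"{path!r}: non-integer values in a labeled mask")
        data = np.round(arr).astype(np.int16)
        found = {int(v) for v in np.unique(data)}
        allowed = set(expected_labels) | {0}
        if not found <= allowed:
            raise LabelError(
                f"{path!r}: unexpected label values {sorted(found - allowed)}; "
                f"expected subset of {sorted(allowed)}"
            )
    mask = MaskVolume(data, np.asarray(img.affine))
    if mask.foreground_count == 0:
        raise EmptyMaskError(f"{path!r}: mask has no foreground voxels")
    return mask


def write_mask(mask: MaskVolume, path: str | os.PathLike) -> str:
    """Write a MaskVolume as NIfTI-1; round-trips through :func:`read_mask`."""
    path = os.fspath(path)
    dtype = np.uint8 if mask.data.max() < 256 else np.int16
    img = nib.Nifti1Image(mask.data.astype(dtype), mask.affine)
    img.set_qform(mask.affine, code=1)
    img.set_sform(mask.affine, code=1)
    try:
        nib.save(img, path)
    except Exception as exc:
        raise MaskIOError(f"cannot write {path!r}: {exc}") from exc
    return path


def validate_pair(
    tumor: MaskVolume, ventricle: MaskVolume, atol: float = 1e-6
) -> tuple[MaskVolume, MaskVolume]:
    """Check that two masks share shape, spacing, and affine.

    Returns the pair unchanged so calls can be inlined; raises
    :class:`GridMismatchError` naming the first differing attribute.
    """
    if tumor.shape != ventricle.shape:
        raise GridMismatchError(f"shape mismatch: {tumor.shape} vs {ventricle.shape}")
    if not np.allclose(tumor.spacing, ventricle.spacing, atol=atol):
        raise GridMismatchError(
            f"spacing mismatch: {tumor.spacing} vs {ventricle.spacing}"
        )
    if not np.allclose(tumor.affine, ventricle.affine, atol=atol):
        raise GridMismatchError("affine mismatch between tumor and ventricle masks")
    return tumor, ventricle
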