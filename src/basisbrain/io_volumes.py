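"""Volumetric I/O, masking, vectorization and intensity standardization.

Masked 3D volumes from a cohort of S subjects are reshaped into a V x S
data matrix Y whose column s holds subject s's voxel values in a fixed
linearization order. All spatial bookkeeping (affines, voxel sizes, the
mask's voxel order) lives here so downstream modules can work with plain
matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import (
    DegenerateDataError,
    DimensionError,
    GridMismatchError,
    InvalidMaskError,
    ParameterError,
)

#: sigma = FWHM / FWHM_TO_SIGMA converts a full-width-at-half-maximum to the
#: standard deviation of the corresponding Gaussian kernel.
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class VolumeGrid:
    """A 3D (or 4D) scalar image together with its voxel-to-world transform.

    Parameters
    ----------
    data
        3D array of voxel values, or 4D with frames stacked on the last axis.
    affine
        4x4 voxel-index-to-world (mm) transform; must be invertible.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise DimensionError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ParameterError("affine is singular")
        if self.data.ndim not in (3, 4):
            raise DimensionError(f"data must be 3D or 4D, got {self.data.ndim}D")

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])

    @property
    def n_frames(self) -> int:
        return 1 if self.data.ndim == 3 else self.data.shape[3]

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm along the three spatial axes."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def frames(self):
        """Iterate over 3D frames (a 3D volume yields itself once)."""
        if self.data.ndim == 3:
            yield self.data
        else:
            for t in range(self.data.shape[3]):
                yield self.data[..., t]


@dataclass
class Mask:
    """A binary region template on a fixed grid with a stable voxel order.

    The linearization order is ascending (x, y, z) voxel index with x
    fastest, which makes weight vectors comparable across runs.
    """

    indicator: np.ndarray
    affine: np.ndarray
    flat_indices: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.indicator = np.asarray(self.indicator).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.indicator.ndim != 3:
            raise DimensionError("mask indicator must be 3D")
        # x-fastest order == Fortran ravel order of the (x, y, z) array
        self.flat_indices = np.flatnonzero(self.indicator.ravel(order="F"))
        if self.flat_indices.size == 0:
            raise InvalidMaskError("mask selects no voxels")

    @property
    def V(self) -> int:
        return int(self.flat_indices.size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.indicator.shape)

    def voxel_ijk(self) -> np.ndarray:
        """(V, 3) integer voxel indices of the mask voxels in voxel order."""
        return np.stack(
            np.unravel_index(self.flat_indices, self.shape, order="F"), axis=1
        )

    def world_coords(self) -> np.ndarray:
        """(V, 3) world-space (mm) coordinates of mask voxel centres."""
        ijk = self.voxel_ijk()
        homog = np.c_[ijk, np.ones(len(ijk))]
        return (homog @ self.affine.T)[:, :3]

    def extract(self, frame: np.ndarray) -> np.ndarray:
        """Pull the masked voxels from one 3D frame in voxel order."""
        return frame.ravel(order="F")[self.flat_indices]


@dataclass
class DataMatrix:
    """V x S matrix Y of masked, vectorized images (one column per subject)."""

    values: np.ndarray
    subject_ids: list[str]
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionError("DataMatrix values must be 2D (V x S)")
        if len(self.subject_ids) != self.values.shape[1]:
            raise DimensionError(
                f"{len(self.subject_ids)} subject ids for "
                f"{self.values.shape[1]} columns"
            )

    @property
    def V(self) -> int:
        return self.values.shape[0]

    @property
    def S(self) -> int:
        return self.values.shape[1]


def _check_grid(volume: VolumeGrid, mask: Mask) -> None:
    if volume.shape3d != mask.shape:
        raise GridMismatchError(
            f"volume shape {volume.shape3d} != mask shape {mask.shape}"
        )
    if not np.allclose(volume.affine, mask.affine, atol=1e-6):
        raise GridMismatchError("volume affine differs from mask affine")


def vectorize_cohort(
    volumes: Sequence[VolumeGrid], mask: Mask, subject_ids: Sequence[str] | None = None
) -> DataMatrix:
    """Reshape masked volumes into the V x S data matrix Y.

    4D volumes contribute one column per frame.
    """
    columns: list[np.ndarray] = []
    ids: list[str] = []
    for i, vol in enumerate(volumes):
        _check_grid(vol, mask)
        for f, frame in enumerate(vol.frames()):
            columns.append(mask.extract(frame))
            base = subject_ids[i] if subject_ids is not None else f"sub-{i:04d}"
            ids.append(base if vol.n_frames == 1 else f"{base}_frame{f:03d}")
    if not columns:
        raise DimensionError("no volumes supplied")
    return DataMatrix(np.stack(columns, axis=1), ids)


def unmask(vector: np.ndarray, mask: Mask, fill: float = 0.0) -> VolumeGrid:
    """Scatter a length-V vector back into a 3D volume on the mask's grid."""
    vector = np.asarray(vector, dtype=float).ravel()
    if vector.size != mask.V:
        raise DimensionError(f"vector length {vector.size} != mask V {mask.V}")
    flat = np.full(int(np.prod(mask.shape)), fill, dtype=float)
    flat[mask.flat_indices] = vector
    return VolumeGrid(flat.reshape(mask.shape, order="F"), mask.affine)


def standardize(matrix: DataMatrix, tol: float = 1e-12) -> DataMatrix:
    """Standardize each subject's image to zero mean, unit SD.

    The SD convention is the population SD (divide by V). Constant columns
    are rejected because they carry no spatial signal to model.
    """
    Y = matrix.values
    mu = Y.mean(axis=0)
    sd = Y.std(axis=0)  # ddof=0: population SD
    bad = np.flatnonzero(sd < tol)
    if bad.size:
        names = ", ".join(matrix.subject_ids[i] for i in bad[:5])
        raise DegenerateDataError(f"constant image column(s) for subject(s): {names}")
    return DataMatrix((Y - mu) / sd, list(matrix.subject_ids), standardized=True)


def smooth_fwhm(volume: VolumeGrid, fwhm_mm: float) -> VolumeGrid:
    """Gaussian-smooth a volume with kernel width given as FWHM in mm.

    sigma_mm = fwhm / (2 sqrt(2 ln 2)) per axis, converted to voxel units
    through the grid's voxel size. Boundary mode is constant zero padding;
    images are re-masked afterwards in every pipeline that uses this.
    """
    if fwhm_mm < 0:
        raise ParameterError(f"fwhm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return VolumeGrid(volume.data.copy(), volume.affine)
    sigma_vox = (fwhm_mm / FWHM_TO_SIGMA) / volume.voxel_size
    if volume.data.ndim == 3:
        out = gaussian_filter(volume.data, sigma=sigma_vox, mode="constant", cval=0.0)
    else:
        out = np.stack(
            [
                gaussian_filter(f, sigma=sigma_vox, mode="constant", cval=0.0)
                for f in volume.frames()
            ],
            axis=-1,
        )
    return VolumeGrid(out, volume.affine)


# ---------------------------------------------------------------------------
# NIfTI round-trips


def load_volume(path: str | Path) -> VolumeGrid:
    img = nib.load(str(path))
    return VolumeGrid(np.asanyarray(img.dataobj, dtype=float), img.affine)


def save_volume(volume: VolumeGrid, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(volume.data.astype(np.float64), volume.affine), str(path))


def load_mask(path: str | Path) -> Mask:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.isin(np.unique(data), [0, 1]).all():
        raise InvalidMaskError("mask volume must be binary (0/1)")
    return Mask(data > 0, img.affine)


def save_mask(mask: Mask, path: str | Path) -> None:
    nib.save(
        nib.Nifti1Image(mask.indicator.astype(np.uint8), mask.affine), str(path)
    )
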