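"""Spatial basis-set construction and characterization.

A basis set is a V x M matrix Phi whose columns are fixed spatial maps over
the mask voxels; images are modelled as weighted sums of these columns.
Constructors provided here:

* multiscale tilings of compactly supported bisquare functions,
* probabilistic-atlas maps (any user-supplied non-negative volumes),

plus summaries used to compare basis sets: mean/SD absolute pairwise
spatial correlation and the normalized eigenspectrum.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

from .errors import (
    DimensionError,
    EmptyBasisError,
    ParameterError,
)
from .io_volumes import Mask, VolumeGrid, smooth_fwhm, unmask

#: default support radii (mm) of the three bisquare detail levels
DEFAULT_BISQUARE_RADII_MM = (6.0, 12.0, 18.0)

#: radius = RADIUS_SPACING_RATIO * centre spacing at each detail level
RADIUS_SPACING_RATIO = 1.5


@dataclass
class BasisSet:
    """V x M design matrix of spatial basis functions.

    Attributes
    ----------
    matrix
        V x M array; column m is basis function phi_m evaluated at the mask
        voxels (in the mask's voxel order).
    names
        Length-M labels.
    provenance
        One of {"bisquare", "atlas", "icp", "ica", "custom"}.
    level_of
        Optional per-column detail-level / model-order index.
    """

    matrix: np.ndarray
    names: list[str]
    provenance: str = "custom"
    level_of: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] < 1:
            raise DimensionError("basis matrix must be V x M with M >= 1")
        if not np.isfinite(self.matrix).all():
            raise DimensionError("basis matrix contains non-finite entries")
        if len(self.names) != self.M:
            raise DimensionError("names length != number of columns")
        if np.any(np.all(self.matrix == 0, axis=0)):
            raise EmptyBasisError("basis contains an all-zero column")
        if self.level_of is not None:
            self.level_of = np.asarray(self.level_of)
            if self.level_of.shape != (self.M,):
                raise DimensionError("level_of must have one entry per column")

    @property
    def V(self) -> int:
        return self.matrix.shape[0]

    @property
    def M(self) -> int:
        return self.matrix.shape[1]

    def select(self, columns: Sequence[int]) -> "BasisSet":
        cols = np.asarray(columns, dtype=int)
        return BasisSet(
            self.matrix[:, cols],
            [self.names[c] for c in cols],
            provenance=self.provenance,
            level_of=None if self.level_of is None else self.level_of[cols],
        )

    @staticmethod
    def concat(parts: Sequence["BasisSet"], provenance: str | None = None) -> "BasisSet":
        """Stack several basis sets column-wise into one multi-level set."""
        if not parts:
            raise EmptyBasisError("no basis sets to concatenate")
        V = parts[0].V
        if any(p.V != V for p in parts):
            raise DimensionError("basis sets live on different masks")
        levels = []
        for i, p in enumerate(parts):
            levels.append(p.level_of if p.level_of is not None else np.full(p.M, i))
        return BasisSet(
            np.concatenate([p.matrix for p in parts], axis=1),
            [n for p in parts for n in p.names],
            provenance=provenance or parts[0].provenance,
            level_of=np.concatenate(levels),
        )


@dataclass
class BisquareLevelSpec:
    """One detail level of a bisquare tiling.

    The support radius is tied to the centre spacing: r = 1.5 * spacing.
    Centres lie on a regular lattice covering the mask's bounding box
    expanded by one spacing per side; the lattice origin is that expanded
    minimum corner.
    """

    spacing_mm: float
    level: int = 0
    centers: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise ParameterError("spacing must be positive")

    @property
    def r_mm(self) -> float:
        return RADIUS_SPACING_RATIO * self.spacing_mm

    @classmethod
    def from_radius(cls, r_mm: float, level: int = 0) -> "BisquareLevelSpec":
        return cls(spacing_mm=r_mm / RADIUS_SPACING_RATIO, level=level)

    def candidate_centers(self, mask: Mask) -> np.ndarray:
        """All lattice centre points over the dilated mask bounding box."""
        coords = mask.world_coords()
        lo = coords.min(axis=0) - self.spacing_mm
        hi = coords.max(axis=0) + self.spacing_mm
        axes = [np.arange(lo[k], hi[k] + 1e-9, self.spacing_mm) for k in range(3)]
        grid = np.meshgrid(*axes, indexing="ij")
        return np.stack([g.ravel() for g in grid], axis=1)


def bisquare_value(x: np.ndarray, c: np.ndarray, r: float) -> np.ndarray:
    """Compactly supported bisquare radial function.

    [1 - (||x - c|| / r)^2]^2 for ||x - c|| <= r, else 0. Values lie in
    [0, 1] and vanish continuously at the support boundary.
    """
    if r <= 0:
        raise ParameterError("bisquare radius must be positive")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    d2 = ((x - np.asarray(c, dtype=float)) ** 2).sum(axis=1)
    u = 1.0 - d2 / (r * r)
    out = np.where(d2 <= r * r, u * u, 0.0)
    return out if out.size > 1 else float(out[0])


def tile_bisquare(mask: Mask, specs: Sequence[BisquareLevelSpec]) -> BasisSet:
    """Tile multi-resolution bisquare functions over the masked domain.

    At each detail level, lattice centres whose support contains no mask
    voxel (all basis values zero after masking) are dropped; the total
    M is the sum of retained centres over levels.
    """
    if not specs:
        raise ParameterError("at least one level spec required")
    coords = mask.world_coords()
    blocks: list[np.ndarray] = []
    names: list[str] = []
    levels: list[int] = []
    for spec in specs:
        centers = (
            spec.centers if spec.centers is not None else spec.candidate_centers(mask)
        )
        kept = 0
        for c in centers:
            col = bisquare_value(coords, c, spec.r_mm)
            col = np.atleast_1d(col)
            if np.any(col > 0):
                blocks.append(col)
                names.append(f"bisq_L{spec.level}_{kept:04d}")
                levels.append(spec.level)
                kept += 1
    if not blocks:
        raise EmptyBasisError("no bisquare centre overlaps the mask")
    return BasisSet(
        np.stack(blocks, axis=1), names, provenance="bisquare",
        level_of=np.asarray(levels),
    )


def default_bisquare_specs() -> list[BisquareLevelSpec]:
    """Three detail levels with support radii 6, 12 and 18 mm."""
    return [
        BisquareLevelSpec.from_radius(r, level=d)
        for d, r in enumerate(DEFAULT_BISQUARE_RADII_MM)
    ]


def atlas_to_basis(
    prob_volumes: Sequence[VolumeGrid],
    mask: Mask,
    names: Sequence[str] | None = None,
    strict: bool = False,
) -> BasisSet:
    """Build a basis set from probabilistic-atlas maps (one column per map)."""
    cols = []
    kept_names = []
    for i, vol in enumerate(prob_volumes):
        if np.any(vol.data < 0):
            raise ParameterError(f"probability map {i} has negative values")
        col = mask.extract(vol.data)
        name = names[i] if names is not None else f"atlas_{i:03d}"
        if not np.any(col != 0):
            if strict:
                raise EmptyBasisError(f"atlas map {name} is zero inside the mask")
            warnings.warn(f"dropping atlas map {name}: zero inside the mask")
            continue
        cols.append(col)
        kept_names.append(name)
    if not cols:
        raise EmptyBasisError("no atlas map overlaps the mask")
    return BasisSet(np.stack(cols, axis=1), kept_names, provenance="atlas")


def correlation_summary(basis: BasisSet) -> tuple[float, float]:
    """Mean and SD of absolute pairwise spatial correlations between columns."""
    if basis.M < 2:
        raise DimensionError("correlation summary needs at least 2 columns")
    C = np.corrcoef(basis.matrix, rowvar=False)
    iu = np.triu_indices(basis.M, k=1)
    vals = np.abs(C[iu])
    return float(vals.mean()), float(vals.std())


def eigenspectrum(basis: BasisSet) -> np.ndarray:
    """Normalized eigenvalue spectrum of the basis Gram structure.

    Eigenvalues are the squared singular values of the column-centred
    matrix, sorted descending and normalized to sum to one; a flatter
    spectrum indicates higher intrinsic dimensionality.
    """
    X = basis.matrix - basis.matrix.mean(axis=0)
    s = np.linalg.svd(X, compute_uv=False)
    lam = np.zeros(basis.M)
    lam[: s.size] = s**2
    total = lam.sum()
    if total == 0:
        raise EmptyBasisError("basis has zero variance in all columns")
    return np.sort(lam)[::-1] / total


def smooth_basis(basis: BasisSet, mask: Mask, fwhm_mm: float) -> BasisSet:
    """Smooth each column in volume space (emulating a scanner PSF).

    Columns are unmasked onto the grid, Gaussian-smoothed, and re-masked;
    columns that become all-zero are dropped with a warning.
    """
    if fwhm_mm == 0:
        return BasisSet(
            basis.matrix.copy(), list(basis.names), basis.provenance, basis.level_of
        )
    cols, names, levels = [], [], []
    for m in range(basis.M):
        vol = unmask(basis.matrix[:, m], mask, fill=0.0)
        col = mask.extract(smooth_fwhm(vol, fwhm_mm).data)
        if not np.any(col != 0):
            warnings.warn(f"dropping basis column {basis.names[m]} after smoothing")
            continue
        cols.append(col)
        names.append(basis.names[m])
        if basis.level_of is not None:
            levels.append(basis.level_of[m])
    if not cols:
        raise EmptyBasisError("smoothing removed every basis column")
    return BasisSet(
        np.stack(cols, axis=1),
        names,
        provenance=basis.provenance,
        level_of=np.asarray(levels) if levels else None,
    )


# ---------------------------------------------------------------------------
# persistence: 4D NIfTI (one frame per basis function) + JSON sidecar


def save_basis(basis: BasisSet, mask: Mask, path: str | Path) -> None:
    path = Path(path)
    frames = np.stack(
        [unmask(basis.matrix[:, m], mask, fill=0.0).data for m in range(basis.M)],
        axis=-1,
    )
    nib.save(nib.Nifti1Image(frames, mask.affine), str(path))
    sidecar = {
        "names": list(basis.names),
        "provenance": basis.provenance,
        "level_of": None
        if basis.level_of is None
        else [int(v) for v in basis.level_of],
    }
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_basis(path: str | Path, mask: Mask) -> BasisSet:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    cols = np.stack([mask.extract(data[..., m]) for m in range(data.shape[-1])], axis=1)
    sidecar_path = path.with_suffix("").with_suffix(".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        level = meta["level_of"]
        return BasisSet(
            cols,
            meta["names"],
            provenance=meta["provenance"],
            level_of=None if level is None else np.asarray(level),
        )
    return BasisSet(cols, [f"basis_{m:04d}" for m in range(cols.shape[1])])
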