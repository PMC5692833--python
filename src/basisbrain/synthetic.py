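"""Synthetic cohorts, timeseries and two-class data from the generative model.

Everything here is a pure function of its arguments and a seed, so tests
and pipelines can regenerate inputs exactly. Cohorts follow the model the
inference modules assume: per-subject weights drawn from N(0, Sigma_alpha),
images Phi w_s plus isotropic Gaussian noise of precision beta. The 4D
timeseries generator plants temporally coherent subnetworks (parcels with
shared smooth latent timecourses) for the parcellation pipeline to recover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.ndimage import gaussian_filter1d

from .basis import BasisSet
from .errors import DimensionError, ParameterError
from .icp import TimeseriesSet
from .io_volumes import DataMatrix, Mask


@dataclass
class SimulationTruth:
    """Ground-truth record for recovery assertions."""

    W_true: np.ndarray
    beta_true: float
    Sigma_alpha_true: np.ndarray
    seed: int
    labels_true: np.ndarray | None = None


def simulate_cohort(
    basis: BasisSet,
    Sigma_alpha: np.ndarray,
    beta: float,
    S: int,
    seed: int,
    mean_W: np.ndarray | None = None,
) -> tuple[DataMatrix, SimulationTruth]:
    """Draw S subjects from the hierarchical linear model.

    w_s ~ N(mean_W, Sigma_alpha) i.i.d.; y_s = Phi w_s + eps_s with
    eps_s ~ N(0, beta^{-1} I). ``beta = np.inf`` gives noise-free images.
    """
    if S < 1:
        raise ParameterError("need at least one subject")
    if beta <= 0:
        raise ParameterError("beta must be positive (np.inf for noise-free)")
    Sigma_alpha = np.asarray(Sigma_alpha, dtype=float)
    M = basis.M
    if Sigma_alpha.shape != (M, M):
        raise DimensionError("Sigma_alpha must be M x M")
    try:
        L = linalg.cholesky(0.5 * (Sigma_alpha + Sigma_alpha.T), lower=True)
    except linalg.LinAlgError:
        raise ParameterError("Sigma_alpha must be positive definite")
    rng = np.random.default_rng(seed)
    W = L @ rng.standard_normal((M, S))
    if mean_W is not None:
        W = W + np.asarray(mean_W, dtype=float).reshape(M, 1)
    Y = basis.matrix @ W
    if np.isfinite(beta):
        Y = Y + rng.standard_normal(Y.shape) / np.sqrt(beta)
    data = DataMatrix(Y, [f"sim-{s:04d}" for s in range(S)])
    return data, SimulationTruth(
        W_true=W, beta_true=float(beta), Sigma_alpha_true=Sigma_alpha, seed=int(seed)
    )


def simulate_timeseries(
    parcels: np.ndarray,
    T: int,
    noise_sd: float,
    seed: int,
    smooth_len: float = 3.0,
    normalized: bool = False,
) -> TimeseriesSet:
    """4D-style timeseries with planted subnetworks.

    Each of the K parcels (columns of the non-negative V x K map matrix)
    receives an independent band-limited latent timecourse (Gaussian white
    noise smoothed over ``smooth_len`` frames, then normalized); voxel
    series are the parcel-weighted mixture plus white noise.
    """
    parcels = np.asarray(parcels, dtype=float)
    if parcels.ndim != 2 or parcels.shape[1] < 2:
        raise ParameterError("parcels must be V x K with K >= 2")
    if np.any(parcels < 0):
        raise ParameterError("parcel maps must be non-negative")
    if np.any(np.all(parcels == 0, axis=0)):
        raise ParameterError("degenerate (all-zero) parcel map")
    K = parcels.shape[1]
    if T < 2 * K:
        raise ParameterError(f"need T >= 2K = {2 * K}")
    rng = np.random.default_rng(seed)
    latents = gaussian_filter1d(
        rng.standard_normal((K, T)), sigma=smooth_len, axis=1, mode="wrap"
    )
    latents = (latents - latents.mean(axis=1, keepdims=True)) / latents.std(
        axis=1, keepdims=True
    )
    series = parcels @ latents
    if noise_sd > 0:
        series = series + noise_sd * rng.standard_normal(series.shape)
    ts = TimeseriesSet(series, normalized=False)
    if normalized:
        from .icp import normalize

        ts = normalize(ts)
    return ts


def simulate_two_class(
    basis: BasisSet,
    effect_map: np.ndarray,
    sizes: tuple[int, int],
    beta: float,
    seed: int,
    Sigma_alpha: np.ndarray | None = None,
) -> tuple[DataMatrix, np.ndarray, SimulationTruth]:
    """Two-class cohort with a planted mean shift in weight space.

    Class 0 weights are N(0, Sigma_alpha); class 1 weights are shifted by
    ``effect_map``. Returns (data, labels, truth) with subjects ordered
    class 0 first.
    """
    n0, n1 = sizes
    if n0 < 1 or n1 < 1:
        raise ParameterError("both class sizes must be >= 1")
    M = basis.M
    Sigma_alpha = np.eye(M) if Sigma_alpha is None else np.asarray(Sigma_alpha)
    effect = np.asarray(effect_map, dtype=float).reshape(M)
    children = np.random.SeedSequence(int(seed)).spawn(2)
    seed0 = int(children[0].generate_state(1)[0] % (2**31 - 1))
    seed1 = int(children[1].generate_state(1)[0] % (2**31 - 1))
    data0, truth0 = simulate_cohort(basis, Sigma_alpha, beta, n0, seed0)
    data1, truth1 = simulate_cohort(
        basis, Sigma_alpha, beta, n1, seed1, mean_W=effect
    )
    Y = np.concatenate([data0.values, data1.values], axis=1)
    ids = [f"c0-{s:04d}" for s in range(n0)] + [f"c1-{s:04d}" for s in range(n1)]
    labels = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    truth = SimulationTruth(
        W_true=np.concatenate([truth0.W_true, truth1.W_true], axis=1),
        beta_true=float(beta),
        Sigma_alpha_true=Sigma_alpha,
        seed=int(seed),
        labels_true=labels,
    )
    return DataMatrix(Y, ids), labels, truth


def two_lobe_mask(
    shape: tuple[int, int, int] = (12, 12, 8), voxel_mm: float = 2.0
) -> Mask:
    """Toy two-lobed "pseudo-striatum" mask on a small box grid.

    Two overlapping ellipsoids mimic a bilateral pair of nuclei; generated
    programmatically so no mask file ships with the package.
    """
    nx, ny, nz = shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    centers = [
        (nx * 0.3, ny * 0.5, nz * 0.5),
        (nx * 0.7, ny * 0.5, nz * 0.5),
    ]
    radii = (nx * 0.22, ny * 0.32, nz * 0.38)
    ind = np.zeros(shape, dtype=bool)
    for cx, cy, cz in centers:
        d = (
            ((ii - cx) / radii[0]) ** 2
            + ((jj - cy) / radii[1]) ** 2
            + ((kk - cz) / radii[2]) ** 2
        )
        ind |= d <= 1.0
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    return Mask(ind, affine)


def random_smooth_basis(
    mask: Mask, M: int, seed: int, fwhm_mm: float = 6.0
) -> BasisSet:
    """Random spatially smooth basis columns on a mask (test scaffolding)."""
    from .basis import BasisSet as _BS
    from .io_volumes import smooth_fwhm, unmask

    rng = np.random.default_rng(seed)
    cols = []
    for m in range(M):
        vol = unmask(rng.standard_normal(mask.V), mask, fill=0.0)
        sm = smooth_fwhm(vol, fwhm_mm)
        col = mask.extract(sm.data)
        col = col / max(np.abs(col).max(), 1e-12)
        cols.append(col)
    return _BS(
        np.stack(cols, axis=1),
        [f"rand_{m:03d}" for m in range(M)],
        provenance="custom",
    )
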