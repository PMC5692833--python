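"""Instantaneous-connectivity parcellation (ICP) basis construction.

A region's 4D timeseries is sub-divided into soft, possibly overlapping
parcels by (i) temporally "unfolding" each voxel's Pearson correlation with
the regional grand-mean reference timecourse into its element-wise product
series, (ii) decomposing the resulting V x T matrix with spatial ICA at a
sequence of model orders d = 2..D, and (iii) converting each spatial mode
into a non-negative confidence map. Concatenating the confidence maps over
orders yields a multiscale basis set with sum(d) columns.

For normalized timecourses a, b of length T the Pearson correlation is
rho = (1/T) * sum_t a_t b_t, so the row mean of the unfolded product matrix
recovers rho exactly; the unfolding simply declines to average over time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .basis import BasisSet
from .errors import ConvergenceError, DegenerateDataError, ParameterError

#: rows with SD below this are treated as constant (zeroed, excluded from
#: the reference mean)
CONSTANT_SD_TOL = 1e-12


@dataclass
class TimeseriesSet:
    """V x T matrix of per-voxel timecourses."""

    series: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2:
            raise ParameterError("timeseries must be a V x T matrix")

    @property
    def V(self) -> int:
        return self.series.shape[0]

    @property
    def T(self) -> int:
        return self.series.shape[1]


@dataclass
class UnfoldedMatrix:
    """Element-wise products of each voxel timecourse with the reference.

    The row mean of ``products`` equals the voxel's Pearson correlation
    with the reference (exact algebraic identity for normalized rows).
    """

    products: np.ndarray
    reference: np.ndarray


def _normalize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Zero-mean, unit-SD rows (population SD); returns (normed, ok_mask)."""
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    ok = (sd > CONSTANT_SD_TOL).ravel()
    out = np.zeros_like(X)
    out[ok] = (X[ok] - mu[ok]) / sd[ok]
    return out, ok


def normalize(ts: TimeseriesSet, strict: bool = False) -> TimeseriesSet:
    """Normalize each voxel timecourse to zero mean and unit SD.

    Constant rows are zeroed (or rejected under ``strict``).
    """
    normed, ok = _normalize_rows(ts.series)
    if strict and not ok.all():
        raise DegenerateDataError(
            f"{(~ok).sum()} constant voxel timecourse(s) in strict mode"
        )
    return TimeseriesSet(normed, normalized=True)


def unfold(ts: TimeseriesSet, strict: bool = False) -> UnfoldedMatrix:
    """Temporally unfold voxel-to-reference connectivity.

    The reference is the grand-mean timecourse over (non-constant) voxels
    of the row-normalized data, itself normalized; the output row for voxel
    v is the Hadamard product of v's normalized timecourse with the
    reference.
    """
    if ts.T < 2:
        raise ParameterError("need at least 2 timepoints")
    normed = ts if ts.normalized else normalize(ts, strict=strict)
    ok = np.abs(normed.series).max(axis=1) > 0
    if not ok.any():
        raise DegenerateDataError("all voxel timecourses are constant")
    reference = normed.series[ok].mean(axis=0)
    ref_sd = reference.std()
    if ref_sd < CONSTANT_SD_TOL:
        raise DegenerateDataError("grand-mean reference timecourse is constant")
    reference = (reference - reference.mean()) / ref_sd
    return UnfoldedMatrix(normed.series * reference[None, :], reference)


def row_correlations(unfolded: UnfoldedMatrix) -> np.ndarray:
    """Per-voxel Pearson correlation with the reference (= row means)."""
    return unfolded.products.mean(axis=1)


def decompose_order(
    unfolded: UnfoldedMatrix, order: int, seed: int, max_retries: int = 5
) -> np.ndarray:
    """Spatial ICA of the unfolded matrix at one model order.

    Returns a V x order array of spatial maps (unit variance), each
    sign-aligned so its maximum-magnitude voxel is positive. Deterministic
    given ``seed``; non-convergence triggers documented reseeded retries
    before raising.
    """
    return _spatial_ica(unfolded.products, order, seed, max_retries)


def _spatial_ica(
    X: np.ndarray, order: int, seed: int, max_retries: int = 5
) -> np.ndarray:
    V, T = X.shape
    if not (2 <= order <= min(V, T)):
        raise ParameterError(
            f"order must be in [2, min(V, T)] = [2, {min(V, T)}], got {order}"
        )
    last_err: Exception | None = None
    # retries reseed the unmixing init and progressively relax the
    # fixed-point tolerance: orders above the data's effective rank
    # otherwise stall on noise directions
    for attempt in range(max_retries):
        ica = FastICA(
            n_components=order,
            random_state=int(seed) + 7919 * attempt,
            whiten="unit-variance",
            max_iter=2000,
            tol=1e-5 * 10.0**attempt,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                maps = ica.fit_transform(X)  # voxels are samples: spatial ICA
            except ConvergenceWarning as err:  # retry with a shifted seed
                last_err = err
                continue
        return _sign_align(maps)
    raise ConvergenceError(
        f"FastICA failed to converge at order {order} after {max_retries} "
        f"restarts: {last_err}"
    )


def _sign_align(maps: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    out = maps.copy()
    for k in range(out.shape[1]):
        peak = np.argmax(np.abs(out[:, k]))
        if out[peak, k] < 0:
            out[:, k] = -out[:, k]
    return out


def confidence_maps(maps: np.ndarray, method: str = "mixture") -> np.ndarray:
    """Soft-assignment confidences from spatial-mode maps.

    Each map is z-scored and converted to a non-negative confidence that is
    monotone in |z|:

    * ``mixture`` (default): fit a zero-mean two-component Gaussian scale
      mixture (small-variance null + large-variance alternative) by EM and
      return the alternative/null responsibility ratio. The ratio of two
      zero-mean Gaussian densities with sigma_alt > sigma_null is monotone
      increasing in |z| by construction.
    * ``abs``: plain rectified z, |z|.
    """
    maps = np.asarray(maps, dtype=float)
    if not np.isfinite(maps).all():
        raise ParameterError("maps must be finite")
    out = np.zeros_like(maps)
    for k in range(maps.shape[1]):
        col = maps[:, k]
        sd = col.std()
        if sd < CONSTANT_SD_TOL:
            continue  # all-zero map -> uniform minimal confidence 0
        z = (col - col.mean()) / sd
        if method == "abs":
            out[:, k] = np.abs(z)
        elif method == "mixture":
            out[:, k] = _scale_mixture_ratio(z)
        else:
            raise ParameterError(f"unknown confidence method {method!r}")
    return out


def _scale_mixture_ratio(z: np.ndarray, n_iter: int = 200, tol: float = 1e-9):
    """EM fit of pi0*N(0,s0^2) + pi1*N(0,s1^2), s0 < s1; returns the
    responsibility ratio pi1*N1 / (pi0*N0), clipped at zero."""
    s0, s1 = 0.7, 2.0
    pi1 = 0.2
    z2 = z**2
    for _ in range(n_iter):
        logp0 = np.log1p(-pi1) - 0.5 * z2 / s0**2 - np.log(s0)
        logp1 = np.log(pi1) - 0.5 * z2 / s1**2 - np.log(s1)
        m = np.maximum(logp0, logp1)
        r1 = np.exp(logp1 - m) / (np.exp(logp0 - m) + np.exp(logp1 - m))
        pi1_new = float(np.clip(r1.mean(), 1e-6, 1 - 1e-6))
        s0_new = float(np.sqrt(((1 - r1) * z2).sum() / max((1 - r1).sum(), 1e-12)))
        s1_new = float(np.sqrt((r1 * z2).sum() / max(r1.sum(), 1e-12)))
        s0_new = max(s0_new, 1e-6)
        s1_new = max(s1_new, s0_new * (1 + 1e-6))  # keep alternative wider
        moved = abs(s0_new - s0) + abs(s1_new - s1) + abs(pi1_new - pi1)
        s0, s1, pi1 = s0_new, s1_new, pi1_new
        if moved < tol:
            break
    if s1 - s0 < 1e-4:  # mixture collapsed; fall back to rectified z
        return np.abs(z)
    log_ratio = (
        np.log(pi1)
        - np.log1p(-pi1)
        + np.log(s0)
        - np.log(s1)
        + 0.5 * z2 * (1.0 / s0**2 - 1.0 / s1**2)
    )
    return np.exp(np.clip(log_ratio, -700, 700))


def planned_basis_count(orders: Iterable[int]) -> int:
    """Column count of a multiscale basis before any degenerate dropping.

    Each model order d contributes d confidence maps, so the total is the
    arithmetic sum of the requested orders.
    """
    return int(sum(orders))


def multiscale_basis(
    ts: TimeseriesSet,
    orders: Iterable[int],
    seed: int,
    confidence: str = "mixture",
) -> BasisSet:
    """Multiscale soft-parcellation basis from repeated decompositions.

    Decomposes the unfolded timeseries at every requested model order and
    concatenates the confidence maps; ``level_of`` records the model order
    of each column. Reproducible bit-for-bit under a fixed seed (per-order
    child seeds are derived deterministically).
    """
    orders = list(orders)
    if not orders:
        raise ParameterError("no model orders requested")
    unfolded = unfold(ts)
    children = np.random.SeedSequence(int(seed)).spawn(len(orders))
    cols, names, levels = [], [], []
    for d, child in zip(orders, children):
        child_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        maps = decompose_order(unfolded, d, seed=child_seed)
        conf = confidence_maps(maps, method=confidence)
        for k in range(d):
            col = conf[:, k]
            if not np.any(col != 0):
                warnings.warn(f"dropping degenerate ICP map (order {d}, comp {k})")
                continue
            cols.append(col)
            names.append(f"icp_d{d:02d}_{k:02d}")
            levels.append(d)
    if not cols:
        raise DegenerateDataError("all ICP confidence maps were degenerate")
    return BasisSet(
        np.stack(cols, axis=1), names, provenance="icp", level_of=np.asarray(levels)
    )


def single_scale_basis(
    ts: TimeseriesSet, order: int, seed: int, confidence: str = "mixture"
) -> BasisSet:
    """ICA-style basis: one spatial ICA of the normalized timeseries at a
    fixed (typically high) model order, without the unfolding step."""
    normed = ts if ts.normalized else normalize(ts)
    maps = _spatial_ica(normed.series, order, seed=seed)
    conf = confidence_maps(maps, method=confidence)
    return BasisSet(
        conf,
        [f"ica_{k:03d}" for k in range(order)],
        provenance="ica",
        level_of=np.full(order, order),
    )
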