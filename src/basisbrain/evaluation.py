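"""Model assessment: explained variance, spatial-subsampling CV, ARD
relevance ranking, complexity/accuracy curves, structure coefficients and
split reproducibility.

Because the modelling target is spatial interpolation, cross-validation
subsamples *voxels* rather than subjects: the model is refit on a random
fraction of mask voxels and scored on the held-out remainder.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .ard_regression import (
    Hyperparameters,
    fit_empirical_bayes,
)
from .basis import BasisSet
from .errors import DegenerateDataError, DimensionError, ParameterError
from .gibbs import PosteriorSamples, PriorSpec, run_chain
from .io_volumes import DataMatrix

Engine = Literal["eb", "fb"]


@dataclass
class RelevanceRanking:
    """Basis functions ordered by ARD relevance.

    ``scores`` are normalized prior variances 1/alpha_m (max exactly 1):
    under ARD a large precision prunes a basis function, so large prior
    variance means relevant. ``alpha_ratio`` additionally reports the
    normalized |alpha_m| / alpha_max, the complementary convention some
    relevance displays use; both are surfaced because the two conventions
    coexist in the literature. Ties break by ascending column index.
    """

    order: np.ndarray
    scores: np.ndarray
    alpha_ratio: np.ndarray


@dataclass
class ComplexityCurve:
    """Mean +/- SD explained variance across subjects per model order M'."""

    model_orders: list[int]
    ev_mean: np.ndarray
    ev_sd: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model_order": self.model_orders,
                "ev_mean": self.ev_mean,
                "ev_sd": self.ev_sd,
            }
        )


def explained_variance(y: np.ndarray, y_hat: np.ndarray) -> float:
    """EV = 1 - SS_res / SS_tot; can be negative out of sample."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size != y_hat.size:
        raise DimensionError("y and y_hat lengths differ")
    if y.size < 2:
        raise ParameterError("need at least 2 observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 0:
        raise DegenerateDataError("constant target: explained variance undefined")
    ss_res = float(np.sum((y - y_hat) ** 2))
    return 1.0 - ss_res / ss_tot


def _fit_weights(
    basis: BasisSet,
    data: DataMatrix,
    engine: Engine,
    seed: int,
    engine_opts: dict | None,
) -> np.ndarray:
    """Fit the chosen engine and return posterior-mean weights (M x S)."""
    opts = dict(engine_opts or {})
    if engine == "eb":
        _, post, _ = fit_empirical_bayes(basis, data, **opts)
        return post.W_bar
    if engine == "fb":
        opts.setdefault("n_burn", 200)
        opts.setdefault("n_samples", 1000)
        samples, _ = run_chain(
            basis, data, prior=opts.pop("prior", None), seed=seed, **opts
        )
        return samples.pooled()[0].mean(axis=0)
    raise ParameterError(f"unknown engine {engine!r}")


def spatial_subsample_cv(
    basis: BasisSet,
    data: DataMatrix,
    fractions: Sequence[float] = (0.1, 0.2, 0.5),
    repeats: int = 10,
    engine: Engine = "eb",
    seed: int = 0,
    engine_opts: dict | None = None,
) -> pd.DataFrame:
    """Spatial-subsampling cross-validation.

    For each training fraction and repeat, a uniformly random voxel subset
    trains the model (hyperparameters refit within the split; no held-out
    leakage) and the complementary voxels score it. Fraction 1.0 degrades
    gracefully to in-sample evaluation. Returns a long-format table with
    columns (fraction, repeat, subject, ev).
    """
    if repeats < 1:
        raise ParameterError("repeats must be >= 1")
    if any(not (0 < f <= 1) for f in fractions):
        raise ParameterError("fractions must lie in (0, 1]")
    V = data.V
    rng = np.random.default_rng(seed)
    rows = []
    for frac in fractions:
        for rep in range(repeats):
            if frac >= 1.0:
                train = np.arange(V)
                test = np.arange(V)
            else:
                n_train = max(int(round(frac * V)), 2)
                perm = rng.permutation(V)
                train, test = perm[:n_train], perm[n_train:]
            sub_basis = BasisSet(
                basis.matrix[train], list(basis.names), basis.provenance, basis.level_of
            )
            sub_data = DataMatrix(
                data.values[train], list(data.subject_ids), data.standardized
            )
            W = _fit_weights(
                sub_basis, sub_data, engine, seed=seed + 1000 * rep, engine_opts=engine_opts
            )
            Y_hat = basis.matrix[test] @ W
            for s in range(data.S):
                rows.append(
                    {
                        "fraction": frac,
                        "repeat": rep,
                        "subject": data.subject_ids[s],
                        "ev": explained_variance(data.values[test, s], Y_hat[:, s]),
                    }
                )
    return pd.DataFrame(rows)


def rank_by_relevance(
    fitted: Hyperparameters | PosteriorSamples,
) -> RelevanceRanking:
    """Order basis functions by ARD relevance.

    Empirical Bayes: relevance = prior variance 1/alpha_m. Full Bayes:
    relevance = posterior mean of the diagonal of Sigma_alpha =
    Lambda_alpha^{-1}. Scores are normalized to max 1.
    """
    if isinstance(fitted, Hyperparameters):
        variance = 1.0 / fitted.alpha
        alpha_abs = np.abs(fitted.alpha)
    elif isinstance(fitted, PosteriorSamples):
        Lam = fitted.pooled()[2]
        Sigma_diag = np.mean(
            np.stack([np.diag(np.linalg.inv(L)) for L in Lam]), axis=0
        )
        variance = Sigma_diag
        alpha_abs = np.abs(np.mean(np.stack([np.diag(L) for L in Lam]), axis=0))
    else:
        raise ParameterError("expected Hyperparameters or PosteriorSamples")
    scores = variance / variance.max()
    # stable sort descending with ascending-index tie-break
    order = np.lexsort((np.arange(scores.size), -scores))
    return RelevanceRanking(
        order=order, scores=scores, alpha_ratio=alpha_abs / alpha_abs.max()
    )


def complexity_curve(
    basis: BasisSet,
    data: DataMatrix,
    ranking: RelevanceRanking,
    model_orders: Sequence[int],
    engine: Engine = "eb",
    seed: int = 0,
    engine_opts: dict | None = None,
) -> ComplexityCurve:
    """Accuracy/complexity tradeoff: refit with the top-M' relevant columns.

    For each requested M' the model is refit using only the M' most
    relevant basis functions and the in-sample explained variance is
    summarized across subjects (mean +/- SD).
    """
    orders = sorted(int(m) for m in model_orders)
    if not orders or orders[0] < 1:
        raise ParameterError("model orders must be positive")
    if orders[-1] > basis.M:
        raise ParameterError(f"model order {orders[-1]} exceeds M={basis.M}")
    means, sds = [], []
    for m_prime in orders:
        sub = basis.select(ranking.order[:m_prime])
        W = _fit_weights(sub, data, engine, seed=seed, engine_opts=engine_opts)
        Y_hat = sub.matrix @ W
        evs = [
            explained_variance(data.values[:, s], Y_hat[:, s]) for s in range(data.S)
        ]
        means.append(np.mean(evs))
        sds.append(np.std(evs))
    return ComplexityCurve(
        model_orders=orders, ev_mean=np.asarray(means), ev_sd=np.asarray(sds)
    )


def structure_coefficients(basis: BasisSet, Y_hat: np.ndarray) -> np.ndarray:
    """Univariate correlations between each basis column and each subject's
    fitted values; the standard interpretation aid under collinearity.

    Entry (m, s) is the Pearson correlation of phi_m with y_hat_s over the
    mask. Zero-variance columns or predictions yield NaN entries.
    """
    Y_hat = np.asarray(Y_hat, dtype=float)
    if Y_hat.shape[0] != basis.V:
        raise DimensionError("Y_hat rows must equal basis V")
    Phi_c = basis.matrix - basis.matrix.mean(axis=0)
    H_c = Y_hat - Y_hat.mean(axis=0)
    phi_sd = np.sqrt((Phi_c**2).sum(axis=0))
    h_sd = np.sqrt((H_c**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (Phi_c.T @ H_c) / np.outer(phi_sd, h_sd)
    out[~np.isfinite(out)] = np.nan
    return out


def split_reproducibility(
    basis: BasisSet,
    data: DataMatrix,
    engine: Engine = "eb",
    seed: int = 0,
    engine_opts: dict | None = None,
) -> float:
    """Correlation of per-basis mean weights across two random subject halves.

    High r indicates the fitted coefficients reflect stable signal rather
    than suppressor effects or split-specific noise.
    """
    if data.S < 4:
        raise ParameterError("split reproducibility needs S >= 4")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(data.S)
    half = data.S // 2
    means = []
    for idx in (perm[:half], perm[half : 2 * half]):
        sub = DataMatrix(
            data.values[:, idx],
            [data.subject_ids[i] for i in idx],
            data.standardized,
        )
        W = _fit_weights(basis, sub, engine, seed=seed, engine_opts=engine_opts)
        means.append(W.mean(axis=1))
    return float(np.corrcoef(means[0], means[1])[0, 1])
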