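"""Bayesian probit regression with ARD priors, fitted by expectation
propagation (EP).

Model: binary labels t_s in {0, 1} for S' subjects with feature vectors
w_s (typically the spatial-model weights), likelihood

    p(t | z) = prod_s H(z^T w_s)^{t_s} (1 - H(z^T w_s))^{1 - t_s},

H the standard-normal CDF, and prior z ~ N(0, Lambda_z^{-1}) with diagonal
ARD precision Lambda_z. The posterior over z is non-Gaussian; EP builds a
Gaussian approximation from per-subject "site" factors over the latent
values f_s = z^T w_s (the model is a linear-kernel Gaussian process, so
standard GP-classification EP applies with K = X Lambda_z^{-1} X^T).

The EP evidence approximation is used to choose the ARD precisions by
coordinate fixed-point (EM-style) updates; a pure isotropic-prior mode is
also available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.special import log_ndtr, ndtr
from scipy.stats import norm
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .errors import (
    ConvergenceError,
    DegenerateDataError,
    DimensionError,
    ParameterError,
)

#: site-precision floor guards against negative/zero EP variances
TAU_FLOOR = 1e-10

#: damping weight applied to new site parameters (stabilizes updates)
EP_DAMPING = 0.8


@dataclass
class LabeledFeatures:
    """S' x M feature matrix (rows = subjects' weight vectors) + binary labels."""

    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels).astype(int)
        if self.features.ndim != 2:
            raise DimensionError("features must be 2D (subjects x features)")
        if self.labels.shape != (self.features.shape[0],):
            raise DimensionError("labels length != number of feature rows")
        if not np.isin(self.labels, [0, 1]).all():
            raise ParameterError("labels must be binary 0/1")
        if len(np.unique(self.labels)) < 2:
            raise DegenerateDataError("both classes must be present")
        if not np.isfinite(self.features).all():
            raise ParameterError("features contain non-finite values")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def M(self) -> int:
        return self.features.shape[1]


@dataclass
class ClassifierModel:
    """EP Gaussian posterior over the classification coefficients z."""

    z_mean: np.ndarray
    z_cov: np.ndarray
    Lambda_z: np.ndarray  # diagonal entries
    log_evidence: float
    converged: bool = True
    n_sweeps: int = 0


@dataclass
class _EPState:
    nu: np.ndarray  # site natural means  nu_i = tau_i * mu_i
    tau: np.ndarray  # site precisions
    mu_f: np.ndarray  # posterior marginal means of f
    sigma2_f: np.ndarray  # posterior marginal variances of f
    Sigma_f: np.ndarray  # full posterior covariance of f


def _posterior_f(K: np.ndarray, nu: np.ndarray, tau: np.ndarray):
    """Posterior over the latent f given Gaussian sites (natural params)."""
    n = K.shape[0]
    sqrt_tau = np.sqrt(np.maximum(tau, 0.0))
    B = np.eye(n) + sqrt_tau[:, None] * K * sqrt_tau[None, :]
    L = linalg.cholesky(B, lower=True)
    # Sigma = K - K S^{1/2} B^{-1} S^{1/2} K  (stable form)
    VK = linalg.solve_triangular(L, sqrt_tau[:, None] * K, lower=True)
    Sigma = K - VK.T @ VK
    mu = Sigma @ nu
    return mu, Sigma, L


def _probit_moments(y: float, mu_c: float, s2_c: float):
    """Zeroth/first/second moments of N(f|mu_c, s2_c) * H(y f)."""
    denom = np.sqrt(1.0 + s2_c)
    zi = y * mu_c / denom
    log_Z = log_ndtr(zi)
    ratio = np.exp(norm.logpdf(zi) - log_Z)  # N(zi)/Phi(zi), stable
    mu_hat = mu_c + y * s2_c * ratio / denom
    s2_hat = s2_c - s2_c**2 * ratio * (zi + ratio) / (1.0 + s2_c)
    return log_Z, mu_hat, max(s2_hat, TAU_FLOOR)


def ep_fit(
    data: LabeledFeatures,
    Lambda_z: np.ndarray | float = 1.0,
    max_sweeps: int = 200,
    tol: float = 1e-6,
    damping: float = EP_DAMPING,
) -> ClassifierModel:
    """Expectation-propagation fit of the probit model with fixed prior.

    Site parameters are updated sequentially with damping until the largest
    site-parameter change in a sweep falls below ``tol``; negative cavity
    precisions cause a skipped update, and the run warns (but still returns
    the approximation) if the sweep cap is reached.
    """
    X, t = data.features, data.labels
    n, M = X.shape
    lam = np.full(M, float(Lambda_z)) if np.isscalar(Lambda_z) else np.asarray(
        Lambda_z, dtype=float
    )
    if lam.shape != (M,) or np.any(lam <= 0):
        raise ParameterError("Lambda_z must be positive with one entry per feature")
    y = 2.0 * t - 1.0  # {-1, +1}

    K = (X / lam[None, :]) @ X.T  # X Lambda^{-1} X^T
    K = 0.5 * (K + K.T)
    nu = np.zeros(n)
    tau = np.zeros(n)
    mu, Sigma, _ = _posterior_f(K, nu, tau)
    sigma2 = np.diag(Sigma).copy()

    converged = False
    sweep = 0
    for sweep in range(1, max_sweeps + 1):
        max_delta = 0.0
        for i in range(n):
            tau_c = 1.0 / sigma2[i] - tau[i]
            if tau_c <= TAU_FLOOR:
                continue  # cavity undefined; skip this site
            nu_c = mu[i] / sigma2[i] - nu[i]
            mu_c, s2_c = nu_c / tau_c, 1.0 / tau_c
            _, mu_hat, s2_hat = _probit_moments(y[i], mu_c, s2_c)
            tau_new = max(1.0 / s2_hat - tau_c, TAU_FLOOR)
            nu_new = mu_hat / s2_hat - nu_c
            d_tau = damping * (tau_new - tau[i])
            d_nu = damping * (nu_new - nu[i])
            max_delta = max(max_delta, abs(d_tau), abs(d_nu))
            tau[i] += d_tau
            nu[i] += d_nu
            # rank-one refresh of Sigma and mu (O(n^2) / O(n))
            si = Sigma[:, i].copy()
            denom = 1.0 + d_tau * Sigma[i, i]
            Sigma -= np.outer(si, si) * (d_tau / denom)
            coef = d_nu - d_tau * (mu[i] + d_nu * si[i]) / denom
            mu = mu + coef * si
            sigma2 = np.diag(Sigma).copy()
        # full recompute once per sweep for numerical hygiene
        mu, Sigma, _ = _posterior_f(K, nu, tau)
        sigma2 = np.diag(Sigma).copy()
        if max_delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn("EP reached the sweep cap without meeting tolerance")

    log_evidence = _ep_log_evidence(K, y, nu, tau)

    # map the latent posterior back to coefficient space:
    # posterior precision = Lambda + X^T T X, mean = cov @ X^T nu
    P = np.diag(lam) + X.T @ (tau[:, None] * X)
    try:
        cho = linalg.cho_factor(0.5 * (P + P.T), lower=True)
    except linalg.LinAlgError as err:
        raise ConvergenceError(f"EP coefficient posterior not PD: {err}")
    z_cov = linalg.cho_solve(cho, np.eye(M))
    z_mean = z_cov @ (X.T @ nu)
    return ClassifierModel(
        z_mean=z_mean,
        z_cov=0.5 * (z_cov + z_cov.T),
        Lambda_z=lam,
        log_evidence=log_evidence,
        converged=converged,
        n_sweeps=sweep,
    )


def _ep_log_evidence(K, y, nu, tau) -> float:
    """EP approximation to log p(t).

    Z_EP = [prod_i Ztilde_i] * integral N(f|0,K) prod_i N(f_i|mu_i, 1/tau_i) df
    where the site normalizers match the cavity-likelihood zeroth moments:
    Ztilde_i = Phi(y_i mu_c / sqrt(1 + s2_c)) / N(mu_site | mu_c, 1/tau_i + s2_c).
    """
    n = K.shape[0]
    mu, Sigma, _ = _posterior_f(K, nu, tau)
    sigma2 = np.diag(Sigma)
    active = tau > TAU_FLOOR
    log_z = 0.0
    mu_site = np.where(active, nu / np.where(active, tau, 1.0), 0.0)
    for i in range(n):
        if not active[i]:
            continue
        tau_c = 1.0 / sigma2[i] - tau[i]
        if tau_c <= TAU_FLOOR:
            continue
        nu_c = mu[i] / sigma2[i] - nu[i]
        mu_c, s2_c = nu_c / tau_c, 1.0 / tau_c
        log_z += float(log_ndtr(y[i] * mu_c / np.sqrt(1.0 + s2_c)))
        log_z -= float(
            norm.logpdf(mu_site[i], loc=mu_c, scale=np.sqrt(1.0 / tau[i] + s2_c))
        )
    # integral of prior times product of (normalized) site Gaussians:
    # N(mu_site | 0, K + S^{-1}) over active sites
    idx = np.flatnonzero(active)
    if idx.size:
        C = K[np.ix_(idx, idx)] + np.diag(1.0 / tau[idx])
        sign, logdet = np.linalg.slogdet(C)
        if sign <= 0:
            raise ConvergenceError("EP evidence covariance not PD")
        m = mu_site[idx]
        sol = np.linalg.solve(C, m)
        log_z += -0.5 * (idx.size * np.log(2 * np.pi) + logdet + m @ sol)
    return float(log_z)


def fit_probit_ard(
    data: LabeledFeatures,
    max_outer: int = 25,
    outer_tol: float = 1e-3,
    alpha_bounds: tuple[float, float] = (1e-6, 1e6),
    isotropic: bool = False,
    **ep_kwargs,
) -> ClassifierModel:
    """Probit classifier with ARD precisions chosen by EP-evidence ascent.

    The diagonal of Lambda_z is updated by the EM-style fixed point
    alpha_j <- 1 / (mean_j^2 + cov_jj) between EP fits; the best-evidence
    iterate (including the isotropic initialization) is returned, so the
    returned evidence never falls below the initialization's.
    """
    sd = data.features.std(axis=0)
    if np.any(sd < 1e-12):
        raise DegenerateDataError(
            f"constant feature column(s): {np.flatnonzero(sd < 1e-12).tolist()}"
        )
    lam = np.ones(data.M)
    best = ep_fit(data, lam, **ep_kwargs)
    if isotropic:
        return best
    current = best
    for _ in range(max_outer):
        lam_new = 1.0 / np.clip(
            current.z_mean**2 + np.diag(current.z_cov),
            1.0 / alpha_bounds[1],
            1.0 / alpha_bounds[0],
        )
        if np.max(np.abs(np.log(lam_new) - np.log(current.Lambda_z))) < outer_tol:
            break
        current = ep_fit(data, lam_new, **ep_kwargs)
        if current.log_evidence > best.log_evidence:
            best = current
    return best


def predict_proba(model: ClassifierModel, features: np.ndarray) -> np.ndarray:
    """Probit predictive probability with posterior-variance correction.

    p(t = 1 | f) = H( m / sqrt(1 + v) ) with m = z_mean^T f and
    v = f^T z_cov f; accepts a single feature vector or a batch of rows.
    """
    F = np.atleast_2d(np.asarray(features, dtype=float))
    if F.shape[1] != model.z_mean.size:
        raise DimensionError(
            f"feature dimension {F.shape[1]} != model dimension {model.z_mean.size}"
        )
    m = F @ model.z_mean
    v = np.einsum("ij,jk,ik->i", F, model.z_cov, F)
    p = ndtr(m / np.sqrt(1.0 + v))
    return p if np.asarray(features).ndim > 1 else float(p[0])


def stratified_cv_auroc(
    data: LabeledFeatures,
    k: int = 10,
    seed: int = 0,
    isotropic: bool = False,
    **fit_kwargs,
) -> tuple[float, "pd.DataFrame"]:
    """Stratified k-fold cross-validated AUROC.

    Folds preserve class proportions to within one subject; the AUROC is
    computed from the pooled out-of-fold predictive probabilities via the
    rank (Mann-Whitney) formulation. If the smaller class has fewer than k
    members the fold count is reduced with a warning.
    """
    import pandas as pd

    counts = np.bincount(data.labels, minlength=2)
    k_eff = int(min(k, counts.min()))
    if k_eff < 2:
        raise ParameterError("need at least 2 members per class for CV")
    if k_eff < k:
        warnings.warn(f"reducing folds from {k} to {k_eff} (small class)")
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=int(seed))
    rows = []
    for fold, (train, test) in enumerate(skf.split(data.features, data.labels)):
        model = fit_probit_ard(
            LabeledFeatures(data.features[train], data.labels[train]),
            isotropic=isotropic,
            **fit_kwargs,
        )
        probs = predict_proba(model, data.features[test])
        for idx, p in zip(test, np.atleast_1d(probs)):
            rows.append(
                {"fold": fold, "index": int(idx), "label": int(data.labels[idx]),
                 "prob": float(p)}
            )
    table = pd.DataFrame(rows)
    auroc = float(roc_auc_score(table["label"], table["prob"]))
    return auroc, table
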