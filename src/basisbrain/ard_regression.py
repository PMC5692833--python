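"""Empirical-Bayes inference for the ARD spatial regression model.

Model: y_s = Phi w_s + eps_s, eps_s ~ N(0, beta^{-1} I), with an
automatic-relevance-determination prior w_s ~ N(0, Lambda_alpha^{-1}),
Lambda_alpha = diag(alpha_1..alpha_M) shared across subjects. The weight
posterior is Gaussian in closed form,

    A = beta Phi^T Phi + Lambda_alpha,      w_bar_s = beta A^{-1} Phi^T y_s,

and the hyperparameters (alpha, beta) are set by type-II maximum
likelihood: maximizing the log marginal likelihood

    L = S [ (V/2) log beta - (V/2) log 2pi + (1/2) log|Lambda_alpha|
            - (1/2) log|A| ]
        - sum_s [ (beta/2) ||y_s - Phi w_bar_s||^2
                  + (1/2) w_bar_s^T Lambda_alpha w_bar_s ],

which equals sum_s log N(y_s | 0, beta^{-1} I + Phi Lambda_alpha^{-1} Phi^T).
Derivatives are analytic; since w_bar minimizes the inner quadratic, terms
through w_bar vanish (envelope theorem):

    dL/dalpha_m = (S/2)(1/alpha_m - [A^{-1}]_mm) - (1/2) sum_s w_bar_{m,s}^2
    dL/dbeta    = SV/(2 beta) - (S/2) tr(A^{-1} Phi^T Phi)
                  - (1/2) sum_s ||y_s - Phi w_bar_s||^2

Optimization runs over (log alpha, log beta) to enforce positivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .basis import BasisSet
from .errors import ConditioningError, DimensionError, ParameterError
from .io_volumes import DataMatrix


@dataclass
class Hyperparameters:
    """ARD precisions alpha (diagonal of Lambda_alpha) and noise precision beta."""

    alpha: np.ndarray
    beta: float

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        if np.any(self.alpha <= 0) or not np.isfinite(self.alpha).all():
            raise ParameterError("all ARD precisions must be positive and finite")
        if self.beta <= 0 or not np.isfinite(self.beta):
            raise ParameterError("noise precision beta must be positive")

    @property
    def M(self) -> int:
        return self.alpha.size

    @property
    def Lambda_alpha(self) -> np.ndarray:
        return np.diag(self.alpha)

    @property
    def Sigma_alpha(self) -> np.ndarray:
        return np.diag(1.0 / self.alpha)


@dataclass
class PosteriorState:
    """Per-subject posterior weight means and the shared posterior precision.

    A is identical for all subjects because the posterior variance depends
    only on Phi, beta and Lambda_alpha, never on the data values.
    """

    W_bar: np.ndarray  # M x S
    A: np.ndarray  # M x M posterior precision
    prior_mean: float = 0.0


@dataclass
class FitTrace:
    objective: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0
    message: str = ""


def _check_dims(basis: BasisSet, data: DataMatrix, hyper: Hyperparameters) -> None:
    if basis.V != data.V:
        raise DimensionError(f"basis V={basis.V} != data V={data.V}")
    if hyper.M != basis.M:
        raise DimensionError(f"hyper M={hyper.M} != basis M={basis.M}")


def _posterior_core(Phi, Y, alpha, beta):
    """Shared plumbing: returns (A, cho_factor, W_bar, residual matrix)."""
    G = Phi.T @ Phi
    A = beta * G + np.diag(alpha)
    try:
        cho = linalg.cho_factor(A, lower=True)
    except linalg.LinAlgError as err:
        raise ConditioningError(f"posterior precision not factorizable: {err}")
    W_bar = beta * linalg.cho_solve(cho, Phi.T @ Y)
    R = Y - Phi @ W_bar
    return G, A, cho, W_bar, R


def compute_posterior(
    basis: BasisSet, data: DataMatrix, hyper: Hyperparameters
) -> PosteriorState:
    """Closed-form Gaussian weight posterior, one factorization for all subjects."""
    _check_dims(basis, data, hyper)
    _, A, _, W_bar, _ = _posterior_core(
        basis.matrix, data.values, hyper.alpha, hyper.beta
    )
    return PosteriorState(W_bar=W_bar, A=A)


def log_marginal_likelihood(
    basis: BasisSet, data: DataMatrix, hyper: Hyperparameters
) -> float:
    """Log evidence of the data with the weights integrated out."""
    _check_dims(basis, data, hyper)
    Phi, Y = basis.matrix, data.values
    V, S = Y.shape
    alpha, beta = hyper.alpha, hyper.beta
    _, _, cho, W_bar, R = _posterior_core(Phi, Y, alpha, beta)
    logdet_A = 2.0 * np.sum(np.log(np.diag(cho[0])))
    logdet_Lambda = np.sum(np.log(alpha))
    data_term = 0.5 * beta * np.sum(R**2) + 0.5 * np.sum(alpha[:, None] * W_bar**2)
    return float(
        S
        * (
            0.5 * V * np.log(beta)
            - 0.5 * V * np.log(2 * np.pi)
            + 0.5 * logdet_Lambda
            - 0.5 * logdet_A
        )
        - data_term
    )


def lml_gradient(
    basis: BasisSet, data: DataMatrix, hyper: Hyperparameters
) -> np.ndarray:
    """Gradient of the log evidence w.r.t. (log alpha_1..M, log beta)."""
    _check_dims(basis, data, hyper)
    Phi, Y = basis.matrix, data.values
    V, S = Y.shape
    alpha, beta = hyper.alpha, hyper.beta
    G, _, cho, W_bar, R = _posterior_core(Phi, Y, alpha, beta)
    Ainv = linalg.cho_solve(cho, np.eye(alpha.size))
    d_alpha = 0.5 * S * (1.0 / alpha - np.diag(Ainv)) - 0.5 * np.sum(W_bar**2, axis=1)
    d_beta = (
        0.5 * S * V / beta - 0.5 * S * np.trace(Ainv @ G) - 0.5 * np.sum(R**2)
    )
    return np.concatenate([alpha * d_alpha, [beta * d_beta]])


def default_init(basis: BasisSet, data: DataMatrix) -> Hyperparameters:
    """Neutral start: alpha = 1 for every basis function, beta = 1/var(Y)."""
    pooled_var = float(np.var(data.values))
    if pooled_var <= 0:
        raise ParameterError("data have zero variance")
    return Hyperparameters(alpha=np.ones(basis.M), beta=1.0 / pooled_var)


def fit_empirical_bayes(
    basis: BasisSet,
    data: DataMatrix,
    init: Hyperparameters | None = None,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> tuple[Hyperparameters, PosteriorState, FitTrace]:
    """Type-II maximum likelihood over (alpha, beta).

    The evidence and its analytic gradient are optimized in log space
    (positivity by construction) with a deterministic quasi-Newton scheme.
    Returns the best iterate even on non-convergence, with the trace's
    ``converged`` flag cleared.
    """
    if init is None:
        init = default_init(basis, data)
    _check_dims(basis, data, init)
    trace = FitTrace()

    def negative(x: np.ndarray) -> tuple[float, np.ndarray]:
        hyper = Hyperparameters(alpha=np.exp(x[:-1]), beta=float(np.exp(x[-1])))
        f = log_marginal_likelihood(basis, data, hyper)
        g = lml_gradient(basis, data, hyper)
        return -f, -g

    x0 = np.concatenate([np.log(init.alpha), [np.log(init.beta)]])
    f0 = log_marginal_likelihood(basis, data, init)
    trace.objective.append(f0)

    def callback(xk: np.ndarray) -> None:
        trace.objective.append(-negative(xk)[0])

    res = optimize.minimize(
        negative,
        x0,
        jac=True,
        method="L-BFGS-B",
        callback=callback,
        options={"maxiter": max_iter, "ftol": tol * 1e-3, "gtol": 1e-8},
    )
    best_x = res.x if -res.fun >= f0 else x0
    trace.converged = bool(res.success) and -res.fun >= f0
    trace.n_iter = int(res.nit)
    trace.message = str(res.message)
    hyper = Hyperparameters(alpha=np.exp(best_x[:-1]), beta=float(np.exp(best_x[-1])))
    post = compute_posterior(basis, data, hyper)
    trace.objective.append(log_marginal_likelihood(basis, data, hyper))
    return hyper, post, trace


# ---------------------------------------------------------------------------
# persistence


def save_fit(path, hyper: Hyperparameters, post: PosteriorState, meta: dict | None = None):
    """Store a fitted model (hyperparameters + posterior) as a single archive."""
    np.savez(
        path,
        alpha=hyper.alpha,
        beta=np.asarray(hyper.beta),
        W_bar=post.W_bar,
        A=post.A,
        meta=np.asarray(str(meta or {})),
    )


def load_fit(path) -> tuple[Hyperparameters, PosteriorState]:
    with np.load(path, allow_pickle=False) as z:
        hyper = Hyperparameters(alpha=z["alpha"], beta=float(z["beta"]))
        post = PosteriorState(W_bar=z["W_bar"], A=z["A"])
    return hyper, post
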