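"""Full-Bayes inference by blocked Gibbs sampling.

The hierarchical model extends the ARD regression with priors over the
noise precision and a *full* (off-diagonal) ARD precision matrix:

    beta         ~ Gamma(a, b)                      (shape/rate)
    Lambda_alpha ~ Wishart(N_df, P)                 (df, rate convention)
    w_s          ~ N(0, Lambda_alpha^{-1})
    y_s          ~ N(Phi w_s, beta^{-1} I)

Conjugacy gives exact full conditionals, sampled in the order W, beta,
Lambda_alpha per sweep:

    W      | .  ~ prod_s N(w_s | w_bar_s, A^{-1}),  A = beta Phi'Phi + Lambda
    beta   | .  ~ Gamma(a + SV/2, b + (1/2) sum_s ||y_s - Phi w_s||^2)
    Lambda | .  ~ Wishart(N_df + S, P + sum_s w_s w_s')

Wishart parameterization is (degrees of freedom, rate = inverse scale), so
the conditional update is the additive form above and the mean of
Wishart(nu, R) is nu * R^{-1}. Vague defaults: a = b = 1, N_df = M + 2,
P = I; burn-in 200 sweeps, 1000 retained samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .ard_regression import Hyperparameters, PosteriorState, compute_posterior
from .basis import BasisSet
from .errors import ConditioningError, DimensionError, ParameterError
from .io_volumes import DataMatrix


@dataclass
class PriorSpec:
    """Conjugate prior parameters: Gamma(a, b) on beta, Wishart(N_df, P) on
    Lambda_alpha (rate convention)."""

    a: float = 1.0
    b: float = 1.0
    N_df: float = None  # type: ignore[assignment]
    P: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ParameterError("Gamma prior parameters a, b must be positive")

    @classmethod
    def vague(cls, M: int) -> "PriorSpec":
        """The default vague priors: a = b = 1, N_df = M + 2, P = I."""
        return cls(a=1.0, b=1.0, N_df=float(M + 2), P=np.eye(M))

    def resolved(self, M: int) -> "PriorSpec":
        """Fill unset Wishart parameters for dimension M and validate."""
        N_df = float(M + 2) if self.N_df is None else float(self.N_df)
        P = np.eye(M) if self.P is None else np.asarray(self.P, dtype=float)
        if N_df < M:
            raise ParameterError(f"Wishart df {N_df} < dimension {M}")
        if P.shape != (M, M) or not np.allclose(P, P.T):
            raise ParameterError("Wishart rate P must be symmetric M x M")
        try:
            linalg.cholesky(P, lower=True)
        except linalg.LinAlgError:
            raise ParameterError("Wishart rate P must be positive definite")
        return PriorSpec(a=self.a, b=self.b, N_df=N_df, P=P)


@dataclass
class PosteriorSamples:
    """Retained Gibbs draws, shaped (n_chains, n_samples, ...)."""

    W_draws: np.ndarray  # (C, n, M, S)
    beta_draws: np.ndarray  # (C, n)
    Lambda_draws: np.ndarray  # (C, n, M, M)
    burn_in: int
    seed: int

    @property
    def n_chains(self) -> int:
        return self.W_draws.shape[0]

    @property
    def n_samples(self) -> int:
        return self.W_draws.shape[1]

    def pooled(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Draws flattened across chains: (W, beta, Lambda)."""
        C, n = self.W_draws.shape[:2]
        return (
            self.W_draws.reshape(C * n, *self.W_draws.shape[2:]),
            self.beta_draws.reshape(C * n),
            self.Lambda_draws.reshape(C * n, *self.Lambda_draws.shape[2:]),
        )

    def posterior_mean_state(self) -> PosteriorState:
        W, _, _ = self.pooled()
        A_mean = np.linalg.inv(
            np.mean(np.linalg.inv(self.pooled()[2]), axis=0)
        )  # informal summary only
        return PosteriorState(W_bar=W.mean(axis=0), A=A_mean)


def sample_weights(
    basis: BasisSet,
    data: DataMatrix,
    beta: float,
    Lambda: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One draw of all subjects' weights from the Gaussian full conditional."""
    Phi, Y = basis.matrix, data.values
    M, S = Phi.shape[1], Y.shape[1]
    A = beta * (Phi.T @ Phi) + Lambda
    try:
        L = linalg.cholesky(A, lower=True)
    except linalg.LinAlgError as err:
        raise ConditioningError(f"conditional precision not PD: {err}")
    W_bar = beta * linalg.cho_solve((L, True), Phi.T @ Y)
    # x = W_bar + L^{-T} z has covariance A^{-1}
    Z = rng.standard_normal((M, S))
    return W_bar + linalg.solve_triangular(L, Z, lower=True, trans="T")


def sample_noise_precision(
    basis: BasisSet,
    data: DataMatrix,
    W: np.ndarray,
    prior: PriorSpec,
    rng: np.random.Generator,
) -> float:
    """One Gamma draw: shape a + SV/2, rate b + (1/2) sum of squared residuals."""
    Y = data.values
    V, S = Y.shape
    R = Y - basis.matrix @ W
    shape = prior.a + 0.5 * S * V
    rate = prior.b + 0.5 * float(np.sum(R**2))
    return float(rng.gamma(shape, 1.0 / rate))


def sample_ard_precision(
    W: np.ndarray, prior: PriorSpec, rng: np.random.Generator
) -> np.ndarray:
    """One Wishart draw: df N_df + S, rate P + sum_s w_s w_s^T."""
    M, S = W.shape
    prior = prior.resolved(M)
    rate = prior.P + W @ W.T
    try:
        scale = np.linalg.inv(rate)
    except np.linalg.LinAlgError as err:
        raise ConditioningError(f"Wishart rate not invertible: {err}")
    scale = 0.5 * (scale + scale.T)
    draw = stats.wishart.rvs(df=prior.N_df + S, scale=scale, random_state=rng)
    draw = np.atleast_2d(draw)
    return 0.5 * (draw + draw.T)


@dataclass
class ChainDiagnostics:
    psrf_beta: float | None = None
    psrf_W_max: float | None = None
    notes: list[str] = field(default_factory=list)


def run_chain(
    basis: BasisSet,
    data: DataMatrix,
    prior: PriorSpec | None = None,
    n_burn: int = 200,
    n_samples: int = 1000,
    n_chains: int = 1,
    seed: int = 0,
) -> tuple[PosteriorSamples, ChainDiagnostics]:
    """Run the blocked Gibbs sampler (sweep order: W, beta, Lambda_alpha).

    Chains are seeded from independent spawned streams of ``seed`` so the
    run is reproducible and chains are independent by construction.
    Initialization: beta from the pooled data variance, Lambda_alpha = I,
    W = 0.
    """
    if n_burn < 0 or n_samples < 1:
        raise ParameterError("need n_burn >= 0 and n_samples >= 1")
    M, S = basis.M, data.S
    prior = (prior or PriorSpec.vague(M)).resolved(M)
    V = data.V
    if basis.V != V:
        raise DimensionError("basis and data disagree on V")
    streams = np.random.SeedSequence(int(seed)).spawn(n_chains)

    W_out = np.empty((n_chains, n_samples, M, S))
    beta_out = np.empty((n_chains, n_samples))
    Lambda_out = np.empty((n_chains, n_samples, M, M))

    for c, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        beta = 1.0 / max(float(np.var(data.values)), 1e-12)
        Lambda = np.eye(M)
        W = np.zeros((M, S))
        for t in range(n_burn + n_samples):
            W = sample_weights(basis, data, beta, Lambda, rng)
            beta = sample_noise_precision(basis, data, W, prior, rng)
            Lambda = sample_ard_precision(W, prior, rng)
            if not (np.isfinite(W).all() and np.isfinite(beta)):
                raise ConditioningError(f"chain {c} diverged at sweep {t}")
            if t >= n_burn:
                k = t - n_burn
                W_out[c, k] = W
                beta_out[c, k] = beta
                Lambda_out[c, k] = Lambda

    samples = PosteriorSamples(
        W_draws=W_out,
        beta_draws=beta_out,
        Lambda_draws=Lambda_out,
        burn_in=n_burn,
        seed=int(seed),
    )
    diag = ChainDiagnostics()
    if n_chains >= 2:
        diag.psrf_beta = float(psrf(beta_out))
        r_w = psrf(W_out.reshape(n_chains, n_samples, M * S))
        diag.psrf_W_max = float(np.max(r_w))
    return samples, diag


def psrf(chains: np.ndarray) -> np.ndarray | float:
    """Gelman-Rubin potential scale reduction factor R-hat.

    ``chains`` has shape (n_chains, n_draws) or (n_chains, n_draws, ...);
    the statistic is computed independently for each trailing index. With
    identical chains the between-chain variance is zero and R-hat sits at
    its finite-sample floor sqrt((n-1)/n).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim < 2 or chains.shape[0] < 2:
        raise ParameterError("psrf needs >= 2 chains")
    n = chains.shape[1]
    if n < 2:
        raise ParameterError("psrf needs chains of length >= 2")
    means = chains.mean(axis=1)  # (C, ...)
    within = chains.var(axis=1, ddof=1).mean(axis=0)
    between = n * means.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * within + between / n
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.sqrt(var_hat / within)
    out = np.where(within > 0, r, 1.0)
    return float(out) if out.ndim == 0 else out


def frozen_weight_posterior(
    basis: BasisSet, data: DataMatrix, beta: float, Lambda_diag: np.ndarray
) -> PosteriorState:
    """The weight conditional with beta and diagonal Lambda frozen equals the
    empirical-Bayes posterior; provided for cross-checks."""
    return compute_posterior(
        basis, data, Hyperparameters(alpha=Lambda_diag, beta=beta)
    )
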