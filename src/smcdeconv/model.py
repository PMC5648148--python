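"""Mixing model, likelihood, priors and tempered full conditionals.

The data model is the linear mixing model

    Y = X M + E,

where ``Y`` (genes x samples) holds measured intensities from heterogeneous
samples, ``X`` (genes x cell types) the unknown cell-type-specific expression
signatures, ``M`` (cell types x samples) the unknown mixing proportions and
``E`` i.i.d. zero-mean Gaussian noise with precision ``lambda``.

Priors are conjugate: Gaussian on every ``x_ik`` and ``m_kj``, Gamma on the
precision.  The likelihood-tempered target at inverse temperature
``eps in [0, 1]`` is ``p(theta) * p(Y|theta)**eps``; its full conditionals
remain Gaussian/Gamma and are exposed here in closed form.  All density
computation is in log space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "PriorSpec",
    "ParticleState",
    "TemperatureSchedule",
    "log_likelihood",
    "log_prior",
    "log_unnormalized_target",
    "partial_mixture",
    "conditional_m_params",
    "conditional_x_params",
    "conditional_lambda_params",
    "incremental_log_weight",
    "sample_prior",
    "default_priors",
    "priors_from_pure_samples",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples intensity matrix on the linear (non-log) scale."""

    values: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if values.ndim != 2:
            raise ValueError(f"expression values must be 2-D, got shape {values.shape}")
        if values.shape[0] < 1 or values.shape[1] < 1:
            raise ValueError("expression matrix must have at least one gene and one sample")
        if len(self.gene_ids) != values.shape[0]:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {values.shape[0]} rows"
            )
        if len(self.sample_ids) != values.shape[1]:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {values.shape[1]} columns"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_values(cls, values: np.ndarray, gene_ids=None, sample_ids=None) -> "ExpressionMatrix":
        values = np.asarray(values, dtype=float)
        if gene_ids is None:
            gene_ids = [f"g{i}" for i in range(values.shape[0])]
        if sample_ids is None:
            sample_ids = [f"s{j}" for j in range(values.shape[1])]
        return cls(values, tuple(gene_ids), tuple(sample_ids))


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the conjugate prior.

    ``mu_x``/``nu_x`` are the Gaussian means and precisions for the signature
    entries ``x_ik`` (I x K); ``mu_m``/``nu_m`` those for the proportions
    ``m_kj`` (K x J); ``alpha``/``beta`` the Gamma shape and rate for the
    noise precision.
    """

    mu_x: np.ndarray
    nu_x: np.ndarray
    mu_m: np.ndarray
    nu_m: np.ndarray
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("mu_x", "nu_x", "mu_m", "nu_m"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.mu_x.shape != self.nu_x.shape or self.mu_x.ndim != 2:
            raise ValueError("mu_x and nu_x must be equal-shape 2-D arrays")
        if self.mu_m.shape != self.nu_m.shape or self.mu_m.ndim != 2:
            raise ValueError("mu_m and nu_m must be equal-shape 2-D arrays")
        if self.mu_x.shape[1] != self.mu_m.shape[0]:
            raise ValueError(
                f"inconsistent K: mu_x has {self.mu_x.shape[1]} columns, "
                f"mu_m has {self.mu_m.shape[0]} rows"
            )
        if not (np.all(self.nu_x > 0) and np.all(self.nu_m > 0)):
            raise ValueError("prior precisions must be strictly positive")
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("Gamma hyperparameters alpha, beta must be positive")

    @property
    def n_genes(self) -> int:
        return self.mu_x.shape[0]

    @property
    def n_types(self) -> int:
        return self.mu_x.shape[1]

    @property
    def n_samples(self) -> int:
        return self.mu_m.shape[1]


@dataclass
class ParticleState:
    """One draw of theta = (X, M, lambda)."""

    X: np.ndarray
    M: np.ndarray
    lam: float

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        self.lam = float(self.lam)
        if self.X.ndim != 2 or self.M.ndim != 2:
            raise ValueError("X and M must be 2-D")
        if self.X.shape[1] != self.M.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[1]} cell types but M has {self.M.shape[0]}"
            )
        if self.lam <= 0:
            raise ValueError(f"precision lambda must be positive, got {self.lam}")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.M))):
            raise ValueError("non-finite entries in particle state")

    def copy(self) -> "ParticleState":
        return ParticleState(self.X.copy(), self.M.copy(), self.lam)


@dataclass(frozen=True)
class TemperatureSchedule:
    """Nondecreasing inverse-temperature ladder eps_1 = 0 <= ... <= eps_T = 1."""

    eps: np.ndarray

    def __post_init__(self) -> None:
        eps = np.asarray(self.eps, dtype=float)
        object.__setattr__(self, "eps", eps)
        if eps.ndim != 1 or eps.size < 2:
            raise ValueError("schedule needs at least two temperatures")
        if eps[0] != 0.0 or eps[-1] != 1.0:
            raise ValueError("schedule must start at 0 and end at 1")
        if np.any(np.diff(eps) < 0):
            raise ValueError("schedule must be nondecreasing")

    def __len__(self) -> int:
        return self.eps.size

    @classmethod
    def linear(cls, n_steps: int) -> "TemperatureSchedule":
        return cls(np.linspace(0.0, 1.0, n_steps))

    @classmethod
    def quadratic(cls, n_steps: int) -> "TemperatureSchedule":
        """Default ladder: eps_t = ((t-1)/(T-1))^2, slow early likelihood onset."""
        return cls(np.linspace(0.0, 1.0, n_steps) ** 2)


def _check_shapes(Y: ExpressionMatrix, theta: ParticleState) -> None:
    I, J = Y.values.shape
    if theta.X.shape[0] != I or theta.M.shape[1] != J:
        raise ValueError(
            f"data is {I}x{J} but theta implies {theta.X.shape[0]}x{theta.M.shape[1]}"
        )


def log_likelihood(Y: ExpressionMatrix, theta: ParticleState) -> float:
    """Gaussian log-likelihood of the mixing model.

    Equals ``(IJ/2) log(lam/(2 pi)) - (lam/2) sum_ij (y_ij - (XM)_ij)^2``.
    """
    _check_shapes(Y, theta)
    if theta.lam <= 0:
        raise ValueError("lambda must be positive")
    I, J = Y.values.shape
    resid = Y.values - theta.X @ theta.M
    rss = float(np.sum(resid * resid))
    return 0.5 * I * J * (np.log(theta.lam) - _LOG_2PI) - 0.5 * theta.lam * rss


def log_prior(theta: ParticleState, priors: PriorSpec) -> float:
    """Sum of Gaussian log-densities for X and M and the Gamma log-density for lambda."""
    if theta.lam <= 0:
        raise ValueError("lambda outside prior support")
    lp = float(
        stats.gamma.logpdf(theta.lam, a=priors.alpha, scale=1.0 / priors.beta)
    )
    lp += float(
        np.sum(stats.norm.logpdf(theta.X, loc=priors.mu_x, scale=priors.nu_x ** -0.5))
    )
    lp += float(
        np.sum(stats.norm.logpdf(theta.M, loc=priors.mu_m, scale=priors.nu_m ** -0.5))
    )
    return lp


def log_unnormalized_target(
    theta: ParticleState, Y: ExpressionMatrix, eps_t: float, priors: PriorSpec
) -> float:
    """log of the tempered target: log p(theta) + eps_t * log p(Y|theta)."""
    if not 0.0 <= eps_t <= 1.0:
        raise ValueError(f"eps_t must lie in [0, 1], got {eps_t}")
    lp = log_prior(theta, priors)
    if eps_t == 0.0:
        return lp
    return lp + eps_t * log_likelihood(Y, theta)


def partial_mixture(theta: ParticleState, i: int, j: int, k: int) -> float:
    """Mixture value at (i, j) excluding cell type k: sum_{k' != k} x_ik' m_k'j."""
    I, K = theta.X.shape
    J = theta.M.shape[1]
    if not (0 <= i < I and 0 <= j < J and 0 <= k < K):
        raise IndexError(f"index (i={i}, j={j}, k={k}) out of range for ({I}, {J}, {K})")
    return float(theta.X[i, :] @ theta.M[:, j] - theta.X[i, k] * theta.M[k, j])


def conditional_m_params(
    Y: ExpressionMatrix,
    theta: ParticleState,
    k: int,
    j: int,
    eps_t: float,
    priors: PriorSpec,
) -> tuple[float, float]:
    """Mean and variance of the tempered Gaussian conditional for m_kj.

    With ``U = nu_kj + eps*lam*sum_i x_ik^2`` and
    ``V = mu_kj*nu_kj + eps*lam*(sum_i y_ij x_ik - sum_i Y_ijk x_ik)``,
    the conditional is Normal(V/U, 1/U).
    """
    _check_shapes(Y, theta)
    if not 0.0 <= eps_t <= 1.0:
        raise ValueError(f"eps_t must lie in [0, 1], got {eps_t}")
    xk = theta.X[:, k]
    yj = Y.values[:, j]
    # Y_ijk = (XM)_ij - x_ik m_kj, the mixture with type k removed
    part = theta.X @ theta.M[:, j] - xk * theta.M[k, j]
    U = priors.nu_m[k, j] + eps_t * theta.lam * float(xk @ xk)
    V = priors.mu_m[k, j] * priors.nu_m[k, j] + eps_t * theta.lam * float(
        yj @ xk - part @ xk
    )
    return V / U, 1.0 / U


def conditional_x_params(
    Y: ExpressionMatrix,
    theta: ParticleState,
    i: int,
    k: int,
    eps_t: float,
    priors: PriorSpec,
) -> tuple[float, float]:
    """Mean and variance of the tempered Gaussian conditional for x_ik.

    With ``A = nu_ik + eps*lam*sum_j m_kj^2`` and
    ``B = mu_ik*nu_ik + eps*lam*(sum_j y_ij m_kj - sum_j Y_ijk m_kj)``,
    the conditional is Normal(B/A, 1/A).
    """
    _check_shapes(Y, theta)
    if not 0.0 <= eps_t <= 1.0:
        raise ValueError(f"eps_t must lie in [0, 1], got {eps_t}")
    mk = theta.M[k, :]
    yi = Y.values[i, :]
    part = theta.X[i, :] @ theta.M - theta.X[i, k] * mk
    A = priors.nu_x[i, k] + eps_t * theta.lam * float(mk @ mk)
    B = priors.mu_x[i, k] * priors.nu_x[i, k] + eps_t * theta.lam * float(
        yi @ mk - part @ mk
    )
    return B / A, 1.0 / A


def conditional_lambda_params(
    Y: ExpressionMatrix, theta: ParticleState, eps_t: float, priors: PriorSpec
) -> tuple[float, float]:
    """Shape and rate of the tempered Gamma conditional for the precision."""
    _check_shapes(Y, theta)
    if not 0.0 <= eps_t <= 1.0:
        raise ValueError(f"eps_t must lie in [0, 1], got {eps_t}")
    I, J = Y.values.shape
    resid = Y.values - theta.X @ theta.M
    rss = float(np.sum(resid * resid))
    return priors.alpha + eps_t * I * J / 2.0, priors.beta + 0.5 * eps_t * rss


def incremental_log_weight(
    theta_prev: ParticleState, Y: ExpressionMatrix, eps_t: float, eps_prev: float
) -> float:
    """Log incremental importance weight of the tempering move.

    With conditional-target forward kernels and their optimal-backward
    approximation, the weight update collapses to
    ``(eps_t - eps_prev) * log p(Y | theta_prev)`` — it depends only on the
    particle value *before* propagation.
    """
    if eps_prev > eps_t:
        raise ValueError(f"eps_prev ({eps_prev}) exceeds eps_t ({eps_t})")
    if eps_t == eps_prev:
        return 0.0
    return (eps_t - eps_prev) * log_likelihood(Y, theta_prev)


def sample_prior(priors: PriorSpec, rng: np.random.Generator) -> ParticleState:
    """Independent draw from the prior: lambda, then M, then X."""
    lam = rng.gamma(shape=priors.alpha, scale=1.0 / priors.beta)
    M = rng.normal(priors.mu_m, priors.nu_m ** -0.5)
    X = rng.normal(priors.mu_x, priors.nu_x ** -0.5)
    return ParticleState(X=X, M=M, lam=lam)


def default_priors(Y: ExpressionMatrix, K: int, *, delta: float = 1e-6) -> PriorSpec:
    """Weakly informative, data-scaled default hyperparameters.

    Signature priors are centred on the row means of Y with precision
    ``1/(row variance + delta)``; proportion priors sit at 1/K with prior sd
    0.1 (nu = 100); the precision prior is the vague Gamma(1e-3, 1e-3).
    """
    if K <= 0:
        raise ValueError(f"number of cell types must be positive, got {K}")
    I, J = Y.values.shape
    if K > I or K > J:
        warnings.warn(
            f"K={K} exceeds the number of genes ({I}) or samples ({J}); "
            "the decomposition may not be identifiable",
            UserWarning,
            stacklevel=2,
        )
    row_mean = Y.values.mean(axis=1)
    row_var = Y.values.var(axis=1)
    mu_x = np.tile(row_mean[:, None], (1, K))
    nu_x = np.tile(1.0 / (row_var + delta)[:, None], (1, K))
    mu_m = np.full((K, J), 1.0 / K)
    nu_m = np.full((K, J), 100.0)
    return PriorSpec(mu_x=mu_x, nu_x=nu_x, mu_m=mu_m, nu_m=nu_m, alpha=1e-3, beta=1e-3)


def priors_from_pure_samples(
    Y_pure: ExpressionMatrix,
    labels: list[str] | tuple[str, ...],
    J: int,
    *,
    delta: float = 1e-6,
    nu_m_value: float = 100.0,
    alpha: float = 1e-3,
    beta: float = 1e-3,
) -> PriorSpec:
    """Signature priors derived from pure-sample technical replicates.

    When replicate measurements of the pure cell types are available (as in
    every mixture benchmark with a ground-truth design), the natural
    informative prior centres ``x_ik`` on the replicate mean of gene i in
    type k with precision ``1/(replicate variance + delta)``.  The blind
    decomposition is then anchored both in scale and in cell-type labels,
    while the proportions keep the weak equal-proportion prior.

    ``labels`` assigns a cell type to every column of ``Y_pure``; types are
    ordered by first appearance.  ``J`` is the number of heterogeneous
    samples the priors will be used with.
    """
    if len(labels) != Y_pure.n_samples:
        raise ValueError(f"{len(labels)} labels for {Y_pure.n_samples} pure samples")
    types: list[str] = []
    for lab in labels:
        if lab not in types:
            types.append(lab)
    K = len(types)
    mu_cols, var_cols = [], []
    for t in types:
        cols = [j for j, lab in enumerate(labels) if lab == t]
        block = Y_pure.values[:, cols]
        mu_cols.append(block.mean(axis=1))
        if len(cols) > 1:
            var_cols.append(block.var(axis=1, ddof=1))
        else:
            var_cols.append(np.zeros(Y_pure.n_genes))
    mu_x = np.column_stack(mu_cols)
    var_x = np.column_stack(var_cols)
    pooled = var_x[var_x > 0]
    fallback = float(pooled.mean()) if pooled.size else 1.0
    var_x = np.where(var_x > 0, var_x, fallback)
    nu_x = 1.0 / (var_x + delta)
    mu_m = np.full((K, J), 1.0 / K)
    nu_m = np.full((K, J), float(nu_m_value))
    return PriorSpec(mu_x=mu_x, nu_x=nu_x, mu_m=mu_m, nu_m=nu_m,
                     alpha=alpha, beta=beta)
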