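"""Likelihood-tempered SMC sampler and Gibbs comparator.

The sampler targets the tempered sequence ``pi_t \\propto p(theta) *
p(Y|theta)**eps_t`` with ``eps_1 = 0 < ... < eps_T = 1``.  Particles start as
prior draws with uniform weights; at every later temperature the log-weights
are updated by ``(eps_t - eps_{t-1}) * log p(Y|theta_{t-1})``, normalized,
resampled when the effective sample size drops below a fraction of N, and only
then propagated through a kernel that leaves the current tempered target
invariant (conjugate Gibbs draws by default).

Internally an entire particle system is held as stacked arrays — X of shape
(N, I, K), M of shape (N, K, J), lam of shape (N,) — and the Gibbs scan updates
one cell-type block at a time.  For a fixed cell type k the entries x_ik are
mutually conditionally independent across genes i (and m_kj across samples j),
so a block draw is distributionally identical to the scalar sweep while being
a single vectorized normal draw across genes and particles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .model import (
    ExpressionMatrix,
    ParticleState,
    PriorSpec,
    TemperatureSchedule,
    default_priors,
)

__all__ = [
    "ParticleSystem",
    "SMCConfig",
    "RunDiagnostics",
    "GibbsSummary",
    "DegenerateWeightsError",
    "ess",
    "normalize_log_weights",
    "resample",
    "propagate_gibbs",
    "propagate_mh_dirichlet",
    "run_smc",
    "gibbs_oracle",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


class DegenerateWeightsError(RuntimeError):
    """All particle weights vanished (or are non-finite)."""


@dataclass
class RunDiagnostics:
    """Per-run bookkeeping: ESS trace, resampling events, schedule used."""

    ess_trace: list[float] = field(default_factory=list)
    resample_events: list[int] = field(default_factory=list)
    eps_used: TemperatureSchedule | None = None
    final_log_weight_spread: float = float("nan")
    # per-step (eps_t - eps_{t-1}) * loglik(theta_{t-1}) arrays, kept only
    # when SMCConfig.track_history is on
    incremental_log_weights: list[np.ndarray] = field(default_factory=list)


@dataclass
class ParticleSystem:
    """N weighted particles held as stacked arrays.

    ``X`` is (N, I, K), ``M`` is (N, K, J), ``lam`` is (N,).  ``log_weights``
    are unnormalized; ``norm_weights`` always sum to one.
    """

    X: np.ndarray
    M: np.ndarray
    lam: np.ndarray
    log_weights: np.ndarray
    t: int = 0
    diagnostics: RunDiagnostics = field(default_factory=RunDiagnostics)

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("a particle system needs at least 2 particles")

    @property
    def n_particles(self) -> int:
        return self.X.shape[0]

    @property
    def norm_weights(self) -> np.ndarray:
        return normalize_log_weights(self.log_weights)

    def particle(self, n: int) -> ParticleState:
        """Materialize particle n as a ParticleState."""
        return ParticleState(self.X[n].copy(), self.M[n].copy(), float(self.lam[n]))

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(
            self.X.copy(), self.M.copy(), self.lam.copy(),
            self.log_weights.copy(), self.t, self.diagnostics,
        )


@dataclass(frozen=True)
class SMCConfig:
    """Sampler configuration.

    ``resample_fraction`` is the ESS/N threshold below which multinomial
    resampling is triggered (default the N/10 rule).  The ``mh_dirichlet``
    kernel replaces the Gaussian prior on proportion columns by a
    Dirichlet(``dirichlet_alpha``) and propagates them with ``mh_sweeps``
    Metropolis-Hastings sweeps in additive-log-ratio space.
    """

    n_particles: int = 1024
    n_steps: int = 100
    schedule_shape: Literal["linear", "quadratic", "custom"] = "quadratic"
    custom_schedule: tuple[float, ...] | None = None
    resample_fraction: float = 0.1
    resample_method: Literal["multinomial", "systematic"] = "multinomial"
    kernel: Literal["conjugate_gibbs", "mh_dirichlet"] = "conjugate_gibbs"
    mh_sweeps: int = 10
    mh_step: float = 0.1
    dirichlet_alpha: float = 1.0
    seed: int = 0
    track_history: bool = False

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("n_particles must be >= 2")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if not 0.0 < self.resample_fraction <= 1.0:
            raise ValueError("resample_fraction must lie in (0, 1]")
        if self.schedule_shape == "custom" and self.custom_schedule is None:
            raise ValueError("custom schedule_shape requires custom_schedule")

    def schedule(self) -> TemperatureSchedule:
        if self.schedule_shape == "linear":
            return TemperatureSchedule.linear(self.n_steps)
        if self.schedule_shape == "quadratic":
            return TemperatureSchedule.quadratic(self.n_steps)
        return TemperatureSchedule(np.asarray(self.custom_schedule, dtype=float))


def ess(norm_weights: np.ndarray) -> float:
    """Effective sample size 1 / sum_n w_n^2 of normalized weights."""
    w = np.asarray(norm_weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    s = float(np.sum(w * w))
    if s == 0.0:
        raise DegenerateWeightsError("all weights are zero")
    return 1.0 / s


def normalize_log_weights(log_weights: np.ndarray) -> np.ndarray:
    """Shift-by-max exponentiation; invariant to adding a constant."""
    lw = np.asarray(log_weights, dtype=float)
    m = np.max(lw)
    if not np.isfinite(m):
        raise DegenerateWeightsError("no finite log-weight to normalize")
    w = np.exp(lw - m)
    return w / w.sum()


def _resample_indices(
    w: np.ndarray, n: int, rng: np.random.Generator, method: str
) -> np.ndarray:
    if method == "systematic":
        positions = (rng.uniform() + np.arange(n)) / n
        return np.searchsorted(np.cumsum(w), positions).clip(max=n - 1)
    counts = rng.multinomial(n, w)
    return np.repeat(np.arange(n), counts)


def resample(
    system: ParticleSystem,
    rng: np.random.Generator,
    method: str = "multinomial",
) -> ParticleSystem:
    """Redraw N particles with replacement by weight; reset weights to 1/N."""
    n = system.n_particles
    idx = _resample_indices(system.norm_weights, n, rng, method)
    out = ParticleSystem(
        X=system.X[idx].copy(),
        M=system.M[idx].copy(),
        lam=system.lam[idx].copy(),
        log_weights=np.full(n, -np.log(n)),
        t=system.t,
        diagnostics=system.diagnostics,
    )
    out.diagnostics.resample_events.append(system.t)
    return out


def _residual(Yv: np.ndarray, X: np.ndarray, M: np.ndarray) -> np.ndarray:
    """E = Y - X M for every particle, shape (N, I, J)."""
    return Yv[None, :, :] - np.einsum("nik,nkj->nij", X, M)


def _log_likelihood_stacked(
    Yv: np.ndarray, X: np.ndarray, M: np.ndarray, lam: np.ndarray
) -> np.ndarray:
    I, J = Yv.shape
    E = _residual(Yv, X, M)
    rss = np.einsum("nij,nij->n", E, E)
    # lam can underflow to 0 for prior draws from a very vague Gamma; the
    # likelihood is genuinely -inf there
    with np.errstate(divide="ignore"):
        return np.where(
            lam > 0,
            0.5 * I * J * (np.log(np.maximum(lam, 1e-300)) - _LOG_2PI) - 0.5 * lam * rss,
            -np.inf,
        )


def _gibbs_sweep(
    Yv: np.ndarray,
    X: np.ndarray,
    M: np.ndarray,
    lam: np.ndarray,
    eps: float,
    priors: PriorSpec,
    rng: np.random.Generator,
    *,
    update_m: bool = True,
) -> None:
    """One in-place blocked Gibbs scan of the eps-tempered conditionals.

    Draw order: lambda, then proportion blocks k = 1..K, then signature
    blocks k = 1..K.  The residual E = Y - XM is maintained incrementally
    within the scan.
    """
    N = X.shape[0]
    I, J = Yv.shape
    K = X.shape[2]
    E = _residual(Yv, X, M)

    shape = priors.alpha + eps * I * J / 2.0
    rate = priors.beta + 0.5 * eps * np.einsum("nij,nij->n", E, E)
    lam[:] = rng.gamma(shape, 1.0 / rate)

    if update_m:
        for k in range(K):
            xk = X[:, :, k]
            sxx = np.einsum("ni,ni->n", xk, xk)
            U = priors.nu_m[k][None, :] + eps * lam[:, None] * sxx[:, None]
            cross = np.einsum("ni,nij->nj", xk, E) + M[:, k, :] * sxx[:, None]
            V = (priors.mu_m[k] * priors.nu_m[k])[None, :] + eps * lam[:, None] * cross
            new = V / U + rng.standard_normal((N, J)) / np.sqrt(U)
            E -= xk[:, :, None] * (new - M[:, k, :])[:, None, :]
            M[:, k, :] = new

    for k in range(K):
        mk = M[:, k, :]
        smm = np.einsum("nj,nj->n", mk, mk)
        A = priors.nu_x[:, k][None, :] + eps * lam[:, None] * smm[:, None]
        cross = np.einsum("nj,nij->ni", mk, E) + X[:, :, k] * smm[:, None]
        B = (priors.mu_x[:, k] * priors.nu_x[:, k])[None, :] + eps * lam[:, None] * cross
        new = B / A + rng.standard_normal((N, I)) / np.sqrt(A)
        E -= (new - X[:, :, k])[:, :, None] * mk[:, None, :]
        X[:, :, k] = new


def propagate_gibbs(
    system: ParticleSystem,
    eps_t: float,
    Y: ExpressionMatrix,
    priors: PriorSpec,
    rng: np.random.Generator,
) -> ParticleSystem:
    """Propagate every particle with one tempered conjugate-Gibbs scan.

    Weights are untouched: the kernel leaves the current tempered target
    invariant and the incremental weight depends only on the pre-move state.
    """
    if not 0.0 <= eps_t <= 1.0:
        raise ValueError(f"eps_t must lie in [0, 1], got {eps_t}")
    out = system.copy()
    _gibbs_sweep(Y.values, out.X, out.M, out.lam, eps_t, priors, rng)
    return out


def _mh_update_columns(
    Yv: np.ndarray,
    X: np.ndarray,
    M: np.ndarray,
    lam: np.ndarray,
    eps: float,
    alpha_dir: np.ndarray,
    step: float,
    n_sweeps: int,
    rng: np.random.Generator,
) -> int:
    """MH sweeps on every proportion column, vectorized over (particle, sample).

    Proposal: additive Gaussian step in additive-log-ratio coordinates
    y_k = log(m_k / m_K), symmetric there; the simplex-space acceptance ratio
    therefore carries the Jacobian term sum_k log m_k.  Target: Dirichlet
    prior times the eps-tempered likelihood factor of the column.
    Returns the number of accepted moves.
    """
    N, K, J = M.shape
    accepted = 0
    for _ in range(n_sweeps):
        logm = np.log(np.clip(M, 1e-300, None))
        y = logm[:, :-1, :] - logm[:, -1:, :]
        y_prop = y + step * rng.standard_normal((N, K - 1, J))
        full = np.concatenate([y_prop, np.zeros((N, 1, J))], axis=1)
        full -= full.max(axis=1, keepdims=True)
        expf = np.exp(full)
        M_prop = expf / expf.sum(axis=1, keepdims=True)
        logm_prop = np.log(np.clip(M_prop, 1e-300, None))

        E = _residual(Yv, X, M)
        E_prop = _residual(Yv, X, M_prop)
        rss = np.einsum("nij,nij->nj", E, E)
        rss_prop = np.einsum("nij,nij->nj", E_prop, E_prop)
        # prior (alpha_k - 1) log m + Jacobian log m collapse to alpha_k log m
        dlog = np.einsum("k,nkj->nj", alpha_dir, logm_prop - logm)
        dlog += eps * (-0.5) * lam[:, None] * (rss_prop - rss)

        accept = np.log(rng.uniform(size=(N, J))) < dlog
        M[:, :, :] = np.where(accept[:, None, :], M_prop, M)
        accepted += int(accept.sum())
    return accepted


def propagate_mh_dirichlet(
    system: ParticleSystem,
    eps_t: float,
    Y: ExpressionMatrix,
    priors: PriorSpec,
    rng: np.random.Generator,
    *,
    dirichlet_alpha: float | np.ndarray = 1.0,
    mh_sweeps: int = 10,
    mh_step: float = 0.1,
) -> ParticleSystem:
    """Non-conjugate variant: Dirichlet prior on proportion columns.

    lambda and X are propagated exactly as in :func:`propagate_gibbs`; every
    proportion column is updated by ``mh_sweeps`` Metropolis-Hastings steps
    targeting the tempered target, staying on the simplex throughout.
    """
    if not 0.0 <= eps_t <= 1.0:
        raise ValueError(f"eps_t must lie in [0, 1], got {eps_t}")
    K = system.M.shape[1]
    if np.any(system.M < 0) or not np.allclose(system.M.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("proportion columns must lie on the simplex")
    alpha_dir = np.broadcast_to(
        np.asarray(dirichlet_alpha, dtype=float), (K,)
    ).copy()
    out = system.copy()
    _gibbs_sweep(Y.values, out.X, out.M, out.lam, eps_t, priors, rng, update_m=False)
    _mh_update_columns(
        Y.values, out.X, out.M, out.lam, eps_t, alpha_dir, mh_step, mh_sweeps, rng
    )
    return out


def _check_system(w: np.ndarray, n: int) -> float:
    """In-loop invariants: weights normalized and ESS within [1, N]."""
    if abs(float(w.sum()) - 1.0) > 1e-9:
        raise RuntimeError("normalized weights do not sum to 1")
    e = ess(w)
    if not 1.0 - 1e-9 <= e <= n + 1e-9:
        raise RuntimeError(f"ESS {e} outside [1, {n}]")
    return e


def run_smc(
    Y: ExpressionMatrix,
    K: int,
    config: SMCConfig | None = None,
    priors: PriorSpec | None = None,
) -> tuple[ParticleSystem, RunDiagnostics]:
    """Run the full tempered SMC sampler on Y with K cell types.

    At every temperature the order is fixed: (i) log-weight update from the
    previous particle values, (ii) normalization, (iii) ESS check and
    resampling, (iv) propagation.  Returns the final weighted particle
    system and its diagnostics.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    config = config or SMCConfig()
    if priors is None:
        priors = default_priors(Y, K)
    if priors.n_genes != Y.n_genes or priors.n_samples != Y.n_samples or priors.n_types != K:
        raise ValueError("priors are inconsistent with Y and K")
    rng = np.random.default_rng(config.seed)
    sched = config.schedule()
    eps = sched.eps
    N = config.n_particles
    Yv = Y.values
    I, J = Yv.shape

    lam = rng.gamma(priors.alpha, 1.0 / priors.beta, size=N)
    if config.kernel == "mh_dirichlet":
        alpha_dir = np.full(K, float(config.dirichlet_alpha))
        M = rng.dirichlet(alpha_dir, size=(N, J)).transpose(0, 2, 1)
    else:
        M = rng.normal(priors.mu_m, priors.nu_m ** -0.5, size=(N, K, J))
    X = rng.normal(priors.mu_x, priors.nu_x ** -0.5, size=(N, I, K))

    diag = RunDiagnostics(eps_used=sched)
    log_w = np.full(N, -np.log(N))
    diag.ess_trace.append(float(N))
    system = ParticleSystem(X, M, lam, log_w, t=0, diagnostics=diag)

    for t in range(1, len(eps)):
        d_eps = eps[t] - eps[t - 1]
        ll = _log_likelihood_stacked(Yv, system.X, system.M, system.lam)
        bad = ~np.isfinite(ll)
        if np.any(bad):
            ll = np.where(bad, -np.inf, ll)
        new_lw = system.log_weights + d_eps * ll
        if config.track_history:
            diag.incremental_log_weights.append(d_eps * ll)
        if not np.any(np.isfinite(new_lw)):
            raise DegenerateWeightsError(
                f"every particle has non-finite weight at temperature index {t}"
            )
        system.log_weights = new_lw
        system.t = t
        w = system.norm_weights
        e = _check_system(w, N)
        diag.ess_trace.append(e)
        if e < config.resample_fraction * N:
            system = resample(system, rng, config.resample_method)

        if config.kernel == "mh_dirichlet":
            system = propagate_mh_dirichlet(
                system, eps[t], Y, priors, rng,
                dirichlet_alpha=config.dirichlet_alpha,
                mh_sweeps=config.mh_sweeps,
                mh_step=config.mh_step,
            )
        else:
            system = propagate_gibbs(system, eps[t], Y, priors, rng)

    lw = system.log_weights
    diag.final_log_weight_spread = float(np.max(lw) - np.min(lw))
    return system, diag


@dataclass
class GibbsSummary:
    """Posterior means/sds from a plain Gibbs run, plus thinned draws."""

    X_mean: np.ndarray
    X_sd: np.ndarray
    M_mean: np.ndarray
    M_sd: np.ndarray
    lam_mean: float
    lam_sd: float
    n_draws: int
    M_draws: np.ndarray
    lam_draws: np.ndarray


def gibbs_oracle(
    Y: ExpressionMatrix,
    K: int,
    priors: PriorSpec | None = None,
    chain_length: int = 40_000,
    burn_in: int = 20_000,
    thin: int = 20,
    rng: np.random.Generator | int | None = None,
) -> GibbsSummary:
    """Plain Gibbs sampler on the untempered posterior (eps = 1).

    Uses exactly the tempered conditionals at eps = 1.  The chain starts from
    equal proportions and the prior-mean signatures.  Post-burn-in draws are
    thinned and summarized by mean and standard deviation.
    """
    if burn_in >= chain_length:
        raise ValueError("burn_in must be smaller than chain_length")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    if priors is None:
        priors = default_priors(Y, K)
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    Yv = Y.values
    I, J = Yv.shape

    X = np.tile(priors.mu_x[None], (1, 1, 1)).astype(float).copy()
    M = np.full((1, K, J), 1.0 / K)
    lam = np.ones(1)

    kept_X_sum = np.zeros((I, K))
    kept_X_sq = np.zeros((I, K))
    M_draws, lam_draws = [], []
    for it in range(chain_length):
        _gibbs_sweep(Yv, X, M, lam, 1.0, priors, rng)
        if it >= burn_in and (it - burn_in) % thin == 0:
            kept_X_sum += X[0]
            kept_X_sq += X[0] ** 2
            M_draws.append(M[0].copy())
            lam_draws.append(float(lam[0]))

    M_arr = np.asarray(M_draws)
    lam_arr = np.asarray(lam_draws)
    n = len(lam_draws)
    X_mean = kept_X_sum / n
    X_var = np.maximum(kept_X_sq / n - X_mean ** 2, 0.0)
    return GibbsSummary(
        X_mean=X_mean,
        X_sd=np.sqrt(X_var),
        M_mean=M_arr.mean(axis=0),
        M_sd=M_arr.std(axis=0),
        lam_mean=float(lam_arr.mean()),
        lam_sd=float(lam_arr.std()),
        n_draws=n,
        M_draws=M_arr,
        lam_draws=lam_arr,
    )
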