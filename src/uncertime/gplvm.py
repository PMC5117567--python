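"""Bayesian Gaussian-process latent variable model for probabilistic pseudotime.

The model assigns each cell i a latent pseudotime t_i in [0, 1) and treats
each dimension j of the low-dimensional embedding as a draw from a Gaussian
process over pseudotime:

    gamma      ~ Gamma(gamma_alpha, gamma_beta)          (shape-rate)
    lambda_j   ~ Exponential(gamma),        j = 1..P
    sigma_j^2  ~ InvGamma(alpha, beta),     j = 1..P
    t_i        ~ TruncNormal_[0,1)(mu_t, sigma_t^2)
    K^(j)(t, t') = exp(-lambda_j (t - t')^2)
    X_{. j} | t ~ MultiNormal(0, K^(j) + sigma_j^2 I)

The GP mean functions are marginalized analytically, so the sampled state is
(t, lambda, sigma^2, gamma) only.  |lambda| behaves like the arc-length of
the trajectory: shrinking it (via the Gamma hyperprior on the Exponential
rate gamma) yields smoother trajectories.

Posterior inference is by Hamiltonian Monte Carlo on unconstrained
reparameterizations (logit of t, log of the positive parameters) with
analytic gradients of the GP marginal likelihood, dual-averaging step-size
adaptation and a diagonal mass matrix estimated during warmup.  An adaptive
random-walk Metropolis fallback is available (``method="rw"``).  The
contract is "draws from the model posterior", not a specific algorithm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit, gammaln, logit
from scipy.stats import norm

from .embed import Embedding

__all__ = [
    "GPLVMHyperparams",
    "GPLVMState",
    "MCMCSettings",
    "PseudotimePosterior",
    "NumericalError",
    "kernel_matrix",
    "log_marginal",
    "log_prior",
    "log_joint",
    "sample_posterior",
    "orient_and_map",
    "hpd_interval",
    "predictive_density",
    "summarize_posterior",
]

DEFAULT_JITTER = 1e-6
MAX_JITTER = 1e-3
RHAT_WARN_THRESHOLD = 1.1


class NumericalError(RuntimeError):
    """Raised when a covariance factorization fails even after jitter escalation."""


@dataclass(frozen=True)
class GPLVMHyperparams:
    """Fixed constants of the hierarchical model.

    Defaults use the high-shrinkage setting (gamma_alpha, gamma_beta) =
    (30, 5) under which independent chains agree on the mean trajectory,
    a diffuse InvGamma(1, 1) on the noise variances, and a wide truncated
    normal centred at 0.5 on the pseudotimes.
    """

    gamma_alpha: float = 30.0
    gamma_beta: float = 5.0
    alpha: float = 1.0
    beta: float = 1.0
    mu_t: float = 0.5
    sigma_t_sq: float = 1.0

    def __post_init__(self) -> None:
        for name in ("gamma_alpha", "gamma_beta", "alpha", "beta", "sigma_t_sq"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 <= self.mu_t <= 1.0:
            raise ValueError("mu_t must be in [0, 1]")


@dataclass(frozen=True)
class GPLVMState:
    """One point in parameter space: pseudotimes, inverse squared
    length-scales, noise variances and the shrinkage rate."""

    t: np.ndarray
    lam: np.ndarray
    sigma_sq: np.ndarray
    gamma: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "lam", np.atleast_1d(np.asarray(self.lam, dtype=float)))
        object.__setattr__(self, "sigma_sq", np.atleast_1d(np.asarray(self.sigma_sq, dtype=float)))

    def in_support(self) -> bool:
        return bool(
            np.all((self.t >= 0.0) & (self.t < 1.0))
            and np.all(self.lam > 0)
            and np.all(self.sigma_sq > 0)
            and self.gamma > 0
        )


@dataclass(frozen=True)
class MCMCSettings:
    chains: int = 2
    warmup: int = 1000
    samples: int = 1000
    thin: int = 1
    seed: int = 1
    method: str = "hmc"  # "hmc" or "rw"
    init: str = "pc1"  # "pc1" or "prior"
    target_accept: float = 0.8

    def __post_init__(self) -> None:
        if self.chains < 1 or self.warmup < 10 or self.samples < 1 or self.thin < 1:
            raise ValueError("invalid MCMC settings")
        if self.method not in ("hmc", "rw"):
            raise ValueError("method must be 'hmc' or 'rw'")
        if self.init not in ("pc1", "prior"):
            raise ValueError("init must be 'pc1' or 'prior'")


@dataclass
class PseudotimePosterior:
    """Retained post-warmup draws of the model state plus chain metadata."""

    t: np.ndarray  # S x N
    lam: np.ndarray  # S x P
    sigma_sq: np.ndarray  # S x P
    gamma: np.ndarray  # S
    chain_id: np.ndarray  # S
    log_posterior: np.ndarray  # S
    map_index: int
    cell_ids: tuple[str, ...]
    hyperparams: GPLVMHyperparams
    diagnostics: dict = field(default_factory=dict)
    warnings_: list = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return self.t.shape[0]

    @property
    def n_cells(self) -> int:
        return self.t.shape[1]

    def state(self, s: int) -> GPLVMState:
        return GPLVMState(self.t[s], self.lam[s], self.sigma_sq[s], float(self.gamma[s]))

    def map_state(self) -> GPLVMState:
        return self.state(self.map_index)

    def t_mean(self) -> np.ndarray:
        return self.t.mean(axis=0)


# ---------------------------------------------------------------------------
# Model densities
# ---------------------------------------------------------------------------


def kernel_matrix(t: np.ndarray, lam: float, jitter: float = 0.0) -> np.ndarray:
    """Squared-exponential (double exponential) kernel exp(-lam (t - t')^2)
    with ``jitter`` added to the diagonal."""
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise NumericalError("non-finite pseudotimes in kernel evaluation")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    D = (t[:, None] - t[None, :]) ** 2
    K = np.exp(-lam * D)
    if jitter:
        K[np.diag_indices_from(K)] += jitter
    return K


def _coords(X) -> np.ndarray:
    if isinstance(X, Embedding):
        return X.coords
    return np.atleast_2d(np.asarray(X, dtype=float))


def _chol_with_escalation(C: np.ndarray, lam: float, base_jitter: float):
    jitter = max(base_jitter, DEFAULT_JITTER)
    extra = 0.0
    while True:
        try:
            return cho_factor(C + extra * np.eye(C.shape[0]), lower=True)
        except np.linalg.LinAlgError:
            extra = jitter if extra == 0.0 else extra * 10.0
            if extra > MAX_JITTER:
                raise NumericalError(
                    f"covariance factorization failed for lambda={lam:g} even with "
                    f"jitter {MAX_JITTER:g}"
                ) from None


def log_marginal(t, lam, sigma_sq, X, jitter: float = DEFAULT_JITTER) -> float:
    """Log-likelihood of the embedding with the GP mean functions integrated out.

    Per dimension j the column X_{. j} is a zero-mean multivariate normal
    with covariance K^(j) + sigma_j^2 I; computed via Cholesky factorization,
    never an explicit inverse.
    """
    Xc = _coords(X)
    t = np.asarray(t, dtype=float)
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    sigma_sq = np.atleast_1d(np.asarray(sigma_sq, dtype=float))
    N, P = Xc.shape
    if len(t) != N or len(lam) != P or len(sigma_sq) != P:
        raise ValueError("inconsistent dimensions in log_marginal")
    total = 0.0
    for j in range(P):
        K = kernel_matrix(t, lam[j], jitter)
        C = K + sigma_sq[j] * np.eye(N)
        cho = _chol_with_escalation(C, lam[j], jitter)
        x = Xc[:, j]
        alpha = cho_solve(cho, x)
        logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
        total += -0.5 * (x @ alpha + logdet + N * np.log(2.0 * np.pi))
    return float(total)


def _trunc_norm_const(h: GPLVMHyperparams) -> float:
    sd = np.sqrt(h.sigma_t_sq)
    return float(np.log(norm.cdf((1.0 - h.mu_t) / sd) - norm.cdf((0.0 - h.mu_t) / sd)))


def log_prior(state: GPLVMState, h: GPLVMHyperparams) -> float:
    """Sum of the log prior densities, with normalizing constants (including
    the [0, 1) truncation constant).  Outside the support returns -inf."""
    if not state.in_support():
        return -np.inf
    g, lam, s, t = state.gamma, state.lam, state.sigma_sq, state.t
    P, N = len(lam), len(t)
    lp = (
        h.gamma_alpha * np.log(h.gamma_beta)
        - gammaln(h.gamma_alpha)
        + (h.gamma_alpha - 1.0) * np.log(g)
        - h.gamma_beta * g
    )
    lp += P * np.log(g) - g * np.sum(lam)
    lp += np.sum(
        h.alpha * np.log(h.beta) - gammaln(h.alpha) - (h.alpha + 1.0) * np.log(s) - h.beta / s
    )
    lp += np.sum(-0.5 * np.log(2.0 * np.pi * h.sigma_t_sq) - (t - h.mu_t) ** 2 / (2.0 * h.sigma_t_sq))
    lp -= N * _trunc_norm_const(h)
    return float(lp)


def log_joint(state: GPLVMState, X, h: GPLVMHyperparams, jitter: float = DEFAULT_JITTER) -> float:
    """Log joint density of the state and data: marginal GP likelihood plus
    all prior terms.  States outside the prior support get -inf, not an
    exception."""
    lp = log_prior(state, h)
    if not np.isfinite(lp):
        return -np.inf
    return lp + log_marginal(state.t, state.lam, state.sigma_sq, X, jitter)


# ---------------------------------------------------------------------------
# Unconstrained parameterization and gradients
# ---------------------------------------------------------------------------
# z = [logit(t) (N), log(lambda) (P), log(sigma_sq) (P), log(gamma) (1)]


def _marginal_and_grad(t, lam, sigma_sq, Xc, jitter):
    """Log marginal likelihood plus its gradients w.r.t. t, lambda, sigma^2.

    Uses the standard GP identity d logL = 1/2 tr((aa' - C^{-1}) dC) with
    a = C^{-1} x, evaluated per embedding dimension.
    """
    N, P = Xc.shape
    tdiff = t[:, None] - t[None, :]
    D = tdiff**2
    lp = 0.0
    g_t = np.zeros(N)
    g_lam = np.zeros(P)
    g_sig = np.zeros(P)
    eye = np.eye(N)
    for j in range(P):
        K = np.exp(-lam[j] * D)
        C = K + (sigma_sq[j] + jitter) * eye
        cho = _chol_with_escalation(C, lam[j], jitter)
        x = Xc[:, j]
        a = cho_solve(cho, x)
        Cinv = cho_solve(cho, eye)
        logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
        lp += -0.5 * (x @ a + logdet + N * np.log(2.0 * np.pi))
        M = np.outer(a, a) - Cinv
        g_sig[j] = 0.5 * np.trace(M)
        g_lam[j] = -0.5 * np.sum(M * D * K)
        W = (-2.0 * lam[j]) * tdiff * K
        g_t += np.sum(M * W, axis=1)
    return lp, g_t, g_lam, g_sig


def _split_z(z: np.ndarray, N: int, P: int):
    return z[:N], z[N : N + P], z[N + P : N + 2 * P], z[-1]


def _logpost_and_grad(z: np.ndarray, Xc: np.ndarray, h: GPLVMHyperparams, jitter: float):
    """Log posterior density and gradient in the unconstrained space
    (including the change-of-variables Jacobian)."""
    N, P = Xc.shape
    if not np.all(np.isfinite(z)) or np.max(np.abs(z)) > 50.0:
        # divergent leapfrog trajectory; treat as zero density
        return -np.inf, np.zeros_like(z)
    z_t, z_l, z_s, z_g = _split_z(z, N, P)
    t = expit(z_t)
    lam = np.exp(z_l)
    sig = np.exp(z_s)
    gam = np.exp(z_g)
    if not (np.all(np.isfinite(t)) and np.all(lam > 0) and np.all(sig > 0) and gam > 0):
        return -np.inf, np.zeros_like(z)
    if np.any(t <= 0.0) or np.any(t >= 1.0):  # expit rounded to the boundary
        return -np.inf, np.zeros_like(z)

    try:
        lp, g_t, g_lam, g_sig = _marginal_and_grad(t, lam, sig, Xc, jitter)
    except (NumericalError, np.linalg.LinAlgError, ValueError):
        return -np.inf, np.zeros_like(z)

    # priors (constrained space), with normalizing constants
    lp += (
        h.gamma_alpha * np.log(h.gamma_beta)
        - gammaln(h.gamma_alpha)
        + (h.gamma_alpha - 1.0) * np.log(gam)
        - h.gamma_beta * gam
    )
    lp += P * np.log(gam) - gam * np.sum(lam)
    lp += np.sum(
        h.alpha * np.log(h.beta) - gammaln(h.alpha) - (h.alpha + 1.0) * np.log(sig) - h.beta / sig
    )
    lp += np.sum(
        -0.5 * np.log(2.0 * np.pi * h.sigma_t_sq) - (t - h.mu_t) ** 2 / (2.0 * h.sigma_t_sq)
    )
    lp -= N * _trunc_norm_const(h)

    g_t += -(t - h.mu_t) / h.sigma_t_sq
    g_lam += -gam
    g_sig += -(h.alpha + 1.0) / sig + h.beta / sig**2
    g_gam = (h.gamma_alpha - 1.0) / gam - h.gamma_beta + P / gam - np.sum(lam)

    # Jacobian of the transform and chain rule to z-space
    lp += np.sum(np.log(t) + np.log1p(-t)) + np.sum(z_l) + np.sum(z_s) + z_g
    gz = np.empty_like(z)
    gz[:N] = g_t * t * (1.0 - t) + (1.0 - 2.0 * t)
    gz[N : N + P] = g_lam * lam + 1.0
    gz[N + P : N + 2 * P] = g_sig * sig + 1.0
    gz[-1] = g_gam * gam + 1.0
    if not np.isfinite(lp):
        return -np.inf, np.zeros_like(z)
    return float(lp), gz


def _z_to_state(z: np.ndarray, N: int, P: int) -> GPLVMState:
    z_t, z_l, z_s, z_g = _split_z(z, N, P)
    return GPLVMState(expit(z_t), np.exp(z_l), np.exp(z_s), float(np.exp(z_g)))


def _log_jacobian(z: np.ndarray, N: int, P: int) -> float:
    z_t, z_l, z_s, z_g = _split_z(z, N, P)
    t = expit(z_t)
    return float(np.sum(np.log(t) + np.log1p(-t)) + np.sum(z_l) + np.sum(z_s) + z_g)


# ---------------------------------------------------------------------------
# Samplers
# ---------------------------------------------------------------------------


def _hmc_chain(z0, logpost_grad, n_warmup, n_samples, thin, rng, target_accept):
    d = len(z0)
    z = z0.copy()
    lp, g = logpost_grad(z)
    if not np.isfinite(lp):
        raise NumericalError("initial state has zero posterior density")

    mass_inv = np.ones(d)
    eps = _find_reasonable_eps(z, lp, g, logpost_grad, mass_inv, rng)
    # dual averaging (Nesterov) constants
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    da_gamma, da_t0, da_kappa = 0.05, 10.0, 0.75
    da_count = 0

    win_start = n_warmup // 4
    win_end = n_warmup // 2
    window: list[np.ndarray] = []

    draws = np.empty((n_samples, d))
    lps = np.empty(n_samples)
    n_accept = 0
    n_total = 0
    kept = 0
    it = 0
    total_iters = n_warmup + n_samples * thin
    while kept < n_samples:
        L = int(rng.integers(5, 16))
        p = rng.normal(size=d) / np.sqrt(mass_inv)
        H0 = -lp + 0.5 * np.sum(p**2 * mass_inv)
        z_new, g_new, lp_new = z.copy(), g.copy(), lp
        ok = True
        p_new = p + 0.5 * eps * g_new
        for _ in range(L):
            z_new = z_new + eps * mass_inv * p_new
            lp_new, g_new = logpost_grad(z_new)
            if not np.isfinite(lp_new):
                ok = False
                break
            p_new = p_new + eps * g_new
        if ok:
            p_new = p_new - 0.5 * eps * g_new  # undo the extra half step
            H1 = -lp_new + 0.5 * np.sum(p_new**2 * mass_inv)
            accept_prob = min(1.0, np.exp(min(0.0, H0 - H1)))
        else:
            accept_prob = 0.0
        if rng.uniform() < accept_prob:
            z, lp, g = z_new, lp_new, g_new
            if it >= n_warmup:
                n_accept += 1
        if it >= n_warmup:
            n_total += 1

        if it < n_warmup:
            # dual-averaging step-size adaptation
            da_count += 1
            frac = 1.0 / (da_count + da_t0)
            h_bar = (1.0 - frac) * h_bar + frac * (target_accept - accept_prob)
            log_eps = mu - np.sqrt(da_count) / da_gamma * h_bar
            eta = da_count ** (-da_kappa)
            log_eps_bar = eta * log_eps + (1.0 - eta) * log_eps_bar
            eps = float(np.exp(log_eps))
            if win_start <= it < win_end:
                window.append(z.copy())
            if it == win_end and len(window) > 10:
                var = np.var(np.asarray(window), axis=0)
                mass_inv = np.clip(var, 1e-6, None)
                # restart step-size search under the new metric
                eps = _find_reasonable_eps(z, lp, g, logpost_grad, mass_inv, rng)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, da_count = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            post_it = it - n_warmup
            if (post_it + 1) % thin == 0:
                draws[kept] = z
                lps[kept] = lp
                kept += 1
        it += 1
        if it > 50 * total_iters:  # safety net; cannot normally trigger
            raise NumericalError("sampler failed to make progress")
    accept_rate = n_accept / max(n_total, 1)
    return draws, lps, accept_rate


def _find_reasonable_eps(z, lp, g, logpost_grad, mass_inv, rng, eps0=0.1):
    """Double/halve the step size until one leapfrog step has acceptance
    probability near 0.5 (the standard initialization heuristic)."""
    eps = eps0
    p = rng.normal(size=len(z)) / np.sqrt(mass_inv)
    H0 = -lp + 0.5 * np.sum(p**2 * mass_inv)

    def one_step(eps):
        p1 = p + 0.5 * eps * g
        z1 = z + eps * mass_inv * p1
        lp1, g1 = logpost_grad(z1)
        if not np.isfinite(lp1):
            return -np.inf
        p1 = p1 + 0.5 * eps * g1
        return -(-lp1 + 0.5 * np.sum(p1**2 * mass_inv)) + H0

    log_ratio = one_step(eps)
    direction = 1.0 if log_ratio > np.log(0.5) else -1.0
    for _ in range(50):
        eps = eps * (2.0**direction)
        log_ratio = one_step(eps)
        if (direction == 1.0 and log_ratio <= np.log(0.5)) or (
            direction == -1.0 and log_ratio >= np.log(0.5)
        ):
            break
        if eps < 1e-8 or eps > 1e3:
            break
    return float(eps)


def _rw_chain(z0, logpost_grad, n_warmup, n_samples, thin, rng, target_accept=0.234):
    """Adaptive random-walk Metropolis fallback (gradient-free)."""
    d = len(z0)
    z = z0.copy()
    lp, _ = logpost_grad(z)
    if not np.isfinite(lp):
        raise NumericalError("initial state has zero posterior density")
    log_scale = np.log(0.1 / np.sqrt(d))
    scale_vec = np.ones(d)
    window: list[np.ndarray] = []
    draws = np.empty((n_samples, d))
    lps = np.empty(n_samples)
    n_accept = n_total = kept = it = 0
    while kept < n_samples:
        prop = z + np.exp(log_scale) * scale_vec * rng.normal(size=d)
        lp_prop, _ = logpost_grad(prop)
        accept_prob = np.exp(min(0.0, lp_prop - lp)) if np.isfinite(lp_prop) else 0.0
        if rng.uniform() < accept_prob:
            z, lp = prop, lp_prop
            if it >= n_warmup:
                n_accept += 1
        if it >= n_warmup:
            n_total += 1
        if it < n_warmup:
            log_scale += (accept_prob - target_accept) / (1.0 + it) ** 0.6
            if n_warmup // 4 <= it < n_warmup // 2:
                window.append(z.copy())
            if it == n_warmup // 2 and len(window) > 10:
                scale_vec = np.sqrt(np.clip(np.var(np.asarray(window), axis=0), 1e-6, None))
        else:
            post_it = it - n_warmup
            if (post_it + 1) % thin == 0:
                draws[kept] = z
                lps[kept] = lp
                kept += 1
        it += 1
    return draws, lps, n_accept / max(n_total, 1)


def _initial_z(Xc, h, settings, chain, rng):
    N, P = Xc.shape
    eps_edge = 0.025
    if settings.init == "pc1":
        ranks = np.argsort(np.argsort(Xc[:, 0])).astype(float)
        t0 = eps_edge + (1.0 - 2.0 * eps_edge) * ranks / max(N - 1, 1)
        if chain % 2 == 1:
            t0 = 1.0 - t0  # alternate orientation across chains
        t0 = np.clip(t0 + rng.normal(0.0, 0.02, size=N), 1e-4, 1.0 - 1e-4)
        lam0 = np.full(P, 5.0) * np.exp(rng.normal(0.0, 0.2, size=P))
        sig0 = np.full(P, 0.1) * np.exp(rng.normal(0.0, 0.2, size=P))
        gam0 = h.gamma_alpha / h.gamma_beta
    else:
        gam0 = rng.gamma(h.gamma_alpha, 1.0 / h.gamma_beta)
        lam0 = rng.exponential(1.0 / gam0, size=P) + 1e-3
        sig0 = 1.0 / rng.gamma(h.alpha, 1.0 / h.beta, size=P)
        sig0 = np.clip(sig0, 1e-3, 10.0)
        sd = np.sqrt(h.sigma_t_sq)
        t0 = np.clip(
            h.mu_t + sd * rng.standard_normal(N), 1e-3, 1.0 - 1e-3
        )
    z = np.concatenate([logit(t0), np.log(lam0), np.log(sig0), [np.log(gam0)]])
    return z


def sample_posterior(
    X,
    h: GPLVMHyperparams | None = None,
    settings: MCMCSettings | None = None,
    jitter: float = DEFAULT_JITTER,
) -> PseudotimePosterior:
    """Draw posterior samples of (t, lambda, sigma^2, gamma) given an
    N x P embedding.

    The embedding should be standardized (zero mean, unit sd per dimension)
    since the kernel amplitude is fixed at 1.  Runs ``settings.chains``
    independent chains; per-parameter split-R-hat and effective sample sizes
    are stored in ``diagnostics`` and an R-hat above 1.1 produces a warning
    recorded on the result (never silent).
    """
    if h is None:
        h = GPLVMHyperparams()
    if settings is None:
        settings = MCMCSettings()
    Xc = _coords(X)
    N, P = Xc.shape
    if N < 3:
        raise ValueError("need at least 3 cells")
    cell_ids = (
        X.cell_ids if isinstance(X, Embedding) else tuple(f"cell_{i:04d}" for i in range(N))
    )

    def logpost_grad(z):
        try:
            return _logpost_and_grad(z, Xc, h, jitter)
        except NumericalError:
            return -np.inf, np.zeros_like(z)

    chain_fn = _hmc_chain if settings.method == "hmc" else _rw_chain
    all_z, all_lp, all_chain, accept_rates = [], [], [], []
    root = np.random.SeedSequence(settings.seed)
    chain_seeds = root.spawn(settings.chains)
    for c in range(settings.chains):
        rng = np.random.default_rng(chain_seeds[c])
        z0 = _initial_z(Xc, h, settings, c, rng)
        if settings.method == "hmc":
            draws, lps, acc = chain_fn(
                z0, logpost_grad, settings.warmup, settings.samples, settings.thin,
                rng, settings.target_accept,
            )
        else:
            draws, lps, acc = chain_fn(
                z0, logpost_grad, settings.warmup, settings.samples, settings.thin, rng
            )
        all_z.append(draws)
        all_lp.append(lps)
        all_chain.append(np.full(settings.samples, c))
        accept_rates.append(acc)

    Z = np.concatenate(all_z)
    S = Z.shape[0]
    t_draws = expit(Z[:, :N])
    lam_draws = np.exp(Z[:, N : N + P])
    sig_draws = np.exp(Z[:, N + P : N + 2 * P])
    gam_draws = np.exp(Z[:, -1])
    # stored log posterior is the constrained-space joint density
    lp_draws = np.concatenate(all_lp) - np.array(
        [_log_jacobian(Z[s], N, P) for s in range(S)]
    )

    diagnostics = _diagnostics(t_draws, lam_draws, sig_draws, gam_draws, settings)
    diagnostics["accept_rate"] = accept_rates
    warn_list = []
    max_rhat = diagnostics.get("max_rhat", np.nan)
    if np.isfinite(max_rhat) and max_rhat > RHAT_WARN_THRESHOLD:
        msg = f"split R-hat {max_rhat:.3f} exceeds {RHAT_WARN_THRESHOLD}; chains may not have mixed"
        warn_list.append(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)

    return PseudotimePosterior(
        t=t_draws,
        lam=lam_draws,
        sigma_sq=sig_draws,
        gamma=gam_draws,
        chain_id=np.concatenate(all_chain),
        log_posterior=lp_draws,
        map_index=int(np.argmax(lp_draws)),
        cell_ids=tuple(cell_ids),
        hyperparams=h,
        diagnostics=diagnostics,
        warnings_=warn_list,
    )


def _diagnostics(t_draws, lam_draws, sig_draws, gam_draws, settings) -> dict:
    import arviz as az

    C, S = settings.chains, t_draws.shape[0] // settings.chains

    def by_chain(a):
        return a.reshape(C, S, *a.shape[1:])

    # the posterior is invariant under t -> 1 - t, so chains are aligned to a
    # common orientation before computing cross-chain diagnostics (otherwise
    # R-hat on t reports the reversal symmetry, not a mixing failure)
    t_by_chain = by_chain(t_draws).copy()
    ref = t_by_chain[0].mean(axis=0)
    for c in range(1, C):
        m = t_by_chain[c].mean(axis=0)
        if np.corrcoef(m, ref)[0, 1] < 0:
            t_by_chain[c] = 1.0 - t_by_chain[c]

    data = {
        "t": t_by_chain,
        "lam": by_chain(lam_draws),
        "sigma_sq": by_chain(sig_draws),
        "gamma": by_chain(gam_draws),
    }
    if C == 1 and S >= 8:
        # split the single chain in half so split-R-hat is still defined
        half = S // 2
        data = {k: v[:, : 2 * half].reshape(2, half, *v.shape[2:]) for k, v in data.items()}
    elif C == 1:
        return {"rhat": {}, "ess": {}, "max_rhat": float("nan"), "min_ess": float("nan")}
    idata = az.from_dict(posterior=data)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    rhat_d = {k: np.asarray(v.values) for k, v in rhat.data_vars.items()}
    ess_d = {k: np.asarray(v.values) for k, v in ess.data_vars.items()}
    max_rhat = float(np.nanmax([np.nanmax(v) for v in rhat_d.values()]))
    min_ess = float(np.nanmin([np.nanmin(v) for v in ess_d.values()]))
    return {"rhat": rhat_d, "ess": ess_d, "max_rhat": max_rhat, "min_ess": min_ess}


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------


def orient_and_map(post: PseudotimePosterior, anchor) -> PseudotimePosterior:
    """Resolve the arbitrary direction of pseudotime.

    ``anchor`` is either a per-cell real covariate (each draw is flipped
    t -> 1 - t when its correlation with the anchor is negative) or a cell
    ID declared "early" (a draw is flipped when that cell's pseudotime
    exceeds 0.5).  Idempotent; the MAP index is re-derived from the stored
    log posteriors.
    """
    if post.n_draws < 1:
        raise ValueError("empty posterior")
    t = post.t.copy()
    if isinstance(anchor, str):
        try:
            idx = post.cell_ids.index(anchor)
        except ValueError:
            raise KeyError(f"anchor cell {anchor!r} not found") from None
        flip = t[:, idx] > 0.5
    else:
        a = np.asarray(anchor, dtype=float)
        if a.shape != (post.n_cells,):
            raise ValueError("anchor covariate must have one value per cell")
        if np.ptp(a) == 0:
            raise ValueError("anchor is constant; orientation undefined")
        ac = a - a.mean()
        cov = (t - t.mean(axis=1, keepdims=True)) @ ac
        flip = cov < 0
    t[flip] = 1.0 - t[flip]
    return replace(post, t=t, map_index=int(np.argmax(post.log_posterior)))


def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ceil(mass * S) of the sorted
    samples (the empirical HPD of Chen & Shao)."""
    s = np.sort(np.asarray(samples, dtype=float))
    n = len(s)
    if n < 20:
        raise ValueError("need at least 20 samples for an HPD interval")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    m = int(np.ceil(mass * n))
    if m >= n:
        return float(s[0]), float(s[-1])
    widths = s[m - 1 :] - s[: n - m + 1]
    i = int(np.argmin(widths))
    return float(s[i]), float(s[i + m - 1])


def predictive_density(
    post: PseudotimePosterior,
    X,
    grid: np.ndarray,
    t_star: float | None = None,
    n_draws: int = 30,
    n_tstar: int = 30,
    seed: int = 0,
    jitter: float = DEFAULT_JITTER,
) -> np.ndarray:
    """Posterior predictive data density over a grid of embedding points.

    Without ``t_star``: averages, over posterior draws and over pseudotimes
    drawn from the truncated-normal prior, the per-dimension GP predictive
    normal density (conditional mean/variance plus the noise variance) —
    p(x* | X).  With ``t_star``: averages over draws only, conditioning the
    GP at that pseudotime — p(x* | t*, X).  Returns one nonnegative value
    per grid row.
    """
    Xc = _coords(X)
    grid = np.atleast_2d(np.asarray(grid, dtype=float))
    N, P = Xc.shape
    if grid.shape[1] != P:
        raise ValueError("grid dimensionality must match the embedding")
    if t_star is not None and not 0.0 <= t_star < 1.0:
        raise ValueError("t_star must be in [0, 1)")
    rng = np.random.default_rng(seed)
    h = post.hyperparams
    sel = np.unique(np.linspace(0, post.n_draws - 1, min(n_draws, post.n_draws)).astype(int))
    density = np.zeros(grid.shape[0])
    count = 0
    for s in sel:
        t = post.t[s]
        if t_star is not None:
            tstars = np.array([t_star])
        else:
            sd = np.sqrt(h.sigma_t_sq)
            a, b = (0.0 - h.mu_t) / sd, (1.0 - h.mu_t) / sd
            from scipy.stats import truncnorm

            tstars = truncnorm.rvs(a, b, loc=h.mu_t, scale=sd, size=n_tstar, random_state=rng)
            tstars = np.clip(tstars, 0.0, np.nextafter(1.0, 0.0))
        chos, xs = [], []
        for j in range(P):
            K = kernel_matrix(t, post.lam[s, j], jitter)
            C = K + post.sigma_sq[s, j] * np.eye(N)
            chos.append(_chol_with_escalation(C, post.lam[s, j], jitter))
            xs.append(Xc[:, j])
        for ts in tstars:
            dens = np.ones(grid.shape[0])
            for j in range(P):
                kstar = np.exp(-post.lam[s, j] * (ts - t) ** 2)
                mean_j = kstar @ cho_solve(chos[j], xs[j])
                var_j = 1.0 + jitter - kstar @ cho_solve(chos[j], kstar) + post.sigma_sq[s, j]
                var_j = max(var_j, 1e-12)
                dens *= norm.pdf(grid[:, j], loc=mean_j, scale=np.sqrt(var_j))
            density += dens
            count += 1
    return density / count


def summarize_posterior(post: PseudotimePosterior, masses=(0.75, 0.95)) -> pd.DataFrame:
    """Per-cell summary table: posterior mean, MAP pseudotime and HPD
    credible-interval bounds at the requested masses."""
    t_map = post.t[post.map_index]
    rows = {"cell": list(post.cell_ids), "t_mean": post.t.mean(axis=0), "t_map": t_map}
    for mass in masses:
        los, his = [], []
        for i in range(post.n_cells):
            lo, hi = hpd_interval(post.t[:, i], mass)
            los.append(lo)
            his.append(hi)
        pct = int(round(mass * 100))
        rows[f"hpd{pct}_lo"] = los
        rows[f"hpd{pct}_hi"] = his
    return pd.DataFrame(rows)
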