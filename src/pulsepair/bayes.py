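"""Horseshoe-prior Bayesian regression via Hamiltonian Monte Carlo.

The probes downstream of the encoder are logistic (hospitalization) and
linear (heart rate, respiratory rate, SpO2) regressions with a horseshoe
prior on the coefficients:

    β_m = z_m · λ_m · τ_g,   z_m ~ N(0, 1),
    λ_m ~ Half-Cauchy(1),    τ_g ~ Half-Cauchy(τ₀),    α ~ N(0, 10²)

(non-centred parameterization; local scales λ_m give per-coefficient
shrinkage, the global scale τ_g pulls everything toward zero).  The linear
model adds a Half-Cauchy(1) prior on the Gaussian noise scale σ.

Sampling uses Hamiltonian Monte Carlo with analytic gradients in the
unconstrained space (log-transformed scales with Jacobian corrections),
dual-averaging step-size adaptation toward a target acceptance rate, and a
diagonal mass matrix estimated during warmup.  Path length is fixed and the
number of leapfrog steps jittered to avoid resonances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

logger = logging.getLogger(__name__)

__all__ = ["HorseshoeConfig", "HorseshoePosterior", "hmc_sample",
           "fit_horseshoe", "posterior_beta"]


@dataclass(frozen=True)
class HorseshoeConfig:
    """Prior and sampler settings for the horseshoe probes."""

    tau0: float = 1.0       # scale of the Half-Cauchy prior on the global scale
    warmup: int = 500
    draws: int = 500
    chains: int = 1
    target_accept: float = 0.85
    path_length: float = 0.6   # leapfrog integration time per proposal
    seed: int = 0

    def __post_init__(self):
        if self.tau0 <= 0:
            raise ValueError("tau0 must be > 0")
        if self.draws < 1 or self.warmup < 1 or self.chains < 1:
            raise ValueError("draws, warmup and chains must be >= 1")


# ---------------------------------------------------------------------------
# generic HMC

def hmc_sample(logp_and_grad, theta0: np.ndarray, config: HorseshoeConfig,
               rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    """Sample with adaptive HMC; returns (draws, diagnostics).

    Warmup runs in two halves: the first adapts the step size under a unit
    mass matrix, the second re-adapts after estimating a diagonal mass from
    the first half's draws.  Diagnostics report the post-warmup acceptance
    rate and the share of divergent (non-finite) proposals.
    """
    dim = theta0.size
    theta = theta0.astype(np.float64).copy()
    lp, grad = logp_and_grad(theta)

    # dual averaging state (Hoffman & Gelman defaults)
    eps = 0.1
    mu = np.log(10 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    inv_mass = np.ones(dim)
    half = config.warmup // 2
    warm_draws = np.empty((half, dim))
    draws = np.empty((config.draws, dim))
    n_accept = n_div = 0

    total = config.warmup + config.draws
    for it in range(total):
        adapting = it < config.warmup
        r0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        n_steps = max(1, int(config.path_length / eps))
        n_steps = int(rng.integers(max(1, n_steps // 2), n_steps + 1))
        n_steps = min(n_steps, 256)

        th, r, g = theta.copy(), r0.copy(), grad.copy()
        lp_prop = lp
        diverged = False
        # overflow during exploration is expected: it marks a divergent
        # trajectory, which is detected and rejected below
        with np.errstate(over="ignore", invalid="ignore"):
            for _ in range(n_steps):  # leapfrog
                r += 0.5 * eps * g
                th += eps * inv_mass * r
                lp_prop, g = logp_and_grad(th)
                if not np.all(np.isfinite(g)) or not np.isfinite(lp_prop):
                    diverged = True
                    break
                r += 0.5 * eps * g

        if diverged:
            accept_prob = 0.0
            n_div += 0 if adapting else 1
        else:
            h0 = lp - 0.5 * np.sum(inv_mass * r0 * r0)
            h1 = lp_prop - 0.5 * np.sum(inv_mass * r * r)
            accept_prob = min(1.0, np.exp(min(0.0, -(h0 - h1))))
            if rng.random() < accept_prob:
                theta, lp, grad = th, lp_prop, g
                n_accept += 0 if adapting else 1

        if adapting:
            m = it + 1 if it < half else it - half + 1
            h_bar = (1 - 1 / (m + t0)) * h_bar + (
                config.target_accept - accept_prob) / (m + t0)
            log_eps = mu - np.sqrt(m) / gamma * h_bar
            w = m ** -kappa
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            if it < half:
                warm_draws[it] = theta
            if it == half - 1:
                # diagonal mass from first-half variances, then restart
                var = warm_draws.var(axis=0)
                inv_mass = np.clip(var, 1e-6, 1e6)
                eps = float(np.exp(log_eps_bar))
                mu = np.log(10 * eps)
                log_eps_bar, h_bar = 0.0, 0.0
            if it == config.warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            draws[it - config.warmup] = theta

    diag = {"accept_rate": n_accept / config.draws,
            "divergence_rate": n_div / config.draws,
            "step_size": eps}
    if diag["divergence_rate"] > 0.05:
        logger.warning("HMC divergence rate %.1f%% — posterior may be "
                       "under-explored", 100 * diag["divergence_rate"])
    return draws, diag


# ---------------------------------------------------------------------------
# horseshoe regression log-posteriors

def _unpack(theta: np.ndarray, m: int, linear: bool):
    alpha = theta[0]
    z = theta[1: 1 + m]
    eta = theta[1 + m: 1 + 2 * m]      # log local scales
    gamma = theta[1 + 2 * m]           # log global scale
    rho = theta[2 + 2 * m] if linear else None  # log noise scale
    return alpha, z, eta, gamma, rho


def _horseshoe_logp_and_grad(theta, x, y, tau0, linear):
    n, m = x.shape
    alpha, z, eta, gamma, rho = _unpack(theta, m, linear)
    lam = np.exp(eta)
    tau = np.exp(gamma)
    beta = z * lam * tau
    pred = alpha + x @ beta

    grad = np.empty_like(theta)
    if linear:
        inv_var = np.exp(-2 * np.clip(rho, -300, 300))
        resid = y - pred
        ll = -n * rho - 0.5 * np.sum(resid ** 2) * inv_var
        dpred = resid * inv_var
        grad[2 + 2 * m] = (-n + np.sum(resid ** 2) * inv_var
                           - 2.0 / (1.0 + np.exp(np.clip(-2 * rho, None, 300))) + 1)
    else:
        # logistic: ll = sum y*pred - log(1 + e^pred)
        ll = float(np.sum(y * pred) - np.sum(np.logaddexp(0.0, pred)))
        dpred = y - 1.0 / (1.0 + np.exp(-pred))

    dbeta = x.T @ dpred
    grad[0] = np.sum(dpred) - alpha / 100.0
    grad[1: 1 + m] = dbeta * lam * tau - z
    grad[1 + m: 1 + 2 * m] = (dbeta * beta
                              - 2.0 / (1.0 + np.exp(np.clip(-2 * eta, None, 300))) + 1)
    grad[1 + 2 * m] = (np.sum(dbeta * beta)
                       - 2 * (tau / tau0) ** 2 / (1 + (tau / tau0) ** 2) + 1)

    logp = (ll - 0.5 * alpha ** 2 / 100.0 - 0.5 * np.sum(z ** 2)
            - np.sum(np.logaddexp(0.0, 2 * eta)) + np.sum(eta)
            - np.log1p((tau / tau0) ** 2) + gamma)
    if linear:
        logp += -np.logaddexp(0.0, 2 * rho) + rho
    return logp, grad


@dataclass
class HorseshoePosterior:
    """Posterior draws of a horseshoe regression on standardized features."""

    alpha: np.ndarray          # (draws,)
    beta: np.ndarray           # (draws, m)
    tau: np.ndarray            # (draws,) global scale
    sigma: np.ndarray | None   # (draws,) noise SD, linear models only
    linear: bool
    diagnostics: dict

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Posterior-mean probability (logistic) or linear predictor."""
        pred = self.alpha[:, None] + self.beta @ x.T  # (draws, n)
        if self.linear:
            return pred.mean(axis=0)
        return expit(pred).mean(axis=0)

    def coef_summary(self) -> dict[str, np.ndarray]:
        return {
            "mean": self.beta.mean(axis=0),
            "ci_low": np.quantile(self.beta, 0.025, axis=0),
            "ci_high": np.quantile(self.beta, 0.975, axis=0),
        }


def fit_horseshoe(x: np.ndarray, y: np.ndarray, config: HorseshoeConfig,
                  linear: bool) -> HorseshoePosterior:
    """Fit a horseshoe logistic (``linear=False``) or linear regression.

    Features are expected standardized; chains are run sequentially with
    deterministically derived seeds and their draws pooled.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, m = x.shape
    if y.shape != (n,):
        raise ValueError(f"y must have shape ({n},), got {y.shape}")
    if not linear:
        classes = np.unique(y)
        if not np.array_equal(classes, [0.0, 1.0]):
            raise ValueError("logistic probe needs both classes present "
                             f"(labels 0/1); got values {classes}")
    elif np.var(y) == 0:
        raise ValueError("constant target: linear probe undefined")

    dim = 2 + 2 * m + (1 if linear else 0)
    all_draws = []
    diags = []
    for chain in range(config.chains):
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 97, chain]))
        theta0 = 0.1 * rng.standard_normal(dim)
        theta0[1 + m: ] -= 1.0  # start scales small (log-scale ≈ -1)
        draws, diag = hmc_sample(
            lambda th: _horseshoe_logp_and_grad(th, x, y, config.tau0, linear),
            theta0, config, rng)
        all_draws.append(draws)
        diags.append(diag)
    draws = np.concatenate(all_draws, axis=0)

    alpha = draws[:, 0]
    z = draws[:, 1: 1 + m]
    lam = np.exp(draws[:, 1 + m: 1 + 2 * m])
    tau = np.exp(draws[:, 1 + 2 * m])
    beta = z * lam * tau[:, None]
    sigma = np.exp(draws[:, 2 + 2 * m]) if linear else None
    diag = {k: float(np.mean([d[k] for d in diags])) for k in diags[0]}
    return HorseshoePosterior(alpha, beta, tau, sigma, linear, diag)


def posterior_beta(post: HorseshoePosterior) -> np.ndarray:
    """Posterior-mean coefficients."""
    return post.beta.mean(axis=0)
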