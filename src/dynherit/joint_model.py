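"""Whitened joint MCMC over dynamic variance components and heritability.

The model places Matérn-1.5 Gaussian-process priors on the log variance
curves, reparameterized as log sigma2 = C(lambda)^{1/2} eta with eta standard
normal (whitening).  One sweep updates eta_E and eta_G by elliptical slice
sampling and log lambda_E, log lambda_G by adaptive random-walk MH, in that
order.  Draws are stored as variance curves on the analysis scale (data
scaled to mean total variance 2) together with the scale factor needed to map
back to the original phenotype scale; h2(t) is computed per draw.
"""

from __future__ import annotations

import math
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

from .gpcov import MaternKernel, TimeGrid, cov_matrix, cov_sqrt, lengthscale_hyperprior
from .grm import RelationshipMatrix
from .likelihood import (
    EigenGRM,
    PhenotypePanel,
    _loglik_arrays,
    center_scale,
    eigendecompose_grm,
)
from .samplers import AdaptiveRWState, adaptive_rw_step, elliptical_slice_step

__all__ = [
    "WhitenedState",
    "PosteriorDraws",
    "CurveSummary",
    "CovSqrtCache",
    "log_posterior",
    "run_joint_mcmc",
    "summarize",
    "breeding_values",
    "split_chain_check",
]


@dataclass
class WhitenedState:
    """Sampler parameter block (eta_G, eta_E, log lambda_G, log lambda_E)."""

    eta_G: np.ndarray
    eta_E: np.ndarray
    log_lambda_G: float
    log_lambda_E: float

    def __post_init__(self) -> None:
        self.eta_G = np.asarray(self.eta_G, dtype=float)
        self.eta_E = np.asarray(self.eta_E, dtype=float)
        if not (
            np.all(np.isfinite(self.eta_G))
            and np.all(np.isfinite(self.eta_E))
            and np.isfinite(self.log_lambda_G)
            and np.isfinite(self.log_lambda_E)
        ):
            raise ValueError("whitened state contains non-finite values")


@dataclass
class CurveSummary:
    """Pointwise posterior mean and 95% credible band of one curve."""

    mean: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray


@dataclass
class PosteriorDraws:
    """Thinned post-burn-in draws of the variance curves and hyperparameters.

    Curves are on the analysis scale; divide by ``meta['scale_factor']`` for
    the original phenotype scale (h2 is scale-free).
    """

    sigma2_G: np.ndarray  # S x T
    sigma2_E: np.ndarray  # S x T
    h2: np.ndarray  # S x T
    lambda_G: np.ndarray  # S
    lambda_E: np.ndarray  # S
    meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.sigma2_G.shape[0]

    @property
    def sigma2_G_original(self) -> np.ndarray:
        return self.sigma2_G / self.meta["scale_factor"]

    @property
    def sigma2_E_original(self) -> np.ndarray:
        return self.sigma2_E / self.meta["scale_factor"]


class CovSqrtCache:
    """Memoizes C(lambda)^{1/2} per length scale; counts true factorizations.

    The sweep only changes lambda inside the random-walk updates, so between
    those the factor is reused; ``n_factorizations`` exposes the call count
    for the caching contract.
    """

    def __init__(self, grid: TimeGrid, maxsize: int = 8) -> None:
        self._grid = grid
        self._cache: OrderedDict[float, np.ndarray] = OrderedDict()
        self._maxsize = maxsize
        self.n_factorizations = 0

    def __call__(self, lengthscale: float) -> np.ndarray:
        key = float(lengthscale)
        hit = self._cache.get(key)
        if hit is not None:
            self._cache.move_to_end(key)
            return hit
        factor = cov_sqrt(cov_matrix(self._grid, MaternKernel(lengthscale=key)))
        self.n_factorizations += 1
        self._cache[key] = factor
        if len(self._cache) > self._maxsize:
            self._cache.popitem(last=False)
        return factor


def _curve(sqrt_factor: np.ndarray, eta: np.ndarray) -> np.ndarray:
    return np.exp(sqrt_factor @ eta)


def log_posterior(
    state: WhitenedState,
    z: np.ndarray,
    xi: np.ndarray,
    grid: TimeGrid,
    hyperprior: tuple[float, float],
    cache_G: CovSqrtCache | None = None,
    cache_E: CovSqrtCache | None = None,
) -> float:
    """Unnormalized log posterior of the whitened parameter block.

    Likelihood (eigen-factorized) + standard-normal log priors on eta_G and
    eta_E + N(mu_lambda, zeta_lambda^2) log priors on the log length scales.
    """
    cache_G = cache_G or CovSqrtCache(grid)
    cache_E = cache_E or CovSqrtCache(grid)
    mu_l, zeta_l = hyperprior

    sg = _curve(cache_G(math.exp(state.log_lambda_G)), state.eta_G)
    se = _curve(cache_E(math.exp(state.log_lambda_E)), state.eta_E)
    ll = _loglik_arrays(np.asarray(z, float), np.maximum(np.asarray(xi, float), 0.0), sg, se)
    if not np.isfinite(ll):
        raise ValueError("non-finite likelihood term in log_posterior")

    t = len(grid)
    lp_eta = -0.5 * (state.eta_G @ state.eta_G + state.eta_E @ state.eta_E) \
        - t * math.log(2.0 * math.pi)
    if not np.isfinite(lp_eta):
        raise ValueError("non-finite eta prior term in log_posterior")
    lp_lambda = (
        stats.norm.logpdf(state.log_lambda_G, mu_l, zeta_l)
        + stats.norm.logpdf(state.log_lambda_E, mu_l, zeta_l)
    )
    if not np.isfinite(lp_lambda):
        raise ValueError("non-finite length-scale prior term in log_posterior")
    return float(ll + lp_eta + lp_lambda)


def run_joint_mcmc(
    panel: PhenotypePanel,
    grm: RelationshipMatrix,
    iterations: int,
    burnin: int | None = None,
    thin: int = 10,
    seed: int | None = None,
    progress: Callable[[int, dict], None] | None = None,
) -> PosteriorDraws:
    """Run the whitened joint sampler and return thinned posterior draws.

    Sweep order: ESS on eta_E, ESS on eta_G, adaptive RW on log lambda_E,
    adaptive RW on log lambda_G.  Initialization is eta = 0 (all-ones curves
    on the analysis scale) and log lambda = mu_lambda.  ``seed`` is required;
    identical seeds give bitwise-identical draws.
    """
    if seed is None:
        raise ValueError("seed is required for reproducible sampling")
    if burnin is None:
        burnin = iterations // 2
    if not (iterations > burnin >= 0):
        raise ValueError("need iterations > burnin >= 0")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    if list(panel.individual_ids) != list(grm.individual_ids):
        raise ValueError("phenotype and relationship matrix individual IDs differ")

    scaled, scale_factor = center_scale(panel)
    eig = eigendecompose_grm(grm)  # raises on non-PSD / non-symmetric G
    z = eig.transform(scaled.values)
    xi = eig.xi
    grid = panel.grid
    hyper = lengthscale_hyperprior(grid)
    mu_l, zeta_l = hyper
    t_pts = len(grid)

    rng = np.random.default_rng(seed)
    cache_G, cache_E = CovSqrtCache(grid), CovSqrtCache(grid)

    eta_G = np.zeros(t_pts)
    eta_E = np.zeros(t_pts)
    log_lam_G = mu_l
    log_lam_E = mu_l
    sqrt_G = cache_G(math.exp(log_lam_G))
    sqrt_E = cache_E(math.exp(log_lam_E))
    sg = _curve(sqrt_G, eta_G)
    se = _curve(sqrt_E, eta_E)

    rw_G = AdaptiveRWState()
    rw_E = AdaptiveRWState()

    keep = [i for i in range(iterations) if i >= burnin and (i - burnin) % thin == 0]
    n_keep = len(keep)
    draws_G = np.empty((n_keep, t_pts))
    draws_E = np.empty((n_keep, t_pts))
    draws_lam_G = np.empty(n_keep)
    draws_lam_E = np.empty(n_keep)
    keep_idx = 0

    def ll_eta_E(eta: np.ndarray) -> float:
        return _loglik_arrays(z, xi, sg, _curve(sqrt_E, eta))

    def ll_eta_G(eta: np.ndarray) -> float:
        return _loglik_arrays(z, xi, _curve(sqrt_G, eta), se)

    def lp_lam_E(log_lam: float) -> float:
        if abs(log_lam) > 50.0:  # guard exp overflow far outside the prior
            return -np.inf
        se_prop = _curve(cache_E(math.exp(log_lam)), eta_E)
        return _loglik_arrays(z, xi, sg, se_prop) + float(
            stats.norm.logpdf(log_lam, mu_l, zeta_l)
        )

    def lp_lam_G(log_lam: float) -> float:
        if abs(log_lam) > 50.0:
            return -np.inf
        sg_prop = _curve(cache_G(math.exp(log_lam)), eta_G)
        return _loglik_arrays(z, xi, sg_prop, se) + float(
            stats.norm.logpdf(log_lam, mu_l, zeta_l)
        )

    for i in range(iterations):
        eta_E, _ = elliptical_slice_step(eta_E, ll_eta_E, rng)
        se = _curve(sqrt_E, eta_E)
        eta_G, _ = elliptical_slice_step(eta_G, ll_eta_G, rng)
        sg = _curve(sqrt_G, eta_G)

        log_lam_E, rw_E, acc_E = adaptive_rw_step(log_lam_E, lp_lam_E, rw_E, rng)
        if acc_E:
            sqrt_E = cache_E(math.exp(log_lam_E))
            se = _curve(sqrt_E, eta_E)
        log_lam_G, rw_G, acc_G = adaptive_rw_step(log_lam_G, lp_lam_G, rw_G, rng)
        if acc_G:
            sqrt_G = cache_G(math.exp(log_lam_G))
            sg = _curve(sqrt_G, eta_G)

        if keep_idx < n_keep and i == keep[keep_idx]:
            draws_G[keep_idx] = sg
            draws_E[keep_idx] = se
            draws_lam_G[keep_idx] = math.exp(log_lam_G)
            draws_lam_E[keep_idx] = math.exp(log_lam_E)
            keep_idx += 1

        if progress is not None and (i + 1) % 1000 == 0:
            progress(
                i + 1,
                {
                    "accept_lambda_E": rw_E.acceptance_rate,
                    "accept_lambda_G": rw_G.acceptance_rate,
                },
            )

    h2 = draws_G / (draws_G + draws_E)
    meta = {
        "seed": seed,
        "iterations": iterations,
        "burnin": burnin,
        "thin": thin,
        "scale_factor": scale_factor,
        "hyperprior_mu": mu_l,
        "hyperprior_zeta": zeta_l,
        "accept_rate_lambda_G": rw_G.acceptance_rate,
        "accept_rate_lambda_E": rw_E.acceptance_rate,
        "n_cov_sqrt_G": cache_G.n_factorizations,
        "n_cov_sqrt_E": cache_E.n_factorizations,
    }
    return PosteriorDraws(draws_G, draws_E, h2, draws_lam_G, draws_lam_E, meta)


def summarize(
    draws: PosteriorDraws, scale: str = "analysis"
) -> tuple[CurveSummary, CurveSummary, CurveSummary]:
    """Pointwise posterior means and 2.5%/97.5% quantiles for (sigma2_G,
    sigma2_E, h2); the h2 band comes from per-draw h2 values, never from
    interval arithmetic on the component bands."""
    if draws.n_draws < 2:
        raise ValueError("need at least 2 draws to summarize")
    if scale == "analysis":
        sg, se = draws.sigma2_G, draws.sigma2_E
    elif scale == "original":
        sg, se = draws.sigma2_G_original, draws.sigma2_E_original
    else:
        raise ValueError("scale must be 'analysis' or 'original'")

    def _summary(arr: np.ndarray) -> CurveSummary:
        return CurveSummary(
            mean=arr.mean(axis=0),
            lower95=np.quantile(arr, 0.025, axis=0),
            upper95=np.quantile(arr, 0.975, axis=0),
        )

    return _summary(sg), _summary(se), _summary(draws.h2)


def breeding_values(
    grm: RelationshipMatrix | EigenGRM,
    sigma2_G_hat: float,
    sigma2_E_hat: float,
    y_t: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior breeding values at one time point.

    mu_u = s_G G (s_G G + s_E I)^{-1} y and Sigma_u = s_G G - s_G G (...)^{-1}
    s_G G, evaluated through the eigendecomposition of G (no explicit inverse).
    """
    if not (sigma2_G_hat > 0 and sigma2_E_hat > 0):
        raise ValueError("variance estimates must be strictly positive")
    eig = grm if isinstance(grm, EigenGRM) else eigendecompose_grm(grm)
    y_t = np.asarray(y_t, dtype=float)
    if y_t.shape != (eig.xi.size,):
        raise ValueError("phenotype vector length does not match G")
    g_eigs = sigma2_G_hat * eig.xi
    denom = g_eigs + sigma2_E_hat
    shrink = g_eigs / denom
    mu_u = eig.U @ (shrink * (eig.U.T @ y_t))
    sigma_u = (eig.U * (g_eigs - g_eigs * shrink)) @ eig.U.T
    return mu_u, sigma_u


def split_chain_check(chain: np.ndarray, n_batches: int = 20) -> tuple[bool, float]:
    """Basic stationarity check: |mean(first half) - mean(second half)| < 3 MCSE.

    MCSE of the mean-difference is estimated by batch means within each half.
    Returns (passed, z_score).
    """
    chain = np.asarray(chain, dtype=float)
    half = chain.size // 2
    if half < n_batches:
        raise ValueError("chain too short for the split-chain check")

    def _mcse(x: np.ndarray) -> float:
        usable = (x.size // n_batches) * n_batches
        batches = x[:usable].reshape(n_batches, -1).mean(axis=1)
        return float(batches.std(ddof=1) / np.sqrt(n_batches))

    a, b = chain[:half], chain[half:]
    se = math.hypot(_mcse(a), _mcse(b))
    z = abs(a.mean() - b.mean()) / se if se > 0 else 0.0
    return z < 3.0, float(z)
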