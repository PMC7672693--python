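"""Generic MCMC kernels.

Two building blocks: elliptical slice sampling for vectors with a standard
multivariate-normal prior (whitened parameterizations), and an adaptive
Gaussian random-walk Metropolis-Hastings step for scalars whose proposal
standard deviation is tuned toward a 0.44 acceptance rate with a
Robbins-Monro schedule of diminishing gain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["AdaptiveRWState", "elliptical_slice_step", "adaptive_rw_step"]

#: optimal univariate random-walk acceptance rate targeted by the adaptation
TARGET_ACCEPT = 0.44
_MAX_SHRINK = 1000


def elliptical_slice_step(
    eta: np.ndarray,
    loglik: Callable[[np.ndarray], float],
    rng: np.random.Generator,
    cur_loglik: float | None = None,
) -> tuple[np.ndarray, float]:
    """One elliptical slice sampling update for eta ~ N(0, I) a priori.

    Rejection-free: the angle bracket shrinks toward 0 until a point above the
    slice height is found, so the kernel always returns an accepted state.
    Returns ``(eta_new, loglik(eta_new))`` so callers never re-evaluate the
    likelihood at the new state.
    """
    eta = np.asarray(eta, dtype=float)
    if cur_loglik is None:
        cur_loglik = loglik(eta)
    if np.isnan(cur_loglik):
        raise ValueError("log-likelihood is NaN at the current state")

    nu = rng.standard_normal(eta.shape)
    log_u = cur_loglik + np.log(rng.uniform())
    theta = rng.uniform(0.0, 2.0 * np.pi)
    lo, hi = theta - 2.0 * np.pi, theta

    for _ in range(_MAX_SHRINK):
        prop = eta * np.cos(theta) + nu * np.sin(theta)
        ll = loglik(prop)
        if np.isnan(ll):
            raise ValueError("log-likelihood returned NaN during slice shrinkage")
        if ll > log_u:
            return prop, float(ll)
        if theta < 0.0:
            lo = theta
        else:
            hi = theta
        theta = rng.uniform(lo, hi)
    raise RuntimeError(
        f"elliptical slice bracket failed to shrink within {_MAX_SHRINK} contractions"
    )


@dataclass
class AdaptiveRWState:
    """Adaptation state of one scalar random-walk chain."""

    log_step: float = 0.0
    iteration: int = 0
    accept_count: int = 0

    @property
    def step(self) -> float:
        return float(np.exp(self.log_step))

    @property
    def acceptance_rate(self) -> float:
        return self.accept_count / self.iteration if self.iteration else 0.0


def adaptive_rw_step(
    theta: float,
    logpost: Callable[[float], float],
    state: AdaptiveRWState,
    rng: np.random.Generator,
) -> tuple[float, AdaptiveRWState, bool]:
    """One adaptive Gaussian random-walk Metropolis-Hastings update.

    Proposal N(theta, step^2); after the accept/reject decision the log step
    size moves by min(0.01, i^{-1/2}) * (accepted - 0.44), a Robbins-Monro
    scheme with diminishing adaptation whose stationary acceptance rate is
    0.44.  Mutates and returns ``state``.
    """
    lp_cur = logpost(theta)
    if np.isnan(lp_cur):
        raise ValueError("log-posterior is NaN at the current state")

    state.iteration += 1
    prop = theta + state.step * rng.standard_normal()
    lp_prop = logpost(prop)
    if np.isnan(lp_prop):
        warnings.warn("log-posterior NaN at proposal; treating as rejection")
        accepted = False
    else:
        accepted = np.log(rng.uniform()) < lp_prop - lp_cur

    if accepted:
        theta = prop
        state.accept_count += 1
    gain = min(0.01, state.iteration ** -0.5)
    state.log_step += gain * ((1.0 if accepted else 0.0) - TARGET_ACCEPT)
    return float(theta), state, bool(accepted)
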