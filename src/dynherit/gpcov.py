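"""Matérn-1.5 covariance construction, PSD square roots and the length-scale hyperprior.

The smoothness is fixed at nu = 1.5 and the magnitude defaults to tau^2 = 1;
the only free kernel parameter is the length scale.  The hyperprior for
log(lambda) is the normal distribution placing ~95% of its mass between the
log of the smallest and largest pairwise distances of the time grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MaternKernel",
    "TimeGrid",
    "matern15",
    "cov_matrix",
    "cov_sqrt",
    "lengthscale_hyperprior",
]

#: diagonal jitter (times tau^2) added before factorization
JITTER = 1e-10
#: relative eigenvalue floor used by the PSD square root
EIG_FLOOR = 1e-12


@dataclass(frozen=True)
class MaternKernel:
    """Matérn covariance with smoothness fixed at 1.5."""

    lengthscale: float
    magnitude: float = 1.0
    smoothness: float = 1.5

    def __post_init__(self) -> None:
        if self.smoothness != 1.5:
            raise ValueError("only smoothness nu = 1.5 is supported")
        if not (self.lengthscale > 0 and np.isfinite(self.lengthscale)):
            raise ValueError("lengthscale must be positive and finite")
        if not (self.magnitude > 0 and np.isfinite(self.magnitude)):
            raise ValueError("magnitude must be positive and finite")


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing measurement times."""

    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.atleast_1d(np.asarray(self.times, dtype=float))
        if t.ndim != 1 or t.size < 1:
            raise ValueError("time grid must be a non-empty 1-D array")
        if not np.all(np.isfinite(t)):
            raise ValueError("time grid contains non-finite values")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("time grid must be strictly increasing (no duplicates)")
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return self.times.size


def matern15(distance, kernel: MaternKernel):
    """Evaluate tau^2 (1 + d / lambda) exp(-d / lambda) at distance(s) d >= 0."""
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be nonnegative")
    r = d / kernel.lengthscale
    out = kernel.magnitude * (1.0 + r) * np.exp(-r)
    return out if out.ndim else float(out)


def cov_matrix(grid: TimeGrid, kernel: MaternKernel) -> np.ndarray:
    """Dense T x T kernel matrix [C]_ij = C(t_i, t_j); symmetric, unit diagonal at tau^2 = 1."""
    t = grid.times
    d = np.abs(t[:, None] - t[None, :])
    return matern15(d, kernel)


def cov_sqrt(c: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root L with L L' = C.

    Uses an eigendecomposition with jitter 1e-10 * max-diagonal added first and
    an eigenvalue floor of max(eig) * 1e-12, so near-singular kernels on dense
    grids factorize deterministically.  Any L with L L' = C induces the same
    whitened prior law.
    """
    c = np.asarray(c, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(c, c.T, atol=1e-8, rtol=0):
        raise ValueError("covariance matrix is not symmetric")
    scale = float(np.max(np.diag(c))) if c.size else 1.0
    cj = c + (JITTER * max(scale, 1.0)) * np.eye(c.shape[0])
    w, v = np.linalg.eigh(cj)
    if not np.all(np.isfinite(w)):
        raise np.linalg.LinAlgError("eigendecomposition of covariance failed")
    floor = w.max() * EIG_FLOOR
    if w.max() <= 0:
        raise np.linalg.LinAlgError("covariance has no positive eigenvalues")
    w = np.maximum(w, floor)
    return v * np.sqrt(w)  # columns scaled: L = V sqrt(W), L L' = V W V'


def lengthscale_hyperprior(grid: TimeGrid) -> tuple[float, float]:
    """Solve mu - 1.96 zeta = log a, mu + 1.96 zeta = log b for (mu, zeta).

    a and b are the smallest nonzero and largest pairwise distances of the
    grid, so ~95% of the N(mu, zeta^2) mass for log(lambda) falls in
    [log a, log b].
    """
    t = grid.times
    if t.size < 2:
        raise ValueError("need at least 2 time points for the length-scale hyperprior")
    a = float(np.min(np.diff(t)))  # min nonzero pairwise distance on a sorted grid
    b = float(t[-1] - t[0])
    if a <= 0:
        raise ValueError("smallest pairwise distance must be positive")
    if a == b:
        raise ValueError("degenerate grid: smallest and largest distances coincide")
    mu = 0.5 * (np.log(a) + np.log(b))
    zeta = (np.log(b) - np.log(a)) / (2.0 * 1.96)
    return float(mu), float(zeta)
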