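"""Data centering/scaling and the eigen-factorized joint log-likelihood.

The longitudinal covariance is block-diagonal over time points with blocks
sigma2_G(t) G + sigma2_E(t) I.  After transforming each time point's centred
phenotype vector by the eigenvectors of G (z(t) = U' y_c(t)), the joint
log-likelihood collapses to a double sum of univariate normal log-densities
with variances sigma2_G(t) xi_n + sigma2_E(t), never materializing an NT x NT
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gpcov import TimeGrid
from .grm import RelationshipMatrix

__all__ = [
    "PhenotypePanel",
    "EigenGRM",
    "VarianceCurves",
    "center_scale",
    "eigendecompose_grm",
    "joint_loglik",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class PhenotypePanel:
    """N x T phenotype values on a strictly increasing time grid."""

    values: np.ndarray
    grid: TimeGrid
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("phenotype values must be a 2-D array")
        n, t = self.values.shape
        if n < 2:
            raise ValueError("need at least 2 individuals")
        if t != len(self.grid):
            raise ValueError("number of columns does not match the time grid")
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match row count")
        if np.isnan(self.values).any():
            raise ValueError("missing phenotypes unsupported")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class EigenGRM:
    """Cached eigendecomposition of G: U orthogonal, xi descending, xi >= 0."""

    U: np.ndarray
    xi: np.ndarray

    def transform(self, values: np.ndarray) -> np.ndarray:
        """z = U' Y column-wise (decorrelates individuals at every time point)."""
        return self.U.T @ values


@dataclass
class VarianceCurves:
    """Strictly positive per-time-point genetic and environmental variances."""

    sigma2_G: np.ndarray
    sigma2_E: np.ndarray

    def __post_init__(self) -> None:
        self.sigma2_G = np.atleast_1d(np.asarray(self.sigma2_G, dtype=float))
        self.sigma2_E = np.atleast_1d(np.asarray(self.sigma2_E, dtype=float))
        if self.sigma2_G.shape != self.sigma2_E.shape:
            raise ValueError("variance curves must have equal length")
        if np.any(self.sigma2_G <= 0) or np.any(self.sigma2_E <= 0):
            raise ValueError("variance curves must be strictly positive")


def center_scale(panel: PhenotypePanel) -> tuple[PhenotypePanel, float]:
    """Center each time point and scale so the mean over time of the per-time
    sample variance equals 2.

    Returns the scaled panel and the *variance* scale factor: scaled variance =
    scale_factor * original variance, i.e. data were multiplied by
    sqrt(scale_factor) after centering; divide analysis-scale variance
    components by scale_factor to report them on the original scale.  Sample
    variance uses the unbiased 1/(N-1) denominator.
    """
    centered = panel.values - panel.values.mean(axis=0)
    variances = centered.var(axis=0, ddof=1)
    mean_var = float(variances.mean())
    if mean_var <= 0.0:
        raise ValueError("zero phenotypic variance")
    scale_factor = 2.0 / mean_var
    scaled = centered * np.sqrt(scale_factor)
    out = PhenotypePanel(scaled, panel.grid, list(panel.individual_ids))
    return out, scale_factor


def eigendecompose_grm(grm: RelationshipMatrix | np.ndarray) -> EigenGRM:
    """Eigendecompose G once; eigenvalues sorted descending and clamped at 0.

    Tiny negative eigenvalues (>= -1e-8 * max) are round-off and clamped;
    anything more negative means G is not PSD and raises.
    """
    g = grm.values if isinstance(grm, RelationshipMatrix) else np.asarray(grm, float)
    if g.ndim != 2 or g.shape[0] != g.shape[1]:
        raise ValueError("relationship matrix must be square")
    if not np.allclose(g, g.T, atol=1e-10, rtol=0):
        raise ValueError("relationship matrix is not symmetric")
    w, v = np.linalg.eigh(g)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    tol = -1e-8 * max(float(w.max()), 1.0)
    if w.min() < tol:
        raise ValueError(f"relationship matrix is not PSD: min eigenvalue {w.min():.3e}")
    return EigenGRM(U=v, xi=np.maximum(w, 0.0))


def _loglik_arrays(
    z: np.ndarray, xi: np.ndarray, sigma2_G: np.ndarray, sigma2_E: np.ndarray
) -> float:
    """Hot path: sum_t sum_n log N(z_nt; 0, sG(t) xi_n + sE(t)) on raw arrays."""
    var = sigma2_G[None, :] * xi[:, None] + sigma2_E[None, :]
    return float(-0.5 * (var.size * _LOG2PI + np.log(var).sum() + (z * z / var).sum()))


def joint_loglik(z: np.ndarray, xi: np.ndarray, curves: VarianceCurves) -> float:
    """Factorized joint log-likelihood of the transformed data z = U' Y_c.

    Memory use is O(N T); no NT x NT matrix is ever formed.
    """
    z = np.asarray(z, dtype=float)
    xi = np.asarray(xi, dtype=float)
    if z.ndim != 2:
        raise ValueError("z must be N x T")
    if xi.shape != (z.shape[0],):
        raise ValueError("eigenvalue vector length must match rows of z")
    if curves.sigma2_G.shape != (z.shape[1],):
        raise ValueError("variance curve length must match columns of z")
    xi = np.maximum(xi, 0.0)
    var = curves.sigma2_G[None, :] * xi[:, None] + curves.sigma2_E[None, :]
    if np.any(var <= 0):
        raise ValueError("nonpositive variance in the factorized likelihood")
    ll = _loglik_arrays(z, xi, curves.sigma2_G, curves.sigma2_E)
    if not np.isfinite(ll):
        raise ValueError("non-finite log-likelihood")
    return ll
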