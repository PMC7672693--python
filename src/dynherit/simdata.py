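"""Synthetic-data generators for longitudinal polygenic and twin designs.

The longitudinal design draws a random relationship matrix G = S S'/N + 0.1 I
(S standard normal), a Matérn-5/2 time covariance C with length scale 50/3,
genetic and environmental components from N(0, C (x) G) and N(0, C (x) I),
scales each component column by the target per-time-point variance and sums
them.  The Kronecker draws use square-root factors applied as L_G Z L_C', so
the NT x NT covariance is never formed.  The twin design builds the
block-diagonal kinship with MZ within-pair covariance 1, DZ 0.5 and 0
between pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gpcov import TimeGrid, cov_sqrt
from .grm import RelationshipMatrix
from .likelihood import PhenotypePanel

__all__ = [
    "SimTruth",
    "sim_grm",
    "sim_time_cov",
    "simulate_longitudinal",
    "sim_twin_kinship",
    "default_truth_curves",
]

#: time-covariance length scale of the longitudinal design
SIM_LENGTHSCALE = 50.0 / 3.0


@dataclass
class SimTruth:
    """Ground truth bundled with a simulated panel."""

    sigma2_G_true: np.ndarray
    sigma2_E_true: np.ndarray
    h2_true: np.ndarray
    G_true: RelationshipMatrix
    genetic_component: np.ndarray
    environmental_component: np.ndarray


def sim_grm(n: int, seed: int) -> RelationshipMatrix:
    """Random relationship matrix G = S S' / N + 0.1 I, S iid standard normal.

    The 0.1 diagonal shift makes G positive definite with smallest eigenvalue
    >= 0.1.
    """
    if n < 2:
        raise ValueError("need at least 2 individuals")
    rng = np.random.default_rng(seed)
    s = rng.standard_normal((n, n))
    g = s @ s.T / n + 0.1 * np.eye(n)
    return RelationshipMatrix(g, [f"ind{i}" for i in range(n)])


def sim_time_cov(grid: TimeGrid) -> np.ndarray:
    """Matérn-5/2 time covariance with length scale 50/3 and unit diagonal:
    (1 + sqrt(5) d / l + 5 d^2 / (3 l^2)) exp(-sqrt(5) d / l)."""
    t = grid.times
    d = np.abs(t[:, None] - t[None, :])
    r = np.sqrt(5.0) * d / SIM_LENGTHSCALE
    return (1.0 + r + r * r / 3.0) * np.exp(-r)


def _chol_or_sqrt(mat: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(mat)
    except np.linalg.LinAlgError:
        return cov_sqrt(mat)


def simulate_longitudinal(
    n: int,
    grid: TimeGrid,
    sigma2_G_true: np.ndarray,
    sigma2_E_true: np.ndarray,
    seed: int,
    grm: RelationshipMatrix | None = None,
) -> tuple[PhenotypePanel, SimTruth]:
    """Simulate a longitudinal phenotype panel with known truth curves.

    The genetic component is L_G Z_G L_C' (Z_G standard normal N x T) and the
    environmental one Z_E L_C'; columns are then scaled by the square roots of
    the corresponding truth variances and summed.  ``sigma2_E_true`` may be
    identically zero for one-component boundary tests; otherwise both curves
    must be nonnegative with positive sum.  Pass ``grm`` to reuse a fixed
    relationship matrix (e.g. a twin kinship); by default a fresh ``sim_grm``
    matrix is drawn from the same seed sequence.
    """
    sigma2_G_true = np.atleast_1d(np.asarray(sigma2_G_true, dtype=float))
    sigma2_E_true = np.atleast_1d(np.asarray(sigma2_E_true, dtype=float))
    t_pts = len(grid)
    if sigma2_G_true.shape != (t_pts,) or sigma2_E_true.shape != (t_pts,):
        raise ValueError("truth curves must match the time grid length")
    if np.any(sigma2_G_true < 0) or np.any(sigma2_E_true < 0):
        raise ValueError("truth variance curves must be nonnegative")
    if np.any(sigma2_G_true + sigma2_E_true <= 0):
        raise ValueError("total truth variance must be positive at every time point")

    ss = np.random.SeedSequence(seed)
    seed_grm, seed_gen, seed_env = ss.spawn(3)
    if grm is None:
        grm = sim_grm(n, int(seed_grm.generate_state(1)[0]))
    if grm.n_individuals != n:
        raise ValueError("relationship matrix size does not match n")

    c = sim_time_cov(grid)
    l_c = _chol_or_sqrt(c + 1e-10 * np.eye(t_pts))
    l_g = _chol_or_sqrt(grm.values)

    rng_gen = np.random.default_rng(seed_gen)
    rng_env = np.random.default_rng(seed_env)
    genetic = l_g @ rng_gen.standard_normal((n, t_pts)) @ l_c.T
    environmental = rng_env.standard_normal((n, t_pts)) @ l_c.T
    genetic *= np.sqrt(sigma2_G_true)[None, :]
    environmental *= np.sqrt(sigma2_E_true)[None, :]

    panel = PhenotypePanel(genetic + environmental, grid, list(grm.individual_ids))
    truth = SimTruth(
        sigma2_G_true=sigma2_G_true,
        sigma2_E_true=sigma2_E_true,
        h2_true=sigma2_G_true / (sigma2_G_true + sigma2_E_true),
        G_true=grm,
        genetic_component=genetic,
        environmental_component=environmental,
    )
    return panel, truth


def sim_twin_kinship(n_mz_pairs: int, n_dz_pairs: int) -> RelationshipMatrix:
    """Block-diagonal twin kinship: MZ blocks [[1,1],[1,1]], DZ blocks
    [[1,.5],[.5,1]], zero between pairs."""
    if n_mz_pairs < 0 or n_dz_pairs < 0:
        raise ValueError("pair counts must be nonnegative")
    if n_mz_pairs + n_dz_pairs < 1:
        raise ValueError("need at least one twin pair")
    n = 2 * (n_mz_pairs + n_dz_pairs)
    g = np.eye(n)
    ids = []
    for p in range(n_mz_pairs):
        i = 2 * p
        g[i, i + 1] = g[i + 1, i] = 1.0
        ids += [f"mz{p}a", f"mz{p}b"]
    for p in range(n_dz_pairs):
        i = 2 * (n_mz_pairs + p)
        g[i, i + 1] = g[i + 1, i] = 0.5
        ids += [f"dz{p}a", f"dz{p}b"]
    return RelationshipMatrix(g, ids)


def default_truth_curves(
    grid: TimeGrid,
    h2_start: float = 0.2,
    h2_end: float = 0.7,
    total_variance: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Packaged fixture curves: h2 rises logistically from ``h2_start`` to
    ``h2_end`` over the grid; total variance is constant."""
    t = grid.times
    span = t[-1] - t[0] if len(grid) > 1 else 1.0
    x = (t - t[0]) / span  # in [0, 1]
    h2 = h2_start + (h2_end - h2_start) / (1.0 + np.exp(-10.0 * (x - 0.5)))
    sigma2_g = h2 * total_variance
    sigma2_e = (1.0 - h2) * total_variance
    return sigma2_g, sigma2_e
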