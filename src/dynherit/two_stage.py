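"""Two-stage baseline: per-time-point variance estimation, then GP smoothing.

Stage one fits y_c(t) ~ N(0, sigma2_G(t) G + sigma2_E(t) I) independently at
every time point with N(0, 1) priors on both log variances, updating one log
variance at a time by adaptive random-walk MH.  Stage two smooths the
logarithmized posterior-mean curve and each 95% interval-limit curve with a
Matérn-1.5 GP observed under iid noise (log gamma2 ~ N(0, 10000), log lambda
from the length-scale hyperprior), reconstructing the latent curve at the
grid with the conjugate formula at the posterior-mean hyperparameters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .gpcov import MaternKernel, TimeGrid, cov_matrix, lengthscale_hyperprior
from .grm import RelationshipMatrix
from .likelihood import (
    EigenGRM,
    PhenotypePanel,
    _loglik_arrays,
    center_scale,
    eigendecompose_grm,
)
from .joint_model import CurveSummary
from .samplers import AdaptiveRWState, adaptive_rw_step

__all__ = [
    "Stage1Result",
    "SmoothingFit",
    "stage1_fit",
    "stage2_smooth",
    "gp_reconstruct",
    "run_two_stage",
]

logger = logging.getLogger(__name__)


@dataclass
class Stage1Result:
    """Per-time-point posterior summaries of the log variance components."""

    post_mean_logG: np.ndarray
    post_mean_logE: np.ndarray
    lower95_logG: np.ndarray
    upper95_logG: np.ndarray
    lower95_logE: np.ndarray
    upper95_logE: np.ndarray


@dataclass
class SmoothingFit:
    """Stage-two smoothing result for one curve."""

    gamma2: float
    lam: float
    f_mean: np.ndarray
    f_cov: np.ndarray


def _stage1_single(
    z_t: np.ndarray,
    xi: np.ndarray,
    iterations: int,
    rng: np.random.Generator,
) -> tuple[float, float, float, float, float, float]:
    """Sample (log sigma2_G, log sigma2_E) at one time point; return posterior
    mean and 2.5/97.5 quantiles of each (second half of the chain)."""
    z_col = z_t[:, None]
    one = np.ones(1)

    log_g, log_e = 0.0, 0.0
    rw_g, rw_e = AdaptiveRWState(), AdaptiveRWState()
    burnin = iterations // 2
    kept_g = np.empty(iterations - burnin)
    kept_e = np.empty(iterations - burnin)

    def lp_g(lg: float) -> float:
        if abs(lg) > 50.0:
            return -np.inf
        ll = _loglik_arrays(z_col, xi, math.exp(lg) * one, math.exp(log_e) * one)
        return ll - 0.5 * lg * lg

    def lp_e(le: float) -> float:
        if abs(le) > 50.0:
            return -np.inf
        ll = _loglik_arrays(z_col, xi, math.exp(log_g) * one, math.exp(le) * one)
        return ll - 0.5 * le * le

    for i in range(iterations):
        log_g, rw_g, _ = adaptive_rw_step(log_g, lp_g, rw_g, rng)
        log_e, rw_e, _ = adaptive_rw_step(log_e, lp_e, rw_e, rng)
        if i >= burnin:
            kept_g[i - burnin] = log_g
            kept_e[i - burnin] = log_e

    return (
        float(kept_g.mean()),
        float(np.quantile(kept_g, 0.025)),
        float(np.quantile(kept_g, 0.975)),
        float(kept_e.mean()),
        float(np.quantile(kept_e, 0.025)),
        float(np.quantile(kept_e, 0.975)),
    )


def stage1_fit(
    y_t: np.ndarray,
    grm: RelationshipMatrix | EigenGRM,
    iterations: int,
    seed: int,
) -> dict[str, float]:
    """Single-time-point posterior for (log sigma2_G, log sigma2_E).

    ``y_t`` must already be centred and on the shared analysis scale (the same
    global center/scale step as the joint method).
    """
    eig = grm if isinstance(grm, EigenGRM) else eigendecompose_grm(grm)
    y_t = np.asarray(y_t, dtype=float)
    if y_t.shape != (eig.xi.size,):
        raise ValueError("phenotype vector length does not match G")
    rng = np.random.default_rng(seed)
    z_t = eig.U.T @ y_t
    mg, lg, ug, me, le, ue = _stage1_single(z_t, eig.xi, iterations, rng)
    return {
        "post_mean_logG": mg,
        "lower95_logG": lg,
        "upper95_logG": ug,
        "post_mean_logE": me,
        "lower95_logE": le,
        "upper95_logE": ue,
    }


def gp_reconstruct(
    y: np.ndarray, grid: TimeGrid, lam: float, gamma2: float
) -> tuple[np.ndarray, np.ndarray]:
    """Conjugate GP reconstruction: f | y ~ N(C (C + g2 I)^{-1} y, C - C (C + g2 I)^{-1} C)."""
    c = cov_matrix(grid, MaternKernel(lengthscale=lam))
    a = c + gamma2 * np.eye(len(grid))
    solve = np.linalg.solve(a, np.column_stack([y, c.T]).reshape(len(grid), -1))
    f_mean = c @ solve[:, 0]
    f_cov = c - c @ solve[:, 1:]
    f_cov = (f_cov + f_cov.T) / 2.0
    return f_mean, f_cov


def stage2_smooth(
    y_curve: np.ndarray,
    grid: TimeGrid,
    iterations: int,
    seed: int,
) -> SmoothingFit:
    """Smooth one T-vector with the noisy-GP model y ~ N(0, C_lambda + gamma2 I).

    The curve is standardized to mean 0 / variance 1 for estimation and the
    reconstruction is de-standardized on return.  Hyperparameters are sampled
    one at a time by adaptive RW-MH; the reconstruction uses the posterior
    means of lambda and gamma2 on the natural scale.
    """
    y_curve = np.asarray(y_curve, dtype=float)
    t_pts = len(grid)
    if y_curve.shape != (t_pts,):
        raise ValueError("curve length does not match the time grid")
    mean_y = float(y_curve.mean())
    sd_y = float(y_curve.std(ddof=1))
    if sd_y <= 0.0:
        raise ValueError("constant curve: zero variance standardization")
    y_std = (y_curve - mean_y) / sd_y

    mu_l, zeta_l = lengthscale_hyperprior(grid)
    eye = np.eye(t_pts)
    rng = np.random.default_rng(seed)

    log_lam, log_g2 = mu_l, 0.0

    def _mvn_ll(lg2: float, llam: float) -> float:
        if abs(lg2) > 50.0 or abs(llam) > 50.0:
            return -np.inf
        c = cov_matrix(grid, MaternKernel(lengthscale=math.exp(llam)))
        k = c + math.exp(lg2) * eye
        try:
            chol = np.linalg.cholesky(k)
        except np.linalg.LinAlgError:
            return -np.inf
        alpha = np.linalg.solve(chol, y_std)
        return float(
            -0.5 * (alpha @ alpha)
            - np.log(np.diag(chol)).sum()
            - 0.5 * t_pts * np.log(2.0 * np.pi)
        )

    def lp_g2(lg2: float) -> float:
        return _mvn_ll(lg2, log_lam) + float(stats.norm.logpdf(lg2, 0.0, 100.0))

    def lp_lam(llam: float) -> float:
        return _mvn_ll(log_g2, llam) + float(stats.norm.logpdf(llam, mu_l, zeta_l))

    rw_g2, rw_lam = AdaptiveRWState(), AdaptiveRWState()
    burnin = iterations // 2
    kept_g2 = np.empty(iterations - burnin)
    kept_lam = np.empty(iterations - burnin)
    for i in range(iterations):
        log_g2, rw_g2, _ = adaptive_rw_step(log_g2, lp_g2, rw_g2, rng)
        log_lam, rw_lam, _ = adaptive_rw_step(log_lam, lp_lam, rw_lam, rng)
        if i >= burnin:
            kept_g2[i - burnin] = math.exp(log_g2)
            kept_lam[i - burnin] = math.exp(log_lam)

    g2_hat = float(kept_g2.mean())
    lam_hat = float(kept_lam.mean())
    f_mean_std, f_cov_std = gp_reconstruct(y_std, grid, lam_hat, g2_hat)
    return SmoothingFit(
        gamma2=g2_hat,
        lam=lam_hat,
        f_mean=f_mean_std * sd_y + mean_y,
        f_cov=f_cov_std * sd_y**2,
    )


def run_two_stage(
    panel: PhenotypePanel,
    grm: RelationshipMatrix,
    iterations: int,
    seed: int,
    stage2_iterations: int | None = None,
) -> tuple[CurveSummary, CurveSummary, CurveSummary]:
    """Full baseline: stage one at each time point, stage two smoothing.

    Returns (sigma2_G, sigma2_E, h2) curve summaries on the analysis scale.
    h2 summaries are formed from the smoothed component curves with the ratio
    heuristic h2_lower = G_lo/(G_lo + E_hi), h2_upper = G_hi/(G_hi + E_lo),
    clipped to (0, 1).  For T = 1 the stage-one quantities are returned
    directly (nothing to smooth).
    """
    if list(panel.individual_ids) != list(grm.individual_ids):
        raise ValueError("phenotype and relationship matrix individual IDs differ")
    if stage2_iterations is None:
        stage2_iterations = iterations

    scaled, _ = center_scale(panel)
    eig = eigendecompose_grm(grm)  # shared by every time point
    z = eig.transform(scaled.values)
    t_pts = panel.n_timepoints

    rng = np.random.default_rng(seed)
    res = np.empty((t_pts, 6))
    for t in range(t_pts):
        res[t] = _stage1_single(z[:, t], eig.xi, iterations, rng)
    stage1 = Stage1Result(
        post_mean_logG=res[:, 0],
        lower95_logG=res[:, 1],
        upper95_logG=res[:, 2],
        post_mean_logE=res[:, 3],
        lower95_logE=res[:, 4],
        upper95_logE=res[:, 5],
    )

    if t_pts == 1:
        g_mean, g_lo, g_hi = (
            np.exp(stage1.post_mean_logG),
            np.exp(stage1.lower95_logG),
            np.exp(stage1.upper95_logG),
        )
        e_mean, e_lo, e_hi = (
            np.exp(stage1.post_mean_logE),
            np.exp(stage1.lower95_logE),
            np.exp(stage1.upper95_logE),
        )
    else:
        curves = {}
        for name, log_curve in [
            ("g_mean", stage1.post_mean_logG),
            ("g_lo", stage1.lower95_logG),
            ("g_hi", stage1.upper95_logG),
            ("e_mean", stage1.post_mean_logE),
            ("e_lo", stage1.lower95_logE),
            ("e_hi", stage1.upper95_logE),
        ]:
            fit = stage2_smooth(
                log_curve,
                panel.grid,
                stage2_iterations,
                seed=int(rng.integers(2**31)),
            )
            curves[name] = np.exp(fit.f_mean)
        g_mean, g_lo, g_hi = curves["g_mean"], curves["g_lo"], curves["g_hi"]
        e_mean, e_lo, e_hi = curves["e_mean"], curves["e_lo"], curves["e_hi"]

        for label, (lo, mid, hi) in {
            "sigma2_G": (g_lo, g_mean, g_hi),
            "sigma2_E": (e_lo, e_mean, e_hi),
        }.items():
            n_cross = int(np.sum((mid < lo) | (mid > hi)))
            if n_cross:
                logger.warning(
                    "smoothed %s mean crosses its smoothed limits at %d/%d time points",
                    label,
                    n_cross,
                    t_pts,
                )

    h2_mean = g_mean / (g_mean + e_mean)
    h2_lo = np.clip(g_lo / (g_lo + e_hi), 0.0, 1.0)
    h2_hi = np.clip(g_hi / (g_hi + e_lo), 0.0, 1.0)
    return (
        CurveSummary(g_mean, g_lo, g_hi),
        CurveSummary(e_mean, e_lo, e_hi),
        CurveSummary(h2_mean, h2_lo, h2_hi),
    )
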