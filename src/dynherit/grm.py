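"""Genotype handling and the VanRaden genomic relationship matrix.

Genotypes are coded -1 (one homozygote), 0 (heterozygote), +1 (the other
homozygote); missing entries are NaN.  Imputation replaces a missing call
with the mean of the observed calls at that marker (kept fractional, not
re-rounded to codes), after which allele frequencies and the relationship
matrix G = QQ' / (2 * sum_i p_i (1 - p_i)) can be formed, with Q = M - P and
the i-th column of P equal to 2 * (p_i - 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenotypeMatrix",
    "RelationshipMatrix",
    "impute_missing",
    "allele_freqs",
    "vanraden_grm",
    "snp_backtransform",
]

_VALID_CODES = (-1.0, 0.0, 1.0)


@dataclass
class GenotypeMatrix:
    """N x M marker matrix with NaN for missing calls.

    Raw genotypes must be coded in {-1, 0, 1}; fractional values in [-1, 1]
    are accepted so that mean-imputed matrices remain valid instances.
    """

    values: np.ndarray
    individual_ids: list[str]
    marker_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D array")
        n, m = self.values.shape
        if n < 2:
            raise ValueError(f"need at least 2 individuals, got {n}")
        if m < 1:
            raise ValueError("need at least 1 marker")
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match row count")
        if len(self.marker_ids) != m:
            raise ValueError("marker_ids length does not match column count")
        observed = self.values[~np.isnan(self.values)]
        if observed.size and (observed.min() < -1 or observed.max() > 1):
            raise ValueError("genotype codes must lie in [-1, 1]")
        integral = observed[observed == np.round(observed)]
        if integral.size and not np.isin(integral, _VALID_CODES).all():
            raise ValueError("integer genotype codes must be in {-1, 0, 1}")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())


@dataclass
class RelationshipMatrix:
    """Symmetric PSD N x N relationship matrix with individual labels."""

    values: np.ndarray
    individual_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("relationship matrix must be square")
        n = self.values.shape[0]
        if not self.individual_ids:
            self.individual_ids = [f"ind{i}" for i in range(n)]
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match matrix size")
        if not np.allclose(self.values, self.values.T, atol=1e-10, rtol=0):
            raise ValueError("relationship matrix is not symmetric (tol 1e-10)")
        eigs = np.linalg.eigvalsh(self.values)
        if eigs.min() < -1e-8:
            raise ValueError(
                f"relationship matrix is not PSD: min eigenvalue {eigs.min():.3e}"
            )

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]


def impute_missing(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing call with the mean of its marker's observed calls.

    Imputed values stay fractional.  Idempotent; a fully missing marker is an
    error naming the offending marker.
    """
    vals = geno.values.copy()
    missing = np.isnan(vals)
    if not missing.any():
        return GenotypeMatrix(vals, list(geno.individual_ids), list(geno.marker_ids))
    all_missing = missing.all(axis=0)
    if all_missing.any():
        bad = geno.marker_ids[int(np.argmax(all_missing))]
        raise ValueError(f"marker has no observed genotypes: {bad!r}")
    col_means = np.nanmean(vals, axis=0)
    rows, cols = np.nonzero(missing)
    vals[rows, cols] = col_means[cols]
    return GenotypeMatrix(vals, list(geno.individual_ids), list(geno.marker_ids))


def allele_freqs(geno: GenotypeMatrix) -> np.ndarray:
    """Second-allele frequency per marker: p_i = mean over individuals of (g + 1) / 2."""
    if geno.has_missing:
        raise ValueError("genotypes contain missing values; run impute_missing first")
    p = ((geno.values + 1.0) / 2.0).mean(axis=0)
    return p


def vanraden_grm(geno: GenotypeMatrix) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix G = QQ' / (2 * sum p_i (1 - p_i))."""
    if geno.has_missing:
        raise ValueError("genotypes contain missing values; run impute_missing first")
    p = allele_freqs(geno)
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0.0:
        raise ValueError("zero denominator: no polymorphic markers")
    q = geno.values - 2.0 * (p - 0.5)  # Q = M - P, P columns broadcast
    g = (q @ q.T) / denom
    g = (g + g.T) / 2.0  # kill round-off asymmetry
    return RelationshipMatrix(g, list(geno.individual_ids))


def snp_backtransform(
    grm: RelationshipMatrix,
    mu_u: np.ndarray,
    geno: GenotypeMatrix,
    p: np.ndarray,
) -> np.ndarray:
    """SNP effects m = R' G^- mu_u with [R]_ij = (M_ij + 1 - 2 p_j) / (2 p_j (1 - p_j)).

    A pseudo-inverse with relative eigenvalue cutoff 1e-10 handles singular G.
    Fixed allele frequencies (p_j in {0, 1}) are rejected: R would divide by zero.
    """
    mu_u = np.asarray(mu_u, dtype=float)
    p = np.asarray(p, dtype=float)
    if mu_u.shape != (grm.n_individuals,):
        raise ValueError("mu_u length does not match relationship matrix size")
    if p.shape != (geno.n_markers,):
        raise ValueError("allele frequency vector length does not match marker count")
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("allele frequency in {0, 1}: back-transformation undefined")
    if geno.has_missing:
        raise ValueError("genotypes contain missing values; run impute_missing first")
    r = (geno.values + 1.0 - 2.0 * p) / (2.0 * p * (1.0 - p))
    g_pinv = np.linalg.pinv(grm.values, rcond=1e-10, hermitian=True)
    return r.T @ (g_pinv @ mu_u)
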