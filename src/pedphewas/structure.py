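"""Population-structure adjustment: genotype PCA, outlier removal and
genomic inflation.

The PCA standardizes each variant column to mean 2p̂ and unit drift
variance sqrt(2 p̂ (1 - p̂)) (the EIGENSTRAT convention), mean-imputes
missing genotypes, and takes the top-K left singular directions as
subject scores. Outliers are removed iteratively: any subject more than
``sd_limit`` standard deviations from the mean on a retained axis is
dropped and the PCA recomputed, up to ``max_iter`` rounds. Genomic
inflation lambda is the median association chi-square divided by the
null chi-square(1) median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .exceptions import ParameterError
from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

#: median of the chi-square distribution with 1 df
CHI2_1_MEDIAN = float(chi2.ppf(0.5, 1))


@dataclass
class PCSet:
    """Top-K principal-component scores for a cohort."""

    subjects: np.ndarray
    scores: np.ndarray            # n_subjects x K, zero mean per axis
    eigenvalues: np.ndarray       # full non-increasing spectrum
    k: int
    removed_outliers: list[str] = field(default_factory=list)

    def covariates(self) -> np.ndarray:
        """Score matrix to append to a regression design (may be 0-column)."""
        return self.scores[:, : self.k]


def _standardize(G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """EIGENSTRAT-standardized matrix and the indices of variants used
    (monomorphic variants are excluded with a warning)."""
    d = G.dosages.copy()
    p = G.allele_freq()
    poly = np.flatnonzero((p > 0) & (p < 1))
    if len(poly) < G.n_variants:
        logger.warning("pca: excluded %d monomorphic variants", G.n_variants - len(poly))
    d = d[:, poly]
    p = p[poly]
    mean = 2.0 * p
    # mean-imputation leaves the column mean unchanged
    d = np.where(np.isnan(d), mean, d)
    sd = np.sqrt(2.0 * p * (1.0 - p))
    return (d - mean) / sd, poly


def pca(G: GenotypeMatrix, k: int = 2) -> PCSet:
    """Genotype principal components.

    Eigenvalues are singular values squared over n, so their sum equals
    the total variance of the standardized matrix. Sign convention: the
    loading of largest magnitude on each axis is positive.
    """
    if k < 0:
        raise ParameterError("k must be >= 0")
    if G.n_subjects < k + 1:
        raise ParameterError("need at least K+1 subjects")
    x, _ = _standardize(G)
    if k == 0:
        return PCSet(G.subjects, np.zeros((G.n_subjects, 0)), np.array([]), 0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    for axis in range(len(s)):
        j = np.argmax(np.abs(vt[axis]))
        if vt[axis, j] < 0:
            vt[axis] *= -1
            u[:, axis] *= -1
    eigenvalues = s**2 / G.n_subjects
    scores = u[:, :k] * s[:k]
    return PCSet(G.subjects, scores, eigenvalues, k)


def remove_outliers(
    G: GenotypeMatrix, k: int = 2, sd_limit: float = 6.0, max_iter: int = 5
) -> tuple[PCSet, list[str]]:
    """Iterative PCA outlier removal (defaults follow EIGENSTRAT: 6 SD on
    any retained axis, up to 5 rounds). Returns the final PCSet computed
    on the retained subjects and the removed ids."""
    removed: list[str] = []
    current = G
    pcs = pca(current, k)
    if k == 0 or not np.isfinite(sd_limit):
        pcs.removed_outliers = removed
        return pcs, removed
    for _ in range(max_iter):
        scores = pcs.scores
        sd = scores.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        z = np.abs(scores - scores.mean(axis=0)) / sd
        bad = np.flatnonzero((z > sd_limit).any(axis=1))
        if bad.size == 0:
            break
        removed.extend(map(str, current.subjects[bad]))
        keep = np.setdiff1d(np.arange(current.n_subjects), bad)
        current = current.subset(subject_idx=keep)
        pcs = pca(current, k)
    pcs.removed_outliers = removed
    if removed:
        logger.info("remove_outliers: removed %d subjects", len(removed))
    return pcs, removed


@dataclass
class InflationEstimate:
    lambda_gc: float
    n_tests: int

    def __post_init__(self) -> None:
        if self.lambda_gc <= 0:
            raise ParameterError("lambda must be positive")


def genomic_lambda(
    p_values: np.ndarray | None = None, chi2_stats: np.ndarray | None = None
) -> InflationEstimate:
    """Genomic-control inflation factor.

    lambda = median(chi2_1 statistics) / median of the null chi2_1
    (~0.4549). Accepts either association p-values (converted through the
    inverse upper tail) or the chi-square statistics directly.
    """
    if (p_values is None) == (chi2_stats is None):
        raise ParameterError("pass exactly one of p_values or chi2_stats")
    if chi2_stats is None:
        p = np.asarray(p_values, dtype=float)
        if p.size < 1:
            raise ParameterError("at least one test required")
        if ((p <= 0) | (p > 1)).any():
            raise ParameterError("p-values must lie in (0, 1]")
        stats = chi2.isf(p, 1)
    else:
        stats = np.asarray(chi2_stats, dtype=float)
        if stats.size < 1:
            raise ParameterError("at least one test required")
    lam = float(np.median(stats) / CHI2_1_MEDIAN)
    return InflationEstimate(lambda_gc=lam, n_tests=int(stats.size))
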