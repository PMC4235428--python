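"""Variant and sample quality control.

Filters follow standard array-QC practice: variants are removed for
missingness > 5%, Hardy–Weinberg disequilibrium (exact test p < 0.001 in
controls) or minor-allele frequency < 1%; samples are removed for call
rate < 98%; and variants whose allele frequencies differ between the two
recruitment sites at p < 1e-5 are removed as genotyping artifacts. All
thresholds are arguments with those defaults.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2_contingency, fisher_exact

from .exceptions import ConfigurationError, ParameterError
from .genotypes import GenotypeMatrix, genotype_counts

logger = logging.getLogger(__name__)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional test of Hardy–Weinberg equilibrium.

    Conditions on the observed minor-allele count and enumerates every
    compatible heterozygote count; the two-sided p-value sums the
    probabilities of all configurations no more likely than the observed
    one:

        P(n_Aa | n, n_A) ∝ n! / (n_AA! n_Aa! n_aa!) · 2^{n_Aa}

    Returns a p-value in (0, 1].
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ParameterError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ParameterError("at least one genotype required")
    n_A = 2 * n_AA + n_Aa
    n_A = min(n_A, 2 * n - n_A)  # orient to the minor allele
    # all heterozygote counts with the right parity
    het = np.arange(n_A % 2, min(n_A, 2 * n - n_A) + 1, 2)
    hom_minor = (n_A - het) // 2
    hom_major = n - hom_minor - het
    logp = (
        het * np.log(2.0)
        - gammaln(hom_minor + 1)
        - gammaln(het + 1)
        - gammaln(hom_major + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs_het = n_Aa
    p_obs = prob[np.flatnonzero(het == obs_het)[0]]
    return float(min(1.0, prob[prob <= p_obs * (1.0 + 1e-12)].sum()))


@dataclass
class QCThresholds:
    """Defaults mirror the standard array-QC recipe."""

    max_missing: float = 0.05
    hwe_p: float = 1e-3
    min_maf: float = 0.01
    min_call_rate: float = 0.98
    site_alpha: float = 1e-5
    hard_call_tol: float = 0.1


def variant_qc(
    G: GenotypeMatrix,
    thresholds: QCThresholds | None = None,
    controls: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, "np.ndarray"]:
    """Apply missingness / HWE-in-controls / MAF filters.

    ``controls`` is a boolean mask (or index array) over subjects used
    for the HWE test; cohort-wide HWE is obtained by passing all
    subjects. Returns the filtered matrix (A1 oriented to the minor
    allele) and the annotated variant table for *all* input variants with
    columns ``maf, missing_rate, hwe_p, qc_flags`` (semicolon-joined
    flags, empty when retained).

    The filter is idempotent: re-running on its own output removes
    nothing further.
    """
    thresholds = thresholds or QCThresholds()
    if controls is None:
        raise ConfigurationError(
            "HWE filtering requires designated controls "
            "(pass all subjects for cohort-wide HWE)"
        )
    controls = np.asarray(controls)
    if controls.dtype == bool:
        controls = np.flatnonzero(controls)
    if controls.size == 0:
        raise ConfigurationError("empty control set for HWE filtering")

    G = G.orient_to_minor()
    miss = G.variant_missing_rate()
    maf = G.maf()
    hard = G.hard_call_matrix(thresholds.hard_call_tol)[controls]
    hwe_p = np.empty(G.n_variants)
    for j in range(G.n_variants):
        hwe_p[j] = hwe_exact_test(*genotype_counts(hard[:, j]))

    flags = []
    for j in range(G.n_variants):
        f = []
        if miss[j] > thresholds.max_missing:
            f.append("missingness")
        if hwe_p[j] < thresholds.hwe_p:
            f.append("hwe")
        if maf[j] < thresholds.min_maf:
            f.append("maf")
        flags.append(";".join(f))
    flags = np.array(flags, dtype=object)

    report = G.variants.copy()
    report["maf"] = maf
    report["missing_rate"] = miss
    report["hwe_p"] = hwe_p
    report["qc_flags"] = flags
    keep = np.flatnonzero(flags == "")
    logger.info("variant_qc: %d of %d variants retained", len(keep), G.n_variants)
    return G.subset(variant_idx=keep), report


def sample_qc(
    G: GenotypeMatrix, min_call_rate: float = 0.98
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Drop subjects with genotype call rate below ``min_call_rate``.

    Returns the filtered matrix and the ids of removed subjects.
    """
    rate = G.subject_call_rate()
    keep = np.flatnonzero(rate >= min_call_rate)
    removed = G.subjects[rate < min_call_rate]
    if removed.size:
        logger.info("sample_qc: removed %d subjects below call rate %.3f",
                    removed.size, min_call_rate)
    return G.subset(subject_idx=keep), removed


def site_effect_test(hard_calls: np.ndarray, site: np.ndarray) -> float:
    """p-value for a between-site allele-frequency difference at one variant.

    Builds the 2 x 2 allele-count table (two alleles per subject) and
    applies the chi-square test, falling back to Fisher's exact test when
    any expected cell is below 5.
    """
    table = np.zeros((2, 2))
    for k, s in enumerate(np.unique(site)[:2]):
        d = hard_calls[site == s]
        d = d[~np.isnan(d)]
        a1 = d.sum()
        table[k] = (a1, 2 * len(d) - a1)
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        return 1.0
    expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
    if (expected < 5).any():
        return float(fisher_exact(table.astype(int))[1])
    return float(chi2_contingency(table, correction=False)[1])


def site_effect_filter(
    G: GenotypeMatrix,
    site: np.ndarray,
    alpha: float = 1e-5,
    hard_call_tol: float = 0.1,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Remove variants whose allele frequencies differ between sites at
    p < ``alpha``. With a single site the filter is skipped with a
    warning. Returns (filtered matrix, per-variant p-values)."""
    site = np.asarray(site)
    if len(site) != G.n_subjects:
        raise ParameterError("site labels must align with subjects")
    if len(np.unique(site)) < 2:
        logger.warning("site_effect_filter: single site, filter skipped")
        return G, np.ones(G.n_variants)
    hard = G.hard_call_matrix(hard_call_tol)
    p = np.array([site_effect_test(hard[:, j], site) for j in range(G.n_variants)])
    keep = np.flatnonzero(p >= alpha)
    logger.info("site_effect_filter: removed %d of %d variants",
                G.n_variants - len(keep), G.n_variants)
    return G.subset(variant_idx=keep), p
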