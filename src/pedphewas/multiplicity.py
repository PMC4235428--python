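"""Multiple-testing machinery: LD statistics, LD pruning, Benjamini–
Hochberg q-values and adaptive label permutation.

Two r-squared estimators live here on purpose. :func:`ld_stats` computes
haplotype-based LD (r², D′) by EM from unphased genotypes and is the
reporting estimator; :func:`prune` uses the squared Pearson correlation
of dosage vectors (the PLINK ``--indep-pairwise`` convention), which
needs no haplotype model and is defined for dosage data. The pruned
variant set defines the grid over which the BH false-discovery rate is
estimated, mirroring the practice of counting only quasi-independent
tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .exceptions import ParameterError, UndefinedLdError
from .genotypes import GenotypeMatrix
from .assoc import fit_logistic

logger = logging.getLogger(__name__)


@dataclass
class LdStats:
    """Two-locus LD summary. Haplotypes ordered (AB, Ab, aB, ab) where A
    and B are the counted alleles at each locus."""

    r2: float
    d_prime: float
    hap_freqs: np.ndarray
    n: int

    def __post_init__(self) -> None:
        if abs(self.hap_freqs.sum() - 1.0) > 1e-8:
            raise ParameterError("haplotype frequencies must sum to 1")


def _em_haplotypes(n33: np.ndarray, tol: float = 1e-10, max_iter: int = 1000) -> np.ndarray:
    """EM estimate of (pAB, pAb, paB, pab) from a 3x3 genotype count
    table indexed by minor-allele counts (g1, g2)."""
    n = n33.sum()
    # haplotype contributions fixed for every cell except the double het
    fixed = np.zeros(4)
    for i in range(3):
        for j in range(3):
            c = n33[i, j]
            if c == 0 or (i == 1 and j == 1):
                continue
            # each subject contributes two haplotypes
            a_counts = {2: (2, 0), 1: (1, 1), 0: (0, 2)}[i]  # copies of A, a
            b_counts = {2: (2, 0), 1: (1, 1), 0: (0, 2)}[j]
            # unambiguous: min(aA, bB) pairings are forced
            # build the two haplotypes explicitly
            haps = []
            a_list = ["A"] * a_counts[0] + ["a"] * a_counts[1]
            b_list = ["B"] * b_counts[0] + ["b"] * b_counts[1]
            for al, bl in zip(a_list, b_list):
                haps.append((al, bl))
            for al, bl in haps:
                idx = {"AB": 0, "Ab": 1, "aB": 2, "ab": 3}[al + bl]
                fixed[idx] += c
    n_dh = n33[1, 1]
    p = np.full(4, 0.25)
    for _ in range(max_iter):
        if n_dh:
            denom = p[0] * p[3] + p[1] * p[2]
            frac = 0.5 if denom == 0 else p[0] * p[3] / denom
            dh = n_dh * np.array([frac, 1 - frac, 1 - frac, frac])
        else:
            dh = np.zeros(4)
        new = (fixed + dh) / (2.0 * n)
        if np.max(np.abs(new - p)) < tol:
            p = new
            break
        p = new
    return p


def ld_stats(g1: np.ndarray, g2: np.ndarray, hard_call_tol: float = 0.1) -> LdStats:
    """Haplotype-based LD between two loci from unphased genotypes.

    Dosages are hard-called, complete pairs tabulated into a 3x3 table,
    haplotype frequencies estimated by EM, and D, D' and r² derived:
    D = pAB - pA pB; D' = |D| / Dmax; r² = D² / (pA pa pB pb).
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise ParameterError("genotype vectors differ in length")
    r1 = np.round(g1)
    r2v = np.round(g2)
    ok = (
        ~np.isnan(g1) & ~np.isnan(g2)
        & (np.abs(g1 - r1) <= hard_call_tol) & (np.abs(g2 - r2v) <= hard_call_tol)
    )
    a, b = r1[ok].astype(int), r2v[ok].astype(int)
    if len(a) == 0:
        raise UndefinedLdError("no complete genotype pairs")
    if a.min() == a.max() or b.min() == b.max():
        raise UndefinedLdError("LD undefined for a monomorphic locus")
    # table indexed directly by copies of the counted allele at each locus
    n33 = np.zeros((3, 3), dtype=int)
    np.add.at(n33, (a, b), 1)
    hap = _em_haplotypes(n33)
    p_a = hap[0] + hap[1]
    p_b = hap[0] + hap[2]
    d = hap[0] - p_a * p_b
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = 0.0 if d_max == 0 else abs(d) / d_max
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    r2 = 0.0 if denom == 0 else d * d / denom
    return LdStats(r2=float(r2), d_prime=float(d_prime), hap_freqs=hap, n=int(len(a)))


def dosage_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over complete
    pairs (the pruning estimator)."""
    ok = ~np.isnan(g1) & ~np.isnan(g2)
    a, b = g1[ok], g2[ok]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def prune(
    G: GenotypeMatrix,
    r2_threshold: float = 0.5,
    window_kb: float = 500.0,
) -> tuple[list[str], pd.DataFrame]:
    """Greedy LD pruning in position order.

    Sweeping each chromosome by position, a variant is dropped when its
    r² with any already-kept variant within ``window_kb`` exceeds the
    threshold; the output therefore contains no within-window pair above
    it (asserted before returning). Returns the kept variant ids and a
    report frame (variant, kept, culprit, r2).
    """
    pos = G.variants["pos"].to_numpy()
    chrom = G.variants["chrom"].to_numpy()
    order = np.lexsort((pos, chrom))
    window = window_kb * 1000.0
    kept: list[int] = []
    report_rows = []
    for j in order:
        culprit, worst = None, 0.0
        for k in kept:
            if chrom[k] != chrom[j] or abs(pos[k] - pos[j]) > window:
                continue
            r2 = dosage_r2(G.dosages[:, j], G.dosages[:, k])
            if r2 > r2_threshold and r2 >= worst:
                culprit, worst = k, r2
        if culprit is None:
            kept.append(j)
            report_rows.append((G.variants["id"][j], True, "", np.nan))
        else:
            report_rows.append(
                (G.variants["id"][j], False, G.variants["id"][culprit], worst)
            )
    # post-hoc invariant: no within-window kept pair above threshold
    for a, b in combinations(kept, 2):
        if chrom[a] == chrom[b] and abs(pos[a] - pos[b]) <= window:
            assert dosage_r2(G.dosages[:, a], G.dosages[:, b]) <= r2_threshold
    kept_ids = [G.variants["id"][j] for j in sorted(kept)]
    report = pd.DataFrame(report_rows, columns=["variant", "kept", "culprit", "r2"])
    logger.info("prune: kept %d of %d variants", len(kept_ids), G.n_variants)
    return kept_ids, report


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values.

    q_(i) = min_{j >= i} m p_(j) / j, mapped back to input order;
    requires p in (0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ParameterError("p must be a non-empty 1-d vector")
    if ((p <= 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ParameterError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def fdr_over_pruned(assoc: pd.DataFrame, kept_variants: list[str]) -> pd.DataFrame:
    """Attach a ``q`` column computed by BH over the pooled grid of
    (pruned variant x phenotype) tests; tests at pruned-away variants or
    with degenerate fits get q = NaN."""
    out = assoc.copy()
    out["q"] = np.nan
    in_grid = out["variant"].isin(set(kept_variants)) & out["p"].notna()
    if in_grid.any():
        out.loc[in_grid, "q"] = bh_qvalues(out.loc[in_grid, "p"].to_numpy())
    return out


@dataclass
class PermutationResult:
    n_trials: int
    n_exceedances: int
    p_perm: float
    stopped_early: bool
    exhaustive: bool = False
    variant: str | None = None
    phecode: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p_perm <= 1.0:
            raise ParameterError("p_perm must lie in (0, 1]")


def adaptive_permutation(
    y: np.ndarray,
    g: np.ndarray,
    covariates: np.ndarray | None = None,
    max_trials: int = 1_000_000,
    early_stop_exceedances: int = 10,
    seed: int | np.random.Generator = 0,
) -> PermutationResult:
    """Empirical p-value by case/control label permutation.

    Case and control labels are shuffled (preserving the case count;
    covariates stay attached to their subjects), the regression refit,
    and permuted |Wald z| compared with the observed one. Sampling stops
    once ``early_stop_exceedances`` permuted statistics reach the
    observed value, or at ``max_trials``; p = (r + 1) / (n + 1). When the
    number of distinct case-label assignments does not exceed the trial
    budget the null is enumerated exhaustively instead (flagged, p =
    exceedances / total).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    observed = fit_logistic(y, g, covariates)
    obs_stat = abs(observed.zstat)
    n = len(y)
    n_cases = int(y.sum())

    def perm_stat(y_perm: np.ndarray) -> float:
        try:
            fit = fit_logistic(y_perm, g, covariates)
        except Exception:
            return np.nan
        z = abs(fit.zstat)
        return z if np.isfinite(z) else np.nan

    total_distinct = comb(n, n_cases)
    if total_distinct <= max_trials:
        logger.info("adaptive_permutation: exhaustive enumeration of %d assignments",
                    total_distinct)
        exceed = 0
        for case_idx in combinations(range(n), n_cases):
            y_perm = np.zeros(n)
            y_perm[list(case_idx)] = 1.0
            z = perm_stat(y_perm)
            if np.isfinite(z) and z >= obs_stat - 1e-12:
                exceed += 1
        return PermutationResult(
            n_trials=total_distinct, n_exceedances=exceed,
            p_perm=max(exceed, 1) / total_distinct,
            stopped_early=False, exhaustive=True,
        )

    exceed = 0
    trials = 0
    while trials < max_trials:
        y_perm = rng.permutation(y)
        trials += 1
        z = perm_stat(y_perm)
        if np.isfinite(z) and z >= obs_stat - 1e-12:
            exceed += 1
            if exceed >= early_stop_exceedances:
                break
    return PermutationResult(
        n_trials=trials, n_exceedances=exceed,
        p_perm=(exceed + 1) / (trials + 1),
        stopped_early=trials < max_trials, exhaustive=False,
    )
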