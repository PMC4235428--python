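"""The core PheWAS scan: per (phenotype, variant) logistic regression.

Each eligible binary phenotype is regressed on additive minor-allele
dosage with the top principal components as covariates; the per-allele
log-odds ratio is tested with a two-sided Wald test. Subjects excluded
from a phenotype's control group are dropped for that phenotype; missing
genotypes are dropped per test (complete-case, as in PLINK).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .exceptions import (
    DegeneratePredictorError,
    DegenerateResponseError,
    ParameterError,
)
from .genotypes import GenotypeMatrix
from .structure import PCSet

logger = logging.getLogger(__name__)

#: column order of the association result table
ASSOC_COLUMNS = (
    "phecode", "variant", "chrom", "pos", "minor_allele",
    "n_cases", "n_controls", "case_freq", "control_freq",
    "beta", "se", "or_", "ci_lo", "ci_hi", "p", "converged",
)

_MAX_ITER = 25
_SCORE_TOL = 1e-8
_LL_RTOL = 1e-10
_SEPARATION_BETA = 10.0


@dataclass
class LogisticFit:
    """Wald inference for the genotype term of one logistic fit."""

    beta: float
    se: float
    p: float
    converged: bool
    n: int
    coefficients: np.ndarray

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci95(self) -> tuple[float, float]:
        # exponent clipped: quasi-separated fits have huge SEs
        lo = np.clip(self.beta - 1.96 * self.se, -700, 700)
        hi = np.clip(self.beta + 1.96 * self.se, -700, 700)
        return float(np.exp(lo)), float(np.exp(hi))

    @property
    def zstat(self) -> float:
        return self.beta / self.se


def _log_likelihood(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable: -log(1 + exp(-(2y-1) eta))
    return float(-np.logaddexp(0.0, -(2.0 * y - 1.0) * eta).sum())


def fit_logistic(
    y: np.ndarray,
    g: np.ndarray,
    covariates: np.ndarray | None = None,
) -> LogisticFit:
    """Maximum-likelihood logistic regression of ``y`` on dosage ``g``.

    Fit by iteratively reweighted least squares with an intercept;
    convergence when the maximum absolute score drops below 1e-8 or the
    relative log-likelihood change below 1e-10, within 25 iterations.
    Rows with a missing genotype or covariate are dropped pairwise.
    Quasi-separation (non-convergence or |beta| > 10) is flagged via
    ``converged=False`` rather than raising.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    if y.shape != g.shape:
        raise ParameterError("y and g lengths differ")
    cols = [np.ones_like(g), g]
    if covariates is not None and np.size(covariates):
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(y):
            cov = cov.T
        if cov.shape[0] != len(y):
            raise ParameterError("covariates do not align with y")
        cols.extend(cov.T)
    x = np.column_stack(cols)
    keep = ~(np.isnan(y) | np.isnan(x).any(axis=1))
    y, x = y[keep], x[keep]
    if not np.isin(y, (0.0, 1.0)).all():
        raise ParameterError("y must be binary 0/1")
    if y.min() == y.max():
        raise DegenerateResponseError("response is all-case or all-control")
    if x[:, 1].min() == x[:, 1].max():
        raise DegeneratePredictorError("genotype column is constant")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise DegeneratePredictorError("design matrix is rank deficient (collinear)")

    beta = np.zeros(x.shape[1])
    ll = _log_likelihood(y, x @ beta)
    converged = False
    for _ in range(_MAX_ITER):
        eta = x @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        score = x.T @ (y - mu)
        hessian = x.T @ (w[:, None] * x)
        try:
            step = np.linalg.solve(hessian, score)
        except np.linalg.LinAlgError:
            break  # information matrix singular: quasi-separation
        beta = beta + step
        ll_new = _log_likelihood(y, x @ beta)
        if np.max(np.abs(score)) < _SCORE_TOL:
            converged = True
            break
        if abs(ll_new - ll) < _LL_RTOL * (abs(ll) + 1e-300):
            converged = True
            break
        ll = ll_new

    mu = expit(x @ beta)
    w = mu * (1.0 - mu)
    hessian = x.T @ (w[:, None] * x)
    try:
        cov_beta = np.linalg.inv(hessian)
        se = float(np.sqrt(max(cov_beta[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        se = float("nan")
        converged = False
    if abs(beta[1]) > _SEPARATION_BETA:
        converged = False
    p = float(2.0 * norm.sf(abs(beta[1] / se))) if se and np.isfinite(se) and se > 0 else float("nan")
    p = min(p, 1.0) if np.isfinite(p) else p
    p = max(p, np.nextafter(0, 1)) if np.isfinite(p) else p
    return LogisticFit(
        beta=float(beta[1]), se=se, p=p, converged=converged,
        n=int(len(y)), coefficients=beta,
    )


def allelic_or(p_case: float, p_ctrl: float) -> float:
    """Unadjusted allelic odds ratio from case and control allele
    frequencies: [p1/(1-p1)] / [p0/(1-p0)]. Boundary frequencies give an
    explicit 0 or inf with a warning rather than an exception."""
    for v in (p_case, p_ctrl):
        if not 0.0 <= v <= 1.0:
            raise ParameterError("allele frequencies must lie in [0, 1]")
    if p_case in (0.0, 1.0) or p_ctrl in (0.0, 1.0):
        logger.warning("allelic_or: boundary frequency, OR is 0 or infinite")
        if p_case == p_ctrl:
            return float("nan")
        if p_case == 1.0 or p_ctrl == 0.0:
            return float("inf")
        return 0.0
    return (p_case / (1.0 - p_case)) / (p_ctrl / (1.0 - p_ctrl))


def scan(
    phenotypes: pd.DataFrame,
    G: GenotypeMatrix,
    pcs: PCSet | None = None,
    min_cases: int = 20,
) -> pd.DataFrame:
    """Run the full phenotype x variant association scan.

    Parameters
    ----------
    phenotypes : DataFrame
        Wide subjects x phecodes matrix with entries 1 (case),
        0 (control) or NaN (excluded), indexed by subject id.
    G : GenotypeMatrix
        QC-passed genotypes, A1 oriented to the minor allele.
    pcs : PCSet, optional
        Principal-component covariates; omit (or K=0) for an
        unadjusted scan.
    min_cases : int
        A phenotype enters the scan only with case count STRICTLY
        greater than this.

    Returns
    -------
    DataFrame
        One row per (eligible phenotype, variant), ordered by phecode
        then variant position. Degenerate fits are retained with
        ``converged=False`` and NaN statistics.
    """
    pheno = phenotypes.reindex(np.asarray(G.subjects, dtype=object))
    cov = None
    if pcs is not None and pcs.k > 0:
        if not np.array_equal(np.asarray(pcs.subjects, dtype=object), G.subjects):
            raise ParameterError("PC scores do not align with genotype subjects")
        cov = pcs.covariates()
    order = np.argsort(G.variants["pos"].to_numpy(), kind="stable")
    rows = []
    eligible = [
        pc for pc in pheno.columns
        if (pheno[pc] == 1).sum() > min_cases and (pheno[pc] == 0).sum() > 0
    ]
    eligible = sorted(eligible, key=_phecode_key)
    for pc in eligible:
        y_full = pheno[pc].to_numpy(dtype=float)
        analyzed = ~np.isnan(y_full)
        for j in order:
            g_full = G.dosages[:, j]
            use = analyzed & ~np.isnan(g_full)
            y, g = y_full[use], g_full[use]
            c = cov[use] if cov is not None else None
            n_cases = int((y == 1).sum())
            n_controls = int((y == 0).sum())
            case_freq = float(g[y == 1].mean() / 2.0) if n_cases else float("nan")
            ctrl_freq = float(g[y == 0].mean() / 2.0) if n_controls else float("nan")
            v = G.variants.iloc[j]
            try:
                fit = fit_logistic(y, g, c)
                ci_lo, ci_hi = fit.ci95
                rows.append((
                    pc, v["id"], v["chrom"], v["pos"], v["a1"],
                    n_cases, n_controls, case_freq, ctrl_freq,
                    fit.beta, fit.se, fit.odds_ratio, ci_lo, ci_hi,
                    fit.p, fit.converged,
                ))
            except (DegeneratePredictorError, DegenerateResponseError) as exc:
                logger.debug("degenerate fit %s x %s: %s", pc, v["id"], exc)
                rows.append((
                    pc, v["id"], v["chrom"], v["pos"], v["a1"],
                    n_cases, n_controls, case_freq, ctrl_freq,
                    np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, False,
                ))
    return pd.DataFrame(rows, columns=ASSOC_COLUMNS)


def _phecode_key(pc: str):
    try:
        return (0, float(pc), "")
    except ValueError:
        return (1, 0.0, str(pc))
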