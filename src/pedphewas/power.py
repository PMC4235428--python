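"""Conditional analyses, gene-gene interaction tests, and case-control
power / minimum-case calculations.

The analytic power engine is the normal approximation to the allelic
two-proportion test. With control risk-allele frequency p0 and per-allele
odds ratio OR, the case frequency is p1 = OR·odds0 / (1 + OR·odds0); each
subject contributes two alleles, so

    power = Phi( |p1 - p0| / SE_alt - z_{1-alpha/2} ),
    SE_alt = sqrt( p1(1-p1) / (2 n_cases) + p0(1-p0) / (2 n_controls) ).

A binomial simulation oracle (:func:`simulated_power`) cross-checks the
closed form by drawing allele counts and applying the same two-proportion
z-test; published minimum-case figures are treated as upper bounds on
what this approximation returns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .exceptions import (
    DegeneratePredictorError,
    NoSolutionError,
    ParameterError,
)
from .multiplicity import dosage_r2
from .assoc import LogisticFit, fit_logistic

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# conditional and interaction analyses
# ---------------------------------------------------------------------------

def conditional_fit(
    y: np.ndarray,
    g: np.ndarray,
    covariates: np.ndarray | None = None,
    condition_on: np.ndarray | None = None,
) -> LogisticFit:
    """Association of ``g`` with ``y`` conditioning on another phenotype
    or genotype: the conditioning vector is appended to the covariates
    and the Wald p for ``g`` reported. A conditioning column nearly
    collinear with the genotype (r² > 0.99) is rejected."""
    if condition_on is None:
        raise ParameterError("condition_on is required")
    cond = np.asarray(condition_on, dtype=float)
    if cond.shape[0] != len(np.asarray(y)):
        raise ParameterError("conditioning vector does not align with subjects")
    if dosage_r2(np.asarray(g, dtype=float), cond) > 0.99:
        raise DegeneratePredictorError(
            "conditioning column is collinear with the tested genotype"
        )
    cov = cond[:, None] if covariates is None else np.column_stack(
        [np.atleast_2d(np.asarray(covariates, dtype=float).T).T, cond]
    )
    return fit_logistic(y, g, cov)


def interaction_test(
    y: np.ndarray,
    g1: np.ndarray,
    g2: np.ndarray,
    covariates: np.ndarray | None = None,
) -> float:
    """Wald p-value for the multiplicative g1 x g2 interaction term in a
    logistic model containing both main effects."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    product = g1 * g2
    ok = ~(np.isnan(g1) | np.isnan(g2))
    if np.nanstd(g2[ok]) == 0 or np.nanstd(g1[ok]) == 0:
        raise DegeneratePredictorError("a genotype vector is constant")
    if np.nanstd(product[ok]) == 0:
        raise DegeneratePredictorError("interaction column is constant")
    base = [g2[:, None]]
    if covariates is not None and np.size(covariates):
        base.append(np.atleast_2d(np.asarray(covariates, dtype=float).T).T)
    base.append(g1[:, None])
    cov = np.column_stack(base)
    # fit with the product as the tested term; g1, g2 (and extra
    # covariates) enter as nuisance columns
    fit = fit_logistic(y, product, cov)
    return fit.p


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------

@dataclass
class PowerQuery:
    """Design of a case-control allelic power calculation."""

    raf: float                       # control risk-allele frequency
    odds_ratio: float                # per-allele OR
    alpha: float = 0.05              # two-sided
    n_controls: int | None = None
    control_case_ratio: float | None = None
    target_power: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 < self.raf < 1.0:
            raise ParameterError("risk-allele frequency must be in (0, 1)")
        if self.odds_ratio <= 0:
            raise ParameterError("odds ratio must be > 0")
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError("alpha must be in (0, 1)")
        if not 0.0 < self.target_power < 1.0:
            raise ParameterError("target power must be in (0, 1)")
        if (self.n_controls is None) == (self.control_case_ratio is None):
            raise ParameterError(
                "give exactly one of n_controls or control_case_ratio"
            )

    def controls_for(self, n_cases: int) -> int:
        if self.n_controls is not None:
            return self.n_controls
        return max(1, int(round(self.control_case_ratio * n_cases)))

    @property
    def case_freq(self) -> float:
        odds0 = self.raf / (1.0 - self.raf)
        odds1 = self.odds_ratio * odds0
        return odds1 / (1.0 + odds1)


def power_at(n_cases: int, query: PowerQuery) -> float:
    """Power of the two-proportion allelic test at ``n_cases`` cases.

    At OR = 1 the test has no effect to detect and the function returns
    the type-I rate alpha (boundary case, logged)."""
    if n_cases < 1:
        raise ParameterError("n_cases must be >= 1")
    if query.odds_ratio == 1.0:
        logger.warning("power_at: OR = 1, returning the null rejection rate alpha")
        return query.alpha
    p0, p1 = query.raf, query.case_freq
    n_controls = query.controls_for(n_cases)
    se_alt = np.sqrt(
        p1 * (1.0 - p1) / (2.0 * n_cases) + p0 * (1.0 - p0) / (2.0 * n_controls)
    )
    z_alpha = norm.isf(query.alpha / 2.0)
    return float(norm.cdf(abs(p1 - p0) / se_alt - z_alpha))


def min_cases(query: PowerQuery, max_cases: int = 10_000_000) -> int:
    """Smallest case count reaching the target power.

    Integer bisection on the monotone ``power_at``; the returned n
    satisfies power_at(n) >= target and power_at(n-1) < target."""
    if query.odds_ratio == 1.0:
        raise NoSolutionError("no case count attains the target power at OR = 1")
    lo, hi = 1, 1
    while power_at(hi, query) < query.target_power:
        hi *= 2
        if hi > max_cases:
            raise NoSolutionError(f"target power unattainable below {max_cases} cases")
    while lo < hi:
        mid = (lo + hi) // 2
        if power_at(mid, query) >= query.target_power:
            hi = mid
        else:
            lo = mid + 1
    return lo


def simulated_power(
    n_cases: int,
    query: PowerQuery,
    n_reps: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Monte-Carlo rejection rate of the allelic two-proportion z-test.

    Draws case and control minor-allele counts binomially at the design
    frequencies and applies the same test the closed form approximates;
    serves as the independent oracle for :func:`power_at`.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p0, p1 = query.raf, query.case_freq
    n_controls = query.controls_for(n_cases)
    a_case = rng.binomial(2 * n_cases, p1, size=n_reps)
    a_ctrl = rng.binomial(2 * n_controls, p0, size=n_reps)
    f1 = a_case / (2.0 * n_cases)
    f0 = a_ctrl / (2.0 * n_controls)
    pooled = (a_case + a_ctrl) / (2.0 * n_cases + 2.0 * n_controls)
    se0 = np.sqrt(pooled * (1 - pooled) * (1 / (2 * n_cases) + 1 / (2 * n_controls)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se0 > 0, np.abs(f1 - f0) / se0, 0.0)
    z_alpha = norm.isf(query.alpha / 2.0)
    return float((z >= z_alpha).mean())
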