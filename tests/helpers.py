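"""Independent oracles used across the test suite.

These deliberately re-derive quantities by brute force (enumeration,
naive quadratic algorithms, closed forms) without touching the package
implementations they check.
"""

from __future__ import annotations

from fractions import Fraction
from math import factorial

import numpy as np


def hwe_enumeration_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE p-value by full rational enumeration of heterozygote
    counts conditional on the minor-allele count."""
    n = n_AA + n_Aa + n_aa
    n_minor = min(2 * n_AA + n_Aa, 2 * n - (2 * n_AA + n_Aa))
    probs = {}
    total = Fraction(0)
    for het in range(n_minor % 2, n_minor + 1, 2):
        hom_minor = (n_minor - het) // 2
        hom_major = n - hom_minor - het
        if hom_major < 0:
            continue
        w = Fraction(
            factorial(n) * 2**het,
            factorial(hom_minor) * factorial(het) * factorial(hom_major),
        )
        probs[het] = w
        total += w
    obs = probs[n_Aa]
    p = sum(w for w in probs.values() if w <= obs) / total
    return float(p)


def bh_naive_oracle(p: np.ndarray) -> np.ndarray:
    """O(m^2) Benjamini–Hochberg step-up, straight from the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_idx in range(m):
        candidates = [
            m * p[order[j]] / (j + 1) for j in range(rank_idx, m)
        ]
        q[order[rank_idx]] = min(1.0, min(candidates))
    return q


def greedy_prune_oracle(
    dosages: np.ndarray, pos: np.ndarray, r2_threshold: float, window_bp: float
) -> list[int]:
    """Naive position-order greedy pruning on one chromosome."""
    kept: list[int] = []
    for j in np.argsort(pos, kind="stable"):
        ok = True
        for k in kept:
            if abs(pos[k] - pos[j]) > window_bp:
                continue
            a, b = dosages[:, j], dosages[:, k]
            m = ~np.isnan(a) & ~np.isnan(b)
            if m.sum() < 2 or a[m].std() == 0 or b[m].std() == 0:
                continue
            if np.corrcoef(a[m], b[m])[0, 1] ** 2 > r2_threshold:
                ok = False
                break
        if ok:
            kept.append(j)
    return sorted(kept)


def logit_newton_oracle(y, x, tol=1e-12, max_iter=200):
    """Brute-force Newton optimiser for logistic regression returning
    (coefficients, standard errors); independent of the package IRLS."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    beta = np.zeros(x.shape[1])
    for _ in range(max_iter):
        eta = np.clip(x @ beta, -500, 500)
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = x.T @ (y - mu)
        hess = x.T @ ((mu * (1 - mu))[:, None] * x)
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = np.clip(x @ beta, -500, 500)
    mu = 1.0 / (1.0 + np.exp(-eta))
    hess = x.T @ ((mu * (1 - mu))[:, None] * x)
    se = np.sqrt(np.diag(np.linalg.inv(hess)))
    return beta, se


def draw_case_control_genotypes(rng, n_cases, n_controls, p_case, p_ctrl):
    """Retrospective sampling: HWE genotypes at the case and control
    allele frequencies."""
    g_case = rng.binomial(2, p_case, size=n_cases).astype(float)
    g_ctrl = rng.binomial(2, p_ctrl, size=n_controls).astype(float)
    g = np.concatenate([g_case, g_ctrl])
    y = np.concatenate([np.ones(n_cases), np.zeros(n_controls)])
    return y, g
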