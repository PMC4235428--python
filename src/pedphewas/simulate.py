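"""Synthetic EMR-linked genotype cohorts with known ground truth.

The generator emulates the statistical structure a pediatric PheWAS
assumes: two recruitment sites, a structured European-like population of
two subpopulations (Balding–Nichols allele-frequency divergence at a
given FST), Hardy–Weinberg genotypes within subpopulation, LD blocks via
a haplotype copy-with-mutation chain, site-divergent artifact variants,
missing genotype entries, and ICD-9 event tables produced by a logistic
liability model with planted per-allele odds ratios. Everything hidden
from the analysis (subpopulation labels, planted log-ORs, artifact
variant ids) is returned in a :class:`CohortTruth` so downstream stages
can be tested for parameter recovery.

One RNG stream per stage, split deterministically from the master seed,
so the same spec and seed reproduce byte-identical output and stages can
be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .exceptions import DefinitionError, ParameterError
from .genotypes import GenotypeMatrix
from .phecodes import CATEGORIES, PhecodeMap, load_mini_map

_STAGES = {"labels": 0, "frequencies": 1, "genotypes": 2, "missing": 3, "events": 4}


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGES[stage],))
    )


@dataclass(frozen=True)
class VariantSpec:
    """One simulated variant: ancestral MAF, optional LD block membership,
    and whether it carries a between-site genotyping artifact."""

    maf: float
    ld_block: int | None = None
    site_effect: bool = False
    copy_prob: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise ParameterError(f"ancestral MAF must be in (0, 0.5], got {self.maf}")
        if not 0.0 <= self.copy_prob < 1.0:
            raise ParameterError("copy_prob must be in [0, 1)")
        if self.site_effect and self.ld_block is not None:
            raise ParameterError("site-artifact variants cannot sit inside an LD block")


@dataclass(frozen=True)
class PhenotypeSpec:
    """One simulated phenotype: phecode id, baseline prevalence, planted
    (variant index, per-allele OR) effects and a subpopulation loading on
    the liability scale (log-odds shift for subpopulation 1)."""

    phecode: str
    prevalence: float
    effects: tuple[tuple[int, float], ...] = ()
    structure_loading: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ParameterError(f"prevalence must be in (0, 1), got {self.prevalence}")
        for _, odds_ratio in self.effects:
            if odds_ratio <= 0:
                raise ParameterError("all planted ORs must be > 0")


@dataclass
class CohortSpec:
    """Full design of a simulated cohort.

    Defaults mirror the study conditions the package targets: a cohort of
    4,268 European-ancestry children recruited at two sites (83% / 17%
    split), mild within-European substructure (two subpopulations at
    FST = 0.01) and a small genotype missing rate.
    """

    n_subjects: int = 4268
    n_sites: int = 2
    site_fractions: tuple[float, ...] | None = (0.83, 0.17)
    subpop_fractions: tuple[float, ...] = (0.5, 0.5)
    fst: float = 0.01
    variant_specs: tuple[VariantSpec, ...] = ()
    phenotype_specs: tuple[PhenotypeSpec, ...] = ()
    missing_rate: float = 0.005
    site_shift: float = 0.30
    bp_spacing: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ParameterError("n_subjects must be >= 2")
        if not 0.0 <= self.fst <= 0.2:
            raise ParameterError(f"fst must be in [0, 0.2], got {self.fst}")
        if abs(sum(self.subpop_fractions) - 1.0) > 1e-12:
            raise ParameterError("subpop_fractions must sum to 1")
        if self.site_fractions is None:
            self.site_fractions = tuple([1.0 / self.n_sites] * self.n_sites)
        if len(self.site_fractions) != self.n_sites:
            raise ParameterError("site_fractions length must equal n_sites")
        if abs(sum(self.site_fractions) - 1.0) > 1e-12:
            raise ParameterError("site_fractions must sum to 1")
        if not 0.0 <= self.missing_rate <= 0.1:
            raise ParameterError("missing_rate must be in [0, 0.1]")
        if self.site_shift < 0.15:
            raise ParameterError("site_shift must be >= 0.15 to qualify as an artifact")
        for ph in self.phenotype_specs:
            for j, _ in ph.effects:
                if not 0 <= j < len(self.variant_specs):
                    raise ParameterError(
                        f"phenotype {ph.phecode}: variant index {j} out of range"
                    )


@dataclass
class CohortTruth:
    """Hidden simulator state for recovery tests."""

    subpop: np.ndarray
    site: np.ndarray
    beta: dict[tuple[str, str], float]          # (variant id, phecode) -> log-OR
    artifact_ids: list[str]
    subpop_freqs: np.ndarray                     # n_subpops x n_variants
    alpha: dict[str, float] = field(default_factory=dict)
    case_status: dict[str, np.ndarray] = field(default_factory=dict)


def _balding_nichols(rng, ancestral: np.ndarray, fst: float, n_subpops: int) -> np.ndarray:
    """Subpopulation allele frequencies around the ancestral frequency.

    p_k ~ Beta(p (1-F)/F, (1-p)(1-F)/F); F -> 0 collapses to p exactly.
    """
    if fst == 0.0:
        return np.tile(ancestral, (n_subpops, 1))
    a = ancestral * (1.0 - fst) / fst
    b = (1.0 - ancestral) * (1.0 - fst) / fst
    draws = rng.beta(a, b, size=(n_subpops, len(ancestral)))
    return np.clip(draws, 1e-3, 1.0 - 1e-3)


def simulate_genotypes(spec: CohortSpec) -> tuple[GenotypeMatrix, CohortTruth]:
    """Draw the genotype matrix and its ground truth from a cohort spec."""
    if not spec.variant_specs:
        raise ParameterError("spec has no variants")
    n, m = spec.n_subjects, len(spec.variant_specs)
    label_rng = _stage_rng(spec.seed, "labels")
    subpop = label_rng.choice(len(spec.subpop_fractions), size=n, p=spec.subpop_fractions)
    site = label_rng.choice(spec.n_sites, size=n, p=spec.site_fractions)

    freq_rng = _stage_rng(spec.seed, "frequencies")
    ancestral = np.array([v.maf for v in spec.variant_specs])
    subpop_freqs = _balding_nichols(freq_rng, ancestral, spec.fst, len(spec.subpop_fractions))

    geno_rng = _stage_rng(spec.seed, "genotypes")
    dosages = np.empty((n, m), dtype=float)
    # per-subject per-variant frequency, with site shifts on artifact variants
    p_subject = subpop_freqs[subpop, :]          # n x m
    artifact_cols = [j for j, v in enumerate(spec.variant_specs) if v.site_effect]
    for j in artifact_cols:
        base = subpop_freqs[:, j].mean()
        shift = spec.site_shift if base <= 0.5 else -spec.site_shift
        shifted = np.clip(p_subject[:, j] + shift, 1e-3, 1.0 - 1e-3)
        p_subject[:, j] = np.where(site == 1, shifted, p_subject[:, j])

    blocks: dict[int, list[int]] = {}
    for j, v in enumerate(spec.variant_specs):
        if v.ld_block is not None:
            blocks.setdefault(v.ld_block, []).append(j)
    in_block = {j for cols in blocks.values() for j in cols}

    free = [j for j in range(m) if j not in in_block]
    if free:
        dosages[:, free] = geno_rng.binomial(2, p_subject[:, free])
    for cols in blocks.values():
        # haplotype copy-with-mutation chain down the block, per haplotype
        hap = np.empty((n, 2, len(cols)), dtype=np.int8)
        first = cols[0]
        hap[:, :, 0] = geno_rng.binomial(1, p_subject[:, [first, first]])
        for t, j in enumerate(cols[1:], start=1):
            copy_prob = spec.variant_specs[j].copy_prob
            copy = geno_rng.random((n, 2)) < copy_prob
            fresh = geno_rng.binomial(1, p_subject[:, [j, j]])
            hap[:, :, t] = np.where(copy, hap[:, :, t - 1], fresh)
        dosages[:, cols] = hap.sum(axis=1)

    if spec.missing_rate > 0:
        miss_rng = _stage_rng(spec.seed, "missing")
        mask = miss_rng.random((n, m)) < spec.missing_rate
        dosages[mask] = np.nan

    alleles = np.array(["A", "C", "G", "T"])
    pick = _stage_rng(spec.seed, "frequencies").integers(0, 4, size=(m, 2))
    pick[:, 1] = (pick[:, 0] + 1 + pick[:, 1] % 3) % 4
    variants = pd.DataFrame(
        {
            "id": [f"rs{1_000_000 + j}" for j in range(m)],
            "chrom": np.ones(m, dtype=int),
            "pos": (np.arange(m) + 1) * spec.bp_spacing,
            "a1": alleles[pick[:, 0]],
            "a2": alleles[pick[:, 1]],
        }
    )
    G = GenotypeMatrix(
        subjects=np.array([f"S{i:06d}" for i in range(n)], dtype=object),
        variants=variants,
        dosages=dosages,
    )
    truth = CohortTruth(
        subpop=subpop,
        site=site,
        beta={},
        artifact_ids=[variants["id"][j] for j in artifact_cols],
        subpop_freqs=subpop_freqs,
    )
    return G, truth


def _calibrate_intercept(eta: np.ndarray, prevalence: float) -> float:
    """Intercept such that mean logistic(alpha + eta) equals prevalence."""

    def gap(alpha: float) -> float:
        return expit(alpha + eta).mean() - prevalence

    return brentq(gap, -30.0, 30.0, xtol=1e-10)


def simulate_events(
    G: GenotypeMatrix,
    spec: CohortSpec,
    truth: CohortTruth,
    phecode_map: PhecodeMap | None = None,
    exclusion_emit_rate: float = 0.05,
) -> pd.DataFrame:
    """Generate the ICD-9 event table from a logistic liability model.

    Subject i becomes a case for phecode k with probability
    ``logistic(alpha_k + sum_j beta_jk g_ij + loading_k z_i)`` where
    ``z_i`` indicates membership of subpopulation 1 and ``alpha_k`` is
    calibrated so the marginal prevalence matches the spec. Cases emit
    1–3 ICD-9 codes (with replacement) from the phecode's code list; a
    fraction of non-cases emit one code from a phecode inside the
    exclusion range, to exercise control exclusion downstream. Dates are
    uniform over a five-year window, attached for schema realism only.
    """
    phecode_map = phecode_map or load_mini_map()
    rng = _stage_rng(spec.seed, "events")
    z = (truth.subpop == 1).astype(float)
    mean_fill = np.nanmean(G.dosages, axis=0)
    dosages = np.where(np.isnan(G.dosages), mean_fill, G.dosages)
    rows: list[tuple[str, str, str]] = []
    day0 = np.datetime64("2008-01-01")
    n_days = int((np.datetime64("2013-01-01") - day0) / np.timedelta64(1, "D"))
    for ph in spec.phenotype_specs:
        if ph.phecode not in phecode_map:
            raise DefinitionError(f"phecode {ph.phecode!r} not in map")
        definition = phecode_map[ph.phecode]
        codes = sorted(definition.icd9_codes)
        eta = ph.structure_loading * z
        for j, odds_ratio in ph.effects:
            beta = float(np.log(odds_ratio))
            eta = eta + beta * dosages[:, j]
            truth.beta[(G.variants["id"][j], ph.phecode)] = beta
        eta = eta - eta.mean()
        alpha = _calibrate_intercept(eta, ph.prevalence)
        truth.alpha[ph.phecode] = alpha
        y = rng.random(len(eta)) < expit(alpha + eta)
        truth.case_status[ph.phecode] = y.astype(np.int8)
        # case events
        n_codes = rng.integers(1, 4, size=int(y.sum()))
        case_ids = np.flatnonzero(y)
        for i, k in zip(case_ids, n_codes):
            for code in rng.choice(codes, size=k, replace=True):
                day = day0 + rng.integers(0, n_days)
                rows.append((str(G.subjects[i]), str(code), str(day)))
        # exclusion-range events from non-cases
        siblings = [
            pc for pc in phecode_map.phecodes
            if pc != ph.phecode and definition.excludes(pc)
        ]
        if siblings and exclusion_emit_rate > 0:
            sib_codes = sorted(phecode_map[siblings[0]].icd9_codes)
            non_cases = np.flatnonzero(~y)
            emit = non_cases[rng.random(len(non_cases)) < exclusion_emit_rate]
            for i in emit:
                code = rng.choice(sib_codes)
                day = day0 + rng.integers(0, n_days)
                rows.append((str(G.subjects[i]), str(code), str(day)))
    return pd.DataFrame(rows, columns=["subject_id", "icd9", "date"])


@dataclass
class SimulatedCohort:
    genotypes: GenotypeMatrix
    truth: CohortTruth
    events: pd.DataFrame
    sites: pd.DataFrame
    phecode_map: PhecodeMap


def simulate_cohort(
    spec: CohortSpec,
    phecode_map: PhecodeMap | None = None,
    exclusion_emit_rate: float = 0.05,
) -> SimulatedCohort:
    """Genotypes + events + site table in one call."""
    phecode_map = phecode_map or load_mini_map()
    G, truth = simulate_genotypes(spec)
    events = simulate_events(G, spec, truth, phecode_map, exclusion_emit_rate)
    sites = pd.DataFrame(
        {"subject_id": G.subjects, "site": [f"site{k}" for k in truth.site]}
    )
    return SimulatedCohort(G, truth, events, sites, phecode_map)


def synthetic_phecode_map(
    n_phenotypes: int, codes_per_phecode: int = 3, with_siblings: bool = True
) -> PhecodeMap:
    """Programmatic synthetic map with ``n_phenotypes`` primary phecodes.

    Phecode i is ``(100+i).1`` with ICD-9 codes ``(100+i).01..``; its
    exclusion range covers ``[100+i, 100+i+0.99]`` and (optionally) a
    sibling phecode ``(100+i).8`` lives inside that range so exclusion
    logic is exercised. Categories cycle through the 14 concept paths.
    """
    rows = []
    for i in range(n_phenotypes):
        base = 100 + i
        cat = CATEGORIES[i % len(CATEGORIES)]
        for c in range(codes_per_phecode):
            rows.append(
                (f"{base}.{c:02d}", f"{base}.1", f"synthetic phenotype {i}",
                 base, base + 0.99, cat)
            )
        if with_siblings:
            rows.append(
                (f"{base}.81", f"{base}.8", f"synthetic sibling {i}",
                 base, base + 0.99, cat)
            )
    frame = pd.DataFrame(
        rows, columns=["icd9", "phecode", "description", "exclude_lo", "exclude_hi", "category"]
    )
    return PhecodeMap.from_frame(frame)
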