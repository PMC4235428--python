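"""In-memory genotype container.

Genotypes are held as an additive dosage matrix (subjects x variants) with
values in [0, 2] counting copies of the A1 allele; ``NaN`` marks missing
entries. Variant metadata travels in a pandas DataFrame so QC stages can
append per-variant statistics (MAF, missingness, HWE p, site-difference p,
QC flags) without touching the numeric block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParameterError

#: required columns of the variant metadata frame
VARIANT_COLUMNS = ("id", "chrom", "pos", "a1", "a2")


@dataclass
class GenotypeMatrix:
    """Subjects x variants additive dosage matrix with metadata.

    Parameters
    ----------
    subjects : sequence of str
        Ordered subject identifiers.
    variants : pandas.DataFrame
        One row per variant with at least ``id, chrom, pos, a1, a2``.
        ``a1`` is the counted (minor, after orientation) allele.
    dosages : numpy.ndarray
        ``(n_subjects, n_variants)`` float array, entries in [0, 2] or NaN.
    hard_calls : bool
        True when every non-missing entry is an integer genotype call.
    """

    subjects: np.ndarray
    variants: pd.DataFrame
    dosages: np.ndarray
    hard_calls: bool = True

    def __post_init__(self) -> None:
        self.subjects = np.asarray(self.subjects, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.subjects), len(self.variants)):
            raise ParameterError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.subjects)} subjects x {len(self.variants)} variants"
            )
        missing_cols = set(VARIANT_COLUMNS) - set(self.variants.columns)
        if missing_cols:
            raise ParameterError(f"variant table lacks columns {sorted(missing_cols)}")
        ids = self.variants["id"]
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].tolist()
            raise ParameterError(f"duplicate variant ids: {dups[:5]}")
        with np.errstate(invalid="ignore"):
            bad = np.nansum((self.dosages < 0) | (self.dosages > 2))
        if bad:
            raise ParameterError("dosages must lie in [0, 2] or be NaN")
        self.variants = self.variants.reset_index(drop=True)

    # -- basic shape -----------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    # -- per-variant / per-subject summaries -----------------------------
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def variant_missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def subject_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def allele_freq(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Frequency of the A1 allele per variant, over ``rows`` subjects."""
        d = self.dosages if rows is None else self.dosages[rows]
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def maf(self, rows: np.ndarray | None = None) -> np.ndarray:
        p = self.allele_freq(rows)
        return np.minimum(p, 1.0 - p)

    # -- derived views ---------------------------------------------------
    def hard_call_matrix(self, tol: float = 0.1) -> np.ndarray:
        """Round dosages to {0,1,2}; entries further than ``tol`` from an
        integer become NaN. Used where fractional dosage is undefined
        (HWE and site-frequency contingency tests)."""
        rounded = np.round(self.dosages)
        out = np.where(np.abs(self.dosages - rounded) <= tol, rounded, np.nan)
        return out

    def subset(
        self,
        subject_idx: np.ndarray | None = None,
        variant_idx: np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        si = np.arange(self.n_subjects) if subject_idx is None else np.asarray(subject_idx)
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypeMatrix(
            subjects=self.subjects[si],
            variants=self.variants.iloc[vi].reset_index(drop=True),
            dosages=self.dosages[np.ix_(si, vi)],
            hard_calls=self.hard_calls,
        )

    def orient_to_minor(self, rows: np.ndarray | None = None) -> "GenotypeMatrix":
        """Flip variants so A1 is the minor allele (ties at 0.5 keep the
        input orientation). Frequencies judged on ``rows`` subjects."""
        p = self.allele_freq(rows)
        flip = p > 0.5
        if not flip.any():
            return self
        dosages = self.dosages.copy()
        dosages[:, flip] = 2.0 - dosages[:, flip]
        variants = self.variants.copy()
        a1 = variants["a1"].to_numpy().copy()
        a2 = variants["a2"].to_numpy().copy()
        a1[flip], a2[flip] = a2[flip], a1[flip].copy()
        variants["a1"], variants["a2"] = a1, a2
        return GenotypeMatrix(self.subjects, variants, dosages, self.hard_calls)


def genotype_counts(hard_dosage: np.ndarray) -> tuple[int, int, int]:
    """Counts (n_AA, n_Aa, n_aa) from one hard-call dosage vector, where
    A is the counted A1 allele (dosage 2 = AA homozygote)."""
    d = hard_dosage[~np.isnan(hard_dosage)]
    n_aa = int((d == 0).sum())
    n_het = int((d == 1).sum())
    n_AA = int((d == 2).sum())
    return n_AA, n_het, n_aa
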