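"""ICD-9 -> phecode phenotyping with exclusion-based controls.

Phecodes group related ICD-9 billing codes into one clinical phenotype.
Each phecode also carries an *exclusion range*: phecodes so clinically
close that carriers cannot serve as controls (a subject with ulcerative
colitis is neither a Crohn's case nor a Crohn's control). For each
phenotype the cohort is partitioned into

* ``case``     — carries the phecode (>= ``min_code_count`` mapped events),
* ``excluded`` — not a case but carries a phecode inside the exclusion range,
* ``control``  — everything else, including subjects with no mapped events.

Phenotypes enter the association scan only when the case count is
strictly greater than ``min_cases`` (default 20).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .exceptions import DefinitionError, ParameterError

logger = logging.getLogger(__name__)

CASE, CONTROL, EXCLUDED = "case", "control", "excluded"

#: the 14 top-level disease concept-path categories used for rollups
CATEGORIES = (
    "infectious diseases",
    "neoplasms",
    "endocrine/metabolic",
    "hematopoietic",
    "mental disorders",
    "neurological",
    "sense organs",
    "circulatory system",
    "respiratory",
    "digestive",
    "genitourinary",
    "dermatologic",
    "musculoskeletal",
    "congenital anomalies",
)


@dataclass(frozen=True)
class PhecodeDefinition:
    """One phecode: its ICD-9 code list, exclusion range and category."""

    phecode: str
    description: str
    icd9_codes: frozenset[str]
    exclude_range: tuple[tuple[float, float], ...]
    category: str

    def __post_init__(self) -> None:
        try:
            value = float(self.phecode)
        except ValueError as exc:
            raise ParameterError(f"phecode {self.phecode!r} is not decimal") from exc
        for lo, hi in self.exclude_range:
            if lo > hi:
                raise ParameterError(
                    f"phecode {self.phecode}: exclude interval [{lo}, {hi}] inverted"
                )
        if self.exclude_range and not any(
            lo <= value <= hi for lo, hi in self.exclude_range
        ):
            raise ParameterError(
                f"phecode {self.phecode} lies outside its own exclusion range"
            )

    def excludes(self, other: str) -> bool:
        """True when ``other`` (a phecode string) falls in the exclusion range."""
        v = float(other)
        return any(lo <= v <= hi for lo, hi in self.exclude_range)


class PhecodeMap:
    """ICD-9 -> phecode lookup plus per-phecode definitions.

    Built from the documented CSV schema
    ``icd9,phecode,description,exclude_lo,exclude_hi,category``
    (one row per icd9->phecode pair; definition columns repeated).
    """

    def __init__(self, definitions: dict[str, PhecodeDefinition]):
        self.definitions = dict(sorted(definitions.items(), key=lambda kv: float(kv[0])))
        self.icd9_to_phecodes: dict[str, set[str]] = {}
        for d in self.definitions.values():
            for code in d.icd9_codes:
                self.icd9_to_phecodes.setdefault(code, set()).add(d.phecode)

    def __len__(self) -> int:
        return len(self.definitions)

    def __contains__(self, phecode: str) -> bool:
        return phecode in self.definitions

    def __getitem__(self, phecode: str) -> PhecodeDefinition:
        try:
            return self.definitions[phecode]
        except KeyError:
            raise DefinitionError(f"phecode {phecode!r} not in map") from None

    @property
    def phecodes(self) -> list[str]:
        return list(self.definitions)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PhecodeMap":
        required = {"icd9", "phecode", "description", "exclude_lo", "exclude_hi", "category"}
        missing = required - set(frame.columns)
        if missing:
            raise ParameterError(f"map is missing columns {sorted(missing)}")
        defs: dict[str, PhecodeDefinition] = {}
        for phecode, grp in frame.groupby("phecode", sort=False):
            phecode = str(phecode)
            ranges = {
                (float(lo), float(hi))
                for lo, hi in zip(grp["exclude_lo"], grp["exclude_hi"])
                if pd.notna(lo) and pd.notna(hi)
            }
            defs[phecode] = PhecodeDefinition(
                phecode=phecode,
                description=str(grp["description"].iloc[0]),
                icd9_codes=frozenset(str(c) for c in grp["icd9"]),
                exclude_range=tuple(sorted(ranges)),
                category=str(grp["category"].iloc[0]),
            )
        return cls(defs)

    @classmethod
    def from_csv(cls, path) -> "PhecodeMap":
        return cls.from_frame(pd.read_csv(path, dtype=str))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d in self.definitions.values():
            lo, hi = (d.exclude_range[0] if d.exclude_range else (np.nan, np.nan))
            for code in sorted(d.icd9_codes):
                rows.append((code, d.phecode, d.description, lo, hi, d.category))
        return pd.DataFrame(
            rows,
            columns=["icd9", "phecode", "description", "exclude_lo", "exclude_hi", "category"],
        )


def load_mini_map() -> PhecodeMap:
    """Bundled synthetic miniature phecode map (~40 phecodes, 14 categories).

    A hand-built stand-in patterned on the public phecode map conventions;
    it is NOT the published map, which is an external resource.
    """
    with resources.files("pedphewas.data").joinpath(
        "phecode_map_synthetic_mini.csv"
    ).open() as fh:
        return PhecodeMap.from_csv(fh)


def _valid_icd9(code: str) -> bool:
    """Dot-formatted ICD-9: 3 digits (optionally V/E-prefixed) + optional
    1-2 decimal digits."""
    code = str(code)
    body = code
    if body[:1] in ("V", "E"):
        body = body[1:]
    parts = body.split(".")
    if len(parts) > 2 or not parts[0]:
        return False
    if not parts[0].isdigit() or len(parts[0]) > (4 if code[:1] == "E" else 3):
        return False
    if len(parts) == 2 and not (parts[1].isdigit() and 1 <= len(parts[1]) <= 2):
        return False
    return True


@dataclass
class Occurrences:
    """Per-subject phecode occurrence sets with ICD-9 provenance."""

    #: phecode -> {subject -> number of mapped events}
    counts: dict[str, dict[str, int]]
    #: (subject, phecode) -> set of triggering ICD-9 codes
    triggers: dict[tuple[str, str], set[str]]
    n_events: int
    n_unmapped: int
    unmapped_codes: dict[str, int]
    n_malformed: int

    def carriers(self, phecode: str, min_code_count: int = 1) -> set[str]:
        return {s for s, c in self.counts.get(phecode, {}).items() if c >= min_code_count}


def translate(events: pd.DataFrame, phecode_map: PhecodeMap) -> Occurrences:
    """Map an ICD-9 event table to per-subject phecode occurrence sets.

    ``events`` needs columns ``subject_id`` and ``icd9``; repeated events
    increment the per-phecode count but occurrence is a set property.
    Unmapped ICD-9 codes are tallied, never silently dropped; malformed
    codes are skipped with a warning.
    """
    if not {"subject_id", "icd9"} <= set(events.columns):
        raise ParameterError("events table needs subject_id and icd9 columns")
    counts: dict[str, dict[str, int]] = {}
    triggers: dict[tuple[str, str], set[str]] = {}
    unmapped: dict[str, int] = {}
    n_malformed = 0
    for subject, code in zip(events["subject_id"].astype(str), events["icd9"].astype(str)):
        if not _valid_icd9(code):
            n_malformed += 1
            logger.warning("malformed ICD-9 code %r for subject %s; skipped", code, subject)
            continue
        phecodes = phecode_map.icd9_to_phecodes.get(code)
        if not phecodes:
            unmapped[code] = unmapped.get(code, 0) + 1
            continue
        for pc in phecodes:
            counts.setdefault(pc, {})
            counts[pc][subject] = counts[pc].get(subject, 0) + 1
            triggers.setdefault((subject, pc), set()).add(code)
    n_unmapped = sum(unmapped.values())
    if n_unmapped:
        logger.info("%d events carried ICD-9 codes absent from the map", n_unmapped)
    return Occurrences(
        counts=counts,
        triggers=triggers,
        n_events=len(events),
        n_unmapped=n_unmapped,
        unmapped_codes=unmapped,
        n_malformed=n_malformed,
    )


def assign_case_control(
    phecode: str,
    occurrences: Occurrences,
    phecode_map: PhecodeMap,
    subjects,
    min_code_count: int = 1,
) -> pd.DataFrame:
    """Partition ``subjects`` into case / excluded / control for one phecode.

    Returns a frame with columns ``subject_id, phecode, status, triggers``
    (triggers comma-joined, empty for non-cases). The three statuses
    partition the cohort exactly.
    """
    definition = phecode_map[phecode]
    cases = occurrences.carriers(phecode, min_code_count)
    related = [
        pc for pc in phecode_map.phecodes if pc != phecode and definition.excludes(pc)
    ]
    excluded: set[str] = set()
    for pc in related:
        excluded |= occurrences.carriers(pc, min_code_count)
    excluded -= cases
    rows = []
    for s in map(str, subjects):
        if s in cases:
            status = CASE
            trig = ",".join(sorted(occurrences.triggers.get((s, phecode), set())))
        elif s in excluded:
            status, trig = EXCLUDED, ""
        else:
            status, trig = CONTROL, ""
        rows.append((s, phecode, status, trig))
    return pd.DataFrame(rows, columns=["subject_id", "phecode", "status", "triggers"])


def assign_all(
    occurrences: Occurrences,
    phecode_map: PhecodeMap,
    subjects,
    min_code_count: int = 1,
) -> pd.DataFrame:
    """Long-format assignments for every phecode in the map."""
    frames = [
        assign_case_control(pc, occurrences, phecode_map, subjects, min_code_count)
        for pc in phecode_map.phecodes
    ]
    return pd.concat(frames, ignore_index=True)


def phenotype_matrix(assignments: pd.DataFrame) -> pd.DataFrame:
    """Wide subjects x phecodes matrix: 1 case, 0 control, NaN excluded."""
    value = assignments["status"].map({CASE: 1.0, CONTROL: 0.0, EXCLUDED: np.nan})
    wide = (
        assignments.assign(value=value)
        .pivot(index="subject_id", columns="phecode", values="value")
    )
    order = sorted(wide.columns, key=float)
    return wide[order]


def eligible_phenotypes(assignments: pd.DataFrame, min_cases: int = 20) -> list[str]:
    """Phecodes with case count STRICTLY greater than ``min_cases``,
    sorted numerically by phecode."""
    cases = assignments[assignments["status"] == CASE]
    counts = cases.groupby("phecode").size()
    keep = counts[counts > min_cases].index.tolist()
    return sorted(keep, key=float)


def combine(phecode_a: str, phecode_b: str, assignments: pd.DataFrame) -> pd.DataFrame:
    """Merge two phenotypes into one subgroup (case = case of either;
    excluded = excluded for either unless a case; control = control for
    both). Used e.g. to pool a disease with a closely related allergy."""
    if phecode_a == phecode_b:
        logger.warning("combine called with identical phecodes %s; no-op", phecode_a)
        return assignments[assignments["phecode"] == phecode_a].copy()
    a = assignments[assignments["phecode"] == phecode_a].set_index("subject_id")
    b = assignments[assignments["phecode"] == phecode_b].set_index("subject_id")
    if a.empty or b.empty:
        raise DefinitionError("both phecodes must be assigned before combining")
    subjects = a.index
    sa, sb = a["status"], b["status"].reindex(subjects)
    status = np.where(
        (sa == CASE) | (sb == CASE),
        CASE,
        np.where((sa == EXCLUDED) | (sb == EXCLUDED), EXCLUDED, CONTROL),
    )
    trig = np.where(
        status == CASE,
        (a["triggers"].fillna("") + "," + b["triggers"].reindex(subjects).fillna("")).str.strip(","),
        "",
    )
    out = pd.DataFrame(
        {
            "subject_id": subjects,
            "phecode": f"{phecode_a}+{phecode_b}",
            "status": status,
            "triggers": trig,
        }
    ).reset_index(drop=True)
    return out


def concept_path_counts(
    assignments: pd.DataFrame, phecode_map: PhecodeMap
) -> pd.DataFrame:
    """Roll phecodes up to the 14 concept-path categories.

    Returns one row per category with the number of distinct phecodes and
    the total case-event frequency (sum of case counts over its phecodes),
    sorted by descending case frequency. Categories present in the map but
    with no phecodes in ``assignments`` report zero.
    """
    cat_of = {pc: d.category for pc, d in phecode_map.definitions.items()}
    cases = assignments[assignments["status"] == CASE]
    per_code = cases.groupby("phecode").size()
    rows = {}
    for pc in assignments["phecode"].unique():
        cat = cat_of.get(pc)
        if cat is None:
            raise DefinitionError(f"phecode {pc!r} has no category in the map")
        n_codes, n_cases = rows.get(cat, (0, 0))
        rows[cat] = (n_codes + 1, n_cases + int(per_code.get(pc, 0)))
    for cat in {d.category for d in phecode_map.definitions.values()}:
        rows.setdefault(cat, (0, 0))
    out = pd.DataFrame(
        [(cat, n, c) for cat, (n, c) in rows.items()],
        columns=["category", "n_phecodes", "case_frequency"],
    )
    return out.sort_values(
        ["case_frequency", "n_phecodes", "category"], ascending=[False, False, True]
    ).reset_index(drop=True)
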