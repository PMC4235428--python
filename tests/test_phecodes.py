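"""Phecode phenotyping: translation, case/control/excluded partition,
eligibility, combination and concept-path rollups."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

from pedphewas import phecodes
from pedphewas.exceptions import DefinitionError, ParameterError
from pedphewas.phecodes import (
    CASE, CONTROL, EXCLUDED,
    PhecodeDefinition, assign_all, assign_case_control, combine,
    concept_path_counts, eligible_phenotypes, phenotype_matrix, translate,
)


def events_frame(pairs):
    return pd.DataFrame(pairs, columns=["subject_id", "icd9"])


class TestTranslate:
    def test_direct_lookup(self, toy_map):
        occ = translate(events_frame([("s1", "714.30")]), toy_map)
        assert occ.carriers("714.1") == {"s1"}

    def test_idempotent_under_repeats(self, toy_map):
        once = translate(events_frame([("s1", "714.30")]), toy_map)
        twice = translate(events_frame([("s1", "714.30")] * 2), toy_map)
        assert once.carriers("714.1") == twice.carriers("714.1")

    def test_hand_enumerated_occurrence_matrix(self, toy_map):
        # four subjects, hand-listed events, hand-computed carrier sets
        ev = events_frame([
            ("s1", "714.30"), ("s1", "555.9"),
            ("s2", "714.31"), ("s2", "714.30"),
            ("s3", "556.9"), ("s3", "493.90"), ("s3", "477.9"),
            ("s4", "477.9"),
        ])
        occ = translate(ev, toy_map)
        assert occ.carriers("714.1") == {"s1", "s2"}
        assert occ.carriers("555.1") == {"s1"}
        assert occ.carriers("555.2") == {"s3"}
        assert occ.carriers("495") == {"s3"}
        assert occ.carriers("476") == {"s3", "s4"}

    def test_unmapped_codes_are_tallied_not_dropped(self, toy_map):
        occ = translate(events_frame([("s1", "999.99"), ("s1", "714.30")]), toy_map)
        assert occ.n_unmapped == 1
        assert occ.unmapped_codes == {"999.99": 1}

    def test_malformed_code_skipped_with_tally(self, toy_map):
        occ = translate(events_frame([("s1", "71X.3"), ("s1", "714.30")]), toy_map)
        assert occ.n_malformed == 1
        assert occ.carriers("714.1") == {"s1"}


class TestAssign:
    def test_case_for_own_phecode(self, toy_map):
        occ = translate(events_frame([("s1", "555.9")]), toy_map)
        out = assign_case_control("555.1", occ, toy_map, ["s1", "s2"])
        assert dict(zip(out.subject_id, out.status)) == {"s1": CASE, "s2": CONTROL}

    def test_related_phecode_is_excluded_from_controls(self, toy_map):
        # ulcerative colitis carrier is neither case nor control for Crohn's
        occ = translate(events_frame([("s1", "556.9")]), toy_map)
        out = assign_case_control("555.1", occ, toy_map, ["s1"])
        assert out.status.tolist() == [EXCLUDED]

    def test_missing_phecode_raises(self, toy_map):
        occ = translate(events_frame([("s1", "555.9")]), toy_map)
        with pytest.raises(DefinitionError):
            assign_case_control("999", occ, toy_map, ["s1"])

    def test_partition_matches_bruteforce_set_arithmetic(self, toy_map, rng):
        codes = ["714.30", "714.31", "555.9", "556.9", "493.90", "477.9"]
        subjects = [f"s{i}" for i in range(10)]
        ev = [
            (s, rng.choice(codes))
            for s in subjects
            for _ in range(rng.integers(0, 4))
        ]
        occ = translate(events_frame(ev), toy_map)
        for pc in toy_map.phecodes:
            out = assign_case_control(pc, occ, toy_map, subjects)
            d = toy_map[pc]
            carriers = {pc2: occ.carriers(pc2) for pc2 in toy_map.phecodes}
            cases = carriers[pc]
            excl = set().union(*(
                carriers[o] for o in toy_map.phecodes
                if o != pc and d.excludes(o)
            )) - cases
            expected = {
                s: (CASE if s in cases else EXCLUDED if s in excl else CONTROL)
                for s in subjects
            }
            assert dict(zip(out.subject_id, out.status)) == expected
            # partition property: one status per subject
            assert len(out) == len(subjects)

    def test_case_rows_carry_triggering_codes(self, toy_map):
        occ = translate(events_frame([("s1", "714.30"), ("s1", "714.31")]), toy_map)
        out = assign_case_control("714.1", occ, toy_map, ["s1"])
        assert out.triggers.iloc[0] == "714.30,714.31"

    @settings(max_examples=25, deadline=None,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(st.data())
    def test_monotone_adding_events_never_demotes(self, toy_map, data):
        codes = ["714.30", "714.31", "555.9", "556.9", "493.90", "477.9"]
        subjects = ["a", "b", "c"]
        base = data.draw(st.lists(
            st.tuples(st.sampled_from(subjects), st.sampled_from(codes)),
            max_size=8))
        extra = data.draw(st.tuples(st.sampled_from(subjects), st.sampled_from(codes)))
        before = assign_all(translate(events_frame(base), toy_map), toy_map, subjects)
        after = assign_all(
            translate(events_frame(base + [extra]), toy_map), toy_map, subjects
        )
        merged = before.merge(after, on=["subject_id", "phecode"], suffixes=("_0", "_1"))
        was_case = merged.status_0 == CASE
        assert (merged.loc[was_case, "status_1"] == CASE).all()


class TestEligibility:
    def _assignments(self, counts):
        rows = []
        for k, n_cases in enumerate(counts):
            pc = f"{100 + k}.1"
            for i in range(max(counts)):
                rows.append((f"s{i}", pc, CASE if i < n_cases else CONTROL, ""))
        return pd.DataFrame(rows, columns=["subject_id", "phecode", "status", "triggers"])

    def test_boundary_at_twenty_cases_is_strict(self):
        asg = self._assignments([20, 21])
        assert eligible_phenotypes(asg, min_cases=20) == ["101.1"]

    def test_hand_counted_fixture(self):
        asg = self._assignments([5, 20, 21, 300])
        assert len(eligible_phenotypes(asg, min_cases=20)) == 2

    def test_min_cases_zero_keeps_any_case(self):
        asg = self._assignments([0, 1, 5])
        assert eligible_phenotypes(asg, min_cases=0) == ["101.1", "102.1"]


class TestCombine:
    def _two_pheno(self, status_a, status_b):
        subjects = [f"s{i}" for i in range(len(status_a))]
        rows = [(s, "100.1", st_, "") for s, st_ in zip(subjects, status_a)]
        rows += [(s, "200.1", st_, "") for s, st_ in zip(subjects, status_b)]
        return pd.DataFrame(rows, columns=["subject_id", "phecode", "status", "triggers"])

    def test_disjoint_union_of_cases(self):
        a = [CASE] * 30 + [CONTROL] * 40 + [CONTROL] * 30
        b = [CONTROL] * 30 + [CASE] * 40 + [CONTROL] * 30
        out = combine("100.1", "200.1", self._two_pheno(a, b))
        assert (out.status == CASE).sum() == 70

    def test_overlapping_cases_inclusion_exclusion(self):
        # 30 and 40 cases with 10 shared -> 60
        a = [CASE] * 30 + [CONTROL] * 50
        b = [CONTROL] * 20 + [CASE] * 40 + [CONTROL] * 20
        out = combine("100.1", "200.1", self._two_pheno(a, b))
        assert (out.status == CASE).sum() == 60

    def test_excluded_for_one_stays_excluded(self):
        out = combine("100.1", "200.1", self._two_pheno([EXCLUDED], [CONTROL]))
        assert out.status.tolist() == [EXCLUDED]

    def test_case_wins_over_exclusion(self):
        out = combine("100.1", "200.1", self._two_pheno([EXCLUDED], [CASE]))
        assert out.status.tolist() == [CASE]

    def test_identical_phecodes_noop(self):
        df = self._two_pheno([CASE], [CONTROL])
        out = combine("100.1", "100.1", df)
        assert out.status.tolist() == [CASE]


class TestConceptPaths:
    def test_hand_built_three_category_fixture(self, toy_map):
        occ = translate(events_frame([
            ("s1", "714.30"), ("s2", "555.9"), ("s3", "493.90"), ("s4", "477.9"),
        ]), toy_map)
        asg = assign_all(occ, toy_map, ["s1", "s2", "s3", "s4"])
        out = concept_path_counts(asg, toy_map)
        table = out.set_index("category")
        assert table.loc["respiratory", "n_phecodes"] == 2
        assert table.loc["respiratory", "case_frequency"] == 2
        assert table.loc["digestive", "n_phecodes"] == 2
        assert table.loc["digestive", "case_frequency"] == 1
        assert table.loc["musculoskeletal", "case_frequency"] == 1
        # sorted descending by case frequency
        assert out.case_frequency.is_monotonic_decreasing

    def test_single_category_single_row(self):
        frame = pd.DataFrame(
            [("111.1", "111", "x", 111, 111.99, "digestive")],
            columns=["icd9", "phecode", "description", "exclude_lo", "exclude_hi", "category"],
        )
        pmap = phecodes.PhecodeMap.from_frame(frame)
        asg = pd.DataFrame(
            [("s1", "111", CASE, "")],
            columns=["subject_id", "phecode", "status", "triggers"],
        )
        out = concept_path_counts(asg, pmap)
        assert len(out) == 1


class TestDefinitions:
    def test_phecode_outside_own_exclusion_range_rejected(self):
        with pytest.raises(ParameterError):
            PhecodeDefinition("700", "x", frozenset({"700.0"}),
                              ((100.0, 200.0),), "digestive")

    def test_inverted_interval_rejected(self):
        with pytest.raises(ParameterError):
            PhecodeDefinition("150", "x", frozenset({"150.0"}),
                              ((200.0, 100.0),), "digestive")

    def test_mini_map_loads_with_14_categories(self, mini_map):
        cats = {d.category for d in mini_map.definitions.values()}
        assert cats == set(phecodes.CATEGORIES)
        assert len(mini_map) >= 35


def test_phenotype_matrix_codes_statuses_as_1_0_nan(toy_map):
    occ = translate(events_frame([("s1", "555.9"), ("s2", "556.9")]), toy_map)
    asg = assign_all(occ, toy_map, ["s1", "s2", "s3"])
    wide = phenotype_matrix(asg)
    col = wide["555.1"]
    assert col["s1"] == 1.0 and col["s3"] == 0.0 and np.isnan(col["s2"])
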