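from datetime import date

import numpy as np
import pytest

from autogvp.clinvar_engine import (
    METHOD_EXCLUDED_ALL,
    ResolutionOptions,
    filter_by_concept_ids,
    is_conflicting_status,
    normalize_significance,
    resolve_conflict,
    select_clinvar_subset,
    stars_from_review_status,
)
from autogvp.io_formats import ClinVarAssertion, SubmissionRecord
from autogvp.variant_model import Call, normalize_variant


def sub(sig, iso_date=None, criteria=True, concepts=("C0027651",), vid=1):
    return SubmissionRecord(
        variation_id=vid,
        significance=sig,
        date_last_evaluated=date.fromisoformat(iso_date) if iso_date else None,
        assertion_criteria_provided=criteria,
        concept_ids=frozenset(concepts),
        submitter="lab",
    )


class TestStars:
    @pytest.mark.parametrize(
        "status, stars",
        [
            ("practice guideline", 4),
            ("reviewed by expert panel", 3),
            ("criteria provided, multiple submitters, no conflicts", 2),
            ("criteria provided, conflicting classifications", 1),
            ("criteria provided, conflicting interpretations", 1),
            ("criteria provided, single submitter", 1),
            ("no assertion criteria provided", 0),
            ("no classification provided", 0),
            ("no assertion provided", 0),
            # underscore dialect as printed in the ClinVar VCF
            ("criteria_provided,_single_submitter", 1),
        ],
    )
    def test_mapping(self, status, stars):
        assert stars_from_review_status(status) == stars

    def test_unknown_status_is_a_hard_error(self):
        with pytest.raises(ValueError, match="unrecognized"):
            stars_from_review_status("criteria provided by a wizard")

    def test_conflict_detection(self):
        assert is_conflicting_status("criteria provided, conflicting classifications")
        assert is_conflicting_status("criteria provided, conflicting interpretations")
        assert not is_conflicting_status("criteria provided, single submitter")


class TestNormalizeSignificance:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("Pathogenic", Call.P),
            ("likely pathogenic", Call.LP),
            ("Uncertain significance", Call.VUS),
            ("Likely benign", Call.LB),
            ("BENIGN", Call.B),
            ("Pathogenic/Likely pathogenic", Call.LP),
            ("Benign/Likely benign", Call.LB),
            ("Affects|risk_factor", None),
            ("association_not_found", None),
            ("drug response", None),
            ("risk factor", None),
            ("Pathogenic, low penetrance", None),
            ("", None),
        ],
    )
    def test_total_mapping(self, raw, expected):
        assert normalize_significance(raw) == expected


class TestConceptFilter:
    def test_intersection_keeps_order(self):
        subs = [
            sub("Pathogenic", concepts=("C1",)),
            sub("Benign", concepts=("C2",)),
            sub("Likely benign", concepts=("C1", "C3")),
        ]
        kept = filter_by_concept_ids(subs, {"C1"})
        assert kept == [subs[0], subs[2]]

    def test_no_match_empty(self):
        assert filter_by_concept_ids([sub("Pathogenic", concepts=("C1",))], {"C9"}) == []

    def test_full_match_identity(self):
        subs = [sub("Pathogenic", concepts=("C1",)), sub("Benign", concepts=("C1",))]
        assert filter_by_concept_ids(subs, {"C1"}) == subs

    def test_empty_id_set_rejected(self):
        with pytest.raises(ValueError):
            filter_by_concept_ids([sub("Pathogenic")], set())


class TestResolveConflict:
    def test_strict_plurality(self):
        r = resolve_conflict(
            [sub("Pathogenic"), sub("Pathogenic"), sub("Uncertain significance")],
            ResolutionOptions(),
        )
        assert (r.call, r.method, r.n_considered) == (Call.P, "majority", 3)

    def test_tie_latest_vs_most_severe(self):
        subs = [sub("Pathogenic", "2019-01-01"), sub("Likely pathogenic", "2021-05-05")]
        latest = resolve_conflict(subs, ResolutionOptions(tiebreak="latest"))
        severe = resolve_conflict(subs, ResolutionOptions(tiebreak="most_severe"))
        assert (latest.call, latest.method, latest.n_considered) == (Call.LP, "latest", 2)
        assert (severe.call, severe.method, severe.n_considered) == (Call.P, "most_severe", 2)

    def test_concept_filter_then_majority(self):
        subs = [
            sub("Pathogenic", "2020-01-01", concepts=("C1",)),
            sub("Likely pathogenic", "2021-01-01", concepts=("C2",)),
            sub("Uncertain significance", "2019-01-01", concepts=("C0027672",)),
        ]
        r = resolve_conflict(
            subs, ResolutionOptions(concept_ids=frozenset({"C0027672"}))
        )
        assert (r.call, r.method, r.n_considered) == (Call.VUS, "majority", 1)

    def test_all_excluded(self):
        subs = [sub("Pathogenic", criteria=False), sub("Benign", criteria=False)]
        r = resolve_conflict(subs, ResolutionOptions())
        assert r.call is None
        assert r.method == METHOD_EXCLUDED_ALL
        assert r.n_considered == 0

    def test_dateless_sorts_below_dated(self):
        subs = [sub("Pathogenic", None), sub("Likely benign", "2015-01-01")]
        r = resolve_conflict(subs, ResolutionOptions(tiebreak="latest"))
        assert r.call == Call.LB

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            resolve_conflict([], ResolutionOptions())

    def test_superset_concept_filter_equivalent_to_none(self):
        rng = np.random.default_rng(3)
        sigs = ["Pathogenic", "Likely pathogenic", "Uncertain significance",
                "Likely benign", "Benign"]
        all_ids = frozenset({"C1", "C2", "C3"})
        for _ in range(200):
            subs = [
                sub(
                    sigs[int(rng.integers(0, 5))],
                    f"20{int(rng.integers(10, 24))}-01-0{int(rng.integers(1, 9))}",
                    concepts=(f"C{int(rng.integers(1, 4))}",),
                )
                for _ in range(int(rng.integers(1, 6)))
            ]
            with_filter = resolve_conflict(subs, ResolutionOptions(concept_ids=all_ids))
            without = resolve_conflict(subs, ResolutionOptions())
            assert with_filter == without


class TestSelectSubset:
    def _assertion(self, sig, status, vid=42):
        return ClinVarAssertion(
            key=normalize_variant("1", 1000 + vid, "A", "T"),
            variation_id=vid,
            significance=sig,
            review_status=status,
            stars=stars_from_review_status(status),
        )

    def test_two_plus_stars_direct_regardless_of_submissions(self):
        a = self._assertion("Pathogenic", "reviewed by expert panel")
        # conflicting submissions present, but stars >= 2 wins outright
        subs = {42: [sub("Benign", vid=42), sub("Likely benign", vid=42)]}
        result = select_clinvar_subset([a], subs, ResolutionOptions())
        assert result[a.key].call == Call.P
        assert result[a.key].resolution_method == "direct"
        assert result[a.key].stars == 3

    def test_zero_star_falls_through(self):
        a = self._assertion("Pathogenic", "no assertion criteria provided")
        notes = {}
        result = select_clinvar_subset([a], {}, ResolutionOptions(), fallthrough_notes=notes)
        assert a.key not in result
        assert notes[a.key] == "clinvar_zero_star"

    def test_conflict_with_all_excluded_falls_through(self):
        a = self._assertion(
            "Conflicting classifications of pathogenicity",
            "criteria provided, conflicting classifications",
        )
        subs = {42: [sub("Pathogenic", criteria=False, vid=42)]}
        notes = {}
        result = select_clinvar_subset([a], subs, ResolutionOptions(), fallthrough_notes=notes)
        assert a.key not in result
        assert notes[a.key] == "conflict_excluded_all"

    def test_calls_always_on_five_level_scale(self):
        assertions = [
            self._assertion("Pathogenic", "practice guideline", vid=1),
            self._assertion("Benign/Likely benign", TWO_STAR := "criteria provided, multiple submitters, no conflicts", vid=2),
            self._assertion("drug response", TWO_STAR, vid=3),
        ]
        result = select_clinvar_subset(assertions, {}, ResolutionOptions())
        assert all(fc.call in set(Call) for fc in result.values())
        assert len(result) == 2  # drug response is not classifiable
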