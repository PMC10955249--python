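from types import SimpleNamespace

import numpy as np
import pytest

from acmg_oracle import oracle_call
from autogvp.acmg_engine import (
    CriteriaVector,
    EvidenceCounts,
    EvidenceParseError,
    Strength,
    apply_pvs1_strength,
    combine,
    counts_from_vector,
    intervar_modified_call,
    parse_intervar_evidence,
    strip_pp5_bp6,
)
from autogvp.fixtures import random_criteria_vector
from autogvp.variant_model import Call

CV = CriteriaVector.build


def ap(strength: Strength):
    """Minimal stand-in for an AutoPVS1 record."""
    return SimpleNamespace(strength=strength)


class TestParseEvidence:
    def test_full_cell(self):
        cell = (
            "InterVar: Pathogenic PVS1=1 PS=[1, 0, 0, 0, 0] "
            "PM=[0, 0, 0, 0, 0, 0, 0] PP=[0, 0, 0, 0, 0, 0] BA1=0 "
            "BS=[0, 0, 0, 0, 0] BP=[0, 0, 0, 0, 0, 0, 0, 0]"
        )
        call, cv = parse_intervar_evidence(cell)
        assert call == "Pathogenic"
        assert cv == CV(pvs1=Strength.VERY_STRONG, ps=[1])

    def test_positional_flags(self):
        cell = (
            "InterVar: Uncertain significance PVS1=1 PS=[0, 0, 0, 0, 0] "
            "PM=[0, 1, 0, 0, 0, 0, 0] PP=[0, 0, 0, 0, 1, 0] BA1=0 "
            "BS=[0, 0, 0, 0, 0] BP=[0, 0, 0, 0, 0, 0, 0, 0]"
        )
        call, cv = parse_intervar_evidence(cell)
        assert call == "Uncertain significance"
        assert cv.pvs1 is Strength.VERY_STRONG
        assert cv.pm[1]  # PM2
        assert cv.pp[4]  # PP5
        assert not any(cv.ps) and not any(cv.bs) and not any(cv.bp)

    def test_ba1_only(self):
        cell = (
            "InterVar: Benign PVS1=0 PS=[0, 0, 0, 0] PM=[0, 0, 0, 0, 0, 0] "
            "PP=[0, 0, 0, 0, 0] BA1=1 BS=[0, 0, 0, 0] BP=[0, 0, 0, 0, 0, 0, 0]"
        )
        _, cv = parse_intervar_evidence(cell)
        assert cv.ba1 and cv.pvs1 is Strength.UNMET
        assert not any(cv.ps + cv.pm + cv.pp + cv.bs + cv.bp)

    def test_all_zero_is_empty_vector(self):
        cell = (
            "InterVar: Uncertain significance PVS1=0 PS=[0, 0, 0, 0] "
            "PM=[0, 0, 0, 0, 0, 0] PP=[0, 0, 0, 0, 0] BA1=0 BS=[0, 0, 0, 0] "
            "BP=[0, 0, 0, 0, 0, 0, 0]"
        )
        _, cv = parse_intervar_evidence(cell)
        assert cv.is_empty()

    def test_upgraded_values_count_as_set(self):
        cell = (
            "InterVar: Pathogenic PVS1=0 PS=[2, 0, 0, 0] PM=[0, 0, 0, 0, 0, 0] "
            "PP=[0, 0, 0, 0, 0] BA1=0 BS=[0, 0, 0, 0] BP=[0, 0, 0, 0, 0, 0, 0]"
        )
        _, cv = parse_intervar_evidence(cell)
        assert cv.ps[0]

    def test_malformed_cell_echoed(self):
        with pytest.raises(EvidenceParseError, match="not an evidence cell"):
            parse_intervar_evidence("not an evidence cell")


class TestModifications:
    def test_strip_clears_only_pp5_bp6(self):
        cv = CV(pp=[5])
        assert strip_pp5_bp6(cv).is_empty()
        cv = CV(bp=[4, 6])
        stripped = strip_pp5_bp6(cv)
        assert stripped == CV(bp=[4])

    def test_strip_idempotent(self):
        cv = CV(pvs1=Strength.VERY_STRONG, ps=[1], pp=[1, 5], bp=[6, 7])
        once = strip_pp5_bp6(cv)
        assert strip_pp5_bp6(once) == once

    def test_pvs1_demoted_by_autopvs1(self):
        cv = CV(pvs1=Strength.VERY_STRONG)
        assert apply_pvs1_strength(cv, ap(Strength.MODERATE)).pvs1 is Strength.MODERATE
        assert apply_pvs1_strength(cv, ap(Strength.UNMET)).pvs1 is Strength.UNMET

    def test_pvs1_never_upgraded(self):
        cv = CV()  # InterVar did not flag PVS1
        assert apply_pvs1_strength(cv, ap(Strength.STRONG)) == cv

    def test_missing_record_keeps_full_strength(self, caplog):
        cv = CV(pvs1=Strength.VERY_STRONG)
        with caplog.at_level("WARNING"):
            assert apply_pvs1_strength(cv, None) == cv
        assert any("AutoPVS1" in r.message for r in caplog.records)

    def test_strip_and_adjust_commute(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            cv = random_criteria_vector(rng, p=0.3)
            rec = ap(list(Strength)[int(rng.integers(0, 5))])
            assert strip_pp5_bp6(apply_pvs1_strength(cv, rec)) == apply_pvs1_strength(
                strip_pp5_bp6(cv), rec
            )


class TestCombine:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            (dict(very_strong=1, strong=1), Call.P),
            (dict(very_strong=1, moderate=1), Call.LP),
            (dict(), Call.VUS),
            # PVS1 downgraded to Supporting alongside one Moderate
            (dict(moderate=1, supporting=1), Call.VUS),
            # contradictory: stand-alone benign vs a pathogenic rule
            (dict(standalone_benign=1, very_strong=1, strong=1), Call.VUS),
            (dict(strong=2), Call.P),
            (dict(strong=1, moderate=2), Call.LP),
            (dict(moderate=3), Call.LP),
            (dict(standalone_benign=1), Call.B),
            (dict(strong_benign=2), Call.B),
            (dict(strong_benign=1, supporting_benign=1), Call.LB),
            (dict(supporting_benign=2), Call.LB),
        ],
    )
    def test_rule_table_examples(self, counts, expected):
        assert combine(EvidenceCounts(**counts)) == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            EvidenceCounts(strong=-1)

    def test_spot_agreement_with_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(500):
            t = [int(rng.integers(0, hi + 1)) for hi in (1, 3, 4, 5, 1, 3, 4)]
            counts = EvidenceCounts(*t)
            assert combine(counts).value == oracle_call(*t)


class TestModifiedCall:
    def test_pp5_removal_demotes_lone_pvs1(self):
        # raw InterVar: P from PVS1 + PP5; after removal only VeryStrong -> VUS
        final = intervar_modified_call(
            CV(pvs1=Strength.VERY_STRONG, pp=[5]), ap(Strength.VERY_STRONG)
        )
        assert final.call == Call.VUS
        assert final.source == "InterVar"

    def test_strong_plus_two_moderate_is_lp(self):
        final = intervar_modified_call(CV(ps=[1], pm=[1, 2]), None)
        assert final.call == Call.LP

    def test_empty_vector_is_vus(self):
        final = intervar_modified_call(CV(), None)
        assert final.call == Call.VUS
        assert "no_rule_fired" in final.notes

    def test_counts_bucketing_by_strength(self):
        for strength, bucket in [
            (Strength.STRONG, "strong"),
            (Strength.MODERATE, "moderate"),
            (Strength.SUPPORTING, "supporting"),
        ]:
            counts = counts_from_vector(CV(pvs1=strength))
            assert getattr(counts, bucket) == 1
            assert counts.very_strong == 0
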