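"""Coherent miniature input bundles for testing the whole pipeline offline.

Each :class:`Scenario` describes one variant: its ClinVar state (aggregate
significance, review status, individual submissions), its InterVar evidence
vector, its AutoPVS1 strength, and the final call the decision tree must
produce - derived by hand when the catalog was written and recorded next to
each scenario, never computed by the engines under test.

:func:`generate_bundle` materializes a scenario list as the seven input files
the pipeline consumes (VEP VCF, ANNOVAR multianno, InterVar, AutoPVS1, and
the ClinVar VCF / variant_summary / submission_summary trio), plus a
Concept-ID list and the golden ``expected_calls.tsv``.  Generation is fully
deterministic in the seed (gzip members are written with a zeroed mtime), so
repeated runs are byte-identical.

The default catalog covers: direct retention at 2-4 stars, 1-star single
submitter, conflict resolution by majority / latest / most-severe /
Concept-ID filtering, unresolvable conflicts, zero-star and non-standard
ClinVar states, every InterVar outcome for ClinVar-absent variants, the
PP5-removal demotion, the PVS1 strength-downgrade ladder, transcript
selection, indel key joining, and PASS/user filtering.

What the generator does *not* emulate: realistic allele-frequency spectra,
sequencing artifacts, multi-gene loci, or ClinVar-scale file sizes.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .acmg_engine import CriteriaVector, Strength
from .variant_model import Call

# Significance strings as ClinVar prints them.
P, LP, VUS, LB, B = (
    "Pathogenic",
    "Likely pathogenic",
    "Uncertain significance",
    "Likely benign",
    "Benign",
)

CONFLICT_STATUS = "criteria provided, conflicting classifications"
CONFLICT_AGG = "Conflicting classifications of pathogenicity"
TWO_STAR = "criteria provided, multiple submitters, no conflicts"
SINGLE = "criteria provided, single submitter"
NO_CRITERIA = "no assertion criteria provided"

#: Concept IDs shipped in the bundle's concept_ids.txt (a disease-of-interest
#: list); submissions elsewhere in the catalog use CONCEPT_DEFAULT, which is
#: on the list, so the filter is a no-op outside the concept scenarios.
CONCEPT_LIST = ("C0027651", "C0006826")
CONCEPT_DEFAULT = "C0027651"

CV = CriteriaVector.build


@dataclass(frozen=True)
class Submission:
    """One synthetic submitter assertion."""

    significance: str
    date: Optional[str] = None  # ISO yyyy-mm-dd
    criteria: bool = True
    concepts: Tuple[str, ...] = (CONCEPT_DEFAULT,)


@dataclass(frozen=True)
class Scenario:
    """One variant with its inputs and hand-traced expected outcome.

    ``expected_call_latest`` / ``expected_call_most_severe`` are the calls
    under the two tiebreak settings with the Concept-ID list supplied;
    ``expected_call_no_concept`` is the latest-tiebreak call without the
    list.  Unset expectations default to the latest-with-list value.
    """

    label: str
    clinvar_state: str  # absent|stars0|stars1_single|stars1_conflict|stars2plus|non_standard
    expected_call_latest: Call
    expected_source: str
    aggregate_significance: str = ""
    review_status: str = ""
    submissions: Tuple[Submission, ...] = ()
    intervar: Optional[CriteriaVector] = None
    intervar_call: str = ""
    autopvs1_strength: Optional[Strength] = None
    n_transcripts: int = 1
    autopvs1_tx_index: int = 0
    canonical_index: int = 0
    filter_status: str = "PASS"
    dp: int = 40
    indel: Optional[str] = None  # None | "ins" | "del"
    grch37_decoy: bool = False
    expected_call_most_severe: Optional[Call] = None
    expected_call_no_concept: Optional[Call] = None
    expected_source_no_concept: Optional[str] = None
    in_output: bool = True

    def finalized(self) -> "Scenario":
        updates = {}
        if self.expected_call_most_severe is None:
            updates["expected_call_most_severe"] = self.expected_call_latest
        if self.expected_call_no_concept is None:
            updates["expected_call_no_concept"] = self.expected_call_latest
        if self.expected_source_no_concept is None:
            updates["expected_source_no_concept"] = self.expected_source
        return replace(self, **updates) if updates else self


# A neutral InterVar row (PM2 only -> VUS) for variants whose call must come
# from ClinVar: if the hierarchy is broken the golden comparison sees VUS.
_NEUTRAL_IV = CV(pm=[2])
_NEUTRAL_IV_CALL = VUS


def _clinvar_scenario(
    label: str,
    aggregate: str,
    review: str,
    state: str,
    expected: Call,
    subs: Sequence[Submission],
    **kw,
) -> Scenario:
    return Scenario(
        label=label,
        clinvar_state=state,
        aggregate_significance=aggregate,
        review_status=review,
        submissions=tuple(subs),
        intervar=kw.pop("intervar", _NEUTRAL_IV),
        intervar_call=kw.pop("intervar_call", _NEUTRAL_IV_CALL),
        expected_call_latest=expected,
        expected_source=kw.pop("expected_source", "ClinVar"),
        **kw,
    )


def default_catalog() -> List[Scenario]:
    """The full branch-coverage catalog (hand-traced expectations)."""
    s: List[Scenario] = []

    # --- Direct retention: >= 2 stars, standard aggregate ---------------------
    for label, agg, review, call in [
        ("direct_p_4star", P, "practice guideline", Call.P),
        ("direct_lp_3star", LP, "reviewed by expert panel", Call.LP),
        ("direct_vus_2star", VUS, TWO_STAR, Call.VUS),
        ("direct_lb_2star", LB, TWO_STAR, Call.LB),
        ("direct_b_2star", B, TWO_STAR, Call.B),
        # Combined aggregates map to the weaker assertion.
        ("direct_plp_combined_2star", "Pathogenic/Likely pathogenic", TWO_STAR, Call.LP),
        ("direct_blb_combined_2star", "Benign/Likely benign", TWO_STAR, Call.LB),
    ]:
        s.append(
            _clinvar_scenario(
                label, agg, review, "stars2plus", call,
                [Submission(agg.split("/")[0], "2021-03-01"),
                 Submission(agg.split("/")[0], "2022-07-15")],
                grch37_decoy=(len(s) % 3 == 0),
            )
        )

    # --- 1 star, single criteria-based submitter ------------------------------
    for label, agg, call in [
        ("single_1star_p", P, Call.P),
        ("single_1star_lp", LP, Call.LP),
        ("single_1star_vus", VUS, Call.VUS),
        ("single_1star_lb", LB, Call.LB),
        ("single_1star_b", B, Call.B),
    ]:
        s.append(
            _clinvar_scenario(
                label, agg, SINGLE, "stars1_single", call,
                [Submission(agg, "2020-05-05")],
            )
        )
    # 1-star single submitter with a non-standard call -> no ClinVar
    # classification; neutral InterVar evidence decides (PM2 -> VUS).
    s.append(
        _clinvar_scenario(
            "single_1star_nonstd", "drug response", SINGLE, "non_standard",
            Call.VUS, [Submission("drug response", "2020-05-05")],
            expected_source="InterVar",
        )
    )

    # --- 1-star conflicts: strict-plurality majority ---------------------------
    for label, subs, call in [
        ("conflict_majority_p", [Submission(P, "2020-01-01"), Submission(P, "2021-01-01"), Submission(LP, "2022-01-01")], Call.P),
        ("conflict_majority_lp", [Submission(LP, "2020-01-01"), Submission(LP, "2021-01-01"), Submission(P, "2022-01-01")], Call.LP),
        ("conflict_majority_vus", [Submission(VUS, "2020-01-01"), Submission(VUS, "2021-01-01"), Submission(B, "2022-01-01")], Call.VUS),
        ("conflict_majority_lb", [Submission(LB, "2020-01-01"), Submission(LB, "2021-01-01"), Submission(VUS, "2022-01-01")], Call.LB),
        ("conflict_majority_b", [Submission(B, "2020-01-01"), Submission(B, "2021-01-01"), Submission(P, "2022-01-01")], Call.B),
    ]:
        s.append(
            _clinvar_scenario(label, CONFLICT_AGG, CONFLICT_STATUS, "stars1_conflict", call, subs)
        )

    # --- 1-star conflicts: tied tallies, resolved by the tiebreak --------------
    # Hand trace: a 1-1 tie falls through to the tiebreak; "latest" takes the
    # newest date, "most_severe" the severity maximum of the candidates.
    for label, subs, latest_call, severe_call in [
        ("conflict_latest_p", [Submission(P, "2022-01-05"), Submission(LB, "2020-03-01")], Call.P, Call.P),
        ("conflict_latest_lp", [Submission(LP, "2023-03-03"), Submission(P, "2018-01-01")], Call.LP, Call.P),
        ("conflict_latest_vus", [Submission(VUS, "2023-01-01"), Submission(P, "2019-06-01")], Call.VUS, Call.P),
        ("conflict_latest_lb", [Submission(LB, "2022-06-01"), Submission(VUS, "2020-02-02")], Call.LB, Call.VUS),
        ("conflict_latest_b", [Submission(B, "2024-01-01"), Submission(LB, "2021-01-01")], Call.B, Call.LB),
        ("conflict_severe_p", [Submission(P, "2018-05-05"), Submission(VUS, "2023-04-04")], Call.VUS, Call.P),
        ("conflict_severe_lp", [Submission(LP, "2019-01-01"), Submission(LB, "2022-01-01")], Call.LB, Call.LP),
        ("conflict_severe_vus", [Submission(VUS, "2019-09-09"), Submission(LB, "2023-11-11")], Call.LB, Call.VUS),
        ("conflict_severe_lb", [Submission(LB, "2019-02-02"), Submission(B, "2023-08-08")], Call.B, Call.LB),
    ]:
        s.append(
            _clinvar_scenario(
                label, CONFLICT_AGG, CONFLICT_STATUS, "stars1_conflict",
                latest_call, subs, expected_call_most_severe=severe_call,
            )
        )

    # All submissions dateless: "latest" falls back to severity (P over LB).
    s.append(
        _clinvar_scenario(
            "conflict_dateless", CONFLICT_AGG, CONFLICT_STATUS, "stars1_conflict",
            Call.P, [Submission(P, None), Submission(LB, None)],
        )
    )
    # Exact date tie: broken by severity among the tied submissions.
    s.append(
        _clinvar_scenario(
            "conflict_date_tie", CONFLICT_AGG, CONFLICT_STATUS, "stars1_conflict",
            Call.P, [Submission(P, "2021-01-01"), Submission(LB, "2021-01-01")],
        )
    )
    # Non-standard votes are dropped before tallying: only the P remains.
    s.append(
        _clinvar_scenario(
            "conflict_nonstd_votes", CONFLICT_AGG, CONFLICT_STATUS, "stars1_conflict",
            Call.P,
            [Submission(P, "2020-01-01"),
             Submission("drug response", "2021-01-01"),
             Submission("risk factor", "2022-01-01")],
        )
    )
    # No-criteria submissions are excluded first: [LB, VUS] remain, 1-1 tie,
    # latest -> VUS (2021); most_severe -> VUS as well.
    s.append(
        _clinvar_scenario(
            "conflict_mixed_criteria", CONFLICT_AGG, CONFLICT_STATUS, "stars1_conflict",
            Call.VUS,
            [Submission(P, "2015-01-01", criteria=False),
             Submission(LB, "2020-01-01"),
             Submission(VUS, "2021-01-01")],
        )
    )
    # Every submission excluded -> conflict unresolved -> InterVar decides.
    s.append(
        _clinvar_scenario(
            "conflict_excluded_all_p", CONFLICT_AGG, CONFLICT_STATUS, "stars1_conflict",
            Call.P,
            [Submission(P, "2020-01-01", criteria=False),
             Submission(LP, "2021-01-01", criteria=False)],
            intervar=CV(ps=[1, 2]), intervar_call=P,
            expected_source="InterVar",
        )
    )
    s.append(
        _clinvar_scenario(
            "conflict_excluded_all_lb", CONFLICT_AGG, CONFLICT_STATUS, "stars1_conflict",
            Call.LB,
            [Submission(VUS, "2019-01-01", criteria=False),
             Submission(VUS, "2020-01-01", criteria=False)],
            intervar=CV(bp=[4, 7]), intervar_call=LB,
            expected_source="InterVar",
        )
    )

    # --- Concept-ID filtering ---------------------------------------------------
    # With the list: only the submission tagged with a listed Concept ID
    # survives, and is its own majority.  Without the list: 1-1-1 tie ->
    # latest (LP, 2021).
    s.append(
        _clinvar_scenario(
            "concept_single_vus", CONFLICT_AGG, CONFLICT_STATUS, "stars1_conflict",
            Call.VUS,
            [Submission(P, "2020-04-04", concepts=("C9999001",)),
             Submission(LP, "2021-04-04", concepts=("C9998002",)),
             Submission(VUS, "2019-04-04", concepts=(CONCEPT_DEFAULT,))],
            expected_call_no_concept=Call.LP,
        )
    )
    # With the list: [P]; without: majority B (2 of 3).
    s.append(
        _clinvar_scenario(
            "concept_p_vs_b", CONFLICT_AGG, CONFLICT_STATUS, "stars1_conflict",
            Call.P,
            [Submission(P, "2019-01-01", concepts=("C0006826",)),
             Submission(B, "2023-01-01", concepts=("C9999001",)),
             Submission(B, "2022-01-01", concepts=("C9998002",))],
            expected_call_no_concept=Call.B,
        )
    )
    # With the list: [LB]; without: 1-1 tie -> latest P (2024).
    s.append(
        _clinvar_scenario(
            "concept_lb_overrides_new_p", CONFLICT_AGG, CONFLICT_STATUS, "stars1_conflict",
            Call.LB,
            [Submission(LB, "2018-01-01", concepts=(CONCEPT_DEFAULT,)),
             Submission(P, "2024-01-01", concepts=("C9999001",))],
            expected_call_no_concept=Call.P,
        )
    )
    # With the list: LP majority (2-0); without: 2-2 tie -> latest P (2022).
    s.append(
        _clinvar_scenario(
            "concept_majority_lp", CONFLICT_AGG, CONFLICT_STATUS, "stars1_conflict",
            Call.LP,
            [Submission(LP, "2019-01-01", concepts=("C0006826",)),
             Submission(LP, "2020-01-01", concepts=(CONCEPT_DEFAULT,)),
             Submission(P, "2021-01-01", concepts=("C9999001",)),
             Submission(P, "2022-01-01", concepts=("C9998002",))],
            expected_call_no_concept=Call.P,
        )
    )
    # With the list nothing survives the filter -> unresolved -> InterVar VUS;
    # without the list: 1-1 tie -> latest LP (2021), sourced from ClinVar.
    s.append(
        _clinvar_scenario(
            "concept_excluded", CONFLICT_AGG, CONFLICT_STATUS, "stars1_conflict",
            Call.VUS,
            [Submission(P, "2020-01-01", concepts=("C9999001",)),
             Submission(LP, "2021-01-01", concepts=("C9998002",))],
            expected_source="InterVar",
            expected_call_no_concept=Call.LP,
            expected_source_no_concept="ClinVar",
        )
    )

    # --- Zero stars / non-standard aggregates -> InterVar ----------------------
    s.append(
        _clinvar_scenario(
            "zero_star_p", P, NO_CRITERIA, "stars0", Call.VUS,
            [Submission(P, "2015-01-01", criteria=False)],
            expected_source="InterVar",
        )
    )
    s.append(
        _clinvar_scenario(
            "zero_star_no_classification", VUS, "no classification provided",
            "stars0", Call.B,
            [Submission(VUS, None, criteria=False)],
            intervar=CV(ba1=True), intervar_call=B,
            expected_source="InterVar",
        )
    )
    s.append(
        _clinvar_scenario(
            "nonstd_agg_risk_factor", "risk factor", TWO_STAR, "non_standard",
            Call.LP, [Submission("risk factor", "2019-01-01")],
            intervar=CV(ps=[1], pm=[1, 2]), intervar_call=LP,
            expected_source="InterVar",
        )
    )
    s.append(
        _clinvar_scenario(
            "nonstd_agg_affects", "Affects|risk_factor", TWO_STAR, "non_standard",
            Call.B, [Submission("Affects", "2019-01-01")],
            intervar=CV(bs=[1, 2]), intervar_call=B,
            expected_source="InterVar",
        )
    )

    # --- Not in ClinVar: one scenario per modified-InterVar outcome ------------
    for label, cv, iv_call, strength, call in [
        # PVS1 VeryStrong + PS1 -> P (AutoPVS1 confirms VeryStrong)
        ("novel_p", CV(pvs1=Strength.VERY_STRONG, ps=[1]), P, Strength.VERY_STRONG, Call.P),
        # 1 Strong + 2 Moderate -> LP
        ("novel_lp", CV(ps=[1], pm=[1, 2]), LP, None, Call.LP),
        # 1 Moderate + 1 Supporting -> no rule -> VUS
        ("novel_vus", CV(pm=[2], pp=[3]), VUS, None, Call.VUS),
        # 1 Strong benign + 1 Supporting benign -> LB
        ("novel_lb", CV(bs=[1], bp=[4]), LB, None, Call.LB),
        # 2 Strong benign -> B
        ("novel_b", CV(bs=[1, 2]), B, None, Call.B),
    ]:
        s.append(
            Scenario(
                label=label, clinvar_state="absent",
                intervar=cv, intervar_call=iv_call,
                autopvs1_strength=strength,
                expected_call_latest=call, expected_source="InterVar",
            )
        )

    # --- Qualitative regressions ------------------------------------------------
    # Raw InterVar called P from PVS1 + PP5 alone; PP5 removal leaves a lone
    # VeryStrong criterion -> VUS.
    s.append(
        Scenario(
            label="pp5_demotion", clinvar_state="absent",
            intervar=CV(pvs1=Strength.VERY_STRONG, pp=[5]), intervar_call=P,
            autopvs1_strength=Strength.VERY_STRONG,
            expected_call_latest=Call.VUS, expected_source="InterVar",
        )
    )
    # PVS1 downgrade ladder with fixed co-evidence PM2: VeryStrong -> LP,
    # Strong -> LP (1S+1M), Moderate -> VUS (2M), Supporting -> VUS (1M+1P),
    # Unmet -> VUS (1M).  The call sequence is monotone non-increasing.
    for strength, call in [
        (Strength.VERY_STRONG, Call.LP),
        (Strength.STRONG, Call.LP),
        (Strength.MODERATE, Call.VUS),
        (Strength.SUPPORTING, Call.VUS),
        (Strength.UNMET, Call.VUS),
    ]:
        s.append(
            Scenario(
                label=f"pvs1_ladder_{strength.value.lower()}",
                clinvar_state="absent",
                intervar=CV(pvs1=Strength.VERY_STRONG, pm=[2]), intervar_call=LP,
                autopvs1_strength=strength,
                expected_call_latest=call, expected_source="InterVar",
            )
        )
    # PVS1 flagged but the variant is absent from the AutoPVS1 table: the
    # full-strength flag is kept (with a warning) -> P via VS + 1 Strong.
    s.append(
        Scenario(
            label="pvs1_no_autopvs1_record", clinvar_state="absent",
            intervar=CV(pvs1=Strength.VERY_STRONG, ps=[1]), intervar_call=P,
            autopvs1_strength=None,
            expected_call_latest=Call.P, expected_source="InterVar",
        )
    )

    # --- Pipeline edges ----------------------------------------------------------
    # No evidence anywhere: emitted as VUS with a no_evidence note.
    s.append(
        Scenario(
            label="no_intervar_row", clinvar_state="absent",
            intervar=None, intervar_call="",
            expected_call_latest=Call.VUS, expected_source="InterVar",
        )
    )
    # Transcript selection: AutoPVS1 names the 2nd of 3 CSQ entries (with a
    # mismatching version suffix); the ClinVar 2-star P is untouched.
    s.append(
        _clinvar_scenario(
            "multi_transcript_pick", P, TWO_STAR, "stars2plus", Call.P,
            [Submission(P, "2020-10-10"), Submission(P, "2021-11-11")],
            n_transcripts=3, autopvs1_tx_index=1,
            autopvs1_strength=Strength.UNMET,
        )
    )
    # No AutoPVS1 record: the CANONICAL CSQ entry is chosen.
    s.append(
        _clinvar_scenario(
            "canonical_fallback", LB, TWO_STAR, "stars2plus", Call.LB,
            [Submission(LB, "2019-03-03"), Submission(LB, "2020-04-04")],
            n_transcripts=2, canonical_index=1,
        )
    )
    # Indels exercise the ANNOVAR-coordinate join and ClinVar key matching.
    s.append(
        _clinvar_scenario(
            "indel_ins_p", P, TWO_STAR, "stars2plus", Call.P,
            [Submission(P, "2022-02-02"), Submission(P, "2023-03-03")],
            indel="ins",
        )
    )
    s.append(
        _clinvar_scenario(
            "indel_del_lb", LB, TWO_STAR, "stars2plus", Call.LB,
            [Submission(LB, "2021-06-06"), Submission(LB, "2022-07-07")],
            indel="del",
        )
    )
    # Low depth but PASS: kept by the default run, dropped by a DP>=10 filter.
    s.append(
        _clinvar_scenario(
            "lowdp_2star_p", P, TWO_STAR, "stars2plus", Call.P,
            [Submission(P, "2020-01-01"), Submission(P, "2021-01-01")],
            dp=5,
        )
    )
    # Non-PASS records never reach classification.
    s.append(
        _clinvar_scenario(
            "fail_filter_lowgq", P, TWO_STAR, "stars2plus", Call.P,
            [Submission(P, "2020-01-01"), Submission(P, "2021-01-01")],
            filter_status="lowGQ", in_output=False,
        )
    )
    s.append(
        Scenario(
            label="fail_filter_lowqual", clinvar_state="absent",
            intervar=_NEUTRAL_IV, intervar_call=_NEUTRAL_IV_CALL,
            filter_status="LowQual", in_output=False,
            expected_call_latest=Call.VUS, expected_source="InterVar",
        )
    )

    labels = [sc.label for sc in s]
    if len(set(labels)) != len(labels):
        raise ValueError("scenario labels must be unique")
    return [sc.finalized() for sc in s]


def minimal_catalog() -> List[Scenario]:
    """A handful of scenarios for quick smoke runs."""
    keep = {
        "direct_p_4star", "single_1star_lp", "conflict_majority_vus",
        "zero_star_p", "novel_lb", "pp5_demotion",
    }
    return [sc for sc in default_catalog() if sc.label in keep]


# --- Naming helpers (shared with tests) ----------------------------------------


def gene_name(i: int) -> str:
    return f"GENE{i:03d}"


def transcript_name(i: int, j: int, version: Optional[int] = None) -> str:
    base = f"ENST{i * 10 + j:08d}"
    return base if version is None else f"{base}.{version}"


_CONTIGS = ["1", "2", "3", "7", "11", "17", "X"]

CSQ_FIELDS = ["Allele", "Consequence", "IMPACT", "SYMBOL", "Feature", "CANONICAL", "PICK"]


def _variant_for(i: int, sc: Scenario, rng: np.random.Generator) -> Tuple[str, int, str, str]:
    contig = _CONTIGS[i % len(_CONTIGS)]
    pos = 1_000_000 + i * 1_000 + int(rng.integers(0, 999))
    bases = "ACGT"
    anchor = bases[int(rng.integers(0, 4))]
    if sc.indel == "ins":
        return contig, pos, anchor, anchor + "T"
    if sc.indel == "del":
        return contig, pos, anchor + "A", anchor
    alt = bases[int(rng.integers(0, 4))]
    while alt == anchor:
        alt = bases[int(rng.integers(0, 4))]
    return contig, pos, anchor, alt


def _evidence_cell(call_str: str, cv: CriteriaVector) -> str:
    """Serialize a criteria vector in InterVar's printed layout.

    Each bracketed family carries one surplus reserved slot, as recent
    InterVar versions do.
    """

    def fmt(flags: Sequence[bool]) -> str:
        return "[" + ", ".join(str(int(f)) for f in list(flags) + [False]) + "]"

    pvs1 = 1 if cv.pvs1 is Strength.VERY_STRONG else 0
    return (
        f"InterVar: {call_str} PVS1={pvs1} PS={fmt(cv.ps)} PM={fmt(cv.pm)} "
        f"PP={fmt(cv.pp)} BA1={int(cv.ba1)} BS={fmt(cv.bs)} BP={fmt(cv.bp)}"
    )


def _iso_to_clinvar_date(iso: Optional[str]) -> str:
    if iso is None:
        return "-"
    return datetime.strptime(iso, "%Y-%m-%d").strftime("%b %d, %Y")


def _annovar_rep(pos: int, ref: str, alt: str) -> Tuple[int, int, str, str]:
    if len(ref) == 1 and len(alt) == 1:
        return pos, pos, ref, alt
    if len(ref) == 1 and alt.startswith(ref):
        return pos, pos, "-", alt[1:]
    if len(alt) == 1 and ref.startswith(alt):
        return pos + 1, pos + len(ref) - 1, ref[1:], "-"
    return pos, pos + len(ref) - 1, ref, alt


def _write_gz(path: str, text: str) -> None:
    # fixed mtime and empty internal name -> byte-identical across runs
    with open(path, "wb") as raw:
        with gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0) as gz:
            gz.write(text.encode("utf-8"))


def generate_bundle(
    scenarios: Sequence[Scenario], seed: int, out_dir: str, prefix: str = "test"
) -> Dict[str, str]:
    """Write the full input bundle plus the golden table; returns the paths."""
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    scenarios = [sc.finalized() for sc in scenarios]
    variants = [_variant_for(i, sc, rng) for i, sc in enumerate(scenarios)]

    paths = {
        "vep_vcf": os.path.join(out_dir, f"{prefix}_VEP.vcf"),
        "multianno": os.path.join(out_dir, f"{prefix}_hg38_multianno.txt"),
        "intervar": os.path.join(out_dir, f"{prefix}_multianno.txt.intervar"),
        "autopvs1": os.path.join(out_dir, f"{prefix}_autopvs1.txt"),
        "clinvar_vcf": os.path.join(out_dir, "clinvar.vcf.gz"),
        "variant_summary": os.path.join(out_dir, "variant_summary.txt.gz"),
        "submission_summary": os.path.join(out_dir, "submission_summary.txt.gz"),
        "concept_ids": os.path.join(out_dir, "concept_ids.txt"),
        "expected_calls": os.path.join(out_dir, "expected_calls.tsv"),
    }

    # --- VEP VCF ---
    used_contigs = []
    for contig, _, _, _ in variants:
        if contig not in used_contigs:
            used_contigs.append(contig)
    vcf_lines = [
        "##fileformat=VCFv4.2",
        '##FILTER=<ID=PASS,Description="All filters passed">',
        '##FILTER=<ID=lowGQ,Description="Low genotype quality">',
        '##FILTER=<ID=LowQual,Description="Low variant quality">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Combined depth">',
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">',
        '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations from Ensembl VEP. Format: '
        + "|".join(CSQ_FIELDS)
        + '">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    for contig in used_contigs:
        vcf_lines.append(f"##contig=<ID=chr{contig}>")
    vcf_lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample01")
    for i, (sc, (contig, pos, ref, alt)) in enumerate(zip(scenarios, variants)):
        csq_entries = []
        for j in range(sc.n_transcripts):
            canonical = "YES" if j == sc.canonical_index else ""
            pick = "1" if j == sc.canonical_index else ""
            csq_entries.append(
                "|".join(
                    [
                        alt,
                        "missense_variant",
                        "MODERATE",
                        gene_name(i),
                        transcript_name(i, j, version=j + 2),
                        canonical,
                        pick,
                    ]
                )
            )
        info = f"DP={sc.dp};AF=0.0001;CSQ=" + ",".join(csq_entries)
        vcf_lines.append(
            f"chr{contig}\t{pos}\t.\t{ref}\t{alt}\t50\t{sc.filter_status}\t{info}\tGT:DP\t0/1:{sc.dp}"
        )
    with open(paths["vep_vcf"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(vcf_lines) + "\n")

    # --- ANNOVAR multianno (--vcfinput layout) ---
    anno_cols = [
        "Chr", "Start", "End", "Ref", "Alt", "Func.refGene", "Gene.refGene",
        "GeneDetail.refGene", "ExonicFunc.refGene", "AAChange.refGene",
        "gnomad311_AF",
    ] + [f"Otherinfo{k}" for k in range(1, 14)]
    anno_lines = ["\t".join(anno_cols)]
    for i, (sc, (contig, pos, ref, alt)) in enumerate(zip(scenarios, variants)):
        a_start, a_end, a_ref, a_alt = _annovar_rep(pos, ref, alt)
        csq_allele = alt
        info = f"DP={sc.dp};AF=0.0001;CSQ={csq_allele}|missense_variant|MODERATE|{gene_name(i)}|{transcript_name(i, 0, 2)}|YES|1"
        row = [
            f"chr{contig}", str(a_start), str(a_end), a_ref, a_alt,
            "exonic", gene_name(i), ".", "nonsynonymous SNV",
            f"{gene_name(i)}:{transcript_name(i, 0)}:exon1:c.100A>T:p.K34*",
            "0.0001",
            "het", "50", str(sc.dp),
            # original VCF record (the join key)
            f"chr{contig}", str(pos), ".", ref, alt, "50", sc.filter_status,
            f"DP={sc.dp};AF=0.0001", "GT:DP", f"0/1:{sc.dp}",
        ]
        anno_lines.append("\t".join(row))
    with open(paths["multianno"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(anno_lines) + "\n")

    # --- InterVar ---
    iv_cols = ["#Chr", "Start", "End", "Ref", "Alt", "Ref.Gene", "avsnp147",
               " InterVar: InterVar and Evidence ", "Otherinfo"]
    iv_lines = ["\t".join(iv_cols)]
    for i, (sc, (contig, pos, ref, alt)) in enumerate(zip(scenarios, variants)):
        if sc.intervar is None:
            continue
        a_start, a_end, a_ref, a_alt = _annovar_rep(pos, ref, alt)
        iv_lines.append(
            "\t".join(
                [
                    contig, str(a_start), str(a_end), a_ref, a_alt,
                    gene_name(i), ".",
                    _evidence_cell(sc.intervar_call, sc.intervar),
                    ".",
                ]
            )
        )
    with open(paths["intervar"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(iv_lines) + "\n")

    # --- AutoPVS1 ---
    ap_cols = ["variant_id", "symbol", "transcript", "consequence", "strength", "criterion"]
    ap_lines = ["\t".join(ap_cols)]
    for i, (sc, (contig, pos, ref, alt)) in enumerate(zip(scenarios, variants)):
        if sc.autopvs1_strength is None:
            continue
        # a deliberately different version suffix than the CSQ Feature
        tx = transcript_name(i, sc.autopvs1_tx_index, version=9)
        ap_lines.append(
            "\t".join(
                [
                    f"{contig}-{pos}-{ref}-{alt}",
                    gene_name(i), tx, "stop_gained",
                    f"Strength.{sc.autopvs1_strength.value}",
                    "NF1",
                ]
            )
        )
    with open(paths["autopvs1"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(ap_lines) + "\n")

    # --- ClinVar trio ---
    clinvar_scenarios = [
        (i, sc, var)
        for i, (sc, var) in enumerate(zip(scenarios, variants))
        if sc.clinvar_state != "absent"
    ]
    vcf = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=CLNSIG,Number=.,Type=String,Description="Aggregate germline classification">',
        '##INFO=<ID=CLNREVSTAT,Number=.,Type=String,Description="Review status">',
    ]
    for contig in used_contigs:
        vcf.append(f"##contig=<ID={contig}>")
    vcf.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for i, sc, (contig, pos, ref, alt) in clinvar_scenarios:
        vid = 500000 + i
        clnsig = sc.aggregate_significance.replace(" ", "_")
        clnrev = sc.review_status.replace(" ", "_")
        vcf.append(
            f"{contig}\t{pos}\t{vid}\t{ref}\t{alt}\t.\t.\tCLNSIG={clnsig};CLNREVSTAT={clnrev}"
        )
    _write_gz(paths["clinvar_vcf"], "\n".join(vcf) + "\n")

    vs_cols = [
        "#AlleleID", "Type", "Name", "GeneSymbol", "ClinicalSignificance",
        "ClinSigSimple", "LastEvaluated", "Assembly", "Chromosome", "Start",
        "Stop", "ReferenceAllele", "AlternateAllele", "ReviewStatus",
        "NumberSubmitters", "VariationID", "PositionVCF",
        "ReferenceAlleleVCF", "AlternateAlleleVCF",
    ]
    vs_lines = ["\t".join(vs_cols)]
    for i, sc, (contig, pos, ref, alt) in clinvar_scenarios:
        vid = 500000 + i
        a_start, a_end, a_ref, a_alt = _annovar_rep(pos, ref, alt)
        vs_lines.append(
            "\t".join(
                [
                    str(700000 + i), "single nucleotide variant",
                    f"NM_000000.0({gene_name(i)}):c.100A>T", gene_name(i),
                    sc.aggregate_significance, "1", "Jan 01, 2023",
                    "GRCh38", contig, str(a_start), str(a_end), a_ref, a_alt,
                    sc.review_status, str(max(1, len(sc.submissions))),
                    str(vid), str(pos), ref, alt,
                ]
            )
        )
        if sc.grch37_decoy:
            # same variation on the other assembly with a deliberately wrong
            # state; assembly filtering must ignore it
            vs_lines.append(
                "\t".join(
                    [
                        str(700000 + i), "single nucleotide variant",
                        f"NM_000000.0({gene_name(i)}):c.100A>T", gene_name(i),
                        "Benign", "0", "Jan 01, 2010",
                        "GRCh37", contig, str(a_start + 100), str(a_end + 100),
                        a_ref, a_alt, NO_CRITERIA, "1",
                        str(vid), str(pos + 100), ref, alt,
                    ]
                )
            )
    _write_gz(paths["variant_summary"], "\n".join(vs_lines) + "\n")

    ss_cols = [
        "VariationID", "ClinicalSignificance", "DateLastEvaluated",
        "Description", "SubmittedPhenotypeInfo", "ReportedPhenotypeInfo",
        "ReviewStatus", "CollectionMethod", "OriginCounts", "Submitter",
        "SCV", "SubmittedGeneSymbol",
    ]
    ss_lines = [
        "# Synthetic ClinVar submission_summary (fixture bundle)",
        "# One line per submitter interpretation",
        "#" + "\t".join(ss_cols),
    ]
    scv = 3000000
    for i, sc, _ in clinvar_scenarios:
        vid = 500000 + i
        for k, sub in enumerate(sc.submissions):
            scv += 1
            status = SINGLE if sub.criteria else NO_CRITERIA
            phenotype = ";".join(f"{cid}:Condition {cid}" for cid in sub.concepts)
            ss_lines.append(
                "\t".join(
                    [
                        str(vid), sub.significance,
                        _iso_to_clinvar_date(sub.date), "-",
                        "na", phenotype, status, "clinical testing",
                        "germline:na", f"Lab_{i}_{k}", f"SCV{scv:09d}.1",
                        gene_name(i),
                    ]
                )
            )
    _write_gz(paths["submission_summary"], "\n".join(ss_lines) + "\n")

    with open(paths["concept_ids"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# disease-of-interest MedGen Concept IDs\n")
        for cid in CONCEPT_LIST:
            fh.write(cid + "\n")

    # --- Golden expected-calls table ---
    exp_cols = [
        "label", "chr", "start", "ref", "alt",
        "call_latest", "call_most_severe", "call_no_concept",
        "source", "source_no_concept",
    ]
    exp_lines = ["\t".join(exp_cols)]
    for sc, (contig, pos, ref, alt) in zip(scenarios, variants):
        if not sc.in_output:
            continue
        exp_lines.append(
            "\t".join(
                [
                    sc.label, f"chr{contig}", str(pos), ref, alt,
                    sc.expected_call_latest.value,
                    sc.expected_call_most_severe.value,
                    sc.expected_call_no_concept.value,
                    sc.expected_source,
                    sc.expected_source_no_concept,
                ]
            )
        )
    with open(paths["expected_calls"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(exp_lines) + "\n")

    return paths


def random_criteria_vector(rng: np.random.Generator, p: float = 0.2) -> CriteriaVector:
    """Random evidence vector for property tests.

    Each boolean flag is set independently with probability ``p``; the PVS1
    strength is uniform over the five grades.
    """
    strengths = list(Strength)

    def flags(n: int) -> Tuple[bool, ...]:
        return tuple(bool(rng.random() < p) for _ in range(n))

    return CriteriaVector(
        pvs1=strengths[int(rng.integers(0, len(strengths)))],
        ps=flags(4),
        pm=flags(6),
        pp=flags(5),
        ba1=bool(rng.random() < p),
        bs=flags(4),
        bp=flags(7),
    )
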