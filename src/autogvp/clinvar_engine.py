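"""ClinVar interpretation: stars, significance normalization, conflict resolution.

ClinVar's aggregate classification carries a review status whose confidence is
summarized as 0-4 stars.  The pipeline keeps the ClinVar call outright for
variants with >= 2 stars, or 1 star from a single criteria-based submitter.
One-star variants with conflicting interpretations go through a decision tree
over the individual submissions:

1. drop submissions with no assertion criteria provided;
2. drop submissions whose significance is not expressible on the P/LP/VUS/LB/B
   scale (drug response, risk factor, ...);
3. if a MedGen Concept-ID list was supplied, keep only submissions whose
   reported condition intersects it;
4. nothing left -> the conflict is unresolved and the variant falls through to
   the InterVar-based classifier;
5. a unique most-frequent call (strict plurality) wins;
6. otherwise the tiebreak applies: ``latest`` takes the call of the most
   recently evaluated submission (dateless submissions rank lowest; exact date
   ties and the all-dateless case resolve to the most severe call among the
   tied submissions), ``most_severe`` takes the most severe remaining call.

Zero-star variants and non-standard aggregate classifications are treated as
not classified by ClinVar at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

from .variant_model import (
    Call,
    FinalCall,
    METHOD_DIRECT,
    METHOD_LATEST,
    METHOD_MAJORITY,
    METHOD_MOST_SEVERE,
    SOURCE_CLINVAR,
    VariantKey,
    severity_max,
)

log = logging.getLogger(__name__)

METHOD_EXCLUDED_ALL = "excluded_all"

TIEBREAK_LATEST = "latest"
TIEBREAK_MOST_SEVERE = "most_severe"


# --- Review-status stars --------------------------------------------------------

#: ClinVar review-status vocabulary -> star count.  Keys are compared after
#: lower-casing and whitespace normalization.  An unknown status is a hard
#: error: new ClinVar vocabulary must be mapped deliberately, because a silent
#: zero-star downgrade would quietly reroute variants to the InterVar branch.
_STAR_MAP = {
    "practice guideline": 4,
    "reviewed by expert panel": 3,
    "criteria provided, multiple submitters, no conflicts": 2,
    "criteria provided, multiple submitters": 2,
    "criteria provided, conflicting classifications": 1,
    "criteria provided, conflicting interpretations": 1,
    "criteria provided, single submitter": 1,
    "no assertion criteria provided": 0,
    "no classification provided": 0,
    "no assertion provided": 0,
    "no classification for the single variant": 0,
    "no classifications from unflagged records": 0,
}


def stars_from_review_status(status: str) -> int:
    """Map a ClinVar review-status string to its 0-4 star count."""
    key = " ".join(status.strip().lower().replace("_", " ").split())
    try:
        return _STAR_MAP[key]
    except KeyError:
        raise ValueError(
            f"unrecognized ClinVar review status {status!r}; known statuses: "
            + ", ".join(sorted(_STAR_MAP))
        ) from None


def is_conflicting_status(status: str) -> bool:
    """True for the 1-star 'criteria provided, conflicting ...' statuses."""
    return "conflicting" in status.lower()


# --- Significance normalization -------------------------------------------------

_SIGNIFICANCE_MAP = {
    "pathogenic": Call.P,
    "likely pathogenic": Call.LP,
    "uncertain significance": Call.VUS,
    "likely benign": Call.LB,
    "benign": Call.B,
    # Combined aggregates map to the weaker (more conservative) assertion.
    "pathogenic/likely pathogenic": Call.LP,
    "benign/likely benign": Call.LB,
}


def normalize_significance(raw: str) -> Optional[Call]:
    """Map a ClinVar significance string to the five-level scale.

    Returns ``None`` for anything not expressible on the scale (risk factor,
    drug response, ``Affects|risk_factor``, association strings, compound
    values with modifiers, ...).  Total: never raises.
    """
    key = " ".join(raw.strip().lower().replace("_", " ").split())
    return _SIGNIFICANCE_MAP.get(key)


# --- Conflict resolution --------------------------------------------------------


@dataclass(frozen=True)
class ResolutionOptions:
    """User options for 1-star conflict resolution.

    ``concept_ids=None`` disables condition filtering entirely (distinct from
    an empty set, which would exclude everything).
    """

    concept_ids: Optional[FrozenSet[str]] = None
    tiebreak: str = TIEBREAK_LATEST

    def __post_init__(self) -> None:
        if self.tiebreak not in (TIEBREAK_LATEST, TIEBREAK_MOST_SEVERE):
            raise ValueError(f"unknown tiebreak {self.tiebreak!r}")


@dataclass(frozen=True)
class ResolvedClinVar:
    """Outcome of resolving one conflicting variation."""

    variation_id: int
    call: Optional[Call]
    method: str
    n_considered: int

    def __post_init__(self) -> None:
        if (self.method == METHOD_EXCLUDED_ALL) != (self.call is None):
            raise ValueError("call must be unresolved exactly when method=excluded_all")
        if (self.n_considered == 0) != (self.method == METHOD_EXCLUDED_ALL):
            raise ValueError("n_considered == 0 iff every submission was excluded")


def filter_by_concept_ids(submissions: Sequence, ids: FrozenSet[str] | set) -> List:
    """Keep submissions whose reported-condition Concept IDs intersect ``ids``."""
    if not ids:
        raise ValueError("concept-ID filter requires a non-empty ID set")
    return [s for s in submissions if s.concept_ids & set(ids)]


def resolve_conflict(submissions: Sequence, options: ResolutionOptions) -> ResolvedClinVar:
    """Resolve a 1-star conflicting variation from its individual submissions.

    ``submissions`` are :class:`~autogvp.io_formats.SubmissionRecord` objects
    for a single variation_id.  See the module docstring for the decision
    tree.  Raises on an empty input list (the caller only invokes this on
    variations flagged as conflicting, which necessarily have submissions).
    """
    if not submissions:
        raise ValueError("resolve_conflict called with no submissions")
    variation_id = submissions[0].variation_id

    candidates = [s for s in submissions if s.assertion_criteria_provided]
    candidates = [s for s in candidates if normalize_significance(s.significance) is not None]
    if options.concept_ids is not None:
        candidates = filter_by_concept_ids(candidates, options.concept_ids)
    if not candidates:
        return ResolvedClinVar(variation_id, None, METHOD_EXCLUDED_ALL, 0)

    calls = [normalize_significance(s.significance) for s in candidates]
    tally: Dict[Call, int] = {}
    for c in calls:
        tally[c] = tally.get(c, 0) + 1
    best = max(tally.values())
    leaders = [c for c, n in tally.items() if n == best]
    if len(leaders) == 1:
        return ResolvedClinVar(variation_id, leaders[0], METHOD_MAJORITY, len(candidates))

    if options.tiebreak == TIEBREAK_MOST_SEVERE:
        return ResolvedClinVar(
            variation_id, severity_max(calls), METHOD_MOST_SEVERE, len(candidates)
        )

    # latest: dateless submissions sort below any dated one; ties on the
    # maximum date (including the all-dateless case) break by severity.
    def date_rank(s) -> Tuple[int, str]:
        d = s.date_last_evaluated
        return (1, d.isoformat()) if d is not None else (0, "")

    top = max(date_rank(s) for s in candidates)
    tied = [s for s in candidates if date_rank(s) == top]
    call = severity_max([normalize_significance(s.significance) for s in tied])
    return ResolvedClinVar(variation_id, call, METHOD_LATEST, len(candidates))


# --- The select-submissions pre-step --------------------------------------------


def select_clinvar_subset(
    assertions: Sequence,
    submissions_by_id: Dict[int, List],
    options: ResolutionOptions,
    resolved_sink: Optional[List[ResolvedClinVar]] = None,
    fallthrough_notes: Optional[Dict[VariantKey, str]] = None,
) -> Dict[VariantKey, FinalCall]:
    """Decide, per variant, whether ClinVar provides the final call.

    Returns a map from variant key to a ClinVar-sourced :class:`FinalCall`;
    variants absent from the map fall through to the InterVar classifier.
    ``resolved_sink``, when given, collects the per-conflict resolution
    records (the pre-step artifact); ``fallthrough_notes`` collects the reason
    a ClinVar-known variant was nevertheless left unclassified.
    """
    out: Dict[VariantKey, FinalCall] = {}
    for a in assertions:
        call = normalize_significance(a.significance)
        if a.stars == 1 and is_conflicting_status(a.review_status):
            subs = submissions_by_id.get(a.variation_id, [])
            if not subs:
                if fallthrough_notes is not None:
                    fallthrough_notes[a.key] = "conflict_without_submissions"
                continue
            resolved = resolve_conflict(subs, options)
            if resolved_sink is not None:
                resolved_sink.append(resolved)
            if resolved.call is None:
                if fallthrough_notes is not None:
                    fallthrough_notes[a.key] = "conflict_excluded_all"
                continue
            out[a.key] = FinalCall(
                call=resolved.call,
                source=SOURCE_CLINVAR,
                stars=a.stars,
                resolution_method=resolved.method,
                notes=f"variation_id={a.variation_id};n_considered={resolved.n_considered}",
            )
        elif a.stars >= 2 and call is not None:
            out[a.key] = FinalCall(
                call=call,
                source=SOURCE_CLINVAR,
                stars=a.stars,
                resolution_method=METHOD_DIRECT,
                notes=f"variation_id={a.variation_id}",
            )
        elif a.stars == 1 and call is not None:
            # 1 star, criteria provided by a single submitter.
            out[a.key] = FinalCall(
                call=call,
                source=SOURCE_CLINVAR,
                stars=1,
                resolution_method=METHOD_DIRECT,
                notes=f"variation_id={a.variation_id}",
            )
        else:
            if fallthrough_notes is not None:
                if a.stars == 0:
                    fallthrough_notes[a.key] = "clinvar_zero_star"
                else:
                    fallthrough_notes[a.key] = "clinvar_non_standard_significance"
    return out


def write_resolved_subset(resolved: Sequence[ResolvedClinVar], path: str) -> None:
    """Write the conflict-resolution artifact as a TSV (pre-step output)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("variation_id\tcall\tmethod\tn_considered\n")
        for r in resolved:
            call = r.call.value if r.call is not None else "unresolved"
            fh.write(f"{r.variation_id}\t{call}\t{r.method}\t{r.n_considered}\n")
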