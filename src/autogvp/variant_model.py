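"""Core domain types shared by every stage of the pipeline.

The five-level pathogenicity scale (P > LP > VUS > LB > B), the normalized
variant key used to join the annotation tables, and the final-call record
that the pipeline emits live here.  Everything is plain, hashable data so
that records can be used as dictionary keys when merging files produced by
different tools with different coordinate conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence


class VariantError(ValueError):
    """Base class for malformed variant input."""


class SymbolicAlleleError(VariantError):
    """Symbolic / structural alleles (<DEL>, breakends, '*') are not supported."""


class MultiAllelicError(VariantError):
    """Multi-allelic records must be split upstream before classification."""


class Call(str, Enum):
    """Five-level germline pathogenicity call.

    Severity is totally ordered: P > LP > VUS > LB > B.
    """

    P = "P"
    LP = "LP"
    VUS = "VUS"
    LB = "LB"
    B = "B"

    @property
    def severity(self) -> int:
        return _SEVERITY[self]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_SEVERITY = {Call.B: 0, Call.LB: 1, Call.VUS: 2, Call.LP: 3, Call.P: 4}

#: Human-readable long form of each call, as printed by classification tools.
CALL_LONG_NAMES = {
    Call.P: "Pathogenic",
    Call.LP: "Likely pathogenic",
    Call.VUS: "Uncertain significance",
    Call.LB: "Likely benign",
    Call.B: "Benign",
}


def severity_max(calls: Sequence[Call] | Iterable[Call]) -> Call:
    """Return the most severe call in ``calls`` (P > LP > VUS > LB > B).

    Raises ``ValueError`` on an empty input.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("severity_max of an empty call list is undefined")
    return max(calls, key=lambda c: c.severity)


_VALID_ALLELE_CHARS = frozenset("ACGTN")


@dataclass(frozen=True, order=True)
class VariantKey:
    """Normalized genomic identity: contig (no 'chr' prefix), 1-based pos, ref, alt.

    Alleles are uppercase and minimally represented (shared suffix then shared
    prefix trimmed), so the same variant written by VEP, ANNOVAR or ClinVar
    hashes identically.
    """

    contig: str
    pos: int
    ref: str
    alt: str

    def __str__(self) -> str:
        return f"{self.contig}:{self.pos}:{self.ref}>{self.alt}"


def _strip_chr(contig: str) -> str:
    if contig.lower().startswith("chr"):
        contig = contig[3:]
    if contig.lower() in ("x", "y", "m", "mt"):
        contig = contig.upper()
    return contig


def normalize_variant(contig: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Build the canonical join key for one bi-allelic variant.

    ``chr`` prefixes are stripped, alleles uppercased, and the pair reduced to
    its minimal representation: trim the shared trailing bases first, then the
    shared leading bases (advancing ``pos`` one per trimmed leading base),
    never trimming an allele to empty.

    Raises
    ------
    MultiAllelicError
        if ``alt`` contains a comma (pre-split input required).
    SymbolicAlleleError
        for symbolic alleles (``<DEL>``, breakend notation, ``*``).
    VariantError
        for empty alleles, non-ACGTN characters, ref == alt, or pos < 1.
    """
    if "," in alt:
        raise MultiAllelicError(
            f"multi-allelic ALT {alt!r} at {contig}:{pos}; split the record "
            "into bi-allelic rows (e.g. `bcftools norm -m-`) before running"
        )
    for allele in (ref, alt):
        if any(ch in allele for ch in "<>[]*"):
            raise SymbolicAlleleError(
                f"symbolic or structural allele {allele!r} at {contig}:{pos} "
                "is not supported"
            )
    if not ref or not alt:
        raise VariantError(f"empty allele at {contig}:{pos} (ref={ref!r}, alt={alt!r})")
    if pos < 1:
        raise VariantError(f"position must be >= 1, got {pos}")

    ref = ref.upper()
    alt = alt.upper()
    if not set(ref) <= _VALID_ALLELE_CHARS or not set(alt) <= _VALID_ALLELE_CHARS:
        raise VariantError(
            f"alleles must be over A/C/G/T/N, got ref={ref!r} alt={alt!r} "
            f"at {contig}:{pos}"
        )
    if ref == alt:
        raise VariantError(f"ref == alt ({ref!r}) at {contig}:{pos}")

    # Minimal representation: right-trim shared suffix, then left-trim shared
    # prefix.  Each trimmed leading base advances pos by one.
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1

    return VariantKey(contig=_strip_chr(contig), pos=pos, ref=ref, alt=alt)


#: Evidence sources for a final call.
SOURCE_CLINVAR = "ClinVar"
SOURCE_INTERVAR = "InterVar"

#: Resolution methods recorded in the output.
METHOD_DIRECT = "direct"
METHOD_MAJORITY = "majority"
METHOD_LATEST = "latest"
METHOD_MOST_SEVERE = "most_severe"
METHOD_NOT_IN_CLINVAR = "not_in_clinvar"


@dataclass(frozen=True)
class FinalCall:
    """The pipeline's decision for one variant.

    ``source`` records whether the call came from ClinVar (direct retention or
    conflict resolution) or from the modified InterVar classifier; ``stars``
    is the ClinVar review-status star count when the source is ClinVar;
    ``resolution_method`` is one of direct/majority/latest/most_severe for
    ClinVar calls and ``not_in_clinvar`` otherwise, in which case ``notes``
    explains any zero-star / non-standard / unresolved-conflict fallback.
    """

    call: Call
    source: str
    stars: Optional[int] = None
    resolution_method: str = METHOD_NOT_IN_CLINVAR
    notes: str = ""

    def __post_init__(self) -> None:
        if self.source not in (SOURCE_CLINVAR, SOURCE_INTERVAR):
            raise ValueError(f"unknown call source {self.source!r}")
        if self.source == SOURCE_CLINVAR and self.stars is None:
            raise ValueError("ClinVar-sourced calls must carry a star count")
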