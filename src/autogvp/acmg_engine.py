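"""Modified InterVar classifier.

InterVar emits, per variant, the raw ACMG-AMP evidence vector it assembled
(PVS1, PS1-4, PM1-6, PP1-5, BA1, BS1-4, BP1-7) together with its own call.
This module re-derives the five-level call from that vector after two
modifications:

* **PP5/BP6 removal** - the "reputable source" criteria are cleared before
  combining, so ClinVar assertions are never double counted (ClinVar is
  consulted directly, upstream of this classifier).
* **PVS1 strength adjustment** - InterVar applies PVS1 at full (VeryStrong)
  weight to every putative loss-of-function variant in a LOF-intolerant gene.
  Refined guidance grades PVS1 as VeryStrong / Strong / Moderate / Supporting
  / Unmet depending on the predicted consequence; we take the graded strength
  from an AutoPVS1 run and substitute it for InterVar's flag.  The adjustment
  only ever demotes: if InterVar did not set PVS1 the AutoPVS1 grade is
  ignored.

The combining rules themselves are the standard ACMG-AMP evidence-combination
table over bucket counts (very strong / strong / moderate / supporting on the
pathogenic side; stand-alone / strong / supporting on the benign side), with
simultaneously satisfied pathogenic and benign rules collapsing to VUS as
contradictory evidence.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, List, Optional, Tuple

from .variant_model import (
    Call,
    FinalCall,
    METHOD_NOT_IN_CLINVAR,
    SOURCE_INTERVAR,
)

log = logging.getLogger(__name__)


class Strength(str, Enum):
    """Graded evidence strength for PVS1 (VeryStrong > ... > Unmet)."""

    VERY_STRONG = "VeryStrong"
    STRONG = "Strong"
    MODERATE = "Moderate"
    SUPPORTING = "Supporting"
    UNMET = "Unmet"

    @property
    def rank(self) -> int:
        return _STRENGTH_RANK[self]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_STRENGTH_RANK = {
    Strength.UNMET: 0,
    Strength.SUPPORTING: 1,
    Strength.MODERATE: 2,
    Strength.STRONG: 3,
    Strength.VERY_STRONG: 4,
}

# Fixed arity of each criteria family (positions are 1-based in ACMG naming).
N_PS, N_PM, N_PP, N_BS, N_BP = 4, 6, 5, 4, 7


def _bool_tuple(n: int, set_positions: Iterable[int] = ()) -> Tuple[bool, ...]:
    flags = [False] * n
    for p in set_positions:
        if not 1 <= p <= n:
            raise ValueError(f"criterion position {p} out of range 1..{n}")
        flags[p - 1] = True
    return tuple(flags)


@dataclass(frozen=True)
class CriteriaVector:
    """One variant's ACMG-AMP evidence state.

    Boolean families are positional and 1-based in ACMG naming (``ps[0]`` is
    PS1 etc.).  PVS1 carries a graded :class:`Strength` rather than a boolean
    so the loss-of-function adjustment is representable.
    """

    pvs1: Strength = Strength.UNMET
    ps: Tuple[bool, ...] = (False,) * N_PS
    pm: Tuple[bool, ...] = (False,) * N_PM
    pp: Tuple[bool, ...] = (False,) * N_PP
    ba1: bool = False
    bs: Tuple[bool, ...] = (False,) * N_BS
    bp: Tuple[bool, ...] = (False,) * N_BP

    def __post_init__(self) -> None:
        for name, flags, n in (
            ("ps", self.ps, N_PS),
            ("pm", self.pm, N_PM),
            ("pp", self.pp, N_PP),
            ("bs", self.bs, N_BS),
            ("bp", self.bp, N_BP),
        ):
            if len(flags) != n:
                raise ValueError(f"{name} must have exactly {n} slots, got {len(flags)}")

    @classmethod
    def build(
        cls,
        pvs1: Strength = Strength.UNMET,
        ps: Iterable[int] = (),
        pm: Iterable[int] = (),
        pp: Iterable[int] = (),
        ba1: bool = False,
        bs: Iterable[int] = (),
        bp: Iterable[int] = (),
    ) -> "CriteriaVector":
        """Convenience constructor from 1-based set positions (PS1 == 1 ...)."""
        return cls(
            pvs1=pvs1,
            ps=_bool_tuple(N_PS, ps),
            pm=_bool_tuple(N_PM, pm),
            pp=_bool_tuple(N_PP, pp),
            ba1=ba1,
            bs=_bool_tuple(N_BS, bs),
            bp=_bool_tuple(N_BP, bp),
        )

    def is_empty(self) -> bool:
        return (
            self.pvs1 is Strength.UNMET
            and not any(self.ps)
            and not any(self.pm)
            and not any(self.pp)
            and not self.ba1
            and not any(self.bs)
            and not any(self.bp)
        )


@dataclass(frozen=True)
class EvidenceCounts:
    """Bucketed evidence counts fed to the combining rules.

    PVS1 contributes to the bucket named by its strength; PS criteria count as
    strong, PM as moderate, PP as supporting; BA1 is the stand-alone benign
    criterion, BS strong benign, BP supporting benign.
    """

    very_strong: int = 0
    strong: int = 0
    moderate: int = 0
    supporting: int = 0
    standalone_benign: int = 0
    strong_benign: int = 0
    supporting_benign: int = 0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"negative evidence count for {f.name}")


def counts_from_vector(cv: CriteriaVector) -> EvidenceCounts:
    """Collapse a criteria vector into per-strength bucket counts."""
    vs = strong = moderate = supporting = 0
    if cv.pvs1 is Strength.VERY_STRONG:
        vs = 1
    elif cv.pvs1 is Strength.STRONG:
        strong = 1
    elif cv.pvs1 is Strength.MODERATE:
        moderate = 1
    elif cv.pvs1 is Strength.SUPPORTING:
        supporting = 1
    return EvidenceCounts(
        very_strong=vs,
        strong=strong + sum(cv.ps),
        moderate=moderate + sum(cv.pm),
        supporting=supporting + sum(cv.pp),
        standalone_benign=int(cv.ba1),
        strong_benign=sum(cv.bs),
        supporting_benign=sum(cv.bp),
    )


# --- InterVar evidence-cell parsing -------------------------------------------

_EVIDENCE_RE = re.compile(
    r"InterVar:\s*(?P<call>.+?)\s+"
    r"PVS1=(?P<pvs1>\d+)\s+"
    r"PS=\[(?P<ps>[^\]]*)\]\s+"
    r"PM=\[(?P<pm>[^\]]*)\]\s+"
    r"PP=\[(?P<pp>[^\]]*)\]\s+"
    r"BA1=(?P<ba1>\d+)\s+"
    r"BS=\[(?P<bs>[^\]]*)\]\s+"
    r"BP=\[(?P<bp>[^\]]*)\]\s*$"
)


class EvidenceParseError(ValueError):
    """Raised when an InterVar evidence cell does not match the printed layout."""


def _parse_flag_list(raw: str, arity: int, family: str) -> Tuple[bool, ...]:
    tokens = [t.strip() for t in raw.split(",") if t.strip() != ""]
    try:
        values = [int(t) for t in tokens]
    except ValueError:
        raise EvidenceParseError(f"non-integer entry in {family} list: [{raw}]")
    if len(values) < arity:
        raise EvidenceParseError(
            f"{family} list has {len(values)} slots, expected at least {arity}: [{raw}]"
        )
    if any(v > 0 for v in values[arity:]):
        log.debug("ignoring set flag in surplus %s slot(s): [%s]", family, raw)
    # Values > 1 (evidence upgraded in a custom InterVar config) count as set.
    return tuple(v > 0 for v in values[:arity])


def parse_intervar_evidence(cell: str) -> Tuple[str, CriteriaVector]:
    """Parse InterVar's combined "InterVar and Evidence" cell.

    Returns the call string exactly as InterVar printed it, plus the evidence
    vector.  ``PVS1=1`` maps to ``Strength.VERY_STRONG`` (InterVar has no
    graded PVS1); bracketed integers > 0 set the positional flag.
    """
    m = _EVIDENCE_RE.search(cell.strip())
    if m is None:
        raise EvidenceParseError(f"unrecognized InterVar evidence cell: {cell!r}")
    pvs1 = Strength.VERY_STRONG if int(m.group("pvs1")) > 0 else Strength.UNMET
    cv = CriteriaVector(
        pvs1=pvs1,
        ps=_parse_flag_list(m.group("ps"), N_PS, "PS"),
        pm=_parse_flag_list(m.group("pm"), N_PM, "PM"),
        pp=_parse_flag_list(m.group("pp"), N_PP, "PP"),
        ba1=int(m.group("ba1")) > 0,
        bs=_parse_flag_list(m.group("bs"), N_BS, "BS"),
        bp=_parse_flag_list(m.group("bp"), N_BP, "BP"),
    )
    return m.group("call").strip(), cv


# --- Modifications -------------------------------------------------------------


def strip_pp5_bp6(cv: CriteriaVector) -> CriteriaVector:
    """Clear the deprecated reputable-source criteria PP5 and BP6.

    All other flags are untouched; the operation is idempotent.
    """
    pp = list(cv.pp)
    bp = list(cv.bp)
    pp[4] = False  # PP5
    bp[5] = False  # BP6
    return dataclasses.replace(cv, pp=tuple(pp), bp=tuple(bp))


def apply_pvs1_strength(cv: CriteriaVector, autopvs1: Optional[object]) -> CriteriaVector:
    """Substitute the graded AutoPVS1 strength for InterVar's binary PVS1.

    The adjustment is demote-only: when InterVar did not set PVS1 the vector
    is returned unchanged regardless of the AutoPVS1 grade, and when no
    AutoPVS1 record exists for a PVS1-flagged variant the full-strength flag
    is kept with a warning.

    ``autopvs1`` is any object with a ``strength`` attribute (an
    :class:`~autogvp.io_formats.AutoPVS1Record`) or ``None``.
    """
    if cv.pvs1 is Strength.UNMET:
        return cv
    if autopvs1 is None:
        log.warning(
            "PVS1 set by InterVar but variant absent from the AutoPVS1 table; "
            "keeping full VeryStrong weight"
        )
        return cv
    # demote-only: never raise the grade above what was already assigned
    new = autopvs1.strength
    if new.rank > cv.pvs1.rank:
        new = cv.pvs1
    return dataclasses.replace(cv, pvs1=new)


# --- Combining rules ------------------------------------------------------------


def combine_with_trace(counts: EvidenceCounts) -> Tuple[Call, List[str]]:
    """Apply the ACMG-AMP combining table; also report which rules fired.

    Pathogenic and likely-pathogenic rules are conjunctions of lower-bound
    thresholds on bucket counts; so are benign/likely-benign rules.  If rules
    from both the pathogenic and the benign group are satisfied the evidence
    is contradictory and the call is VUS.
    """
    vs, st, mo, su = counts.very_strong, counts.strong, counts.moderate, counts.supporting
    sa, sb, pb = counts.standalone_benign, counts.strong_benign, counts.supporting_benign

    fired: List[str] = []
    pathogenic = False
    if vs >= 1 and (st >= 1 or mo >= 2 or (mo >= 1 and su >= 1) or su >= 2):
        pathogenic = True
        fired.append("P:VS+support")
    if st >= 2:
        pathogenic = True
        fired.append("P:2Strong")
    if st >= 1 and (mo >= 3 or (mo >= 2 and su >= 2) or (mo >= 1 and su >= 4)):
        pathogenic = True
        fired.append("P:Strong+Moderate/Supporting")

    likely_pathogenic = False
    if (
        (vs >= 1 and mo >= 1)
        or (st >= 1 and mo >= 1)
        or (st >= 1 and su >= 2)
        or mo >= 3
        or (mo >= 2 and su >= 2)
        or (mo >= 1 and su >= 4)
    ):
        likely_pathogenic = True
        fired.append("LP")

    benign = False
    if sa >= 1:
        benign = True
        fired.append("B:BA1")
    if sb >= 2:
        benign = True
        fired.append("B:2StrongBenign")

    likely_benign = False
    if (sb >= 1 and pb >= 1) or pb >= 2:
        likely_benign = True
        fired.append("LB")

    pathogenic_side = pathogenic or likely_pathogenic
    benign_side = benign or likely_benign
    if pathogenic_side and benign_side:
        return Call.VUS, fired + ["VUS:contradictory"]
    if pathogenic:
        return Call.P, fired
    if likely_pathogenic:
        return Call.LP, fired
    if benign:
        return Call.B, fired
    if likely_benign:
        return Call.LB, fired
    return Call.VUS, fired


def combine(counts: EvidenceCounts) -> Call:
    """Five-level call from bucketed evidence counts (see combine_with_trace)."""
    return combine_with_trace(counts)[0]


def intervar_modified_call(
    cv_raw: CriteriaVector,
    autopvs1: Optional[object],
    notes: str = "",
) -> FinalCall:
    """Full modified-InterVar classification of one variant.

    Pipeline: strip PP5/BP6, apply the graded PVS1 strength, bucket the
    counts, combine.  The rule trace is recorded in the provenance notes.
    """
    cv = apply_pvs1_strength(strip_pp5_bp6(cv_raw), autopvs1)
    call, fired = combine_with_trace(counts_from_vector(cv))
    trace = ";".join(fired) if fired else "no_rule_fired"
    full_notes = f"rules={trace}" if not notes else f"{notes};rules={trace}"
    return FinalCall(
        call=call,
        source=SOURCE_INTERVAR,
        stars=None,
        resolution_method=METHOD_NOT_IN_CLINVAR,
        notes=full_notes,
    )
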