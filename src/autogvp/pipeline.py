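"""End-to-end orchestration: filter, join, classify, write.

The VEP-annotated VCF defines the variant universe.  After PASS filtering
(plus any user criteria), each surviving variant is classified by the
hierarchical decision tree: a usable ClinVar classification (>= 2 stars, or
1 star single submitter, or a resolved 1-star conflict) wins; otherwise the
modified InterVar classifier decides.  Each variant is annotated to a single
transcript (the AutoPVS1 transcript when it matches a CSQ entry, else the
canonical/picked one), with the remaining CSQ entries retained in the
``csq_vep`` output column.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

from . import io_formats
from .clinvar_engine import (
    ResolutionOptions,
    ResolvedClinVar,
    TIEBREAK_LATEST,
    select_clinvar_subset,
    write_resolved_subset,
)
from .acmg_engine import intervar_modified_call
from .io_formats import (
    AutoPVS1Record,
    InterVarRecord,
    ResultRow,
    VepVcfRecord,
    annovar_representation,
)
from .variant_model import (
    Call,
    FinalCall,
    METHOD_NOT_IN_CLINVAR,
    SOURCE_INTERVAR,
    VariantKey,
)

log = logging.getLogger(__name__)

_OPS = ["<=", ">=", "==", "!=", "<", ">"]


@dataclass(frozen=True)
class FilterCriterion:
    """One user filter: ``FIELD OP VALUE`` against an INFO or FORMAT field.

    Numeric comparisons on a missing or non-numeric value fail the criterion
    (the variant is dropped and counted), never raise.
    """

    field: str
    op: str
    value: str

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ValueError(f"unknown comparison operator {self.op!r}")
        if not _is_number(self.value) and self.op not in ("==", "!="):
            raise ValueError(
                f"ordering comparison {self.op!r} is undefined for the "
                f"string value {self.value!r}"
            )

    def evaluate(self, record: VepVcfRecord) -> bool:
        raw = record.info().get(self.field)
        if raw is None:
            raw = record.sample().get(self.field)
        if raw is None or raw == ".":
            return False
        if _is_number(self.value):
            token = raw.split(",")[0]
            try:
                left = float(token)
            except ValueError:
                return False
            right = float(self.value)
            return {
                "<": left < right,
                "<=": left <= right,
                ">": left > right,
                ">=": left >= right,
                "==": left == right,
                "!=": left != right,
            }[self.op]
        return (raw == self.value) if self.op == "==" else (raw != self.value)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def parse_filter_criteria(spec: str) -> List[FilterCriterion]:
    """Parse a comma-separated criteria string like ``"DP>=10,AF<0.001"``."""
    criteria = []
    for token in spec.split(","):
        token = token.strip()
        if not token:
            continue
        for op in _OPS:
            if op in token:
                name, _, value = token.partition(op)
                criteria.append(FilterCriterion(name.strip(), op, value.strip()))
                break
        else:
            raise ValueError(f"cannot parse filter criterion {token!r}")
    return criteria


def apply_filters(
    records: Sequence[VepVcfRecord],
    criteria: Sequence[FilterCriterion],
    declared_fields: Optional[FrozenSet[str]] = None,
    drop_counts: Optional[Dict[str, int]] = None,
) -> List[VepVcfRecord]:
    """Keep PASS records satisfying every criterion (order preserved).

    A criterion referencing a field the VCF header does not declare raises
    before any record is examined.
    """
    if declared_fields is not None:
        for c in criteria:
            if c.field not in declared_fields:
                raise ValueError(
                    f"filter criterion references undeclared field {c.field!r}"
                )
    kept: List[VepVcfRecord] = []
    counts = drop_counts if drop_counts is not None else {}
    for rec in records:
        if rec.filter_status != "PASS":
            counts["not_pass"] = counts.get("not_pass", 0) + 1
            continue
        failed = next((c for c in criteria if not c.evaluate(rec)), None)
        if failed is not None:
            label = f"fail_{failed.field}{failed.op}{failed.value}"
            counts[label] = counts.get(label, 0) + 1
            continue
        kept.append(rec)
    return kept


# --- Classification -------------------------------------------------------------


def classify_variant(
    record: VepVcfRecord,
    clinvar_resolved: Dict[VariantKey, FinalCall],
    intervar: Optional[InterVarRecord],
    autopvs1: Optional[AutoPVS1Record],
    clinvar_note: str = "",
) -> FinalCall:
    """Hierarchical call: ClinVar when usable, else modified InterVar.

    A variant absent from the InterVar table and unresolved in ClinVar is
    emitted as VUS with a ``no_evidence`` note rather than dropped.
    """
    hit = clinvar_resolved.get(record.key)
    if hit is not None:
        return hit
    note = clinvar_note or "not_in_clinvar"
    if intervar is None:
        log.warning(
            "variant %s has no InterVar row and no usable ClinVar "
            "classification; emitting VUS", record.key
        )
        return FinalCall(
            call=Call.VUS,
            source=SOURCE_INTERVAR,
            stars=None,
            resolution_method=METHOD_NOT_IN_CLINVAR,
            notes=f"{note};no_evidence",
        )
    return intervar_modified_call(intervar.criteria, autopvs1, notes=note)


_VERSION_RE = re.compile(r"\.\d+$")


def _strip_tx_version(tx: str) -> str:
    return _VERSION_RE.sub("", tx)


def select_transcript(
    record: VepVcfRecord, autopvs1: Optional[AutoPVS1Record]
) -> Tuple[Dict[str, str], List[Dict[str, str]]]:
    """Choose the single reported transcript annotation.

    The AutoPVS1 transcript wins when it matches a CSQ entry's Feature
    (version-insensitively); otherwise the entry flagged CANONICAL/PICK, and
    failing that the first entry.  Everything else is retained for the
    ``csq_vep`` column.
    """
    entries = record.csq()
    if not entries:
        raise ValueError(f"variant {record.key} has no CSQ entries")
    primary_idx = None
    if autopvs1 is not None:
        want = _strip_tx_version(autopvs1.transcript)
        for i, entry in enumerate(entries):
            if _strip_tx_version(entry.get("Feature", "")) == want:
                primary_idx = i
                break
    if primary_idx is None:
        for i, entry in enumerate(entries):
            if entry.get("CANONICAL", "") == "YES" or entry.get("PICK", "") == "1":
                primary_idx = i
                break
    if primary_idx is None:
        primary_idx = 0
    retained = [e for i, e in enumerate(entries) if i != primary_idx]
    return entries[primary_idx], retained


def _serialize_csq(entries: List[Dict[str, str]]) -> str:
    # mirror VEP's own encoding: fields joined by '|', entries by ','
    return ",".join("|".join(e.values()) for e in entries)


# --- Run configuration and the full pipeline ------------------------------------


@dataclass
class RunConfig:
    """Everything one run needs; paths are the seven inputs plus options."""

    vep_vcf: str
    multianno: str
    intervar: str
    autopvs1: str
    clinvar_vcf: str
    variant_summary: str
    submission_summary: str
    out_prefix: str
    concept_id_list: Optional[str] = None
    tiebreak: str = TIEBREAK_LATEST
    filter_criteria: str = ""
    build: str = "GRCh38"

    def __post_init__(self) -> None:
        if self.build not in ("GRCh38", "GRCh37"):
            raise ValueError(f"genome build must be GRCh38 or GRCh37, got {self.build!r}")


@dataclass
class RunResult:
    abridged_path: str
    full_path: str
    summary_path: str
    resolved_subset_path: str
    rows: List[ResultRow] = field(default_factory=list)
    summary: Dict[str, int] = field(default_factory=dict)


def run(config: RunConfig) -> RunResult:
    """Execute the full pipeline; deterministic in the input order."""
    records = io_formats.read_vep_vcf(config.vep_vcf)
    declared = io_formats.vcf_declared_fields(config.vep_vcf)
    chr_prefixed = bool(records) and records[0].contig_raw.lower().startswith("chr")

    criteria = parse_filter_criteria(config.filter_criteria)
    drop_counts: Dict[str, int] = {}
    kept = apply_filters(records, criteria, declared, drop_counts)

    multianno = dict(io_formats.read_multianno(config.multianno))

    intervar_by_anno = {}
    for rec in io_formats.read_intervar(config.intervar):
        intervar_by_anno[rec.anno_key] = rec
    intervar_by_key: Dict[VariantKey, InterVarRecord] = {}
    for record in kept:
        anno = annovar_representation(record.key)
        hit = intervar_by_anno.get(anno)
        if hit is not None:
            hit.key = record.key
            intervar_by_key[record.key] = hit
    n_intervar_unmatched = len(intervar_by_anno) - len(
        {id(r) for r in intervar_by_key.values()}
    )

    autopvs1_by_key = {r.key: r for r in io_formats.read_autopvs1(config.autopvs1)}

    concept_ids = (
        io_formats.read_concept_id_list(config.concept_id_list)
        if config.concept_id_list
        else None
    )
    options = ResolutionOptions(concept_ids=concept_ids, tiebreak=config.tiebreak)

    assertions, submissions = io_formats.read_clinvar_files(
        config.clinvar_vcf,
        config.variant_summary,
        config.submission_summary,
        assembly=config.build,
    )
    resolved_records: List[ResolvedClinVar] = []
    fallthrough_notes: Dict[VariantKey, str] = {}
    clinvar_map = select_clinvar_subset(
        assertions, submissions, options, resolved_records, fallthrough_notes
    )
    resolved_subset_path = f"{config.out_prefix}.clinvar_resolved.tsv"
    write_resolved_subset(resolved_records, resolved_subset_path)

    rows: List[ResultRow] = []
    method_counts: Dict[str, int] = {}
    for record in kept:
        iv = intervar_by_key.get(record.key)
        ap = autopvs1_by_key.get(record.key)
        final = classify_variant(
            record, clinvar_map, iv, ap, fallthrough_notes.get(record.key, "")
        )
        primary, retained = select_transcript(record, ap)
        gene = primary.get("SYMBOL", "") or (iv.gene if iv else "")
        transcript = primary.get("Feature", "")
        anno_row = multianno.get(record.key, {})
        chrom_display = ("chr" + record.key.contig) if chr_prefixed else record.key.contig
        rows.append(
            ResultRow(
                chrom_display=chrom_display,
                pos=record.key.pos,
                ref=record.key.ref,
                alt=record.key.alt,
                gene=gene,
                transcript=transcript,
                final=final,
                csq_vep=_serialize_csq(retained),
                vcf_info=";".join(
                    k if v == "" else f"{k}={v}"
                    for k, v in record.info_fields
                    if k != "CSQ"
                ),
                annovar=anno_row,
                intervar_evidence=iv.evidence_cell if iv else "",
                intervar_original_call=iv.original_call if iv else "",
                autopvs1_strength=ap.strength.value if ap else "",
                autopvs1_criterion=ap.criterion_path if ap else "",
            )
        )
        label = f"{final.source}_{final.resolution_method}"
        method_counts[label] = method_counts.get(label, 0) + 1

    abridged_path, full_path = io_formats.write_outputs(rows, config.out_prefix)

    summary: Dict[str, int] = {
        "n_input": len(records),
        "n_kept": len(kept),
        "n_intervar_rows_unmatched": n_intervar_unmatched,
        "n_clinvar_conflicts_resolved": sum(1 for r in resolved_records if r.call is not None),
        "n_clinvar_conflicts_unresolved": sum(1 for r in resolved_records if r.call is None),
    }
    for reason, n in sorted(drop_counts.items()):
        summary[f"n_dropped_{reason}"] = n
    for label, n in sorted(method_counts.items()):
        summary[f"n_call_{label}"] = n

    summary_path = f"{config.out_prefix}.summary.log"
    with open(summary_path, "w", encoding="utf-8", newline="\n") as fh:
        for k, v in summary.items():
            fh.write(f"{k}={v}\n")

    return RunResult(
        abridged_path=abridged_path,
        full_path=full_path,
        summary_path=summary_path,
        resolved_subset_path=resolved_subset_path,
        rows=rows,
        summary=summary,
    )
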