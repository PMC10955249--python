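"""Readers and writers for the seven input dialects and the two output tables.

Inputs
------
* VEP-annotated VCF (plain or gzip) with a ``CSQ`` INFO field whose header
  Description declares the per-transcript sub-field layout;
* ANNOVAR multianno TSV produced with ``--vcfinput`` (the trailing Otherinfo
  columns carry the original VCF record, which is the trusted join key);
* InterVar ``*.intervar`` TSV with the combined "InterVar and Evidence" cell;
* AutoPVS1 TSV with per-variant transcript, consequence and graded strength;
* the ClinVar distribution trio: ``clinvar.vcf.gz`` (variant key ->
  variation_id), ``variant_summary.txt.gz`` (per-assembly aggregate
  classification and review status) and ``submission_summary.txt.gz``
  (individual submissions).

Readers preserve input order and never silently drop rows; structural
problems raise with the offending content.  Classification never depends on
the ANNOVAR table - it is carried through for annotation only.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import pysam

from .acmg_engine import CriteriaVector, Strength, parse_intervar_evidence
from .variant_model import (
    Call,
    MultiAllelicError,
    VariantKey,
    normalize_variant,
)

log = logging.getLogger(__name__)


def _open_text(path: str):
    """Open plain or gzip text transparently."""
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


# --- VEP VCF --------------------------------------------------------------------


@dataclass(frozen=True)
class VepVcfRecord:
    """One data row of the VEP-annotated VCF, with the CSQ field expanded."""

    key: VariantKey
    contig_raw: str
    pos: int
    vid: str
    ref: str
    alt: str
    qual: str
    filter_status: str
    info_fields: Tuple[Tuple[str, str], ...]  # ordered (name, raw value); flags -> ""
    format_keys: Tuple[str, ...]
    format_values: Tuple[Tuple[str, str], ...]  # single germline sample
    csq_entries: Tuple[Tuple[Tuple[str, str], ...], ...]

    def info(self) -> Dict[str, str]:
        return dict(self.info_fields)

    def sample(self) -> Dict[str, str]:
        return dict(self.format_values)

    def csq(self) -> List[Dict[str, str]]:
        return [dict(entry) for entry in self.csq_entries]

    def to_vcf_line(self) -> str:
        """Re-serialize the record as the VCF data line it was parsed from."""
        info = ";".join(k if v == "" else f"{k}={v}" for k, v in self.info_fields)
        cols = [
            self.contig_raw,
            str(self.pos),
            self.vid,
            self.ref,
            self.alt,
            self.qual,
            self.filter_status,
            info or ".",
        ]
        if self.format_keys:
            cols.append(":".join(self.format_keys))
            cols.append(":".join(v for _, v in self.format_values))
        return "\t".join(cols)


_CSQ_FORMAT_RE = re.compile(r"Format:\s*([^\"]+)")


def _csq_field_names(header: pysam.VariantHeader) -> List[str]:
    rec = header.info.get("CSQ")
    if rec is None:
        raise ValueError(
            "VCF header does not declare a CSQ INFO field; a VEP-annotated "
            "VCF (with '##INFO=<ID=CSQ,...Format: ...>') is required"
        )
    m = _CSQ_FORMAT_RE.search(rec.description or "")
    if m is None:
        raise ValueError(
            "CSQ INFO Description does not declare the sub-field layout "
            f"('Format: a|b|...'): {rec.description!r}"
        )
    return [f.strip() for f in m.group(1).split("|")]


def _parse_info_column(raw: str) -> Tuple[Tuple[str, str], ...]:
    if raw == "." or raw == "":
        return ()
    out = []
    for token in raw.split(";"):
        if not token:
            continue
        name, _, value = token.partition("=")
        out.append((name, value))
    return tuple(out)


def vcf_declared_fields(path: str) -> FrozenSet[str]:
    """INFO and FORMAT field names declared in the VCF header."""
    with pysam.VariantFile(path) as vf:
        return frozenset(vf.header.info.keys()) | frozenset(vf.header.formats.keys())


def read_vep_vcf(path: str) -> List[VepVcfRecord]:
    """Parse a VEP-annotated VCF (gzip or plain) into records, in file order.

    Each record's CSQ field is split into per-transcript maps using the
    header's ``Format:`` declaration.  Multi-allelic rows raise (the input
    must be pre-split); a record with zero CSQ entries raises.
    """
    records: List[VepVcfRecord] = []
    with pysam.VariantFile(path) as vf:
        csq_names = _csq_field_names(vf.header)
        for n, rec in enumerate(vf, start=1):
            cols = str(rec).rstrip("\n").split("\t")
            if len(cols) < 8:
                raise ValueError(f"malformed VCF row at data line {n}: {cols!r}")
            chrom, pos_s, vid, ref, alt = cols[0], cols[1], cols[2], cols[3], cols[4]
            try:
                key = normalize_variant(chrom, int(pos_s), ref, alt)
            except MultiAllelicError:
                raise
            except ValueError as exc:
                raise ValueError(f"VCF data line {n}: {exc}") from exc
            info = _parse_info_column(cols[7])
            info_map = dict(info)
            if "CSQ" not in info_map or info_map["CSQ"] == "":
                raise ValueError(f"VCF data line {n} has no CSQ annotation")
            entries = []
            for chunk in info_map["CSQ"].split(","):
                values = chunk.split("|")
                if len(values) != len(csq_names):
                    raise ValueError(
                        f"VCF data line {n}: CSQ entry has {len(values)} fields, "
                        f"header declares {len(csq_names)}"
                    )
                entries.append(tuple(zip(csq_names, values)))
            fmt_keys: Tuple[str, ...] = ()
            fmt_values: Tuple[Tuple[str, str], ...] = ()
            if len(cols) >= 10:
                if len(cols) > 10:
                    raise ValueError(
                        f"VCF data line {n}: multi-sample VCFs are not supported "
                        "(a single germline sample is expected)"
                    )
                fmt_keys = tuple(cols[8].split(":"))
                fmt_values = tuple(zip(fmt_keys, cols[9].split(":")))
            records.append(
                VepVcfRecord(
                    key=key,
                    contig_raw=chrom,
                    pos=int(pos_s),
                    vid=vid,
                    ref=ref,
                    alt=alt,
                    qual=cols[5],
                    filter_status=cols[6],
                    info_fields=info,
                    format_keys=fmt_keys,
                    format_values=fmt_values,
                    csq_entries=tuple(entries),
                )
            )
    return records


def read_vcf_header_text(path: str) -> str:
    """The verbatim header block of a VCF, for round-trip serialization."""
    lines = []
    with _open_text(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            lines.append(line.rstrip("\n"))
    return "\n".join(lines) + "\n"


def write_vep_vcf(records: Sequence[VepVcfRecord], header_text: str, path: str) -> None:
    """Serialize records under an existing header (testing / round-trips)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(header_text)
        for rec in records:
            fh.write(rec.to_vcf_line() + "\n")


# --- ANNOVAR multianno ----------------------------------------------------------


def annovar_representation(key: VariantKey) -> Tuple[str, int, int, str, str]:
    """Convert a normalized VCF key to ANNOVAR's (Chr, Start, End, Ref, Alt).

    ANNOVAR uses '-' alleles and shifted coordinates for indels; this is the
    bridge used to join InterVar rows (which inherit ANNOVAR coordinates)
    back to VCF keys.
    """
    c, p, r, a = key.contig, key.pos, key.ref, key.alt
    if len(r) == 1 and len(a) == 1:
        return (c, p, p, r, a)
    if len(r) == 1 and a.startswith(r):  # insertion after p
        return (c, p, p, "-", a[1:])
    if len(a) == 1 and r.startswith(a):  # deletion of r[1:]
        return (c, p + 1, p + len(r) - 1, r[1:], "-")
    return (c, p, p + len(r) - 1, r, a)  # block substitution


def read_multianno(path: str) -> List[Tuple[VariantKey, Dict[str, str]]]:
    """Read an ANNOVAR ``--vcfinput`` multianno table.

    The variant key is re-derived from the original VCF record stored in the
    trailing Otherinfo columns (the last ten tab-separated fields of each
    row) rather than from ANNOVAR's shifted Start/End/Ref/Alt.  All columns
    are passed through verbatim for the full output.
    """
    out: List[Tuple[VariantKey, Dict[str, str]]] = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            return out
        names = header.split("\t")
        n_otherinfo = sum(1 for n in names if n.startswith("Otherinfo"))
        if n_otherinfo < 10:
            raise ValueError(
                "multianno table lacks the Otherinfo columns of ANNOVAR's "
                "--vcfinput mode; the original VCF record is required to "
                "derive join keys"
            )
        for ln, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(names):
                raise ValueError(
                    f"multianno row {ln} has {len(cells)} cells, header has {len(names)}"
                )
            vcf_fields = cells[-10:]
            chrom, pos_s, _, ref, alt = vcf_fields[0], vcf_fields[1], vcf_fields[2], vcf_fields[3], vcf_fields[4]
            key = normalize_variant(chrom, int(pos_s), ref, alt)
            out.append((key, dict(zip(names, cells))))
    return out


# --- InterVar -------------------------------------------------------------------


@dataclass
class InterVarRecord:
    """One InterVar row: ANNOVAR-style coordinates, call and evidence vector.

    ``key`` is resolved against the VCF variant universe by the pipeline
    (InterVar prints ANNOVAR-shifted coordinates, not VCF ones).
    """

    anno_chrom: str
    anno_start: int
    anno_end: int
    anno_ref: str
    anno_alt: str
    gene: str
    original_call: str
    criteria: CriteriaVector
    evidence_cell: str
    key: Optional[VariantKey] = None

    @property
    def anno_key(self) -> Tuple[str, int, int, str, str]:
        return (self.anno_chrom, self.anno_start, self.anno_end, self.anno_ref, self.anno_alt)


def read_intervar(path: str) -> List[InterVarRecord]:
    """Read an InterVar ``*.intervar`` table.

    The combined " InterVar: InterVar and Evidence " cell is parsed into the
    call string (kept verbatim) and the criteria vector.
    """
    out: List[InterVarRecord] = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            return out
        names = [n.strip() for n in header.split("\t")]
        lower = [n.lower() for n in names]

        def col(candidates: List[str], what: str) -> int:
            for cand in candidates:
                if cand in lower:
                    return lower.index(cand)
            raise ValueError(f"InterVar table lacks a {what} column (header: {names})")

        i_chr = col(["#chr", "chr"], "chromosome")
        i_start = col(["start"], "start")
        i_end = col(["end"], "end")
        i_ref = col(["ref"], "ref")
        i_alt = col(["alt"], "alt")
        i_gene = col(["ref.gene", "gene", "gene.refgene"], "gene")
        i_ev = next(
            (i for i, n in enumerate(lower) if "intervar" in n and "evidence" in n),
            None,
        )
        if i_ev is None:
            raise ValueError(
                "InterVar table lacks the combined 'InterVar: InterVar and "
                f"Evidence' column (header: {names})"
            )
        for ln, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            cell = cells[i_ev]
            try:
                original_call, cv = parse_intervar_evidence(cell)
            except ValueError as exc:
                raise ValueError(f"InterVar row {ln}: {exc}") from exc
            out.append(
                InterVarRecord(
                    anno_chrom=cells[i_chr].removeprefix("chr"),
                    anno_start=int(cells[i_start]),
                    anno_end=int(cells[i_end]),
                    anno_ref=cells[i_ref].upper() if cells[i_ref] != "-" else "-",
                    anno_alt=cells[i_alt].upper() if cells[i_alt] != "-" else "-",
                    gene=cells[i_gene],
                    original_call=original_call,
                    criteria=cv,
                    evidence_cell=cell,
                )
            )
    return out


# --- AutoPVS1 -------------------------------------------------------------------


@dataclass(frozen=True)
class AutoPVS1Record:
    """One AutoPVS1 row: the graded PVS1 strength for a putative LOF variant."""

    key: VariantKey
    gene: str
    transcript: str
    consequence: str
    strength: Strength
    criterion_path: str


_STRENGTH_TOKENS = {
    "verystrong": Strength.VERY_STRONG,
    "very_strong": Strength.VERY_STRONG,
    "strong": Strength.STRONG,
    "moderate": Strength.MODERATE,
    "supporting": Strength.SUPPORTING,
    "unmet": Strength.UNMET,
    "unset": Strength.UNMET,
    "na": Strength.UNMET,
    "nan": Strength.UNMET,
    "": Strength.UNMET,
}


def parse_strength_token(token: str) -> Strength:
    """Normalize an AutoPVS1 strength token ('Strength.Moderate', 'NA', ...)."""
    t = token.strip()
    if t.lower().startswith("strength."):
        t = t[len("strength."):]
    try:
        return _STRENGTH_TOKENS[t.lower()]
    except KeyError:
        raise ValueError(
            f"unrecognized AutoPVS1 strength token {token!r}; accepted: "
            "VeryStrong, Strong, Moderate, Supporting, Unmet, NA "
            "(optionally prefixed 'Strength.')"
        ) from None


def read_autopvs1(path: str) -> List[AutoPVS1Record]:
    """Read an AutoPVS1 output table.

    The variant column is a ``chrom-pos-ref-alt`` string; strengths are
    normalized to the five-level vocabulary (absent/NA -> Unmet).
    """
    out: List[AutoPVS1Record] = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            return out
        names = [n.strip().lower() for n in header.split("\t")]

        def col(candidates: List[str], what: str) -> int:
            for cand in candidates:
                if cand in names:
                    return names.index(cand)
            raise ValueError(f"AutoPVS1 table lacks a {what} column (header: {names})")

        i_var = col(["variant_id", "variant", "vcf_id"], "variant")
        i_gene = col(["symbol", "gene"], "gene")
        i_tx = col(["transcript", "feature"], "transcript")
        i_csq = col(["consequence", "trans_name"], "consequence")
        i_str = col(["strength", "strength_adjusted", "criterion_strength"], "strength")
        i_crit = next((names.index(c) for c in ("criterion", "criterions", "path") if c in names), None)
        for ln, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            parts = cells[i_var].split("-")
            if len(parts) != 4:
                raise ValueError(
                    f"AutoPVS1 row {ln}: variant id {cells[i_var]!r} is not "
                    "'chrom-pos-ref-alt'"
                )
            key = normalize_variant(parts[0], int(parts[1]), parts[2], parts[3])
            out.append(
                AutoPVS1Record(
                    key=key,
                    gene=cells[i_gene],
                    transcript=cells[i_tx],
                    consequence=cells[i_csq],
                    strength=parse_strength_token(cells[i_str]),
                    criterion_path=cells[i_crit] if i_crit is not None else "",
                )
            )
    return out


# --- ClinVar distribution files -------------------------------------------------


@dataclass(frozen=True)
class ClinVarAssertion:
    """Aggregate ClinVar state of one variant on the configured assembly."""

    key: VariantKey
    variation_id: int
    significance: str
    review_status: str
    stars: int


@dataclass(frozen=True)
class SubmissionRecord:
    """One submitter's assertion for a variation."""

    variation_id: int
    significance: str
    date_last_evaluated: Optional[date]
    assertion_criteria_provided: bool
    concept_ids: FrozenSet[str]
    submitter: str


_CONCEPT_RE = re.compile(r"\bCN?\d+\b")
_DATE_FORMATS = ("%b %d, %Y", "%Y-%m-%d", "%d/%m/%Y")


def _parse_clinvar_date(raw: str) -> Optional[date]:
    raw = raw.strip()
    if raw in ("", "-", "na", "NA", "not provided"):
        return None
    for fmt in _DATE_FORMATS:
        try:
            return datetime.strptime(raw, fmt).date()
        except ValueError:
            continue
    raise ValueError(f"unparseable ClinVar date {raw!r}")


def _submission_criteria_provided(review_status: str) -> bool:
    s = review_status.strip().lower()
    return not (s.startswith("no assertion") or s.startswith("no classification"))


def read_clinvar_files(
    vcf_path: str,
    variant_summary_path: str,
    submission_summary_path: str,
    assembly: str = "GRCh38",
) -> Tuple[List[ClinVarAssertion], Dict[int, List[SubmissionRecord]]]:
    """Load the ClinVar distribution trio.

    The ClinVar VCF supplies the variant-key -> variation_id mapping (its ID
    column is the VariationID); ``variant_summary`` is the per-assembly
    authority for aggregate significance and review status (rows for other
    assemblies are dropped); ``submission_summary`` supplies the individual
    submissions, grouped by variation_id.  A variation with no submissions is
    tolerated (empty list on lookup).
    """
    # variant_summary: VariationID -> (significance, review status), per assembly.
    summary: Dict[int, Tuple[str, str]] = {}
    with _open_text(variant_summary_path) as fh:
        header = fh.readline().rstrip("\n").lstrip("#")
        names = header.split("\t")
        idx = {n: i for i, n in enumerate(names)}
        for need in ("Assembly", "ClinicalSignificance", "ReviewStatus", "VariationID"):
            if need not in idx:
                raise ValueError(f"variant_summary lacks required column {need!r}")
        for line in fh:
            cells = line.rstrip("\n").split("\t")
            if len(cells) < len(names):
                continue
            if cells[idx["Assembly"]] != assembly:
                continue
            vid = int(cells[idx["VariationID"]])
            summary[vid] = (cells[idx["ClinicalSignificance"]], cells[idx["ReviewStatus"]])

    # The ClinVar VCF is consumed column-wise (key -> VariationID), so it is
    # parsed directly; plain gzip as shipped on the ClinVar FTP site is fine.
    assertions: List[ClinVarAssertion] = []
    with _open_text(vcf_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                raise ValueError(f"truncated ClinVar VCF row: {line!r}")
            chrom, pos_s, vid_s, ref, alt = cols[0], cols[1], cols[2], cols[3], cols[4]
            if alt in (".", "") or "," in alt:
                log.debug("skipping ClinVar VCF row without a usable ALT at %s:%s", chrom, pos_s)
                continue
            try:
                key = normalize_variant(chrom, int(pos_s), ref, alt)
            except ValueError:
                log.debug("skipping unnormalizable ClinVar VCF row at %s:%s", chrom, pos_s)
                continue
            try:
                vid = int(vid_s)
            except ValueError:
                log.warning("ClinVar VCF row at %s:%s has non-numeric ID %r", chrom, pos_s, vid_s)
                continue
            if vid not in summary:
                log.warning(
                    "variation %d present in clinvar.vcf but absent from "
                    "variant_summary (%s); skipping", vid, assembly
                )
                continue
            significance, review_status = summary[vid]
            info_map = dict(_parse_info_column(cols[7]))
            vcf_sig = info_map.get("CLNSIG", "").replace("_", " ")
            if vcf_sig and vcf_sig.lower() != significance.lower():
                log.info(
                    "variation %d: significance differs between clinvar.vcf (%r) "
                    "and variant_summary (%r); variant_summary wins",
                    vid, vcf_sig, significance,
                )
            assertions.append(
                ClinVarAssertion(
                    key=key,
                    variation_id=vid,
                    significance=significance,
                    review_status=review_status,
                    stars=stars_from_review_status_cached(review_status),
                )
            )

    submissions: Dict[int, List[SubmissionRecord]] = {}
    with _open_text(submission_summary_path) as fh:
        header_cells: Optional[List[str]] = None
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                header_cells = line.lstrip("#").split("\t")
                continue
            if header_cells is None:
                raise ValueError(
                    "submission_summary has no '#'-prefixed header line before data"
                )
            idx = {n: i for i, n in enumerate(header_cells)}
            cells = line.split("\t")
            vid = int(cells[idx["VariationID"]])
            phenotype = cells[idx.get("ReportedPhenotypeInfo", idx.get("SubmittedPhenotypeInfo", 0))]
            rec = SubmissionRecord(
                variation_id=vid,
                significance=cells[idx["ClinicalSignificance"]],
                date_last_evaluated=_parse_clinvar_date(cells[idx["DateLastEvaluated"]])
                if "DateLastEvaluated" in idx
                else None,
                assertion_criteria_provided=_submission_criteria_provided(
                    cells[idx["ReviewStatus"]]
                )
                if "ReviewStatus" in idx
                else True,
                concept_ids=frozenset(_CONCEPT_RE.findall(phenotype)),
                submitter=cells[idx["Submitter"]] if "Submitter" in idx else "",
            )
            submissions.setdefault(vid, []).append(rec)

    return assertions, submissions


def stars_from_review_status_cached(status: str) -> int:
    # thin indirection so io_formats does not import clinvar_engine at top
    # level in both directions
    from .clinvar_engine import stars_from_review_status

    return stars_from_review_status(status)


def read_concept_id_list(path: str) -> FrozenSet[str]:
    """One MedGen Concept ID per line; '#' comments and blanks ignored."""
    ids = set()
    with _open_text(path) as fh:
        for line in fh:
            token = line.strip()
            if not token or token.startswith("#"):
                continue
            ids.add(token)
    return frozenset(ids)


# --- Output tables --------------------------------------------------------------


@dataclass
class ResultRow:
    """One classified variant, ready for serialization."""

    chrom_display: str
    pos: int
    ref: str
    alt: str
    gene: str
    transcript: str
    final: "object"  # FinalCall; typed loosely to avoid a circular import hint
    csq_vep: str = ""
    vcf_info: str = ""
    annovar: Dict[str, str] = field(default_factory=dict)
    intervar_evidence: str = ""
    intervar_original_call: str = ""
    autopvs1_strength: str = ""
    autopvs1_criterion: str = ""


ABRIDGED_COLUMNS = [
    "chr",
    "start",
    "ref",
    "alt",
    "gene",
    "transcript",
    "autogvp_call",
    "call_source",
    "clinvar_stars",
    "resolution_method",
]


def write_outputs(rows: Sequence[ResultRow], out_prefix: str) -> Tuple[str, str]:
    """Write the abridged and full TSVs; returns their paths.

    Row order is preserved; text is UTF-8 with LF endings; the star cell is
    empty for InterVar-sourced calls.
    """
    abridged_path = f"{out_prefix}.autogvp_abridged.tsv"
    full_path = f"{out_prefix}.autogvp_full.tsv"

    annovar_cols: List[str] = []
    seen = set()
    for row in rows:
        for name in row.annovar:
            if name not in seen:
                seen.add(name)
                annovar_cols.append(name)

    def abridged_cells(row: ResultRow) -> List[str]:
        fc = row.final
        stars = "" if fc.stars is None else str(fc.stars)
        return [
            row.chrom_display,
            str(row.pos),
            row.ref,
            row.alt,
            row.gene,
            row.transcript,
            fc.call.value,
            fc.source,
            stars,
            fc.resolution_method,
        ]

    with open(abridged_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(ABRIDGED_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(abridged_cells(row)) + "\n")

    full_columns = ABRIDGED_COLUMNS + [
        "notes",
        "csq_vep",
        "vcf_info",
        "intervar_call",
        "intervar_evidence",
        "autopvs1_strength",
        "autopvs1_criterion",
    ] + [f"ANNOVAR_{c}" for c in annovar_cols]
    with open(full_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(full_columns) + "\n")
        for row in rows:
            cells = abridged_cells(row) + [
                row.final.notes,
                row.csq_vep,
                row.vcf_info,
                row.intervar_original_call,
                row.intervar_evidence,
                row.autopvs1_strength,
                row.autopvs1_criterion,
            ] + [row.annovar.get(c, "") for c in annovar_cols]
            fh.write("\t".join(cells) + "\n")

    return abridged_path, full_path
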