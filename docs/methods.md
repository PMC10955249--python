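# Methods

## Classification model

The package assigns each germline variant one of five calls,
P > LP > VUS > LB > B (a total severity order used throughout), by a
two-tier hierarchy: curated ClinVar knowledge when it is trustworthy enough,
and rule-based ACMG-AMP evidence combination otherwise.

### ClinVar tier

ClinVar's review status is mapped to its 0–4 star confidence scale with a
fixed vocabulary table (`practice guideline` → 4, `reviewed by expert
panel` → 3, `criteria provided, multiple submitters, no conflicts` → 2,
single-submitter and conflicting statuses → 1, the `no assertion …` family
→ 0).  The mapping is deliberately closed: an unrecognized status raises
instead of defaulting to 0 stars, because a silent downgrade would quietly
reroute variants to the rule-based tier when ClinVar revises its
vocabulary (as it did when "conflicting interpretations" became
"conflicting classifications"; both spellings are mapped).

Aggregate significance strings are normalized case-insensitively onto the
five-level scale.  The combined aggregates `Pathogenic/Likely pathogenic`
and `Benign/Likely benign` map to the *weaker* member (LP, LB): the
combined label asserts no more than its weaker half, so taking the stronger
one would manufacture certainty.  Everything else — `drug response`,
`risk factor`, `Affects|risk_factor`, association strings, compound values
with modifiers — is non-standard and treated as *no ClinVar
classification*, as are all zero-star records.

**Conflict resolution** (1 star, conflicting interpretations) works on the
individual submissions of the variation:

1. drop submissions with no assertion criteria;
2. drop submissions whose significance is non-standard (a `drug response`
   vote cannot be tallied on a five-level scale);
3. if a MedGen Concept-ID list was supplied, keep only submissions whose
   reported condition intersects it (filtering happens before the majority
   attempt, so a disease-specific list can itself create the majority);
4. if nothing remains the conflict is unresolved and the variant falls to
   the rule-based tier;
5. a strict plurality — the unique most frequent call — wins.  Majority is
   plurality, not >50%: it maximizes the number of deterministically
   resolved conflicts without inventing a quorum rule.  P and LP are
   counted as distinct calls for the same reason the output scale is
   five-valued;
6. ties fall to the tiebreak: **latest** takes the call of the most
   recently evaluated submission (dateless submissions sort below any dated
   one; ties on the winning date, and the all-dateless case, resolve to the
   most severe call among the tied submissions, giving a deterministic
   total order), **most_severe** takes the severity maximum of the
   remaining candidates.  By construction the most-severe resolution is
   never less severe than the latest one over the same candidate set — a
   property the test suite checks on random submission sets.

### Rule-based tier (modified InterVar)

InterVar's printed evidence vector is parsed positionally (PS list slots
1–4 are PS1–PS4, and so on); the surplus reserved slots newer InterVar
versions print are ignored, and values above 1 (locally upgraded evidence)
count as "set".  Two corrections are applied before re-combination:

* **PP5/BP6 removal.**  The reputable-source criteria are cleared outright.
  ClinVar is consulted directly in the first tier, so keeping PP5/BP6 would
  double-count the same assertions — and, notably, lets a variant whose
  only support was PVS1 + PP5 drop to VUS.
* **PVS1 strength adjustment.**  InterVar applies PVS1 at full weight to
  every loss-of-function variant in a LOF-intolerant gene; refined guidance
  grades it VeryStrong/Strong/Moderate/Supporting/unmet by predicted
  consequence.  The AutoPVS1 grade replaces InterVar's flag, contributing
  to the corresponding evidence bucket.  The adjustment is **demote-only**:
  when InterVar did not set PVS1 the grade is ignored (the correction
  targets over-calling, and upgrading would be a new rule), and a variant
  missing from the AutoPVS1 table keeps full strength with a warning.  The
  two corrections touch disjoint fields and commute.

The call is re-derived from bucket counts (very-strong/strong/moderate/
supporting; stand-alone/strong-benign/supporting-benign) using the standard
ACMG-AMP combining table, implemented with lower-bound thresholds.  If both
a pathogenic-group and a benign-group rule fire, the evidence is
contradictory and the call is VUS.  The implementation is diff-tested
exhaustively (~47 000 bounded count tuples) against an independently
written brute-force transcription of the table, and is monotone: clearing
any single pathogenic criterion never moves a call toward P, clearing any
benign criterion never moves it toward B.  The shipped modification can
only demote or preserve calls relative to raw InterVar on the pathogenic
side; the guarantee is stated with BP6 clear, since deleting benign-side
evidence necessarily pushes severity up.

## Joining the four annotation tables

All tables are joined on a normalized variant key: `chr` prefix stripped
(re-emitted on output in the input VCF's style), alleles uppercased and
reduced to minimal representation (shared suffix trimmed first, then shared
prefix, advancing the position).  Minimal representation is not full
left-alignment: a homopolymer indel reported at different anchor points
keeps its reported anchor.  Since every per-sample input file descends from
the same VCF this cannot desynchronize a join; it only matters if inputs
from different normalization pipelines are mixed.  Multi-allelic records
are rejected with instructions to pre-split rather than split silently,
which could desynchronize the four files.

InterVar rows inherit ANNOVAR's shifted indel coordinates and `-` alleles;
they are joined by converting each VCF key to its ANNOVAR representation.
The ANNOVAR multianno table itself is read only for pass-through annotation
columns — classification never depends on it — and its join key is taken
from the original VCF record embedded in the `--vcfinput` Otherinfo
columns, not from ANNOVAR's Start/End.  The ClinVar VCF supplies the
key → VariationID mapping; `variant_summary` is the per-assembly authority
for aggregate significance and review status (rows for the other assembly
are dropped; disagreements with the ClinVar VCF's own INFO fields are
logged and `variant_summary` wins).  The transcript reported per variant is
the AutoPVS1 transcript when it matches a CSQ entry (version-insensitively),
else the CANONICAL/PICK entry, else the first; remaining CSQ entries are
retained in `csq_vep` using VEP's own `|`/`,` encoding.

## Filtering

Only `FILTER == PASS` records are classified.  User criteria
(`--filter_criteria "DP>=10,AF<0.001"`) are conjunctive, evaluated against
INFO first and then the single sample's FORMAT fields; a missing value
fails the criterion (dropped, counted, logged) rather than passing
silently, and a criterion naming an undeclared field aborts before any
record is touched.  Ordering comparisons on non-numeric values are rejected
at parse time.

## Synthetic data

The fixture generator emits a ~62-variant bundle in which every branch of
the decision tree appears at least once: direct retention at each star
level and for each of the five calls, combined aggregates, every conflict
resolution path (majority, date tiebreak, severity tiebreak, date ties,
dateless sets, Concept-ID filtering, fully excluded conflicts), zero-star
and non-standard states, each rule-based outcome for ClinVar-absent
variants, the PP5 demotion, the five-step PVS1 downgrade ladder, indel
joins, transcript selection, and filter drops.  Expected calls were traced
by hand through the decision tree when the catalog was written and are
stored alongside the inputs; the pipeline must reproduce them exactly under
both tiebreaks and with/without the Concept list.  Variant positions and
alleles are drawn from a seeded generator; gzip members are written with a
zeroed timestamp so bundles are byte-identical across runs.

A GRCh37 decoy row with a deliberately wrong classification accompanies
some `variant_summary` entries, so broken assembly filtering surfaces as a
golden-call mismatch rather than passing unnoticed.

Because the bundle is synthetic and branch-oriented, passing tests
demonstrate the correctness of the decision logic and file-format handling
— not performance or behavior on ClinVar-scale inputs, population-realistic
allele spectra, or malformed third-party files beyond the dialects
generated here.

## Numerical and degenerate-input choices

* Severity is the only numeric scale (B=0 … P=4); there are no floating
  point tolerances anywhere in classification.
* `resolve_conflict` on an empty submission list raises (the caller only
  reaches it for variations flagged conflicting); a conflicting variation
  with no submission records at all falls through with a note.
* A variant absent from both ClinVar and the InterVar table is emitted as
  VUS with a `no_evidence` note, never dropped: downstream tallies must
  conserve the filtered variant universe.
* Readers preserve input order; outputs are UTF-8, LF, tab-separated, and
  deterministic given identical inputs.

## Known limitations

* Gene-specific ClinGen VCEP rule sets are not applied; calls for genes
  with a published VCEP specification should be re-reviewed.
* Germline only; somatic classifications in ClinVar are not modeled.
* Minimal representation without reference-based left-alignment (above).
* The ClinVar review-status and significance vocabularies are closed lists;
  new ClinVar terms require a deliberate mapping update (by design).
* Single-sample VCFs only; multi-sample inputs are rejected.
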