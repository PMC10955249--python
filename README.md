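# autogvp

Automated germline variant pathogenicity classification that integrates
ClinVar assertions with a modified InterVar ACMG-AMP re-scoring into a single
five-level call — Pathogenic (P), Likely Pathogenic (LP), Uncertain
Significance (VUS), Likely Benign (LB), Benign (B) — per variant.

It is aimed at research groups classifying large germline variant sets
(exome/genome cohorts, biobanks) who already run the standard annotation
stack — VEP, ANNOVAR, InterVar, AutoPVS1 — and want a reproducible,
clinically oriented final call that respects current ACMG-AMP guidance.

## What it computes

For each PASS variant of a VEP-annotated VCF, the call is decided by a
hierarchical decision tree:

1. **ClinVar first.** The aggregate ClinVar classification is retained
   outright when its review status carries ≥ 2 stars, or 1 star from a
   single criteria-based submitter.
2. **1-star conflicts are resolved** from the individual submissions:
   submissions without assertion criteria or with calls not expressible on
   the P/LP/VUS/LB/B scale are excluded; an optional MedGen Concept-ID list
   restricts submissions to a disease of interest; a strict-plurality
   majority wins; remaining ties are broken by the most recently evaluated
   submission (`--latest`, the default) or the most severe call
   (`--most_severe`, under the order P > LP > VUS > LB > B).
3. **Zero-star and non-standard** ClinVar states (e.g. `Affects|risk_factor`,
   `drug response`) count as *no ClinVar classification*.
4. **Otherwise, modified InterVar decides.** InterVar's per-variant evidence
   vector (PVS1, PS1–4, PM1–6, PP1–5, BA1, BS1–4, BP1–7) is re-combined
   after two corrections:
   * the deprecated reputable-source criteria **PP5/BP6 are removed**
     (ClinVar evidence is consulted directly and must not be double
     counted), and
   * **PVS1 is re-weighted** to the graded strength reported by AutoPVS1
     (PVS1 / PVS1_Strong / PVS1_Moderate / PVS1_Supporting / unmet), never
     upgrading a variant InterVar did not flag.

   The five-level call is then re-derived with the standard ACMG-AMP
   evidence-combining rules; simultaneously satisfied pathogenic and benign
   rules yield VUS (contradictory evidence).

Two TSVs are written per run: an abridged table (coordinates, gene,
transcript, call, call source, stars, resolution method) and a full table
adding VCF INFO, ANNOVAR annotations, the InterVar evidence string, AutoPVS1
columns, and the retained extra transcript annotations (`csq_vep`).

## Worked example

The package ships a synthetic-data generator that emits a coherent miniature
bundle of all seven inputs plus a hand-traced table of expected calls:

```bash
autogvp make-fixtures --out demo --seed 7
autogvp run \
  --vcf demo/test_VEP.vcf \
  --multianno demo/test_hg38_multianno.txt \
  --intervar demo/test_multianno.txt.intervar \
  --autopvs1 demo/test_autopvs1.txt \
  --clinvar-vcf demo/clinvar.vcf.gz \
  --variant-summary demo/variant_summary.txt.gz \
  --submission-summary demo/submission_summary.txt.gz \
  --conceptID_list demo/concept_ids.txt \
  --latest --out-prefix demo/out
```

First lines of `demo/out.autogvp_abridged.tsv`:

```
chr	start	ref	alt	gene	transcript	autogvp_call	call_source	clinvar_stars	resolution_method
chr1	1000943	G	T	GENE000	ENST00000000.2	P	ClinVar	4	direct
chr2	1001577	T	A	GENE001	ENST00000010.2	LP	ClinVar	3	direct
chr3	1002055	C	T	GENE002	ENST00000020.2	VUS	ClinVar	2	direct
```

Each row is one classified variant: the first is retained directly from a
4-star ClinVar assertion, the others from 3- and 2-star assertions.  The
machine-readable summary (`demo/out.summary.log`) reports the branch counts:

```
n_input=62
n_kept=60
n_intervar_rows_unmatched=2
n_clinvar_conflicts_resolved=22
n_clinvar_conflicts_unresolved=3
n_dropped_not_pass=2
n_call_ClinVar_direct=17
n_call_ClinVar_latest=12
```

i.e. of 62 input records, 60 pass filtering; 17 calls are direct ClinVar
retentions, 12 come from conflicts broken by the most recent submission, and
the 3 unresolved conflicts fall through to the modified-InterVar classifier.
The conflict-resolution pre-step can also be run on its own
(`autogvp select-submissions …`), writing the per-variation resolution table.

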