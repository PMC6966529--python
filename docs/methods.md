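# Methods

## Model

`somaclass` implements somatic variant interpretation as a deterministic
decision cascade rather than a statistical model. The underlying assumptions
are the standard ones for targeted tumour NGS panels: calls arrive already
annotated at the transcript level (HGVS c. and p. with a versioned accession);
the biological contribution of a variant to tumorigenesis is independent of
the tumour type, while its clinical meaning is not; and curated evidence
(hotspot consensus lists, database entry counts, in-silico predictions,
functional-study and database verdicts, population frequencies) can be frozen
into offline snapshot tables without changing the decision semantics. Within
one run the engine is a pure function of (record, snapshots, knowledge
tables, configuration), which is what makes results reproducible from the
manifest.

Stage order is fixed: technical filter → population frequency → gene-specific
exceptions → consensus hotspot → clear-LoF routing → scoring table. The
exceptions run before the hotspot stage because they exist precisely to take
their genes out of the general workflow; to preserve the invariant that a
consensus-hotspot hit always ends Pathogenic, the TP53 handler first checks
the hotspot table and declines to claim hotspot residues.

## Parameters that matter

All thresholds live in `LabConfig`, in the units used internally
(fractions in [0, 1] for VAF and MAF):

| parameter | default | meaning |
|---|---|---|
| `vaf_min` | 0.05 | panel-validated VAF floor; relaxable per validated site |
| `depth_min` | 500 | minimum read depth at the call |
| `recurrence_fraction` | 0.10 | run-level artefact threshold (fraction of samples) |
| `maf_likely_benign` | 0.001 | strict lower MAF bound for Likely Benign |
| `maf_benign` | 0.01 | MAF at or above which a variant is Benign |
| `min_allele_number` | 2000 | alleles a population needs to be eligible |
| `germline_het_band` | (0.40, 0.60) | "close to 50%" heterozygous band |
| `germline_hom_band` | (0.90, 1.00) | "close to 100%" homozygous band |
| `regional_benign_min_samples` | 3 | distinct samples for the regional-benign call |
| `cebpa_bzip_span` | (278, 358) | protein interval treated as the CEBPA bZIP domain |

The MAF band is encoded with a strict lower bound: a variant at exactly 0.1%
is *not* (Likely) Benign and continues through the workflow. The COSMIC
entry-count bands are half-open — solid: [50, ∞) → +2, (10, 50) → +1,
[0, 10] → 0; haematological: [10, ∞) → +2, (5, 10) → +1, [0, 5] → 0 — so the
printed boundary counts (10 solid, 5 haematological) score 0. Scores are
half-unit rationals; every reachable total is a multiple of 0.5 and exact in
floating point, so class boundaries are compared with plain `>=`.

## Design choices where the design was open

- **"Close to 50% / 100%"** is quantified as the two configurable bands
  above; no tolerance is published, and labs can tighten them.
- **Region cells** in the hotspot tables distinguish containment spans
  ("X-Y": the whole reported change must lie inside) from exact spans
  ("X_Y": both endpoints must match); the distinction is recovered from the
  verbatim cell text each entry retains.
- **Any-missense hotspot cells** (MPL W515) match missense substitutions
  only; a nonsense change at the same residue is not a hotspot hit and routes
  through LoF logic instead.
- **TP53 database disagreement** has no published tie rule: the handler falls
  through to the general workflow and sets a `manual_review` flag rather than
  guessing. TP53 synonymous calls are exempt from the synonymous drop so they
  can be database-checked; without a consensus they are VUS with the same
  flag.
- **BRCA1/2 non-LoF variants** take the dedicated-database verdict; the
  aggregated verdict pairs "(Likely) Pathogenic" / "(Likely) Benign" are
  mapped to the conservative member of each pair (Likely Pathogenic, Likely
  Benign). Last-exon LoF cannot be distinguished without a gene model, and
  since all clear LoF in these genes is Pathogenic anyway, no last-exon
  special case exists.
- **Strongly negative scores** (total ≤ −1) still return VUS, not Likely
  Benign: the printed class rule for the scoring table has exactly two
  outcomes, and benign demotion is reserved for population evidence and the
  regional-benign check.
- **Overrides** are curated upward-only reclassifications with provenance;
  an override that would lower a class is rejected as an input error.
- **CEBPA bZIP boundaries** are not published; the packaged default
  (residues 278–358 of the full-length p42 protein) covers the C-terminal
  basic leucine-zipper and is configurable.
- **Class switches**: the local store is append-only; downgrades surface in
  the diff report with an expert-review flag.

## Synthetic data

The fixture generator (`somaclass.fixtures`) emulates the flat-file inputs
of a diagnostic batch: calls with VAF/depth, transcript-level annotations,
per-variant population and evidence snapshots, a lab configuration, an
observation log and an override table. Each generated case belongs to one
workflow branch, and its expected class is fixed by that branch at
construction time — the engine is never consulted while generating, so
engine-agreement tests cannot self-confirm. Well-known worked examples (the
ALK Pro1599His African-population case, EGFR Ser768Ile / Leu858Arg /
Leu747Pro, KRAS Asp57Asn / Gly115*, TET2 Ser1870* / Thr822Pro, the type-I
CALR deletion, the ASXL1 c.1934dup stutter, and others) are embedded
verbatim; randomized fields (VAF, depth, MAF, allele numbers) are drawn
uniformly inside branch-legal intervals from a seeded generator, and kept
branches avoid the germline VAF bands so no incidental flags blur the truth
labels. Default batch size is 8 cases per branch over 29 branches (232
cases), which covers every rule identifier the engine can emit.

What the generator does **not** emulate: read-level artefacts (strand bias,
alignment error), realistic mutational signatures, indel normalisation
ambiguity, multi-nucleotide neighbouring variants, and annotation
disagreements between transcript versions. Passing the fixture suite
therefore demonstrates that the decision logic is implemented as specified,
not that upstream calling and annotation are reliable.

## Numerical and degenerate-input choices

- An empty population snapshot, an unknown variant in the evidence table, or
  an unknown gene role never raise: they degrade to "no evidence" states
  that route the variant toward VUS with review flags where appropriate.
- Unparseable protein HGVS raises a named parse error; it is never silently
  coerced to VUS, because a bad three-letter/one-letter conversion is a known
  source of wrong hotspot lookups.
- Hotspot matching resolves ties by match-kind specificity (exact residue >
  residue region > exon event > any-clear-LoF > splice event), then label,
  so results are independent of table row order.
- Batch results are sorted by (sample, gene, cDNA); re-runs are
  byte-identical and input row order is irrelevant.

## Limitations

The engine classifies; it does not call, align, annotate or visually review.
Evidence snapshots reflect whatever database state the lab exported — the
package has no opinion on currency. Clinical evidence levels (A–D) are
expert curation supplied as input; only the hard tier constraints are
enforced. The conditional-tier rule table ships with a single packaged rule
(the EGFR Leu747Pro resistance example) and is meant to be extended by the
lab.
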