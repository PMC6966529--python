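# somaclass

Rule-based two-level classification of somatic tumour variants detected by
targeted NGS: a tumour-type-independent **biological class** (Benign, Likely
Benign, VUS, Likely Pathogenic, Pathogenic) followed by a tumour-type-dependent
**clinical tier** (ACMG/AMP Tier I–IV), with auditable rule trails and clinical
report rendering.

## Who this is for

Molecular diagnostic laboratories interpret thousands of somatic calls per
year, and without a shared procedure the same variant routinely receives
different classes in different labs. `somaclass` encodes one consensus
workflow as a deterministic rule engine: every decision is driven by explicit
thresholds and curated tables, every result carries the ordered list of rules
that produced it, and the whole pipeline runs offline against snapshot tables
(no live database queries ever).

## The workflow

Each annotated call passes through a fixed cascade; the first stage that
yields a class terminates it:

1. **Technical filter** — drop intronic calls (outside the ±1/±2 AG/GT core
   splice positions), stand-alone synonymous changes, recurrent artefacts
   (lab blacklist or seen in ≥10% of the run's samples, hotspots exempt),
   short-tandem-repeat stutter below a validated site threshold, and calls
   under the VAF (default 5%) or depth (default 500×) gates. Sub-threshold
   hotspot or tumour-suppressor-LoF candidates are surfaced for re-analysis.
2. **Population frequency** — with m the maximum ethnic minor allele
   frequency over populations with ≥2000 interrogated alleles:
   m ≥ 1% → Benign; 0.1% < m < 1% → Likely Benign; otherwise continue.
   Database-negative calls at germline-like VAF (~50% or ~100%) are flagged.
3. **Gene-specific exceptions** — TP53 (dedicated-database consensus; core
   splice → Likely Pathogenic), BRCA1/2 (clear LoF → Pathogenic, otherwise
   the dedicated database verdict), CALR exon-9 and NPM1 exon-11 out-of-frame
   indels → Pathogenic, CEBPA bZIP in-frame indels → Likely Pathogenic,
   MET exon-14 splice → Pathogenic, and a regional-benign check against the
   lab's observation history.
4. **Consensus hotspot (CPV) match** — curated per-category hotspot tables
   (exact residue, residue region, exon-level event, any-clear-LoF, splice
   event, in decreasing specificity); a hit is Pathogenic.
5. **Clear-LoF routing** — frameshift / nonsense / core-splice variants:
   tumour suppressor → Likely Pathogenic, oncogene → VUS.
6. **Scoring table** — remaining missense and in-frame indels receive an
   additive four-parameter score:

   | parameter | +2 | +1 | +0.5 | 0 | −1 |
   |---|---|---|---|---|---|
   | COSMIC entries (solid) | ≥50 | 10<n<50 | | ≤10 | |
   | COSMIC entries (haem.) | ≥10 | 5<n<10 | | ≤5 | |
   | SIFT & MutationTaster | | | both damaging | other | |
   | functional studies | | | harmful | not reported | shown benign |
   | genomic databases | | | (L)Pathogenic | not described | (L)Benign |

   Total ≥ 2 → Likely Pathogenic, < 2 → VUS; in genes outside the hotspot
   lists, the maximal total of +3.5 → Pathogenic. Curated overrides may raise
   (never lower) a class.

Clinical tiers are then constrained by the biological class: (Likely) Benign
⇒ Tier IV and never reported; VUS ⇒ Tier III, reported only in a disclaimed
annex; (Likely) Pathogenic ⇒ Tier I with level A/B evidence, Tier II with
C/D, Tier III without. Evidence levels are clinical curation and arrive as
input.

## Worked example

```python
import somaclass as sc

kb = sc.KnowledgeBase.load()
record = sc.VariantRecord(
    sample_id="S1", chrom="chr7", pos=55191822, ref="T", alt="G",
    vaf=0.22, depth=1480, gene="EGFR", transcript="NM_005228.4",
    cdna_hgvs="c.2573T>G", protein_hgvs="p.(Leu858Arg)",
    consequence=sc.Consequence.MISSENSE,
    tumour_category=sc.TumourCategory.SOLID, tumour_type="NSCLC",
)
result, decision = sc.classify_record(
    record, sc.PopulationFrequencySnapshot(), sc.EvidenceBundle(),
    kb, sc.LabConfig(),
)
print(result.biological_class.value)
for t in result.rule_trail:
    print(f"  {t.rule_id}: {t.outcome}  {t.detail}")
print("Tier", sc.assign_tier(result.biological_class, sc.EvidenceLevel.A).tier.value)
```

prints

```
Pathogenic
  BOX1-DROP: pass
  BOX2-POPULATION: none  no eligible MAF above 0.1%
  BOX3-CPV: Pathogenic  matched consensus hotspot: L858R
Tier I
```

The EGFR Leu858Arg call at 22% VAF and 1480× depth passes the quality gates,
is absent from population data, matches the curated L858R hotspot and is
therefore Pathogenic; with level-A clinical evidence in lung adenocarcinoma
it reports as Tier I.

The same engine runs from the shell over batch files:

```
somaclass fixtures generate --seed 42 --n-per-branch 2 --out batch
somaclass classify --calls batch/calls.tsv --annotations batch/annotations.tsv \
    --popfreq batch/popfreq.tsv --evidence batch/evidence.tsv \
    --config batch/config.yaml --observations batch/observations.tsv \
    --overrides batch/overrides.tsv --out out
# classified 46/58 records (skipped joins: 0) → out
```

`out/results.tsv` then holds one classified row per kept call, e.g.

```
sample_id  gene  transcript      cdna_hgvs  biological_class  terminal_rule    score_total
S0012      ALK   NM_004304.4     c.4796C>A  Likely Benign     BOX2-POPULATION  .
S0016      DNMT3A NM_175629.2    c.955G>A   VUS               BOX5-SCORE       0
```

together with `manifest.json` (thresholds, table versions, counts),
`review_queue.tsv` (flagged calls) and `reanalysis.tsv` (sub-threshold
hotspot candidates).

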