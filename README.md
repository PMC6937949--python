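# varitriage

Desk-scale, fully testable clinical variant triage: from a raw VCF through
annotation, automated ACMG/AMP classification, phenotype-keyword gene
prioritization, inheritance-model filtering and structural-variant
scoring, to a versioned clinical report — with every knowledgebase input
emulated by a deterministic synthetic-data generator, so the whole
pipeline runs and is verifiable with no downloads.

It is aimed at people who build or evaluate clinical-genetics analysis
pipelines: each stage that commercial interpretation platforms run as an
opaque service is reimplemented here as a small, inspectable, unit-tested
component operating on plain text files.

## What it computes

**Ingestion.** VCFs are sanitized line-by-line (non-canonical chromosomes
dropped, missing `DP`/`DP4` header definitions injected, stale annotation
INFO keys stripped, malformed lines skipped and logged), restricted to BED
regions, decomposed into biallelic records, and indels are left-aligned
and trimmed to their parsimonious representation.

**Annotation** attaches seven categories to each variant: genomic/genetic
data, calling quality and reliability, clinical evidence (assertion
matches and the phenotype score), effect and prediction (a strand-aware
codon-level consequence caller plus a majority consensus over emulated
prediction tools and the ACMG class), control-population frequencies
(filterable as `max_af` over sources), and in-house / sharing-group allele
frequencies from the case store.

**ACMG classification** auto-assigns twelve criteria decidable from local
tables (PVS1, PS1, PM2, PM4, PM5, PP3, PP5, BA1, BS1, BP4, BP6, BP7) and
combines them with the 2015 guideline rules into the five classes;
evidence on both sides yields *uncertain significance*.

**Phenotype prioritization** scores each gene's sectioned document against
the case keywords,

    direct(g) = (|matched terms| / |terms|) · Σ_s w_s · log2(1 + hits_s)
    indirect(g) = max_n  w(g,n) · 0.5 · direct(n),   total = max(direct, indirect)

with evidence snippets ("MiniCards") quoting each hit in context.

**Genetic models** apply logged filter cascades (zygosity, reliability,
frequency, severity) for dominant-HET (with de-novo flagging in trios),
recessive-HOM (Mendelian-violation flagging), compound-HET (in-trans test
from parental transmission), and the incidental-findings panel screen.

**SV module** maps structural events to genes and regulatory elements and
scores each element as

    score = element_confidence · association_confidence · phenotype(target)

maximized over the element's targets, so a distal high-scoring target can
outrank the overlapped host gene; events are ranked by their best entity.

## Worked example

Generate a trio case with a planted de novo stop-gain and analyze it:

```bash
varitriage fixtures --seed 7 --scenario de_novo_dominant --out case/
varitriage analyze --case case/ --out out/
```

The dominant-HET tab of `out/report.md` contains exactly one candidate:

```
### 1:887 G>T (GENE01)

- effect: stop_gained p.E36*
- severity tier: HIGH
- control max AF: 0.0
- ACMG: likely_pathogenic (PVS1, PM2)
- phenotype score: 12.0 (matched: short stature, skeletal dysplasia)
```

and the methods section documents the cascade that produced it: 127
sanitized variants → 40 heterozygous in the proband → 40 reliable → 1
below the 0.1% frequency cutoff → 1 with HIGH/MODERATE predicted effect.
The variant is flagged `de_novo` because both parents are confidently
homozygous reference, it gets PVS1 (null effect in a loss-of-function
gene) and PM2 (absent from controls), and its phenotype score of 12.0 is
the section-weighted log score of the two matched keywords in the GENE01
disorders and phenotypes sections. Every report ends with a version
manifest listing each knowledge table with its version string and
checksum.

Account-level statistics come from the case store:

```bash
varitriage stats --store store/ --classes classes.yaml
```

prints per-phenotype-class totals, resolved counts (a case counts as
resolved when any selected variant is marked High or Med relevance) and
the resolution percentage.

## Layout

- `src/varitriage/vcf_ingest.py` — sanitization, regions, splitting, normalization
- `src/varitriage/annotate.py` — consequence caller, frequency/assertion/prediction tables
- `src/varitriage/acmg.py` — criterion assignment and class combination
- `src/varitriage/phenotyper.py` — keyword scoring, gene links, MiniCards
- `src/varitriage/genetic_models.py` — protocols, cascades, inheritance models
- `src/varitriage/sv.py` — SV→gene/element mapping and event ranking
- `src/varitriage/case_store.py` — case persistence, in-house AF, account stats
- `src/varitriage/report.py` — JSON/Markdown reports, variant-table export
- `src/varitriage/fixtures.py` — synthetic genome, knowledgebase and cases
- `src/varitriage/pipeline.py` — end-to-end orchestration
- `docs/methods.md` — model assumptions, parameter defaults, limitations
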