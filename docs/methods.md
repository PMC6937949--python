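# Methods

This note documents the procedures, parameter defaults and design choices
behind varitriage, and what the synthetic study conditions do and do not
establish about behavior on real data.

## Coordinate and naming conventions

All internal positions are 1-based inclusive (the VCF convention); BED
input is converted from 0-based half-open at the I/O boundary, so a
variant at position *p* falls in BED interval `[start, end)` iff
`start < p ≤ end`. Chromosome names are normalized to prefix-free form
("1", "X", "MT") before any comparison or table join; this removes the
most common source of silent join misses between `chr1`- and `1`-style
resources.

## Sanitization

The sanitizer is a line-level pass rather than an htslib parse, because it
must repair inputs htslib rejects: it injects missing `DP`/`DP4` header
definitions, drops records on non-canonical chromosomes, strips
pre-existing annotation INFO keys (`ANN`, `EFF`, `CSQ`, `LOF`, `NMD`), and
skips malformed record lines individually, counting each drop by reason.
Only systemic malformation — more than half of all record lines bad —
aborts the run. Pipeline order is fixed as sanitize → region filter →
multi-allelic split → normalize; splitting after region filtering is safe
because splitting never changes a record's position.

Multi-allelic decomposition re-expresses each sample's genotype relative
to one alternative allele per output record; per-allele `AD` counts follow
their allele and total depth is shared, so read support is conserved.
Indel normalization right-trims shared suffixes (extending left from the
reference when an allele would become empty) and then left-trims shared
prefixes — the standard left-align-and-parsimony algorithm; it is
idempotent and haplotype-preserving.

## Consequence calling

The caller operates on explicit transcript models (sorted non-overlapping
exons, CDS bounds; fixture CDS lengths are multiples of 3). CDS SNVs are
translated codon-wise, honoring strand; classification compares the
reference and mutated residue (synonymous / missense / stop-gained /
start-lost). Indels touching the CDS are classified by length modulo 3
(frameshift vs in-frame). Intronic positions within 2 bp of an exon
boundary are splice donor/acceptor (direction strand-aware); 3–8 bp are
splice region. Effects map to fixed severity tiers (HIGH for null effects,
MODERATE for missense/in-frame, LOW for synonymous/splice-region, MODIFIER
otherwise), and per-transcript calls merge to the single worst call with a
documented tie-break: tier, then a fixed effect order, then transcript id.
There are no splice-strength models, UTR-regulatory effects or
protein-structure features; "utr" and "intronic" are terminal categories.

## Frequencies, assertions, predictions

Control-population frequencies are per-source columns in a TSV keyed by
the normalized variant; the filterable quantity is `max_af`, the maximum
over sources present, with 0 meaning absent everywhere. Damage-prediction
consensus is a majority rule over non-abstaining tools requiring at least
two votes ("damaging" / "tolerated", otherwise "mixed", "unknown" when all
abstain). Clinical assertions use a closed five-value significance
vocabulary; a per-gene assertion pool supports residue-level lookups.

## ACMG classification

Twelve criteria decidable from local tables are auto-assigned:

| criterion | trigger |
|---|---|
| PVS1 | HIGH-tier null effect in a gene with a curated LOF mechanism |
| PS1 | same amino-acid change as a pathogenic assertion |
| PM5 | different change at a residue with a pathogenic assertion |
| PM2 | `max_af` < 1e-5 (numeric proxy for "absent from controls") |
| PM4 | in-frame indel |
| PP3 / BP4 | prediction consensus damaging / tolerated |
| PP5 / BP6 | conflict-free reported pathogenic / benign assertion |
| BA1 | `max_af` ≥ 0.05 |
| BS1 | `max_af` ≥ the per-gene disease frequency cutoff (below BA1) |
| BP7 | synonymous with no splice-region call |

Criteria needing segregation data, functional assays or confirmed de novo
status are deliberately not auto-assigned; they are analyst judgment.
Criteria whose annotation block is missing are withheld and logged, never
guessed. Combination follows the 2015 guideline rule table; any
pathogenic-side criterion together with any benign-side criterion yields
*uncertain significance* (the contradiction clause, applied at the
evidence level). The combiner is verified against an independent
enumeration over all 4096 criterion subsets, including monotonicity:
adding pathogenic-side evidence never moves the class toward benign and
vice versa.

## Phenotype scoring

Gene documents have six sections with default weights: disorders 3.0,
phenotypes 3.0, summaries 2.0, function 1.5, pathways 1.0, publications
1.0 (configurable). Matching is whole-word, case-insensitive, phrase-exact
— no stemming, synonyms or ontology expansion; at this scale
reproducibility is preferred to recall. The direct score is
`coverage · Σ_s w_s · log2(1 + hits_s)` with coverage the matched-term
fraction under OR semantics (an AND query scores zero unless every term
appears). The log saturation keeps a single verbose section from
dominating; coverage rewards genes matching more of the phenotype list.
The indirect ("guilt by association") score takes one hop over gene–gene
links with a fixed damping of 0.5 and reports the best neighbor; one hop
keeps scores interpretable and is the deliberate stand-in for an
unpublished proprietary ranking — the formula above *is* this package's
specification of the score. No cross-gene or query-length normalization is
applied. Scores are not comparable across different queries.

## Genetic models

Reliability requires quality ≥ 20, proband depth ≥ 8 and alt-read fraction
≥ 0.2 (all configurable). The default frequency gate is 0.1%, and the
severity gate excludes LOW and MODIFIER tiers. Dominant-HET annotates
(never requires) de novo status: both parents homozygous reference with
depth ≥ 10, else `de_novo_unconfirmed` — parental dropout otherwise
produces false de novos. Recessive-HOM flags Mendelian violations rather
than dropping them. Compound-HET requires ≥ 2 passing HETs per gene and,
with a trio, an in-trans pair by transmitted-allele logic (one variant
carried only by the mother, one only by the father); no read-backed
phasing is attempted, and singleton groups are kept flagged
`phase_unknown`. Hemizygous calls (single-allele genotypes, e.g. male X)
are treated as homozygous-alternative, so X-linked recessive cases surface
in the recessive model. Candidate tables sort by phenotype score
descending with deterministic tie-breaks.

## SV scoring

Events map to genes and regulatory elements by ≥ 1 bp overlap (insertions
act at a point; no flanking window). The element score is the plain
product of element confidence, element–gene association confidence and the
target's phenotype score, maximized over targets — monotone in every
factor, zero when any factor is absent. Inversions are treated as
full-span overlaps; this is a documented simplification, since an
inversion may disrupt only at its two breakpoints. Events rank by best
entity score, ties to the shorter event then coordinate.

## Case store and account statistics

The store is newline-delimited JSON (one case per line) plus a derived
allele-count TSV — diffable and serializable without a database. Allele
counting is diploid (two alleles per genotyped case; one for hemizygous
X), and a case is always excluded from its own in-house frequency to avoid
self-counting. Sharing-group frequencies pool counts across member stores,
so pooling is associative and commutative. Class membership for account
statistics is exact case-insensitive keyword intersection; a case is
resolved when any selected variant carries a High or Med relevance mark,
and percentages are rounded to one decimal.

## Synthetic study conditions

The generator emits, deterministically in the seed: a two-chromosome
genome with twelve multi-exon genes on both strands and verified ORFs; a
knowledgebase in which each scenario's causal gene carries its keywords in
the disorders/phenotypes sections while a decoy gene carries a partial
match in a low-weight section; frequency/assertion/prediction tables; an
intronic regulatory element in GENE10 whose higher-confidence target
GENE09 lies more than 100 kb away (the distal-enhancer geometry, at
reduced scale); and trio cases of ~120 background variants with planted
causal records for five scenarios (de novo dominant, recessive homozygous,
compound heterozygous, incidental panel finding, enhancer-deleting SV).

Background genotypes are drawn by explicit allele transmission
(Mendelian-consistent by construction except planted de novos), and
background allele frequencies are sampled from a Beta(2, 8) truncated
below at 0.005 — so every background variant fails the 0.1% gate and
planted rare variants are separable by construction. Consequently the
planted-truth recovery tests demonstrate the *correctness of the filtering
and ranking logic*, not the diagnostic yield on real data: real exomes
contain rare benign variants, incomplete phenotype matches, and annotation
ambiguity that the generator intentionally omits. Problem sizes (12 genes,
~120 background variants, 20 seeds per scenario) were chosen so the entire
suite exercises every code path while remaining a few-second run.

## Known limitations

No realignment, liftover, somatic subtraction, mosaicism, ROH, CNV-specific
ACMG scoring, or HPO/UMLS expansion. The consequence caller covers the
effect classes the filters consume, not the full sequence-ontology tree.
Report output is JSON and Markdown; PDF/Word conversion is external.
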