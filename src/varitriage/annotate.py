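"""Variant annotation: functional consequence, control-population
frequencies, clinical assertions and damage-prediction consensus.

The consequence caller is a compact, self-contained effect predictor over
explicit transcript models: SNVs inside a CDS are translated codon-wise
(strand-aware), indels are classified by length modulo 3, and positions
within two intronic bases of an exon boundary become splice donor/acceptor
calls.  It deliberately covers only the effect classes the downstream
filters consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

from intervaltree import IntervalTree

from .vcf_ingest import RawVariantRecord, normalize_chrom

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    return "".join(CODON_TABLE[cds[i : i + 3]] for i in range(0, len(cds) - 2, 3))


#: fixed effect → severity-tier mapping; list order is also the documented
#: tie-break order inside a tier (earlier wins).
EFFECT_ORDER = [
    ("stop_gained", "HIGH"),
    ("frameshift", "HIGH"),
    ("splice_acceptor", "HIGH"),
    ("splice_donor", "HIGH"),
    ("start_lost", "HIGH"),
    ("missense", "MODERATE"),
    ("inframe_indel", "MODERATE"),
    ("synonymous", "LOW"),
    ("splice_region", "LOW"),
    ("utr", "MODIFIER"),
    ("intronic", "MODIFIER"),
    ("intergenic", "MODIFIER"),
]
EFFECT_TIER = dict(EFFECT_ORDER)
_EFFECT_RANK = {e: i for i, (e, _) in enumerate(EFFECT_ORDER)}
TIER_RANK = {"HIGH": 0, "MODERATE": 1, "LOW": 2, "MODIFIER": 3}
#: effects that abolish the gene product (null variants)
NULL_EFFECTS = {"stop_gained", "frameshift", "splice_acceptor", "splice_donor", "start_lost"}


@dataclass(frozen=True)
class ConsequenceCall:
    transcript_id: str
    gene_symbol: str
    effect: str
    aa_change: str = ""

    @property
    def severity_tier(self) -> str:
        return EFFECT_TIER[self.effect]


@dataclass
class TranscriptModel:
    """A gene transcript: sorted non-overlapping exons plus CDS bounds,
    all 1-based inclusive on the genomic forward strand."""

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int

    def __post_init__(self):
        self.chrom = normalize_chrom(self.chrom)
        self.exons = sorted(self.exons)
        last = 0
        for s, e in self.exons:
            if s <= last:
                raise ValueError(f"{self.transcript_id}: exons overlap or unsorted")
            if e < s:
                raise ValueError(f"{self.transcript_id}: exon end < start")
            last = e
        if not (
            self.exons[0][0] <= self.cds_start <= self.cds_end <= self.exons[-1][1]
        ):
            raise ValueError(f"{self.transcript_id}: CDS outside exon span")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def cds_intervals(self) -> list[tuple[int, int]]:
        out = []
        for s, e in self.exons:
            s2, e2 = max(s, self.cds_start), min(e, self.cds_end)
            if s2 <= e2:
                out.append((s2, e2))
        return out

    def cds_coordinate(self, pos: int) -> int | None:
        """0-based offset of a genomic position within the spliced CDS, in
        translation order (strand-aware); None when not inside the CDS."""
        offset = 0
        for s, e in self.cds_intervals():
            if s <= pos <= e:
                fwd = offset + (pos - s)
                if self.strand == "+":
                    return fwd
                total = sum(e2 - s2 + 1 for s2, e2 in self.cds_intervals())
                return total - 1 - fwd
            offset += e - s + 1
        return None

    def cds_sequence(self, reference) -> str:
        seq = "".join(
            _fetch(reference, self.chrom, s, e) for s, e in self.cds_intervals()
        )
        return revcomp(seq) if self.strand == "-" else seq


def _fetch(reference, chrom: str, start: int, end: int) -> str:
    if callable(reference):
        return reference(chrom, start, end).upper()
    return str(reference[chrom][start - 1 : end]).upper()


def load_transcripts_tsv(path: str) -> list[TranscriptModel]:
    """Read the transcript table (TSV: transcript_id, gene, chrom, strand,
    exons as comma-joined start-end pairs, cds_start, cds_end)."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            exons = [
                (int(a), int(b))
                for a, b in (p.split("-") for p in row["exons"].split(","))
            ]
            out.append(
                TranscriptModel(
                    row["transcript_id"],
                    row["gene_symbol"],
                    row["chrom"],
                    row["strand"],
                    exons,
                    int(row["cds_start"]),
                    int(row["cds_end"]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# consequence calling


def _splice_call(tx: TranscriptModel, pos: int) -> str | None:
    """Classify an intronic position near an exon boundary.

    Within 2 bp of a boundary: donor at the 5' end of the intron (in
    transcription direction), acceptor at the 3' end.  3–8 bp: splice_region.
    """
    for i in range(len(tx.exons) - 1):
        intron_start = tx.exons[i][1] + 1
        intron_end = tx.exons[i + 1][0] - 1
        if not (intron_start <= pos <= intron_end):
            continue
        d5 = pos - intron_start  # distance from forward-strand 5' intron end
        d3 = intron_end - pos
        if tx.strand == "+":
            near_donor, near_acceptor = d5, d3
        else:
            near_donor, near_acceptor = d3, d5
        if near_donor <= 1:
            return "splice_donor"
        if near_acceptor <= 1:
            return "splice_acceptor"
        if min(d5, d3) <= 7:
            return "splice_region"
        return "intronic"
    return None


def call_consequence(
    variant: RawVariantRecord,
    transcripts: list[TranscriptModel],
    reference,
) -> list[ConsequenceCall]:
    """One consequence call per overlapping transcript; a single intergenic
    call when nothing overlaps.  The variant must be biallelic/normalized."""
    ref, alt, pos = variant.ref, variant.alt, variant.pos
    span_end = pos + len(ref) - 1
    calls = []
    for tx in transcripts:
        if tx.chrom != variant.chrom or span_end < tx.start or pos > tx.end:
            continue
        calls.append(_call_one(variant, tx, reference))
    if not calls:
        calls.append(ConsequenceCall("", "", "intergenic"))
    return calls


def _call_one(
    variant: RawVariantRecord, tx: TranscriptModel, reference
) -> ConsequenceCall:
    ref, alt, pos = variant.ref, variant.alt, variant.pos

    def call(effect, aa=""):
        return ConsequenceCall(tx.transcript_id, tx.gene_symbol, effect, aa)

    if len(ref) != len(alt):  # indel
        # any overlap with the CDS decides coding-indel classification
        span = range(pos, pos + max(len(ref), 1))
        in_cds = any(
            s <= p <= e for p in span for s, e in tx.cds_intervals()
        )
        if in_cds:
            if abs(len(ref) - len(alt)) % 3 == 0:
                return call("inframe_indel")
            return call("frameshift")
        sp = _splice_call(tx, pos)
        if sp:
            return call(sp)
        in_exon = any(s <= pos <= e for s, e in tx.exons)
        return call("utr" if in_exon else "intronic")

    # SNV
    cds_off = tx.cds_coordinate(pos)
    if cds_off is None:
        sp = _splice_call(tx, pos)
        if sp:
            return call(sp)
        in_exon = any(s <= pos <= e for s, e in tx.exons)
        return call("utr" if in_exon else "intronic")

    cds = tx.cds_sequence(reference)
    base = alt if tx.strand == "+" else revcomp(alt)
    mutated = cds[:cds_off] + base + cds[cds_off + 1 :]
    codon_idx = cds_off // 3
    old_codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
    new_codon = mutated[codon_idx * 3 : codon_idx * 3 + 3]
    if len(old_codon) < 3:
        return call("utr")
    old_aa, new_aa = CODON_TABLE[old_codon], CODON_TABLE[new_codon]
    aa = f"p.{old_aa}{codon_idx + 1}{new_aa}"
    if old_aa == new_aa:
        return call("synonymous", aa)
    if codon_idx == 0 and old_aa == "M":
        return call("start_lost", aa)
    if new_aa == "*":
        return call("stop_gained", aa)
    return call("missense", aa)


def merge_transcript_calls(calls: list[ConsequenceCall]) -> ConsequenceCall:
    """Worst call wins: severity tier, then the fixed effect order, then
    lexicographic transcript id."""
    if not calls:
        raise ValueError("no consequence calls to merge")
    return min(
        calls,
        key=lambda c: (
            TIER_RANK[c.severity_tier],
            _EFFECT_RANK[c.effect],
            c.transcript_id,
        ),
    )


# ---------------------------------------------------------------------------
# frequencies

FREQ_SOURCES = ("kg_like", "esp_like", "gnomad_like", "converge_like")


@dataclass
class FrequencyRecord:
    """Per-source control-population allele frequencies."""

    per_source: dict = field(default_factory=dict)

    @property
    def max_af(self) -> float:
        return max(self.per_source.values(), default=0.0)


class FrequencyTable:
    """TSV-backed lookup keyed by normalized (chrom, pos, ref, alt)."""

    def __init__(self, rows: Mapping[tuple, dict]):
        for key, srcs in rows.items():
            for src, af in srcs.items():
                if not 0.0 <= af <= 1.0:
                    raise ValueError(f"AF out of range for {key} {src}: {af}")
        self._rows = dict(rows)

    @classmethod
    def from_tsv(cls, path: str) -> "FrequencyTable":
        rows: dict[tuple, dict] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                row = dict(zip(header, line.rstrip("\n").split("\t")))
                key = (
                    normalize_chrom(row["chrom"]),
                    int(row["pos"]),
                    row["ref"],
                    row["alt"],
                )
                srcs = {
                    c: float(row[c])
                    for c in header[4:]
                    if row.get(c, "") not in ("", ".")
                }
                rows[key] = srcs
        return cls(rows)

    def lookup(self, key: tuple) -> FrequencyRecord:
        return FrequencyRecord(dict(self._rows.get(key, {})))


def attach_frequencies(
    variant: RawVariantRecord, table: FrequencyTable
) -> FrequencyRecord:
    """Pure lookup; a variant absent from every source has ``max_af == 0``."""
    return table.lookup(variant.key)


# ---------------------------------------------------------------------------
# clinical assertions

SIGNIFICANCE_VOCAB = (
    "pathogenic",
    "likely_pathogenic",
    "uncertain",
    "likely_benign",
    "benign",
)


@dataclass(frozen=True)
class ClinicalAssertion:
    source: str
    condition: str
    significance: str
    aa_change: str = ""

    def __post_init__(self):
        if self.significance not in SIGNIFICANCE_VOCAB:
            raise ValueError(f"unknown significance {self.significance!r}")


class AssertionTable:
    """Clinical assertions keyed by variant, with a gene+residue index for
    same-residue lookups."""

    def __init__(self, by_variant: Mapping[tuple, list], by_gene: Mapping[str, list]):
        self.by_variant = dict(by_variant)
        # gene -> list of (aa_change, assertion)
        self.by_gene = dict(by_gene)

    @classmethod
    def from_tsv(cls, path: str) -> "AssertionTable":
        by_variant: dict[tuple, list] = {}
        by_gene: dict[str, list] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                row = dict(zip(header, line.rstrip("\n").split("\t")))
                key = (
                    normalize_chrom(row["chrom"]),
                    int(row["pos"]),
                    row["ref"],
                    row["alt"],
                )
                a = ClinicalAssertion(
                    row["source"], row["condition"], row["significance"],
                    row.get("aa_change", ""),
                )
                by_variant.setdefault(key, []).append(a)
                gene = row.get("gene_symbol", "")
                if gene:
                    by_gene.setdefault(gene, []).append(a)
        return cls(by_variant, by_gene)

    def lookup(self, key: tuple) -> list[ClinicalAssertion]:
        return list(self.by_variant.get(key, []))

    def gene_assertions(self, gene: str) -> list[ClinicalAssertion]:
        return list(self.by_gene.get(gene, []))


# ---------------------------------------------------------------------------
# prediction consensus

PREDICTION_TOOLS = ("sift_like", "polyphen_like", "mutationtaster_like", "gerp_like")


@dataclass
class PredictionProfile:
    verdicts: dict = field(default_factory=dict)  # tool -> damaging/tolerated/unknown

    @property
    def consensus_severity(self) -> str:
        return severity_consensus(self)


def severity_consensus(profile: PredictionProfile) -> str:
    """Majority rule over non-unknown verdicts, requiring at least two
    votes; otherwise mixed; unknown when every tool abstains."""
    votes = [v for v in profile.verdicts.values() if v != "unknown"]
    if not votes:
        return "unknown"
    n_dam = votes.count("damaging")
    n_tol = votes.count("tolerated")
    if len(votes) >= 2 and n_dam * 2 > len(votes):
        return "damaging"
    if len(votes) >= 2 and n_tol * 2 > len(votes):
        return "tolerated"
    return "mixed"


class PredictionTable:
    def __init__(self, rows: Mapping[tuple, dict]):
        self._rows = dict(rows)

    @classmethod
    def from_tsv(cls, path: str) -> "PredictionTable":
        rows: dict[tuple, dict] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                row = dict(zip(header, line.rstrip("\n").split("\t")))
                key = (
                    normalize_chrom(row["chrom"]),
                    int(row["pos"]),
                    row["ref"],
                    row["alt"],
                )
                rows[key] = {c: row[c] for c in header[4:] if row.get(c)}
        return cls(rows)

    def lookup(self, key: tuple) -> PredictionProfile:
        verdicts = dict(self._rows.get(key, {}))
        for tool in PREDICTION_TOOLS:
            verdicts.setdefault(tool, "unknown")
        return PredictionProfile(verdicts)


# ---------------------------------------------------------------------------
# the assembled record


@dataclass
class AnnotatedVariant:
    """A clean biallelic variant carrying every annotation category the
    downstream filters, classifiers and reports consume."""

    record: RawVariantRecord
    gene_symbol: str = ""
    consequence: ConsequenceCall | None = None
    all_calls: list = field(default_factory=list)
    frequency: FrequencyRecord | None = None
    assertions: list = field(default_factory=list)
    #: assertions for other variants in the same gene (residue-level lookups)
    gene_assertion_pool: list = field(default_factory=list)
    predictions: PredictionProfile | None = None
    acmg: object = None  # AcmgAssessment, filled by the acmg module
    phenotype_score: object = None  # PhenotypeScore, filled by the phenotyper
    inhouse_af: float | None = None
    sharing_af: float | None = None
    prior_interpretations: list = field(default_factory=list)
    flags: list = field(default_factory=list)

    @property
    def key(self) -> tuple:
        return self.record.key

    @property
    def max_af(self) -> float | None:
        return self.frequency.max_af if self.frequency is not None else None

    @property
    def severity_tier(self) -> str | None:
        return self.consequence.severity_tier if self.consequence else None

    @property
    def matched_phenotype_count(self) -> int:
        ps = self.phenotype_score
        return len(ps.matched_terms) if ps is not None else 0


class TranscriptIndex:
    """Interval index over transcripts for fast overlap queries."""

    def __init__(self, transcripts: list[TranscriptModel]):
        self.transcripts = transcripts
        self._trees: dict[str, IntervalTree] = {}
        for tx in transcripts:
            self._trees.setdefault(tx.chrom, IntervalTree()).addi(
                tx.start, tx.end + 1, tx
            )

    def overlapping(self, chrom: str, start: int, end: int) -> list[TranscriptModel]:
        tree = self._trees.get(normalize_chrom(chrom))
        if tree is None:
            return []
        return sorted(
            (iv.data for iv in tree.overlap(start, end + 1)),
            key=lambda t: t.transcript_id,
        )


def annotate_variants(
    records: list[RawVariantRecord],
    tx_index: TranscriptIndex,
    reference,
    freq_table: FrequencyTable,
    assertion_table: AssertionTable,
    prediction_table: PredictionTable,
) -> list[AnnotatedVariant]:
    """Run the full annotation pass over normalized biallelic records.

    Calls with the same gene are merged to the single worst call per
    variant–gene pair; the variant-level worst call and its gene become the
    record's primary annotation.
    """
    out = []
    for rec in records:
        span_end = rec.pos + len(rec.ref) - 1
        txs = tx_index.overlapping(rec.chrom, rec.pos, span_end)
        calls = call_consequence(rec, txs, reference) if txs else [
            ConsequenceCall("", "", "intergenic")
        ]
        per_gene: dict[str, list[ConsequenceCall]] = {}
        for c in calls:
            per_gene.setdefault(c.gene_symbol, []).append(c)
        merged = [merge_transcript_calls(cs) for cs in per_gene.values()]
        worst = merge_transcript_calls(merged)
        out.append(
            AnnotatedVariant(
                record=rec,
                gene_symbol=worst.gene_symbol,
                consequence=worst,
                all_calls=calls,
                frequency=attach_frequencies(rec, freq_table),
                assertions=assertion_table.lookup(rec.key),
                gene_assertion_pool=assertion_table.gene_assertions(
                    worst.gene_symbol
                ),
                predictions=prediction_table.lookup(rec.key),
            )
        )
    return out
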