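"""VCF ingestion: sanitization, region filtering, multi-allelic splitting,
indel normalization.

Incoming clinical VCFs arrive in many dialects.  The sanitizer is a
line-level pass that validates structure, injects required-but-missing
header definitions, drops records on non-canonical chromosomes, strips
pre-existing annotation INFO keys, and logs every drop with its reason.
Downstream stages then operate on clean, biallelic, normalized records.

Coordinate conventions: VCF positions are 1-based inclusive and stored
as such internally; BED intervals are 0-based half-open and converted at
the I/O boundary.  Chromosome names are normalized to prefix-free form
("1", "X", "MT") for all internal joins.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping

from intervaltree import IntervalTree

CANONICAL_CHROMS = frozenset(
    [str(i) for i in range(1, 23)] + ["X", "Y", "MT"]
)

#: zygosity vocabulary
HOM_REF = "HOM_REF"
HET = "HET"
HOM_ALT = "HOM_ALT"
MISSING = "MISSING"


def normalize_chrom(name: str) -> str:
    """Strip a ``chr`` prefix and map ``M``→``MT``."""
    n = name[3:] if name.lower().startswith("chr") else name
    return "MT" if n.upper() == "M" else n


@dataclass
class GenotypeCall:
    """One sample's genotype at a site with its quality metrics."""

    sample_id: str
    zygosity: str
    depth: int | None = None
    alt_reads: int | None = None

    @property
    def alt_fraction(self) -> float | None:
        if self.depth and self.alt_reads is not None and self.depth > 0:
            return self.alt_reads / self.depth
        return None


@dataclass
class RawVariantRecord:
    """A single VCF record, possibly multi-allelic."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    qual: float | None = None
    info: dict = field(default_factory=dict)
    genotypes: list[GenotypeCall] = field(default_factory=list)
    #: per-sample allelic depths as parsed from AD (ref first), or None
    allelic_depths: list[tuple[int, ...] | None] = field(default_factory=list)
    #: raw genotype allele indices per sample, e.g. (1, 2)
    gt_indices: list[tuple[int | None, int | None]] = field(default_factory=list)

    @property
    def alt(self) -> str:
        if len(self.alts) != 1:
            raise ValueError("record is not biallelic")
        return self.alts[0]

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Normalized variant key (chrom, pos, ref, alt) for table joins."""
        return (self.chrom, self.pos, self.ref, self.alt)

    def genotype_of(self, sample_id: str) -> GenotypeCall | None:
        for g in self.genotypes:
            if g.sample_id == sample_id:
                return g
        return None


@dataclass
class HeaderPolicy:
    """What the sanitizer guarantees about headers and chromosomes."""

    required_fields: tuple[str, ...] = ("DP", "DP4")
    canonical_chromosomes: frozenset = CANONICAL_CHROMS
    strip_info_keys: tuple[str, ...] = ("ANN", "EFF", "CSQ", "LOF", "NMD")


@dataclass
class SanitationLog:
    """Per-reason drop counts plus free-form warnings."""

    dropped: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    n_input_records: int = 0
    n_retained: int = 0

    def drop(self, reason: str) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + 1

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())

    def to_tsv(self) -> str:
        lines = ["metric\tvalue"]
        lines.append(f"input_records\t{self.n_input_records}")
        lines.append(f"retained_records\t{self.n_retained}")
        for reason in sorted(self.dropped):
            lines.append(f"dropped:{reason}\t{self.dropped[reason]}")
        for w in self.warnings:
            lines.append(f"warning\t{w}")
        return "\n".join(lines) + "\n"


class RegionSet:
    """Indexed genomic intervals from a BED file (0-based half-open)."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]], label: str = ""):
        self.label = label
        self._trees: dict[str, IntervalTree] = {}
        self.intervals = []
        for chrom, start, end in intervals:
            if start >= end:
                raise ValueError(f"empty BED interval {chrom}:{start}-{end}")
            c = normalize_chrom(chrom)
            self.intervals.append((c, start, end))
            self._trees.setdefault(c, IntervalTree()).addi(start, end)

    @classmethod
    def from_bed(cls, path: str, label: str = "") -> "RegionSet":
        ivs = []
        with _open_text(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                ivs.append((parts[0], int(parts[1]), int(parts[2])))
        return cls(ivs, label=label or path)

    def contains(self, chrom: str, pos: int) -> bool:
        """1-based position query: True iff start < pos <= end for some interval."""
        tree = self._trees.get(normalize_chrom(chrom))
        if tree is None:
            return False
        return bool(tree.overlaps(pos - 1, pos))

    def __len__(self) -> int:
        return len(self.intervals)


def _open_text(path: str):
    if str(path).endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


# ---------------------------------------------------------------------------
# sanitization


def _parse_gt_field(gt: str) -> tuple[int | None, int | None]:
    sep = "|" if "|" in gt else "/"
    parts = gt.split(sep)
    out = []
    for p in parts[:2]:
        out.append(None if p in (".", "") else int(p))
    while len(out) < 2:
        out.append(out[0] if out else None)
    return (out[0], out[1])


def _zygosity_from_indices(a: int | None, b: int | None, allele: int = 1) -> str:
    if a is None and b is None:
        return MISSING
    carried = sum(1 for x in (a, b) if x == allele)
    if carried == 2:
        return HOM_ALT
    if carried == 1:
        return HET
    return HOM_REF


def _parse_record_line(
    line: str, samples: list[str], strip_keys: frozenset
) -> RawVariantRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 10:
        raise ValueError("fewer than 10 columns")
    chrom, pos_s, _id, ref, alt_s, qual_s, _filt, info_s = fields[:8]
    fmt = fields[8].split(":")
    pos = int(pos_s)
    if pos < 1:
        raise ValueError("position < 1")
    ref = ref.upper()
    if not ref or any(c not in "ACGTN" for c in ref):
        raise ValueError("invalid REF allele")
    alts = tuple(a.upper() for a in alt_s.split(","))
    if not alts or alts == (".",):
        raise ValueError("missing ALT allele")
    for a in alts:
        if a == ref:
            raise ValueError("ALT equals REF")
        if a.startswith("<"):
            raise ValueError("symbolic ALT in short-variant stream")
        if any(c not in "ACGTN*" for c in a):
            raise ValueError("invalid ALT allele")
    qual = None if qual_s in (".", "") else float(qual_s)

    info: dict = {}
    if info_s not in (".", ""):
        for item in info_s.split(";"):
            k, _, v = item.partition("=")
            if k in strip_keys:
                continue
            info[k] = v if v else True

    genotypes: list[GenotypeCall] = []
    allelic_depths: list[tuple[int, ...] | None] = []
    gt_indices: list[tuple[int | None, int | None]] = []
    for sample_id, col in zip(samples, fields[9:]):
        vals = dict(zip(fmt, col.split(":")))
        a, b = _parse_gt_field(vals.get("GT", "."))
        gt_indices.append((a, b))
        depth = None
        if vals.get("DP", ".") not in (".", ""):
            depth = int(vals["DP"])
        ad: tuple[int, ...] | None = None
        if vals.get("AD", ".") not in (".", ""):
            try:
                ad = tuple(int(x) for x in vals["AD"].split(","))
            except ValueError:
                ad = None
        alt_reads = ad[1] if ad is not None and len(ad) > 1 else None
        if depth is None and ad is not None:
            depth = sum(ad)
        genotypes.append(
            GenotypeCall(sample_id, _zygosity_from_indices(a, b), depth, alt_reads)
        )
        allelic_depths.append(ad)
    return RawVariantRecord(
        chrom=normalize_chrom(chrom),
        pos=pos,
        ref=ref,
        alts=alts,
        qual=qual,
        info=info,
        genotypes=genotypes,
        allelic_depths=allelic_depths,
        gt_indices=gt_indices,
    )


_HEADER_DEFS = {
    "DP": '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    "DP4": '##INFO=<ID=DP4,Number=4,Type=Integer,Description="Strand read counts: ref fwd, ref rev, alt fwd, alt rev">',
    "AD": '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    "GT": '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
}


def sanitize_vcf(
    vcf_text: str | Iterable[str], policy: HeaderPolicy | None = None
) -> tuple[list[RawVariantRecord], list[str], SanitationLog]:
    """Sanitize VCF content.

    Returns ``(records, header_lines, log)``.  Records on non-canonical
    chromosomes are dropped; malformed lines are skipped and counted unless
    they exceed half of all record lines, which raises; annotation INFO keys
    named in the policy are stripped; required header definitions absent
    from the header are injected.

    Raises ``ValueError`` on a VCF with no sample columns or no #CHROM line.
    """
    policy = policy or HeaderPolicy()
    if isinstance(vcf_text, str):
        lines: Iterable[str] = vcf_text.splitlines()
    else:
        lines = (l.rstrip("\n") for l in vcf_text)

    header: list[str] = []
    samples: list[str] | None = None
    records: list[RawVariantRecord] = []
    log = SanitationLog()
    strip = frozenset(policy.strip_info_keys)
    canonical = {normalize_chrom(c) for c in policy.canonical_chromosomes}
    n_malformed = 0

    for line in lines:
        if not line.strip():
            continue
        if line.startswith("##"):
            header.append(line)
            continue
        if line.startswith("#CHROM"):
            cols = line.split("\t")
            if len(cols) < 10:
                raise ValueError("VCF has zero sample columns")
            samples = cols[9:]
            header.append(line)
            continue
        if samples is None:
            raise ValueError("record line before #CHROM header")
        log.n_input_records += 1
        try:
            rec = _parse_record_line(line, samples, strip)
        except (ValueError, IndexError) as exc:
            n_malformed += 1
            log.drop(f"malformed:{exc}")
            continue
        if rec.chrom not in canonical:
            log.drop("non_canonical_chromosome")
            continue
        records.append(rec)

    if samples is None:
        raise ValueError("no #CHROM header line found")
    if log.n_input_records > 0 and n_malformed * 2 > log.n_input_records:
        raise ValueError(
            f"systemic malformation: {n_malformed}/{log.n_input_records} bad lines"
        )

    defined = set()
    for h in header:
        for kind in ("INFO", "FORMAT"):
            tag = f"##{kind}=<ID="
            if h.startswith(tag):
                defined.add(h[len(tag):].split(",", 1)[0])
    insert_at = len(header) - 1  # before #CHROM
    for key in policy.required_fields:
        if key not in defined and key in _HEADER_DEFS:
            header.insert(insert_at, _HEADER_DEFS[key])
            insert_at += 1
    log.n_retained = len(records)
    return records, header, log


def sanitize_vcf_file(path: str, policy: HeaderPolicy | None = None):
    with _open_text(path) as fh:
        return sanitize_vcf(fh, policy)


def write_vcf(records: list[RawVariantRecord], header: list[str], path: str) -> None:
    """Write records back out as a minimal, valid VCF (GT:DP:AD per sample)."""
    if not any(h.startswith("#CHROM") for h in header):
        raise ValueError("header lacks #CHROM line")
    with open(path, "w") as fh:
        for h in header:
            fh.write(h + "\n")
        for r in records:
            info = ";".join(
                k if v is True else f"{k}={v}" for k, v in sorted(r.info.items())
            ) or "."
            cols = [
                r.chrom,
                str(r.pos),
                ".",
                r.ref,
                ",".join(r.alts),
                "." if r.qual is None else f"{r.qual:g}",
                ".",
                info,
                "GT:DP:AD",
            ]
            for g, ad, idx in zip(r.genotypes, r.allelic_depths, r.gt_indices):
                gt = "/".join("." if i is None else str(i) for i in idx)
                dp = "." if g.depth is None else str(g.depth)
                ad_s = "." if ad is None else ",".join(str(x) for x in ad)
                cols.append(f"{gt}:{dp}:{ad_s}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# region filtering


def filter_regions(
    records: list[RawVariantRecord], regions: RegionSet
) -> list[RawVariantRecord]:
    """Keep records whose 1-based position falls inside a BED interval."""
    return [r for r in records if regions.contains(r.chrom, r.pos)]


# ---------------------------------------------------------------------------
# multi-allelic splitting


def split_multiallelic(record: RawVariantRecord) -> list[RawVariantRecord]:
    """Decompose a multi-allelic record into one biallelic record per ALT.

    Genotypes are re-expressed relative to each ALT (a sample carrying
    allele *i* is HET or HOM_ALT on record *i* and HOM_REF otherwise);
    per-allele AD read counts follow their allele; total depth is shared.
    """
    if len(record.alts) == 1:
        return [record]
    out = []
    for i, alt in enumerate(record.alts, start=1):
        genos = []
        ads = []
        for g, ad, (a, b) in zip(
            record.genotypes, record.allelic_depths, record.gt_indices
        ):
            zyg = _zygosity_from_indices(a, b, allele=i)
            alt_reads = None
            new_ad = None
            if ad is not None and len(ad) > i:
                alt_reads = ad[i]
                new_ad = (ad[0], ad[i])
            genos.append(GenotypeCall(g.sample_id, zyg, g.depth, alt_reads))
            ads.append(new_ad)
        new_idx = [
            tuple(
                None if x is None else (1 if x == i else 0) for x in pair
            )
            for pair in record.gt_indices
        ]
        out.append(
            replace(
                record,
                alts=(alt,),
                genotypes=genos,
                allelic_depths=ads,
                gt_indices=new_idx,  # type: ignore[arg-type]
            )
        )
    return out


# ---------------------------------------------------------------------------
# indel normalization


def normalize_indel(
    record: RawVariantRecord, reference: Callable[[str, int, int], str] | Mapping
) -> RawVariantRecord:
    """Trim shared prefix/suffix and left-align a biallelic allele pair.

    ``reference`` is either a callable ``(chrom, start_1based, end_1based) ->
    sequence`` or a mapping chrom -> full sequence string.  Idempotent.
    Raises ``ValueError`` when the stated REF disagrees with the reference
    sequence at the locus.
    """
    ref, alt, pos = record.ref, record.alt, record.pos

    def fetch(chrom: str, start: int, end: int) -> str:
        if callable(reference):
            return reference(chrom, start, end).upper()
        return str(reference[chrom][start - 1 : end]).upper()

    if fetch(record.chrom, pos, pos + len(ref) - 1) != ref:
        raise ValueError(
            f"REF mismatch at {record.chrom}:{pos} (stated {ref})"
        )

    # right-trim shared suffix, extending left from the reference whenever
    # an allele would become empty
    while ref[-1] == alt[-1]:
        if (len(ref) == 1 or len(alt) == 1) and pos == 1:
            break
        ref, alt = ref[:-1], alt[:-1]
        if not ref or not alt:
            base = fetch(record.chrom, pos - 1, pos - 1)
            ref, alt, pos = base + ref, base + alt, pos - 1
    # left-trim shared prefix
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return replace(record, pos=pos, ref=ref, alts=(alt,))
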