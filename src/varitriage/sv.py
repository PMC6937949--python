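"""Structural-variant interpretation: map events to genes and regulatory
elements, score each affected entity against the phenotype, rank events.

An element's score combines its confidence, the element–gene association
confidence and the phenotype score of the target gene as a plain product,
maximized over the element's targets.  The product is monotone in every
factor and zero whenever any factor is absent, which lets a distal
high-scoring target outrank the overlapped host gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .phenotyper import PhenotypeScore
from .vcf_ingest import normalize_chrom

SV_TYPES = ("DEL", "DUP", "INV", "INS")


@dataclass
class SvEvent:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    sv_type: str
    copy_number: int | None = None
    event_id: str = ""

    def __post_init__(self):
        self.chrom = normalize_chrom(self.chrom)
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if self.sv_type == "INS":
            self.end = self.start  # insertions act at a point
        if self.start > self.end:
            raise ValueError("SV start > end")
        if not self.event_id:
            self.event_id = f"{self.sv_type}_{self.chrom}_{self.start}_{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class RegulatoryElement:
    element_id: str
    chrom: str
    start: int
    end: int
    element_confidence: float
    #: list of (gene_symbol, association_confidence)
    targets: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self):
        self.chrom = normalize_chrom(self.chrom)
        if not 0 < self.element_confidence <= 1:
            raise ValueError("element confidence outside (0,1]")
        if not self.targets:
            raise ValueError(f"element {self.element_id} has no targets")
        for gene, conf in self.targets:
            if not 0 < conf <= 1:
                raise ValueError(f"association confidence outside (0,1] for {gene}")


@dataclass
class AffectedEntity:
    event_id: str
    kind: str  # gene | element
    name: str  # gene symbol or element id
    score: float = 0.0
    via_target: str | None = None


@dataclass
class GeneInterval:
    gene_symbol: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        self.chrom = normalize_chrom(self.chrom)


class IntervalMap:
    """Chromosome-sharded interval index over genes or elements."""

    def __init__(self, items, key=lambda x: (x.chrom, x.start, x.end)):
        self._trees: dict[str, IntervalTree] = {}
        self.items = list(items)
        for item in self.items:
            chrom, start, end = key(item)
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end + 1, item)

    def overlapping(self, chrom: str, start: int, end: int) -> list:
        tree = self._trees.get(normalize_chrom(chrom))
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end + 1)]


def map_event(
    event: SvEvent, genes: IntervalMap, elements: IntervalMap
) -> list[AffectedEntity]:
    """Every gene and element whose span intersects the event, once each."""
    out: list[AffectedEntity] = []
    seen = set()
    for g in genes.overlapping(event.chrom, event.start, event.end):
        if ("gene", g.gene_symbol) not in seen:
            seen.add(("gene", g.gene_symbol))
            out.append(AffectedEntity(event.event_id, "gene", g.gene_symbol))
    for el in elements.overlapping(event.chrom, event.start, event.end):
        if ("element", el.element_id) not in seen:
            seen.add(("element", el.element_id))
            out.append(AffectedEntity(event.event_id, "element", el.element_id))
    return out


def combined_element_score(
    element: RegulatoryElement, pheno_scores: dict
) -> tuple[float, str | None]:
    """max over targets of element_confidence * association_confidence *
    phenotype_total(target); returns (score, argmax gene)."""
    best, via = 0.0, None
    for gene, assoc in element.targets:
        ps = pheno_scores.get(gene)
        total = ps.total if isinstance(ps, PhenotypeScore) else float(ps or 0.0)
        s = element.element_confidence * assoc * total
        if s > best or (s == best and s > 0 and (via is None or gene < via)):
            best, via = s, gene
    return best, via


@dataclass
class ScoredEvent:
    event: SvEvent
    entities: list[AffectedEntity]

    @property
    def max_score(self) -> float:
        return max((e.score for e in self.entities), default=0.0)


def score_event_entities(
    event: SvEvent,
    genes: IntervalMap,
    elements_by_id: dict,
    element_map: IntervalMap,
    pheno_scores: dict,
) -> ScoredEvent:
    entities = map_event(event, genes, element_map)
    for ent in entities:
        if ent.kind == "gene":
            ps = pheno_scores.get(ent.name)
            ent.score = ps.total if isinstance(ps, PhenotypeScore) else float(ps or 0.0)
        else:
            score, via = combined_element_score(elements_by_id[ent.name], pheno_scores)
            ent.score, ent.via_target = score, via
    entities.sort(key=lambda e: (-e.score, e.kind, e.name))
    return ScoredEvent(event, entities)


def rank_events(scored: list[ScoredEvent]) -> list[ScoredEvent]:
    """Descending by best entity score; ties favor the shorter event, then
    genomic coordinate."""
    return sorted(
        scored,
        key=lambda s: (
            -s.max_score,
            s.event.length,
            s.event.chrom,
            s.event.start,
            s.event.end,
        ),
    )


# ---------------------------------------------------------------------------
# I/O


def load_sv_tsv(path: str) -> list[SvEvent]:
    """Tab-delimited SV calls: chrom, start, end, type, copy_number."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            cn = row.get("copy_number", "")
            out.append(
                SvEvent(
                    row["chrom"],
                    int(row["start"]),
                    int(row["end"]),
                    row["sv_type"],
                    int(cn) if cn not in ("", ".") else None,
                )
            )
    return out


def load_elements_tsv(path: str) -> list[RegulatoryElement]:
    """BED-like element map: chrom, start, end, element_id, confidence,
    targets as semicolon-joined gene:score pairs."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            targets = []
            for pair in row["targets"].split(";"):
                gene, _, conf = pair.partition(":")
                targets.append((gene, float(conf)))
            out.append(
                RegulatoryElement(
                    row["element_id"],
                    row["chrom"],
                    int(row["start"]),
                    int(row["end"]),
                    float(row["confidence"]),
                    targets,
                )
            )
    return out
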