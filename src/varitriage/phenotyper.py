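"""Phenotype-keyword gene prioritization over a sectioned gene-document
knowledgebase.

Each gene carries a document split into named sections (summaries,
disorders, phenotypes, publications, pathways, function).  A query is a
list of phrase keywords combined with OR or AND.  Matching is whole-word,
case-insensitive, no stemming.

The direct score is section-weighted and log-saturated::

    direct = (matched_terms / total_terms) * sum_s w_s * log2(1 + hits_s)

(the term-coverage factor applies under OR semantics; an AND query either
matches every term or scores zero).  The indirect ("guilt by association")
score propagates one hop over gene–gene links with a fixed damping of 0.5:

    indirect = max_n link_weight(g, n) * 0.5 * direct(n)

A gene's total is the larger of the two.  Evidence snippets (MiniCards)
show each hit in its original context with the matched span delimited.
"""

from __future__ import annotations

import json
import math
import os
import re
from dataclasses import dataclass, field

SECTION_VOCAB = (
    "summaries",
    "disorders",
    "phenotypes",
    "publications",
    "pathways",
    "function",
)

DEFAULT_SECTION_WEIGHTS = {
    "disorders": 3.0,
    "phenotypes": 3.0,
    "summaries": 2.0,
    "function": 1.5,
    "pathways": 1.0,
    "publications": 1.0,
}

INDIRECT_DAMPING = 0.5
MARK_OPEN = "[["
MARK_CLOSE = "]]"


@dataclass
class GeneDoc:
    gene_symbol: str
    sections: dict = field(default_factory=dict)
    section_weights: dict = field(default_factory=lambda: dict(DEFAULT_SECTION_WEIGHTS))

    def __post_init__(self):
        for name in self.sections:
            if name not in SECTION_VOCAB:
                raise ValueError(f"unknown section {name!r}")
        for name, w in self.section_weights.items():
            if w <= 0:
                raise ValueError(f"non-positive weight for section {name!r}")


@dataclass(frozen=True)
class GeneLink:
    gene_a: str
    gene_b: str
    link_type: str = "shared_pathway"
    weight: float = 1.0

    def __post_init__(self):
        if self.gene_a == self.gene_b:
            raise ValueError("self-link")
        if not 0 < self.weight <= 1:
            raise ValueError("link weight outside (0,1]")


@dataclass
class KeywordQuery:
    terms: list[str]
    operator: str = "OR"
    case_insensitive: bool = True

    def __post_init__(self):
        if not self.terms:
            raise ValueError("a scoring run needs at least one keyword")
        if self.operator not in ("OR", "AND"):
            raise ValueError(f"unknown operator {self.operator!r}")


@dataclass
class PhenotypeScore:
    gene_symbol: str
    direct_score: float = 0.0
    indirect_score: float = 0.0
    matched_terms: set = field(default_factory=set)
    via_gene: str | None = None

    @property
    def total(self) -> float:
        return max(self.direct_score, self.indirect_score)

    @property
    def mode(self) -> str:
        if self.total == 0:
            return "none"
        return "direct" if self.direct_score >= self.indirect_score else "indirect"


@dataclass
class EvidenceSnippet:
    gene_symbol: str
    section: str
    text: str  # window with the matched span delimited by markers
    term: str
    source_pointer: str


def _term_pattern(term: str) -> re.Pattern:
    """Whole-word contiguous phrase match, case-insensitive."""
    words = [re.escape(w) for w in term.split()]
    return re.compile(r"\b" + r"\s+".join(words) + r"\b", re.IGNORECASE)


def _find_hits(text: str, term: str) -> list[tuple[int, int]]:
    return [(m.start(), m.end()) for m in _term_pattern(term).finditer(text)]


def search_gene(doc: GeneDoc, query: KeywordQuery) -> tuple[dict, set]:
    """Per-section occurrence counts plus the set of matched terms.

    AND queries require every term to appear somewhere in the document;
    otherwise counts are empty.
    """
    counts: dict[str, int] = {}
    matched: set[str] = set()
    per_term_present = {}
    for term in query.terms:
        present = False
        for section, text in doc.sections.items():
            hits = _find_hits(text, term)
            if hits:
                present = True
                counts[section] = counts.get(section, 0) + len(hits)
        per_term_present[term] = present
        if present:
            matched.add(term)
    if query.operator == "AND" and not all(per_term_present.values()):
        return {}, set()
    return counts, matched


def score_direct(
    hits: dict, matched: set, query: KeywordQuery, weights: dict | None = None
) -> float:
    weights = weights or DEFAULT_SECTION_WEIGHTS
    raw = sum(
        weights.get(section, 1.0) * math.log2(1 + n) for section, n in hits.items()
    )
    coverage = len(matched) / len(query.terms)
    return raw * coverage


def score_indirect(
    gene: str, links: list[GeneLink], direct_scores: dict
) -> tuple[float, str | None]:
    """Best one-hop neighbor contribution with fixed damping."""
    best, via = 0.0, None
    for link in links:
        if gene == link.gene_a:
            neighbor = link.gene_b
        elif gene == link.gene_b:
            neighbor = link.gene_a
        else:
            continue
        s = link.weight * INDIRECT_DAMPING * direct_scores.get(neighbor, 0.0)
        if s > best or (s == best and s > 0 and (via is None or neighbor < via)):
            best, via = s, neighbor
    return best, via


def score_genes(
    docs: dict, query: KeywordQuery, links: list[GeneLink] | None = None
) -> dict:
    """Score every gene in the knowledgebase: direct pass, then one
    indirect hop.  Returns gene -> PhenotypeScore."""
    links = links or []
    direct: dict[str, float] = {}
    matched: dict[str, set] = {}
    for gene, doc in docs.items():
        hits, terms = search_gene(doc, query)
        direct[gene] = score_direct(hits, terms, query, doc.section_weights)
        matched[gene] = terms
    out = {}
    for gene in docs:
        ind, via = score_indirect(gene, links, direct)
        out[gene] = PhenotypeScore(
            gene_symbol=gene,
            direct_score=direct[gene],
            indirect_score=ind,
            matched_terms=matched[gene],
            via_gene=via,
        )
    return out


def build_minicard(
    doc: GeneDoc,
    query: KeywordQuery,
    window: int = 60,
    per_section_cap: int = 3,
) -> list[EvidenceSnippet]:
    """Evidence snippets: one per hit, ordered by position, capped per
    section, with the matched span delimited and the window clipped at the
    section bounds."""
    snippets = []
    for section in SECTION_VOCAB:
        text = doc.sections.get(section)
        if not text:
            continue
        hits = []
        for term in query.terms:
            for s, e in _find_hits(text, term):
                hits.append((s, e, term))
        hits.sort()
        for s, e, term in hits[:per_section_cap]:
            lo = max(0, s - window)
            hi = min(len(text), e + window)
            marked = (
                text[lo:s] + MARK_OPEN + text[s:e] + MARK_CLOSE + text[e:hi]
            )
            snippets.append(
                EvidenceSnippet(
                    gene_symbol=doc.gene_symbol,
                    section=section,
                    text=marked,
                    term=text[s:e],
                    source_pointer=f"{doc.gene_symbol}#{section}:{s}",
                )
            )
    return snippets


def rank_genes(scores: list[PhenotypeScore]) -> list[PhenotypeScore]:
    """Descending by total, ties by matched-term count then gene symbol."""
    return sorted(
        scores,
        key=lambda s: (-s.total, -len(s.matched_terms), s.gene_symbol),
    )


# ---------------------------------------------------------------------------
# knowledgebase I/O


def load_gene_docs(path: str) -> dict:
    """Directory of per-gene JSON documents ({gene_symbol, sections}) or a
    single JSON file mapping gene -> sections."""
    docs = {}
    if os.path.isdir(path):
        for name in sorted(os.listdir(path)):
            if not name.endswith(".json"):
                continue
            with open(os.path.join(path, name)) as fh:
                d = json.load(fh)
            docs[d["gene_symbol"]] = GeneDoc(
                d["gene_symbol"], d["sections"],
                d.get("section_weights", dict(DEFAULT_SECTION_WEIGHTS)),
            )
    else:
        with open(path) as fh:
            data = json.load(fh)
        for gene, sections in data.items():
            docs[gene] = GeneDoc(gene, sections)
    return docs


def load_links_tsv(path: str) -> list[GeneLink]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            out.append(
                GeneLink(
                    row["gene_a"], row["gene_b"], row["link_type"],
                    float(row["weight"]),
                )
            )
    return out


def parse_keywords(raw: str, operator: str = "OR") -> KeywordQuery:
    """Split a CLI/YAML keyword string on ';' into a query."""
    terms = [t.strip() for t in raw.split(";") if t.strip()]
    return KeywordQuery(terms, operator)
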