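"""Persistent case store: analyst-marked cases, in-house and sharing-group
allele frequencies, prior interpretations, and account-level resolution
statistics by phenotype class.

The store is a directory of newline-delimited JSON (one case per line in
``cases.ndjson``) plus a derived allele-count sidecar TSV.  Frequencies use
a diploid convention — two counted alleles per genotyped case — with
hemizygous male X genotypes contributing a single allele.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

from .vcf_ingest import HET, HOM_ALT

RELEVANCE_VOCAB = ("High", "Med", "Low")


@dataclass
class VariantSelection:
    """An analyst's mark on one variant of a case."""

    variant_key: tuple  # (chrom, pos, ref, alt)
    gene_symbol: str
    relevance: str
    pathogenicity: str = ""
    note: str = ""

    def __post_init__(self):
        self.variant_key = tuple(self.variant_key)
        if self.relevance not in RELEVANCE_VOCAB:
            raise ValueError(f"relevance must be one of {RELEVANCE_VOCAB}")


@dataclass
class GenotypeSummary:
    """Allele-count contribution of one case at one variant."""

    variant_key: tuple
    alt_alleles: int  # 0/1/2 (1 for hemizygous carriers)
    total_alleles: int = 2

    def __post_init__(self):
        self.variant_key = tuple(self.variant_key)


@dataclass
class CaseRecord:
    case_id: str
    protocol: str = ""
    keywords: list[str] = field(default_factory=list)
    analysis_date: str = ""
    selections: list[VariantSelection] = field(default_factory=list)
    genotype_summary: list[GenotypeSummary] = field(default_factory=list)

    @property
    def resolved(self) -> bool:
        """High or Medium relevance marks are the resolved-case proxy."""
        return any(s.relevance in ("High", "Med") for s in self.selections)


def genotype_summary_from_zygosity(
    variant_key: tuple, zygosity: str, hemizygous: bool = False
) -> GenotypeSummary:
    if hemizygous:
        return GenotypeSummary(variant_key, 1 if zygosity in (HET, HOM_ALT) else 0, 1)
    alt = {HOM_ALT: 2, HET: 1}.get(zygosity, 0)
    return GenotypeSummary(variant_key, alt, 2)


class CaseStore:
    """All analyzed cases of one account."""

    def __init__(self, cases: list[CaseRecord] | None = None):
        self.cases: dict[str, CaseRecord] = {}
        for c in cases or []:
            self.add(c)

    def add(self, case: CaseRecord) -> None:
        if case.case_id in self.cases:
            raise ValueError(f"duplicate case_id {case.case_id!r}")
        self.cases[case.case_id] = case

    def __len__(self) -> int:
        return len(self.cases)

    # -- persistence --------------------------------------------------------

    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        with open(os.path.join(directory, "cases.ndjson"), "w") as fh:
            for cid in sorted(self.cases):
                fh.write(json.dumps(asdict(self.cases[cid]), sort_keys=True) + "\n")
        counts = self.allele_counts()
        with open(os.path.join(directory, "allele_counts.tsv"), "w") as fh:
            fh.write("chrom\tpos\tref\talt\talt_alleles\ttotal_alleles\n")
            for key in sorted(counts):
                alt_n, tot = counts[key]
                fh.write("\t".join(map(str, key)) + f"\t{alt_n}\t{tot}\n")

    @classmethod
    def load(cls, directory: str) -> "CaseStore":
        store = cls()
        with open(os.path.join(directory, "cases.ndjson")) as fh:
            for line in fh:
                d = json.loads(line)
                store.add(
                    CaseRecord(
                        case_id=d["case_id"],
                        protocol=d.get("protocol", ""),
                        keywords=list(d.get("keywords", [])),
                        analysis_date=d.get("analysis_date", ""),
                        selections=[
                            VariantSelection(**s) for s in d.get("selections", [])
                        ],
                        genotype_summary=[
                            GenotypeSummary(**g) for g in d.get("genotype_summary", [])
                        ],
                    )
                )
        return store

    # -- frequencies --------------------------------------------------------

    def allele_counts(self, exclude_case: str | None = None) -> dict:
        counts: dict[tuple, tuple[int, int]] = {}
        for cid, case in self.cases.items():
            if cid == exclude_case:
                continue
            for g in case.genotype_summary:
                a, t = counts.get(g.variant_key, (0, 0))
                counts[g.variant_key] = (a + g.alt_alleles, t + g.total_alleles)
        return counts


def inhouse_af(
    variant_key: tuple, store: CaseStore, exclude_case: str | None = None
) -> float:
    """In-house allele frequency over stored genotypes, excluding the case
    under analysis from its own count.  Unseen variant → 0."""
    counts = store.allele_counts(exclude_case=exclude_case)
    alt, total = counts.get(tuple(variant_key), (0, 0))
    return alt / total if total else 0.0


def sharing_af(variant_key: tuple, stores: list[CaseStore]) -> float:
    """Pooled allele frequency across all sharing-group member stores."""
    alt = total = 0
    for store in stores:
        a, t = store.allele_counts().get(tuple(variant_key), (0, 0))
        alt += a
        total += t
    return alt / total if total else 0.0


def prior_interpretations(
    store: CaseStore, variant_key: tuple | None = None, gene: str | None = None
) -> list[tuple]:
    """All (case_id, relevance, pathogenicity, note) marks matching a
    variant key and/or gene, newest case first (by analysis date, then id)."""
    out = []
    for case in store.cases.values():
        for s in case.selections:
            if variant_key is not None and s.variant_key != tuple(variant_key):
                continue
            if gene is not None and s.gene_symbol != gene:
                continue
            out.append(
                (case.analysis_date, case.case_id, s.relevance, s.pathogenicity, s.note)
            )
    out.sort(key=lambda t: (t[0], t[1]), reverse=True)
    return [(cid, rel, path, note) for _, cid, rel, path, note in out]


# ---------------------------------------------------------------------------
# account statistics


@dataclass
class ClassStats:
    class_name: str
    keywords: list[str]
    total_cases: int
    resolved_cases: int

    @property
    def percent_resolved(self) -> float | None:
        if self.total_cases == 0:
            return None
        return round(100.0 * self.resolved_cases / self.total_cases, 1)


@dataclass
class AccountStats:
    rows: list[ClassStats]

    def to_tsv(self) -> str:
        lines = ["phenotype_class\tkeywords\ttotal_cases\tresolved_cases\tpercent_resolved"]
        for r in self.rows:
            pct = "" if r.percent_resolved is None else f"{r.percent_resolved:.1f}"
            lines.append(
                f"{r.class_name}\t{', '.join(r.keywords)}\t{r.total_cases}"
                f"\t{r.resolved_cases}\t{pct}"
            )
        return "\n".join(lines) + "\n"


def class_resolution_stats(store: CaseStore, class_defs: dict) -> AccountStats:
    """Per-phenotype-class resolution statistics.

    ``class_defs`` maps class name -> list of keywords.  A case belongs to
    every class whose keyword set intersects the case's own keywords
    (exact, case-insensitive string equality); it is resolved when any of
    its selections is marked High or Med.
    """
    rows = []
    for class_name, keywords in class_defs.items():
        kw = {k.lower() for k in keywords}
        total = resolved = 0
        for case in store.cases.values():
            if kw & {k.lower() for k in case.keywords}:
                total += 1
                if case.resolved:
                    resolved += 1
        rows.append(ClassStats(class_name, list(keywords), total, resolved))
    return AccountStats(rows)
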