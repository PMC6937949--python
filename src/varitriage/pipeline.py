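"""End-to-end case analysis: ingest → annotate → classify → prioritize →
inheritance models → SV scoring → report.

The batch equivalent of an interactive triage session: a case directory
with a VCF (and optionally an SV table and pedigree) is analyzed against a
knowledgebase directory, producing per-model candidate tables, ranked SV
events and a report structure.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from pyfaidx import Fasta

from . import __version__
from .acmg import assess, load_gene_knowledge_tsv
from .annotate import (
    AssertionTable,
    FrequencyTable,
    PredictionTable,
    TranscriptIndex,
    annotate_variants,
    load_transcripts_tsv,
)
from .case_store import CaseStore, inhouse_af
from .genetic_models import (
    MODEL_FUNCS,
    ModelResult,
    PedigreeTrio,
    Protocol,
    incidental_findings,
    sort_candidates,
)
from .phenotyper import (
    build_minicard,
    load_gene_docs,
    load_links_tsv,
    score_genes,
)
from .report import VersionManifest, build_report, render_report
from .sv import (
    GeneInterval,
    IntervalMap,
    load_elements_tsv,
    load_sv_tsv,
    rank_events,
    score_event_entities,
)
from .vcf_ingest import (
    RegionSet,
    filter_regions,
    normalize_indel,
    sanitize_vcf_file,
    split_multiallelic,
)


@dataclass
class Knowledgebase:
    """All loaded knowledge resources of one fixture/installation."""

    reference: object
    transcripts: list
    tx_index: TranscriptIndex
    regions: RegionSet
    freq_table: FrequencyTable
    assertion_table: AssertionTable
    prediction_table: PredictionTable
    gene_knowledge: dict
    gene_docs: dict
    links: list
    elements: list
    panel: list
    manifest: VersionManifest

    @classmethod
    def load(cls, directory: str) -> "Knowledgebase":
        ref = Fasta(os.path.join(directory, "reference.fa"))
        transcripts = load_transcripts_tsv(os.path.join(directory, "transcripts.tsv"))
        manifest = VersionManifest(artifact_version=__version__)
        manifest_path = os.path.join(directory, "manifest.tsv")
        if os.path.exists(manifest_path):
            with open(manifest_path) as fh:
                header = fh.readline().rstrip("\n").split("\t")
                for line in fh:
                    row = dict(zip(header, line.rstrip("\n").split("\t")))
                    manifest.add_table(row["name"], row["version"], row["checksum"])
        panel_path = os.path.join(directory, "panel.txt")
        panel = []
        if os.path.exists(panel_path):
            with open(panel_path) as fh:
                panel = [l.strip() for l in fh if l.strip()]
        elements_path = os.path.join(directory, "elements.tsv")
        elements = load_elements_tsv(elements_path) if os.path.exists(elements_path) else []
        return cls(
            reference=ref,
            transcripts=transcripts,
            tx_index=TranscriptIndex(transcripts),
            regions=RegionSet.from_bed(os.path.join(directory, "regions.bed"), "Exome"),
            freq_table=FrequencyTable.from_tsv(os.path.join(directory, "frequencies.tsv")),
            assertion_table=AssertionTable.from_tsv(os.path.join(directory, "assertions.tsv")),
            prediction_table=PredictionTable.from_tsv(os.path.join(directory, "predictions.tsv")),
            gene_knowledge=load_gene_knowledge_tsv(os.path.join(directory, "gene_flags.tsv")),
            gene_docs=load_gene_docs(os.path.join(directory, "gene_docs")),
            links=load_links_tsv(os.path.join(directory, "links.tsv")),
            elements=elements,
            panel=panel,
            manifest=manifest,
        )


@dataclass
class CaseAnalysis:
    """Everything a finished run produces, pre-report."""

    variants: list
    model_results: dict  # model name -> ModelResult
    incidental: ModelResult | None
    sv_events: list  # ranked ScoredEvent list
    pheno_scores: dict
    sanitation_log: object
    protocol: Protocol
    pedigree: PedigreeTrio


def run_case(
    kb: Knowledgebase,
    vcf_path: str,
    protocol: Protocol,
    pedigree: PedigreeTrio,
    sv_path: str | None = None,
    store: CaseStore | None = None,
    case_id: str | None = None,
) -> CaseAnalysis:
    records, _header, log = sanitize_vcf_file(vcf_path)
    records = filter_regions(records, kb.regions)
    split = []
    for rec in records:
        split.extend(split_multiallelic(rec))
    normalized = [normalize_indel(r, kb.reference) for r in split]

    variants = annotate_variants(
        normalized,
        kb.tx_index,
        kb.reference,
        kb.freq_table,
        kb.assertion_table,
        kb.prediction_table,
    )
    for v in variants:
        assess(v, kb.gene_knowledge)
        if store is not None:
            v.inhouse_af = inhouse_af(v.key, store, exclude_case=case_id)

    pheno_scores = {}
    if protocol.keyword_query is not None:
        pheno_scores = score_genes(kb.gene_docs, protocol.keyword_query, kb.links)
        for v in variants:
            if v.gene_symbol in pheno_scores:
                v.phenotype_score = pheno_scores[v.gene_symbol]

    model_results = {}
    for model in protocol.genetic_models:
        if model not in MODEL_FUNCS:
            raise KeyError(f"unknown genetic model {model!r}")
        mr = MODEL_FUNCS[model](variants, pedigree, protocol)
        mr.candidates = sort_candidates(mr.candidates)
        model_results[model] = mr

    inc = incidental_findings(variants, protocol.gene_panel or kb.panel)
    inc.candidates = sort_candidates(inc.candidates)

    sv_events = []
    if sv_path is not None and os.path.exists(sv_path):
        events = load_sv_tsv(sv_path)
        gene_ivs = [
            GeneInterval(tx.gene_symbol, tx.chrom, tx.start, tx.end)
            for tx in kb.transcripts
        ]
        gene_map = IntervalMap(gene_ivs)
        el_map = IntervalMap(kb.elements)
        el_by_id = {e.element_id: e for e in kb.elements}
        scored = [
            score_event_entities(ev, gene_map, el_by_id, el_map, pheno_scores)
            for ev in events
        ]
        sv_events = rank_events(scored)

    return CaseAnalysis(
        variants=variants,
        model_results=model_results,
        incidental=inc,
        sv_events=sv_events,
        pheno_scores=pheno_scores,
        sanitation_log=log,
        protocol=protocol,
        pedigree=pedigree,
    )


def analysis_report(
    analysis: CaseAnalysis,
    kb: Knowledgebase,
    case_meta: dict,
    selections: list | None = None,
    fmt: str = "json",
) -> str:
    """Render a report for a finished analysis."""
    selections = selections or []
    snippets = {}
    if analysis.protocol.keyword_query is not None:
        genes = {
            v.gene_symbol
            for mr in analysis.model_results.values()
            for v in mr.candidates
        }
        if analysis.incidental:
            genes |= {v.gene_symbol for v in analysis.incidental.candidates}
        for gene in sorted(genes):
            if gene in kb.gene_docs:
                snippets[gene] = build_minicard(
                    kb.gene_docs[gene], analysis.protocol.keyword_query
                )
    doc = build_report(
        case_meta=case_meta,
        keywords=analysis.protocol.keyword_query.terms
        if analysis.protocol.keyword_query
        else [],
        model_results=analysis.model_results,
        selections=selections,
        manifest=kb.manifest,
        snippets_by_gene=snippets,
        incidental=analysis.incidental,
    )
    return render_report(doc, fmt)


def run_scenario_dir(case_dir: str, kb_dir: str | None = None) -> CaseAnalysis:
    """Analyze a generated scenario directory (knowledgebase and case files
    side by side, as the generator emits them)."""
    kb = Knowledgebase.load(kb_dir or case_dir)
    protocol = Protocol.from_yaml(os.path.join(case_dir, "protocol.yaml"))
    pedigree = PedigreeTrio.from_ped(os.path.join(case_dir, "case.ped"))
    return run_case(
        kb,
        os.path.join(case_dir, "case.vcf"),
        protocol,
        pedigree,
        sv_path=os.path.join(case_dir, "sv.tsv"),
    )
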