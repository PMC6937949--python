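"""Clinical report assembly: JSON (lossless, schema-checked) and Markdown
generated from the same intermediate structure, plus per-model variant
table export.

Every report carries a methods section reproducing the filter-cascade logs
exactly, and a version manifest naming each knowledge table used in the
run with its version string and checksum.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

REPORT_SCHEMA_VERSION = "1.0"

#: required top-level keys of a report document
REPORT_SCHEMA = (
    "schema_version",
    "case",
    "keywords",
    "model_sections",
    "incidental_findings",
    "methods",
    "version_manifest",
)


def file_checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


@dataclass
class VersionManifest:
    artifact_version: str
    tables: list[dict] = field(default_factory=list)  # name, version, checksum
    protocol_name: str = ""
    protocol_hash: str = ""
    run_timestamp: str = ""
    seed: int | None = None

    def add_table(self, name: str, version: str, checksum: str) -> None:
        if any(t["name"] == name for t in self.tables):
            raise ValueError(f"table {name!r} already in manifest")
        self.tables.append({"name": name, "version": version, "checksum": checksum})

    def to_dict(self) -> dict:
        return {
            "artifact_version": self.artifact_version,
            "tables": sorted(self.tables, key=lambda t: t["name"]),
            "protocol_name": self.protocol_name,
            "protocol_hash": self.protocol_hash,
            "run_timestamp": self.run_timestamp,
            "seed": self.seed,
        }


def _variant_block(v, selection=None) -> dict:
    """Serializable per-variant report block from an AnnotatedVariant."""
    chrom, pos, ref, alt = v.key
    block = {
        "variant": {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt},
        "gene": v.gene_symbol,
        "effect": v.consequence.effect if v.consequence else "",
        "aa_change": v.consequence.aa_change if v.consequence else "",
        "severity_tier": v.severity_tier or "",
        "max_af": v.max_af,
        "acmg_class": v.acmg.classification if v.acmg else "",
        "acmg_criteria": v.acmg.codes if v.acmg else [],
        "phenotype_score": round(v.phenotype_score.total, 6)
        if v.phenotype_score
        else 0.0,
        "matched_phenotypes": sorted(v.phenotype_score.matched_terms)
        if v.phenotype_score
        else [],
        "inhouse_af": v.inhouse_af,
        "flags": sorted(set(v.flags)),
        "evidence_snippets": [],
    }
    if selection is not None:
        block["relevance"] = selection.relevance
        block["pathogenicity"] = selection.pathogenicity
        block["note"] = selection.note
    return block


def build_report(
    case_meta: dict,
    keywords: list[str],
    model_results: dict,
    selections: list,
    manifest: VersionManifest,
    snippets_by_gene: dict | None = None,
    incidental=None,
) -> dict:
    """Assemble the intermediate report structure shared by both formats.

    ``model_results`` maps model name -> ModelResult.  Each selection must
    reference a variant present in some model's candidate list; otherwise a
    ``ValueError`` is raised.
    """
    snippets_by_gene = snippets_by_gene or {}
    known_keys = {
        v.key for mr in model_results.values() for v in mr.candidates
    }
    if incidental is not None:
        known_keys |= {v.key for v in incidental.candidates}
    for s in selections:
        if tuple(s.variant_key) not in known_keys:
            raise ValueError(
                f"selection references variant {s.variant_key} absent from the analysis"
            )
    sel_by_key = {tuple(s.variant_key): s for s in selections}

    def section(mr):
        blocks = []
        for v in mr.candidates:
            sel = sel_by_key.get(v.key)
            block = _variant_block(v, sel)
            for sn in snippets_by_gene.get(v.gene_symbol, []):
                block["evidence_snippets"].append(
                    {
                        "section": sn.section,
                        "text": sn.text,
                        "term": sn.term,
                        "source_pointer": sn.source_pointer,
                    }
                )
            blocks.append(block)
        return {
            "model": mr.model,
            "n_candidates": len(mr.candidates),
            "variants": blocks,
        }

    methods = []
    for model, mr in model_results.items():
        for step in mr.steps:
            methods.append(
                {
                    "model": model,
                    "filter": step.name,
                    "params": step.params,
                    "n_in": step.n_in,
                    "n_out": step.n_out,
                }
            )
    if incidental is not None:
        for step in incidental.steps:
            methods.append(
                {
                    "model": "incidental",
                    "filter": step.name,
                    "params": step.params,
                    "n_in": step.n_in,
                    "n_out": step.n_out,
                }
            )

    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "case": dict(case_meta),
        "keywords": list(keywords),
        "model_sections": [section(mr) for mr in model_results.values()],
        "incidental_findings": section(incidental) if incidental is not None else None,
        "methods": methods,
        "version_manifest": manifest.to_dict(),
    }


def validate_report(doc: dict) -> None:
    missing = [k for k in REPORT_SCHEMA if k not in doc]
    if missing:
        raise ValueError(f"report missing keys: {missing}")
    for sec in doc["model_sections"]:
        if sec["n_candidates"] != len(sec["variants"]):
            raise ValueError(f"candidate count mismatch in model {sec['model']}")


def render_report(doc: dict, fmt: str = "json") -> str:
    """Render the intermediate structure; byte-identical for identical
    inputs (keys sorted, no timestamps added at render time)."""
    validate_report(doc)
    if fmt == "json":
        return json.dumps(doc, sort_keys=True, indent=2) + "\n"
    if fmt == "markdown":
        return _render_markdown(doc)
    raise ValueError(f"unknown report format {fmt!r}")


def _render_markdown(doc: dict) -> str:
    out = []
    case = doc["case"]
    out.append(f"# Clinical variant report — case {case.get('case_id', '?')}")
    out.append("")
    for k in sorted(case):
        out.append(f"- **{k}**: {case[k]}")
    out.append("")
    out.append(f"**Phenotype keywords**: {'; '.join(doc['keywords']) or '(none)'}")
    out.append("")
    sections = list(doc["model_sections"])
    if doc.get("incidental_findings"):
        sections.append(doc["incidental_findings"])
    any_variant = False
    for sec in sections:
        out.append(f"## Genetic model: {sec['model']}")
        out.append("")
        if not sec["variants"]:
            out.append("_No candidate variants._")
            out.append("")
            continue
        any_variant = True
        for b in sec["variants"]:
            v = b["variant"]
            out.append(
                f"### {v['chrom']}:{v['pos']} {v['ref']}>{v['alt']} ({b['gene']})"
            )
            out.append("")
            out.append(f"- effect: {b['effect']} {b['aa_change']}".rstrip())
            out.append(f"- severity tier: {b['severity_tier']}")
            out.append(f"- control max AF: {b['max_af']}")
            out.append(
                f"- ACMG: {b['acmg_class']} ({', '.join(b['acmg_criteria']) or 'no criteria'})"
            )
            out.append(
                f"- phenotype score: {b['phenotype_score']}"
                f" (matched: {', '.join(b['matched_phenotypes']) or 'none'})"
            )
            if "relevance" in b:
                out.append(
                    f"- analyst: relevance {b['relevance']},"
                    f" pathogenicity {b['pathogenicity'] or 'n/a'}"
                )
                if b.get("note"):
                    out.append(f"- note: {b['note']}")
            for sn in b["evidence_snippets"]:
                out.append(f"- evidence [{sn['section']}]: {sn['text']}")
            out.append("")
    if not any_variant:
        out.insert(4, "**No reportable findings.**")
    out.append("## Methods")
    out.append("")
    out.append("| model | filter | parameters | in | out |")
    out.append("|---|---|---|---|---|")
    for m in doc["methods"]:
        params = json.dumps(m["params"], sort_keys=True)
        out.append(
            f"| {m['model']} | {m['filter']} | `{params}` | {m['n_in']} | {m['n_out']} |"
        )
    out.append("")
    out.append("## Knowledgebase versions")
    out.append("")
    man = doc["version_manifest"]
    out.append(f"- pipeline version: {man['artifact_version']}")
    out.append(f"- protocol: {man['protocol_name']} ({man['protocol_hash']})")
    for t in man["tables"]:
        out.append(f"- {t['name']}: {t['version']} (sha256:{t['checksum']})")
    out.append("")
    return "\n".join(out)


# ---------------------------------------------------------------------------
# variant table export

EXPORT_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "effect",
    "aa_change",
    "severity_tier",
    "max_af",
    "acmg_class",
    "acmg_criteria",
    "phenotype_score",
    "matched_phenotypes",
    "inhouse_af",
    "flags",
)


def export_variant_table(candidates: list) -> str:
    """TSV export of one model's survivors: all annotation columns, one row
    per variant."""
    lines = ["\t".join(EXPORT_COLUMNS)]
    for v in candidates:
        b = _variant_block(v)
        row = [
            str(b["variant"]["chrom"]),
            str(b["variant"]["pos"]),
            b["variant"]["ref"],
            b["variant"]["alt"],
            b["gene"],
            b["effect"],
            b["aa_change"],
            b["severity_tier"],
            "" if b["max_af"] is None else repr(b["max_af"]),
            b["acmg_class"],
            ",".join(b["acmg_criteria"]),
            repr(b["phenotype_score"]),
            ",".join(b["matched_phenotypes"]),
            "" if b["inhouse_af"] is None else repr(b["inhouse_af"]),
            ",".join(b["flags"]),
        ]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def parse_variant_table(text: str) -> list[dict]:
    """Parse the exported TSV back into row dicts (round-trip check)."""
    lines = text.rstrip("\n").split("\n")
    header = lines[0].split("\t")
    return [dict(zip(header, l.split("\t"))) for l in lines[1:]]
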