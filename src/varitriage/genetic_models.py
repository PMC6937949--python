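"""Inheritance-model filtering: protocol-driven filter cascades, the
dominant/recessive/compound-het genetic models and the incidental-findings
panel screen.

Every filter application is logged with its input and output counts so the
final report's methods section can document the cascade exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .annotate import AnnotatedVariant
from .phenotyper import KeywordQuery, parse_keywords
from .vcf_ingest import HET, HOM_ALT, HOM_REF, GenotypeCall

DEFAULT_AF_CUTOFF = 0.001  # the 0.1% default frequency gate
SEVERITY_GATE = ("HIGH", "MODERATE")  # "low or no predicted effect" excluded
DE_NOVO_MIN_PARENT_DEPTH = 10


@dataclass
class ReliabilityThresholds:
    min_qual: float = 20.0
    min_depth: int = 8
    min_alt_fraction: float = 0.2


@dataclass
class PedigreeTrio:
    proband_id: str
    mother_id: str | None = None
    father_id: str | None = None
    affected: dict = field(default_factory=dict)

    @property
    def is_trio(self) -> bool:
        return bool(self.mother_id and self.father_id)

    @classmethod
    def from_ped(cls, path: str) -> "PedigreeTrio":
        """Minimal PED reader: the first affected sample with named parents
        becomes the proband; a parentless affected sample is a singleton."""
        rows = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                rows.append(line.split())
        for fam, iid, father, mother, _sex, pheno in rows:
            if pheno == "2" and father != "0" and mother != "0":
                return cls(iid, mother, father, {iid: True})
        for fam, iid, father, mother, _sex, pheno in rows:
            if pheno == "2":
                return cls(iid, None, None, {iid: True})
        raise ValueError("no affected sample in PED file")


@dataclass
class FilterStep:
    name: str
    params: dict
    n_in: int
    n_out: int


@dataclass
class FilterSpec:
    """One declarative cascade step: a named predicate plus parameters."""

    name: str
    params: dict = field(default_factory=dict)


@dataclass
class FilterCascade:
    steps: list[FilterSpec] = field(default_factory=list)


@dataclass
class Protocol:
    name: str
    analysis_type: str = "single-exome"
    genetic_models: list[str] = field(default_factory=lambda: ["dominant_het"])
    keyword_query: KeywordQuery | None = None
    af_cutoff: float = DEFAULT_AF_CUTOFF
    gene_panel: list[str] | None = None
    report_template: str = "default"
    reliability: ReliabilityThresholds = field(default_factory=ReliabilityThresholds)
    cascades: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0 <= self.af_cutoff <= 1:
            raise ValueError("af_cutoff outside [0,1]")
        if not self.genetic_models:
            raise ValueError("a protocol needs at least one genetic model")

    @classmethod
    def from_yaml(cls, path: str) -> "Protocol":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        query = None
        if cfg.get("keywords"):
            query = parse_keywords(cfg["keywords"], cfg.get("keyword_operator", "OR"))
        rel = ReliabilityThresholds(**cfg.get("reliability", {}))
        cascades = {
            model: FilterCascade(
                [FilterSpec(s["name"], s.get("params", {})) for s in steps]
            )
            for model, steps in cfg.get("cascades", {}).items()
        }
        return cls(
            name=cfg["name"],
            analysis_type=cfg.get("analysis_type", "single-exome"),
            genetic_models=cfg.get("genetic_models", ["dominant_het"]),
            keyword_query=query,
            af_cutoff=float(cfg.get("af_cutoff", DEFAULT_AF_CUTOFF)),
            gene_panel=cfg.get("gene_panel"),
            report_template=cfg.get("report_template", "default"),
            reliability=rel,
            cascades=cascades,
        )


# ---------------------------------------------------------------------------
# reliability


def reliability_filter(
    v: AnnotatedVariant,
    proband_id: str,
    thresholds: ReliabilityThresholds | None = None,
) -> tuple[bool, str]:
    """Low-reliability gate on quality, depth and alt-read fraction of the
    proband genotype.  Returns (passed, reason)."""
    t = thresholds or ReliabilityThresholds()
    g = v.record.genotype_of(proband_id)
    if g is None or g.depth is None or g.alt_fraction is None:
        return False, "missing_metrics"
    if v.record.qual is not None and v.record.qual < t.min_qual:
        return False, "low_qual"
    if g.depth < t.min_depth:
        return False, "low_depth"
    if g.alt_fraction < t.min_alt_fraction:
        return False, "low_alt_fraction"
    return True, "pass"


# ---------------------------------------------------------------------------
# cascade engine

_PREDICATES = {}


def _predicate(name):
    def deco(fn):
        _PREDICATES[name] = fn
        return fn
    return deco


@_predicate("zygosity")
def _p_zygosity(v: AnnotatedVariant, params: dict) -> bool:
    g = v.record.genotype_of(params["sample"])
    return g is not None and g.zygosity == params["is"]


@_predicate("max_af_below")
def _p_max_af(v: AnnotatedVariant, params: dict) -> bool:
    if v.frequency is None:
        raise KeyError("frequency")
    return v.frequency.max_af < params["cutoff"]


@_predicate("severity_in")
def _p_severity(v: AnnotatedVariant, params: dict) -> bool:
    if v.consequence is None:
        raise KeyError("consequence")
    return v.consequence.severity_tier in params["tiers"]


@_predicate("reliability")
def _p_reliability(v: AnnotatedVariant, params: dict) -> bool:
    thresholds = ReliabilityThresholds(**params.get("thresholds", {}))
    ok, _ = reliability_filter(v, params["sample"], thresholds)
    return ok


@_predicate("gene_in")
def _p_gene_in(v: AnnotatedVariant, params: dict) -> bool:
    return v.gene_symbol in set(params["genes"])


@_predicate("acmg_in")
def _p_acmg(v: AnnotatedVariant, params: dict) -> bool:
    if v.acmg is None:
        raise KeyError("acmg")
    return v.acmg.classification in params["classes"]


def apply_cascade(
    variants: list[AnnotatedVariant], cascade: FilterCascade
) -> tuple[list[AnnotatedVariant], list[FilterStep]]:
    """Apply cascade steps in order, logging survivor counts per step.

    A step naming an unknown predicate or touching a missing annotation
    column raises ``KeyError`` naming it.
    """
    survivors = list(variants)
    log: list[FilterStep] = []
    for spec in cascade.steps:
        if spec.name not in _PREDICATES:
            raise KeyError(f"unknown filter column/predicate: {spec.name}")
        pred = _PREDICATES[spec.name]
        n_in = len(survivors)
        survivors = [v for v in survivors if pred(v, spec.params)]
        log.append(FilterStep(spec.name, dict(spec.params), n_in, len(survivors)))
    return survivors, log


# ---------------------------------------------------------------------------
# genetic models


@dataclass
class ModelResult:
    model: str
    candidates: list[AnnotatedVariant]
    steps: list[FilterStep]
    #: compound-het gene groups (gene -> variants) when applicable
    gene_groups: dict = field(default_factory=dict)


def _zyg(v: AnnotatedVariant, sample: str | None) -> str | None:
    if sample is None:
        return None
    g = v.record.genotype_of(sample)
    return g.zygosity if g else None


def _parent_depth_ok(v: AnnotatedVariant, sample: str | None) -> bool:
    if sample is None:
        return False
    g = v.record.genotype_of(sample)
    return g is not None and g.depth is not None and g.depth >= DE_NOVO_MIN_PARENT_DEPTH


def _core_gates(
    variants: list[AnnotatedVariant],
    pedigree: PedigreeTrio,
    protocol: Protocol,
    zygosity: str,
) -> tuple[list[AnnotatedVariant], list[FilterStep]]:
    cascade = FilterCascade(
        [
            FilterSpec("zygosity", {"sample": pedigree.proband_id, "is": zygosity}),
            FilterSpec(
                "reliability",
                {"sample": pedigree.proband_id,
                 "thresholds": vars(protocol.reliability)},
            ),
            FilterSpec("max_af_below", {"cutoff": protocol.af_cutoff}),
            FilterSpec("severity_in", {"tiers": list(SEVERITY_GATE)}),
        ]
    )
    return apply_cascade(variants, cascade)


def model_dominant_het(
    variants: list[AnnotatedVariant],
    pedigree: PedigreeTrio,
    protocol: Protocol,
) -> ModelResult:
    """HET in the proband, reliable, rare, damaging; trios additionally get
    a de-novo flag when both parents are confidently homozygous reference."""
    candidates, steps = _core_gates(variants, pedigree, protocol, HET)
    if pedigree.is_trio:
        for v in candidates:
            if (
                _zyg(v, pedigree.mother_id) == HOM_REF
                and _zyg(v, pedigree.father_id) == HOM_REF
            ):
                if _parent_depth_ok(v, pedigree.mother_id) and _parent_depth_ok(
                    v, pedigree.father_id
                ):
                    v.flags.append("de_novo")
                else:
                    v.flags.append("de_novo_unconfirmed")
    return ModelResult("dominant_het", candidates, steps)


def model_recessive_hom(
    variants: list[AnnotatedVariant],
    pedigree: PedigreeTrio,
    protocol: Protocol,
) -> ModelResult:
    """Homozygous-alternative in the proband; in trios, parents are expected
    HET — violations are flagged, never dropped.  Hemizygous calls on a male
    X behave as HOM_ALT upstream."""
    candidates, steps = _core_gates(variants, pedigree, protocol, HOM_ALT)
    if pedigree.is_trio:
        for v in candidates:
            mz, fz = _zyg(v, pedigree.mother_id), _zyg(v, pedigree.father_id)
            if mz != HET or fz != HET:
                v.flags.append("mendelian_inconsistent")
    return ModelResult("recessive_hom", candidates, steps)


def _transmission(v: AnnotatedVariant, pedigree: PedigreeTrio) -> str:
    """Which parent carries the alt allele of a proband-HET variant:
    'maternal', 'paternal', 'both', or 'neither'."""
    m = _zyg(v, pedigree.mother_id) in (HET, HOM_ALT)
    f = _zyg(v, pedigree.father_id) in (HET, HOM_ALT)
    if m and f:
        return "both"
    if m:
        return "maternal"
    if f:
        return "paternal"
    return "neither"


def model_compound_het(
    variants: list[AnnotatedVariant],
    pedigree: PedigreeTrio,
    protocol: Protocol,
) -> ModelResult:
    """Genes with at least two passing HET variants.  With a trio, the pair
    must be explainable in trans: at least one variant transmitted only by
    the mother and one only by the father.  Without parents the group is
    kept and flagged phase_unknown."""
    passing, steps = _core_gates(variants, pedigree, protocol, HET)
    by_gene: dict[str, list[AnnotatedVariant]] = {}
    for v in passing:
        if v.gene_symbol:
            by_gene.setdefault(v.gene_symbol, []).append(v)
    groups: dict[str, list[AnnotatedVariant]] = {}
    candidates: list[AnnotatedVariant] = []
    for gene, vs in sorted(by_gene.items()):
        if len(vs) < 2:
            continue
        if pedigree.is_trio:
            sides = {_transmission(v, pedigree) for v in vs}
            if not ({"maternal"} <= sides and {"paternal"} <= sides):
                continue
        else:
            for v in vs:
                if "phase_unknown" not in v.flags:
                    v.flags.append("phase_unknown")
        groups[gene] = vs
        candidates.extend(vs)
    return ModelResult("compound_het", candidates, steps, gene_groups=groups)


def incidental_findings(
    variants: list[AnnotatedVariant], panel: list[str]
) -> ModelResult:
    """Pathogenic / likely-pathogenic variants in the secondary-findings
    gene panel, reported regardless of phenotype score."""
    steps = []
    if not panel:
        return ModelResult("incidental", [], [FilterStep("panel", {"genes": []}, len(variants), 0)])
    panel_set = set(panel)
    n_in = len(variants)
    in_panel = [v for v in variants if v.gene_symbol in panel_set]
    steps.append(FilterStep("gene_in", {"genes": sorted(panel_set)}, n_in, len(in_panel)))
    hits = [
        v
        for v in in_panel
        if v.acmg is not None
        and v.acmg.classification in ("pathogenic", "likely_pathogenic")
    ]
    steps.append(
        FilterStep(
            "acmg_in",
            {"classes": ["pathogenic", "likely_pathogenic"]},
            len(in_panel),
            len(hits),
        )
    )
    return ModelResult("incidental", hits, steps)


def sort_candidates(candidates: list[AnnotatedVariant]) -> list[AnnotatedVariant]:
    """Default candidate ordering: phenotype score descending, then matched
    term count, then genomic coordinate for determinism."""
    def keyfn(v: AnnotatedVariant):
        total = v.phenotype_score.total if v.phenotype_score else 0.0
        return (-total, -v.matched_phenotype_count, v.record.chrom, v.record.pos)

    return sorted(candidates, key=keyfn)


MODEL_FUNCS = {
    "dominant_het": model_dominant_het,
    "recessive_hom": model_recessive_hom,
    "compound_het": model_compound_het,
}
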