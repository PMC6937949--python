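"""Automated ACMG/AMP 2015 evidence assignment and five-class combination.

Twelve criteria that can be decided from local annotation alone are
implemented (PVS1, PS1, PM2, PM4, PM5, PP3, PP5, BA1, BS1, BP4, BP6, BP7).
Criteria requiring segregation, functional assays or confirmed de novo
status are left to analyst judgment and never auto-assigned.

Classification follows the published combining rules; when both a
pathogenic-side and a benign-side rule fire, the variant is reported as of
uncertain significance (the contradiction clause).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .annotate import AnnotatedVariant, NULL_EFFECTS

#: default evidence strength by criterion prefix
CRITERION_STRENGTH = {
    "PVS1": "very_strong",
    "PS1": "strong",
    "PM2": "moderate",
    "PM4": "moderate",
    "PM5": "moderate",
    "PP3": "supporting",
    "PP5": "supporting",
    "BA1": "stand_alone",
    "BS1": "strong",
    "BP4": "supporting",
    "BP6": "supporting",
    "BP7": "supporting",
}
IMPLEMENTED_CODES = tuple(CRITERION_STRENGTH)

CLASSES = (
    "benign",
    "likely_benign",
    "uncertain_significance",
    "likely_pathogenic",
    "pathogenic",
)

#: PM2 numeric proxy for "absent from controls"
PM2_MAX_AF = 1e-5
BA1_MIN_AF = 0.05


@dataclass(frozen=True)
class CriterionEvidence:
    code: str
    rationale: str = ""

    def __post_init__(self):
        if self.code not in CRITERION_STRENGTH:
            raise ValueError(f"unknown ACMG criterion {self.code!r}")

    @property
    def strength(self) -> str:
        return CRITERION_STRENGTH[self.code]


@dataclass
class AcmgAssessment:
    criteria: list[CriterionEvidence]
    classification: str

    @property
    def codes(self) -> list[str]:
        return [c.code for c in self.criteria]

    def serialize_codes(self) -> str:
        return ",".join(self.codes)


@dataclass
class GeneKnowledge:
    """Per-gene curated flags for criterion assignment."""

    gene_symbol: str
    lof_mechanism: bool = False
    disease_af_cutoff: float = 0.001


def load_gene_knowledge_tsv(path: str) -> dict[str, GeneKnowledge]:
    out = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            out[row["gene_symbol"]] = GeneKnowledge(
                row["gene_symbol"],
                row["lof_mechanism"] in ("1", "true", "True"),
                float(row["disease_af_cutoff"]),
            )
    return out


def _residue(aa_change: str) -> str:
    """'p.E123*' -> 'E123' (reference residue + position)."""
    s = aa_change[2:] if aa_change.startswith("p.") else aa_change
    out = s[:1]
    for ch in s[1:]:
        if ch.isdigit():
            out += ch
        else:
            break
    return out


def assign_criteria(
    v: AnnotatedVariant, gene_knowledge: dict[str, GeneKnowledge] | None = None
) -> list[CriterionEvidence]:
    """Assign automatable criteria from the variant's annotation blocks.

    Criteria whose required annotation block is missing are withheld and
    listed in ``v.flags`` for the run log.
    """
    gene_knowledge = gene_knowledge or {}
    crit: list[CriterionEvidence] = []
    gk = gene_knowledge.get(v.gene_symbol)
    cons = v.consequence

    if cons is not None:
        if cons.effect in NULL_EFFECTS and gk is not None and gk.lof_mechanism:
            crit.append(
                CriterionEvidence("PVS1", f"{cons.effect} in LOF-mechanism gene")
            )
        if cons.effect == "inframe_indel":
            crit.append(CriterionEvidence("PM4", "in-frame length change"))
        if cons.effect == "synonymous" and not any(
            c.effect == "splice_region" for c in v.all_calls
        ):
            crit.append(CriterionEvidence("BP7", "synonymous, no splice impact"))

    if v.frequency is not None:
        max_af = v.frequency.max_af
        if max_af < PM2_MAX_AF:
            crit.append(CriterionEvidence("PM2", f"max_af {max_af:g} below {PM2_MAX_AF:g}"))
        if max_af >= BA1_MIN_AF:
            crit.append(CriterionEvidence("BA1", f"max_af {max_af:g} >= {BA1_MIN_AF:g}"))
        elif gk is not None and max_af >= gk.disease_af_cutoff:
            crit.append(
                CriterionEvidence("BS1", f"max_af {max_af:g} above disease cutoff")
            )
    else:
        v.flags.append("acmg:frequency_block_missing")

    path_sigs = {"pathogenic", "likely_pathogenic"}
    benign_sigs = {"benign", "likely_benign"}
    sigs = {a.significance for a in v.assertions}
    if sigs & path_sigs and not sigs & benign_sigs:
        crit.append(CriterionEvidence("PP5", "reported pathogenic, no conflict"))
    if sigs & benign_sigs and not sigs & path_sigs:
        crit.append(CriterionEvidence("BP6", "reported benign, no conflict"))

    if cons is not None and cons.aa_change:
        # residue-level comparisons against pathogenic assertions in the gene
        my_res = _residue(cons.aa_change)
        same_change = False
        same_residue_other = False
        for a in _assertion_pool(v):
            if a.significance not in path_sigs or not a.aa_change:
                continue
            if a.aa_change == cons.aa_change:
                same_change = True
            elif _residue(a.aa_change) == my_res:
                same_residue_other = True
        if same_change:
            crit.append(CriterionEvidence("PS1", "same amino-acid change reported pathogenic"))
        elif same_residue_other:
            crit.append(CriterionEvidence("PM5", "novel change at reported pathogenic residue"))

    if v.predictions is not None:
        consensus = v.predictions.consensus_severity
        if consensus == "damaging":
            crit.append(CriterionEvidence("PP3", "prediction consensus damaging"))
        elif consensus == "tolerated":
            crit.append(CriterionEvidence("BP4", "prediction consensus tolerated"))
    else:
        v.flags.append("acmg:prediction_block_missing")

    order = {c: i for i, c in enumerate(IMPLEMENTED_CODES)}
    return sorted(crit, key=lambda c: order[c.code])


def _assertion_pool(v: AnnotatedVariant):
    """Assertions visible for residue-level matching: the variant's own plus
    any gene-level pool attached by the annotation stage."""
    pool = list(v.assertions)
    if v.gene_assertion_pool:
        pool.extend(v.gene_assertion_pool)
    return pool


# ---------------------------------------------------------------------------
# combining rules


def _counts(criteria: Iterable[CriterionEvidence]) -> dict[str, int]:
    n = {"stand_alone": 0, "very_strong": 0, "ps": 0, "pm": 0, "pp": 0, "bs": 0, "bp": 0}
    for c in criteria:
        code, strength = c.code, c.strength
        if code.startswith("B"):
            if strength == "stand_alone":
                n["stand_alone"] += 1
            elif strength == "strong":
                n["bs"] += 1
            else:
                n["bp"] += 1
        else:
            if strength == "very_strong":
                n["very_strong"] += 1
            elif strength == "strong":
                n["ps"] += 1
            elif strength == "moderate":
                n["pm"] += 1
            else:
                n["pp"] += 1
    return n


def combine_criteria(criteria: list[CriterionEvidence]) -> str:
    """Five-class combination per the 2015 guideline rules, with the
    contradiction clause mapping mixed evidence to uncertain significance."""
    n = _counts(criteria)
    pvs, ps, pm, pp = n["very_strong"], n["ps"], n["pm"], n["pp"]
    ba, bs, bp = n["stand_alone"], n["bs"], n["bp"]

    # contradiction clause: evidence on both sides is unresolvable here
    if (pvs + ps + pm + pp > 0) and (ba + bs + bp > 0):
        return "uncertain_significance"

    pathogenic = (
        (pvs >= 1 and (ps >= 1 or pm >= 2 or (pm == 1 and pp == 1) or pp >= 2))
        or ps >= 2
        or (ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)))
    )
    likely_pathogenic = (
        (pvs >= 1 and pm >= 1)
        or (ps == 1 and 1 <= pm <= 2)
        or (ps == 1 and pp >= 2)
        or pm >= 3
        or (pm == 2 and pp >= 2)
        or (pm == 1 and pp >= 4)
    )
    benign = ba >= 1 or bs >= 2
    likely_benign = (bs == 1 and bp >= 1) or bp >= 2

    if pathogenic:
        return "pathogenic"
    if likely_pathogenic:
        return "likely_pathogenic"
    if benign:
        return "benign"
    if likely_benign:
        return "likely_benign"
    return "uncertain_significance"


def assess(
    v: AnnotatedVariant, gene_knowledge: dict[str, GeneKnowledge] | None = None
) -> AcmgAssessment:
    criteria = assign_criteria(v, gene_knowledge)
    assessment = AcmgAssessment(criteria, combine_criteria(criteria))
    v.acmg = assessment
    return assessment
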