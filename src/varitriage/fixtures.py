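"""Synthetic study-condition generator: a toy genome with valid multi-exon
ORFs, a local knowledgebase (gene documents, gene links, frequency /
assertion / prediction tables, regulatory-element map), and simulated
singleton or trio cases with planted causal truths.

Every emitted dataset is deterministic in the seed (identical bytes for an
identical seed).  Background variants carry control-population frequencies
of at least 0.5%, so a 0.1% frequency gate separates them from planted
causal variants by construction; trio genotypes are generated by explicit
allele transmission, so Mendelian consistency holds everywhere except
where a scenario plants a de novo allele.
"""

from __future__ import annotations

import hashlib
import json
import os
import random
import zlib
from dataclasses import asdict, dataclass, field

from .annotate import (
    CODON_TABLE,
    TranscriptModel,
    _call_one,
    revcomp,
)
from .case_store import CaseRecord, CaseStore, GenotypeSummary, VariantSelection
from .vcf_ingest import RawVariantRecord, normalize_indel

BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")
CODING_CODONS = sorted(set(CODON_TABLE) - set(STOP_CODONS) - {"ATG"})

SCENARIOS = {
    "de_novo_dominant": {
        "causal_gene": "GENE01",
        "decoy_gene": "GENE02",
        "keywords": ["short stature", "skeletal dysplasia"],
        "model": "dominant_het",
    },
    "recessive_hom": {
        "causal_gene": "GENE03",
        "decoy_gene": "GENE04",
        "keywords": ["seizures", "epileptic encephalopathy"],
        "model": "recessive_hom",
    },
    "compound_het": {
        "causal_gene": "GENE05",
        "decoy_gene": "GENE06",
        "keywords": ["chronic diarrhea", "failure to thrive"],
        "model": "compound_het",
    },
    "incidental": {
        "causal_gene": "GENE07",
        "decoy_gene": "GENE08",
        "keywords": ["hearing loss"],
        "model": "incidental",
    },
    "enhancer_sv": {
        "causal_gene": "GENE09",
        "decoy_gene": "GENE11",
        "host_gene": "GENE10",
        "keywords": ["developmental delay", "hypotonia"],
        "model": "sv",
    },
}

#: ACMG secondary-findings panel stand-in (the real list is user-supplied)
INCIDENTAL_PANEL = ["GENE07", "GENE08"]

GENE_CHROMS = {f"GENE{i:02d}": ("1" if i <= 6 else "2") for i in range(1, 13)}


@dataclass
class SimulationConfig:
    seed: int = 7
    n_background_variants: int = 120
    n_background_sv: int = 4
    trio: bool = True
    af_beta_a: float = 2.0
    af_beta_b: float = 8.0
    min_background_af: float = 0.005
    multiallelic_fraction: float = 0.05
    indel_fraction: float = 0.05


@dataclass
class PlantedTruth:
    scenario: str
    causal_gene: str
    expected_model: str
    keywords: list[str]
    variant_keys: list[tuple] = field(default_factory=list)
    sv_event: tuple | None = None  # (chrom, start, end, type)


# ---------------------------------------------------------------------------
# toy genome


@dataclass
class ToyGenome:
    sequences: dict  # chrom -> str
    transcripts: list  # TranscriptModel
    enhancer: dict  # element description for the element map

    def reference(self, chrom: str, start: int, end: int) -> str:
        return self.sequences[chrom][start - 1 : end]

    def transcript_of(self, gene: str) -> TranscriptModel:
        for tx in self.transcripts:
            if tx.gene_symbol == gene:
                return tx
        raise KeyError(gene)


def _random_orf(rng: random.Random, n_codons: int) -> str:
    body = "".join(rng.choice(CODING_CODONS) for _ in range(n_codons - 2))
    return "ATG" + body + rng.choice(STOP_CODONS)


def _build_gene(rng: random.Random, min_intron: int = 80, max_intron: int = 150):
    """Return (local_sequence, local_exons, cds_start, cds_end) on the
    forward strand of the gene's local coordinate system."""
    n_codons = rng.randint(60, 110)
    cds = _random_orf(rng, n_codons)
    utr5 = "".join(rng.choice(BASES) for _ in range(rng.randint(20, 40)))
    utr3 = "".join(rng.choice(BASES) for _ in range(rng.randint(20, 40)))
    mrna = utr5 + cds + utr3
    n_exons = rng.randint(2, 4)
    # cut the mRNA into exon pieces of at least 25 bp
    cuts = sorted(rng.sample(range(25, len(mrna) - 25), n_exons - 1))
    while len(set(cuts)) < n_exons - 1 or any(
        b - a < 25 for a, b in zip(cuts, cuts[1:])
    ):
        cuts = sorted(rng.sample(range(25, len(mrna) - 25), n_exons - 1))
    bounds = [0] + cuts + [len(mrna)]
    pieces = [mrna[a:b] for a, b in zip(bounds, bounds[1:])]
    seq_parts = []
    exons = []
    mrna_to_local = {}
    offset = 0
    mrna_pos = 0
    for i, piece in enumerate(pieces):
        if i > 0:
            ilen = rng.randint(min_intron, max_intron)
            intron = "GT" + "".join(rng.choice(BASES) for _ in range(ilen - 4)) + "AG"
            seq_parts.append(intron)
            offset += ilen
        exons.append((offset + 1, offset + len(piece)))
        for j in range(len(piece)):
            mrna_to_local[mrna_pos + j] = offset + 1 + j
        seq_parts.append(piece)
        offset += len(piece)
        mrna_pos += len(piece)
    local_seq = "".join(seq_parts)
    cds_start = mrna_to_local[len(utr5)]
    cds_end = mrna_to_local[len(utr5) + len(cds) - 1]
    return local_seq, exons, cds_start, cds_end


def make_toy_reference_and_transcripts(config: SimulationConfig) -> ToyGenome:
    """Twelve genes on two chromosomes, alternating strands, multi-exon,
    valid ORFs.  An intronic regulatory element inside GENE10 targets the
    distal GENE09 (placed over 100 kb away)."""
    rng = random.Random(config.seed * 2654435761 % (2**31))
    chrom_parts: dict[str, list] = {"1": [], "2": []}
    chrom_len = {"1": 0, "2": 0}
    transcripts = []
    gene10_intron_local = None
    gene10_offset = None
    for i in range(1, 13):
        gene = f"GENE{i:02d}"
        chrom = GENE_CHROMS[gene]
        strand = "+" if i % 2 else "-"
        gap = rng.randint(400, 800)
        if gene == "GENE10":
            gap += 100_000  # distal enhancer-target geometry
        chrom_parts[chrom].append(
            "".join(rng.choice(BASES) for _ in range(gap))
        )
        chrom_len[chrom] += gap
        local_seq, exons, cds_s, cds_e = _build_gene(rng)
        L = len(local_seq)
        if strand == "-":
            local_seq = revcomp(local_seq)
            exons = sorted((L - e + 1, L - s + 1) for s, e in exons)
            cds_s, cds_e = L - cds_e + 1, L - cds_s + 1
        offset = chrom_len[chrom]
        genomic_exons = [(offset + s, offset + e) for s, e in exons]
        transcripts.append(
            TranscriptModel(
                f"{gene}.t1", gene, chrom, strand,
                genomic_exons, offset + cds_s, offset + cds_e,
            )
        )
        if gene == "GENE10":
            gene10_offset = offset
            # first intron in genomic order
            gene10_intron_local = (exons[0][1] + 1, exons[1][0] - 1)
        chrom_parts[chrom].append(local_seq)
        chrom_len[chrom] += L
    for chrom in chrom_parts:
        tail = "".join(rng.choice(BASES) for _ in range(300))
        chrom_parts[chrom].append(tail)
    sequences = {c: "".join(parts) for c, parts in chrom_parts.items()}

    istart = gene10_offset + gene10_intron_local[0] + 10
    iend = min(istart + 40, gene10_offset + gene10_intron_local[1] - 2)
    enhancer = {
        "element_id": "GH_E001",
        "chrom": "2",
        "start": istart,
        "end": iend,
        "confidence": 0.9,
        "targets": [("GENE09", 0.85), ("GENE10", 0.6)],
    }
    return ToyGenome(sequences, transcripts, enhancer)


def write_fasta(sequences: dict, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sequences):
            fh.write(f">{chrom}\n")
            seq = sequences[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_transcripts_tsv(transcripts: list, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tgene_symbol\tchrom\tstrand\texons\tcds_start\tcds_end\n")
        for tx in transcripts:
            exons = ",".join(f"{s}-{e}" for s, e in tx.exons)
            fh.write(
                f"{tx.transcript_id}\t{tx.gene_symbol}\t{tx.chrom}\t{tx.strand}"
                f"\t{exons}\t{tx.cds_start}\t{tx.cds_end}\n"
            )


def write_regions_bed(transcripts: list, path: str, pad: int = 25) -> None:
    """Exome-style BED: padded exon intervals (0-based half-open)."""
    ivs = []
    for tx in transcripts:
        for s, e in tx.exons:
            ivs.append((tx.chrom, max(0, s - 1 - pad), e + pad))
    ivs.sort()
    with open(path, "w") as fh:
        for chrom, s, e in ivs:
            fh.write(f"{chrom}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# knowledgebase


_GENERIC = {
    "summaries": "{g} encodes a conserved protein expressed in multiple tissues.",
    "function": "The {g} product participates in cellular signaling and transport.",
    "pathways": "{g} is a member of the core metabolism pathway set.",
    "publications": "Early reports describe {g} cloning and expression patterns.",
}


def make_gene_docs() -> dict:
    """Sectioned per-gene documents: causal genes carry their scenario
    keywords in the disorders and phenotypes sections; each decoy carries a
    partial match in its publications section only."""
    docs = {}
    for gene in GENE_CHROMS:
        sections = {k: v.format(g=gene) for k, v in _GENERIC.items()}
        sections["disorders"] = f"No disease association is curated for {gene}."
        sections["phenotypes"] = f"No phenotype records are curated for {gene}."
        docs[gene] = sections
    for scenario, spec in SCENARIOS.items():
        kws = spec["keywords"]
        causal = spec["causal_gene"]
        docs[causal]["disorders"] = (
            f"Biallelic and heterozygous defects of {causal} cause a syndrome of "
            + " and ".join(kws)
            + f". Affected probands show {kws[0]} from infancy."
        )
        docs[causal]["phenotypes"] = (
            f"Cardinal features: {kws[0]}; also reported: "
            + "; ".join(kws)
            + "."
        )
        decoy = spec["decoy_gene"]
        docs[decoy]["publications"] = (
            f"A single case report mentioned {kws[0]} in a carrier of a common "
            f"{decoy} polymorphism."
        )
    host = SCENARIOS["enhancer_sv"]["host_gene"]
    docs[host]["publications"] = (
        f"One abstract speculated about hypotonia in {host} knockout mice."
    )
    return docs


def write_gene_docs(docs: dict, directory: str) -> None:
    os.makedirs(directory, exist_ok=True)
    for gene in sorted(docs):
        with open(os.path.join(directory, f"{gene}.json"), "w") as fh:
            json.dump(
                {"gene_symbol": gene, "sections": docs[gene]},
                fh,
                sort_keys=True,
                indent=1,
            )
            fh.write("\n")


def make_links() -> list[tuple]:
    """gene_a, gene_b, link_type, weight — gives each causal gene one
    pathway neighbor so indirect scoring has structure to traverse."""
    return [
        ("GENE01", "GENE12", "shared_pathway", 0.7),
        ("GENE03", "GENE04", "interaction", 0.5),
        ("GENE05", "GENE06", "shared_pathway", 0.8),
        ("GENE09", "GENE10", "shared_pathway", 0.6),
    ]


def write_links_tsv(links: list, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tlink_type\tweight\n")
        for a, b, t, w in links:
            fh.write(f"{a}\t{b}\t{t}\t{w}\n")


def write_gene_flags_tsv(path: str) -> None:
    lof = {"GENE01", "GENE05", "GENE07", "GENE09"}
    with open(path, "w") as fh:
        fh.write("gene_symbol\tlof_mechanism\tdisease_af_cutoff\n")
        for gene in sorted(GENE_CHROMS):
            fh.write(f"{gene}\t{1 if gene in lof else 0}\t0.001\n")


def write_elements_tsv(enhancer: dict, path: str) -> None:
    targets = ";".join(f"{g}:{c}" for g, c in enhancer["targets"])
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\telement_id\tconfidence\ttargets\n")
        fh.write(
            f"{enhancer['chrom']}\t{enhancer['start']}\t{enhancer['end']}"
            f"\t{enhancer['element_id']}\t{enhancer['confidence']}\t{targets}\n"
        )


def write_panel(path: str) -> None:
    with open(path, "w") as fh:
        for g in INCIDENTAL_PANEL:
            fh.write(g + "\n")


def write_manifest(directory: str, table_files: list[str], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("name\tversion\tchecksum\n")
        for name in sorted(table_files):
            full = os.path.join(directory, name)
            h = hashlib.sha256()
            if os.path.isdir(full):
                for f in sorted(os.listdir(full)):
                    with open(os.path.join(full, f), "rb") as g:
                        h.update(g.read())
            else:
                with open(full, "rb") as g:
                    h.update(g.read())
            fh.write(f"{name}\tfixture-1.0\t{h.hexdigest()[:16]}\n")


# ---------------------------------------------------------------------------
# case simulation


def _cds_positions(tx: TranscriptModel) -> list[int]:
    out = []
    for s, e in tx.cds_intervals():
        out.extend(range(s, e + 1))
    return out


def find_snv_with_effect(
    tx: TranscriptModel, genome: ToyGenome, effect: str, rng: random.Random,
    forbidden: set,
) -> tuple[int, str, str, str]:
    """Search the CDS for an SNV producing the requested effect on this
    transcript; returns (pos, ref, alt, aa_change)."""
    positions = _cds_positions(tx)
    rng.shuffle(positions)
    for pos in positions:
        if (tx.chrom, pos) in forbidden:
            continue
        ref = genome.reference(tx.chrom, pos, pos)
        for alt in BASES:
            if alt == ref:
                continue
            rec = RawVariantRecord(tx.chrom, pos, ref, (alt,))
            call = _call_one(rec, tx, genome.reference)
            if call.effect == effect:
                return pos, ref, alt, call.aa_change
    raise RuntimeError(f"no {effect} SNV found in {tx.transcript_id}")


def find_frameshift_deletion(
    tx: TranscriptModel, genome: ToyGenome, rng: random.Random, forbidden: set
) -> tuple[int, str, str]:
    """A 1-bp CDS deletion, emitted in its normalized (left-aligned)
    representation so downstream table joins see the same key."""
    positions = [p for p in _cds_positions(tx)[10:-10]]
    rng.shuffle(positions)
    for pos in positions:
        if (tx.chrom, pos) in forbidden or (tx.chrom, pos + 1) in forbidden:
            continue
        ref = genome.reference(tx.chrom, pos, pos + 1)
        rec = RawVariantRecord(tx.chrom, pos, ref, (ref[0],))
        norm = normalize_indel(rec, genome.reference)
        if any((tx.chrom, p) in forbidden
               for p in range(norm.pos, norm.pos + len(norm.ref))):
            continue
        if _call_one(norm, tx, genome.reference).effect == "frameshift":
            return norm.pos, norm.ref, norm.alt
    raise RuntimeError(f"no frameshift deletion found in {tx.transcript_id}")


@dataclass
class _PlantedVariant:
    chrom: str
    pos: int
    ref: str
    alts: tuple
    genotypes: dict  # sample -> genotype index pair
    aa_change: str = ""
    predictions: dict | None = None
    assertion: dict | None = None


def _hwe_genotype(rng: random.Random, af: float) -> tuple[int, int]:
    return (int(rng.random() < af), int(rng.random() < af))


def simulate_case(
    config: SimulationConfig,
    genome: ToyGenome,
    scenario: str,
    out_dir: str,
) -> PlantedTruth:
    """Emit a trio (or singleton) case for one scenario: VCF + PED + SV
    table + protocol YAML + knowledge tables + expected-answer sheet.

    Raises ``ValueError`` for scenarios whose genotype pattern needs a trio
    (de novo, compound het phase) when ``config.trio`` is false.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    if not config.trio and scenario in ("de_novo_dominant",):
        raise ValueError(f"scenario {scenario} requires a trio")
    spec = SCENARIOS[scenario]
    rng = random.Random(
        (config.seed * 1_000_003 + zlib.crc32(scenario.encode()) % 997) % (2**31)
    )
    os.makedirs(out_dir, exist_ok=True)

    samples = ["PROBAND", "MOTHER", "FATHER"] if config.trio else ["PROBAND"]
    forbidden: set = set()
    planted: list[_PlantedVariant] = []
    truth = PlantedTruth(
        scenario=scenario,
        causal_gene=spec["causal_gene"],
        expected_model=spec["model"],
        keywords=list(spec["keywords"]),
    )

    def occupy(chrom, pos, span=1):
        for p in range(pos, pos + span):
            forbidden.add((chrom, p))

    # --- plant the causal records ------------------------------------------
    if scenario == "de_novo_dominant":
        tx = genome.transcript_of(spec["causal_gene"])
        pos, ref, alt, aa = find_snv_with_effect(tx, genome, "stop_gained", rng, forbidden)
        gts = {"PROBAND": (0, 1), "MOTHER": (0, 0), "FATHER": (0, 0)}
        planted.append(_PlantedVariant(tx.chrom, pos, ref, (alt,), gts, aa))
        occupy(tx.chrom, pos)
    elif scenario == "recessive_hom":
        tx = genome.transcript_of(spec["causal_gene"])
        pos, ref, alt, aa = find_snv_with_effect(tx, genome, "missense", rng, forbidden)
        gts = {"PROBAND": (1, 1), "MOTHER": (0, 1), "FATHER": (0, 1)}
        planted.append(
            _PlantedVariant(
                tx.chrom, pos, ref, (alt,), gts, aa,
                predictions={
                    "sift_like": "damaging",
                    "polyphen_like": "damaging",
                    "mutationtaster_like": "damaging",
                    "gerp_like": "unknown",
                },
                assertion={
                    "source": "clinvar_like",
                    "condition": "epileptic encephalopathy",
                    "significance": "pathogenic",
                    "aa_change": aa,
                },
            )
        )
        occupy(tx.chrom, pos)
    elif scenario == "compound_het":
        tx = genome.transcript_of(spec["causal_gene"])
        pos1, ref1, alt1, aa1 = find_snv_with_effect(tx, genome, "stop_gained", rng, forbidden)
        occupy(tx.chrom, pos1)
        pos2, ref2, alt2, aa2 = find_snv_with_effect(tx, genome, "missense", rng, forbidden)
        occupy(tx.chrom, pos2)
        planted.append(
            _PlantedVariant(
                tx.chrom, pos1, ref1, (alt1,),
                {"PROBAND": (0, 1), "MOTHER": (0, 1), "FATHER": (0, 0)}, aa1,
            )
        )
        planted.append(
            _PlantedVariant(
                tx.chrom, pos2, ref2, (alt2,),
                {"PROBAND": (0, 1), "MOTHER": (0, 0), "FATHER": (0, 1)}, aa2,
                predictions={
                    "sift_like": "damaging",
                    "polyphen_like": "damaging",
                    "mutationtaster_like": "tolerated",
                    "gerp_like": "damaging",
                },
            )
        )
    elif scenario == "incidental":
        tx = genome.transcript_of(spec["causal_gene"])
        pos, ref, alt = find_frameshift_deletion(tx, genome, rng, forbidden)
        gts = {"PROBAND": (0, 1), "MOTHER": (0, 1), "FATHER": (0, 0)}
        planted.append(
            _PlantedVariant(
                tx.chrom, pos, ref, (alt,), gts,
                assertion={
                    "source": "clinvar_like",
                    "condition": "hereditary cancer predisposition",
                    "significance": "pathogenic",
                    "aa_change": "",
                },
            )
        )
        occupy(tx.chrom, pos, span=len(ref))
    # enhancer_sv plants an SV below, no causal SNV

    # --- background variants -----------------------------------------------
    exonic_sites = []
    for tx in genome.transcripts:
        exonic_sites.extend((tx.chrom, p) for p in _cds_positions(tx))
    rng.shuffle(exonic_sites)
    background = []
    freq_rows = []
    pred_rows = []
    i = 0
    while len(background) < config.n_background_variants and i < len(exonic_sites):
        chrom, pos = exonic_sites[i]
        i += 1
        if (chrom, pos) in forbidden:
            continue
        occupy(chrom, pos)
        ref = genome.reference(chrom, pos, pos)
        alts = [a for a in BASES if a != ref]
        rng.shuffle(alts)
        multi = rng.random() < config.multiallelic_fraction
        alt_alleles = tuple(alts[:2]) if multi else (alts[0],)
        af = max(
            config.min_background_af,
            min(0.5, rng.betavariate(config.af_beta_a, config.af_beta_b)),
        )
        gts = {}
        if config.trio:
            m = _hwe_genotype(rng, af)
            f = _hwe_genotype(rng, af)
            child = (rng.choice(m), rng.choice(f))
            gts = {"PROBAND": child, "MOTHER": m, "FATHER": f}
        else:
            gts = {"PROBAND": _hwe_genotype(rng, af)}
        background.append(_PlantedVariant(chrom, pos, ref, alt_alleles, gts))
        for alt in alt_alleles:
            src_af = round(min(1.0, af * rng.uniform(0.8, 1.2)), 6)
            freq_rows.append((chrom, pos, ref, alt, src_af, round(af, 6)))
            pred_rows.append(
                (
                    chrom, pos, ref, alt,
                    rng.choice(["tolerated", "tolerated", "unknown"]),
                    rng.choice(["tolerated", "unknown"]),
                )
            )

    # --- write knowledge tables --------------------------------------------
    with open(os.path.join(out_dir, "frequencies.tsv"), "w") as fh:
        fh.write("chrom\tpos\tref\talt\tkg_like\tgnomad_like\n")
        for chrom, pos, ref, alt, a1, a2 in sorted(freq_rows):
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{a1}\t{a2}\n")

    with open(os.path.join(out_dir, "predictions.tsv"), "w") as fh:
        fh.write("chrom\tpos\tref\talt\tsift_like\tpolyphen_like\tmutationtaster_like\tgerp_like\n")
        rows = []
        for chrom, pos, ref, alt, v1, v2 in pred_rows:
            rows.append((chrom, pos, ref, alt, v1, v2, "unknown", "unknown"))
        for pv in planted:
            if pv.predictions:
                p = pv.predictions
                rows.append(
                    (
                        pv.chrom, pv.pos, pv.ref, pv.alts[0],
                        p["sift_like"], p["polyphen_like"],
                        p["mutationtaster_like"], p["gerp_like"],
                    )
                )
        for row in sorted(rows):
            fh.write("\t".join(str(x) for x in row) + "\n")

    with open(os.path.join(out_dir, "assertions.tsv"), "w") as fh:
        fh.write("chrom\tpos\tref\talt\tgene_symbol\tsource\tcondition\tsignificance\taa_change\n")
        rows = []
        for pv in planted:
            if pv.assertion:
                gene = next(
                    tx.gene_symbol
                    for tx in genome.transcripts
                    if tx.chrom == pv.chrom and tx.start <= pv.pos <= tx.end
                )
                a = pv.assertion
                rows.append(
                    (
                        pv.chrom, pv.pos, pv.ref, pv.alts[0], gene,
                        a["source"], a["condition"], a["significance"], a["aa_change"],
                    )
                )
        for row in sorted(rows):
            fh.write("\t".join(str(x) for x in row) + "\n")

    # --- SV file -------------------------------------------------------------
    sv_rows = []
    if scenario == "enhancer_sv":
        enh = genome.enhancer
        start = enh["start"] - rng.randint(5, 20)
        end = enh["end"] + rng.randint(5, 20)
        sv_rows.append((enh["chrom"], start, end, "DEL", 1))
        truth.sv_event = (enh["chrom"], start, end, "DEL")
    zero_genes = [g for g in GENE_CHROMS if g not in
                  {s["causal_gene"] for s in SCENARIOS.values()}
                  and g != SCENARIOS["enhancer_sv"]["host_gene"]]
    for _ in range(config.n_background_sv):
        gene = rng.choice(sorted(zero_genes))
        tx = genome.transcript_of(gene)
        start = tx.start - rng.randint(10, 50)
        end = tx.start + rng.randint(100, 400)
        sv_rows.append((tx.chrom, start, end, rng.choice(["DEL", "DUP"]),
                        rng.choice([1, 3])))
    with open(os.path.join(out_dir, "sv.tsv"), "w") as fh:
        fh.write("chrom\tstart\tend\tsv_type\tcopy_number\n")
        for row in sorted(sv_rows):
            fh.write("\t".join(str(x) for x in row) + "\n")

    # --- VCF ------------------------------------------------------------------
    all_vars = sorted(planted + background, key=lambda v: (v.chrom, v.pos))
    _write_case_vcf(all_vars, samples, os.path.join(out_dir, "case.vcf"), rng)

    with open(os.path.join(out_dir, "case.ped"), "w") as fh:
        if config.trio:
            fh.write("FAM1 FATHER 0 0 1 1\n")
            fh.write("FAM1 MOTHER 0 0 2 1\n")
            fh.write("FAM1 PROBAND FATHER MOTHER 1 2\n")
        else:
            fh.write("FAM1 PROBAND 0 0 1 2\n")

    with open(os.path.join(out_dir, "protocol.yaml"), "w") as fh:
        models = ["dominant_het", "recessive_hom", "compound_het"]
        fh.write(f"name: {scenario}_protocol\n")
        fh.write(f"analysis_type: {'trio-exome' if config.trio else 'single-exome'}\n")
        fh.write("genetic_models:\n")
        for m in models:
            fh.write(f"  - {m}\n")
        fh.write(f"keywords: \"{'; '.join(spec['keywords'])}\"\n")
        fh.write("af_cutoff: 0.001\n")
        fh.write("gene_panel:\n")
        for g in INCIDENTAL_PANEL:
            fh.write(f"  - {g}\n")

    for pv in planted:
        for alt in pv.alts:
            truth.variant_keys.append((pv.chrom, pv.pos, pv.ref, alt))
    with open(os.path.join(out_dir, "expected.json"), "w") as fh:
        json.dump(asdict(truth), fh, sort_keys=True, indent=1)
        fh.write("\n")
    return truth


def _write_case_vcf(variants, samples, path, rng: random.Random) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for v in variants:
            qual = round(rng.uniform(60, 900), 1)
            cols = [
                v.chrom, str(v.pos), ".", v.ref, ",".join(v.alts),
                str(qual), "PASS", ".", "GT:DP:AD",
            ]
            n_alleles = 1 + len(v.alts)
            for s in samples:
                a, b = v.genotypes.get(s, (0, 0))
                dp = rng.randint(25, 60)
                ad = [0] * n_alleles
                for idx in (a, b):
                    ad[idx] += dp // 2
                if a == b:
                    ad[a] = dp
                rem = dp - sum(ad)
                ad[0] += max(0, rem)
                cols.append(f"{a}/{b}:{dp}:{','.join(map(str, ad))}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# full knowledgebase + case emission


def make_knowledgebase(config: SimulationConfig, genome: ToyGenome, out_dir: str) -> None:
    """Write the shared (case-independent) knowledge tables and documents."""
    os.makedirs(out_dir, exist_ok=True)
    write_fasta(genome.sequences, os.path.join(out_dir, "reference.fa"))
    write_transcripts_tsv(genome.transcripts, os.path.join(out_dir, "transcripts.tsv"))
    write_regions_bed(genome.transcripts, os.path.join(out_dir, "regions.bed"))
    write_gene_docs(make_gene_docs(), os.path.join(out_dir, "gene_docs"))
    write_links_tsv(make_links(), os.path.join(out_dir, "links.tsv"))
    write_gene_flags_tsv(os.path.join(out_dir, "gene_flags.tsv"))
    write_elements_tsv(genome.enhancer, os.path.join(out_dir, "elements.tsv"))
    write_panel(os.path.join(out_dir, "panel.txt"))
    write_manifest(
        out_dir,
        [
            "transcripts.tsv", "regions.bed", "gene_docs", "links.tsv",
            "gene_flags.tsv", "elements.tsv", "panel.txt",
        ],
        os.path.join(out_dir, "manifest.tsv"),
    )


def generate_scenario(seed: int, scenario: str, out_dir: str,
                      config: SimulationConfig | None = None) -> PlantedTruth:
    """One-call emission of everything a scenario case needs."""
    config = config or SimulationConfig(seed=seed)
    config.seed = seed
    genome = make_toy_reference_and_transcripts(config)
    make_knowledgebase(config, genome, out_dir)
    return simulate_case(config, genome, scenario, out_dir)


# ---------------------------------------------------------------------------
# account-statistics fixture store

#: printed per-class case counts used as generator inputs for the account
#: statistics fixture: class -> (keywords, total cases, resolved cases)
ACCOUNT_CLASS_COUNTS = {
    "Growth Retardation": (["Short stature"], 107, 66),
    "Developmental Delay": (["Mental retardation", "Delayed speech", "Motor delay"], 174, 101),
    "Epilepsy": (["Seizures", "Convulsion", "Spasm"], 191, 121),
    "Genitalia symptoms": (["Scrotum", "Micropenis", "Hypogonadism", "Hypospadia"], 131, 30),
}


def account_class_defs() -> dict:
    return {name: list(kws) for name, (kws, _, _) in ACCOUNT_CLASS_COUNTS.items()}


def make_account_store(
    class_counts: dict | None = None, seed: int = 0
) -> CaseStore:
    """A case store whose per-class totals and resolved counts equal the
    supplied (or packaged default) counts; cases carry one keyword of their
    class, resolved cases one High-relevance selection."""
    class_counts = class_counts or ACCOUNT_CLASS_COUNTS
    rng = random.Random(seed)
    store = CaseStore()
    n = 0
    for class_name, (keywords, total, resolved) in class_counts.items():
        for j in range(total):
            n += 1
            case = CaseRecord(
                case_id=f"CASE{n:05d}",
                protocol="single-exome",
                keywords=[rng.choice(keywords)],
                analysis_date=f"2018-{(n % 12) + 1:02d}-{(n % 28) + 1:02d}",
            )
            key = ("1", 1000 + n, "A", "G")
            case.genotype_summary.append(GenotypeSummary(key, 1, 2))
            if j < resolved:
                case.selections.append(
                    VariantSelection(key, "GENE01", "High", "likely_pathogenic")
                )
            store.add(case)
    return store
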