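"""Shared fixtures: a generated toy genome/scenario and variant factories."""

from __future__ import annotations

import random

import pytest

from varitriage.annotate import (
    AnnotatedVariant,
    ConsequenceCall,
    FrequencyRecord,
    PredictionProfile,
)
from varitriage.fixtures import SimulationConfig, make_toy_reference_and_transcripts
from varitriage.vcf_ingest import GenotypeCall, RawVariantRecord


@pytest.fixture(scope="session")
def toy_genome():
    return make_toy_reference_and_transcripts(SimulationConfig(seed=11))


def make_variant(
    chrom="1",
    pos=100,
    ref="A",
    alt="G",
    qual=100.0,
    genotypes=None,
):
    """RawVariantRecord with explicit per-sample (zygosity, depth, alt_reads)."""
    genotypes = genotypes or {"PROBAND": ("HET", 30, 15)}
    calls = [
        GenotypeCall(sid, zyg, depth, alt_reads)
        for sid, (zyg, depth, alt_reads) in genotypes.items()
    ]
    return RawVariantRecord(
        chrom, pos, ref, (alt,), qual=qual, genotypes=calls,
        allelic_depths=[None] * len(calls),
        gt_indices=[(0, 1)] * len(calls),
    )


def make_annotated(
    effect="missense",
    gene="GENE01",
    max_af=0.0,
    verdicts=None,
    assertions=(),
    aa_change="p.A10V",
    **variant_kwargs,
):
    rec = make_variant(**variant_kwargs)
    sources = {"gnomad_like": max_af} if max_af > 0 else {}
    profile = PredictionProfile(dict(verdicts)) if verdicts else PredictionProfile({})
    cons = ConsequenceCall(f"{gene}.t1", gene, effect, aa_change)
    return AnnotatedVariant(
        record=rec,
        gene_symbol=gene,
        consequence=cons,
        all_calls=[cons],
        frequency=FrequencyRecord(sources),
        assertions=list(assertions),
        predictions=profile,
    )


@pytest.fixture
def rng():
    return random.Random(20240901)
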