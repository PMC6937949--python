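"""Consequence calling, transcript-call merging, frequency joins and
prediction consensus."""

import itertools

import pytest
from Bio.Seq import Seq

from varitriage.annotate import (
    ConsequenceCall,
    FrequencyRecord,
    FrequencyTable,
    PredictionProfile,
    TranscriptModel,
    attach_frequencies,
    call_consequence,
    merge_transcript_calls,
    severity_consensus,
)
from varitriage.vcf_ingest import RawVariantRecord

# a toy single-exon + strand gene: 5'UTR(4) + CDS(12) + 3'UTR(4)
#            pos: 1234 5678901234567890
TOY_SEQ = {"1": "TTTT" + "ATGGAGTGCTAA" + "GGGG" + "T" * 30}
TOY_TX = TranscriptModel("T1.t1", "T1", "1", "+", [(1, 20)], 5, 16)


def snv(pos, ref, alt, chrom="1"):
    return RawVariantRecord(chrom, pos, ref, (alt,))


class TestCallConsequence:
    def test_stop_gained_from_gag_to_tag(self):
        # codon 2 is GAG (E); G->T at its first base gives TAG (*)
        call = call_consequence(snv(8, "G", "T"), [TOY_TX], TOY_SEQ)[0]
        assert call.effect == "stop_gained"
        assert call.severity_tier == "HIGH"
        assert call.aa_change == "p.E2*"

    def test_synonymous_third_position(self):
        # GAG -> GAA both encode E
        call = call_consequence(snv(10, "G", "A"), [TOY_TX], TOY_SEQ)[0]
        assert call.effect == "synonymous"
        assert call.severity_tier == "LOW"

    def test_missense(self):
        # TGC (C) -> TGG (W)
        call = call_consequence(snv(13, "C", "G"), [TOY_TX], TOY_SEQ)[0]
        assert call.effect == "missense"
        assert call.aa_change == "p.C3W"

    def test_start_lost(self):
        call = call_consequence(snv(5, "A", "G"), [TOY_TX], TOY_SEQ)[0]
        assert call.effect == "start_lost"

    def test_utr_and_intergenic(self):
        assert call_consequence(snv(2, "T", "A"), [TOY_TX], TOY_SEQ)[0].effect == "utr"
        far = call_consequence(snv(45, "T", "A"), [TOY_TX], TOY_SEQ)
        assert [c.effect for c in far] == ["intergenic"]
        assert far[0].severity_tier == "MODIFIER"

    def test_frameshift_vs_inframe_indel(self):
        del1 = RawVariantRecord("1", 8, "GA", ("G",))
        del3 = RawVariantRecord("1", 7, "GGAG", ("G",))
        assert call_consequence(del1, [TOY_TX], TOY_SEQ)[0].effect == "frameshift"
        assert call_consequence(del3, [TOY_TX], TOY_SEQ)[0].effect == "inframe_indel"

    def test_splice_sites_on_multi_exon_transcript(self):
        # two exons with an intron 21..60; donor at 21-22, acceptor 59-60
        seq = {"1": "TTTT" + "ATGGAGTGCAAGGGATCCTA"[:16] + "G" * 44 + "GCTAA" + "T" * 20}
        tx = TranscriptModel("T2.t1", "T2", "1", "+", [(1, 20), (61, 80)], 5, 65)
        donor = call_consequence(snv(21, "G", "A"), [tx], seq)[0]
        acceptor = call_consequence(snv(60, "G", "C"), [tx], seq)[0]
        deep = call_consequence(snv(40, "G", "C"), [tx], seq)[0]
        near = call_consequence(snv(25, "G", "C"), [tx], seq)[0]
        assert donor.effect == "splice_donor"
        assert acceptor.effect == "splice_acceptor"
        assert deep.effect == "intronic"
        assert near.effect == "splice_region"

    def test_agrees_with_biopython_translation_on_minus_strand_gene(self, toy_genome):
        """Independent oracle: mutate the genome, re-extract the spliced CDS,
        translate with Biopython, classify from the protein diff."""
        tx = next(t for t in toy_genome.transcripts if t.strand == "-")
        chrom_seq = toy_genome.sequences[tx.chrom]
        cds_ivs = tx.cds_intervals()
        checked = 0
        for s, e in cds_ivs:
            for pos in range(s, min(s + 15, e + 1)):
                ref = chrom_seq[pos - 1]
                for alt in "ACGT":
                    if alt == ref:
                        continue
                    mutated = chrom_seq[: pos - 1] + alt + chrom_seq[pos:]
                    spliced = "".join(mutated[a - 1 : b] for a, b in cds_ivs)
                    spliced = str(Seq(spliced).reverse_complement())
                    prot_mut = str(Seq(spliced).translate())
                    prot_ref = str(
                        Seq(tx.cds_sequence(toy_genome.sequences)).translate()
                    )
                    call = call_consequence(snv(pos, ref, alt, tx.chrom), [tx],
                                            toy_genome.sequences)[0]
                    idx = tx.cds_coordinate(pos) // 3
                    old_aa, new_aa = prot_ref[idx], prot_mut[idx]
                    if old_aa == new_aa:
                        want = "synonymous"
                    elif idx == 0:
                        want = "start_lost"
                    elif new_aa == "*":
                        want = "stop_gained"
                    else:
                        want = "missense"
                    assert call.effect == want, (pos, ref, alt)
                    checked += 1
        assert checked > 50


class TestMergeCalls:
    def test_higher_tier_wins(self):
        calls = [
            ConsequenceCall("a", "G", "synonymous"),
            ConsequenceCall("b", "G", "missense"),
        ]
        assert merge_transcript_calls(calls).effect == "missense"

    def test_single_call_identity(self):
        c = ConsequenceCall("a", "G", "missense")
        assert merge_transcript_calls([c]) == c

    def test_same_tier_uses_fixed_effect_order(self):
        calls = [
            ConsequenceCall("a", "G", "inframe_indel"),
            ConsequenceCall("b", "G", "missense"),
        ]
        assert merge_transcript_calls(calls).effect == "missense"
        assert merge_transcript_calls(list(reversed(calls))).effect == "missense"

    def test_permutation_invariant_and_idempotent(self, rng):
        effects = ["stop_gained", "missense", "synonymous", "intronic", "utr"]
        calls = [ConsequenceCall(f"t{i}", "G", e) for i, e in enumerate(effects)]
        results = {
            merge_transcript_calls(list(p)).transcript_id
            for p in itertools.permutations(calls)
        }
        assert len(results) == 1
        best = merge_transcript_calls(calls)
        assert merge_transcript_calls([best]) == best

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            merge_transcript_calls([])


class TestFrequencies:
    def test_max_over_sources(self):
        rec = FrequencyRecord({"gnomad_like": 0.004, "kg_like": 0.002})
        assert rec.max_af == 0.004

    def test_absent_everywhere_is_zero(self):
        table = FrequencyTable({})
        assert attach_frequencies(snv(5, "A", "G"), table).max_af == 0

    def test_out_of_range_af_rejected_at_load(self):
        with pytest.raises(ValueError):
            FrequencyTable({("1", 5, "A", "G"): {"kg_like": 1.5}})

    def test_max_matches_columnwise_oracle(self, rng):
        rows = {}
        for i in range(100):
            srcs = {
                f"s{j}": round(rng.random(), 4)
                for j in range(rng.randint(0, 4))
            }
            rows[("1", i + 1, "A", "G")] = srcs
        table = FrequencyTable(rows)
        for key, srcs in rows.items():
            got = table.lookup(key).max_af
            assert got == (max(srcs.values()) if srcs else 0.0)

    def test_lookup_is_pure(self):
        table = FrequencyTable({("1", 5, "A", "G"): {"kg_like": 0.1}})
        v = snv(5, "A", "G")
        first = attach_frequencies(v, table)
        first.per_source["kg_like"] = 0.9
        assert attach_frequencies(v, table).max_af == 0.1


class TestSeverityConsensus:
    def test_matches_majority_oracle_on_all_verdict_vectors(self):
        options = ["damaging", "tolerated", "unknown"]
        for combo in itertools.product(options, repeat=4):
            profile = PredictionProfile(dict(zip("abcd", combo)))
            votes = [v for v in combo if v != "unknown"]
            if not votes:
                want = "unknown"
            elif len(votes) >= 2 and votes.count("damaging") > len(votes) / 2:
                want = "damaging"
            elif len(votes) >= 2 and votes.count("tolerated") > len(votes) / 2:
                want = "tolerated"
            else:
                want = "mixed"
            assert severity_consensus(profile) == want, combo
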