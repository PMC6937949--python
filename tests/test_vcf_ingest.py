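"""VCF sanitization, region filtering, multi-allelic splitting and indel
normalization."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varitriage.vcf_ingest import (
    HET,
    HOM_ALT,
    HOM_REF,
    RawVariantRecord,
    RegionSet,
    filter_regions,
    normalize_indel,
    sanitize_vcf,
    split_multiallelic,
    write_vcf,
)

HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
)


def vcf(*rows):
    return HEADER + "".join(r + "\n" for r in rows)


class TestSanitize:
    def test_non_canonical_chromosome_dropped(self):
        text = vcf(
            "chr1\t100\t.\tA\tG\t50\tPASS\t.\tGT\t0/1",
            "chrUn_gl000220\t55\t.\tC\tT\t50\tPASS\t.\tGT\t0/1",
        )
        records, _, log = sanitize_vcf(text)
        assert [r.chrom for r in records] == ["1"]
        assert log.dropped == {"non_canonical_chromosome": 1}

    def test_missing_required_header_injected(self):
        text = vcf("chr1\t100\t.\tA\tG\t50\tPASS\t.\tGT:DP\t0/1:30")
        records, header, _ = sanitize_vcf(text)
        assert any("ID=DP," in h for h in header)
        assert any("ID=DP4," in h for h in header)
        assert records[0].genotypes[0].depth == 30

    def test_empty_vcf_is_identity(self):
        records, _, log = sanitize_vcf(HEADER)
        assert records == [] and log.n_dropped == 0

    def test_zero_samples_is_hard_error(self):
        text = "##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        with pytest.raises(ValueError, match="sample"):
            sanitize_vcf(text)

    def test_annotation_info_keys_stripped(self):
        text = vcf("1\t100\t.\tA\tG\t50\tPASS\tANN=foo;DP4=1,2,3,4\tGT\t0/1")
        records, _, _ = sanitize_vcf(text)
        assert "ANN" not in records[0].info and "DP4" in records[0].info

    def test_malformed_lines_skipped_and_logged(self):
        text = vcf(
            "1\t100\t.\tA\tG\t50\tPASS\t.\tGT\t0/1",
            "1\tnotanumber\t.\tA\tG\t50\tPASS\t.\tGT\t0/1",
            "1\t102\t.\tA\tG\t50\tPASS\t.\tGT\t0/1",
        )
        records, _, log = sanitize_vcf(text)
        assert len(records) == 2 and log.n_dropped == 1

    def test_systemic_malformation_raises(self):
        rows = ["1\tbad\t.\tA\tG\t.\t.\t.\tGT\t0/1"] * 3 + [
            "1\t10\t.\tA\tG\t.\t.\t.\tGT\t0/1"
        ]
        with pytest.raises(ValueError, match="systemic"):
            sanitize_vcf(vcf(*rows))

    def test_retained_records_unaltered(self, rng):
        rows, expected = [], []
        for i in range(30):
            pos = rng.randint(1, 10_000)
            ref = rng.choice("ACGT")
            alt = rng.choice([b for b in "ACGT" if b != ref])
            rows.append(f"2\t{pos}\t.\t{ref}\t{alt}\t60\tPASS\t.\tGT\t0/1")
            expected.append(("2", pos, ref, alt))
        records, _, _ = sanitize_vcf(vcf(*rows))
        assert [(r.chrom, r.pos, r.ref, r.alts[0]) for r in records] == expected

    def test_written_output_is_valid_vcf_for_cyvcf2(self, tmp_path):
        cyvcf2 = pytest.importorskip("cyvcf2")
        text = vcf(
            "chr1\t100\t.\tA\tG\t50\tPASS\t.\tGT:DP\t0/1:30",
            "chr2\t200\t.\tC\tT,A\t99\tPASS\t.\tGT:DP\t1/2:40",
        )
        records, header, _ = sanitize_vcf(text)
        out = tmp_path / "clean.vcf"
        write_vcf(records, header, str(out))
        parsed = list(cyvcf2.VCF(str(out)))
        assert [(v.CHROM, v.POS) for v in parsed] == [("1", 100), ("2", 200)]


class TestRegionFilter:
    def test_bed_boundary_inclusive_end(self):
        regions = RegionSet([("chr1", 99, 100)])
        v = RawVariantRecord("1", 100, "A", ("G",))
        assert filter_regions([v], regions) == [v]

    def test_bed_boundary_exclusive_start(self):
        regions = RegionSet([("chr1", 100, 200)])
        v = RawVariantRecord("1", 100, "A", ("G",))
        assert filter_regions([v], regions) == []

    def test_chromosome_prefix_normalized(self):
        regions = RegionSet([("chr7", 0, 50)])
        v = RawVariantRecord("7", 10, "A", ("G",))
        assert filter_regions([v], regions) == [v]

    def test_matches_brute_force_scan(self, rng):
        for _ in range(20):
            intervals = [
                ("1", s, s + rng.randint(1, 50))
                for s in (rng.randint(0, 500) for _ in range(8))
            ]
            regions = RegionSet(intervals)
            variants = [
                RawVariantRecord("1", rng.randint(1, 600), "A", ("G",))
                for _ in range(20)
            ]
            got = {id(v) for v in filter_regions(variants, regions)}
            want = {
                id(v)
                for v in variants
                if any(s < v.pos <= e for _, s, e in intervals)
            }
            assert got == want


def multiallelic_record(gt, ad):
    from varitriage.vcf_ingest import GenotypeCall

    zyg = {(0, 0): HOM_REF, (0, 1): HET, (1, 1): HOM_ALT}.get(tuple(sorted(gt)), HET)
    return RawVariantRecord(
        "1", 50, "G", ("A", "T"),
        genotypes=[GenotypeCall("S1", zyg, sum(ad), ad[1])],
        allelic_depths=[tuple(ad)],
        gt_indices=[tuple(gt)],
    )


class TestSplitMultiallelic:
    def test_het_alt1_alt2_becomes_two_het_records(self):
        rec = multiallelic_record((1, 2), (0, 12, 14))
        out = split_multiallelic(rec)
        assert [r.alt for r in out] == ["A", "T"]
        assert all(r.genotypes[0].zygosity == HET for r in out)
        assert [r.genotypes[0].alt_reads for r in out] == [12, 14]

    def test_biallelic_returned_unchanged(self):
        rec = RawVariantRecord("1", 50, "G", ("A",))
        assert split_multiallelic(rec) == [rec]

    def test_allele_depth_conserved_on_random_sites(self, rng):
        for _ in range(50):
            n_alts = rng.randint(2, 3)
            ad = [rng.randint(0, 40) for _ in range(n_alts + 1)]
            gt = (rng.randint(0, n_alts), rng.randint(0, n_alts))
            alts = tuple("ATC"[:n_alts])
            from varitriage.vcf_ingest import GenotypeCall

            rec = RawVariantRecord(
                "1", 99, "G", alts,
                genotypes=[GenotypeCall("S1", HET, sum(ad), None)],
                allelic_depths=[tuple(ad)],
                gt_indices=[gt],
            )
            out = split_multiallelic(rec)
            assert [r.genotypes[0].alt_reads for r in out] == ad[1:]
            # the multiset of carried alt alleles is conserved
            carried = [alts[i - 1] for i in gt if i > 0]
            split_carried = []
            for r in out:
                z = r.genotypes[0].zygosity
                split_carried += [r.alt] * {HET: 1, HOM_ALT: 2}.get(z, 0)
            assert sorted(carried) == sorted(split_carried)


# --- indel normalization ----------------------------------------------------


def apply_variant(seq: str, pos: int, ref: str, alt: str) -> str:
    assert seq[pos - 1 : pos - 1 + len(ref)] == ref
    return seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]


def minimal_representation(seq: str, pos: int, ref: str, alt: str):
    """Oracle: enumerate every equivalent parsimonious (pos, ref, alt) and
    return the one at the smallest position."""
    target = apply_variant(seq, pos, ref, alt)
    best = None
    for p in range(1, len(seq) + 1):
        for lr in range(1, 8):
            if p - 1 + lr > len(seq):
                break
            la = len(target) - len(seq) + lr
            if la < 1:
                continue
            r = seq[p - 1 : p - 1 + lr]
            a = target[p - 1 : p - 1 + la]
            if seq[: p - 1] + a + seq[p - 1 + lr :] != target:
                continue
            if r == a:
                continue
            # parsimony: no shared prefix/suffix trimmable without emptying
            if len(r) > 1 and len(a) > 1 and (r[0] == a[0] or r[-1] == a[-1]):
                continue
            if min(len(r), len(a)) == 1 and r[-1] == a[-1] and p > 1:
                continue
            cand = (p, r, a)
            if best is None or cand < best:
                best = cand
    return best


class TestNormalizeIndel:
    def test_deletion_left_aligned_in_repeat(self):
        seq = "GGCAAAAATT"  # CAA->CA at pos 3 is a 1-base A deletion
        rec = RawVariantRecord("1", 3, "CAA", ("CA",))
        out = normalize_indel(rec, {"1": seq})
        assert (out.pos, out.ref, out.alt) == minimal_representation(seq, 3, "CAA", "CA")
        assert out.pos == 3 and out.ref == "CA" and out.alt == "C"

    def test_snv_unchanged(self):
        rec = RawVariantRecord("1", 5, "A", ("G",))
        out = normalize_indel(rec, {"1": "CCCCATTTT"})
        assert (out.pos, out.ref, out.alt) == (5, "A", "G")

    def test_ref_mismatch_raises(self):
        rec = RawVariantRecord("1", 5, "T", ("G",))
        with pytest.raises(ValueError, match="1:5"):
            normalize_indel(rec, {"1": "CCCCATTTT"})

    def test_idempotent_and_minimal_on_random_indels(self, rng):
        for _ in range(100):
            seq = "".join(rng.choice("ACGT") for _ in range(60))
            pos = rng.randint(5, 40)
            if rng.random() < 0.5:  # deletion
                ln = rng.randint(1, 4)
                ref = seq[pos - 1 : pos + ln]
                alt = ref[0]
            else:  # insertion
                ref = seq[pos - 1]
                alt = ref + "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 4)))
            rec = RawVariantRecord("1", pos, ref, (alt,))
            once = normalize_indel(rec, {"1": seq})
            twice = normalize_indel(once, {"1": seq})
            assert (once.pos, once.ref, once.alt) == (twice.pos, twice.ref, twice.alt)
            assert apply_variant(seq, once.pos, once.ref, once.alt) == apply_variant(
                seq, pos, ref, alt
            )
            want = minimal_representation(seq, pos, ref, alt)
            assert (once.pos, once.ref, once.alt) == want

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        seq=st.text(alphabet="ACGT", min_size=30, max_size=60),
        pos=st.integers(5, 25),
        ins=st.text(alphabet="ACGT", min_size=1, max_size=4),
        is_deletion=st.booleans(),
        del_len=st.integers(1, 4),
    )
    def test_normalization_preserves_haplotype(self, seq, pos, ins, is_deletion, del_len):
        """Property: normalization never changes the resulting haplotype and
        is idempotent, for arbitrary insertions and deletions."""
        if is_deletion:
            ref = seq[pos - 1 : pos + del_len]
            alt = ref[0]
        else:
            ref = seq[pos - 1]
            alt = ref + ins
        rec = RawVariantRecord("1", pos, ref, (alt,))
        once = normalize_indel(rec, {"1": seq})
        twice = normalize_indel(once, {"1": seq})
        assert (once.pos, once.ref, once.alt) == (twice.pos, twice.ref, twice.alt)
        assert apply_variant(seq, once.pos, once.ref, once.alt) == apply_variant(
            seq, pos, ref, alt
        )
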