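"""Filter cascades, reliability gating and inheritance-model logic."""

import itertools
import random

import pytest

from varitriage.acmg import AcmgAssessment
from varitriage.genetic_models import (
    FilterCascade,
    FilterSpec,
    PedigreeTrio,
    Protocol,
    ReliabilityThresholds,
    apply_cascade,
    incidental_findings,
    model_compound_het,
    model_dominant_het,
    model_recessive_hom,
    reliability_filter,
)

from conftest import make_annotated

TRIO = PedigreeTrio("PROBAND", "MOTHER", "FATHER")
SINGLETON = PedigreeTrio("PROBAND")
PROTOCOL = Protocol("test", genetic_models=["dominant_het"], af_cutoff=0.001)


def trio_variant(pz="HET", mz="HOM_REF", fz="HOM_REF", depth=30, **kw):
    genotypes = {
        "PROBAND": (pz, depth, depth // 2 if pz == "HET" else depth),
        "MOTHER": (mz, depth, depth // 2 if mz == "HET" else 0),
        "FATHER": (fz, depth, depth // 2 if fz == "HET" else 0),
    }
    return make_annotated(genotypes=genotypes, **kw)


class TestCascade:
    def test_counts_on_small_fixture(self):
        variants = []
        for i in range(10):
            zyg = "HET" if i < 4 else "HOM_ALT"
            af = 0.05 if i == 0 else 0.0
            variants.append(
                make_annotated(
                    pos=100 + i, max_af=af,
                    genotypes={"PROBAND": (zyg, 30, 15)},
                )
            )
        cascade = FilterCascade(
            [
                FilterSpec("zygosity", {"sample": "PROBAND", "is": "HET"}),
                FilterSpec("max_af_below", {"cutoff": 0.001}),
            ]
        )
        survivors, log = apply_cascade(variants, cascade)
        assert len(survivors) == 3
        assert [(s.n_in, s.n_out) for s in log] == [(10, 4), (4, 3)]

    def test_empty_cascade_is_identity(self):
        vs = [make_annotated(pos=i) for i in range(1, 4)]
        survivors, log = apply_cascade(vs, FilterCascade([]))
        assert survivors == vs and log == []

    def test_step_counts_telescope(self, rng):
        vs = [
            make_annotated(
                pos=i + 1,
                max_af=rng.choice([0.0, 0.01, 0.2]),
                effect=rng.choice(["missense", "synonymous", "stop_gained"]),
                genotypes={"PROBAND": (rng.choice(["HET", "HOM_ALT"]), 30, 15)},
            )
            for i in range(40)
        ]
        cascade = FilterCascade(
            [
                FilterSpec("zygosity", {"sample": "PROBAND", "is": "HET"}),
                FilterSpec("max_af_below", {"cutoff": 0.05}),
                FilterSpec("severity_in", {"tiers": ["HIGH", "MODERATE"]}),
            ]
        )
        survivors, log = apply_cascade(vs, cascade)
        for a, b in zip(log, log[1:]):
            assert a.n_out == b.n_in
        assert log[-1].n_out == len(survivors)
        assert log[0].n_in == 40

    def test_unknown_filter_column_raises_by_name(self):
        with pytest.raises(KeyError, match="no_such_column"):
            apply_cascade([], FilterCascade([FilterSpec("no_such_column", {})]))

    def test_missing_annotation_block_raises(self):
        from varitriage.annotate import AnnotatedVariant
        from conftest import make_variant

        bare = AnnotatedVariant(record=make_variant())
        with pytest.raises(KeyError, match="frequency"):
            apply_cascade([bare], FilterCascade([FilterSpec("max_af_below", {"cutoff": 1})]))


class TestReliability:
    def test_all_thresholds_cleared(self):
        v = make_annotated(qual=50, genotypes={"PROBAND": ("HET", 30, 14)})
        assert reliability_filter(v, "PROBAND") == (True, "pass")

    def test_low_depth_fails(self):
        v = make_annotated(qual=50, genotypes={"PROBAND": ("HET", 5, 3)})
        assert reliability_filter(v, "PROBAND")[0] is False

    def test_missing_metrics_reason(self):
        v = make_annotated(genotypes={"PROBAND": ("HET", None, None)})
        assert reliability_filter(v, "PROBAND") == (False, "missing_metrics")

    def test_matches_conjunction_oracle_on_metric_grid(self):
        t = ReliabilityThresholds()
        for qual, depth, frac in itertools.product(
            [5, 20, 60], [4, 8, 30], [0.1, 0.2, 0.5]
        ):
            alt = round(depth * frac)
            v = make_annotated(qual=qual, genotypes={"PROBAND": ("HET", depth, alt)})
            want = qual >= 20 and depth >= 8 and alt / depth >= 0.2
            assert reliability_filter(v, "PROBAND", t)[0] == want, (qual, depth, frac)


class TestDominant:
    def test_common_het_excluded_at_default_cutoff(self):
        v = trio_variant(max_af=0.002)
        assert model_dominant_het([v], TRIO, PROTOCOL).candidates == []

    def test_de_novo_flagged(self):
        v = trio_variant(effect="stop_gained", max_af=0.0)
        out = model_dominant_het([v], TRIO, PROTOCOL)
        assert out.candidates == [v] and "de_novo" in v.flags

    def test_de_novo_unconfirmed_on_low_parental_depth(self):
        v = trio_variant(effect="stop_gained", max_af=0.0, depth=30)
        v.record.genotype_of("MOTHER").depth = 5
        out = model_dominant_het([v], TRIO, PROTOCOL)
        assert "de_novo_unconfirmed" in v.flags and "de_novo" not in v.flags

    def test_hom_alt_excluded(self):
        v = trio_variant(pz="HOM_ALT")
        assert model_dominant_het([v], TRIO, PROTOCOL).candidates == []

    def test_low_severity_excluded(self):
        v = trio_variant(effect="synonymous")
        assert model_dominant_het([v], TRIO, PROTOCOL).candidates == []

    def test_inherited_het_is_candidate_without_de_novo_flag(self):
        v = trio_variant(mz="HET")
        out = model_dominant_het([v], TRIO, PROTOCOL)
        assert out.candidates == [v]
        assert not {"de_novo", "de_novo_unconfirmed"} & set(v.flags)


class TestRecessive:
    def test_consistent_trio(self):
        v = trio_variant(pz="HOM_ALT", mz="HET", fz="HET")
        out = model_recessive_hom([v], TRIO, PROTOCOL)
        assert out.candidates == [v] and "mendelian_inconsistent" not in v.flags

    def test_violation_flagged_not_dropped(self):
        v = trio_variant(pz="HOM_ALT", mz="HET", fz="HOM_REF")
        out = model_recessive_hom([v], TRIO, PROTOCOL)
        assert out.candidates == [v] and "mendelian_inconsistent" in v.flags

    def test_het_excluded(self):
        v = trio_variant(pz="HET", mz="HET", fz="HET")
        assert model_recessive_hom([v], TRIO, PROTOCOL).candidates == []


class TestCompoundHet:
    @staticmethod
    def run(parent_configs, pedigree=TRIO):
        vs = [
            trio_variant(pz="HET", mz=m, fz=f, gene="GENEX", pos=1000 + i)
            for i, (m, f) in enumerate(parent_configs)
        ]
        return model_compound_het(vs, pedigree, PROTOCOL), vs

    def test_maternal_plus_paternal_pair_qualifies(self):
        out, vs = self.run([("HET", "HOM_REF"), ("HOM_REF", "HET")])
        assert out.gene_groups == {"GENEX": vs}

    def test_two_maternal_hets_rejected_in_trio(self):
        out, _ = self.run([("HET", "HOM_REF"), ("HET", "HOM_REF")])
        assert out.gene_groups == {}

    def test_single_het_never_groups(self):
        out, _ = self.run([("HET", "HOM_REF")])
        assert out.gene_groups == {}

    def test_singleton_group_flagged_phase_unknown(self):
        out, vs = self.run(
            [("HOM_REF", "HOM_REF"), ("HOM_REF", "HOM_REF")], pedigree=SINGLETON
        )
        assert out.gene_groups == {"GENEX": vs}
        assert all("phase_unknown" in v.flags for v in vs)

    def test_matches_parental_configuration_enumeration(self):
        """Exhaustive 3^2-per-variant oracle over genotype configurations."""
        zygs = ["HOM_REF", "HET", "HOM_ALT"]
        for m1, f1, m2, f2 in itertools.product(zygs, repeat=4):
            out, _ = self.run([(m1, f1), (m2, f2)])
            def side(m, f):
                mc, fc = m != "HOM_REF", f != "HOM_REF"
                if mc and not fc:
                    return "M"
                if fc and not mc:
                    return "F"
                return "AMBIG"
            sides = {side(m1, f1), side(m2, f2)}
            want = {"M", "F"} <= sides
            assert bool(out.gene_groups) == want, (m1, f1, m2, f2)


class TestIncidental:
    @staticmethod
    def with_acmg(v, classification):
        v.acmg = AcmgAssessment([], classification)
        return v

    def test_lp_variant_in_panel_reported(self):
        v = self.with_acmg(make_annotated(gene="GENE07"), "likely_pathogenic")
        out = incidental_findings([v], ["GENE07"])
        assert out.candidates == [v]

    def test_vus_in_panel_not_reported(self):
        v = self.with_acmg(make_annotated(gene="GENE07"), "uncertain_significance")
        assert incidental_findings([v], ["GENE07"]).candidates == []

    def test_pathogenic_outside_panel_not_reported(self):
        v = self.with_acmg(make_annotated(gene="GENE01"), "pathogenic")
        assert incidental_findings([v], ["GENE07"]).candidates == []

    def test_empty_panel_empty_result(self):
        v = self.with_acmg(make_annotated(gene="GENE07"), "pathogenic")
        assert incidental_findings([v], []).candidates == []
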