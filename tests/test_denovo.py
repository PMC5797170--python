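"""Classification against documented haplotypes, artifact flagging and
independent-observation validation."""

import numpy as np
import pytest

from mthetero import denovo as dn
from mthetero.calling import VariantCall
from mthetero.haplotypes import HaplotypeDefinition, Variant
from mthetero.reference import CircularReference
from mthetero.simulate import SimulationConfig, simulate_mixture_reads, filter_ccs
from mthetero.calling import build_pileup, call_variants


def _call(pos, ref, alt, alt_depth=10, depth=1_000, amplicons=("A",), mixture="0%"):
    return VariantCall(
        circle_position=pos,
        ref_allele=ref,
        alt_allele=alt,
        alt_depth=alt_depth,
        depth=depth,
        allele_frequency=alt_depth / depth,
        amplicons_observed=frozenset(amplicons),
        mixture_id=mixture,
    )


@pytest.fixture()
def truth_pair():
    mutant = HaplotypeDefinition(
        name="mutant", variants=frozenset({Variant(100, "A", "G"), Variant(200, "C", "T")})
    )
    wildtype = HaplotypeDefinition(
        name="wildtype", variants=frozenset({Variant(300, "G", "A")})
    )
    return mutant, wildtype


class TestClassify:
    def test_documented_and_denovo_partition(self, truth_pair):
        mutant, wildtype = truth_pair
        calls = [
            _call(100, "A", "G"),  # documented mutant allele
            _call(100, "A", "T"),  # same position, different allele -> de novo
            _call(300, "G", "A"),  # documented wildtype allele
            _call(5_000, "T", "C"),  # untouched position
        ]
        classified = dn.classify_calls(calls, mutant, wildtype)
        categories = [c.category for c in classified]
        assert categories == [
            dn.CATEGORY_DOCUMENTED,
            dn.CATEGORY_DE_NOVO,
            dn.CATEGORY_DOCUMENTED,
            dn.CATEGORY_DE_NOVO,
        ]

    def test_simulated_background_variants_counted_as_denovo(self, demo):
        cfg = SimulationConfig(
            panel=demo.panel,
            mutant=demo.mutant,
            wildtype=demo.wildtype,
            fraction=0.0,
            seed=31,
            coverage=3_000,
        )
        reads, _ = simulate_mixture_reads(cfg)
        reads = filter_ccs(reads)
        calls = call_variants(build_pileup(reads, demo.extended), demo.reference)
        classified = dn.classify_calls(calls, demo.mutant, demo.wildtype)
        denovo_keys = {c.key for c in classified if c.category == dn.CATEGORY_DE_NOVO}
        injected = {v.key for v, _ in demo.wildtype.background_heteroplasmies}
        assert denovo_keys == injected  # exactly the injected backgrounds


class TestFlagArtifacts:
    def _ref_with_run(self):
        # positions 1..30; A-run of 6 at positions 11-16; run of 3 at 21-23
        seq = "CGTCGTCGTC" + "AAAAAA" + "CGTA" + "GGG" + "TCACGTC"
        return CircularReference(name="runref", sequence=seq)

    def test_inside_long_run_flagged(self, truth_pair):
        ref = self._ref_with_run()
        calls = dn.classify_calls([_call(13, "A", "C")], *truth_pair)
        (flagged,) = dn.flag_artifacts(calls, ref, *truth_pair)
        assert dn.FLAG_HOMOPOLYMER in flagged.artifact_flags

    def test_bordering_base_flagged(self, truth_pair):
        ref = self._ref_with_run()
        calls = dn.classify_calls([_call(10, "C", "T"), _call(17, "C", "T")], *truth_pair)
        flagged = dn.flag_artifacts(calls, ref, *truth_pair)
        assert all(dn.FLAG_HOMOPOLYMER in c.artifact_flags for c in flagged)

    def test_run_of_three_not_flagged_at_min_run_four(self, truth_pair):
        ref = self._ref_with_run()
        calls = dn.classify_calls([_call(22, "G", "C")], *truth_pair)
        (flagged,) = dn.flag_artifacts(calls, ref, *truth_pair)
        assert dn.FLAG_HOMOPOLYMER not in flagged.artifact_flags

    def test_proximity_to_documented_variant(self, truth_pair):
        mutant, wildtype = truth_pair
        rng = np.random.default_rng(1)
        ref = CircularReference(
            name="r", sequence="".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        )
        calls = dn.classify_calls(
            [_call(103, "A", "C"), _call(106, "A", "C"), _call(350, "A", "C")],
            mutant,
            wildtype,
        )
        near, far, alone = dn.flag_artifacts(
            calls, ref, mutant, wildtype, proximity_window=5
        )
        assert dn.FLAG_NEAR_HOMOPLASMIC in near.artifact_flags  # 3 bp from 100
        assert dn.FLAG_NEAR_HOMOPLASMIC not in far.artifact_flags  # 6 bp away
        assert dn.FLAG_NEAR_HOMOPLASMIC not in alone.artifact_flags

    def test_homopolymer_runs_wrap_the_origin(self, truth_pair):
        ref = CircularReference(name="wrap", sequence="AAA" + "CGT" * 8 + "AA")
        calls = dn.classify_calls([_call(1, "A", "C")], *truth_pair)
        (flagged,) = dn.flag_artifacts(calls, ref, *truth_pair)
        # the AA..AAA run spans the origin: total length 5 >= 4
        assert dn.FLAG_HOMOPOLYMER in flagged.artifact_flags


class TestValidate:
    def test_multi_mixture_validation(self, truth_pair):
        mutant, wildtype = truth_pair
        by_mix = {
            "0%": dn.classify_calls([_call(5_000, "T", "C", mixture="0%")], mutant, wildtype),
            "1%": dn.classify_calls([_call(5_000, "T", "C", mixture="1%")], mutant, wildtype),
        }
        validated = dn.validate_denovo(by_mix)
        assert all(
            c.validation == dn.VALIDATED_MULTI_MIXTURE
            for calls in validated.values()
            for c in calls
        )

    def test_overlap_validation_single_mixture(self, truth_pair):
        mutant, wildtype = truth_pair
        by_mix = {
            "10%": dn.classify_calls(
                [_call(5_000, "T", "C", amplicons=("H", "I"), mixture="10%")],
                mutant,
                wildtype,
            )
        }
        (call,) = dn.validate_denovo(by_mix)["10%"]
        assert call.validation == dn.VALIDATED_OVERLAP
        assert call.passes_conservative_threshold

    @pytest.mark.parametrize(
        "af,passes", [(0.002, False), (0.02, True), (0.01, True)]
    )
    def test_unvalidated_call_faces_conservative_threshold(self, truth_pair, af, passes):
        mutant, wildtype = truth_pair
        call = _call(5_000, "T", "C", alt_depth=int(af * 10_000), depth=10_000)
        by_mix = {"1%": dn.classify_calls([call], mutant, wildtype)}
        (validated,) = dn.validate_denovo(by_mix)["1%"]
        assert validated.validation == dn.UNVALIDATED
        assert validated.passes_conservative_threshold is passes

    def test_adding_a_mixture_never_unvalidates(self, truth_pair):
        mutant, wildtype = truth_pair
        base = {
            "0%": dn.classify_calls([_call(5_000, "T", "C", amplicons=("H", "I"))], mutant, wildtype)
        }
        before = dn.validate_denovo(base)["0%"][0]
        base["1%"] = dn.classify_calls([_call(5_000, "T", "C")], mutant, wildtype)
        after = dn.validate_denovo(base)["0%"][0]
        rank = {dn.UNVALIDATED: 0, dn.VALIDATED_OVERLAP: 1, dn.VALIDATED_MULTI_MIXTURE: 1}
        assert rank[after.validation] >= rank[before.validation]
        assert after.passes_conservative_threshold

    def test_report_shape(self, truth_pair):
        mutant, wildtype = truth_pair
        by_mix = {
            "0%": dn.classify_calls([_call(5_000, "T", "C", alt_depth=50, mixture="0%")], mutant, wildtype),
            "1%": dn.classify_calls([_call(5_000, "T", "C", alt_depth=60, mixture="1%")], mutant, wildtype),
        }
        validated = dn.validate_denovo(by_mix)
        report = dn.denovo_report(
            validated, mixture_order=["0%", "1%"], phased={(5_000, "C"): "wildtype"}
        )
        assert list(report.position) == [5_000]
        row = report.iloc[0]
        assert row["af_0%"] == "5" and row["af_1%"] == "6"  # percent, 2 sig figs
        assert row["validation"] == dn.VALIDATED_MULTI_MIXTURE
        assert row["phased_genotype"] == "wildtype"
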