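"""Pileup construction and threshold variant calling."""

import numpy as np
import pytest

from mthetero.calling import (
    VariantCall,
    build_pileup,
    call_variants,
)
from mthetero.reference import (
    CircularReference,
    build_extended_reference,
)
from mthetero.simulate import (
    AlignedRead,
    ReadSet,
    SimulationConfig,
    simulate_mixture_reads,
)


def _read(read_id, start, seq, qual=40, amplicon="A", **kw):
    return AlignedRead(
        read_id=read_id,
        amplicon_id=amplicon,
        start=start,
        seq=seq,
        quals=np.full(len(seq), qual, dtype=np.uint8),
        **kw,
    )


@pytest.fixture(scope="module")
def tiny_ref():
    return CircularReference(name="tiny", sequence="ACGTACGTAC")  # length 10


@pytest.fixture(scope="module")
def tiny_ext(tiny_ref):
    return build_extended_reference(tiny_ref, extension_length=6)


class TestBuildPileup:
    def test_error_free_reads_give_single_allele_depth(self, tiny_ref, tiny_ext):
        reads = [_read(f"r{i}", 1, tiny_ref.sequence) for i in range(10)]
        pileup = build_pileup(reads, tiny_ext)
        col = pileup.column(1)
        assert col.depth == 10
        assert col.counts == {"A": 10, "C": 0, "G": 0, "T": 0}

    def test_extension_folds_onto_circle(self, tiny_ref, tiny_ext):
        # one read on the circle body, one spanning the origin via the
        # extension; both cover circle position 2
        body = _read("body", 1, tiny_ref.sequence[:5])
        spanning = _read("span", 9, tiny_ref.sequence[8:] + tiny_ref.sequence[:3])
        pileup = build_pileup([body, spanning], tiny_ext)
        # hand tally: position 2 ('C') covered once by each read
        assert pileup.column(2).counts["C"] == 2
        assert pileup.column(9).depth == 1
        assert pileup.depth.max() <= 2

    def test_base_quality_boundary(self, tiny_ref, tiny_ext):
        ok = _read("ok", 1, "ACGTA", qual=30)
        low = _read("low", 1, "ACGTA", qual=29)
        pileup = build_pileup([ok, low], tiny_ext, min_base_quality=30)
        assert pileup.column(1).depth == 1

    def test_n_bases_never_counted(self, tiny_ext):
        read = _read("n", 1, "ANGTA")
        pileup = build_pileup([read], tiny_ext)
        assert pileup.column(2).depth == 0

    def test_read_beyond_extended_bounds_rejected_with_id(self, tiny_ref, tiny_ext):
        bad = _read("runaway", 14, "ACGTA")  # 14 + 5 - 1 > 16
        with pytest.raises(ValueError, match="runaway"):
            build_pileup([bad], tiny_ext)

    def test_batched_counts_equal_brute_force_tally(self, demo):
        """Vectorised pileup equals a per-read, per-position hand count."""
        cfg = SimulationConfig(
            panel=demo.panel,
            mutant=demo.mutant,
            wildtype=demo.wildtype,
            fraction=0.2,
            seed=21,
            coverage=40,  # <= 100 reads total
        )
        reads, _ = simulate_mixture_reads(cfg)
        assert reads.n_reads <= 100
        pileup = build_pileup(reads, demo.extended, min_base_quality=30)
        L = demo.reference.length
        brute = np.zeros((4, L), dtype=int)
        for r in reads:  # per-read oracle, plain Python
            for offset, (base, q) in enumerate(zip(r.seq, r.quals)):
                if q < 30 or base == "N":
                    continue
                circle = (r.start - 1 + offset) % L
                brute["ACGT".index(base), circle] += 1
        assert np.array_equal(pileup.counts, brute)
        per_amp_total = sum(pileup.amplicon_counts.values())
        assert np.array_equal(per_amp_total, brute)


class TestCallVariants:
    def _pileup_with_counts(self, tiny_ref, tiny_ext, n_alt, n_ref):
        reads = [_read(f"a{i}", 1, "CCGTA") for i in range(n_alt)]
        reads += [_read(f"r{i}", 1, "ACGTA") for i in range(n_ref)]
        return build_pileup(reads, tiny_ext)

    def test_four_supporting_reads_is_no_call(self, tiny_ref, tiny_ext):
        pileup = self._pileup_with_counts(tiny_ref, tiny_ext, n_alt=4, n_ref=96)
        assert call_variants(pileup, tiny_ref) == []

    def test_five_supporting_reads_is_a_call(self, tiny_ref, tiny_ext):
        pileup = self._pileup_with_counts(tiny_ref, tiny_ext, n_alt=5, n_ref=95)
        (call,) = call_variants(pileup, tiny_ref)
        assert call.circle_position == 1
        assert (call.ref_allele, call.alt_allele) == ("A", "C")
        assert call.alt_depth == 5 and call.depth == 100
        assert call.allele_frequency == pytest.approx(0.05)

    def test_low_af_call_at_deep_position(self, tiny_ref, tiny_ext):
        pileup = self._pileup_with_counts(tiny_ref, tiny_ext, n_alt=5, n_ref=4_995)
        (call,) = call_variants(pileup, tiny_ref)
        assert call.allele_frequency == pytest.approx(0.001)

    def test_multiple_alt_alleles_at_one_position(self, tiny_ref, tiny_ext):
        reads = [_read(f"c{i}", 1, "CCGTA") for i in range(6)]
        reads += [_read(f"g{i}", 1, "GCGTA") for i in range(7)]
        reads += [_read(f"r{i}", 1, "ACGTA") for i in range(87)]
        calls = call_variants(build_pileup(reads, tiny_ext), tiny_ref)
        assert [(c.alt_allele, c.alt_depth) for c in calls] == [("C", 6), ("G", 7)]

    def test_homoplasmic_differing_position_called_above_99pct(self, demo):
        cfg = SimulationConfig(
            panel=demo.panel,
            mutant=demo.mutant,
            wildtype=demo.wildtype,
            fraction=1.0,
            seed=22,
            coverage=2_000,
        )
        reads, _ = simulate_mixture_reads(cfg)
        pileup = build_pileup(reads, demo.extended)
        calls = call_variants(pileup, demo.reference)
        by_pos = {c.circle_position: c for c in calls}
        for pos in demo.differing:
            mut_allele = demo.mutant.effective_allele(pos, demo.reference)
            assert by_pos[pos].alt_allele == mut_allele
            assert by_pos[pos].allele_frequency > 0.99

    def test_overlap_position_attributed_to_both_amplicons(self, demo):
        cfg = SimulationConfig(
            panel=demo.panel,
            mutant=demo.mutant,
            wildtype=demo.wildtype,
            fraction=1.0,
            seed=23,
            coverage=300,
        )
        reads, _ = simulate_mixture_reads(cfg)
        calls = call_variants(build_pileup(reads, demo.extended), demo.reference)
        overlap_calls = [c for c in calls if len(c.amplicons_observed) >= 2]
        single_calls = [c for c in calls if len(c.amplicons_observed) == 1]
        for c in overlap_calls:
            assert c.amplicons_observed <= frozenset(demo.panel.covering(c.circle_position))
        # differing positions sit in single-amplicon interiors of the demo panel
        assert single_calls

    def test_empty_pileup_gives_empty_result(self, tiny_ref, tiny_ext):
        pileup = build_pileup([], tiny_ext)
        assert call_variants(pileup, tiny_ref) == []

    def test_invariants_on_call_record(self):
        with pytest.raises(ValueError):
            VariantCall(
                circle_position=1,
                ref_allele="A",
                alt_allele="C",
                alt_depth=10,
                depth=5,
                allele_frequency=2.0,
                amplicons_observed=frozenset(),
            )


class TestDetectionProbability:
    def test_calling_rate_matches_binomial_tail(self, monte_carlo_detection):
        """The probability that the calling stage reports a differing
        position equals the closed-form P(Binomial(depth, f) >= 5) tail
        (error-free simulation, quality filter disabled), within Monte-Carlo
        error at 500 replicates."""
        for observed_rate, expected, n_rep in monte_carlo_detection:
            sigma = max(np.sqrt(expected * (1 - expected) / n_rep), 1e-6)
            assert abs(observed_rate - expected) <= 3 * sigma
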