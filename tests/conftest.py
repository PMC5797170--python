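import numpy as np
import pytest
from scipy import stats

from mthetero.calling import build_pileup, call_variants
from mthetero.haplotypes import load_table1_fixture
from mthetero.phasing import phase_variant
from mthetero.reference import AmpliconPanel, build_extended_reference
from mthetero.simulate import (
    SimulationConfig,
    Study,
    default_study,
    demo_study,
    filter_ccs,
    random_reference,
    scaled_haplotype_pair,
    simulate_mixture_reads,
)


@pytest.fixture(scope="session")
def full_study():
    """Full-size synthetic study: 16,569 bp circle, 9-amplicon panel,
    haplotype pair built from the packaged truth table."""
    return default_study()


@pytest.fixture(scope="session")
def demo():
    """Scaled-down study: 2,000 bp circle, two overlapping amplicons (one
    spanning the origin), 4 differing positions, one 2% wildtype-phased
    background heteroplasmy."""
    return demo_study()


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


def _single_amplicon_study(ref_length, n_differing, wildtype_background=(),
                           mutant_background=(), seed=16_569):
    ref = random_reference(length=ref_length, seed=seed, name="chrM_mc")
    panel = AmpliconPanel.default(ref, n_amplicons=1, overlap=0)
    mutant, wildtype = scaled_haplotype_pair(
        ref,
        n_differing=n_differing,
        wildtype_background=wildtype_background,
        mutant_background=mutant_background,
    )
    ext = build_extended_reference(ref, extension_length=panel.max_amplicon_length())
    return Study(reference=ref, extended=ext, panel=panel, mutant=mutant, wildtype=wildtype)


@pytest.fixture(scope="session")
def monte_carlo_detection():
    """Monte-Carlo detection rate of the calling stage vs the closed-form
    binomial tail P(Binomial(depth, f) >= 5).

    Error-free single-amplicon simulation with the base-quality filter
    disabled, so the supporting-read count at the differing position is
    exactly Binomial(coverage, f).  Returns (observed_rate, expected, n_rep)
    per condition; 500 seeded replicates each at f = 0.1% (depth 2,000) and
    f = 1% (depth 500).
    """
    study = _single_amplicon_study(ref_length=200, n_differing=1)
    (variant,) = study.mutant.variants
    results = []
    n_rep = 500
    for f, coverage, base_seed in [(0.001, 2_000, 1_000), (0.01, 500, 2_000)]:
        detected = 0
        for i in range(n_rep):
            cfg = SimulationConfig(
                panel=study.panel,
                mutant=study.mutant,
                wildtype=study.wildtype,
                fraction=f,
                seed=base_seed + i,
                coverage=coverage,
                error_rate=0.0,
            )
            reads, _ = simulate_mixture_reads(cfg)
            pileup = build_pileup(reads, study.extended, min_base_quality=0)
            calls = call_variants(pileup, study.reference, min_alt_depth=5)
            if any(c.key == variant.key for c in calls):
                detected += 1
        expected = float(1 - stats.binom.cdf(4, coverage, f))
        results.append((detected / n_rep, expected, n_rep))
    return results


@pytest.fixture(scope="session")
def phasing_replicates():
    """200 seeded replicates of background-variant phasing at f = 10%,
    coverage 1,000x, error rate 0.1%: one heteroplasmy injected on each
    haplotype (3% on wildtype, 30% of mutant molecules), phased against
    3 anchor positions on a single 800 bp amplicon.

    Returns a list of (true_haplotype, PhasingResult) pairs.
    """
    study = _single_amplicon_study(
        ref_length=800,
        n_differing=3,
        wildtype_background=((301, 0.03),),
        mutant_background=((555, 0.30),),
    )
    (wt_bg, _), = study.wildtype.background_heteroplasmies
    (mut_bg, _), = study.mutant.background_heteroplasmies
    out = []
    for i in range(200):
        cfg = SimulationConfig(
            panel=study.panel,
            mutant=study.mutant,
            wildtype=study.wildtype,
            fraction=0.1,
            seed=3_000 + i,
            coverage=1_000,
            error_rate=0.001,
        )
        reads, _ = simulate_mixture_reads(cfg)
        reads = filter_ccs(reads)
        for variant, truth in [(wt_bg, "wildtype"), (mut_bg, "mutant")]:
            res = phase_variant(
                variant.key,
                reads,
                study.mutant,
                study.wildtype,
                ref_length=study.reference.length,
            )
            out.append((truth, res))
    return out


@pytest.fixture(scope="session")
def zero_fraction_replicates():
    """200 seeded replicates of a pure-wildtype sample (f = 0) run through
    filtering, pileup and calling at the study thresholds; returns per
    replicate the list of calls at (differing position, mutant allele)."""
    study = _single_amplicon_study(
        ref_length=800,
        n_differing=3,
        wildtype_background=((301, 0.02),),
    )
    wt_alleles = study.wildtype.allele_map
    mutant_keys = {
        v.key for v in study.mutant.variants if wt_alleles.get(v.position) != v.alt_allele
    }
    out = []
    for i in range(200):
        cfg = SimulationConfig(
            panel=study.panel,
            mutant=study.mutant,
            wildtype=study.wildtype,
            fraction=0.0,
            seed=5_000 + i,
            coverage=1_000,
            error_rate=0.001,
        )
        reads, _ = simulate_mixture_reads(cfg)
        reads = filter_ccs(reads)
        pileup = build_pileup(reads, study.extended, min_base_quality=30)
        calls = call_variants(pileup, study.reference, min_alt_depth=5)
        out.append([c for c in calls if c.key in mutant_keys])
    return out
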