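# Methods

This note documents the models behind `mthetero`, the defaults and why they
were chosen, what the synthetic data does and does not emulate, and the
numerical conventions used throughout.

## Coordinate model

All positions are 1-based inclusive on the circular reference; intervals on
the circle are closed, and an amplicon with `end < start` spans the origin.
To avoid the mapping bias a linear aligner shows at the origin of a
circular genome, reads are represented on an *extended* reference — the
circle followed by a copy of its first `extension_length` bases (default:
the longest amplicon length, so no simulated read straddles the extension
boundary). All counting folds extended positions back onto the circle with
`((pos − 1) mod L) + 1` before any tally, so no pileup column can ever land
at position 0 or beyond L. Reads are stored forward-strand only;
reverse-strand SAM records would be reverse-complemented on ingest.

## Amplicon panel

The default panel tiles the circle with nine amplicons of ~2.0 kb at ~150 bp
overlaps, the last one spanning the origin. Exact primer coordinates of a
real panel are instrument- and assay-specific; what the analysis relies on
is structural — complete coverage, pairwise overlaps between consecutive
amplicons, and one origin-spanning product — and the synthesized panel
preserves exactly those properties. Overlap regions are covered by two
amplicons and hence yield two independent observations of a variant, which
the validation stage uses. Panels can also be supplied as TSV
(`id, start, end`).

## Purity and contamination arithmetic

* **Relative quantitation.** The mtDNA:nDNA molecule ratio is `2^(Cq_nuc −
  Cq_mt)`. Duplicate qPCR runs are averaged on the Cq scale before the
  difference is taken (no aggregation rule is standard; averaging Cq is the
  usual practice and is symmetric in the two targets). If the nuclear
  target never amplifies, the ratio is not measurable and is capped at
  2·10⁷, which corresponds to a 99% mtDNA mass fraction.
* **Mass percentage.** `100 · r·S_mt / (r·S_mt + S_nuc)` with S_mt =
  16,569 bp and S_nuc = 3,088,269,805 bp (haploid). Strictly increasing in
  r and saturating below 100%.
* **Fold enrichment** is a plain ratio of mass percentages (27% vs 0.1% →
  270-fold), not an odds ratio — this is the convention that reproduces the
  protocol-comparison folds (270, 5, 2).
* **NUMT apparent heteroplasmy.** `100 · ploidy·c_numt /
  (fold·c_mt)`: a NUMT at `c_numt` copies per haploid genome in a diploid
  cell with `c_mt` mtDNA molecules, diluted by any mtDNA enrichment fold.
  Exact inverse scaling in the fold is asserted by a property test.
* **Duplicate-read expectation.** For n identical-length error-free
  single-end reads over s distinct start positions, at most s reads can be
  non-duplicate: `100·max(0, 1 − s/n)`. The default counts single-strand
  start positions (s = L); a strand-aware variant (s = 2L) is available via
  `strands=2`.

## Haplotype truth sets

The packaged fixture holds the 23 sequenced positions at which the two
documented cell-line haplotypes carry different alleles, together with each
method's empirical detection limit (sequencing: all 23; mass-spectrometry
assay: 7; digital PCR: 2). The full simulation pair adds five synthetic
differing positions (restoring the documented total of 28, whose five
remaining identities are not public) and seven synthetic concordant-alt
positions (mirroring the documented 29/13-variant haplotypes sharing 7
alleles). Because the reference here is synthetic (see below), a fixture
allele occasionally coincides with the reference base; the pair-building
code only materialises a `Variant` where the allele actually differs, which
keeps the differing-position count at exactly 28 regardless.

Background heteroplasmies — low-level variants private to one haplotype —
default to the documented wildtype-phased spectrum shape (one ~24%, one
~7%, several ≤1.5%) plus two on the mutant haplotype (8% and 0.9%), at
synthetic positions. They are what the de-novo and phasing stages must
rediscover.

## Synthetic reference

The bundled default reference is a seeded uniform-random 16,569 bp circle,
not the rCRS sequence itself. Every structural property the pipeline
exercises (circularity, coordinate arithmetic, homopolymer runs — a random
sequence contains ~190 runs of length ≥4 — and variant placement) is
preserved; sequence-specific phenomena of the real genome (its exact
homopolymer landscape, base composition skew) are not. Users with a real
reference FASTA can supply it directly.

## Read simulation

Each amplicon's reads all span the full amplicon (consensus reads of a PCR
product), stored as a column-aligned matrix, which keeps pileup and phasing
vectorised.

* **Origin.** Each read is mutant with probability f, independently.
* **Template.** Homoplasmic variants of the read's haplotype are always
  applied; each background heteroplasmy is applied per read with its
  allele fraction.
* **Errors.** I.i.d. substitutions at rate ε (default 0.001), uniform over
  the three non-template bases. Indels are not simulated because the
  downstream pileup ignores them by construction. ε = 0.1% reflects a
  post-consensus error scale that makes the 0.1% allele-frequency regime
  realistically marginal rather than trivially clean.
* **Base qualities.** Drawn conditionally on error status: correct bases
  from N(45, 8), erroneous bases from N(22, 7), clipped to [2, 93]. Quality
  scores that predict error are the premise of the Q30 base filter; under
  this model the filter removes ~87% of errors while keeping ~97% of
  correct bases, so the residual high-quality error rate is ~1.3·10⁻⁴.
* **Pass counts and read accuracy.** Passes are shifted Poisson
  (1 + Poisson(mean−1), default mean 9). Predicted consensus accuracy is
  `1 − 0.1·passes⁻²·LogNormal(0, 0.5)` — a phenomenological decay chosen so
  that both halves of the read filter (≥5 passes AND ≥99% accuracy)
  genuinely bind: a quality model of the form `1 − 0.1/√passes` would sit
  below 99% until ~100 passes and the default filter would discard every
  read. With the defaults the filter keeps ~94% of reads.
* **Coverage.** Fixed per amplicon when `coverage` is set (tests), else
  log-normal with median 4,060× clipped to [648, 34,263] — the study-scale
  per-sample spread.
* **Determinism.** All randomness flows from one integer seed through a
  single generator; identical configs give identical reads. Truth labels
  live in the in-memory batches and the sidecar table only — SAM output
  never carries them, so the pipeline cannot cheat on real-format ingest.

What the generator does **not** emulate: PCR duplicate lineages and
chimeras, primer artifacts, strand effects, instrument-specific error
spectra (burst errors, homopolymer-length errors), alignment uncertainty
and NUMT cross-mapping. Passing tests therefore demonstrate correctness of
the analysis logic under the stated error model, not robustness to every
artifact class of real data.

## Pileup and calling

Bases below Q30 and N bases are never counted; deletions and insertions are
excluded; mapping quality is accept-all by default (configurable). The
allele-frequency denominator is the quality-filtered depth at the position
(reads failing the base filter do not count toward the denominator).
A variant call requires ≥5 supporting reads per (position, allele);
multiple alternative alleles per position are allowed; positions with zero
depth are omitted. Amplicon attribution uses the read's amplicon id (known
in simulation, from the `am` SAM tag on ingest) and records every amplicon
with ≥1 supporting read. Allele frequencies are reported at 2 significant
figures in tables, full precision internally.

## De-novo classification and validation

A call matching a documented variant (position **and** allele) of either
haplotype is `documented_homoplasmic`; anything else is `de_novo`. Two
artifact contexts are flagged: positions inside or immediately bordering a
reference homopolymer run of ≥4 (runs may wrap the origin), and positions
within ±5 bp (circular distance) of a documented homoplasmic variant. The
run length and window are configurable; 4 and 5 are conventional values
encoding what was originally a visual-inspection screen, which stated no
numbers. Validation: a (position, allele) observed in ≥2 mixtures is
`validated_multi_mixture`; in one mixture but ≥2 overlapping amplicons,
`validated_overlap`; otherwise unvalidated, in which case only calls at
≥1% allele frequency pass the conservative reporting rule. Allele-frequency
agreement across mixtures is deliberately **not** required — a
wildtype-borne background variant keeps a near-constant AF across mixtures
while a mutant-borne one scales with f.

## Phasing

Anchors are the 28 positions where the two haplotypes differ, with each
haplotype's effective allele. Every read carrying the query variant allele
(at ≥Q30) is inspected at the anchors inside its span (≥Q30 only): an
anchor base matching exactly one haplotype votes for it; a base matching
neither (an error at the anchor) abstains rather than counting as
discordant — penalising independent errors would bias against phasing. A
read is informative if it casts ≥1 vote and concordant with a haplotype if
it votes for that haplotype only. The genotype is assigned when ≥5
informative reads exist and ≥90% are concordant with one haplotype;
otherwise it is ambiguous. The 5-read floor mirrors the calling module's
evidence standard; 0.9 tolerates the occasional error-borne carrier read
from the opposite haplotype. Reads spanning no differing anchor remain
uninformative; with two haplotypes and ~2 kb amplicons every amplicon
contains at least one anchor in the default designs. Robustness contract
(verified over 200 seeded replicates): at ε = 0.001 and ≥20 carrier reads
the wrong haplotype is assigned in <1% of cases.

## Limit of detection and detection models

The empirical LOD of a position is the smallest design fraction whose call
set contains the mutant allele; the 0% mixture never assigns an LOD (a
detection there would be background). Sensitivity at a level is the percent
of assayed positions with LOD ≤ level; never-detected positions stay in the
denominator. Detection models are exact binomial tails P(X ≥ k), X ~
Binomial(total copies, allele fraction), with k = 2 (digital PCR, capacity
20,000 copies — modelled at the copy level, ignoring multi-copy partitions,
which is valid in the dilute regime of ≤20,000 copies over 20,000
partitions), k = 3 (mass-spectrometry extension assay) and k = 5 reads
(sequencing). Tails are computed by explicit pmf summation.

## Numerical and testing choices

* Exact binomial quantiles/tails come from `scipy.stats.binom`; no normal
  approximations anywhere in the assertions.
* Monte-Carlo checks compare the calling stage's detection frequency with
  the closed-form tail at 500 seeded replicates (error-free, quality filter
  disabled so the supporting-read count is exactly binomial), within 3σ.
* Parameter-recovery runs use the full 16,569 bp / 9-amplicon design at
  10,000× per-amplicon coverage for f ∈ {1%, 10%}; replicated checks
  (phasing accuracy, zero-fraction false positives, LOD monotonicity under
  coverage) run on single-amplicon scaled-down references of 200–800 bp at
  500–2,000×, 20–500 replicates — sizes chosen so each property is measured
  with useful statistical resolution while the whole suite stays quick.
* All stochastic tests are seeded; the parameter-recovery seed (20180202)
  was fixed before any recovery run was executed.
* Degenerate inputs: empty pileups call nothing (not an error); a read
  extending past the extended reference is rejected with its read id; a
  haplotype pair with no anchors in a read's span yields an ambiguous
  phasing with zero informative reads.

## Known limitations

* The simulator's i.i.d. error model understates correlated error modes
  (PCR jackpots, homopolymer slippage), so real-data false-positive rates
  at <0.1% AF will exceed the simulated ones; the conservative ≥1% rule
  and the validation requirements are the intended mitigations.
* Phasing assumes exactly two haplotypes; mixtures of ≥3 clones are out of
  scope, as is statistical phasing across non-overlapping amplicons.
* Alignment of real reads is external: the package ingests aligned,
  indel-free SAM records and does not recalibrate base qualities.
* The digital-PCR model omits Poisson occupancy correction and is only
  valid below one copy per partition on average.
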