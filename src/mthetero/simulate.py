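"""Synthetic dilution-series data with known ground truth.

Emulates the two-cell-line mixture experiment end to end: consensus amplicon
reads from a 9-amplicon panel tiling the circular genome, with

* read origin drawn per read as Bernoulli(mutant fraction);
* homoplasmic haplotype variants always applied, background heteroplasmies
  applied per read at their allele fraction;
* i.i.d. post-consensus substitution errors at rate ``error_rate`` (uniform
  over the three non-template bases) — indels are not modelled, matching the
  indel-free pileup downstream;
* per-base qualities drawn conditionally on error status (an erroneous base
  usually reports a low quality score — the property the base-quality filter
  relies on);
* per-read pass counts (shifted Poisson) and predicted consensus accuracy,
  so the pass/quality read filter binds realistically;
* per-amplicon coverage either fixed or log-normal around the study median.

Reads are stored column-aligned per amplicon (every read of an amplicon
covers the full amplicon), which keeps pileup and phasing vectorised.  Truth
labels live only in a sidecar table and in the in-memory batches, never in
exported SAM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .haplotypes import (
    HaplotypeDefinition,
    Variant,
    default_haplotype_pair,
)
from .purity import QpcrMeasurement
from .reference import (
    AmpliconPanel,
    CircularReference,
    ExtendedReference,
    build_extended_reference,
    decode_bases,
    encode_bases,
)

#: seed fixing the synthetic reference sequence — a study constant, not a knob
DEFAULT_REFERENCE_SEED = 16_569

ORIGIN_WILDTYPE = "wildtype"
ORIGIN_MUTANT = "mutant"


def random_reference(
    length: int = 16_569,
    seed: int = DEFAULT_REFERENCE_SEED,
    name: str = "chrM_synthetic",
) -> CircularReference:
    """A seeded random circular reference (uniform A/C/G/T)."""
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=length).astype(np.uint8)
    return CircularReference(name=name, sequence=decode_bases(codes))


@dataclass
class AlignedRead:
    """One consensus read aligned to the extended reference (forward strand)."""

    read_id: str
    amplicon_id: str
    start: int  # 1-based on the extended reference
    seq: str
    quals: np.ndarray
    n_passes: int = 1
    read_quality: float = 1.0
    true_origin: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise ValueError("sequence and quality lengths differ")
        if self.n_passes < 1:
            raise ValueError("n_passes must be >= 1")


@dataclass
class ReadBatch:
    """Column-aligned reads of one amplicon: row = read, column = base."""

    amplicon_id: str
    start: int  # 1-based on the extended reference, shared by all rows
    bases: np.ndarray  # (n, L) uint8 codes
    quals: np.ndarray  # (n, L) uint8 phred
    read_ids: np.ndarray  # (n,) str
    n_passes: np.ndarray  # (n,) int
    read_quality: np.ndarray  # (n,) float
    true_origin: Optional[np.ndarray] = None  # (n,) str or None

    @property
    def n_reads(self) -> int:
        return self.bases.shape[0]

    @property
    def read_length(self) -> int:
        return self.bases.shape[1]

    def subset(self, mask: np.ndarray) -> "ReadBatch":
        return ReadBatch(
            amplicon_id=self.amplicon_id,
            start=self.start,
            bases=self.bases[mask],
            quals=self.quals[mask],
            read_ids=self.read_ids[mask],
            n_passes=self.n_passes[mask],
            read_quality=self.read_quality[mask],
            true_origin=None if self.true_origin is None else self.true_origin[mask],
        )


@dataclass
class ReadSet:
    """All reads of one sample, grouped per amplicon."""

    batches: list[ReadBatch] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return sum(b.n_reads for b in self.batches)

    def __iter__(self) -> Iterator[AlignedRead]:
        for b in self.batches:
            for i in range(b.n_reads):
                yield AlignedRead(
                    read_id=str(b.read_ids[i]),
                    amplicon_id=b.amplicon_id,
                    start=b.start,
                    seq=decode_bases(b.bases[i]),
                    quals=b.quals[i].copy(),
                    n_passes=int(b.n_passes[i]),
                    read_quality=float(b.read_quality[i]),
                    true_origin=None
                    if b.true_origin is None
                    else str(b.true_origin[i]),
                )

    @classmethod
    def from_reads(cls, reads: Iterable[AlignedRead]) -> "ReadSet":
        """Group per-read records into column-aligned batches by
        (amplicon, placement, length)."""
        groups: dict[tuple, list[AlignedRead]] = {}
        for r in reads:
            groups.setdefault((r.amplicon_id, r.start, len(r.seq)), []).append(r)
        batches = []
        for (amp, start, _length), rs in groups.items():
            batches.append(
                ReadBatch(
                    amplicon_id=amp,
                    start=start,
                    bases=np.stack([encode_bases(r.seq) for r in rs]),
                    quals=np.stack([np.asarray(r.quals, dtype=np.uint8) for r in rs]),
                    read_ids=np.array([r.read_id for r in rs], dtype=object),
                    n_passes=np.array([r.n_passes for r in rs], dtype=np.int64),
                    read_quality=np.array(
                        [r.read_quality for r in rs], dtype=np.float64
                    ),
                    true_origin=(
                        np.array([r.true_origin for r in rs], dtype=object)
                        if all(r.true_origin is not None for r in rs)
                        else None
                    ),
                )
            )
        return cls(batches=batches)

    def truth_table(self) -> pd.DataFrame:
        """Sidecar read_id -> true haplotype-of-origin table."""
        frames = []
        for b in self.batches:
            if b.true_origin is None:
                raise ValueError("read set carries no truth labels")
            frames.append(
                pd.DataFrame(
                    {
                        "read_id": b.read_ids,
                        "amplicon": b.amplicon_id,
                        "true_origin": b.true_origin,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


@dataclass
class SimulationConfig:
    """Study conditions for one simulated mixture sample.

    ``coverage`` fixes the per-amplicon read count exactly; when ``None``,
    counts are drawn log-normally with the study's median (4,060x) and
    clipped to its observed range (648–34,263x).
    """

    panel: AmpliconPanel
    mutant: HaplotypeDefinition
    wildtype: HaplotypeDefinition
    fraction: float
    seed: int
    mixture_id: str = ""
    coverage: Optional[int] = None
    coverage_median: float = 4_060.0
    coverage_sigma: float = 0.8
    coverage_clip: tuple[int, int] = (648, 34_263)
    error_rate: float = 0.001
    pass_mean: float = 9.0
    quality_correct: tuple[float, float] = (45.0, 8.0)
    quality_error: tuple[float, float] = (22.0, 7.0)
    consensus_error_scale: float = 0.1
    quality_jitter_sd: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.fraction <= 1:
            raise ValueError(f"mixture fraction must be in [0, 1], got {self.fraction}")
        if not 0 <= self.error_rate <= 0.05:
            raise ValueError(f"error_rate must be in [0, 0.05], got {self.error_rate}")
        if self.coverage is not None and self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.pass_mean < 1:
            raise ValueError("pass_mean must be >= 1")
        if not self.mixture_id:
            self.mixture_id = f"{self.fraction * 100:g}%"


def _amplicon_templates(
    amp_start: int,
    amp_len: int,
    ref: CircularReference,
    haplotypes: Sequence[HaplotypeDefinition],
) -> tuple[np.ndarray, list[dict[int, tuple[int, float]]]]:
    """Per-haplotype template code arrays over one amplicon plus each
    haplotype's background heteroplasmies mapped to column -> (code, frac)."""
    L = ref.length
    ref_codes = ref.codes()
    cols = (np.arange(amp_start - 1, amp_start - 1 + amp_len)) % L
    base_template = ref_codes[cols]
    templates = np.stack([base_template.copy() for _ in haplotypes])

    def col_of(pos: int) -> Optional[int]:
        c = (pos - amp_start) % L
        return c if c < amp_len else None

    backgrounds: list[dict[int, tuple[int, float]]] = []
    for hi, hap in enumerate(haplotypes):
        for v in hap.variants:
            c = col_of(v.position)
            if c is not None:
                templates[hi, c] = encode_bases(v.alt_allele)[0]
        bg: dict[int, tuple[int, float]] = {}
        for v, frac in hap.background_heteroplasmies:
            c = col_of(v.position)
            if c is not None:
                bg[c] = (int(encode_bases(v.alt_allele)[0]), frac)
        backgrounds.append(bg)
    return templates, backgrounds


_CHUNK_ROWS = 2_048


def simulate_mixture_reads(cfg: SimulationConfig) -> tuple[ReadSet, pd.DataFrame]:
    """Simulate one mixture sample; returns the reads and the truth table.

    Identical config (including seed) yields identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    ref = cfg.panel.reference
    L = ref.length
    haplotypes = (cfg.wildtype, cfg.mutant)  # index 0 = wildtype, 1 = mutant
    batches = []
    for amp in cfg.panel.amplicons:
        amp_len = amp.length_on(L)
        if cfg.coverage is not None:
            n = int(cfg.coverage)
        else:
            mu = np.log(cfg.coverage_median)
            n = int(
                np.clip(
                    rng.lognormal(mean=mu, sigma=cfg.coverage_sigma),
                    *cfg.coverage_clip,
                )
            )
        origin_is_mutant = rng.random(n) < cfg.fraction
        n_passes = 1 + rng.poisson(cfg.pass_mean - 1, size=n)
        read_quality = np.clip(
            1.0
            - cfg.consensus_error_scale
            * n_passes.astype(float) ** -2
            * np.exp(rng.normal(0.0, cfg.quality_jitter_sd, size=n)),
            0.0,
            0.999999,
        )
        templates, backgrounds = _amplicon_templates(amp.start, amp_len, ref, haplotypes)
        bases = templates[origin_is_mutant.astype(np.intp)].copy()
        # background heteroplasmies: per-read Bernoulli at the variant's fraction
        for hi, bg in enumerate(backgrounds):
            rows = np.flatnonzero(origin_is_mutant == bool(hi))
            for c, (code, frac) in sorted(bg.items()):
                hit = rows[rng.random(rows.size) < frac]
                bases[hit, c] = code
        quals = np.empty((n, amp_len), dtype=np.uint8)
        mean_ok, sd_ok = cfg.quality_correct
        mean_err, sd_err = cfg.quality_error
        for lo in range(0, n, _CHUNK_ROWS):
            hi_ = min(lo + _CHUNK_ROWS, n)
            block = bases[lo:hi_]
            err = rng.random(block.shape) < cfg.error_rate
            n_err = int(err.sum())
            if n_err:
                block[err] = (
                    block[err] + rng.integers(1, 4, size=n_err).astype(np.uint8)
                ) % 4
            q = rng.normal(mean_ok, sd_ok, size=block.shape)
            if n_err:
                q[err] = rng.normal(mean_err, sd_err, size=n_err)
            quals[lo:hi_] = np.clip(np.rint(q), 2, 93).astype(np.uint8)
        read_ids = np.array(
            [f"{cfg.mixture_id}/{amp.id}/{i:06d}" for i in range(n)], dtype=object
        )
        origin = np.where(origin_is_mutant, ORIGIN_MUTANT, ORIGIN_WILDTYPE).astype(
            object
        )
        batches.append(
            ReadBatch(
                amplicon_id=amp.id,
                start=amp.start,
                bases=bases,
                quals=quals,
                read_ids=read_ids,
                n_passes=n_passes,
                read_quality=read_quality,
                true_origin=origin,
            )
        )
    reads = ReadSet(batches=batches)
    return reads, reads.truth_table()


def filter_ccs(
    reads: Union[ReadSet, Sequence[AlignedRead]],
    min_quality: float = 0.99,
    min_passes: int = 5,
):
    """Keep consensus reads with predicted accuracy >= ``min_quality`` and at
    least ``min_passes`` polymerase passes; order is preserved."""
    if isinstance(reads, ReadSet):
        kept = []
        for b in reads.batches:
            mask = (b.read_quality >= min_quality) & (b.n_passes >= min_passes)
            kept.append(b.subset(mask))
        return ReadSet(batches=kept)
    return [
        r
        for r in reads
        if r.read_quality >= min_quality and r.n_passes >= min_passes
    ]


def simulate_qpcr_plate(
    true_ratio: float,
    n_replicates: int = 2,
    cq_noise_sd: float = 0.0,
    seed: int = 0,
    cq_mt_center: float = 15.0,
) -> list[QpcrMeasurement]:
    """Simulate replicate Cq pairs whose dCq is centred on log2(true_ratio).

    ``true_ratio == inf`` models an extract with no nuclear signal
    (``cq_nuc`` absent); ``true_ratio == 0`` models no mitochondrial signal
    (``cq_mt`` absent).
    """
    if true_ratio < 0:
        raise ValueError("true_ratio must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_replicates):
        if true_ratio == 0:
            out.append(QpcrMeasurement(cq_mt=None, cq_nuc=cq_mt_center, replicate_id=str(i + 1)))
            continue
        cq_mt = cq_mt_center + rng.normal(0.0, cq_noise_sd) if cq_noise_sd else cq_mt_center
        if np.isinf(true_ratio):
            cq_nuc = None
        else:
            cq_nuc = cq_mt + float(np.log2(true_ratio))
            if cq_noise_sd:
                cq_nuc += rng.normal(0.0, cq_noise_sd)
        out.append(QpcrMeasurement(cq_mt=cq_mt, cq_nuc=cq_nuc, replicate_id=str(i + 1)))
    return out


# --- study bundles -----------------------------------------------------------


@dataclass(frozen=True)
class Study:
    """A reference, its extension, the amplicon panel and the haplotype pair."""

    reference: CircularReference
    extended: ExtendedReference
    panel: AmpliconPanel
    mutant: HaplotypeDefinition
    wildtype: HaplotypeDefinition

    @property
    def differing(self) -> set[int]:
        from .haplotypes import differing_positions

        return differing_positions(self.mutant, self.wildtype)


def default_study() -> Study:
    """The full-scale synthetic study: 16,569 bp circle, 9-amplicon panel,
    haplotype pair built from the packaged truth table."""
    ref = random_reference()
    panel = AmpliconPanel.default(ref)
    mutant, wildtype = default_haplotype_pair(ref)
    ext = build_extended_reference(ref, extension_length=panel.max_amplicon_length())
    return Study(reference=ref, extended=ext, panel=panel, mutant=mutant, wildtype=wildtype)


def scaled_haplotype_pair(
    ref: CircularReference,
    n_differing: int = 4,
    wildtype_background: Sequence[tuple[int, float]] = ((301, 0.02),),
    mutant_background: Sequence[tuple[int, float]] = (),
) -> tuple[HaplotypeDefinition, HaplotypeDefinition]:
    """Mutant/wildtype pair for a scaled-down reference: ``n_differing``
    evenly spaced mutant-private variants plus configurable background
    heteroplasmies at explicit (position, fraction) pairs."""
    from .haplotypes import _rotated  # deterministic allele rotation

    bg_positions = {p for p, _ in wildtype_background} | {
        p for p, _ in mutant_background
    }
    positions: list[int] = []
    step = max(1, ref.length // (n_differing + 1))
    p = step
    while len(positions) < n_differing:
        pos = (p - 1) % ref.length + 1
        if pos not in bg_positions and pos not in positions:
            positions.append(pos)
        p += max(1, step // 2)
    mut_vars = []
    for pos in positions:
        base = ref.base_at(pos)
        mut_vars.append(Variant(pos, base, _rotated(base)))

    def _bg(spec):
        return tuple(
            (Variant(pos, ref.base_at(pos), _rotated(ref.base_at(pos), 2)), frac)
            for pos, frac in spec
        )

    mutant = HaplotypeDefinition(
        name="mutant",
        variants=frozenset(mut_vars),
        background_heteroplasmies=_bg(mutant_background),
    )
    wildtype = HaplotypeDefinition(
        name="wildtype", background_heteroplasmies=_bg(wildtype_background)
    )
    return mutant, wildtype


def demo_study(
    ref_length: int = 2_000,
    n_amplicons: int = 2,
    overlap: int = 100,
    n_differing: int = 4,
    seed: int = DEFAULT_REFERENCE_SEED,
    wildtype_background: Sequence[tuple[int, float]] = ((301, 0.02),),
    mutant_background: Sequence[tuple[int, float]] = (),
) -> Study:
    """A scaled-down study sharing every structural property of the full
    design (overlaps, origin-spanning amplicon, differing positions,
    background heteroplasmies) at a size suited to replicated testing."""
    ref = random_reference(length=ref_length, seed=seed, name="chrM_demo")
    panel = AmpliconPanel.default(ref, n_amplicons=n_amplicons, overlap=overlap)
    mutant, wildtype = scaled_haplotype_pair(
        ref,
        n_differing=n_differing,
        wildtype_background=wildtype_background,
        mutant_background=mutant_background,
    )
    ext = build_extended_reference(ref, extension_length=panel.max_amplicon_length())
    return Study(reference=ref, extended=ext, panel=panel, mutant=mutant, wildtype=wildtype)
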