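"""Pileup construction on the extended reference and threshold variant calling.

Counting rules mirror the study's pileup parameters: bases below the
quality threshold (default Q30) are excluded, N bases and indels are never
counted, mapping quality is not filtered (accept-all by default, kept
configurable), and extension positions are folded back onto the circle
before counting.  A variant call requires at least ``min_alt_depth``
(default 5) high-quality reads supporting a non-reference allele; several
alternative alleles may be called at one position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .reference import (
    BASE_ORDER,
    CircularReference,
    ExtendedReference,
    encode_bases,
)
from .simulate import AlignedRead, ReadSet

DEFAULT_MIN_BASE_QUALITY = 30
DEFAULT_MIN_ALT_DEPTH = 5


@dataclass(frozen=True)
class PileupColumn:
    """Per-circle-position allele tally after the base-quality filter."""

    circle_position: int
    counts: dict[str, int]
    depth: int
    per_amplicon: dict[str, dict[str, int]]


@dataclass
class Pileup:
    """Allele counts over the whole circle: ``counts[code, position-1]``."""

    reference_name: str
    length: int
    counts: np.ndarray  # (4, L) int64
    amplicon_counts: dict[str, np.ndarray] = field(default_factory=dict)
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def column(self, pos: int) -> PileupColumn:
        if not 1 <= pos <= self.length:
            raise ValueError(f"position {pos} outside [1, {self.length}]")
        i = pos - 1
        counts = {b: int(self.counts[c, i]) for c, b in enumerate(BASE_ORDER)}
        per_amp = {}
        for amp, arr in self.amplicon_counts.items():
            if arr[:, i].sum() > 0:
                per_amp[amp] = {
                    b: int(arr[c, i]) for c, b in enumerate(BASE_ORDER)
                }
        return PileupColumn(
            circle_position=pos,
            counts=counts,
            depth=int(self.counts[:, i].sum()),
            per_amplicon=per_amp,
        )

    def to_frame(self, include_empty: bool = False) -> pd.DataFrame:
        """Tabular pileup (positions with depth 0 omitted by default)."""
        depth = self.depth
        keep = np.ones(self.length, bool) if include_empty else depth > 0
        pos = np.flatnonzero(keep) + 1
        data = {"position": pos}
        for c, b in enumerate(BASE_ORDER):
            data[b] = self.counts[c, keep]
        data["depth"] = depth[keep]
        return pd.DataFrame(data)

    def write_tsv(self, path: Union[str, Path], header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


def _accumulate(
    counts: np.ndarray,
    amp_counts: dict[str, np.ndarray],
    amplicon_id: str,
    bases: np.ndarray,
    quals: np.ndarray,
    start: int,
    L: int,
    ext_length: int,
    min_base_quality: int,
    read_ids: Optional[np.ndarray] = None,
) -> None:
    n, read_len = bases.shape
    if start < 1 or start - 1 + read_len > ext_length:
        offender = read_ids[0] if read_ids is not None else "<unknown>"
        raise ValueError(
            f"read {offender} (start {start}, length {read_len}) extends beyond "
            f"the extended reference of length {ext_length}"
        )
    circle = (np.arange(start - 1, start - 1 + read_len)) % L
    mask = (quals >= min_base_quality) & (bases < 4)
    flat = bases.astype(np.int64) * L + circle[np.newaxis, :]
    tallies = np.bincount(flat[mask], minlength=4 * L).reshape(4, L)
    counts += tallies
    if amplicon_id not in amp_counts:
        amp_counts[amplicon_id] = np.zeros((4, L), dtype=np.int64)
    amp_counts[amplicon_id] += tallies


def build_pileup(
    reads: Union[ReadSet, Iterable[AlignedRead]],
    ref: ExtendedReference,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
    min_mapping_quality: int = 0,
) -> Pileup:
    """Tally base calls per circle position, folding the linear extension.

    ``min_mapping_quality`` is accepted for interface completeness; the
    simulated reads carry no mapping-quality concept and SAM ingest applies
    it before this function.
    """
    L = ref.base.length
    counts = np.zeros((4, L), dtype=np.int64)
    amp_counts: dict[str, np.ndarray] = {}
    if isinstance(reads, ReadSet):
        for b in reads.batches:
            if b.n_reads == 0:
                continue
            _accumulate(
                counts,
                amp_counts,
                b.amplicon_id,
                b.bases,
                b.quals,
                b.start,
                L,
                ref.length,
                min_base_quality,
                b.read_ids,
            )
    else:
        for r in reads:
            _accumulate(
                counts,
                amp_counts,
                r.amplicon_id,
                encode_bases(r.seq)[np.newaxis, :],
                np.asarray(r.quals, dtype=np.uint8)[np.newaxis, :],
                r.start,
                L,
                ref.length,
                min_base_quality,
                np.array([r.read_id], dtype=object),
            )
    return Pileup(
        reference_name=ref.base.name,
        length=L,
        counts=counts,
        amplicon_counts=amp_counts,
        min_base_quality=min_base_quality,
    )


@dataclass(frozen=True)
class VariantCall:
    """A non-reference allele observed in at least ``min_alt_depth`` reads."""

    circle_position: int
    ref_allele: str
    alt_allele: str
    alt_depth: int
    depth: int
    allele_frequency: float
    amplicons_observed: frozenset[str]
    mixture_id: str = ""

    def __post_init__(self) -> None:
        if self.alt_depth > self.depth:
            raise ValueError("alt_depth cannot exceed depth")
        if not 0 < self.allele_frequency <= 1:
            raise ValueError("allele_frequency must be in (0, 1]")

    @property
    def key(self) -> tuple[int, str]:
        return (self.circle_position, self.alt_allele)


def call_variants(
    pileup: Pileup,
    ref: CircularReference,
    min_alt_depth: int = DEFAULT_MIN_ALT_DEPTH,
    mixture_id: str = "",
) -> list[VariantCall]:
    """One call per (position, non-reference allele) with enough support.

    The allele-frequency denominator is the quality-filtered depth at the
    position; amplicons with at least one supporting read are recorded as
    observations.
    """
    if min_alt_depth < 1:
        raise ValueError("min_alt_depth must be >= 1")
    ref_codes = ref.codes()
    depth = pileup.depth
    calls: list[VariantCall] = []
    for code in range(4):
        alt_counts = pileup.counts[code]
        candidate = (alt_counts >= min_alt_depth) & (ref_codes != code)
        for i in np.flatnonzero(candidate):
            pos = int(i) + 1
            amps = frozenset(
                amp
                for amp, arr in pileup.amplicon_counts.items()
                if arr[code, i] >= 1
            )
            calls.append(
                VariantCall(
                    circle_position=pos,
                    ref_allele=BASE_ORDER[ref_codes[i]],
                    alt_allele=BASE_ORDER[code],
                    alt_depth=int(alt_counts[i]),
                    depth=int(depth[i]),
                    allele_frequency=float(alt_counts[i] / depth[i]),
                    amplicons_observed=amps,
                    mixture_id=mixture_id,
                )
            )
    calls.sort(key=lambda c: (c.circle_position, c.alt_allele))
    return calls


def calls_to_frame(calls: Sequence[VariantCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "position": [c.circle_position for c in calls],
            "ref": [c.ref_allele for c in calls],
            "alt": [c.alt_allele for c in calls],
            "alt_depth": [c.alt_depth for c in calls],
            "depth": [c.depth for c in calls],
            "allele_frequency": [c.allele_frequency for c in calls],
            "amplicons": [",".join(sorted(c.amplicons_observed)) for c in calls],
            "mixture": [c.mixture_id for c in calls],
        }
    )
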