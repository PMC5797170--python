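"""Circular mitochondrial reference, its linear extension, and the amplicon panel.

The human mitochondrial genome is a circle of ~16,569 bp.  Linear aligners
systematically under-map reads that span the origin, so the pipeline aligns
against an *extended* reference: the circle followed by a copy of its first
``extension_length`` bases.  Positions on the extension are folded back onto
the circle with :func:`to_circle_position` before any counting.

The genome is tiled by a panel of overlapping long amplicons (here lettered
A–I).  Overlap regions are covered by two amplicons and therefore yield two
independent observations of a variant, which the downstream validation logic
exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MT_GENOME_LENGTH = 16_569
VALID_BASES = frozenset("ACGTN")

BASE_ORDER = "ACGT"
#: byte value -> base code; A,C,G,T -> 0..3, N -> 4, everything else -> 255
BASE_CODES = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    BASE_CODES[ord(_b)] = _i
    BASE_CODES[ord(_b.lower())] = _i

CODE_TO_BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode_bases(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 code array (A=0,C=1,G=2,T=3,N=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = BASE_CODES[raw]
    if (codes == 255).any():
        bad = seq[int(np.argmax(codes == 255))]
        raise ValueError(f"invalid nucleotide {bad!r} in sequence")
    return codes


def decode_bases(codes: np.ndarray) -> str:
    return CODE_TO_BASE[codes].tobytes().decode("ascii")


@dataclass(frozen=True)
class CircularReference:
    """A circular genome with 1-based inclusive coordinates."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError("reference sequence must be non-empty")
        seq = self.sequence.upper()
        if set(seq) - VALID_BASES:
            raise ValueError(
                f"reference alphabet must be within {sorted(VALID_BASES)}"
            )
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base_at(self, pos: int) -> str:
        """Reference base at a 1-based circle position (wraps around)."""
        if pos < 1:
            raise ValueError(f"position must be >= 1, got {pos}")
        return self.sequence[(pos - 1) % self.length]

    def codes(self) -> np.ndarray:
        return encode_bases(self.sequence)

    @classmethod
    def from_fasta(cls, path: Union[str, Path]) -> "CircularReference":
        record = next(SeqIO.parse(str(path), "fasta"))
        return cls(name=record.id, sequence=str(record.seq))

    def to_fasta(self, path: Union[str, Path]) -> None:
        record = SeqRecord(Seq(self.sequence), id=self.name, description="")
        SeqIO.write([record], str(path), "fasta")


@dataclass(frozen=True)
class ExtendedReference:
    """Circle plus a copy of its first ``extension_length`` bases.

    Built with :func:`build_extended_reference`; do not construct directly.
    """

    base: CircularReference
    extension_length: int
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def name(self) -> str:
        return f"{self.base.name}_ext{self.extension_length}"

    def codes(self) -> np.ndarray:
        return encode_bases(self.sequence)

    def to_fasta(self, path: Union[str, Path]) -> None:
        record = SeqRecord(Seq(self.sequence), id=self.name, description="")
        SeqIO.write([record], str(path), "fasta")


def build_extended_reference(
    ref: CircularReference, extension_length: int = 3_000
) -> ExtendedReference:
    """Extend a circular reference linearly to absorb origin-spanning reads.

    ``extension_length`` must be positive, at most one full circle, and in
    practice at least as long as the longest amplicon so no read straddles
    the extension boundary.
    """
    if not 0 < extension_length <= ref.length:
        raise ValueError(
            f"extension_length must be in (0, {ref.length}], got {extension_length}"
        )
    return ExtendedReference(
        base=ref,
        extension_length=extension_length,
        sequence=ref.sequence + ref.sequence[:extension_length],
    )


def to_circle_position(pos_extended, ref_length: int):
    """Fold a 1-based extended-reference position back onto the circle.

    Accepts scalars or numpy arrays; result is always in ``[1, ref_length]``.
    """
    pos = np.asarray(pos_extended)
    if (pos < 1).any():
        raise ValueError("extended positions are 1-based; got a value < 1")
    out = (pos - 1) % ref_length + 1
    if np.isscalar(pos_extended) or out.ndim == 0:
        return int(out)
    return out


@dataclass(frozen=True)
class Amplicon:
    """One PCR product on the circle, 1-based inclusive; ``end < start``
    means the amplicon spans the origin."""

    id: str
    start: int
    end: int

    def length_on(self, ref_length: int) -> int:
        if self.end >= self.start:
            return self.end - self.start + 1
        return ref_length - self.start + 1 + self.end

    def contains(self, pos: int, ref_length: int) -> bool:
        if not 1 <= pos <= ref_length:
            raise ValueError(f"position {pos} outside [1, {ref_length}]")
        if self.end >= self.start:
            return self.start <= pos <= self.end
        return pos >= self.start or pos <= self.end

    def extended_positions(self, ref_length: int) -> np.ndarray:
        """1-based positions on the *extended* reference, never wrapping."""
        return np.arange(self.start, self.start + self.length_on(ref_length))


@dataclass
class AmpliconPanel:
    """Ordered amplicon tiling of a circular reference.

    Invariants checked at construction: every circle position is covered and
    consecutive amplicons (cyclically) overlap by at least one base.
    """

    amplicons: list[Amplicon]
    reference: CircularReference
    _coverage_sets: list[frozenset[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.amplicons:
            raise ValueError("panel must contain at least one amplicon")
        ids = [a.id for a in self.amplicons]
        if len(set(ids)) != len(ids):
            raise ValueError("amplicon ids must be unique")
        L = self.reference.length
        cover = [set() for _ in range(L)]
        for a in self.amplicons:
            for p in to_circle_position(a.extended_positions(L), L):
                cover[p - 1].add(a.id)
        uncovered = [i + 1 for i, s in enumerate(cover) if not s]
        if uncovered:
            raise ValueError(
                f"panel leaves {len(uncovered)} positions uncovered "
                f"(first: {uncovered[0]})"
            )
        for a, b in zip(self.amplicons, self.amplicons[1:] + self.amplicons[:1]):
            if len(self.amplicons) > 1 and not any(
                a.id in s and b.id in s for s in cover
            ):
                raise ValueError(f"amplicons {a.id} and {b.id} do not overlap")
        self._coverage_sets = [frozenset(s) for s in cover]

    @property
    def ids(self) -> list[str]:
        return [a.id for a in self.amplicons]

    def __getitem__(self, amplicon_id: str) -> Amplicon:
        for a in self.amplicons:
            if a.id == amplicon_id:
                return a
        raise KeyError(amplicon_id)

    def covering(self, pos: int) -> frozenset[str]:
        """Ids of amplicons whose circular interval contains ``pos``."""
        L = self.reference.length
        if not 1 <= pos <= L:
            raise ValueError(f"position {pos} outside [1, {L}]")
        return self._coverage_sets[pos - 1]

    def overlap_length(self) -> int:
        """Total number of circle positions covered by >= 2 amplicons."""
        return sum(1 for s in self._coverage_sets if len(s) >= 2)

    def max_amplicon_length(self) -> int:
        L = self.reference.length
        return max(a.length_on(L) for a in self.amplicons)

    @classmethod
    def default(
        cls,
        reference: CircularReference,
        n_amplicons: int = 9,
        overlap: int = 150,
    ) -> "AmpliconPanel":
        """Evenly spaced tiling: ``n_amplicons`` amplicons with fixed overlap,
        the last one spanning the origin back into the first."""
        L = reference.length
        spacing = -(-L // n_amplicons)  # ceil
        length = spacing + overlap
        if length > L:
            raise ValueError("amplicons longer than the reference")
        letters = [chr(ord("A") + i) for i in range(n_amplicons)]
        amps = []
        for i, letter in enumerate(letters):
            start = 1 + i * spacing
            end = start + length - 1
            if end > L:
                end -= L
            amps.append(Amplicon(id=letter, start=start, end=end))
        return cls(amplicons=amps, reference=reference)

    @classmethod
    def from_tsv(
        cls, path: Union[str, Path], reference: CircularReference
    ) -> "AmpliconPanel":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", comment="#", dtype={"id": str})
        amps = [
            Amplicon(id=row.id, start=int(row.start), end=int(row.end))
            for row in df.itertuples()
        ]
        return cls(amplicons=amps, reference=reference)

    def to_tsv(self, path: Union[str, Path]) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "id": [a.id for a in self.amplicons],
                "start": [a.start for a in self.amplicons],
                "end": [a.end for a in self.amplicons],
            }
        ).to_csv(path, sep="\t", index=False)


def amplicons_covering(panel: AmpliconPanel, pos: int) -> frozenset[str]:
    """Functional alias for :meth:`AmpliconPanel.covering`."""
    return panel.covering(pos)
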