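"""Read-backed allelic phasing of de-novo variants against two known
haplotypes.

Long amplicon reads span many of the positions at which the two documented
haplotypes differ (the *anchors*).  Every read carrying a de-novo variant
allele is inspected at the anchors inside its span: an anchor base matching
exactly one haplotype votes for that haplotype, an anchor base matching
neither (a sequencing error at the anchor) is ignored rather than counted
as discordant.  A read is *informative* if it casts at least one vote and
*concordant* with a haplotype if all its votes agree.  The variant is
assigned a genotype when enough informative reads agree at the configured
concordance; otherwise it is ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .calling import DEFAULT_MIN_BASE_QUALITY
from .haplotypes import HaplotypeDefinition, differing_positions
from .reference import CircularReference, encode_bases
from .simulate import AlignedRead, ReadSet

GENOTYPE_WILDTYPE = "wildtype"
GENOTYPE_MUTANT = "mutant"
GENOTYPE_AMBIGUOUS = "ambiguous"

DEFAULT_MIN_INFORMATIVE = 5
DEFAULT_CONCORDANCE_MIN = 0.9


@dataclass(frozen=True)
class PhasingResult:
    variant: tuple[int, str]
    n_variant_reads: int
    n_informative_reads: int
    n_wildtype_concordant: int
    n_mutant_concordant: int
    genotype: str


def _anchor_alleles(
    mutant: HaplotypeDefinition,
    wildtype: HaplotypeDefinition,
    ref: Optional[CircularReference] = None,
) -> dict[int, tuple[int, int]]:
    """position -> (wildtype code, mutant code) at every differing anchor.

    The allele of the haplotype without a variant at an anchor is the
    reference base, recoverable from the other haplotype's variant record.
    """
    wt_map = {v.position: v for v in wildtype.variants}
    mut_map = {v.position: v for v in mutant.variants}
    anchors = {}
    for pos in differing_positions(mutant, wildtype):
        if pos in wt_map:
            wt_allele = wt_map[pos].alt_allele
        elif pos in mut_map:
            wt_allele = mut_map[pos].ref_allele
        else:  # unreachable: a differing position involves >=1 variant
            wt_allele = ref.base_at(pos)
        if pos in mut_map:
            mut_allele = mut_map[pos].alt_allele
        else:
            mut_allele = wt_map[pos].ref_allele
        anchors[pos] = (
            int(encode_bases(wt_allele)[0]),
            int(encode_bases(mut_allele)[0]),
        )
    return anchors


def phase_variant(
    variant: tuple[int, str],
    reads: Union[ReadSet, Iterable[AlignedRead]],
    mutant: HaplotypeDefinition,
    wildtype: HaplotypeDefinition,
    ref_length: Optional[int] = None,
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
    concordance_min: float = DEFAULT_CONCORDANCE_MIN,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
) -> PhasingResult:
    """Assign a (position, allele) variant to the haplotype its carrier
    reads travel with.

    Reads whose span contains no differing anchor contribute to
    ``n_variant_reads`` but not to the vote; with fewer than
    ``min_informative`` informative reads, or without the required
    concordant majority, the genotype is ambiguous.
    """
    pos, allele = variant
    allele_code = int(encode_bases(allele)[0])
    if not isinstance(reads, ReadSet):
        reads = ReadSet.from_reads(reads)
    if ref_length is None:
        # infer the circle length from the longest batch placement
        ref_length = max(
            (b.start - 1 + b.read_length for b in reads.batches), default=0
        )
    anchors = _anchor_alleles(mutant, wildtype)
    n_variant = n_informative = n_wt = n_mut = 0
    for b in reads.batches:
        if b.n_reads == 0:
            continue
        L_amp = b.read_length
        col = (pos - b.start) % ref_length if ref_length else pos - b.start
        if not 0 <= col < L_amp:
            continue
        carrier = (b.bases[:, col] == allele_code) & (
            b.quals[:, col] >= min_base_quality
        )
        idx = np.flatnonzero(carrier)
        if idx.size == 0:
            continue
        n_variant += int(idx.size)
        anchor_cols, wt_codes, mut_codes = [], [], []
        for apos, (wt_c, mut_c) in anchors.items():
            acol = (apos - b.start) % ref_length if ref_length else apos - b.start
            if 0 <= acol < L_amp and acol != col:
                anchor_cols.append(acol)
                wt_codes.append(wt_c)
                mut_codes.append(mut_c)
        if not anchor_cols:
            continue
        ab = b.bases[np.ix_(idx, anchor_cols)]
        aq = b.quals[np.ix_(idx, anchor_cols)]
        usable = aq >= min_base_quality
        wt_votes = ((ab == np.array(wt_codes)) & usable).sum(axis=1)
        mut_votes = ((ab == np.array(mut_codes)) & usable).sum(axis=1)
        informative = (wt_votes + mut_votes) > 0
        n_informative += int(informative.sum())
        n_wt += int(((wt_votes > 0) & (mut_votes == 0)).sum())
        n_mut += int(((mut_votes > 0) & (wt_votes == 0)).sum())
    genotype = GENOTYPE_AMBIGUOUS
    if n_informative >= min_informative:
        if n_wt / n_informative >= concordance_min:
            genotype = GENOTYPE_WILDTYPE
        elif n_mut / n_informative >= concordance_min:
            genotype = GENOTYPE_MUTANT
    return PhasingResult(
        variant=variant,
        n_variant_reads=n_variant,
        n_informative_reads=n_informative,
        n_wildtype_concordant=n_wt,
        n_mutant_concordant=n_mut,
        genotype=genotype,
    )


def phase_many(
    variants: Sequence[tuple[int, str]],
    reads: Union[ReadSet, Iterable[AlignedRead]],
    mutant: HaplotypeDefinition,
    wildtype: HaplotypeDefinition,
    ref_length: Optional[int] = None,
    **kwargs,
) -> dict[tuple[int, str], PhasingResult]:
    if not isinstance(reads, ReadSet):
        reads = ReadSet.from_reads(reads)
    return {
        v: phase_variant(
            v, reads, mutant, wildtype, ref_length=ref_length, **kwargs
        )
        for v in variants
    }
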