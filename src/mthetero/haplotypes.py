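"""Haplotype truth sets for the two-cell-line dilution experiment.

The limit-of-detection experiment mixes two breast-cancer cell lines whose
mitochondrial genomes are fully documented: one line is treated as the
*mutant* haplotype, the other as *wildtype*.  The lines carry respectively
29 and 13 homoplasmic variants against the reference, 7 of which are shared,
leaving 28 positions at which the two haplotypes carry different alleles.
23 of those 28 were assayed by sequencing and form the packaged
limit-of-detection fixture; each haplotype additionally carries a handful of
low-level heteroplasmic background variants of its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .reference import CircularReference

_VALID_ALLELES = frozenset("ACGT")


@dataclass(frozen=True)
class Variant:
    """A single-nucleotide substitution at a 1-based circle position."""

    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for name in ("ref_allele", "alt_allele"):
            a = getattr(self, name)
            if a not in _VALID_ALLELES:
                raise ValueError(f"{name} must be one of A/C/G/T, got {a!r}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")

    @property
    def key(self) -> tuple[int, str]:
        return (self.position, self.alt_allele)


@dataclass(frozen=True)
class HaplotypeDefinition:
    """A named haplotype: homoplasmic variants plus per-molecule background
    heteroplasmies (variant, allele fraction) carried at low level."""

    name: str
    variants: frozenset[Variant] = frozenset()
    background_heteroplasmies: tuple[tuple[Variant, float], ...] = ()

    def __post_init__(self) -> None:
        positions = [v.position for v in self.variants]
        if len(set(positions)) != len(positions):
            raise ValueError("at most one homoplasmic variant per position")
        for v, f in self.background_heteroplasmies:
            if not 0 < f < 1:
                raise ValueError(
                    f"background fraction must be in (0, 1), got {f} at {v.position}"
                )

    @property
    def allele_map(self) -> dict[int, str]:
        """position -> homoplasmic effective allele (positions with variants only)."""
        return {v.position: v.alt_allele for v in self.variants}

    def effective_allele(self, pos: int, ref: Optional[CircularReference] = None) -> str:
        for v in self.variants:
            if v.position == pos:
                return v.alt_allele
        if ref is None:
            raise ValueError("reference required for positions without a variant")
        return ref.base_at(pos)


@dataclass(frozen=True)
class MixtureDesign:
    """The ordered mutant fractions of the dilution series (as fractions)."""

    fractions: tuple[float, ...] = (0.0, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1)

    def __post_init__(self) -> None:
        fr = self.fractions
        if any(not 0 <= f <= 1 for f in fr):
            raise ValueError("fractions must lie in [0, 1]")
        if any(b <= a for a, b in zip(fr, fr[1:])):
            raise ValueError("fractions must be strictly increasing")

    def label(self, fraction: float) -> str:
        """Mixture id, e.g. 0.001 -> ``'0.1%'``."""
        pct = fraction * 100
        return f"{pct:g}%"

    @property
    def labels(self) -> list[str]:
        return [self.label(f) for f in self.fractions]

    def fraction_of(self, label: str) -> float:
        for f in self.fractions:
            if self.label(f) == label:
                return f
        raise KeyError(f"unknown mixture label {label!r}")


def differing_positions(
    h1: HaplotypeDefinition, h2: HaplotypeDefinition
) -> set[int]:
    """Positions where the two haplotypes carry different effective alleles.

    Positions untouched by both haplotypes agree by definition (both carry
    the reference base), so only variant positions need comparing; a variant
    private to one haplotype always differs because alt != ref.
    """
    a1, a2 = h1.allele_map, h2.allele_map
    out = set()
    for p in set(a1) | set(a2):
        if a1.get(p) != a2.get(p):
            out.add(p)
    return out


@dataclass(frozen=True)
class Table1Fixture:
    """The 23 sequenced differing positions with per-method detection limits.

    ``lod`` columns hold the limit of detection in percent allele frequency
    (NaN where the method did not assay the position).
    """

    mutant: HaplotypeDefinition
    wildtype: HaplotypeDefinition
    lod: pd.DataFrame


def _fixture_path() -> Path:
    return Path(resources.files("mthetero").joinpath("data/table1_lod.tsv"))


def load_table1_fixture() -> Table1Fixture:
    """Load the packaged detection-limit truth table.

    The two restricted haplotypes are built with the wildtype allele taken
    as the local reference allele (the wildtype line matches the reference
    at most assayed positions), so the mutant haplotype carries one variant
    per row and the wildtype haplotype none.
    """
    path = _fixture_path()
    df = pd.read_csv(path, sep="\t", na_values=["na"], dtype={"position": int})
    required = {
        "position",
        "mutant_allele",
        "wildtype_allele",
        "lod_smrt",
        "lod_ultraseek",
        "lod_dpcr",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fixture missing columns: {sorted(missing)}")
    mut_variants = []
    for i, row in df.iterrows():
        try:
            mut_variants.append(
                Variant(
                    position=int(row.position),
                    ref_allele=str(row.wildtype_allele),
                    alt_allele=str(row.mutant_allele),
                )
            )
        except ValueError as exc:
            raise ValueError(f"fixture row {i + 2}: {exc}") from exc
    mutant = HaplotypeDefinition(name="mutant", variants=frozenset(mut_variants))
    wildtype = HaplotypeDefinition(name="wildtype", variants=frozenset())
    return Table1Fixture(mutant=mutant, wildtype=wildtype, lod=df)


# --- default simulation haplotypes ------------------------------------------

#: synthetic differing positions restoring the 23 -> 28 count
EXTRA_DIFFERING_POSITIONS = (3333, 5555, 7777, 9999, 11111)
#: synthetic positions at which both haplotypes share the same alt allele
CONCORDANT_POSITIONS = (444, 2222, 4444, 8888, 10101, 12121, 15151)
#: background heteroplasmies on the wildtype haplotype (position, fraction);
#: pattern follows the observed wildtype-phased spectrum: one ~24%, one ~7%,
#: several at or below ~1%
WILDTYPE_BACKGROUND = ((1500, 0.24), (3210, 0.071), (6543, 0.013), (9876, 0.006), (13131, 0.003))
#: background heteroplasmies on the mutant haplotype
MUTANT_BACKGROUND = ((2500, 0.08), (12000, 0.009))

_ROTATE = {"A": "C", "C": "G", "G": "T", "T": "A", "N": "A"}


def _rotated(base: str, times: int = 1) -> str:
    for _ in range(times):
        base = _ROTATE[base]
    return base


def default_haplotype_pair(
    ref: CircularReference,
    wildtype_background: Sequence[tuple[int, float]] = WILDTYPE_BACKGROUND,
    mutant_background: Sequence[tuple[int, float]] = MUTANT_BACKGROUND,
) -> tuple[HaplotypeDefinition, HaplotypeDefinition]:
    """Build the (mutant, wildtype) pair used for full-scale simulation.

    The 23 packaged positions carry the documented mutant/wildtype alleles;
    5 synthetic positions are added so the pair differs at 28 positions, and
    7 synthetic concordant alt positions are shared by both haplotypes.
    Background heteroplasmies default to the documented wildtype-phased
    pattern at synthetic positions.
    """
    fixture = load_table1_fixture()
    mut_vars: list[Variant] = []
    wt_vars: list[Variant] = []
    for row in fixture.lod.itertuples():
        pos = int(row.position)
        ref_base = ref.base_at(pos)
        if str(row.mutant_allele) != ref_base:
            mut_vars.append(Variant(pos, ref_base, str(row.mutant_allele)))
        if str(row.wildtype_allele) != ref_base:
            wt_vars.append(Variant(pos, ref_base, str(row.wildtype_allele)))
    for pos in EXTRA_DIFFERING_POSITIONS:
        ref_base = ref.base_at(pos)
        mut_vars.append(Variant(pos, ref_base, _rotated(ref_base)))
    for pos in CONCORDANT_POSITIONS:
        ref_base = ref.base_at(pos)
        alt = _rotated(ref_base)
        mut_vars.append(Variant(pos, ref_base, alt))
        wt_vars.append(Variant(pos, ref_base, alt))

    def _background(spec: Sequence[tuple[int, float]]) -> tuple[tuple[Variant, float], ...]:
        out = []
        for pos, frac in spec:
            ref_base = ref.base_at(pos)
            out.append((Variant(pos, ref_base, _rotated(ref_base, 2)), frac))
        return tuple(out)

    mutant = HaplotypeDefinition(
        name="mutant",
        variants=frozenset(mut_vars),
        background_heteroplasmies=_background(mutant_background),
    )
    wildtype = HaplotypeDefinition(
        name="wildtype",
        variants=frozenset(wt_vars),
        background_heteroplasmies=_background(wildtype_background),
    )
    return mutant, wildtype


def haplotype_to_vcf(
    hap: HaplotypeDefinition, ref: CircularReference, path: Union[str, Path]
) -> None:
    """Export a haplotype's homoplasmic variants as a single-sample, GT-only
    VCF for interoperability."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={ref.name},length={ref.length}>")
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(hap.name)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in sorted(hap.variants, key=lambda v: v.position):
            rec = vcf.new_record(
                contig=ref.name,
                start=v.position - 1,
                alleles=(v.ref_allele, v.alt_allele),
            )
            rec.samples[hap.name]["GT"] = (1,)
            vcf.write(rec)
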