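"""Closed-form quantitation of mtDNA purity, enrichment and contamination risk.

All the arithmetic a wet-lab mtDNA-enrichment experiment reports:

* relative qPCR quantitation, converting a mito/nuclear Cq difference into a
  molecule ratio via ``2**dCq``;
* the mass percentage of mtDNA in a double-stranded DNA extract, from that
  ratio and the two genome sizes;
* fold enrichment between extraction protocols;
* the apparent heteroplasmy at which a nuclear insertion of mitochondrial
  origin (NUMT) would masquerade as a low-frequency mtDNA variant, and how
  mtDNA enrichment suppresses it;
* the expected duplicate fraction of short single-end reads from a genome
  with very few distinct start positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

#: rCRS mitochondrial genome size (bp).
MT_GENOME_SIZE = 16_569
#: GRCh38 haploid nuclear genome size (bp).
NUCLEAR_GENOME_SIZE = 3_088_269_805
#: mtDNA:nDNA ratio assigned when the nuclear qPCR target gives no signal.
NO_SIGNAL_RATIO_CAP = 20_000_000


@dataclass(frozen=True)
class QpcrMeasurement:
    """One qPCR well pair: mitochondrial and nuclear quantification cycles.

    ``cq_nuc is None`` encodes "no amplification signal for the nuclear
    target", i.e. an extract so pure the ratio is capped rather than
    measured.
    """

    cq_mt: float
    cq_nuc: Optional[float] = None
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if self.cq_mt is not None and not (
            math.isfinite(self.cq_mt) and self.cq_mt > 0
        ):
            raise ValueError(f"cq_mt must be finite and > 0, got {self.cq_mt}")
        if self.cq_nuc is not None and not (
            math.isfinite(self.cq_nuc) and self.cq_nuc > 0
        ):
            raise ValueError(f"cq_nuc must be finite and > 0, got {self.cq_nuc}")


@dataclass(frozen=True)
class PurityResult:
    ratio: float
    percentage: float


@dataclass(frozen=True)
class NumtScenario:
    """A NUMT present at ``numt_copies_per_haploid_genome`` copies competing
    with ``mt_copies_per_cell`` true mtDNA molecules in a diploid cell."""

    numt_copies_per_haploid_genome: float
    mt_copies_per_cell: float
    ploidy_factor: float = 2.0
    enrichment_fold: float = 1.0

    def __post_init__(self) -> None:
        if self.numt_copies_per_haploid_genome < 0:
            raise ValueError("NUMT copy number must be >= 0")
        if self.mt_copies_per_cell < 0:
            raise ValueError("mtDNA copy number must be >= 0")
        if self.enrichment_fold < 1:
            raise ValueError("enrichment_fold must be >= 1")


def mt_nuc_ratio(
    m: QpcrMeasurement, no_signal_cap: float = NO_SIGNAL_RATIO_CAP
) -> float:
    """mtDNA:nDNA molecule ratio from relative quantitation, ``2**dCq``.

    When the nuclear target never amplifies the ratio cannot be measured and
    is set to ``no_signal_cap``.
    """
    if m.cq_mt is None:
        raise ValueError("cq_mt is required to compute a ratio")
    if m.cq_nuc is None:
        return float(no_signal_cap)
    return 2.0 ** (m.cq_nuc - m.cq_mt)


def mtdna_percentage(
    ratio: float,
    mt_genome_size: int = MT_GENOME_SIZE,
    nuclear_genome_size: int = NUCLEAR_GENOME_SIZE,
) -> float:
    """Percent of dsDNA mass that is mitochondrial, given the molecule ratio.

    ``100 * r*S_mt / (r*S_mt + S_nuc)``: strictly increasing in ``r`` and
    saturating below 100 for any finite ratio.
    """
    if ratio < 0:
        raise ValueError(f"ratio must be >= 0, got {ratio}")
    if mt_genome_size <= 0 or nuclear_genome_size <= 0:
        raise ValueError("genome sizes must be positive")
    mt_mass = ratio * mt_genome_size
    return 100.0 * mt_mass / (mt_mass + nuclear_genome_size)


def percent_reads_mitochondrial(aligned_mt: int, aligned_total: int) -> float:
    """Percent of genome-wide aligned reads that land on the mitochondrial
    contig."""
    if aligned_total <= 0:
        raise ValueError("aligned_total must be > 0")
    if not 0 <= aligned_mt <= aligned_total:
        raise ValueError("aligned_mt must be within [0, aligned_total]")
    return 100.0 * aligned_mt / aligned_total


def enrichment_fold(pct_after: float, pct_before: float) -> float:
    """Fold change between two mtDNA percentages (a plain ratio of percents,
    e.g. 27% vs 0.1% -> 270-fold)."""
    if pct_before <= 0:
        raise ValueError("pct_before must be > 0")
    if not (0 <= pct_after <= 100 and pct_before <= 100):
        raise ValueError("percentages must lie in [0, 100]")
    return pct_after / pct_before


def numt_apparent_heteroplasmy(s: NumtScenario) -> float:
    """Apparent heteroplasmy (%) a NUMT would present as an mtDNA variant.

    ``100 * ploidy * numt_copies / (enrichment_fold * mt_copies)``: 20 NUMT
    copies against 500 mtDNA molecules reads as 8% heteroplasmy in a total
    cellular extract, and 270-fold mtDNA enrichment suppresses it to 0.03%.
    """
    if s.mt_copies_per_cell <= 0:
        raise ValueError("mt_copies_per_cell must be > 0")
    return (
        100.0
        * s.ploidy_factor
        * s.numt_copies_per_haploid_genome
        / (s.enrichment_fold * s.mt_copies_per_cell)
    )


def expected_duplicate_fraction(
    n_reads: int, n_start_positions: int, strands: int = 1
) -> float:
    """Minimum expected percent of duplicate reads for identical-sequence
    single-end reads drawn from ``n_start_positions`` distinct starts.

    With ``strands=2`` start positions on both strands are counted; the
    default matches the single-strand accounting used for the 97.9% figure.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    if n_start_positions <= 0:
        raise ValueError("n_start_positions must be > 0")
    return 100.0 * max(0.0, 1.0 - strands * n_start_positions / n_reads)


# --- plate-level helpers -----------------------------------------------------


def mean_cq(measurements: Sequence[QpcrMeasurement]) -> QpcrMeasurement:
    """Average replicate Cq values on the Cq scale before taking dCq.

    If any replicate lacks a nuclear signal the pooled measurement is
    treated as no-signal (the capped ratio applies).
    """
    if not measurements:
        raise ValueError("need at least one measurement")
    cq_mt = sum(m.cq_mt for m in measurements) / len(measurements)
    if any(m.cq_nuc is None for m in measurements):
        return QpcrMeasurement(cq_mt=cq_mt, cq_nuc=None, replicate_id="mean")
    cq_nuc = sum(m.cq_nuc for m in measurements) / len(measurements)
    return QpcrMeasurement(cq_mt=cq_mt, cq_nuc=cq_nuc, replicate_id="mean")


def read_cq_plate(path: Union[str, Path]) -> pd.DataFrame:
    """Read a Cq plate TSV: sample_id, replicate, cq_mt, cq_nuc (empty cell
    means no nuclear signal)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    required = {"sample_id", "replicate", "cq_mt", "cq_nuc"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Cq plate is missing columns: {sorted(missing)}")
    return df


def purity_from_plate(
    plate: pd.DataFrame, no_signal_cap: float = NO_SIGNAL_RATIO_CAP
) -> pd.DataFrame:
    """Per-sample ratio and mtDNA percentage from a replicate Cq plate."""
    rows = []
    for sample_id, group in plate.groupby("sample_id", sort=False):
        ms = [
            QpcrMeasurement(
                cq_mt=float(r.cq_mt),
                cq_nuc=None if pd.isna(r.cq_nuc) else float(r.cq_nuc),
                replicate_id=str(r.replicate),
            )
            for r in group.itertuples()
        ]
        ratio = mt_nuc_ratio(mean_cq(ms), no_signal_cap=no_signal_cap)
        rows.append(
            {
                "sample_id": sample_id,
                "n_replicates": len(ms),
                "ratio": ratio,
                "mtdna_percentage": mtdna_percentage(ratio),
            }
        )
    return pd.DataFrame(rows)
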