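"""Limit-of-detection analysis and copy-number detection models.

Empirical LOD: over a dilution series, the lowest mutant fraction at which
a position's mutant allele was called (the 0% mixture never assigns an
LOD).  Sensitivity at a level is the percent of assayed positions whose LOD
is at or below that level.

Copy-number models: each method detects a variant once it draws at least a
minimum number of variant molecules — 2 of <=20,000 partitioned copies for
digital PCR, 3 molecules for the mass-spectrometry single-base-extension
assay, 5 independent reads for long-read sequencing.  Detection probability
is the exact binomial tail P(X >= k), X ~ Binomial(total copies, allele
fraction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .calling import VariantCall
from .haplotypes import MixtureDesign


@dataclass(frozen=True)
class DetectionModel:
    """Minimum-molecule detection model for one method."""

    name: str
    min_variant_copies: int
    capacity: Optional[int] = None

    def __post_init__(self) -> None:
        if self.min_variant_copies < 1:
            raise ValueError("min_variant_copies must be >= 1")


DPCR_MODEL = DetectionModel(name="dPCR", min_variant_copies=2, capacity=20_000)
ULTRASEEK_MODEL = DetectionModel(name="UltraSEEK", min_variant_copies=3)
SMRT_MODEL = DetectionModel(name="SMRT", min_variant_copies=5)


def detection_probability(
    model: DetectionModel, allele_fraction: float, total_copies: int
) -> float:
    """P(at least ``min_variant_copies`` variant molecules among
    ``total_copies`` draws at the given allele fraction); exact binomial."""
    if not 0 <= allele_fraction <= 1:
        raise ValueError("allele_fraction must lie in [0, 1]")
    if total_copies < 0:
        raise ValueError("total_copies must be >= 0")
    if model.capacity is not None and total_copies > model.capacity:
        raise ValueError(
            f"{model.name} accepts at most {model.capacity} copies, got {total_copies}"
        )
    k = model.min_variant_copies
    if total_copies < k:
        return 0.0
    # exact: 1 - sum_{i<k} pmf(i)
    i = np.arange(k)
    return float(1.0 - stats.binom.pmf(i, total_copies, allele_fraction).sum())


@dataclass
class LodTable:
    """Per-position empirical detection limits, one column per method, in
    percent allele frequency (NaN = never detected / not assayed)."""

    table: pd.DataFrame

    def lod(self, position: int, method: str) -> float:
        rows = self.table[self.table["position"] == position]
        if rows.empty:
            raise KeyError(f"position {position} not in the LOD table")
        return float(rows.iloc[0][f"lod_{method.lower()}"])


def lod_per_position(
    calls_by_mixture: Mapping[str, Sequence[VariantCall]],
    truth_alleles: Mapping[int, str],
    design: MixtureDesign,
    method: str = "smrt",
) -> LodTable:
    """Lowest mixture fraction whose call set contains each position's
    mutant allele.

    ``calls_by_mixture`` is keyed by the design's mixture labels; the
    zero-fraction mixture is excluded from LOD assignment (a detection there
    is background, not sensitivity).  Results are percent allele frequency.
    """
    known = set(design.labels)
    unknown = set(calls_by_mixture) - known
    if unknown:
        raise ValueError(f"unknown mixture labels: {sorted(unknown)}")
    detected: dict[int, set[float]] = {pos: set() for pos in truth_alleles}
    for label, calls in calls_by_mixture.items():
        fraction = design.fraction_of(label)
        if fraction == 0:
            continue
        keys = {c.key for c in calls}
        for pos, allele in truth_alleles.items():
            if (pos, allele) in keys:
                detected[pos].add(fraction)
    rows = []
    for pos in sorted(truth_alleles):
        fr = detected[pos]
        rows.append(
            {
                "position": pos,
                "mutant_allele": truth_alleles[pos],
                f"lod_{method.lower()}": min(fr) * 100 if fr else np.nan,
            }
        )
    return LodTable(table=pd.DataFrame(rows))


def sensitivity_at(lod_values: Iterable[float], level: float) -> float:
    """Percent of assayed positions detected at or below ``level``.

    ``lod_values`` and ``level`` must share units (the packaged fixture and
    :func:`lod_per_position` use percent allele frequency); NaN entries
    count as assayed but never detected.
    """
    vals = np.asarray(list(lod_values), dtype=float)
    if vals.size == 0:
        raise ValueError("no positions assayed for this method")
    detected = np.sum(~np.isnan(vals) & (vals <= level * (1 + 1e-12)))
    return 100.0 * detected / vals.size


def format_lod(value: float) -> str:
    """Table-style rendering: 0.1 -> '>=0.1%', NaN -> 'nd'."""
    if np.isnan(value):
        return "nd"
    return f">={value:g}%"


def lod_report(lod: LodTable, header_lines: Sequence[str] = ()) -> str:
    """TSV text of an LOD table with formatted limits."""
    df = lod.table.copy()
    for col in df.columns:
        if col.startswith("lod_"):
            df[col] = df[col].map(format_lod)
    lines = [f"# {line}" for line in header_lines]
    lines.append(df.to_csv(sep="\t", index=False).rstrip("\n"))
    return "\n".join(lines) + "\n"
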