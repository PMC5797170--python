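"""Classification and validation of variant calls against the documented
haplotypes.

A call matching a documented homoplasmic variant (position *and* allele) of
either cell line is labelled ``documented_homoplasmic``; everything else is
a de-novo candidate.  Candidates are screened for the two classic artifact
contexts (homopolymer runs and proximity to a homoplasmic variant — the
rules behind the study's visual inspection step) and then validated by
independent observations: the same (position, allele) present in at least
two mixtures, or observed in two overlapping amplicons within one sample.
An unvalidated candidate only survives the conservative reporting rule if
its allele frequency is at least 1%.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .calling import VariantCall
from .haplotypes import HaplotypeDefinition
from .reference import CircularReference

CATEGORY_DOCUMENTED = "documented_homoplasmic"
CATEGORY_DE_NOVO = "de_novo"

FLAG_HOMOPOLYMER = "homopolymer_adjacent"
FLAG_NEAR_HOMOPLASMIC = "near_homoplasmic_variant"

VALIDATED_MULTI_MIXTURE = "validated_multi_mixture"
VALIDATED_OVERLAP = "validated_overlap"
UNVALIDATED = "unvalidated"

CONSERVATIVE_AF = 0.01


@dataclass(frozen=True)
class ClassifiedCall:
    call: VariantCall
    category: str
    artifact_flags: frozenset[str] = frozenset()
    validation: str = UNVALIDATED
    passes_conservative_threshold: bool = False

    @property
    def key(self) -> tuple[int, str]:
        return self.call.key


def documented_keys(
    mutant: HaplotypeDefinition, wildtype: HaplotypeDefinition
) -> set[tuple[int, str]]:
    return {v.key for v in mutant.variants} | {v.key for v in wildtype.variants}


def classify_calls(
    calls: Sequence[VariantCall],
    mutant: HaplotypeDefinition,
    wildtype: HaplotypeDefinition,
) -> list[ClassifiedCall]:
    """Split calls into documented homoplasmic variants and de-novo
    candidates; every call receives exactly one category."""
    documented = documented_keys(mutant, wildtype)
    out = []
    for c in calls:
        category = CATEGORY_DOCUMENTED if c.key in documented else CATEGORY_DE_NOVO
        out.append(ClassifiedCall(call=c, category=category))
    return out


def homopolymer_mask(ref: CircularReference, min_run: int = 4) -> np.ndarray:
    """Boolean per circle position: inside or immediately bordering a run of
    ``min_run`` identical reference bases.  Runs may wrap the origin."""
    codes = ref.codes()
    L = len(codes)
    doubled = np.concatenate([codes, codes])
    mask = np.zeros(2 * L, dtype=bool)
    run_start = 0
    for i in range(1, 2 * L + 1):
        if i == 2 * L or doubled[i] != doubled[run_start]:
            if i - run_start >= min_run:
                lo = max(0, run_start - 1)
                hi = min(2 * L, i + 1)
                mask[lo:hi] = True
            run_start = i
    return mask[:L] | mask[L:]


def flag_artifacts(
    calls: Sequence[ClassifiedCall],
    ref: CircularReference,
    mutant: HaplotypeDefinition,
    wildtype: HaplotypeDefinition,
    homopolymer_min_run: int = 4,
    proximity_window: int = 5,
) -> list[ClassifiedCall]:
    """Attach artifact-context flags to every call (non-destructive)."""
    hp = homopolymer_mask(ref, min_run=homopolymer_min_run)
    L = ref.length
    documented_positions = sorted(
        {v.position for v in mutant.variants} | {v.position for v in wildtype.variants}
    )
    doc_arr = np.array(documented_positions, dtype=np.int64)

    def near_documented(pos: int) -> bool:
        if doc_arr.size == 0:
            return False
        d = np.abs(doc_arr - pos)
        d = np.minimum(d, L - d)  # circular distance
        return bool((d <= proximity_window).any())

    out = []
    for cc in calls:
        flags = set()
        if hp[cc.call.circle_position - 1]:
            flags.add(FLAG_HOMOPOLYMER)
        if near_documented(cc.call.circle_position):
            flags.add(FLAG_NEAR_HOMOPLASMIC)
        out.append(replace(cc, artifact_flags=frozenset(flags)))
    return out


def validate_denovo(
    calls_by_mixture: Mapping[str, Sequence[ClassifiedCall]],
) -> dict[str, list[ClassifiedCall]]:
    """Validate de-novo candidates by independent observations.

    A (position, allele) seen in >= 2 mixtures is ``validated_multi_mixture``;
    seen in one mixture but in >= 2 overlapping amplicons it is
    ``validated_overlap``; otherwise ``unvalidated``.  The conservative
    reporting flag is (validated OR allele frequency >= 1%).
    """
    mixtures_per_key: dict[tuple[int, str], set[str]] = {}
    for mix, calls in calls_by_mixture.items():
        for cc in calls:
            mixtures_per_key.setdefault(cc.key, set()).add(mix)
    out: dict[str, list[ClassifiedCall]] = {}
    for mix, calls in calls_by_mixture.items():
        validated = []
        for cc in calls:
            if len(mixtures_per_key[cc.key]) >= 2:
                status = VALIDATED_MULTI_MIXTURE
            elif len(cc.call.amplicons_observed) >= 2:
                status = VALIDATED_OVERLAP
            else:
                status = UNVALIDATED
            passes = status != UNVALIDATED or cc.call.allele_frequency >= CONSERVATIVE_AF
            validated.append(
                replace(cc, validation=status, passes_conservative_threshold=passes)
            )
        out[mix] = validated
    return out


def denovo_report(
    calls_by_mixture: Mapping[str, Sequence[ClassifiedCall]],
    mixture_order: Optional[Sequence[str]] = None,
    phased: Optional[Mapping[tuple[int, str], str]] = None,
) -> pd.DataFrame:
    """Wide per-variant report: one row per de-novo (position, allele) with
    its allele frequency in every mixture (2 significant figures, in %),
    amplicons, validation status and flags; optionally the phased genotype."""
    if mixture_order is None:
        mixture_order = list(calls_by_mixture)
    rows: dict[tuple[int, str], dict] = {}
    for mix in mixture_order:
        for cc in calls_by_mixture.get(mix, []):
            if cc.category != CATEGORY_DE_NOVO:
                continue
            row = rows.setdefault(
                cc.key,
                {
                    "position": cc.call.circle_position,
                    "variant": cc.call.alt_allele,
                    "amplicons": set(),
                    "validation": cc.validation,
                    "flags": set(),
                    "passes_conservative": cc.passes_conservative_threshold,
                    **{f"af_{m}": "nc" for m in mixture_order},
                },
            )
            row["amplicons"] |= cc.call.amplicons_observed
            row["flags"] |= cc.artifact_flags
            row["passes_conservative"] = (
                row["passes_conservative"] or cc.passes_conservative_threshold
            )
            if cc.validation != UNVALIDATED:
                row["validation"] = cc.validation
            row[f"af_{mix}"] = f"{cc.call.allele_frequency * 100:.2g}"
    records = []
    for key in sorted(rows):
        row = rows[key]
        row["amplicons"] = ",".join(sorted(row["amplicons"]))
        row["flags"] = ",".join(sorted(row["flags"]))
        if phased is not None:
            row["phased_genotype"] = phased.get(key, "ambiguous")
        records.append(row)
    return pd.DataFrame(records)
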