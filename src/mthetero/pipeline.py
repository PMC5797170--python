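"""End-to-end orchestration: simulate -> filter -> pileup -> call ->
classify/validate -> phase -> LOD, with reproducible, self-describing
outputs.

Per-stage randomness is spawned from the single configured seed, so an
identical configuration reproduces byte-identical reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import denovo as dn
from .calling import Pileup, VariantCall, build_pileup, call_variants, calls_to_frame
from .haplotypes import MixtureDesign, default_haplotype_pair
from .io import PipelineConfig, write_calls_vcf
from .lod import LodTable, lod_per_position, lod_report
from .phasing import phase_variant
from .reference import AmpliconPanel, CircularReference, build_extended_reference
from .simulate import (
    ReadSet,
    SimulationConfig,
    Study,
    filter_ccs,
    random_reference,
    simulate_mixture_reads,
)


@dataclass
class PipelineResult:
    study: Study
    calls_by_mixture: dict[str, list]
    classified_by_mixture: dict[str, list]
    phased: dict[tuple[int, str], str]
    lod: LodTable
    denovo_table: pd.DataFrame
    output_files: dict[str, Path] = field(default_factory=dict)


def _build_study(cfg: PipelineConfig) -> Study:
    if cfg.reference_fasta:
        ref = CircularReference.from_fasta(cfg.reference_fasta)
    else:
        ref = random_reference(length=cfg.reference_length)
    if cfg.panel_tsv:
        panel = AmpliconPanel.from_tsv(cfg.panel_tsv, ref)
    else:
        n = cfg.n_amplicons
        overlap = 150 if ref.length > 2_000 else max(20, ref.length // 20)
        panel = AmpliconPanel.default(ref, n_amplicons=n, overlap=overlap)
    if ref.length == 16_569:
        mutant, wildtype = default_haplotype_pair(ref)
    else:
        from .simulate import scaled_haplotype_pair

        mutant, wildtype = scaled_haplotype_pair(ref)
    ext = build_extended_reference(ref, extension_length=panel.max_amplicon_length())
    return Study(reference=ref, extended=ext, panel=panel, mutant=mutant, wildtype=wildtype)


def run_pipeline(cfg: PipelineConfig, write_outputs: bool = True) -> PipelineResult:
    """Run the full analysis on simulated mixtures and write the three
    reports (VCF-like calls, LOD table, de-novo table) plus a run log."""
    cfg.validate()
    study = _build_study(cfg)
    design = MixtureDesign(fractions=tuple(cfg.fractions))
    seeds = np.random.SeedSequence(cfg.seed).spawn(len(cfg.fractions))

    reads_by_mixture: dict[str, ReadSet] = {}
    calls_by_mixture: dict[str, list[VariantCall]] = {}
    for fraction, seed_seq in zip(cfg.fractions, seeds):
        label = design.label(fraction)
        sim_cfg = SimulationConfig(
            panel=study.panel,
            mutant=study.mutant,
            wildtype=study.wildtype,
            fraction=fraction,
            seed=int(seed_seq.generate_state(1)[0] % (2**31)),
            mixture_id=label,
            coverage=cfg.coverage,
            error_rate=cfg.error_rate,
        )
        reads, _truth = simulate_mixture_reads(sim_cfg)
        reads = filter_ccs(
            reads, min_quality=cfg.min_read_quality, min_passes=cfg.min_passes
        )
        reads_by_mixture[label] = reads
        pileup = build_pileup(
            reads, study.extended, min_base_quality=cfg.min_base_quality
        )
        calls_by_mixture[label] = call_variants(
            pileup, study.reference, min_alt_depth=cfg.min_alt_depth, mixture_id=label
        )

    classified = {
        label: dn.flag_artifacts(
            dn.classify_calls(calls, study.mutant, study.wildtype),
            study.reference,
            study.mutant,
            study.wildtype,
            homopolymer_min_run=cfg.homopolymer_min_run,
            proximity_window=cfg.proximity_window,
        )
        for label, calls in calls_by_mixture.items()
    }
    classified = dn.validate_denovo(classified)

    # phase each de-novo key in the mixture where it is best supported
    best: dict[tuple[int, str], tuple[int, str]] = {}
    for label, ccs in classified.items():
        for cc in ccs:
            if cc.category != dn.CATEGORY_DE_NOVO:
                continue
            prev = best.get(cc.key)
            if prev is None or cc.call.alt_depth > prev[0]:
                best[cc.key] = (cc.call.alt_depth, label)
    phased = {
        key: phase_variant(
            key,
            reads_by_mixture[label],
            study.mutant,
            study.wildtype,
            ref_length=study.reference.length,
            min_informative=cfg.min_informative,
            concordance_min=cfg.concordance_min,
            min_base_quality=cfg.min_base_quality,
        ).genotype
        for key, (_depth, label) in best.items()
    }

    wt_alleles = study.wildtype.allele_map
    truth_alleles = {
        v.position: v.alt_allele
        for v in study.mutant.variants
        if wt_alleles.get(v.position) != v.alt_allele
    }
    lod = lod_per_position(calls_by_mixture, truth_alleles, design, method="smrt")
    denovo_table = dn.denovo_report(
        classified, mixture_order=design.labels, phased=phased
    )

    result = PipelineResult(
        study=study,
        calls_by_mixture=calls_by_mixture,
        classified_by_mixture=classified,
        phased=phased,
        lod=lod,
        denovo_table=denovo_table,
    )
    if write_outputs:
        result.output_files = _write_outputs(cfg, design, result)
    return result


def _write_outputs(
    cfg: PipelineConfig, design: MixtureDesign, result: PipelineResult
) -> dict[str, Path]:
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = [f"mthetero_config_hash={cfg.config_hash()}", f"mthetero_seed={cfg.seed}"]
    files: dict[str, Path] = {}
    for label, calls in result.calls_by_mixture.items():
        path = out_dir / f"calls_{label.replace('%', 'pct')}.vcf"
        write_calls_vcf(
            calls, result.study.reference, path, extra_header_lines=stamp
        )
        files[f"calls_{label}"] = path
    lod_path = out_dir / "lod.tsv"
    lod_path.write_text(lod_report(result.lod, header_lines=stamp))
    files["lod"] = lod_path
    denovo_path = out_dir / "denovo.tsv"
    with open(denovo_path, "w") as fh:
        for line in stamp:
            fh.write(f"# {line}\n")
        result.denovo_table.to_csv(fh, sep="\t", index=False)
    files["denovo"] = denovo_path
    log_path = out_dir / "run_log.yaml"
    cfg.to_yaml(log_path)
    files["log"] = log_path
    return files
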