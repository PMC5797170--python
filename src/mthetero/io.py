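"""File formats: SAM dialect, FASTQ, VCF-like calls, YAML pipeline config.

Standard formats are read and written through pysam and Biopython; only the
package-specific tables (panel, Cq plate, truth sidecar, reports) are plain
TSV with ``#`` comment headers.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calling import VariantCall
from .reference import CircularReference, ExtendedReference
from .simulate import AlignedRead, ReadSet

AMPLICON_TAG = "am"
PASSES_TAG = "np"
QUALITY_TAG = "rq"


def write_sam(
    reads: Union[ReadSet, Iterable[AlignedRead]],
    ref: ExtendedReference,
    path: Union[str, Path],
) -> None:
    """Write reads as a text SAM file mapped to the extended reference.

    All reads are forward-strand with indel-free CIGARs; amplicon, pass
    count and predicted accuracy travel as ``am``/``np``/``rq`` tags.
    Truth-of-origin labels are deliberately not emitted.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": ref.name, "LN": ref.length}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = r.read_id
            seg.flag = 0
            seg.reference_id = 0
            seg.reference_start = r.start - 1
            seg.mapping_quality = 60
            seg.cigartuples = [(0, len(r.seq))]
            seg.query_sequence = r.seq
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in np.asarray(r.quals))
            )
            seg.set_tag(AMPLICON_TAG, r.amplicon_id, "Z")
            seg.set_tag(PASSES_TAG, int(r.n_passes), "i")
            seg.set_tag(QUALITY_TAG, float(r.read_quality), "f")
            out.write(seg)


def read_sam(
    path: Union[str, Path], min_mapping_quality: int = 0
) -> list[AlignedRead]:
    """Ingest a SAM dialect file (per-base qualities required, indel-free
    CIGARs, optional amplicon tag)."""
    reads = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped or seg.mapping_quality < min_mapping_quality:
                continue
            if seg.query_qualities is None:
                raise ValueError(f"read {seg.query_name} has no base qualities")
            if any(op not in (0, 7, 8) for op, _ in (seg.cigartuples or [])):
                raise ValueError(
                    f"read {seg.query_name}: only match/mismatch CIGARs supported"
                )
            reads.append(
                AlignedRead(
                    read_id=seg.query_name,
                    amplicon_id=str(seg.get_tag(AMPLICON_TAG))
                    if seg.has_tag(AMPLICON_TAG)
                    else "unassigned",
                    start=seg.reference_start + 1,
                    seq=seg.query_sequence,
                    quals=np.asarray(seg.query_qualities, dtype=np.uint8),
                    n_passes=int(seg.get_tag(PASSES_TAG))
                    if seg.has_tag(PASSES_TAG)
                    else 1,
                    read_quality=float(seg.get_tag(QUALITY_TAG))
                    if seg.has_tag(QUALITY_TAG)
                    else 1.0,
                )
            )
    return reads


def write_fastq(
    reads: Union[ReadSet, Iterable[AlignedRead]], path: Union[str, Path]
) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.seq), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = [int(q) for q in r.quals]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def write_calls_vcf(
    calls: Sequence[VariantCall],
    ref: CircularReference,
    path: Union[str, Path],
    extra_header_lines: Sequence[str] = (),
) -> None:
    """VCF-like export: single contig named after the circular reference,
    1-based circle positions, depth/AF/amplicons in INFO."""
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={ref.name},length={ref.length}>")
    header.info.add("DP", 1, "Integer", "Quality-filtered depth")
    header.info.add("VD", 1, "Integer", "Alternative allele depth")
    header.info.add("VAF", 1, "Float", "Alternative allele frequency")
    header.info.add("AMP", ".", "String", "Amplicons observing the allele")
    header.info.add("MIX", 1, "String", "Mixture id")
    for line in extra_header_lines:
        header.add_line(f"##{line}")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for c in sorted(calls, key=lambda c: (c.circle_position, c.alt_allele)):
            rec = vcf.new_record(
                contig=ref.name,
                start=c.circle_position - 1,
                alleles=(c.ref_allele, c.alt_allele),
            )
            rec.info["DP"] = c.depth
            rec.info["VD"] = c.alt_depth
            rec.info["VAF"] = c.allele_frequency
            if c.amplicons_observed:
                rec.info["AMP"] = tuple(sorted(c.amplicons_observed))
            if c.mixture_id:
                rec.info["MIX"] = c.mixture_id
            vcf.write(rec)


# --- pipeline configuration --------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; see ``validate`` for admitted ranges.

    When ``reference_fasta`` is unset a seeded synthetic reference of
    ``reference_length`` bases is generated; when ``panel_tsv`` is unset the
    default evenly-spaced overlapping panel is used.
    """

    seed: int
    out_dir: str = "mthetero_out"
    reference_fasta: Optional[str] = None
    panel_tsv: Optional[str] = None
    reference_length: int = 16_569
    n_amplicons: int = 9
    fractions: tuple[float, ...] = (0.0, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1)
    coverage: Optional[int] = 2_000
    error_rate: float = 0.001
    min_base_quality: int = 30
    min_alt_depth: int = 5
    min_passes: int = 5
    min_read_quality: float = 0.99
    homopolymer_min_run: int = 4
    proximity_window: int = 5
    concordance_min: float = 0.9
    min_informative: int = 5

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for simulation runs")
        if self.min_alt_depth < 1:
            raise ValueError("min_alt_depth must be >= 1")
        if not 0 <= self.min_base_quality <= 93:
            raise ValueError("min_base_quality must be in [0, 93]")
        if self.min_passes < 1:
            raise ValueError("min_passes must be >= 1")
        if not 0 < self.min_read_quality <= 1:
            raise ValueError("min_read_quality must be in (0, 1]")
        if not 0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")
        if self.coverage is not None and self.coverage < 1:
            raise ValueError("coverage must be >= 1")
        if sorted(set(self.fractions)) != list(self.fractions):
            raise ValueError("fractions must be strictly increasing")
        if any(not 0 <= f <= 1 for f in self.fractions):
            raise ValueError("fractions must lie in [0, 1]")
        if not 0 < self.concordance_min <= 1:
            raise ValueError("concordance_min must be in (0, 1]")
        if self.min_informative < 1:
            raise ValueError("min_informative must be >= 1")
        if self.homopolymer_min_run < 2:
            raise ValueError("homopolymer_min_run must be >= 2")
        if self.proximity_window < 0:
            raise ValueError("proximity_window must be >= 0")

    def config_hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "fractions" in raw:
            raw["fractions"] = tuple(float(f) for f in raw["fractions"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: Union[str, Path]) -> None:
        data = asdict(self)
        data["fractions"] = [float(f) for f in self.fractions]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
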