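"""End-to-end sample typing: FASTQ → alignment → pileup → genotype call."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import align as _align
from .align import (
    AlignmentConfig,
    Pileup,
    VariantProfile,
    assign_reads,
    build_pileup,
    filter_reads,
    read_fastq,
    variant_profile,
)
from .classify import AboCall, DEFAULT_HET_THRESHOLD, DEFAULT_MIN_DEPTH, classify
from .reference import EXON6_NAME, EXON7_NAME

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Tunable parameters of the typing pipeline."""

    mode: str = "5snv"
    het_threshold: float = DEFAULT_HET_THRESHOLD
    min_depth: int = DEFAULT_MIN_DEPTH
    min_read_length: int = 0
    min_mean_quality: float = 0.0
    alignment: AlignmentConfig = field(default_factory=AlignmentConfig)

    def as_dict(self) -> dict:
        d = {
            "mode": self.mode,
            "het_threshold": self.het_threshold,
            "min_depth": self.min_depth,
            "min_read_length": self.min_read_length,
            "min_mean_quality": self.min_mean_quality,
        }
        d.update(
            {
                "min_identity": self.alignment.min_identity,
                "min_window_cov": self.alignment.min_window_cov,
            }
        )
        return d


@dataclass
class SampleResult:
    """Everything computed for one sample."""

    call: AboCall
    profile: VariantProfile
    pileups: dict[str, Pileup]
    alignments: dict[str, list]


def type_sample(
    sample_id: str,
    fastq_paths: Mapping[str, str | Path],
    references: tuple[str, str],
    config: PipelineConfig | None = None,
) -> SampleResult:
    """Type one sample from its per-exon FASTQ files.

    ``fastq_paths`` maps ``"exon6"``/``"exon7"`` to FASTQ(.gz) paths; either
    key may be missing (that exon then has zero coverage and the sample is
    flagged low-coverage).
    """
    config = config or PipelineConfig()
    refs = {EXON6_NAME: references[0], EXON7_NAME: references[1]}

    reads = []
    for exon in ("exon6", "exon7"):
        path = fastq_paths.get(exon)
        if path is None:
            continue
        exon_reads = read_fastq(path)
        reads.extend(
            filter_reads(exon_reads, config.min_read_length, config.min_mean_quality)
        )

    alignments = assign_reads(reads, refs, config.alignment)
    pileups = {
        rid: build_pileup(alns, refs[rid], rid) for rid, alns in alignments.items()
    }
    profile = variant_profile(pileups, sample_id=sample_id)
    call = classify(
        profile,
        mode=config.mode,
        het_threshold=config.het_threshold,
        min_depth=config.min_depth,
    )
    return SampleResult(call=call, profile=profile, pileups=pileups, alignments=alignments)


def discover_samples(input_dir: str | Path) -> dict[str, dict[str, Path]]:
    """Find samples in a directory named ``<sample>.exon{6,7}.fastq[.gz]``."""
    input_dir = Path(input_dir)
    samples: dict[str, dict[str, Path]] = {}
    for path in sorted(input_dir.iterdir()):
        name = path.name
        for exon in ("exon6", "exon7"):
            for suffix in (f".{exon}.fastq", f".{exon}.fastq.gz"):
                if name.endswith(suffix):
                    sample_id = name[: -len(suffix)]
                    samples.setdefault(sample_id, {})[exon] = path
    return samples


def read_sample_mapping(path: str | Path) -> dict[str, dict[str, Path]]:
    """Read a mapping CSV (sample_id, exon6_fastq, exon7_fastq)."""
    df = pd.read_csv(path)
    required = {"sample_id", "exon6_fastq", "exon7_fastq"}
    if not required.issubset(df.columns):
        raise ValueError(f"mapping file must have columns {sorted(required)}")
    base = Path(path).parent
    out: dict[str, dict[str, Path]] = {}
    for row in df.itertuples(index=False):
        paths = {}
        for exon, value in (("exon6", row.exon6_fastq), ("exon7", row.exon7_fastq)):
            if isinstance(value, str) and value:
                p = Path(value)
                paths[exon] = p if p.is_absolute() else base / p
        out[str(row.sample_id)] = paths
    return out
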