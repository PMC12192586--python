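"""Nanopore-like amplicon read simulation for diploid ABO genotypes.

Generates FASTQ reads from the two allele haplotype sequences of a genotype,
with independent per-base substitution, insertion and deletion errors.
Insertions duplicate the current base and deletions drop it, a crude but
useful mimic of the homopolymer-biased indel profile of nanopore data.
Allele-of-origin counts are the deterministic rounding of
``n_reads * allele_ratio`` rather than a binomial draw, so expected allele
fractions at heterozygous positions are exact and testable.

Base qualities are a constant placeholder (Q20): downstream filtering uses
mean read quality only, and real per-base quality modelling is out of scope.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .reference import ALLELES, DIAGNOSTIC_POSITIONS, allele_sequence

logger = logging.getLogger(__name__)

_QUAL_CHAR = chr(20 + 33)  # Q20
_EXONS = ("exon6", "exon7")
_OTHER = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}


@dataclass
class FastqRead:
    """One sequencing read (name, bases, phred+33 quality string)."""

    name: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.name!r}: sequence and quality lengths differ"
            )


@dataclass
class SimulationConfig:
    """Parameters of one simulated sample.

    ``allele_ratio`` is the fraction of reads drawn from the first allele;
    ``min_span``/``max_span`` bound the fraction of the exon covered by each
    read (1.0 = full-length amplicon reads, the default).
    """

    genotype: tuple[str, str]
    n_reads: int = 100
    allele_ratio: float = 0.5
    sub_rate: float = 0.05
    ins_rate: float = 0.02
    del_rate: float = 0.02
    min_span: float = 1.0
    max_span: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for allele in self.genotype:
            if allele not in ALLELES:
                raise ValueError(f"unknown allele {allele!r} in genotype")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if not 0.0 <= self.allele_ratio <= 1.0:
            raise ValueError("allele_ratio must be in [0, 1]")
        for name in ("sub_rate", "ins_rate", "del_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 0.3:
                raise ValueError(f"{name} must be in [0, 0.3], got {rate}")
        if not 0.0 < self.min_span <= self.max_span <= 1.0:
            raise ValueError("require 0 < min_span <= max_span <= 1")


def _apply_errors(seq: str, cfg: SimulationConfig, rng: np.random.Generator) -> str:
    if cfg.sub_rate == 0 and cfg.ins_rate == 0 and cfg.del_rate == 0:
        return seq
    out: list[str] = []
    for base in seq:
        if rng.random() < cfg.del_rate:
            continue
        if rng.random() < cfg.sub_rate:
            base = _OTHER[base][rng.integers(3)]
        out.append(base)
        if rng.random() < cfg.ins_rate:
            out.append(base)  # duplicate current base
    return "".join(out)


def simulate_reads(
    config: SimulationConfig, references: tuple[str, str]
) -> dict[str, list[FastqRead]]:
    """Simulate reads per exon for a diploid genotype.

    Returns ``{"exon6": [...], "exon7": [...]}``.  Deterministic for a fixed
    seed.  Read names encode the exon, index and allele of origin, e.g.
    ``exon7_r0012_B``, for downstream truth tracking.
    """
    rng = np.random.default_rng(config.seed)
    a1, a2 = config.genotype
    n1 = int(config.n_reads * config.allele_ratio + 0.5)
    origins = [a1] * n1 + [a2] * (config.n_reads - n1)

    haplotypes = {
        allele: dict(zip(_EXONS, allele_sequence(allele, references)))
        for allele in {a1, a2}
    }

    out: dict[str, list[FastqRead]] = {}
    for exon_idx, exon in enumerate(_EXONS):
        diag = [
            p.exon_offset for p in DIAGNOSTIC_POSITIONS if p.exon == exon_idx + 6
        ]
        reads: list[FastqRead] = []
        for i, allele in enumerate(origins):
            template = haplotypes[allele][exon]
            span = rng.uniform(config.min_span, config.max_span)
            length = max(1, int(round(span * len(template))))
            start = int(rng.integers(0, len(template) - length + 1))
            fragment = template[start : start + length]
            if config.max_span >= 1.0 and span >= 1.0:
                covered = all(start < off <= start + length for off in diag)
                if not covered:
                    logger.warning(
                        "full-span read %s_r%04d_%s misses a diagnostic position",
                        exon, i, allele,
                    )
            seq = _apply_errors(fragment, config, rng)
            if not seq:
                continue
            reads.append(
                FastqRead(
                    name=f"{exon}_r{i:04d}_{allele}",
                    sequence=seq,
                    quality=_QUAL_CHAR * len(seq),
                )
            )
        out[exon] = reads
    return out


def write_fastq(
    records: Sequence[FastqRead], path: str | Path, gzip_out: bool | None = None
) -> None:
    """Write reads as standard 4-line FASTQ, optionally gzip-compressed.

    ``gzip_out=None`` infers compression from a ``.gz`` suffix.
    """
    path = Path(path)
    if gzip_out is None:
        gzip_out = path.suffix == ".gz"
    opener = gzip.open if gzip_out else open
    with opener(path, "wt") as fh:
        for rec in records:
            fh.write(f"@{rec.name}\n{rec.sequence}\n+\n{rec.quality}\n")
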