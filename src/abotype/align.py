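"""Read alignment, pileup construction and diagnostic-position quantification.

Reads are aligned to the short exon 6/7 references with an affine-gap local
aligner (match +2, mismatch -4, gap of length k costs -4 - 2k).  The
references are at most a few hundred bases, so full dynamic programming is
cheap and fully deterministic — no external mapper is required, although the
SAM export provides a seam for one.

Single-base gaps are left-aligned within homopolymer runs after traceback,
mirroring the indel normalisation convention of standard variant callers, so
the O1-defining deletion always lands on the diagnostic exon 6 column.

A pileup tallies, for every reference position, the base (or deletion)
contributed by each covering read; the allele fractions at the five
diagnostic positions — the per-sample "match-mismatch" percentages — are the
classifier's input.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .reference import (
    DEL,
    DIAGNOSTIC_POSITIONS,
    EXON6_NAME,
    EXON7_NAME,
    DiagnosticPosition,
)
from .simulate import FastqRead

logger = logging.getLogger(__name__)

SYMBOL_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, DEL: 4}
SYMBOLS = ("A", "C", "G", "T", DEL)

#: Pad added on either side of the diagnostic offsets when computing the
#: reference window an alignment must cover.
WINDOW_PAD = 10


# ---------------------------------------------------------------------------
# FASTQ input and filtering
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> list[FastqRead]:
    """Read a plain or gzip-compressed FASTQ file, preserving record order."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records: list[FastqRead] = []
    with opener(path, "rt") as handle:
        iterator = FastqGeneralIterator(handle)
        index = 0
        while True:
            try:
                item = next(iterator, None)
            except ValueError as exc:
                raise ValueError(
                    f"malformed FASTQ record at index {index} in {path}: {exc}"
                ) from exc
            if item is None:
                break
            name, seq, qual = item
            records.append(FastqRead(name.split()[0], seq.upper(), qual))
            index += 1
    return records


def mean_quality(read: FastqRead) -> float:
    """Mean phred base quality of a read (phred+33 encoding)."""
    if not read.quality:
        return 0.0
    return float(np.mean(np.frombuffer(read.quality.encode(), dtype=np.uint8))) - 33.0


def filter_reads(
    records: Sequence[FastqRead], min_length: int = 0, min_mean_q: float = 0.0
) -> list[FastqRead]:
    """Length / mean-quality read filter.

    Keeps reads with ``len >= min_length`` and mean base quality
    ``>= min_mean_q``; logs kept/discarded counts.
    """
    if min_length < 0 or min_mean_q < 0:
        raise ValueError("filter thresholds must be >= 0")
    kept = [
        r
        for r in records
        if len(r.sequence) >= min_length and mean_quality(r) >= min_mean_q
    ]
    logger.info(
        "read filter: kept %d / %d reads (min_length=%d, min_mean_q=%.1f)",
        len(kept), len(records), min_length, min_mean_q,
    )
    return kept


# ---------------------------------------------------------------------------
# Pairwise alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignmentConfig:
    """Scoring and acceptance parameters of the embedded aligner.

    A gap of length k costs ``gap_open + k * gap_extend``.  Alignments with
    identity below ``min_identity`` or covering less than ``min_window_cov``
    of the reference diagnostic window are discarded.
    """

    match: float = 2.0
    mismatch: float = -4.0
    gap_open: float = -4.0
    gap_extend: float = -2.0
    min_identity: float = 0.7
    min_window_cov: float = 0.9


@dataclass
class ReadAlignment:
    """Local alignment of one read against one exon reference.

    ``target_blocks``/``query_blocks`` are matched lists of half-open
    ``(start, end)`` intervals on the reference and read respectively; gaps
    between consecutive blocks are deletions (reference advances) and/or
    insertions (read advances).
    """

    read_id: str
    reference_id: str
    score: float
    identity: float
    target_blocks: list[tuple[int, int]]
    query_blocks: list[tuple[int, int]]
    read_sequence: str

    @property
    def reference_start(self) -> int:
        return self.target_blocks[0][0]

    @property
    def reference_end(self) -> int:
        return self.target_blocks[-1][1]


_ALIGNER_CACHE: dict[tuple, Align.PairwiseAligner] = {}


def _make_aligner(cfg: AlignmentConfig) -> Align.PairwiseAligner:
    key = (cfg.match, cfg.mismatch, cfg.gap_open, cfg.gap_extend)
    cached = _ALIGNER_CACHE.get(key)
    if cached is not None:
        return cached
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = cfg.match
    aligner.mismatch_score = cfg.mismatch
    # Biopython charges open on the first gap base and extend thereafter;
    # our convention charges open once plus extend per base.
    aligner.open_gap_score = cfg.gap_open + cfg.gap_extend
    aligner.extend_gap_score = cfg.gap_extend
    _ALIGNER_CACHE[key] = aligner
    return aligner


def _left_align_gaps(
    tblocks: list[list[int]],
    qblocks: list[list[int]],
    reference: str,
    read: str,
) -> None:
    """Shift single/multi-base gaps left within homopolymers (in place).

    A deletion of reference[i:j] may move to reference[i-1:j-1] when
    reference[i-1] == reference[j-1]; insertions shift analogously on the
    read.  Preserves alignment score and emitted sequences.
    """
    for k in range(1, len(tblocks)):
        # deletion gap between block k-1 and block k
        while True:
            i, j = tblocks[k - 1][1], tblocks[k][0]
            if j <= i:
                break
            if tblocks[k - 1][1] - tblocks[k - 1][0] < 2:
                break  # would empty the preceding block
            if reference[i - 1] != reference[j - 1]:
                break
            tblocks[k - 1][1] -= 1
            qblocks[k - 1][1] -= 1
            tblocks[k][0] -= 1
            qblocks[k][0] -= 1
        while True:
            i, j = qblocks[k - 1][1], qblocks[k][0]
            if j <= i:
                break
            if qblocks[k - 1][1] - qblocks[k - 1][0] < 2:
                break
            if read[i - 1] != read[j - 1]:
                break
            tblocks[k - 1][1] -= 1
            qblocks[k - 1][1] -= 1
            tblocks[k][0] -= 1
            qblocks[k][0] -= 1


def _window(reference_id: str, positions: Sequence[DiagnosticPosition]) -> tuple[int, int]:
    """1-based inclusive diagnostic window on one exon reference."""
    exon = 6 if reference_id == EXON6_NAME else 7
    offsets = [p.exon_offset for p in positions if p.exon == exon]
    return (min(offsets) - WINDOW_PAD, max(offsets) + WINDOW_PAD)


def align_read(
    read: FastqRead,
    reference: str,
    reference_id: str,
    cfg: AlignmentConfig | None = None,
    window: tuple[int, int] | None = None,
) -> ReadAlignment | None:
    """Best local alignment of a read to one exon reference, or ``None``.

    ``window`` is a 1-based inclusive reference interval the alignment must
    cover at ``cfg.min_window_cov``; by default the exon's diagnostic window
    padded by :data:`WINDOW_PAD` bases.
    """
    cfg = cfg or AlignmentConfig()
    if not read.sequence or not reference:
        raise ValueError("read and reference must be non-empty")
    if window is None:
        window = _window(reference_id, DIAGNOSTIC_POSITIONS)

    aligner = _make_aligner(cfg)
    alignments = aligner.align(reference, read.sequence)
    try:
        best = alignments[0]
    except IndexError:
        return None

    taligned, qaligned = best.aligned
    tblocks = [[int(s), int(e)] for s, e in taligned]
    qblocks = [[int(s), int(e)] for s, e in qaligned]
    if not tblocks:
        return None
    _left_align_gaps(tblocks, qblocks, reference, read.sequence)

    matches = 0
    columns = 0
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        seg_ref = reference[ts:te]
        seg_read = read.sequence[qs:qe]
        matches += sum(a == b for a, b in zip(seg_ref, seg_read))
        columns += te - ts
    for k in range(1, len(tblocks)):
        columns += tblocks[k][0] - tblocks[k - 1][1]  # deletion columns
        columns += qblocks[k][0] - qblocks[k - 1][1]  # insertion columns
    identity = matches / columns if columns else 0.0

    lo, hi = window
    lo = max(lo, 1)
    hi = min(hi, len(reference))
    # positions lo..hi (1-based) correspond to 0-based [lo-1, hi)
    covered = max(0, min(tblocks[-1][1], hi) - max(tblocks[0][0], lo - 1))
    window_cov = covered / (hi - lo + 1)

    if identity < cfg.min_identity or window_cov < cfg.min_window_cov:
        return None

    return ReadAlignment(
        read_id=read.name,
        reference_id=reference_id,
        score=float(best.score),
        identity=identity,
        target_blocks=[tuple(b) for b in tblocks],
        query_blocks=[tuple(b) for b in qblocks],
        read_sequence=read.sequence,
    )


def assign_reads(
    reads: Iterable[FastqRead],
    references: Mapping[str, str],
    cfg: AlignmentConfig | None = None,
) -> dict[str, list[ReadAlignment]]:
    """Align each read to every exon reference, keeping all passing hits.

    Reads from a single-exon amplicon pass filters on one reference only;
    a read genuinely spanning both exons is retained on both.
    """
    cfg = cfg or AlignmentConfig()
    out: dict[str, list[ReadAlignment]] = {rid: [] for rid in references}
    for read in reads:
        for rid, ref in references.items():
            aln = align_read(read, ref, rid, cfg)
            if aln is not None:
                out[rid].append(aln)
    return out


# ---------------------------------------------------------------------------
# Pileup
# ---------------------------------------------------------------------------

@dataclass
class PileupColumn:
    """Base/deletion tallies of one 1-based reference position."""

    position: int
    counts: dict[str, int]

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    def fractions(self) -> dict[str, float]:
        depth = self.depth
        if depth == 0:
            return {}
        return {s: c / depth for s, c in self.counts.items()}


@dataclass
class Pileup:
    """Per-position symbol counts over one exon reference."""

    reference_id: str
    counts: np.ndarray  # shape (5, L): rows A, C, G, T, DEL
    n_reads: int = 0

    def column(self, position: int) -> PileupColumn:
        """Column at a 1-based reference position."""
        col = self.counts[:, position - 1]
        return PileupColumn(position, {s: int(col[i]) for s, i in SYMBOL_INDEX.items()})

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts.T, columns=list(SYMBOLS))
        df.insert(0, "position", np.arange(1, self.counts.shape[1] + 1))
        df["depth"] = self.counts.sum(axis=0)
        return df


def build_pileup(
    alignments: Sequence[ReadAlignment], reference: str, reference_id: str = ""
) -> Pileup:
    """Tally base/deletion contributions of accepted alignments.

    Each read contributes exactly one symbol per reference position inside
    its aligned extent: its base on matched columns, ``DEL`` on reference
    positions skipped by a deletion.  Insertions create no columns.
    """
    counts = np.zeros((5, len(reference)), dtype=np.int64)
    for aln in alignments:
        if aln.reference_id and reference_id and aln.reference_id != reference_id:
            raise ValueError(
                f"alignment to {aln.reference_id} passed to pileup of {reference_id}"
            )
        read = aln.read_sequence
        for (ts, te), (qs, qe) in zip(aln.target_blocks, aln.query_blocks):
            for offset in range(te - ts):
                base = read[qs + offset]
                idx = SYMBOL_INDEX.get(base)
                if idx is not None:  # skip ambiguity codes
                    counts[idx, ts + offset] += 1
        for k in range(1, len(aln.target_blocks)):
            gs, ge = aln.target_blocks[k - 1][1], aln.target_blocks[k][0]
            if ge > gs:
                counts[SYMBOL_INDEX[DEL], gs:ge] += 1
    return Pileup(reference_id=reference_id, counts=counts, n_reads=len(alignments))


# ---------------------------------------------------------------------------
# Diagnostic-position quantification
# ---------------------------------------------------------------------------

@dataclass
class VariantProfile:
    """Symbol fractions and depth at the diagnostic positions of one sample."""

    sample_id: str
    fractions: dict[DiagnosticPosition, dict[str, float]]
    depths: dict[DiagnosticPosition, int]
    total_reads: dict[str, int] = field(default_factory=dict)


def variant_profile(
    pileups: Mapping[str, Pileup],
    sample_id: str = "",
    positions: Sequence[DiagnosticPosition] = DIAGNOSTIC_POSITIONS,
) -> VariantProfile:
    """Pool pileup counts into per-diagnostic-position symbol fractions.

    ``pileups`` maps reference names (ABO_exon6 / ABO_exon7) to their
    pileups.  Zero-depth positions get empty fractions and depth 0.
    """
    name_of = {6: EXON6_NAME, 7: EXON7_NAME}
    fractions: dict[DiagnosticPosition, dict[str, float]] = {}
    depths: dict[DiagnosticPosition, int] = {}
    for pos in positions:
        pileup = pileups.get(name_of[pos.exon])
        if pileup is None:
            fractions[pos], depths[pos] = {}, 0
            logger.warning("%s: no pileup for %s", sample_id, pos.label())
            continue
        col = pileup.column(pos.exon_offset)
        depths[pos] = col.depth
        fractions[pos] = {s: f for s, f in col.fractions().items() if f > 0}
        if col.depth == 0:
            logger.warning("%s: zero depth at %s", sample_id, pos.label())
    totals = {rid: p.n_reads for rid, p in pileups.items()}
    return VariantProfile(sample_id, fractions, depths, totals)


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def _cigar(aln: ReadAlignment) -> str:
    parts = []
    qstart = aln.query_blocks[0][0]
    if qstart:
        parts.append(f"{qstart}S")
    for k, ((ts, te), (qs, qe)) in enumerate(zip(aln.target_blocks, aln.query_blocks)):
        if k:
            dlen = ts - aln.target_blocks[k - 1][1]
            ilen = qs - aln.query_blocks[k - 1][1]
            if ilen:
                parts.append(f"{ilen}I")
            if dlen:
                parts.append(f"{dlen}D")
        parts.append(f"{te - ts}M")
    tail = len(aln.read_sequence) - aln.query_blocks[-1][1]
    if tail:
        parts.append(f"{tail}S")
    return "".join(parts)


def write_sam(
    alignments_by_ref: Mapping[str, Sequence[ReadAlignment]],
    references: Mapping[str, str],
    path: str | Path,
) -> None:
    """Export accepted alignments as a plain-text SAM file."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for rid, seq in references.items():
            fh.write(f"@SQ\tSN:{rid}\tLN:{len(seq)}\n")
        fh.write("@PG\tID:abotype\tPN:abotype\n")
        for rid, alignments in alignments_by_ref.items():
            for aln in alignments:
                fh.write(
                    "\t".join(
                        (
                            aln.read_id,
                            "0",
                            rid,
                            str(aln.reference_start + 1),
                            "60",
                            _cigar(aln),
                            "*",
                            "0",
                            "0",
                            aln.read_sequence,
                            "*",
                            f"AS:i:{int(aln.score)}",
                        )
                    )
                    + "\n"
                )


def write_pileup_csv(pileup: Pileup, path: str | Path) -> None:
    """Per-position count spreadsheet (position, A, C, G, T, DEL, depth)."""
    pileup.to_dataframe().to_csv(path, index=False)
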