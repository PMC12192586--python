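"""ABO allele knowledge base and synthetic exon references.

The ABO blood group is determined by the diploid combination of alleles at
the glycosyltransferase locus on chromosome 9.  Five polymorphic positions in
exons 6 and 7 are sufficient to separate the clinically relevant allele
classes:

* ``O1`` — single-base deletion at exon 6 offset 22 (c.261delG, rs8176719),
  a frameshift producing a non-functional enzyme;
* ``O2`` — G>A at exon 7 offset 428 (c.802G>A, rs41302905);
* ``O3`` — the base read at exon 7 offset 431 becomes G (c.804dupG,
  rs782782485), modelled here as a substitution at the readout position;
* ``A``  — the reference (A1-type) allele at all five positions;
* ``B``  — C>A at exon 7 offset 422 (c.796C>A, rs8176746) together with
  G>C at offset 429 (c.803G>C, rs8176747).

This module encodes those patterns, derives the expected heterozygous /
homozygous state vector of every unordered diploid genotype, and builds
deterministic synthetic exon 6/7 reference sequences so the full pipeline
(simulation, alignment, classification) runs without any external download.
Real exon sequences (e.g. derived from NG_006669.2) may be substituted by
the user through the FASTA helpers.

Coordinates are 1-based offsets within each exon; coding-sequence (cDNA)
coordinates follow from the fixed offsets +239 (exon 6) and +374 (exon 7).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALLELES = ("O1", "O2", "O3", "A", "B")
SYMBOLS = ("A", "C", "G", "T", "DEL")
DEL = "DEL"

EXON6_CDNA_OFFSET = 239
EXON7_CDNA_OFFSET = 374

#: FASTA record names for the two reference exons.
EXON6_NAME = "ABO_exon6"
EXON7_NAME = "ABO_exon7"


@dataclass(frozen=True)
class DiagnosticPosition:
    """One of the five interrogated sites.

    ``exon_offset`` is the 1-based position within the exon sequence;
    ``cdna_position`` the 1-based coding-sequence coordinate.
    """

    exon: int
    exon_offset: int
    cdna_position: int
    rsid: str
    consequence: str

    def __post_init__(self) -> None:
        offset = EXON6_CDNA_OFFSET if self.exon == 6 else EXON7_CDNA_OFFSET
        if self.cdna_position != self.exon_offset + offset:
            raise ValueError(
                f"cDNA coordinate {self.cdna_position} inconsistent with "
                f"exon {self.exon} offset {self.exon_offset}"
            )

    @property
    def key(self) -> tuple[int, int]:
        return (self.exon, self.exon_offset)

    def label(self) -> str:
        return f"exon{self.exon}:{self.exon_offset} (c.{self.cdna_position}, {self.rsid})"


DIAGNOSTIC_POSITIONS: tuple[DiagnosticPosition, ...] = (
    DiagnosticPosition(6, 22, 261, "rs8176719", "frameshift"),
    DiagnosticPosition(7, 422, 796, "rs8176746", "missense"),
    DiagnosticPosition(7, 428, 802, "rs41302905", "missense"),
    DiagnosticPosition(7, 429, 803, "rs8176747", "missense"),
    DiagnosticPosition(7, 431, 805, "rs782782485", "frameshift"),
)

#: The reduced 3-SNV panel: deletion site plus the two classic A/B-separating
#: exon 7 substitutions. O2/O3 are indistinguishable from A on this panel.
THREE_SNV_POSITIONS: tuple[DiagnosticPosition, ...] = tuple(
    p for p in DIAGNOSTIC_POSITIONS if p.exon_offset in (22, 422, 429)
)

# Expected base (or deletion) of each allele class at the five positions,
# in panel order 22, 422, 428, 429, 431.
ALLELE_PATTERNS: dict[str, tuple[str, ...]] = {
    "O1": (DEL, "C", "G", "G", "T"),
    "O2": ("G", "C", "A", "G", "T"),
    "O3": ("G", "C", "G", "G", "G"),
    "A": ("G", "C", "G", "G", "T"),
    "B": ("G", "A", "G", "C", "T"),
}


def allele_pattern(allele: str) -> dict[DiagnosticPosition, str]:
    """Expected symbol of one allele class at every diagnostic position."""
    _check_allele(allele)
    return dict(zip(DIAGNOSTIC_POSITIONS, ALLELE_PATTERNS[allele]))


def _check_allele(allele: str) -> None:
    if allele not in ALLELES:
        raise ValueError(f"unknown ABO allele label {allele!r}; expected one of {ALLELES}")


def expected_profile(
    allele1: str, allele2: str
) -> dict[DiagnosticPosition, frozenset[str]]:
    """Expected symbol set per diagnostic position for a diploid genotype.

    The set at each position is the union of the two allele patterns, so a
    size-1 set means the genotype is homozygous there and a size-2 set
    heterozygous.  Symmetric in argument order.
    """
    _check_allele(allele1)
    _check_allele(allele2)
    p1, p2 = ALLELE_PATTERNS[allele1], ALLELE_PATTERNS[allele2]
    return {
        pos: frozenset((s1, s2))
        for pos, s1, s2 in zip(DIAGNOSTIC_POSITIONS, p1, p2)
    }


_LETTER = {"O1": "O", "O2": "O", "O3": "O", "A": "A", "B": "B"}
_LETTER_ORDER = {"A": 0, "B": 1, "O": 2}
_PHENOTYPE = {"OO": "O", "AO": "A", "AA": "A", "BO": "B", "BB": "B", "AB": "AB"}


def simple_genotype_label(allele1: str, allele2: str) -> str:
    """Collapse a diploid allele pair to its simple genotype (AO, OO, AB, ...)."""
    letters = sorted((_LETTER[allele1], _LETTER[allele2]), key=_LETTER_ORDER.get)
    return "".join(letters)


def extended_genotype_label(allele1: str, allele2: str) -> str:
    """Genotype label with O-subtype resolution (AO1, O1O2, BO2, ...)."""

    def sort_key(a: str) -> tuple[int, str]:
        return (_LETTER_ORDER[_LETTER[a]], a)

    return "".join(sorted((allele1, allele2), key=sort_key))


def phenotype_of(simple_genotype: str) -> str:
    """Predicted blood-group phenotype of a simple genotype."""
    try:
        return _PHENOTYPE[simple_genotype]
    except KeyError:
        raise ValueError(f"unknown simple genotype {simple_genotype!r}") from None


@dataclass(frozen=True)
class GenotypeRule:
    """Expected per-position state of one diploid genotype (one table row)."""

    alleles: tuple[str, str]
    expected_states: Mapping[DiagnosticPosition, frozenset[str]]
    simple_genotype: str
    extended_genotype: str
    phenotype: str

    def matches(self, states: Mapping[DiagnosticPosition, frozenset[str]]) -> bool:
        """Exact set equality at every position of this rule's panel."""
        return all(
            states.get(pos) == expected
            for pos, expected in self.expected_states.items()
        )


def _five_snv_rules() -> list[GenotypeRule]:
    rules = []
    for a1, a2 in combinations_with_replacement(ALLELES, 2):
        rules.append(
            GenotypeRule(
                alleles=(a1, a2),
                expected_states=expected_profile(a1, a2),
                simple_genotype=simple_genotype_label(a1, a2),
                extended_genotype=extended_genotype_label(a1, a2),
                phenotype=phenotype_of(simple_genotype_label(a1, a2)),
            )
        )
    return rules


def _three_snv_rules() -> list[GenotypeRule]:
    # On the reduced panel only O1 represents the O class; O2/O3 collapse
    # onto A, which is exactly the mistyping the 5-SNV panel resolves.
    rules = []
    for a1, a2 in combinations_with_replacement(("O1", "A", "B"), 2):
        full = expected_profile(a1, a2)
        restricted = {pos: full[pos] for pos in THREE_SNV_POSITIONS}
        simple = simple_genotype_label(a1, a2)
        rules.append(
            GenotypeRule(
                alleles=(a1, a2),
                expected_states=restricted,
                simple_genotype=simple,
                extended_genotype=simple,
                phenotype=phenotype_of(simple),
            )
        )
    return rules


def rule_table(mode: str = "5snv") -> list[GenotypeRule]:
    """All genotype rules for the chosen panel.

    ``5snv`` yields the 15 unordered diploid combinations of
    {O1, O2, O3, A, B} over all five positions; ``3snv`` the 6 combinations
    of {O, A, B} over positions 22, 422 and 429 only.
    """
    if mode == "5snv":
        return _five_snv_rules()
    if mode == "3snv":
        return _three_snv_rules()
    raise ValueError(f"unknown mode {mode!r}; expected '5snv' or '3snv'")


def mode_positions(mode: str) -> tuple[DiagnosticPosition, ...]:
    """Diagnostic positions interrogated by the chosen panel."""
    if mode == "5snv":
        return DIAGNOSTIC_POSITIONS
    if mode == "3snv":
        return THREE_SNV_POSITIONS
    raise ValueError(f"unknown mode {mode!r}; expected '5snv' or '3snv'")


def rules_to_dataframe(mode: str = "5snv") -> pd.DataFrame:
    """Rule table as a DataFrame (one column per cDNA position)."""
    rows = []
    positions = mode_positions(mode)
    for rule in rule_table(mode):
        row = {
            "genotype": rule.extended_genotype,
            "simple_genotype": rule.simple_genotype,
            "phenotype": rule.phenotype,
        }
        for pos in positions:
            row[f"c.{pos.cdna_position}"] = "/".join(
                sorted(rule.expected_states[pos])
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Synthetic references and allele sequences
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def build_synthetic_references(
    seed: int, exon6_length: int = 135, exon7_length: int = 691
) -> tuple[str, str]:
    """Deterministic synthetic exon 6 and exon 7 reference sequences.

    Non-diagnostic positions are uniform random bases; diagnostic positions
    carry the A-allele symbol (the reference is an A1-type allele).  The
    neighbours of exon 6 offset 22 are constrained to differ from the base
    at 22, so the single-base deletion that defines O1 left-aligns uniquely
    onto the diagnostic column.
    """
    max6 = max(p.exon_offset for p in DIAGNOSTIC_POSITIONS if p.exon == 6)
    max7 = max(p.exon_offset for p in DIAGNOSTIC_POSITIONS if p.exon == 7)
    if exon6_length < max(40, max6):
        raise ValueError(f"exon6_length must be >= 40, got {exon6_length}")
    if exon7_length < max(450, max7):
        raise ValueError(f"exon7_length must be >= 450, got {exon7_length}")

    rng = np.random.default_rng(seed)
    exon6 = rng.choice(_BASES, size=exon6_length).tolist()
    exon7 = rng.choice(_BASES, size=exon7_length).tolist()

    pattern = allele_pattern("A")
    for pos, symbol in pattern.items():
        seq = exon6 if pos.exon == 6 else exon7
        seq[pos.exon_offset - 1] = symbol

    # Forbid a homopolymer around exon 6 offset 22 (0-based index 21) so the
    # 261delG gap placement is unambiguous under left-alignment.
    centre = exon6[21]
    for idx in (20, 22):
        while exon6[idx] == centre:
            exon6[idx] = str(rng.choice(_BASES))

    return "".join(exon6), "".join(exon7)


def allele_sequence(allele: str, references: tuple[str, str]) -> tuple[str, str]:
    """Exon 6/7 sequences carried by one allele class.

    O1 deletes exon 6 base 22 (sequence one base shorter); O2 substitutes
    exon 7 base 428 G>A; O3 sets base 431 to G; B substitutes 422 C>A and
    429 G>C; A returns the references unchanged.
    """
    _check_allele(allele)
    exon6, exon7 = references
    if allele == "A":
        return exon6, exon7
    if allele == "O1":
        return exon6[:21] + exon6[22:], exon7
    e7 = list(exon7)
    if allele == "O2":
        e7[427] = "A"
    elif allele == "O3":
        e7[430] = "G"
    elif allele == "B":
        e7[421] = "A"
        e7[428] = "C"
    return exon6, "".join(e7)


def write_references(references: tuple[str, str], path: str | Path) -> None:
    """Write the exon references as a two-record FASTA file."""
    records = [
        SeqRecord(Seq(references[0]), id=EXON6_NAME, description=""),
        SeqRecord(Seq(references[1]), id=EXON7_NAME, description=""),
    ]
    SeqIO.write(records, str(path), "fasta")


def read_references(path: str | Path) -> tuple[str, str]:
    """Read exon references from FASTA (records ABO_exon6, ABO_exon7)."""
    by_name = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    try:
        return by_name[EXON6_NAME], by_name[EXON7_NAME]
    except KeyError as exc:
        raise ValueError(
            f"reference FASTA {path} must contain records "
            f"{EXON6_NAME!r} and {EXON7_NAME!r}; found {sorted(by_name)}"
        ) from exc
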