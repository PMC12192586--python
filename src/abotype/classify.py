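"""Allele-balance genotype calling and rule-based phenotype inference.

A diagnostic position is called from its pooled symbol fractions with the
80:20 allele-balance rule: every symbol reaching at least 20% of covering
reads is part of the call, so one passing symbol means homozygous, two mean
heterozygous, and three or more make the position ambiguous.  Positions
covered by fewer than 20 reads are not called at all — the sample is flagged
for repeat testing rather than risk an unreliable genotype.

The per-position states are then matched by exact set equality against the
genotype rule table (all 15 diploid combinations of O1/O2/O3/A/B on the
five-position panel, or the 6 combinations of O/A/B on the reduced 3-SNV
panel).  The 3-SNV panel cannot see the O2/O3-defining exon 7 variants and
therefore mistypes O2- and O3-carrying genotypes as A-carrying ones; the
five-position panel resolves them.

Every call carries a qualitative reliability tier derived from the read
depth supporting the panel: Very Low (<20), Low (20-49), Moderate (50-499)
and Robust (>=500).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .reference import (
    DiagnosticPosition,
    GenotypeRule,
    mode_positions,
    phenotype_of,
    rule_table,
)
from .align import VariantProfile

DEFAULT_HET_THRESHOLD = 0.20
DEFAULT_MIN_DEPTH = 20

STATUS_OK = "ok"
STATUS_LOW_COVERAGE = "low_coverage"
STATUS_UNKNOWN = "unknown"

TIER_VERY_LOW = "Very Low"
TIER_LOW = "Low"
TIER_MODERATE = "Moderate"
TIER_ROBUST = "Robust"


@dataclass(frozen=True)
class PositionState:
    """Called symbol set at one diagnostic position."""

    position: DiagnosticPosition
    symbols: frozenset[str]
    status: str  # ok | low_coverage | ambiguous

    def __post_init__(self) -> None:
        if self.status == STATUS_OK and not 1 <= len(self.symbols) <= 2:
            raise ValueError("ok state must carry one or two symbols")
        if self.status != STATUS_OK and self.symbols:
            raise ValueError("non-ok state must carry no symbols")


@dataclass
class AboCall:
    """Final per-sample typing result."""

    sample_id: str
    status: str
    mode: str
    phenotype: str | None = None
    genotype: str | None = None
    extended_genotype: str | None = None
    reliability: str = TIER_VERY_LOW
    reads: int = 0
    fractions: dict[DiagnosticPosition, dict[str, float]] = field(default_factory=dict)
    depths: dict[DiagnosticPosition, int] = field(default_factory=dict)

    @property
    def is_ok(self) -> bool:
        return self.status == STATUS_OK


def reliability_tier(read_count: int) -> str:
    """Qualitative confidence band for a supporting read count."""
    if read_count < 0:
        raise ValueError("read_count must be >= 0")
    if read_count < 20:
        return TIER_VERY_LOW
    if read_count < 50:
        return TIER_LOW
    if read_count < 500:
        return TIER_MODERATE
    return TIER_ROBUST


def phenotype_from_genotype(simple_genotype: str) -> str:
    """Predicted phenotype of a simple genotype (OO→O, AO/AA→A, ...)."""
    return phenotype_of(simple_genotype)


def call_position_state(
    position: DiagnosticPosition,
    fractions: Mapping[str, float],
    depth: int,
    het_threshold: float = DEFAULT_HET_THRESHOLD,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> PositionState:
    """Call one diagnostic position from its symbol fractions.

    Symbols with fraction >= ``het_threshold`` are part of the call; a
    fraction exactly at the threshold counts (an 80:20 split is still a
    heterozygote).  Depth below ``min_depth`` yields a low-coverage state,
    three or more passing symbols an ambiguous one.
    """
    if depth < min_depth:
        return PositionState(position, frozenset(), STATUS_LOW_COVERAGE)
    called = frozenset(s for s, f in fractions.items() if f >= het_threshold)
    if not 1 <= len(called) <= 2:
        return PositionState(position, frozenset(), "ambiguous")
    return PositionState(position, called, STATUS_OK)


def classify(
    profile: VariantProfile,
    mode: str = "5snv",
    het_threshold: float = DEFAULT_HET_THRESHOLD,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> AboCall:
    """Type one sample from its diagnostic-position fractions.

    Any low-coverage position flags the whole sample low-coverage (the
    remedy is repeat testing); otherwise an ambiguous position or a state
    vector matching no rule yields ``unknown``, with the fraction audit
    trail retained on the call.  A unique rule match fills in phenotype,
    simple genotype and extended genotype.
    """
    positions = mode_positions(mode)
    missing = [p for p in positions if p not in profile.fractions]
    if missing:
        raise ValueError(
            f"profile for {profile.sample_id!r} lacks positions: "
            + ", ".join(p.label() for p in missing)
        )

    states = {
        pos: call_position_state(
            pos, profile.fractions[pos], profile.depths.get(pos, 0),
            het_threshold, min_depth,
        )
        for pos in positions
    }
    reads = min(profile.depths.get(pos, 0) for pos in positions)
    call = AboCall(
        sample_id=profile.sample_id,
        status=STATUS_OK,
        mode=mode,
        reliability=reliability_tier(reads),
        reads=reads,
        fractions={p: dict(profile.fractions[p]) for p in positions},
        depths={p: profile.depths.get(p, 0) for p in positions},
    )

    # Low coverage outranks unknown: repeat testing comes before review.
    if any(s.status == STATUS_LOW_COVERAGE for s in states.values()):
        call.status = STATUS_LOW_COVERAGE
        return call
    if any(s.status == "ambiguous" for s in states.values()):
        call.status = STATUS_UNKNOWN
        return call

    vector = {pos: states[pos].symbols for pos in positions}
    matches = [rule for rule in rule_table(mode) if rule.matches(vector)]
    if len(matches) != 1:
        call.status = STATUS_UNKNOWN
        return call

    rule = matches[0]
    call.phenotype = rule.phenotype
    call.genotype = rule.simple_genotype
    call.extended_genotype = rule.extended_genotype
    return call
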