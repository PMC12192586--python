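"""Shared fixtures: synthetic references and in-memory typing helpers."""

from __future__ import annotations

import pytest

from abotype import (
    SimulationConfig,
    build_synthetic_references,
    classify,
    simulate_reads,
)
from abotype.align import (
    VariantProfile,
    assign_reads,
    build_pileup,
    variant_profile,
)
from abotype.reference import DIAGNOSTIC_POSITIONS, EXON6_NAME, EXON7_NAME

REF_SEED = 7


@pytest.fixture(scope="session")
def references() -> tuple[str, str]:
    return build_synthetic_references(REF_SEED)


@pytest.fixture(scope="session")
def reference_map(references) -> dict[str, str]:
    return {EXON6_NAME: references[0], EXON7_NAME: references[1]}


def profile_from_fractions(
    fractions_by_offset: dict[int, dict[str, float]],
    depth: int = 100,
    sample_id: str = "fixture",
) -> VariantProfile:
    """Build a VariantProfile directly from per-offset symbol fractions."""
    fractions = {}
    depths = {}
    for pos in DIAGNOSTIC_POSITIONS:
        fractions[pos] = dict(fractions_by_offset[pos.exon_offset])
        depths[pos] = depth
    return VariantProfile(sample_id, fractions, depths)


def type_simulated(
    genotype: tuple[str, str],
    references: tuple[str, str],
    n_reads: int = 100,
    seed: int = 1,
    mode: str = "5snv",
    **sim_kwargs,
):
    """Simulate one sample in memory and classify it; returns (call, profile)."""
    refmap = {EXON6_NAME: references[0], EXON7_NAME: references[1]}
    config = SimulationConfig(genotype=genotype, n_reads=n_reads, seed=seed, **sim_kwargs)
    reads = simulate_reads(config, references)
    alignments = assign_reads(reads["exon6"] + reads["exon7"], refmap)
    pileups = {
        rid: build_pileup(alns, refmap[rid], rid) for rid, alns in alignments.items()
    }
    profile = variant_profile(pileups, sample_id="sim")
    return classify(profile, mode=mode), profile
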