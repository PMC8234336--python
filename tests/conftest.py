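"""Shared fixtures: a mid-sized synthetic genome with a planted duplication
mix, its reference panel, and the identification/duplication results derived
from it. Session-scoped because the end-to-end stages are the expensive part
and several test modules assert different facets of the same run."""

from __future__ import annotations

import numpy as np
import pytest

from abcsurvey import duplication as dup
from abcsurvey.identify import ReferenceProtein, detect_candidates
from abcsurvey.simulate import (
    GenomeSimConfig,
    PlantedDuplication,
    generate_genome,
    generate_reference_panel,
)

# a 1/10-scale version of a (proximal, tandem, dispersed, WGD) survey mix:
# 2 tandem pairs, 2 proximal pairs, 4 dispersed pairs, one 9-gene segmental
# block pair -> per-gene truth (4, 4, 8, 18)
STANDARD_EVENTS = (
    [PlantedDuplication("B", "tandem", 0.3, 0.2)] * 2
    + [PlantedDuplication("C", "proximal", 0.4, 0.2, intervening_genes=3)] * 2
    + [PlantedDuplication("G", "dispersed", 0.5, 0.2)] * 4
    + [PlantedDuplication("A", "segmental", 0.6, 0.2, block_size=9)]
)


@pytest.fixture(scope="session")
def sim_genome():
    config = GenomeSimConfig(
        n_chromosomes=5,
        chrom_length=3_000_000,
        n_background_genes=450,
        planted_events=tuple(STANDARD_EVENTS),
        seed=11,
    )
    return generate_genome(config)


@pytest.fixture(scope="session")
def reference_panel():
    return [
        ReferenceProtein(pid, sub, seq)
        for pid, sub, seq in generate_reference_panel(seed=99)
    ]


@pytest.fixture(scope="session")
def survey_candidates(sim_genome, reference_panel):
    proteins = {gid: g.protein for gid, g in sim_genome.genome.genes.items()}
    architectures = detect_candidates(proteins, reference_panel)
    return {
        "proteins": proteins,
        "architectures": architectures,
        "candidates": {gid: proteins[gid] for gid in architectures},
    }


@pytest.fixture(scope="session")
def duplication_run(sim_genome, survey_candidates):
    genome = sim_genome.genome
    pairs = dup.pairwise_homology(survey_candidates["candidates"])
    anchors = dup.pairs_to_anchors(pairs, genome)
    blocks = dup.detect_collinear_blocks(anchors)
    calls, counts = dup.classify_duplicates(
        survey_candidates["candidates"], genome, pairs, blocks
    )
    return {
        "pairs": pairs,
        "anchors": anchors,
        "blocks": blocks,
        "calls": calls,
        "counts": counts,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20251001)
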