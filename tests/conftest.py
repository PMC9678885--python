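"""Shared fixtures: small deterministic inputs plus one session-scoped run of
the expensive CyTOF chain reused by unit and acceptance tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from regulome.cytof import (
    CYCLE_MARKERS,
    DEATH_MARKERS,
    PHASE_RULES,
    POPULATION_RULES,
    SURFACE_MARKERS,
    arcsinh_scale,
    derive_thresholds,
    metacluster_annotate,
    train_som,
)
from regulome.intervals import GeneModel, GenomicInterval, PeakSet
from regulome.simulate import SimulationConfig, sim_cytof


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_genes() -> list[GeneModel]:
    return [
        GeneModel("gA", "chr1", "+", 1000, 3000),
        GeneModel("gB", "chr1", "-", 5000, 8000),
        GeneModel("gC", "chr2", "+", 100, 900),
    ]


def random_peakset(rng, set_id="s", n=20, chrom_len=10_000, max_len=400) -> PeakSet:
    ivs = []
    for i in range(n):
        start = int(rng.integers(0, chrom_len - max_len))
        length = int(rng.integers(1, max_len))
        ivs.append(GenomicInterval("chr1", start, start + length, f"{set_id}_{i}",
                                   float(rng.random())))
    return PeakSet(set_id, ivs)


@pytest.fixture(scope="session")
def cytof_run():
    """One full CyTOF chain on the default generator (seed 1): scaled events,
    thresholds, trained SOMs and phase/population labels."""
    cfg = SimulationConfig(seed=1)
    events = sim_cytof(cfg)
    scaled = arcsinh_scale(events, cofactor=cfg.cytof_cofactor)
    thresholds = derive_thresholds(scaled, seed=1)
    som_phase = train_som(scaled, markers=CYCLE_MARKERS + DEATH_MARKERS, seed=1)
    som_pop = train_som(scaled, markers=SURFACE_MARKERS, seed=1)
    phase = metacluster_annotate(som_phase, scaled, k=7, rules=PHASE_RULES,
                                 thresholds=thresholds)
    population = metacluster_annotate(som_pop, scaled, k=7, rules=POPULATION_RULES,
                                      thresholds=thresholds)
    return {
        "config": cfg,
        "scaled": scaled,
        "thresholds": thresholds,
        "som_phase": som_phase,
        "som_pop": som_pop,
        "phase": phase,
        "population": population,
    }
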