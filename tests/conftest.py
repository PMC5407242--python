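"""Shared fixtures: small synthetic datasets and one full pipeline run.

The clean end-to-end run (two 1-Mb chromosomes, no repeats, chimeras or
contaminants) is session-scoped because several integration tests measure
different properties of the same reconstruction.
"""

import logging

import numpy as np
import pytest

from pseudomap.pipeline import run_pipeline
from pseudomap.simulate import (
    SimConfig,
    simulate_bac_library,
    simulate_genome,
    simulate_linkage_evidence,
)

logging.getLogger("pseudomap").setLevel(logging.ERROR)


def clean_config(seed: int = 1, **overrides) -> SimConfig:
    base = dict(
        n_chromosomes=2,
        chr_length=1_000_000,
        repeat_fraction=0.0,
        chimera_rate=0.0,
        contaminant_rate=0.0,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def clean_run():
    """Full pipeline on a clean two-chromosome genome."""
    return run_pipeline(clean_config(seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    """Genome + library + evidence on a small clean genome (no pipeline)."""
    cfg = clean_config(seed=7, chr_length=600_000, hic_pairs=5_000)
    genome = simulate_genome(cfg)
    library, truth = simulate_bac_library(genome, cfg)
    evidence = simulate_linkage_evidence(genome, library, truth, cfg)
    return cfg, genome, library, truth, evidence


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
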