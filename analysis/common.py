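"""Shared configuration for the analysis scripts.

All scripts operate on the same deterministic benchmark dataset: a clean
two-chromosome synthetic genome (1 Mb per chromosome) tiled by ~50 kb BAC
inserts, with every evidence layer derived from the same truth. Scripts are
re-runnable in any order; each recomputes its prerequisites through the
library (the whole pipeline takes well under a minute).
"""

from pathlib import Path

from pseudomap.simulate import SimConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"

BENCH_SEED = 1


def bench_config(**overrides) -> SimConfig:
    base = dict(
        n_chromosomes=2,
        chr_length=1_000_000,
        repeat_fraction=0.0,
        chimera_rate=0.0,
        contaminant_rate=0.0,
        seed=BENCH_SEED,
    )
    base.update(overrides)
    return SimConfig(**base)


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
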