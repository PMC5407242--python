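"""pseudomap: hierarchical BAC-based genome integration.

From per-BAC sequence assemblies plus mapping evidence (physical map,
genetic map, optical map, BAC-end sequences, Hi-C) to ordered, oriented,
redundancy-masked chromosome pseudomolecules — with a synthetic-genome
benchmark carrying a machine-readable truth set.
"""

from importlib import resources as _resources

import pandas as _pd

__version__ = "0.1.0"

from .simulate import SimConfig, simulate_genome, simulate_bac_library  # noqa: F401
from .pipeline import run_pipeline  # noqa: F401


def load_reference_table(name: str) -> _pd.DataFrame:
    """Bundled published per-chromosome summary tables (TSV) for the barley
    cv. Morex map-based assembly; used by the reporting examples."""
    path = _resources.files("pseudomap").joinpath("data", f"{name}.tsv")
    with _resources.as_file(path) as p:
        return _pd.read_csv(p, sep="\t")
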