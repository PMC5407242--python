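"""Validation utilities: full-length cDNA representation and collinearity
between pseudomolecule positions and genetic maps."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr


def cdna_representation(hit_table: pd.DataFrame) -> tuple[int, float]:
    """Count cDNAs recovered intact on a single genomic target.

    ``hit_table`` columns: cdna, target, identity (percent), coverage
    (percent), single_target (bool). For each cDNA only its highest-identity
    hit is considered; it counts as intact if identity >= 98, coverage >= 95
    and the hit is confined to a single target. Returns (intact count,
    fraction of distinct input cDNAs).
    """
    n_input = hit_table["cdna"].nunique()
    if n_input == 0:
        return 0, 0.0
    best = hit_table.sort_values(
        ["cdna", "identity", "target"], ascending=[True, False, True]
    ).drop_duplicates("cdna")
    intact = best[
        (best["identity"] >= 98.0)
        & (best["coverage"] >= 95.0)
        & best["single_target"].astype(bool)
    ]
    return len(intact), len(intact) / n_input


def collinearity_check(
    positions: pd.DataFrame, min_markers: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank correlation between physical and genetic marker order.

    ``positions`` columns: marker, chrom, bp, cm. Returns (per-chromosome
    Spearman rho table, dot-plot data table). Chromosomes with fewer than
    ``min_markers`` shared markers report rho as missing.
    """
    rows = []
    for chrom, grp in positions.groupby("chrom"):
        if len(grp) < min_markers:
            rows.append((chrom, np.nan, len(grp)))
            continue
        rho = spearmanr(grp["bp"], grp["cm"]).statistic
        rows.append((chrom, float(rho), len(grp)))
    table = pd.DataFrame(rows, columns=["chrom", "rho", "n_markers"])
    dotplot = positions[["marker", "chrom", "bp", "cm"]].copy()
    return table, dotplot
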