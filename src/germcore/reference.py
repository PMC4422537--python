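"""Published reference summaries of the AVRDC mungbean collections.

The package ships the printed locus-level and descriptor-level summary
tables of the AVRDC mungbean core (1,481 entries) and mini core (~20% of
the core) collections as plain CSV data.  They serve two purposes: as a
worked example for the report generators, and as fixed benchmark inputs
for the column arithmetic the reports perform (totals, means, deficits).

Aggregates are rounded to the same number of decimals as the printed
source rows, matching how the tables' own summary rows are presented.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import pandas as pd


def _round(x: float, decimals: int) -> float:
    """Half-up decimal rounding, the convention of the printed tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def _load(name: str) -> pd.DataFrame:
    with resources.files("germcore.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_locus_diversity() -> pd.DataFrame:
    """Per-locus allele/genotype counts and diversity indices (core, mini)."""
    return _load("locus_diversity.csv").set_index("locus")


def load_trait_summary() -> pd.DataFrame:
    """Per-descriptor summary statistics for whole/core/mini collections."""
    return _load("trait_summary.csv").set_index("descriptor")


def load_minicore_comparison() -> pd.DataFrame:
    """Per-locus allele/genotype retention of the three mini-core strategies."""
    return _load("minicore_comparison.csv").set_index("locus")


def locus_diversity_summary() -> dict[str, float]:
    """Column arithmetic of the locus diversity table.

    Totals and means of the per-locus allele counts and Shannon indices
    for core and mini core, plus the mini core's total-allele deficit.
    """
    t = load_locus_diversity()
    return {
        "total_alleles_core": int(t["alleles_core"].sum()),
        "total_alleles_mini": int(t["alleles_mini"].sum()),
        "allele_deficit_mini": int(t["alleles_core"].sum() - t["alleles_mini"].sum()),
        "mean_alleles_core": _round(float(t["alleles_core"].mean()), 1),
        "mean_alleles_mini": _round(float(t["alleles_mini"].mean()), 1),
        "mean_genotypes_core": _round(float(t["genotypes_core"].mean()), 1),
        "mean_genotypes_mini": _round(float(t["genotypes_mini"].mean()), 1),
        "mean_shannon_core": _round(float(t["shannon_core"].mean()), 3),
        "mean_shannon_mini": _round(float(t["shannon_mini"].mean()), 3),
        "mean_nei_core": _round(float(t["nei_core"].mean()), 3),
        "mean_nei_mini": _round(float(t["nei_mini"].mean()), 3),
    }


def trait_shannon_means() -> dict[str, float]:
    """Mean Shannon-Weaver trait index per collection, to printed decimals."""
    t = load_trait_summary()
    return {
        "mean_shannon_whole": _round(float(t["shannon_whole"].mean()), 2),
        "mean_shannon_core": _round(float(t["shannon_core"].mean()), 2),
        "mean_shannon_mini": _round(float(t["shannon_mini"].mean()), 2),
    }


def minicore_retention_summary() -> dict[str, float]:
    """Column means of the strategy-comparison table and the deficit of the
    best alternative strategy relative to the optimizer mini core."""
    t = load_minicore_comparison()
    means = {
        f"mean_{col}": _round(float(t[col].mean()), 1)
        for col in t.columns
    }
    best_alt_alleles = max(means["mean_alleles_region"], means["mean_alleles_random"])
    best_alt_genotypes = max(
        means["mean_genotypes_region"], means["mean_genotypes_random"]
    )
    means["best_alternative_allele_deficit"] = _round(
        means["mean_alleles_optimizer"] - best_alt_alleles, 1
    )
    means["best_alternative_genotype_deficit"] = _round(
        means["mean_genotypes_optimizer"] - best_alt_genotypes, 1
    )
    return means
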