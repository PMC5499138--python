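"""Bundled summary tables from the published multiparental maize RCGS
field experiment.

These are the printed summary statistics of the real experiment — cycle
mean grain yields, the per-chromosome marker status-change counts, the
positional cluster counts, and the per-group diversity indices. They serve
as worked-example inputs for the gain-regression and bookkeeping
analytics, and as the scale reference the synthetic generator is
calibrated against. Loading them performs no computation.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("rcgs.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_cycle_means() -> pd.DataFrame:
    """Grain-yield entry/check means and H2 per cycle and location."""
    return _load("cycle_means_gy.csv")


def combined_cycle_means() -> pd.Series:
    """Across-location mean GY per cycle, indexed by cycle label."""
    df = load_cycle_means()
    sub = df[df["scope"] == "combined"]
    return sub.set_index("cycle")["entry_mean"]


def location_cycle_means(location: str) -> pd.Series:
    df = load_cycle_means()
    sub = df[df["scope"] == location]
    if sub.empty:
        raise KeyError(f"no means for location {location!r}")
    return sub.set_index("cycle")["entry_mean"]


def load_status_changes() -> pd.DataFrame:
    """Per-chromosome counts of marker polymorphism-status changes."""
    return _load("status_changes_by_chrom.csv")


def status_change_totals() -> dict:
    """Category and grand totals summed over chromosomes."""
    df = load_status_changes()
    return {
        "allele_swaps": int(df["allele_swaps"].sum()),
        "poly_to_mono": int(df["poly_to_mono"].sum()),
        "mono_to_poly": int(df["mono_to_poly"].sum()),
        "total_changed": int(
            (df["allele_swaps"] + df["poly_to_mono"] + df["mono_to_poly"]).sum()
        ),
        "total_snps": int(df["total_snps"].sum()),
    }


def load_cluster_counts() -> pd.DataFrame:
    """Counts of positional clusters of changed SNPs (chrom x category x size)."""
    return _load("status_change_clusters.csv")


def cluster_total() -> int:
    return int(load_cluster_counts()["n_clusters"].sum())


def load_diversity() -> pd.DataFrame:
    """Shannon index, heterozygosity and SNP counts per sample group."""
    return _load("diversity_by_group.csv")
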