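"""Realized-genetic-gain analytics for cycle evaluation trials.

Cycle means are arithmetic entry means per selection cycle (benchmark
checks reported separately); the realized gain per cycle is the ordinary
least-squares slope of the cycle means on the integer cycle index. Also
provides percent gain, gain per year, the breeders' equation
Gain = i * r * h / I, the least significant difference, and entry-mean
broad-sense heritability.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd
from scipy import stats

CYCLE_ORDER = ["C0", "C1", "C2", "C3", "C4"]


def cycle_index(label: str) -> int:
    m = re.fullmatch(r"C(\d+)", str(label))
    if not m:
        raise ValueError(f"not a cycle label: {label!r}")
    return int(m.group(1))


def cycle_means(records: pd.DataFrame, by: str = "combined", trait: str = "GY") -> pd.DataFrame:
    """Arithmetic entry means per cycle, checks reported separately.

    ``by='location'`` returns one row per (location, cycle); ``'combined'``
    pools the records of all locations. Check plots are excluded from the
    entry means and summarized in their own column.
    """
    if by not in {"location", "combined"}:
        raise ValueError("by must be 'location' or 'combined'")
    df = records.copy()
    keys = ["location", "cycle"] if by == "location" else ["cycle"]
    entries = df[~df["is_check"]]
    if entries.empty:
        raise ValueError("no entry records")
    means = entries.groupby(keys)[trait].mean().rename("entry_mean")
    checks = df[df["is_check"]].groupby(keys)[trait].mean().rename("check_mean")
    out = pd.concat([means, checks], axis=1).reset_index()
    empty = out["entry_mean"].isna()
    if empty.any():
        raise ValueError(f"cycles with no entry records: {list(out.loc[empty, 'cycle'])}")
    out["cycle_index"] = out["cycle"].map(cycle_index)
    sort_keys = ["location", "cycle_index"] if by == "location" else ["cycle_index"]
    return out.sort_values(sort_keys).reset_index(drop=True)


def regress_gain(means: pd.Series | dict, cycles=None) -> float:
    """OLS slope of cycle means on integer cycle index (t/ha per cycle).

    ``means`` maps cycle label (or integer index) to the mean; ``cycles``
    optionally restricts the regression to an ordered subset of labels.
    """
    s = pd.Series(means)
    if cycles is not None:
        s = s.loc[list(cycles)]
    if len(s) < 2:
        raise ValueError("need at least 2 cycle means")
    x = np.array([cycle_index(c) if isinstance(c, str) else int(c) for c in s.index], dtype=float)
    res = stats.linregress(x, s.to_numpy(dtype=float))
    return float(res.slope)


def percent_gain(mean_start: float, mean_end: float) -> float:
    """100 x (end - start) / start."""
    if mean_start <= 0:
        raise ValueError("starting mean must be positive")
    return 100.0 * (mean_end - mean_start) / mean_start


def gain_per_year(gain_per_cycle: float, cycles_per_year: float, total_years: float) -> float:
    """(cycles_per_year x gain_per_cycle) / total_years, in t/ha/yr.

    This is realized gain over the whole program amortized per year: the
    per-cycle gain times cycles completed per year, divided by the years
    from the initial cross to the final harvest.
    """
    if total_years <= 0:
        raise ValueError("total_years must be positive")
    return cycles_per_year * gain_per_cycle / total_years


def selection_intensity(proportion: float) -> float:
    """Standardized selection intensity i for truncation at proportion p.

    i = phi(z_p) / p with z_p the upper-p normal quantile.
    """
    if not 0 < proportion < 1:
        raise ValueError("proportion must be in (0, 1)")
    z = stats.norm.ppf(1.0 - proportion)
    return float(stats.norm.pdf(z) / proportion)


def expected_gain(i: float, r: float, h: float, cycle_length_years: float) -> float:
    """Breeders' equation per unit time: i x r x h / I.

    ``i`` standardized selection intensity, ``r`` selection accuracy,
    ``h`` the square root of narrow-sense heritability, ``I`` the cycle
    length in years. Note this form expresses gain in units of the
    additive SD per year (the sigma_A factor is not included).
    """
    if not -1 <= r <= 1:
        raise ValueError("accuracy must be in [-1, 1]")
    if not 0 <= h <= 1:
        raise ValueError("h must be in [0, 1]")
    if cycle_length_years <= 0:
        raise ValueError("cycle length must be positive")
    return i * r * h / cycle_length_years


def lsd(mse: float, df_error: int, n_per_mean: int, alpha: float = 0.05) -> float:
    """Least significant difference: t_{1-alpha/2, df} sqrt(2 MSE / n)."""
    if df_error < 1:
        raise ValueError("df_error must be >= 1")
    if mse < 0:
        raise ValueError("mse must be non-negative")
    t = stats.t.ppf(1.0 - alpha / 2.0, df_error)
    return float(t * np.sqrt(2.0 * mse / n_per_mean))


def broad_sense_h2(var_g: float, var_ge: float, var_e: float, n_locations: int, n_reps: int) -> float:
    """Entry-mean broad-sense heritability.

    H2 = sigma2_G / (sigma2_G + sigma2_GE/l + sigma2_e/(l r)).
    """
    if min(var_g, var_ge, var_e) < 0:
        raise ValueError("variances must be non-negative")
    denom = var_g + var_ge / n_locations + var_e / (n_locations * n_reps)
    if denom == 0:
        raise ValueError("all variance components are zero")
    return var_g / denom


def gain_table(records: pd.DataFrame, trait: str = "GY") -> pd.DataFrame:
    """Per-location and combined cycle means with gain slopes.

    One row per cycle and scope (each location plus 'combined') with entry
    and check means; slope rows (all cycles, and excluding the base cycle)
    are appended with the cycle column set to the range they cover.
    """
    frames = []
    loc_means = cycle_means(records, by="location", trait=trait)
    for loc, grp in loc_means.groupby("location"):
        grp = grp.copy()
        grp.insert(0, "scope", loc)
        frames.append(grp.drop(columns="location"))
    comb = cycle_means(records, by="combined", trait=trait)
    comb.insert(0, "scope", "combined")
    frames.append(comb)
    table = pd.concat(frames, ignore_index=True)

    slope_rows = []
    for scope, grp in table.groupby("scope"):
        s = grp.set_index("cycle")["entry_mean"]
        labels = sorted(s.index, key=cycle_index)
        slope_rows.append((scope, f"gain/cycle {labels[0]}-{labels[-1]}", regress_gain(s, labels)))
        if len(labels) > 2:
            slope_rows.append(
                (scope, f"gain/cycle {labels[1]}-{labels[-1]}", regress_gain(s, labels[1:]))
            )
    slopes = pd.DataFrame(slope_rows, columns=["scope", "cycle", "entry_mean"])
    return pd.concat([table, slopes], ignore_index=True)
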