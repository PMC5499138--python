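"""Additive trait architecture and multi-location testcross trials.

Grain yield is modeled as a purely additive testcross value: a set of QTL
drawn from segregating markers, normal additive effects, and an intercept
in t/ha. Because every entry is evaluated as a hybrid with a common
single-cross tester, the genetic value used throughout is the expectation
of the hybrid dosage over tester gametes — entry dosage/2 plus tester-F1
dosage/2 at each QTL — which is exact under additivity.

Phenotypes add a fixed location effect, a genotype-by-location deviation,
and plot error. Trials are balanced randomized complete blocks within
location; entry-mean broad-sense heritability is calibrated at
architecture-assignment time by simulating a training-population analogue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import breeding
from .breeding import Population
from .founders import FounderPanel, simulate_founders
from .genome import GeneticMap

#: genetic SD (t/ha) among training-population testcross values that the
#: effect sizes are scaled to; chosen to put cycle means and LSDs on the
#: scale of tropical maize testcross yield trials.
DEFAULT_GENETIC_SD = 0.5
#: SD (t/ha) of fixed location main effects.
DEFAULT_LOCATION_SD = 1.5
#: ratio of genotype-by-location variance to plot-error variance.
DEFAULT_GE_TO_ERROR = 0.5


@dataclass
class TraitArchitecture:
    """Additive architecture plus trial variance components."""

    qtl_idx: np.ndarray
    effects: np.ndarray
    mu: float
    sigma2_ge: float
    sigma2_e: float
    tester_f1_dosage: np.ndarray  # per-marker dosage of the tester F1
    location_sd: float = DEFAULT_LOCATION_SD
    seed: int = 0

    def __post_init__(self):
        self.qtl_idx = np.asarray(self.qtl_idx, dtype=int)
        self.effects = np.asarray(self.effects, dtype=float)
        if self.qtl_idx.shape != self.effects.shape:
            raise ValueError("one effect per QTL required")
        if self.sigma2_ge < 0 or self.sigma2_e < 0:
            raise ValueError("variances must be non-negative")

    def to_json(self, path) -> None:
        payload = {
            "qtl_idx": self.qtl_idx.tolist(),
            "effects": self.effects.tolist(),
            "mu": self.mu,
            "sigma2_ge": self.sigma2_ge,
            "sigma2_e": self.sigma2_e,
            "tester_f1_dosage": np.asarray(self.tester_f1_dosage, dtype=float).tolist(),
            "location_sd": self.location_sd,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TraitArchitecture":
        with open(path) as fh:
            d = json.load(fh)
        d["qtl_idx"] = np.array(d["qtl_idx"], dtype=int)
        d["effects"] = np.array(d["effects"], dtype=float)
        d["tester_f1_dosage"] = np.array(d["tester_f1_dosage"], dtype=float)
        return cls(**d)


def testcross_genetic_value(dosage: np.ndarray, arch: TraitArchitecture) -> np.ndarray:
    """Expected testcross value(s) for entry dosage vector(s).

    ``dosage`` is (n_markers,) or (n, n_markers). The expectation over
    tester gametes is taken analytically: at each QTL the expected hybrid
    dosage is entry_dosage/2 + tester_F1_dosage/2.
    """
    d = np.atleast_2d(np.asarray(dosage, dtype=float))
    hyb = d[:, arch.qtl_idx] / 2.0 + arch.tester_f1_dosage[arch.qtl_idx] / 2.0
    vals = arch.mu + hyb @ arch.effects
    return vals if np.asarray(dosage).ndim == 2 else float(vals[0])


def entry_values(pop: Population, arch: TraitArchitecture, by_family: bool = True) -> pd.DataFrame:
    """Genetic testcross values per entry.

    With ``by_family`` the entry is the family (the selection and trial
    unit of a family-bulk program) and its value is the mean over family
    plants; otherwise one entry per individual.
    """
    vals = testcross_genetic_value(pop.dosages(), arch)
    df = pd.DataFrame(
        {
            "entry": pop.meta["id"],
            "family": pop.meta["family"],
            "cycle": pop.meta["cycle"],
            "genetic_value": vals,
        }
    )
    if by_family:
        df = (
            df.groupby("family", sort=False)
            .agg(cycle=("cycle", "first"), genetic_value=("genetic_value", "mean"))
            .reset_index()
        )
        df.insert(0, "entry", df["family"])
    return df[["entry", "family", "cycle", "genetic_value"]]


def _training_analog_variance(
    founders: FounderPanel,
    arch: TraitArchitecture,
    rng,
    n_families: int = 500,
    plants_per_family: int = 15,
) -> float:
    """Between-family genetic variance of a quick training-cycle analogue.

    Founders are crossed in a half-diallel and intermated once with bulk
    pollen; each resulting plant is selfed into an ear-to-row family and
    the variance of family-mean testcross values is returned. Family means
    (not individual selfed plants) are the trial entries, so calibrating
    on them keeps within-family segregation variance out of the
    entry-level genetic variance.
    """
    f1 = breeding.half_diallel(founders.population, 1, rng)
    inter = breeding.bulk_intermate(f1, n_families, rng, progeny_per_ear=1, cycle="cal")
    fams = breeding.ear_to_row_families(inter, range(inter.n), plants_per_family, rng, prefix="cal")
    vals = testcross_genetic_value(fams.dosages(), arch)
    means = vals.reshape(inter.n, plants_per_family).mean(axis=1)
    return float(np.var(means, ddof=1))


def assign_architecture(
    gmap: GeneticMap,
    founders: FounderPanel,
    n_qtl: int = 40,
    target_h2_entry: float = 0.34,
    n_locations: int = 4,
    n_reps: int = 1,
    seed: int = 0,
    mu: float = 8.5,
    genetic_sd: float = DEFAULT_GENETIC_SD,
    tester: Population | None = None,
) -> TraitArchitecture:
    """Sample QTL and effects, then calibrate the error variances.

    QTL are drawn from markers segregating in the founder panel; effects
    are normal, rescaled so the genetic SD among a simulated training
    population equals ``genetic_sd``. The genotype-by-location and plot
    error variances are then set so the entry-mean broad-sense
    heritability of a trial with ``n_locations`` x ``n_reps`` equals
    ``target_h2_entry``, keeping sigma2_ge / sigma2_e at
    ``DEFAULT_GE_TO_ERROR``.
    """
    if not 0 < target_h2_entry < 1:
        raise ValueError("target_h2_entry must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = founders.population.dosages().mean(axis=0) / 2.0
    segregating = np.flatnonzero((p > 0) & (p < 1))
    if segregating.size == 0:
        raise ValueError("no segregating markers in the founder panel")
    if n_qtl > segregating.size:
        raise ValueError("n_qtl exceeds the number of segregating markers")
    qtl = np.sort(rng.choice(segregating, size=n_qtl, replace=False))
    effects = rng.standard_normal(n_qtl)

    if tester is None:
        tester = simulate_founders(gmap, n_parents=2, seed=seed + 101).population
    tester_f1 = breeding.tester_f1_haplotypes(tester).sum(axis=0).astype(float)

    arch = TraitArchitecture(qtl, effects, mu, 0.0, 0.0, tester_f1, seed=seed)
    var_g = _training_analog_variance(founders, arch, rng)
    if var_g > 0:
        arch.effects = effects * (genetic_sd / np.sqrt(var_g))
        var_g = genetic_sd**2
    # H2 = g / (g + ge/l + e/(l r)) with ge = ratio * e
    ell, r = n_locations, n_reps
    ratio = DEFAULT_GE_TO_ERROR
    noise = var_g * (1.0 - target_h2_entry) / target_h2_entry
    sigma2_e = noise / (ratio / ell + 1.0 / (ell * r))
    arch.sigma2_e = sigma2_e
    arch.sigma2_ge = ratio * sigma2_e
    return arch


def simulate_trial(
    entries: pd.DataFrame | Population,
    arch: TraitArchitecture,
    n_locations: int,
    n_reps: int,
    rng,
    checks: dict | None = None,
    location_names: list | None = None,
) -> pd.DataFrame:
    """Balanced multi-location trial of testcross entries.

    Each plot record is genetic value + location main effect +
    N(0, sigma2_ge) per (entry, location) + N(0, sigma2_e) per plot.
    ``checks`` maps check names to fixed genetic values; check plots are
    repeated within every cycle block present among the entries, as
    benchmark hybrids are in a split-plot cycle evaluation.

    Returns tidy records: entry, family, cycle, location, replicate,
    block, is_check, GY.
    """
    if isinstance(entries, Population):
        entries = entry_values(entries, arch)
    if len(entries) == 0:
        raise ValueError("no entries to evaluate")
    entries = entries.reset_index(drop=True)
    if location_names is None:
        location_names = [f"loc{i + 1}" for i in range(n_locations)]
    loc_eff = dict(zip(location_names, arch.location_sd * rng.standard_normal(n_locations)))

    rows = []
    cycles = list(dict.fromkeys(entries["cycle"]))
    ge_sd = np.sqrt(arch.sigma2_ge)
    e_sd = np.sqrt(arch.sigma2_e)

    check_items = list((checks or {}).items())
    for loc in location_names:
        ge = ge_sd * rng.standard_normal(len(entries))
        ge_checks = {
            (name, cyc): ge_sd * rng.standard_normal()
            for name, _ in check_items
            for cyc in cycles
        }
        for rep in range(1, n_reps + 1):
            noise = e_sd * rng.standard_normal(len(entries))
            for i, row in enumerate(entries.itertuples()):
                rows.append(
                    (
                        row.entry,
                        row.family,
                        row.cycle,
                        loc,
                        rep,
                        cycles.index(row.cycle) + 1,
                        False,
                        row.genetic_value + loc_eff[loc] + ge[i] + noise[i],
                    )
                )
            for name, value in check_items:
                for cyc in cycles:
                    rows.append(
                        (
                            name,
                            "check",
                            cyc,
                            loc,
                            rep,
                            cycles.index(cyc) + 1,
                            True,
                            value + loc_eff[loc] + ge_checks[(name, cyc)] + e_sd * rng.standard_normal(),
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=["entry", "family", "cycle", "location", "replicate", "block", "is_check", "GY"],
    )


def estimate_variance_components(records: pd.DataFrame, trait: str = "GY") -> dict:
    """Method-of-moments variance decomposition of a balanced trial.

    Two-way (entry x location) ANOVA with replicates: expected mean
    squares MS_G = sigma2_e + r sigma2_ge + l r sigma2_g,
    MS_GL = sigma2_e + r sigma2_ge, MS_E = sigma2_e. Checks are excluded.
    Negative moment estimates are clipped at zero. Returns the components
    and the entry-mean broad-sense heritability.
    """
    df = records.loc[~records["is_check"]]
    piv = df.pivot_table(index="entry", columns=["location", "replicate"], values=trait)
    if piv.isna().any().any():
        raise ValueError("variance decomposition requires a balanced trial")
    g = piv.shape[0]
    locs = piv.columns.get_level_values("location").unique()
    ell = len(locs)
    r = piv.shape[1] // ell
    y = piv.to_numpy().reshape(g, ell, r)

    cell = y.mean(axis=2)  # entry x location means
    gbar = cell.mean(axis=1)
    lbar = cell.mean(axis=0)
    grand = cell.mean()

    ms_e = np.sum((y - cell[:, :, None]) ** 2) / (g * ell * max(r - 1, 1)) if r > 1 else 0.0
    ms_gl = r * np.sum((cell - gbar[:, None] - lbar[None, :] + grand) ** 2) / ((g - 1) * (ell - 1))
    ms_g = ell * r * np.sum((gbar - grand) ** 2) / (g - 1)

    sigma2_e = max(ms_e, 0.0)
    sigma2_ge = max((ms_gl - sigma2_e) / r, 0.0)
    sigma2_g = max((ms_g - ms_gl) / (ell * r), 0.0)
    denom = sigma2_g + sigma2_ge / ell + sigma2_e / (ell * r)
    h2 = sigma2_g / denom if denom > 0 else 0.0
    return {
        "sigma2_g": sigma2_g,
        "sigma2_ge": sigma2_ge,
        "sigma2_e": sigma2_e,
        "h2_entry_mean": h2,
        "n_locations": ell,
        "n_reps": r,
    }
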