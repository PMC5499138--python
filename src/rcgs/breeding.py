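"""Meiosis and the recurrent-selection crossing scheme.

Implements the building blocks of a rapid-cycling recurrent selection
program in maize: half-diallel crossing of inbred founders, two-group
bulk-pollen intermating, selfing, testcrossing to a single-cross tester,
family-bulk genotyping, and among-family truncation selection.

Gametes are simulated under the Haldane model (no crossover interference):
crossover counts per chromosome are Poisson(L/100) with uniform positions,
which at the marker level is equivalent to an independent phase-switch
between adjacent markers with probability r = (1 - exp(-2d/100))/2 — the
form used here because it vectorizes over gametes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GeneticMap, GenotypeTable

logger = logging.getLogger(__name__)


@dataclass
class Population:
    """A set of phased diploid individuals sharing one genetic map.

    ``haplotypes`` has shape (n, 2, n_markers) with allele codes 0/1
    (1 = reference allele). ``meta`` carries one row per individual:
    ``id``, ``mother``, ``father``, ``family``, ``cycle``.
    """

    map: GeneticMap
    haplotypes: np.ndarray
    meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        n = self.haplotypes.shape[0]
        if self.haplotypes.shape != (n, 2, self.map.n_markers):
            raise ValueError("haplotype array must be (n, 2, n_markers)")
        if len(self.meta) != n:
            raise ValueError("meta rows must match individuals")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def ids(self) -> list:
        return list(self.meta["id"])

    def dosages(self) -> np.ndarray:
        return self.haplotypes.sum(axis=1).astype(float)

    def genotype_table(self) -> GenotypeTable:
        return GenotypeTable(self.ids, self.map, self.dosages())

    def subset(self, index) -> "Population":
        index = np.asarray(index)
        return Population(self.map, self.haplotypes[index], self.meta.iloc[index])

    def families(self) -> dict:
        """Individual indices per family label, in order of appearance."""
        out: dict = {}
        for i, fam in enumerate(self.meta["family"]):
            out.setdefault(fam, []).append(i)
        return out

    def heterozygosity(self) -> float:
        """Observed fraction of heterozygous (individual, marker) pairs."""
        return float(np.mean(self.haplotypes[:, 0, :] != self.haplotypes[:, 1, :]))

    @staticmethod
    def concat(pops: list) -> "Population":
        if not pops:
            raise ValueError("no populations to concatenate")
        m = pops[0].map
        hap = np.concatenate([p.haplotypes for p in pops], axis=0)
        meta = pd.concat([p.meta for p in pops], ignore_index=True)
        return Population(m, hap, meta)


def make_meta(ids, mother="", father="", family="", cycle="") -> pd.DataFrame:
    def expand(v):
        return list(v) if isinstance(v, (list, np.ndarray, pd.Series)) else [v] * len(ids)

    return pd.DataFrame(
        {
            "id": list(ids),
            "mother": expand(mother),
            "father": expand(father),
            "family": expand(family),
            "cycle": expand(cycle),
        }
    )


# ---------------------------------------------------------------------------
# meiosis


def gametes(parent_haplotypes: np.ndarray, gmap: GeneticMap, n: int, rng) -> np.ndarray:
    """Draw ``n`` gametes from one parent.

    Parameters
    ----------
    parent_haplotypes : (2, n_markers) array of allele codes.
    gmap : the genetic map supplying Haldane recombination fractions.
    n : number of gametes.
    rng : numpy Generator.

    Returns (n, n_markers) array. The phase at the first marker of each
    chromosome is a fair coin; afterwards the phase switches between
    adjacent markers independently with the Haldane fraction of their cM
    gap, the marker-level law of Poisson-count crossovers with uniform
    positions and no interference.
    """
    hap = np.asarray(parent_haplotypes)
    if hap.shape != (2, gmap.n_markers):
        raise ValueError("parent genome does not match map")
    r = gmap.recombination_fractions()
    switch = rng.random((n, gmap.n_markers)) < r
    phase = np.cumsum(switch, axis=1) % 2
    return np.where(phase == 0, hap[0], hap[1]).astype(np.uint8)


def meiosis(parent_haplotypes: np.ndarray, gmap: GeneticMap, rng) -> np.ndarray:
    """Single gamete from one parent (convenience wrapper over :func:`gametes`)."""
    return gametes(parent_haplotypes, gmap, 1, rng)[0]


# ---------------------------------------------------------------------------
# crossing scheme


def half_diallel(parents: Population, progeny_per_cross: int, rng) -> Population:
    """All unordered pairwise crosses among the parents, no selfs.

    Returns one F1 family per parent pair — n(n-1)/2 families — with
    ``progeny_per_cross`` individuals each; family labels record both
    parents.
    """
    if parents.n < 2:
        raise ValueError("half-diallel needs at least 2 parents")
    if progeny_per_cross < 1:
        raise ValueError("progeny_per_cross must be >= 1")
    haps, rows = [], []
    ids = parents.ids
    for i in range(parents.n):
        for j in range(i + 1, parents.n):
            fam = f"F1_{ids[i]}x{ids[j]}"
            g_i = gametes(parents.haplotypes[i], parents.map, progeny_per_cross, rng)
            g_j = gametes(parents.haplotypes[j], parents.map, progeny_per_cross, rng)
            for k in range(progeny_per_cross):
                haps.append(np.stack([g_i[k], g_j[k]]))
                rows.append((f"{fam}_{k}", ids[i], ids[j], fam, "F1"))
    meta = pd.DataFrame(rows, columns=["id", "mother", "father", "family", "cycle"])
    return Population(parents.map, np.stack(haps), meta)


def split_families_in_halves(family_labels: list) -> tuple:
    """Split family labels into two groups for reciprocal bulk pollination.

    Odd counts put the extra family in the first half (logged).
    """
    k = len(family_labels)
    half = (k + 1) // 2
    if k % 2:
        logger.info("odd family count %d: first pollination group gets %d families", k, half)
    return list(family_labels[:half]), list(family_labels[half:])


def bulk_intermate(
    pop: Population,
    ears_to_harvest: int,
    rng,
    progeny_per_ear: int = 1,
    cycle: str = "",
) -> Population:
    """Two-group bulk-pollen intermating.

    Families are split into two halves; every seed has a mother plant from
    one half and a father drawn uniformly from the plants of the opposite
    half (pooled pollen — random paternity, never within the mother's own
    half). One harvested ear = one mother plant; mothers are spread across
    families as evenly as possible, remainders assigned at random. Each ear
    founds a new family of ``progeny_per_ear`` full-/half-sib seeds
    (kernels on one ear may have different fathers).
    """
    fams = pop.families()
    if len(fams) < 2:
        raise ValueError("cannot intermate a single family")
    if ears_to_harvest < 1:
        raise ValueError("ears_to_harvest must be >= 1")
    labels = list(fams)
    first, second = split_families_in_halves(labels)
    opposite = {}
    for f in first:
        opposite[f] = np.concatenate([fams[g] for g in second])
    for f in second:
        opposite[f] = np.concatenate([fams[g] for g in first])

    # even spread of ears over families, remainder at random
    base, extra = divmod(ears_to_harvest, len(labels))
    ears_per_family = {f: base for f in labels}
    for f in rng.choice(labels, size=extra, replace=False):
        ears_per_family[f] += 1

    haps, rows = [], []
    ear_no = 0
    for f in labels:
        members = fams[f]
        for _ in range(ears_per_family[f]):
            mother = int(rng.choice(members))
            fam = f"{cycle or 'X'}_ear{ear_no}"
            egg = gametes(pop.haplotypes[mother], pop.map, progeny_per_ear, rng)
            fathers = rng.choice(opposite[f], size=progeny_per_ear)
            for k in range(progeny_per_ear):
                pollen = gametes(pop.haplotypes[int(fathers[k])], pop.map, 1, rng)[0]
                haps.append(np.stack([egg[k], pollen]))
                rows.append(
                    (
                        f"{fam}_{k}",
                        pop.meta.at[mother, "id"],
                        pop.meta.at[int(fathers[k]), "id"],
                        fam,
                        cycle,
                    )
                )
            ear_no += 1
    meta = pd.DataFrame(rows, columns=["id", "mother", "father", "family", "cycle"])
    return Population(pop.map, np.stack(haps), meta)


def self_pollinate(pop: Population, rng, n_progeny: int = 1, cycle: str = "") -> Population:
    """Self every individual; both gametes of each seed come from its parent.

    Expected heterozygosity halves each selfing generation.
    """
    haps, rows = [], []
    for i in range(pop.n):
        g = gametes(pop.haplotypes[i], pop.map, 2 * n_progeny, rng)
        pid = pop.meta.at[i, "id"]
        fam = pop.meta.at[i, "family"] or pid
        for k in range(n_progeny):
            haps.append(np.stack([g[2 * k], g[2 * k + 1]]))
            rows.append((f"{pid}_s{k}", pid, pid, fam, cycle))
    meta = pd.DataFrame(rows, columns=["id", "mother", "father", "family", "cycle"])
    return Population(pop.map, np.stack(haps), meta)


def self_family(pop: Population, parent_index: int, n_progeny: int, rng,
                family: str, cycle: str = "") -> Population:
    """Family of selfed progeny from one plant (an ear planted ear-to-row)."""
    g = gametes(pop.haplotypes[parent_index], pop.map, 2 * n_progeny, rng)
    pid = pop.meta.at[parent_index, "id"]
    haps = [np.stack([g[2 * k], g[2 * k + 1]]) for k in range(n_progeny)]
    rows = [(f"{family}_p{k}", pid, pid, family, cycle) for k in range(n_progeny)]
    meta = pd.DataFrame(rows, columns=["id", "mother", "father", "family", "cycle"])
    return Population(pop.map, np.stack(haps), meta)


def ear_to_row_families(
    pop: Population,
    parent_indices,
    n_progeny: int,
    rng,
    prefix: str = "fam",
    cycle: str = "",
) -> Population:
    """Selfed ear-to-row families from many parent plants in one batch.

    Equivalent to calling :func:`self_family` per parent but builds the
    population in a single allocation (the per-family path is prohibitively
    slow at a thousand families).
    """
    haps, ids, mothers, fams = [], [], [], []
    m = pop.map.n_markers
    for k, i in enumerate(parent_indices):
        g = gametes(pop.haplotypes[int(i)], pop.map, 2 * n_progeny, rng)
        haps.append(g.reshape(n_progeny, 2, m))
        pid = pop.meta.at[int(i), "id"]
        fam = f"{prefix}{k:04d}"
        ids.extend(f"{fam}_p{j}" for j in range(n_progeny))
        mothers.extend([pid] * n_progeny)
        fams.extend([fam] * n_progeny)
    meta = pd.DataFrame(
        {"id": ids, "mother": mothers, "father": mothers, "family": fams, "cycle": cycle}
    )
    return Population(pop.map, np.concatenate(haps, axis=0), meta)


def tester_f1_haplotypes(tester_parents: Population) -> np.ndarray:
    """Genome of the single-cross (F1) tester from two inbred parents."""
    if tester_parents.n != 2:
        raise ValueError("a single-cross tester has exactly two parents")
    for i in range(2):
        if np.any(tester_parents.haplotypes[i, 0] != tester_parents.haplotypes[i, 1]):
            raise ValueError("tester parents must be fully inbred")
    return np.stack(
        [tester_parents.haplotypes[0, 0], tester_parents.haplotypes[1, 0]]
    )


def testcross(entries: Population, tester_parents: Population, n_hybrids_per_entry: int, rng) -> Population:
    """Cross every entry to the single-cross tester.

    Each hybrid combines a gamete of the entry with a gamete of the tester
    F1; the tester gamete segregates wherever the two tester parents
    differ.
    """
    f1 = tester_f1_haplotypes(tester_parents)
    haps, rows = [], []
    for i in range(entries.n):
        ge = gametes(entries.haplotypes[i], entries.map, n_hybrids_per_entry, rng)
        gt = gametes(f1, entries.map, n_hybrids_per_entry, rng)
        eid = entries.meta.at[i, "id"]
        for k in range(n_hybrids_per_entry):
            haps.append(np.stack([ge[k], gt[k]]))
            rows.append((f"{eid}_tc{k}", eid, "tester", entries.meta.at[i, "family"], "testcross"))
    meta = pd.DataFrame(rows, columns=["id", "mother", "father", "family", "cycle"])
    return Population(entries.map, np.stack(haps), meta)


def bulk_family_genotype(family: Population, rng, n_plants: int = 15) -> np.ndarray:
    """Mean dosage over a bulked leaf-tissue sample of family plants.

    Samples min(n_plants, family size) plants without replacement and
    returns the per-marker mean dosage — the family-bulk analogue of a
    single DNA sample from pooled tissue of 15 plants.
    """
    if family.n < 1:
        raise ValueError("empty family")
    k = min(n_plants, family.n)
    idx = rng.choice(family.n, size=k, replace=False)
    return family.dosages()[idx].mean(axis=0)


# ---------------------------------------------------------------------------
# selection bookkeeping


def select_families(scores: pd.Series, n_keep: int) -> list:
    """Top-``n_keep`` family labels by score, descending.

    Ties at the cut are broken lexicographically by label (logged) so the
    choice is deterministic.
    """
    scores = pd.Series(scores)
    if scores.isna().any():
        bad = list(scores.index[scores.isna()])
        raise ValueError(f"NaN selection scores for {bad}")
    if n_keep > len(scores):
        raise ValueError("cannot keep more families than exist")
    ordered = scores.sort_index().sort_values(ascending=False, kind="mergesort")
    if len(scores) > n_keep and ordered.iloc[n_keep - 1] == ordered.iloc[n_keep]:
        logger.info("tied scores at the selection cut; lexicographic tie-break applied")
    return list(ordered.index[:n_keep])


@dataclass(frozen=True)
class CyclePlan:
    families_sown: int
    families_selected: int
    plants_per_family: int
    ears_selected: int
    criterion: str = "gebv"  # {phenotype, gebv, visual_proxy, random}

    def __post_init__(self):
        if self.families_selected > self.families_sown:
            raise ValueError("cannot select more families than sown")


@dataclass(frozen=True)
class SelectionPlan:
    """Per-cycle sowing/selection counts for the recurrent program.

    ``cycles`` maps cycle label (``C0`` ...) to a :class:`CyclePlan`;
    ``final_ears`` is the number of ears harvested to found the last,
    ungenotyped cycle. ``final_entries_evaluated`` records that the
    evaluation trial may list slightly fewer entries than ears harvested
    (both numbers are kept; the published plan reports 45 ears but 43
    evaluated entries for the final cycle).
    """

    cycles: dict
    final_ears: int
    final_entries_evaluated: int | None = None

    def labels(self) -> list:
        return list(self.cycles)


def full_scale_plan() -> SelectionPlan:
    """The literal published selection plan (1000-family training cycle)."""
    return SelectionPlan(
        cycles={
            "C0": CyclePlan(1000, 50, 25, 157, criterion="phenotype"),
            "C1": CyclePlan(157, 25, 25, 91, criterion="gebv"),
            "C2": CyclePlan(91, 18, 25, 44, criterion="gebv"),
            "C3": CyclePlan(44, 22, 25, 22, criterion="gebv"),
        },
        final_ears=45,
        final_entries_evaluated=43,
    )


def scaled_plan(factor: int = 10) -> SelectionPlan:
    """The full plan with all family/ear counts divided by ``factor``.

    Counts are rounded to the nearest integer with a floor of 2 so that
    every cycle can still be intermated; plants per family are kept, since
    they only affect bulk-genotype sampling.
    """
    full = full_scale_plan()

    def f(x, lo=2):
        # round half away from zero so e.g. 25/10 keeps 3 families
        return max(lo, int(np.floor(x / factor + 0.5)))

    cycles = {}
    for label, c in full.cycles.items():
        cycles[label] = CyclePlan(
            families_sown=f(c.families_sown),
            families_selected=f(c.families_selected),
            plants_per_family=c.plants_per_family,
            ears_selected=f(c.ears_selected),
            criterion=c.criterion,
        )
    return SelectionPlan(
        cycles=cycles,
        final_ears=f(full.final_ears),
        final_entries_evaluated=f(full.final_entries_evaluated),
    )


def compute_selection_intensities(plan: SelectionPlan, within_basis: str = "sown") -> pd.DataFrame:
    """Among-, within-, and total selection proportions per cycle.

    among = families_selected / families_sown. within = ears_selected /
    (families_basis x plants_per_family) where the basis counts either the
    ``sown`` or the ``selected`` families — published plans use both
    conventions, so the basis is explicit. total = among x within.
    """
    if within_basis not in {"sown", "selected"}:
        raise ValueError("within_basis must be 'sown' or 'selected'")
    rows = []
    for label, c in plan.cycles.items():
        if c.families_sown == 0 or c.plants_per_family == 0:
            raise ValueError(f"zero denominator in cycle {label}")
        among = c.families_selected / c.families_sown
        basis = c.families_sown if within_basis == "sown" else c.families_selected
        within = c.ears_selected / (basis * c.plants_per_family)
        rows.append((label, among, within, among * within))
    return pd.DataFrame(rows, columns=["cycle", "among", "within", "total"]).set_index("cycle")
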