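"""Core genomic containers: the genetic map and the dosage genotype table.

The map is the coordinate backbone shared by meiosis, marker QC, and the
positional clustering of selected markers: every marker has a chromosome, a
1-based physical position (bp) and a genetic position (cM). Genotypes are
stored as allele dosages (count of the reference allele, 0..2), real-valued
for family bulks, with ``NaN`` as the explicit missing sentinel — 0 is a
valid dosage and never means missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = np.nan


@dataclass(frozen=True)
class GeneticMap:
    """Marker map sorted by (chromosome, bp position).

    Parameters
    ----------
    table : DataFrame with columns ``marker``, ``chrom``, ``pos_bp``,
        ``pos_cM``. Markers must be unique; positions 1-based.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        required = ["marker", "chrom", "pos_bp", "pos_cM"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValueError(f"map is missing columns {missing}")
        if t["marker"].duplicated().any():
            dup = t.loc[t["marker"].duplicated(), "marker"].iloc[0]
            raise ValueError(f"duplicate marker id {dup!r}")
        srt = t.sort_values(["chrom", "pos_bp"], kind="mergesort").reset_index(drop=True)
        if not srt[["chrom", "pos_bp"]].equals(t[["chrom", "pos_bp"]].reset_index(drop=True)):
            logger.warning("map not sorted by (chrom, pos_bp); sorting")
        object.__setattr__(self, "table", srt)
        for chrom, grp in srt.groupby("chrom", sort=False):
            cm = grp["pos_cM"].to_numpy()
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"cM positions decrease within chromosome {chrom}")
            if (grp["pos_bp"] < 1).any():
                raise ValueError(f"bp positions must be >= 1 (chromosome {chrom})")

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def markers(self) -> np.ndarray:
        return self.table["marker"].to_numpy()

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def pos_bp(self) -> np.ndarray:
        return self.table["pos_bp"].to_numpy()

    @property
    def pos_cM(self) -> np.ndarray:
        return self.table["pos_cM"].to_numpy()

    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.table["chrom"]))

    def chrom_slices(self) -> dict:
        """Contiguous marker index slice per chromosome, in map order."""
        out = {}
        start = 0
        for chrom, grp in self.table.groupby("chrom", sort=False):
            out[chrom] = slice(start, start + len(grp))
            start += len(grp)
        return out

    def recombination_fractions(self) -> np.ndarray:
        """Per-marker phase-switch probabilities for gamete simulation.

        Entry ``i`` is the Haldane recombination fraction between marker
        ``i-1`` and ``i``, r = (1 - exp(-2d/100))/2 for a gap of d cM; the
        first marker of each chromosome gets 0.5 (independent start phase,
        no interference between chromosomes).
        """
        r = np.empty(self.n_markers)
        for sl in self.chrom_slices().values():
            cm = self.pos_cM[sl]
            r[sl.start] = 0.5
            if sl.stop - sl.start > 1:
                d = np.diff(cm)
                r[sl.start + 1 : sl.stop] = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
        return r


@dataclass
class GenotypeTable:
    """Dosage matrix (samples x markers) tied to a :class:`GeneticMap`.

    ``dosage[i, j]`` counts copies of the coded allele (written as ALT in
    the VCF dialect, so GT 0/0, 0/1, 1/1 map to 0, 1, 2) in sample ``i``
    at marker ``j``: integer 0/1/2 for individuals, real in [0, 2] for
    family bulks, ``NaN`` for missing calls.
    """

    samples: list
    map: GeneticMap
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), self.map.n_markers):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {self.map.n_markers} markers"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.dosage < 0) | (self.dosage > 2)
        if np.any(bad):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return self.map.n_markers

    def missing_rate(self) -> np.ndarray:
        """Fraction of missing calls per marker."""
        return np.mean(np.isnan(self.dosage), axis=0)

    def allele_frequency(self) -> np.ndarray:
        """Coded-allele frequency per marker over non-missing calls.

        Markers with no calls at all return NaN.
        """
        obs = ~np.isnan(self.dosage)
        counts = obs.sum(axis=0)
        sums = np.where(obs, self.dosage, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(counts > 0, sums / counts, np.nan) / 2.0

    def subset_samples(self, labels) -> "GenotypeTable":
        idx = [self.samples.index(s) for s in labels]
        return GenotypeTable(list(labels), self.map, self.dosage[idx])

    def subset_markers(self, index: np.ndarray) -> "GenotypeTable":
        sub = self.map.table.iloc[np.asarray(index)].reset_index(drop=True)
        return GenotypeTable(list(self.samples), GeneticMap(sub), self.dosage[:, index])
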