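"""Synthetic genetic maps and inbred founder panels.

Emulates the marker data of an elite tropical maize founder panel as seen
through genotyping-by-sequencing: 10 chromosomes, biallelic SNPs with a
strongly skewed major-allele-frequency spectrum (most markers nearly
fixed), fully inbred founders, and a configurable missing-call rate.
The default spectrum is calibrated so that the panel's expected
heterozygosity lands in the 0.09-0.14 range typical of such panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .breeding import Population, make_meta
from .genome import GeneticMap, GenotypeTable

#: Default major-allele-frequency spectrum: a mixture of a mid-frequency
#: uniform component and a near-fixed component. With weight 0.2 on the
#: mid component the panel's expected heterozygosity is ~0.105.
DEFAULT_MAF_SPECTRUM = {
    "mid_weight": 0.2,
    "mid_range": (0.5, 0.95),
    "high_range": (0.95, 1.0),
}


def simulate_map(
    n_chrom: int = 10,
    markers_per_chrom: int = 200,
    chrom_length_cM: float = 150.0,
    chrom_length_bp: int = 230_000_000,
    seed: int = 0,
    cm_jitter: float = 0.0,
) -> GeneticMap:
    """Uniform-random marker map, cM proportional to bp.

    ``cm_jitter`` adds truncated multiplicative noise to the per-interval
    cM gaps (0 = strictly proportional). Deterministic for a fixed seed.
    """
    if n_chrom < 1 or markers_per_chrom < 1:
        raise ValueError("counts must be >= 1")
    if chrom_length_cM <= 0 or chrom_length_bp <= 0:
        raise ValueError("chromosome lengths must be positive")
    rng = np.random.default_rng(seed)
    frames = []
    width = len(str(n_chrom))
    for c in range(1, n_chrom + 1):
        bp = np.array([], dtype=np.int64)
        while bp.size < markers_per_chrom:
            draw = rng.integers(1, chrom_length_bp + 1, size=markers_per_chrom - bp.size)
            bp = np.unique(np.concatenate([bp, draw]))
        bp = np.sort(bp)
        cm = chrom_length_cM * bp / chrom_length_bp
        if cm_jitter > 0 and markers_per_chrom > 1:
            gaps = np.diff(np.concatenate([[0.0], cm]))
            gaps *= np.clip(1.0 + cm_jitter * rng.standard_normal(len(gaps)), 0.0, None)
            cm = np.cumsum(gaps)
        frames.append(
            pd.DataFrame(
                {
                    "marker": [f"chr{c:0{width}d}_m{k}" for k in range(markers_per_chrom)],
                    "chrom": f"chr{c:0{width}d}",
                    "pos_bp": bp,
                    "pos_cM": cm,
                }
            )
        )
    return GeneticMap(pd.concat(frames, ignore_index=True))


@dataclass
class FounderPanel:
    """Fully inbred founder lines plus their map and genotyping view.

    ``population`` holds the phased genomes (every founder homozygous at
    every marker); ``genotypes`` is the observed dosage table, which may
    contain missing calls injected at the genotyping step.
    """

    population: Population
    genotypes: GenotypeTable
    seed: int = 0

    @property
    def map(self) -> GeneticMap:
        return self.population.map

    @property
    def n_parents(self) -> int:
        return self.population.n

    def expected_heterozygosity(self) -> float:
        """Mean 2pq over markers at the panel's own allele frequencies."""
        p = self.genotypes.allele_frequency()
        p = p[~np.isnan(p)]
        return float(np.mean(2.0 * p * (1.0 - p)))


def simulate_founders(
    gmap: GeneticMap,
    n_parents: int = 18,
    maf_spectrum: dict | None = None,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> FounderPanel:
    """Inbred founder panel with marker frequencies from ``maf_spectrum``.

    Each marker's major-allele frequency is drawn from the spectrum; every
    founder is homozygous (its two haplotypes identical), with the
    reference allele carried with that frequency independently per
    founder. Missing calls are injected independently per (sample, marker)
    cell at ``missing_rate`` into the genotype view only — the underlying
    genomes stay complete for breeding.
    """
    if n_parents < 2:
        raise ValueError("need at least 2 parents")
    if not 0 <= missing_rate <= 0.1:
        raise ValueError("missing_rate must be in [0, 0.1]")
    spec = dict(DEFAULT_MAF_SPECTRUM, **(maf_spectrum or {}))
    rng = np.random.default_rng(seed)
    m = gmap.n_markers

    mid = rng.random(m) < spec["mid_weight"]
    p = np.where(
        mid,
        rng.uniform(*spec["mid_range"], size=m),
        rng.uniform(*spec["high_range"], size=m),
    )
    hap = (rng.random((n_parents, m)) < p).astype(np.uint8)
    if np.all(hap.std(axis=0) == 0):
        raise ValueError("spectrum produced a monomorphic-only panel")
    haplotypes = np.repeat(hap[:, None, :], 2, axis=1)
    ids = [f"P{i + 1:02d}" for i in range(n_parents)]
    pop = Population(gmap, haplotypes, make_meta(ids, family="founders", cycle="parents"))

    dosage = pop.dosages()
    if missing_rate > 0:
        mask = rng.random(dosage.shape) < missing_rate
        dosage[mask] = np.nan
    return FounderPanel(pop, GenotypeTable(ids, gmap, dosage), seed=seed)


def marker_qc(genotypes: GenotypeTable, maf_min: float = 0.05, max_missing: float = 0.10) -> np.ndarray:
    """Indices of markers passing the frequency and missingness filter.

    Retains markers with minor-allele frequency strictly greater than
    ``maf_min`` and a missing-call fraction strictly below ``max_missing``
    (boundary values are excluded on both filters). Order follows the map.
    """
    if genotypes.n_samples == 0 or genotypes.n_markers == 0:
        raise ValueError("empty genotype table")
    p = genotypes.allele_frequency()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p, 1.0 - p)
        keep = (maf > maf_min) & (genotypes.missing_rate() < max_missing)
    keep &= ~np.isnan(p)
    return np.flatnonzero(keep)
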