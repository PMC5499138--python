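"""Diversity metrics, ordination, and marker-status-change analysis.

Diversity of a sample group is summarized over markers from major-allele
frequencies: the Shannon index -(1/A) sum_a p_a ln p_a and the expected
heterozygosity mean(2 p_a (1 - p_a)). Sample structure is visualized by
classical (Torgerson) multidimensional scaling of identity-by-state
distances. Selection footprints are traced by classifying each marker's
polymorphic/monomorphic status between two epochs (e.g. founders vs. an
advanced cycle) and clustering the changed SNPs by physical position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GeneticMap, GenotypeTable

logger = logging.getLogger(__name__)

#: markers with major-allele frequency above this are called monomorphic
MONO_BAND = (0.05, 0.95)
CATEGORIES = ("unchanged", "allele_swap", "poly_to_mono", "mono_to_poly")


@dataclass
class AlleleFrequencyProfile:
    """Per-marker major-allele frequencies of one sample group.

    ``freq`` is the frequency of the major allele (>= 0.5);
    ``major_is_counted`` records whether the major allele is the coded
    (dosage-counted) one, so "major" is comparable across groups. Markers
    with no non-missing calls are flagged invalid and excluded from the
    marker count A.
    """

    group: str
    markers: np.ndarray
    freq: np.ndarray
    major_is_counted: np.ndarray
    valid: np.ndarray = field(default=None)

    def __post_init__(self):
        self.freq = np.asarray(self.freq, dtype=float)
        self.major_is_counted = np.asarray(self.major_is_counted, dtype=bool)
        if self.valid is None:
            self.valid = np.ones_like(self.freq, dtype=bool)
        ok = self.freq[self.valid]
        if np.any((ok < 0.5 - 1e-12) | (ok > 1.0 + 1e-12)):
            raise ValueError("major-allele frequencies must lie in [0.5, 1]")

    @property
    def n_markers(self) -> int:
        return int(self.valid.sum())

    def counted_freq(self) -> np.ndarray:
        """Frequency of the coded allele (regardless of which is major)."""
        return np.where(self.major_is_counted, self.freq, 1.0 - self.freq)


def allele_frequencies(genotypes: GenotypeTable, group=None, label: str = "") -> AlleleFrequencyProfile:
    """Major-allele frequency profile of a sample group.

    Frequencies are computed over non-missing calls; exact 0.5 ties are
    assigned to the reference (non-coded) allele (logged). Markers with
    all calls missing are flagged and excluded from the marker count.
    """
    table = genotypes if group is None else genotypes.subset_samples(group)
    if table.n_samples == 0:
        raise ValueError("empty sample group")
    p = table.allele_frequency()
    valid = ~np.isnan(p)
    if not valid.all():
        logger.info("%d markers with no calls excluded from profile", int((~valid).sum()))
    p = np.where(valid, p, 0.5)
    major_is_counted = p > 0.5
    if np.any(p[valid] == 0.5):
        logger.info("exact 0.5 frequency ties resolved to the reference allele")
    freq = np.where(major_is_counted, p, 1.0 - p)
    return AlleleFrequencyProfile(
        label or "group", genotypes.map.markers.copy(), freq, major_is_counted, valid
    )


def shannon_index(profile: AlleleFrequencyProfile) -> float:
    """-(1/A) sum_a p_a ln(p_a) over major-allele frequencies.

    Fixed markers (p = 1) contribute 0; the value lies in [0, ln(2)/2].
    """
    p = profile.freq[profile.valid]
    if p.size == 0:
        raise ValueError("profile has no valid markers")
    terms = np.where(p < 1.0, -p * np.log(np.clip(p, 1e-300, 1.0)), 0.0)
    return float(terms.mean())


def expected_heterozygosity(profile: AlleleFrequencyProfile) -> float:
    """Mean over markers of 2 p (1 - p): expected heterozygote fraction."""
    p = profile.freq[profile.valid]
    if p.size == 0:
        raise ValueError("profile has no valid markers")
    return float(np.mean(2.0 * p * (1.0 - p)))


def ibs_distance(genotypes: GenotypeTable) -> pd.DataFrame:
    """Pairwise identity-by-state distance: mean |x_i - x_j| / 2.

    Averaged over the markers where both samples have calls; errors if a
    pair shares no markers.
    """
    X = genotypes.dosage
    n = genotypes.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples")
    D = np.zeros((n, n))
    obs = ~np.isnan(X)
    for i in range(n):
        diff = np.abs(X - X[i])
        shared = obs & obs[i]
        counts = shared.sum(axis=1)
        if np.any(counts[np.arange(n) != i] == 0):
            j = int(np.flatnonzero((counts == 0) & (np.arange(n) != i))[0])
            raise ValueError(
                f"samples {genotypes.samples[i]!r} and {genotypes.samples[j]!r} share no markers"
            )
        with np.errstate(invalid="ignore"):
            D[i] = np.where(shared, diff, 0.0).sum(axis=1) / np.maximum(counts, 1) / 2.0
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0  # guard against asymmetric missingness rounding
    return pd.DataFrame(D, index=genotypes.samples, columns=genotypes.samples)


def classical_mds(distance: pd.DataFrame, dims: int = 3) -> tuple:
    """Torgerson classical MDS of a distance matrix.

    Double-centers B = -1/2 J D^2 J and embeds on the top eigenpairs with
    positive eigenvalues; negative eigenvalues are dropped (logged) and
    fewer columns are returned if not enough positive ones exist.

    Returns (coordinates DataFrame, eigenvalues array).
    """
    D = np.asarray(distance, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10) or not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_pos = int(np.sum(evals > 1e-10))
    if n_pos < dims:
        logger.info("only %d positive eigenvalues; returning %d dimensions", n_pos, n_pos)
    k = min(dims, n_pos)
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    labels = list(distance.index) if isinstance(distance, pd.DataFrame) else list(range(n))
    frame = pd.DataFrame(coords, index=labels, columns=[f"dim{i + 1}" for i in range(k)])
    return frame, evals


# ---------------------------------------------------------------------------
# marker status changes


@dataclass
class StatusChangeReport:
    """Per-marker status-change categories between two epochs."""

    markers: np.ndarray
    category: np.ndarray  # values from CATEGORIES
    freq_epoch1: np.ndarray
    freq_epoch2: np.ndarray  # frequency of epoch1's major allele in epoch 2

    def counts(self) -> pd.Series:
        return pd.Series(self.category).value_counts().reindex(list(CATEGORIES), fill_value=0)

    def per_chromosome(self, gmap: GeneticMap) -> pd.DataFrame:
        """Table of category counts by chromosome, with totals and percent."""
        df = pd.DataFrame(
            {"chrom": gmap.chrom, "category": self.category}
        )
        out = (
            df.pivot_table(index="chrom", columns="category", aggfunc="size", fill_value=0)
            .reindex(columns=["allele_swap", "poly_to_mono", "mono_to_poly"], fill_value=0)
            .reindex(gmap.chromosomes(), fill_value=0)
        )
        out["total_changed"] = out.sum(axis=1)
        totals = df.groupby("chrom", sort=False).size().reindex(gmap.chromosomes())
        out["n_markers"] = totals
        out["pct_changed"] = 100.0 * out["total_changed"] / out["n_markers"]
        return out


def classify_marker_status(
    epoch1: AlleleFrequencyProfile,
    epoch2: AlleleFrequencyProfile,
    mono_band: tuple = MONO_BAND,
) -> StatusChangeReport:
    """Classify each marker's polymorphism-status change between epochs.

    Both epochs are expressed as the frequency of epoch 1's major allele.
    A marker with frequency inside ``mono_band`` (inclusive) is
    polymorphic, outside it monomorphic. Categories (mutually exclusive,
    transitions take precedence over swaps):

    - ``poly_to_mono`` — polymorphic in epoch 1, monomorphic in epoch 2;
    - ``mono_to_poly`` — the reverse;
    - ``allele_swap`` — polymorphic in both but the major allele differs;
    - ``unchanged`` — everything else.
    """
    if not np.array_equal(epoch1.markers, epoch2.markers):
        raise ValueError("profiles cover different marker sets")
    lo, hi = mono_band
    f1 = epoch1.freq
    # frequency of epoch1's major allele in epoch2
    same = epoch1.major_is_counted == epoch2.major_is_counted
    f2 = np.where(same, epoch2.freq, 1.0 - epoch2.freq)

    poly1 = (f1 >= lo) & (f1 <= hi)
    poly2 = (f2 >= lo) & (f2 <= hi)
    cat = np.full(f1.shape, "unchanged", dtype=object)
    cat[poly1 & ~poly2] = "poly_to_mono"
    cat[~poly1 & poly2] = "mono_to_poly"
    swap = poly1 & poly2 & (f2 < 0.5)
    cat[swap] = "allele_swap"
    both_valid = epoch1.valid & epoch2.valid
    cat[~both_valid] = "unchanged"
    return StatusChangeReport(epoch1.markers.copy(), cat, f1.copy(), f2)


def cluster_changed_snps(
    report: StatusChangeReport,
    gmap: GeneticMap,
    max_gap_bp: int = 1000,
    min_size: int = 3,
) -> pd.DataFrame:
    """Single-linkage positional clusters of changed SNPs.

    Within each chromosome and each change category separately,
    consecutive changed SNPs are chained into a cluster while the gap to
    the previous member is strictly below ``max_gap_bp``; clusters with at
    least ``min_size`` members are reported with their span and size.
    """
    if len(report.markers) != gmap.n_markers:
        raise ValueError("report not aligned to map")
    rows = []
    df = pd.DataFrame(
        {
            "marker": gmap.markers,
            "chrom": gmap.chrom,
            "pos_bp": gmap.pos_bp,
            "category": report.category,
        }
    )
    changed = df[df["category"] != "unchanged"]
    for (chrom, cat), grp in changed.groupby(["chrom", "category"], sort=False):
        grp = grp.sort_values("pos_bp")
        pos = grp["pos_bp"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) >= max_gap_bp)
        start = 0
        for stop in list(breaks + 1) + [len(pos)]:
            if stop - start >= min_size:
                members = grp.iloc[start:stop]
                rows.append(
                    (
                        chrom,
                        cat,
                        stop - start,
                        int(members["pos_bp"].iloc[0]),
                        int(members["pos_bp"].iloc[-1]),
                        int(members["pos_bp"].iloc[-1] - members["pos_bp"].iloc[0]),
                        ",".join(members["marker"]),
                    )
                )
            start = stop
    return pd.DataFrame(
        rows,
        columns=["chrom", "category", "size", "start_bp", "end_bp", "span_bp", "markers"],
    )


def frequency_shift_summary(
    epoch1: AlleleFrequencyProfile,
    epoch2: AlleleFrequencyProfile,
    shift_threshold: float = 0.15,
    mono_band: tuple = MONO_BAND,
) -> dict:
    """Counts of frequency change that never crosses into monomorphism.

    ``n_changed_nonmono`` counts markers whose frequency changed while
    staying polymorphic in both epochs; ``n_small_shift`` counts changed
    markers with |delta p| below ``shift_threshold``. Fractions are over
    all (jointly valid) markers.
    """
    if not np.array_equal(epoch1.markers, epoch2.markers):
        raise ValueError("profiles cover different marker sets")
    lo, hi = mono_band
    f1 = epoch1.freq
    same = epoch1.major_is_counted == epoch2.major_is_counted
    f2 = np.where(same, epoch2.freq, 1.0 - epoch2.freq)
    valid = epoch1.valid & epoch2.valid
    changed = (f1 != f2) & valid
    poly_both = (f1 >= lo) & (f1 <= hi) & (f2 >= lo) & (f2 <= hi)
    n_changed_nonmono = int(np.sum(changed & poly_both))
    n_small = int(np.sum(changed & (np.abs(f2 - f1) < shift_threshold)))
    total = int(valid.sum())
    return {
        "n_changed_nonmono": n_changed_nonmono,
        "n_small_shift": n_small,
        "frac_changed_nonmono": n_changed_nonmono / total if total else 0.0,
        "frac_small_shift": n_small / total if total else 0.0,
        "n_markers": total,
    }


def diversity_report(genotypes: GenotypeTable, groups: dict) -> pd.DataFrame:
    """Shannon index, heterozygosity and marker count per sample group."""
    rows = []
    for name, labels in groups.items():
        prof = allele_frequencies(genotypes, labels, label=name)
        rows.append(
            (name, len(labels), shannon_index(prof), expected_heterozygosity(prof), prof.n_markers)
        )
    return pd.DataFrame(
        rows, columns=["group", "n_samples", "shannon", "heterozygosity", "n_snps"]
    )
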