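import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import table_from_dosage, uniform_map
from rcgs.diversity import (
    CATEGORIES,
    AlleleFrequencyProfile,
    allele_frequencies,
    classical_mds,
    classify_marker_status,
    cluster_changed_snps,
    diversity_report,
    expected_heterozygosity,
    frequency_shift_summary,
    ibs_distance,
    shannon_index,
)
from rcgs.genome import GeneticMap


def profile(freqs, markers=None, major_is_counted=None, group="g"):
    freqs = np.asarray(freqs, dtype=float)
    markers = np.asarray(markers if markers is not None else [f"m{i}" for i in range(len(freqs))])
    mic = np.ones(len(freqs), bool) if major_is_counted is None else np.asarray(major_is_counted, bool)
    return AlleleFrequencyProfile(group, markers, freqs, mic)


class TestAlleleFrequencies:
    def test_major_allele_from_dosages(self):
        """Dosages {0, 0, 2}: coded-allele frequency 1/3, so the major allele
        is the other one at 2/3."""
        table = table_from_dosage(uniform_map(1), [[0.0], [0.0], [2.0]])
        prof = allele_frequencies(table)
        assert prof.freq[0] == pytest.approx(2 / 3)
        assert not prof.major_is_counted[0]

    def test_fixed_marker(self):
        table = table_from_dosage(uniform_map(1), [[2.0], [2.0]])
        prof = allele_frequencies(table)
        assert prof.freq[0] == 1.0 and prof.major_is_counted[0]

    def test_bulk_dosages(self):
        """Bulks {1.0, 0.5}: coded frequency 0.375 -> major 0.625."""
        table = table_from_dosage(uniform_map(1), [[1.0], [0.5]])
        prof = allele_frequencies(table)
        assert prof.freq[0] == pytest.approx(0.625)

    def test_all_missing_marker_excluded_from_count(self):
        table = table_from_dosage(uniform_map(2), [[np.nan, 1.0], [np.nan, 2.0]])
        prof = allele_frequencies(table)
        assert prof.n_markers == 1
        assert not prof.valid[0]


class TestIndices:
    @pytest.mark.parametrize(
        "freqs,expected",
        [
            ([1.0, 1.0], 0.0),
            ([0.5], 0.34657),
            ([0.9, 0.8, 1.0], 0.09111),
        ],
    )
    def test_shannon_hand_values(self, freqs, expected):
        assert shannon_index(profile(freqs)) == pytest.approx(expected, abs=1e-4)

    @pytest.mark.parametrize(
        "freqs,expected", [([0.5], 0.5), ([1.0], 0.0), ([0.9, 0.7], 0.30)]
    )
    def test_heterozygosity_hand_values(self, freqs, expected):
        assert expected_heterozygosity(profile(freqs)) == pytest.approx(expected)

    @given(
        st.lists(st.floats(min_value=0.5, max_value=1.0, allow_nan=False), min_size=1, max_size=40)
    )
    @settings(max_examples=60, deadline=None)
    def test_index_ranges_and_zero_iff_fixed(self, freqs):
        prof = profile(freqs)
        s = shannon_index(prof)
        h = expected_heterozygosity(prof)
        assert 0.0 <= s <= 0.34658
        assert 0.0 <= h <= 0.5
        all_fixed = all(f == 1.0 for f in freqs)
        assert (s == 0.0) == all_fixed
        assert (h == 0.0) == all_fixed


class TestIbsDistance:
    def test_identical_and_opposite(self):
        table = table_from_dosage(uniform_map(3), [[0, 1, 2.0], [0, 1, 2.0], [2, 1, 0.0]])
        D = ibs_distance(table)
        assert D.iloc[0, 1] == 0.0
        assert D.iloc[0, 2] == pytest.approx((2 + 0 + 2) / 6)

    def test_fully_opposite_is_one(self):
        table = table_from_dosage(uniform_map(2), [[0.0, 0.0], [2.0, 2.0]])
        assert ibs_distance(table).iloc[0, 1] == 1.0

    def test_no_shared_markers_rejected(self):
        table = table_from_dosage(uniform_map(2), [[np.nan, 1.0], [2.0, np.nan]])
        with pytest.raises(ValueError, match="share no markers"):
            ibs_distance(table)


class TestClassicalMds:
    def test_points_on_a_line_reconstructed(self):
        x = np.array([0.0, 1.0, 3.0])
        D = np.abs(x[:, None] - x[None, :])
        coords, evals = classical_mds(pd.DataFrame(D), dims=1)
        rec = np.abs(coords.to_numpy() - coords.to_numpy().T)
        np.testing.assert_allclose(rec, D, atol=1e-8)

    def test_equilateral_configuration(self):
        D = pd.DataFrame(np.ones((3, 3)) - np.eye(3))
        coords, _ = classical_mds(D, dims=2)
        c = coords.to_numpy()
        dists = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=2)
        off = dists[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, off[0], atol=1e-8)

    def test_duplicate_sample_coincides(self):
        x = np.array([[0.0, 0], [0, 0], [3, 4]])
        D = np.linalg.norm(x[:, None] - x[None, :], axis=2)
        coords, _ = classical_mds(pd.DataFrame(D), dims=2)
        np.testing.assert_allclose(coords.iloc[0], coords.iloc[1], atol=1e-8)

    def test_euclidean_distances_reproduced_in_full_rank(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((12, 3))
        D = np.linalg.norm(x[:, None] - x[None, :], axis=2)
        coords, _ = classical_mds(pd.DataFrame(D), dims=3)
        rec = np.linalg.norm(coords.to_numpy()[:, None] - coords.to_numpy()[None, :], axis=2)
        np.testing.assert_allclose(rec, D, atol=1e-8)

    def test_agrees_with_skbio_pcoa(self):
        """Independent oracle: scikit-bio's principal coordinate analysis."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(7)
        x = rng.standard_normal((10, 4))
        D = np.linalg.norm(x[:, None] - x[None, :], axis=2)
        ours, evals = classical_mds(pd.DataFrame(D), dims=3)
        theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(D), number_of_dimensions=3)
        np.testing.assert_allclose(
            np.abs(ours.to_numpy()), np.abs(theirs.samples.to_numpy()), atol=1e-6
        )
        np.testing.assert_allclose(evals[:3], theirs.eigvals.to_numpy()[:3], atol=1e-8)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            classical_mds(pd.DataFrame([[0.0, 1.0], [2.0, 0.0]]))


class TestStatusChange:
    def test_threshold_transitions(self):
        """0.50 -> 0.97 loses polymorphism; 0.96 -> 0.50 gains it; a major
        allele dropping to 0.20 is a swap."""
        e1 = profile([0.50, 0.96, 0.70])
        e2 = profile([0.97, 0.50, 0.80], major_is_counted=[True, True, False])
        rep = classify_marker_status(e1, e2)
        assert list(rep.category) == ["poly_to_mono", "mono_to_poly", "allele_swap"]
        assert rep.freq_epoch2[2] == pytest.approx(0.20)

    def test_boundaries_are_polymorphic_inclusive(self):
        e1 = profile([0.95, 0.95])
        e2 = profile([0.95, 0.96])
        rep = classify_marker_status(e1, e2)
        assert list(rep.category) == ["unchanged", "poly_to_mono"]

    def test_unaligned_marker_sets_rejected(self):
        e1 = profile([0.5], markers=["a"])
        e2 = profile([0.5], markers=["b"])
        with pytest.raises(ValueError):
            classify_marker_status(e1, e2)

    @given(st.data())
    @settings(max_examples=40, deadline=None)
    def test_categories_partition_markers(self, data):
        n = data.draw(st.integers(min_value=1, max_value=50))
        f1 = data.draw(
            st.lists(st.floats(min_value=0.5, max_value=1.0), min_size=n, max_size=n)
        )
        f2 = data.draw(
            st.lists(st.floats(min_value=0.5, max_value=1.0), min_size=n, max_size=n)
        )
        flips = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
        rep = classify_marker_status(profile(f1), profile(f2, major_is_counted=flips))
        assert set(rep.category) <= set(CATEGORIES)
        assert rep.counts().sum() == n


class TestClusters:
    def _map(self, positions, chrom="chr1"):
        return GeneticMap(
            pd.DataFrame(
                {
                    "marker": [f"m{i}" for i in range(len(positions))],
                    "chrom": chrom,
                    "pos_bp": positions,
                    "pos_cM": np.linspace(0, 1, len(positions)),
                }
            )
        )

    def _report(self, gmap, categories):
        n = gmap.n_markers
        return classify_marker_status(
            profile([0.5] * n, markers=gmap.markers),
            profile(
                [0.97 if c != "unchanged" else 0.5 for c in categories],
                markers=gmap.markers,
            ),
        )

    def test_chained_cluster_of_three(self):
        gmap = self._map([100, 600, 1400])
        rep = self._report(gmap, ["poly_to_mono"] * 3)
        clusters = cluster_changed_snps(rep, gmap)
        assert len(clusters) == 1
        assert clusters.iloc[0]["size"] == 3
        assert clusters.iloc[0]["span_bp"] == 1300

    def test_gaps_at_threshold_break_chain(self):
        gmap = self._map([100, 1200, 2300])
        rep = self._report(gmap, ["poly_to_mono"] * 3)
        assert len(cluster_changed_snps(rep, gmap)) == 0

    def test_mixed_categories_do_not_cluster(self):
        gmap = self._map([100, 500, 900])
        e1 = profile([0.70, 0.50, 0.50], markers=gmap.markers)
        e2 = profile([0.80, 0.97, 0.97], markers=gmap.markers, major_is_counted=[False, True, True])
        rep = classify_marker_status(e1, e2)
        assert list(rep.category) == ["allele_swap", "poly_to_mono", "poly_to_mono"]
        assert len(cluster_changed_snps(rep, gmap, min_size=3)) == 0

    def test_min_size_two_allows_pairs(self):
        gmap = self._map([100, 500, 900])
        rep = self._report(gmap, ["unchanged", "poly_to_mono", "poly_to_mono"])
        clusters = cluster_changed_snps(rep, gmap, min_size=2)
        assert len(clusters) == 1 and clusters.iloc[0]["size"] == 2


class TestShiftSummary:
    def test_identical_profiles(self):
        e = profile([0.6, 0.7])
        out = frequency_shift_summary(e, e)
        assert out["n_changed_nonmono"] == 0 and out["n_small_shift"] == 0

    def test_single_small_shift(self):
        out = frequency_shift_summary(profile([0.6]), profile([0.7]))
        assert out["n_changed_nonmono"] == 1 and out["n_small_shift"] == 1

    def test_hand_enumerated_mixture(self):
        """Deltas {0, 0.10, 0.20, into-monomorphic}: two markers changed while
        staying polymorphic, one of them below the 15% shift threshold."""
        e1 = profile([0.60, 0.60, 0.60, 0.55])
        e2 = profile([0.60, 0.70, 0.80, 0.97])
        out = frequency_shift_summary(e1, e2)
        assert out["n_changed_nonmono"] == 2
        assert out["n_small_shift"] == 1
        assert out["n_markers"] == 4


def test_diversity_report_rows(founder_panel):
    table = founder_panel.genotypes
    rep = diversity_report(table, {"all": list(table.samples), "half": list(table.samples[:9])})
    assert list(rep["group"]) == ["all", "half"]
    assert (rep["n_snps"] <= table.n_markers).all()
    assert ((rep["shannon"] >= 0) & (rep["shannon"] <= 0.34658)).all()
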