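import numpy as np
import pandas as pd
import pytest

from conftest import inbred_pair, two_marker_map, uniform_map
from rcgs import breeding
from rcgs.breeding import (
    Population,
    bulk_family_genotype,
    bulk_intermate,
    compute_selection_intensities,
    full_scale_plan,
    gametes,
    half_diallel,
    make_meta,
    select_families,
    self_pollinate,
)
from rcgs.breeding import testcross as cross_to_tester


def het_parent(gmap):
    m = gmap.n_markers
    hap = np.zeros((1, 2, m), dtype=np.uint8)
    hap[0, 1] = 1
    return Population(gmap, hap, make_meta(["H"]))


class TestMeiosis:
    def test_recombinant_fraction_matches_haldane(self, rng):
        """Two markers 50 cM apart: r = (1 - e^-1)/2 over 1e5 meioses."""
        gmap = two_marker_map(50.0)
        parent = het_parent(gmap)
        g = gametes(parent.haplotypes[0], gmap, 100_000, rng)
        frac = np.mean(g[:, 0] != g[:, 1])
        expected = (1.0 - np.exp(-1.0)) / 2.0
        se = np.sqrt(expected * (1 - expected) / 100_000)
        assert abs(frac - expected) < 3 * se

    def test_zero_distance_never_recombines(self, rng):
        gmap = two_marker_map(0.0)
        parent = het_parent(gmap)
        g = gametes(parent.haplotypes[0], gmap, 20_000, rng)
        assert np.all(g[:, 0] == g[:, 1])

    def test_homozygous_parent_gives_parental_haplotype(self, rng):
        gmap = uniform_map(30)
        hap = np.ones((2, 30), dtype=np.uint8)
        g = gametes(hap, gmap, 50, rng)
        assert np.all(g == 1)

    def test_start_phase_is_fair(self, rng):
        gmap = uniform_map(1)
        parent = het_parent(gmap)
        g = gametes(parent.haplotypes[0], gmap, 50_000, rng)
        assert abs(g.mean() - 0.5) < 3 * 0.5 / np.sqrt(50_000)


class TestHalfDiallel:
    @pytest.mark.parametrize("n_parents,n_families", [(2, 1), (4, 6), (18, 153)])
    def test_family_counts(self, founder_panel, rng, n_parents, n_families):
        pop = founder_panel.population.subset(np.arange(n_parents))
        f1 = half_diallel(pop, 1, rng)
        assert len(f1.families()) == n_families

    def test_no_selfs_and_parents_recorded(self, founder_panel, rng):
        pop = founder_panel.population.subset(np.arange(5))
        f1 = half_diallel(pop, 2, rng)
        assert (f1.meta["mother"] != f1.meta["father"]).all()
        assert f1.n == 10 * 2

    def test_rejects_bad_progeny_count(self, founder_panel, rng):
        with pytest.raises(ValueError):
            half_diallel(founder_panel.population, 0, rng)


class TestBulkIntermate:
    def _families(self, gmap, k, rng):
        pops = []
        for i in range(k):
            hap = rng.integers(0, 2, size=(3, 2, gmap.n_markers)).astype(np.uint8)
            pops.append(
                Population(gmap, hap, make_meta([f"f{i}_p{j}" for j in range(3)], family=f"fam{i}"))
            )
        return Population.concat(pops)

    def test_ear_count_and_cross_half_paternity(self, rng):
        gmap = uniform_map(10)
        pop = self._families(gmap, 50, rng)
        out = bulk_intermate(pop, 157, rng)
        assert out.n == 157
        halves = breeding.split_families_in_halves(list(pop.families()))
        half_of = {}
        for h, fams in enumerate(halves):
            for f in fams:
                half_of[f] = h
        fam_of_plant = dict(zip(pop.meta["id"], pop.meta["family"]))
        for _, row in out.meta.iterrows():
            hm = half_of[fam_of_plant[row["mother"]]]
            hf = half_of[fam_of_plant[row["father"]]]
            assert hm != hf, "mating within the same pollination half"

    def test_two_families_always_outcross(self, rng):
        gmap = uniform_map(5)
        pop = self._families(gmap, 2, rng)
        out = bulk_intermate(pop, 20, rng)
        fam_of_plant = dict(zip(pop.meta["id"], pop.meta["family"]))
        mothers = out.meta["mother"].map(fam_of_plant)
        fathers = out.meta["father"].map(fam_of_plant)
        assert (mothers != fathers).all()

    def test_even_ear_spread(self, rng):
        gmap = uniform_map(5)
        pop = self._families(gmap, 4, rng)
        out = bulk_intermate(pop, 4, rng)
        fam_of_plant = dict(zip(pop.meta["id"], pop.meta["family"]))
        mothers = out.meta["mother"].map(fam_of_plant)
        assert mothers.nunique() == 4

    def test_single_family_rejected(self, rng):
        gmap = uniform_map(5)
        pop = self._families(gmap, 1, rng)
        with pytest.raises(ValueError, match="single family"):
            bulk_intermate(pop, 5, rng)

    def test_allele_frequency_martingale_under_random_mating(self):
        """Without selection, replicate-mean allele frequencies stay within
        3 drift SE of the base frequency after a generation of intermating."""
        gmap = uniform_map(40, spacing_cm=5.0)
        base_rng = np.random.default_rng(77)
        hap = (base_rng.random((30, 2, 40)) < 0.4).astype(np.uint8)
        pop = Population(
            gmap, hap, make_meta([f"i{k}" for k in range(30)], family=[f"i{k}" for k in range(30)])
        )
        p0 = pop.dosages().mean(axis=0) / 2.0
        reps = []
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            nxt = bulk_intermate(pop, 30, rng)
            reps.append(nxt.dosages().mean(axis=0) / 2.0)
        mean_p = np.mean(reps, axis=0)
        drift_se = np.sqrt(p0 * (1 - p0) / (2 * 30)) / np.sqrt(100)
        within = np.abs(mean_p - p0) <= 3 * drift_se
        assert within.mean() > 0.95


class TestSelfing:
    def test_f1_selfing_halves_heterozygosity(self, rng):
        """Selfed progeny of an F1 are heterozygous at half the markers."""
        gmap = uniform_map(50, spacing_cm=3.0)
        pair = inbred_pair(gmap)
        f1_hap = np.stack([pair.haplotypes[0, 0], pair.haplotypes[1, 0]])[None]
        f1 = Population(gmap, f1_hap, make_meta(["F1"], family="F1"))
        many = Population(
            gmap, np.repeat(f1.haplotypes, 10_000, axis=0), make_meta([f"F1_{i}" for i in range(10_000)])
        )
        s1 = self_pollinate(many, rng)
        het = s1.heterozygosity()
        assert abs(het - 0.5) < 3 * 0.5 / np.sqrt(10_000)
        s2 = self_pollinate(s1, rng)
        assert abs(s2.heterozygosity() - 0.25) < 0.02

    def test_homozygous_parent_breeds_true(self, rng):
        gmap = uniform_map(20)
        hap = np.ones((1, 2, 20), dtype=np.uint8)
        pop = Population(gmap, hap, make_meta(["X"]))
        child = self_pollinate(pop, rng)
        np.testing.assert_array_equal(child.haplotypes, pop.haplotypes)


class TestTestcross:
    def test_identical_tester_parents_give_identical_hybrids(self, rng):
        gmap = uniform_map(15)
        hap = np.zeros((1, 2, 15), dtype=np.uint8)
        entry = Population(gmap, hap, make_meta(["E"]))
        t_hap = np.ones((2, 2, 15), dtype=np.uint8)
        tester = Population(gmap, t_hap, make_meta(["T1", "T2"]))
        hyb = cross_to_tester(entry, tester, 10, rng)
        assert np.all(hyb.dosages() == hyb.dosages()[0])

    def test_hybrid_counts_and_lineage(self, founder_panel, rng):
        entries = founder_panel.population.subset(np.arange(12))
        tester = founder_panel.population.subset([16, 17])
        hyb = cross_to_tester(entries, tester, 2, rng)
        assert hyb.n == 24
        assert set(hyb.meta["mother"]) == set(entries.ids)

    def test_segregating_tester_marker_dosage(self, rng):
        """Entry AA x tester (AA/aa) F1: hybrid dosage averages 1.5."""
        gmap = uniform_map(1)
        entry = Population(gmap, np.ones((1, 2, 1), np.uint8), make_meta(["E"]))
        t_hap = np.zeros((2, 2, 1), np.uint8)
        t_hap[0] = 1
        tester = Population(gmap, t_hap, make_meta(["T1", "T2"]))
        hyb = cross_to_tester(entry, tester, 20_000, rng)
        mean = hyb.dosages().mean()
        assert abs(mean - 1.5) < 3 * 0.5 / np.sqrt(20_000)

    def test_non_inbred_tester_rejected(self, rng):
        gmap = uniform_map(4)
        hap = np.zeros((2, 2, 4), np.uint8)
        hap[0, 1] = 1  # heterozygous first parent
        tester = Population(gmap, hap, make_meta(["T1", "T2"]))
        entry = Population(gmap, np.zeros((1, 2, 4), np.uint8), make_meta(["E"]))
        with pytest.raises(ValueError, match="inbred"):
            cross_to_tester(entry, tester, 1, rng)


class TestBulkGenotype:
    def test_uniform_family_bulk(self, rng):
        gmap = uniform_map(5)
        hap = np.ones((8, 2, 5), np.uint8)
        fam = Population(gmap, hap, make_meta([f"p{i}" for i in range(8)], family="f"))
        np.testing.assert_array_equal(bulk_family_genotype(fam, rng), np.full(5, 2.0))

    def test_two_plant_average(self, rng):
        gmap = uniform_map(3)
        hap = np.zeros((2, 2, 3), np.uint8)
        hap[1] = 1
        fam = Population(gmap, hap, make_meta(["a", "b"], family="f"))
        np.testing.assert_array_equal(bulk_family_genotype(fam, rng, n_plants=2), np.full(3, 1.0))

    def test_deterministic_and_variance_shrinks_with_plants(self):
        gmap = uniform_map(1)
        base = np.random.default_rng(5)
        hap = (base.random((25, 2, 1)) < 0.5).astype(np.uint8)
        fam = Population(gmap, hap, make_meta([f"p{i}" for i in range(25)], family="f"))
        one = bulk_family_genotype(fam, np.random.default_rng(3), 15)
        two = bulk_family_genotype(fam, np.random.default_rng(3), 15)
        np.testing.assert_array_equal(one, two)
        # finite-population sampling variance ratio (n=5 vs n=15) ~ 6.0
        v5 = np.var([bulk_family_genotype(fam, np.random.default_rng(i), 5)[0] for i in range(800)])
        v15 = np.var([bulk_family_genotype(fam, np.random.default_rng(i), 15)[0] for i in range(800)])
        assert 3.0 < v5 / v15 < 12.0


class TestSelection:
    def test_top_k_descending(self):
        scores = pd.Series({"a": 1.0, "b": 3.0, "c": 2.0})
        assert select_families(scores, 2) == ["b", "c"]

    def test_keep_all_is_identity(self):
        scores = pd.Series({"a": 1.0, "b": 3.0})
        assert set(select_families(scores, 2)) == {"a", "b"}

    def test_tie_break_lexicographic(self):
        scores = pd.Series({"z": 1.0, "b": 2.0, "a": 1.0})
        assert select_families(scores, 2) == ["b", "a"]

    def test_nan_scores_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            select_families(pd.Series({"a": np.nan, "b": 1.0}), 1)

    def test_published_plan_selection_intensities(self):
        """The published plan reproduces its printed intensity rows: 5% among
        and 12.6% within (selected basis) for the training cycle; 2.3%, 1.9%,
        2.0% within (sown basis) for the genomic cycles."""
        plan = full_scale_plan()
        sown = compute_selection_intensities(plan, within_basis="sown")
        sel = compute_selection_intensities(plan, within_basis="selected")
        assert sown.at["C0", "among"] == pytest.approx(0.05)
        assert sel.at["C0", "within"] == pytest.approx(0.1256, abs=5e-4)
        assert sel.at["C0", "total"] == pytest.approx(0.0060, abs=5e-4)
        assert sown.at["C1", "within"] == pytest.approx(0.0232, abs=5e-4)
        assert sown.at["C2", "within"] == pytest.approx(0.0193, abs=5e-4)
        assert sown.at["C3", "within"] == pytest.approx(0.0200, abs=5e-4)
        assert sown.at["C1", "among"] == pytest.approx(25 / 157)
        assert sown.at["C3", "among"] == pytest.approx(0.50)

    def test_operations_deterministic_under_fixed_seed(self, founder_panel):
        a = half_diallel(founder_panel.population, 1, np.random.default_rng(12))
        b = half_diallel(founder_panel.population, 1, np.random.default_rng(12))
        np.testing.assert_array_equal(a.haplotypes, b.haplotypes)
        assert a.meta.equals(b.meta)
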