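"""Kosman distances, PCoA fidelity, frequency-profile clustering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from popkit.diversity_stats import GroupFrequencyTable, allele_frequencies
from popkit.genotype_io import MISSING, UndefinedDistanceError
from popkit.pop_structure import (
    DistanceMatrix, hierarchical_pcoa, kosman_distance, maf_heatmap_cluster,
    pairwise_distances, pcoa,
)

from conftest import make_matrix


def brute_force_kosman(g1, g2):
    """Independent per-locus oracle: shared-allele counting on explicit pairs."""
    pairs = {0: ("A", "A"), 1: ("A", "B"), 2: ("B", "B")}
    sims = []
    for a, b in zip(g1, g2):
        if a == MISSING or b == MISSING:
            continue
        pa, pb = list(pairs[a]), list(pairs[b])
        shared = 0
        for allele in pa:
            if allele in pb:
                pb.remove(allele)
                shared += 1
        sims.append(shared / 2.0)
    if not sims:
        return None
    return 1.0 - float(np.mean(sims))


class TestKosman:
    def test_identical_homozygotes_zero(self):
        assert kosman_distance([0, 2, 0], [0, 2, 0]) == 0.0

    def test_opposite_homozygotes_one(self):
        assert kosman_distance([0, 0, 0], [2, 2, 2]) == 1.0

    def test_hom_vs_het_half(self):
        assert kosman_distance([0], [1]) == 0.5

    def test_het_vs_het_shares_both_alleles(self):
        assert kosman_distance([1, 1], [1, 1]) == 0.0

    def test_no_cocalled_raises(self):
        with pytest.raises(UndefinedDistanceError):
            kosman_distance([MISSING, 0], [1, MISSING])

    @settings(max_examples=100, deadline=None)
    @given(
        g1=st.lists(st.sampled_from([0, 1, 2, MISSING]), min_size=1, max_size=12),
        g2=st.lists(st.sampled_from([0, 1, 2, MISSING]), min_size=1, max_size=12),
    )
    def test_matches_oracle_and_is_symmetric(self, g1, g2):
        g2 = (g2 * len(g1))[: len(g1)]
        expected = brute_force_kosman(g1, g2)
        if expected is None:
            with pytest.raises(UndefinedDistanceError):
                kosman_distance(g1, g2)
            return
        d12 = kosman_distance(g1, g2)
        d21 = kosman_distance(g2, g1)
        assert d12 == pytest.approx(expected, abs=1e-12)
        assert d12 == d21
        # zero iff identical on co-called loci
        co = [(a, b) for a, b in zip(g1, g2) if MISSING not in (a, b)]
        assert (d12 == 0.0) == all(a == b for a, b in co)


class TestPairwise:
    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        calls = rng.choice([0, 1, 2, MISSING], size=(5, 30), p=[0.4, 0.15, 0.4, 0.05])
        m = make_matrix(calls)
        d = pairwise_distances(m)
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                expected = brute_force_kosman(calls[i], calls[j])
                assert d.d[i, j] == pytest.approx(expected, abs=1e-12)

    def test_duplicated_sample_distance_zero(self):
        m = make_matrix([[0, 1, 2], [0, 1, 2], [2, 1, 0]])
        d = pairwise_distances(m)
        assert d.d[0, 1] == 0.0

    def test_no_overlap_pair_is_nan(self):
        m = make_matrix([[0, MISSING], [MISSING, 2], [0, 2]])
        d = pairwise_distances(m)
        assert np.isnan(d.d[0, 1])
        assert np.isfinite(d.d[0, 2])


class TestPcoa:
    def test_planar_points_reproduced(self):
        """Distances from 10 points in the plane are recovered to 1e-8."""
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(10, 2))
        d = squareform(pdist(pts))
        res = pcoa(DistanceMatrix([f"p{i}" for i in range(10)], d), k=2)
        d_rec = squareform(pdist(res.coordinates))
        np.testing.assert_allclose(d_rec, d, atol=1e-8)
        assert res.negative_eigenvalue_mass < 1e-8
        assert np.all(np.diff(res.explained) <= 1e-12)

    def test_all_identical_gives_zero_coordinates(self):
        d = np.zeros((4, 4))
        res = pcoa(DistanceMatrix(list("abcd"), d), k=2)
        np.testing.assert_allclose(res.coordinates, 0.0, atol=1e-12)

    def test_two_clusters_separate_on_axis1(self):
        rng = np.random.default_rng(7)
        pts = np.vstack([rng.normal(0, 0.05, (6, 3)), rng.normal(1, 0.05, (6, 3))])
        d = squareform(pdist(pts))
        res = pcoa(DistanceMatrix([f"x{i}" for i in range(12)], d), k=2)
        a = res.coordinates[:6, 0]
        b = res.coordinates[6:, 0]
        # separation is sign-invariant
        assert max(a.max(), b.max()) > min(a.min(), b.min())
        assert (a.max() < b.min()) or (b.max() < a.min())

    def test_matches_skbio_reference(self):
        """Cross-check the embedding against scikit-bio's classical scaling."""
        from skbio import DistanceMatrix as SkbioDM
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(11)
        pts = rng.normal(size=(8, 3))
        d = squareform(pdist(pts))
        ours = pcoa(DistanceMatrix([f"s{i}" for i in range(8)], d), k=3)
        ref = skbio_pcoa(SkbioDM(d), dimensions=3)
        ref_coords = ref.samples.to_numpy()
        for axis in range(3):
            r = np.corrcoef(ours.coordinates[:, axis], ref_coords[:, axis])[0, 1]
            assert abs(abs(r) - 1.0) < 1e-8
        np.testing.assert_allclose(
            np.abs(ours.coordinates), np.abs(ref_coords), atol=1e-8
        )

    def test_k_too_large_raises(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError):
            pcoa(DistanceMatrix(list("abc"), d), k=3)


class TestHierarchical:
    def test_subset_of_two_raises(self):
        m = make_matrix([[0, 1], [1, 0], [2, 2]])
        with pytest.raises(ValueError):
            hierarchical_pcoa(m, ["s1", "s2"])

    def test_full_subset_equals_top_level(self):
        rng = np.random.default_rng(8)
        calls = rng.choice([0, 2], size=(12, 50), p=[0.5, 0.5]).astype(np.int8)
        m = make_matrix(calls)
        top = hierarchical_pcoa(m, list(m.samples), k=2, prune_r=1.01)
        from popkit.variant_filtering import select_structure_markers
        markers = select_structure_markers(m, prune_r=1.01)
        ref = pcoa(pairwise_distances(markers), k=2)
        np.testing.assert_allclose(top.coordinates, ref.coordinates, atol=1e-10)


class TestMafHeatmap:
    def _freq_table(self, p, groups):
        import pandas as pd
        n_loci = p.shape[1]
        loci = pd.DataFrame(
            {"chrom": ["chr1"] * n_loci, "pos": range(1, n_loci + 1),
             "ref": ["A"] * n_loci, "alt": ["G"] * n_loci, "qual": [50.0] * n_loci}
        )
        n = np.full(p.shape, 20)
        return GroupFrequencyTable(groups, loci, p, n)

    def test_identical_groups_adjacent(self):
        p = np.array([[0.1, 0.9, 0.5], [0.1, 0.9, 0.5], [0.9, 0.1, 0.2]])
        order, _, mat = maf_heatmap_cluster(self._freq_table(p, ["a", "b", "c"]))
        assert order.index("a") + order.index("b") in (1, 3)  # adjacent leaves
        assert mat.shape == (3, 3)

    def test_closest_profiles_pair_first(self):
        p = np.array([[0.1, 0.1, 0.1], [0.15, 0.1, 0.1], [0.9, 0.9, 0.9]])
        order, _, _ = maf_heatmap_cluster(self._freq_table(p, ["a", "b", "c"]))
        ia, ib, ic = order.index("a"), order.index("b"), order.index("c")
        assert abs(ia - ib) == 1  # a and b are the closest pair

    def test_single_group_identity(self):
        p = np.array([[0.2, 0.8]])
        order, _, mat = maf_heatmap_cluster(self._freq_table(p, ["only"]))
        assert order == ["only"] and mat.shape == (1, 2)
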