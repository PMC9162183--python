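"""Tier1 cascade, pericentromere regression, marker selection."""

import itertools

import numpy as np
import pytest

from popkit.genotype_io import MISSING
from popkit.synthetic_data import SimulationConfig, make_genetic_map
from popkit.variant_filtering import (
    FilterParams, PericentromereSet, create_tier1, dosage_correlation,
    fit_chromosome_breakpoints, fit_pericentromeres,
    load_packaged_pericentromeres, mask_pericentromeres,
    select_structure_markers,
)

from conftest import make_matrix


def five_locus_toy():
    """Five loci, each failing exactly one default filter except the last.

    locus 0: QUAL 40 (< 50)                     -> dropped by quality
    locus 1: 2/10 hets (obs het 0.2 > 0.1)      -> dropped by heterozygosity
    locus 2: 5/10 called (call rate 0.5 < 0.6)  -> dropped by call rate
    locus 3: minor allele in 2 samples (< 3)    -> dropped by carrier count
    locus 4: clean                              -> survives
    """
    M = MISSING
    calls = np.array([
        # l0 l1 l2 l3 l4
        [0, 1, 0, 2, 2],
        [0, 1, 0, 2, 2],
        [2, 0, 0, 0, 2],
        [2, 0, 0, 0, 0],
        [2, 0, 0, 0, 0],
        [0, 0, M, 0, 0],
        [0, 0, M, 0, 0],
        [0, 0, M, 0, 0],
        [0, 0, M, 0, 0],
        [0, 0, M, 0, 0],
    ], dtype=np.int8)
    return make_matrix(calls, qual=[40.0, 60.0, 60.0, 60.0, 60.0])


class TestTier1:
    def test_toy_keeps_only_the_clean_locus(self):
        out = create_tier1(five_locus_toy())
        assert out.loci["pos"].tolist() == [500]

    def test_trivial_params_are_identity(self):
        m = five_locus_toy()
        out = create_tier1(m, FilterParams(0.0, 1.0, 0.0, 0))
        np.testing.assert_array_equal(out.calls, m.calls)

    def test_idempotent(self):
        once = create_tier1(five_locus_toy())
        twice = create_tier1(once)
        np.testing.assert_array_equal(once.calls, twice.calls)

    def test_subfilters_order_independent(self):
        """Any permutation of the four single filters gives the same set."""
        m = five_locus_toy()
        singles = [
            FilterParams(50.0, 1.0, 0.0, 0),
            FilterParams(0.0, 0.1, 0.0, 0),
            FilterParams(0.0, 1.0, 0.6, 0),
            FilterParams(0.0, 1.0, 0.0, 3),
        ]
        reference = create_tier1(m)
        for perm in itertools.permutations(range(4)):
            out = m
            for i in perm:
                out = create_tier1(out, singles[i])
            assert out.loci["pos"].tolist() == reference.loci["pos"].tolist()

    def test_zero_loci_in_zero_out(self):
        m = make_matrix(np.zeros((3, 0), dtype=np.int8))
        assert create_tier1(m).n_loci == 0


class TestPericentromeres:
    def test_noiseless_breakpoints_exact(self):
        # slopes 2 / 0.05 / 2 cM/Mb with breaks at 10 and 40 Mb
        x = np.linspace(0, 60e6, 200)
        cm = np.where(
            x < 10e6, 2e-6 * x,
            np.where(x < 40e6, 20 + 0.05e-6 * (x - 10e6),
                     21.5 + 2e-6 * (x - 40e6)),
        )
        b1, b2, slopes = fit_chromosome_breakpoints(x, cm)
        assert abs(b1 - 10e6) < 1e5 and abs(b2 - 40e6) < 1e5
        np.testing.assert_allclose(slopes * 1e6, [2.0, 0.05, 2.0], atol=1e-3)

    def test_noisy_recovery_matches_grid_oracle(self):
        """With cM noise the fit lands within 2 Mb of truth and within the
        grid-search oracle's own tolerance."""
        rng = np.random.default_rng(1)
        x = np.sort(rng.uniform(0, 60e6, 200))
        cm = np.where(
            x < 10e6, 2e-6 * x,
            np.where(x < 40e6, 20 + 0.05e-6 * (x - 10e6),
                     21.5 + 2e-6 * (x - 40e6)),
        ) + rng.normal(0, 0.5, 200)
        b1, b2, _ = fit_chromosome_breakpoints(x, cm)
        assert abs(b1 - 10e6) < 2e6 and abs(b2 - 40e6) < 2e6
        # independent coarse oracle: exhaustive pair search on a fine grid
        def sse(a, b):
            design = np.column_stack(
                [np.ones_like(x), x, np.maximum(x - a, 0), np.maximum(x - b, 0)]
            )
            beta, *_ = np.linalg.lstsq(design, cm, rcond=None)
            return np.sum((cm - design @ beta) ** 2)
        grid = np.linspace(2e6, 58e6, 57)
        best = min(
            ((a, b) for a in grid for b in grid if a < b), key=lambda ab: sse(*ab)
        )
        assert abs(b1 - best[0]) < 2e6 and abs(b2 - best[1]) < 2e6

    def test_single_slope_yields_empty_interval(self, caplog):
        import pandas as pd
        x = np.linspace(0, 50e6, 100)
        mp = pd.DataFrame({"chrom": "chr1", "bp": x, "cM": 1.5e-6 * x})
        regions = fit_pericentromeres(mp)
        assert regions.intervals == {}

    def test_mask_halfopen_boundaries(self):
        m = make_matrix([[0, 1, 2, 0]], pos=[9, 10, 19, 20])
        out = mask_pericentromeres(m, PericentromereSet({"chr1": (10, 20)}))
        assert out.loci["pos"].tolist() == [9, 20]

    def test_empty_region_set_is_identity(self):
        m = make_matrix([[0, 1]])
        out = mask_pericentromeres(m, PericentromereSet({}))
        assert out.n_loci == 2

    def test_packaged_coordinates_hand_count(self):
        """The packaged pericentromere table applied to a hand-built matrix."""
        regions = load_packaged_pericentromeres()
        assert regions.intervals["chr1"] == (5488553, 74024604)
        assert regions.intervals["chr12"] == (5879033, 61255622)
        # chr1 interval is [5488553, 74024603] inclusive
        m = make_matrix(
            [[0, 1, 2, 0, 1]],
            chrom=["chr1"] * 5,
            pos=[5488552, 5488553, 40000000, 74024603, 74024604],
        )
        out = mask_pericentromeres(m, regions)
        assert out.loci["pos"].tolist() == [5488552, 74024604]

    def test_recovery_over_simulated_maps(self):
        """Mean absolute breakpoint error stays within 5% of the length."""
        rng = np.random.default_rng(42)
        cfg = SimulationConfig(n_chromosomes=1)
        errs = []
        for _ in range(10):
            lo, hi = rng.uniform(0.15, 0.35), rng.uniform(0.55, 0.8)
            gm = make_genetic_map(cfg, seed=int(rng.integers(2**31)), plateau=(lo, hi))
            b1, b2, _ = fit_chromosome_breakpoints(
                gm["bp"].to_numpy(float), gm["cM"].to_numpy(float)
            )
            L = cfg.chromosome_length
            errs += [abs(b1 - lo * L) / L, abs(b2 - hi * L) / L]
        assert np.mean(errs) <= 0.05


class TestStructureMarkers:
    def test_target_is_a_cap(self):
        rng = np.random.default_rng(4)
        base = np.array([0, 0, 0, 0, 2, 2, 2, 2, 1, 1], dtype=np.int8)
        calls = np.column_stack([rng.permutation(base) for _ in range(10)])
        m = make_matrix(calls)
        out = select_structure_markers(m, target_count=2000, prune_r=1.01)
        assert out.n_loci == 10

    def test_duplicated_adjacent_loci_collapse(self):
        col = np.array([0, 0, 0, 2, 2, 2, 0, 2, 0, 2], dtype=np.int8)
        calls = np.column_stack([col, col, 1 - 0 * col])
        calls[:, 2] = np.array([2, 0, 2, 0, 2, 0, 2, 0, 2, 0])
        m = make_matrix(calls)
        out = select_structure_markers(m, target_count=2000)
        # the two identical adjacent columns (r = 1) collapse to one
        assert out.n_loci == 2

    def test_even_grid_near_deciles(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 3, size=(12, 100)).astype(np.int8)
        pos = list(range(1000, 101000, 1000))
        m = make_matrix(calls, pos=pos)
        out = select_structure_markers(m, target_count=10, prune_r=1.01)
        got = np.array(out.loci["pos"])
        step = (pos[-1] - pos[0]) / 10
        ideal = pos[0] + (np.arange(10) + 0.5) * step
        assert len(got) == 10
        assert np.all(np.abs(got - ideal) <= step)

    def test_no_informative_markers_raises(self):
        m = make_matrix([[0, 0], [0, 0], [0, 0]])
        with pytest.raises(ValueError, match="no informative markers"):
            select_structure_markers(m)

    def test_no_consecutive_pair_above_prune_r(self):
        rng = np.random.default_rng(9)
        base = rng.integers(0, 3, size=(30, 1)).astype(np.int8)
        noisy = np.repeat(base, 40, axis=1)
        flip = rng.random(noisy.shape) < 0.1
        noisy[flip] = rng.integers(0, 3, size=int(flip.sum()))
        m = make_matrix(noisy)
        out = select_structure_markers(m, target_count=2000, prune_r=0.95)
        for j in range(1, out.n_loci):
            r = dosage_correlation(out.calls[:, j - 1], out.calls[:, j])
            assert not (np.isfinite(r) and abs(r) > 0.95)
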