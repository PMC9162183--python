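"""Generator determinism, frequency recovery, map shapes, truth scoring."""

import numpy as np
import pytest

from popkit.diversity_stats import group_diversity
from popkit.genotype_io import MISSING, write_vcf
from popkit.group_distances import pairwise_dest
from popkit.synthetic_data import (
    SimulationConfig, SyntheticTruth, drift_frequencies, make_genetic_map,
    sample_inbred_genotypes, simulate_collection, truth_report,
)

from conftest import make_matrix, small_sim_config


class TestDeterminism:
    def test_same_seed_identical_vcf_bytes(self, tmp_path, small_config):
        a = simulate_collection(small_config, seed=5)
        b = simulate_collection(small_config, seed=5)
        pa, pb = tmp_path / "a.vcf", tmp_path / "b.vcf"
        write_vcf(a.matrix, str(pa))
        write_vcf(b.matrix, str(pb))
        assert pa.read_bytes() == pb.read_bytes()
        assert a.traits.equals(b.traits)
        assert a.truth.introgressions == b.truth.introgressions

    def test_different_seeds_differ(self, small_config):
        a = simulate_collection(small_config, seed=5)
        b = simulate_collection(small_config, seed=6)
        assert not np.array_equal(a.matrix.calls, b.matrix.calls)


class TestDriftModel:
    def test_no_drift_limit_dest_near_zero(self):
        """F -> 0: replicate demes have (almost) identical frequencies."""
        rng = np.random.default_rng(1)
        p_anc = rng.uniform(0.2, 0.8, 2000)
        a = drift_frequencies(p_anc, 0.001, rng)
        b = drift_frequencies(p_anc, 0.001, rng)
        assert pairwise_dest(a, b) < 0.005

    def test_beta_mean_and_variance(self):
        rng = np.random.default_rng(2)
        p = drift_frequencies(np.full(200_000, 0.3), 0.2, rng)
        assert p.mean() == pytest.approx(0.3, abs=0.005)
        assert p.var() == pytest.approx(0.3 * 0.7 * 0.2, rel=0.05)

    def test_law_of_large_numbers(self):
        """Realised sample frequencies converge to the truth as n grows."""
        rng = np.random.default_rng(3)
        p = rng.uniform(0.1, 0.9, 500)
        errs = []
        for n in (50, 800):
            g = sample_inbred_genotypes(p, n, 0.95, rng)
            errs.append(np.abs(g.mean(axis=0) / 2.0 - p).mean())
        assert errs[1] < errs[0] / 2.5  # ~ 1/sqrt(16) ideally


@pytest.fixture(scope="module")
def default_run():
    return simulate_collection(seed=2)


class TestCollectionShape:
    def test_traditional_percent_polymorphic_contrast(self, default_run):
        """Traditional %P(0.95) sits below 5% while wild exceeds 30%."""
        res = default_run
        gd = group_diversity(res.matrix, res.samples.groups("group_rank1"))
        gd = gd.set_index("group")
        assert gd.loc["traditional", "pct_polymorphic"] < 5.0
        assert gd.loc["wild", "pct_polymorphic"] > 30.0

    def test_traditional_maf_mass_near_fixation(self, default_run):
        """Most traditional variants are almost fixed (lowest MAF bin)."""
        from popkit.diversity_stats import allele_frequencies, maf_spectrum
        res = default_run
        grouping = {"traditional": res.samples.samples_with_status("traditional")}
        spec = maf_spectrum(allele_frequencies(res.matrix, grouping), bins=20)
        share = spec["count"].iloc[0] / spec["count"].sum()
        assert share > 0.8

    def test_expected_he_close_to_realised(self, default_run):
        res = default_run
        gd = group_diversity(res.matrix, res.samples.groups("group_rank1"))
        gd = gd.set_index("group")
        for stratum in ("wild", "semidom", "traditional", "modern"):
            expected = res.truth.expected_he(stratum, n_draw=None)
            group = "semidom" if stratum == "semidom" else stratum
            assert gd.loc[group, "he_all"] == pytest.approx(expected, rel=0.08)

    def test_modern_samples_carry_blocks(self, default_run):
        truth = default_run.truth
        moderns = [s for s, st in truth.strata.items() if st == "modern"]
        assert all(len(truth.introgressions[s]) == 3 for s in moderns)
        # backbone blocks are shared by every modern sample
        backbone = set(truth.donor_blocks[:2])
        for s in moderns:
            assert backbone <= set(truth.introgressions[s])

    def test_missingness_near_configured_rate(self, default_run):
        res = default_run
        rate = (res.matrix.calls == MISSING).mean()
        assert rate == pytest.approx(res.truth.expected_missing(), abs=0.005)


class TestGeneticMap:
    def test_zero_noise_breakpoints_exact(self):
        cfg = SimulationConfig(n_chromosomes=2)
        gm = make_genetic_map(cfg, noise_sd_cm=0.0, plateau=(0.3, 0.6))
        one = gm[gm.chrom == "chr01"]
        x = one.bp.to_numpy(float)
        cm = one.cM.to_numpy(float)
        slopes = np.diff(cm) / np.diff(x)
        changes = np.flatnonzero(np.abs(np.diff(slopes)) > 1e-9)
        # slope changes bracket the configured breakpoints
        L = cfg.chromosome_length
        assert x[changes[0] + 1] <= 0.3 * L + L / 39 + 1
        assert x[changes[-1] + 1] >= 0.6 * L - L / 39 - 1

    def test_zero_length_plateau_single_slope(self):
        cfg = SimulationConfig(n_chromosomes=1)
        gm = make_genetic_map(cfg, noise_sd_cm=0.0, plateau=(0.5, 0.5))
        x = gm.bp.to_numpy(float)
        cm = gm.cM.to_numpy(float)
        slopes = np.diff(cm) / np.diff(x)
        # bp values are rounded to integers, so allow that quantisation
        np.testing.assert_allclose(slopes, slopes[0], rtol=1e-4)


class TestTruth:
    def test_json_roundtrip(self, tmp_path, small_config):
        res = simulate_collection(small_config, seed=9)
        p = tmp_path / "truth.json"
        res.truth.to_json(str(p))
        back = SyntheticTruth.from_json(str(p))
        assert back.strata == res.truth.strata
        assert back.causal == res.truth.causal
        assert back.introgressions == res.truth.introgressions
        np.testing.assert_allclose(
            back.stratum_freqs["wild"], res.truth.stratum_freqs["wild"]
        )
        assert back.config.n_loci == small_config.n_loci

    def test_perfect_outputs_score_one(self, small_config):
        import pandas as pd
        res = simulate_collection(small_config, seed=9)
        truth = res.truth
        rec = pd.DataFrame(
            {
                "sample": list(truth.strata),
                "proposed_status": [
                    "modern-like" if truth.introgressions[s] else "consistent"
                    for s in truth.strata
                ],
            }
        )
        rep = truth_report(truth, reclassification=rec)
        assert rep["introgression_sensitivity"] == 1.0
        assert rep["introgression_specificity"] == 1.0

    def test_shuffled_labels_score_at_chance(self, small_config):
        """Negative control: permuted PCoA coordinates lose separation."""
        res = simulate_collection(small_config, seed=9)
        truth = res.truth
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(len(truth.strata), 3))
        rep = truth_report(
            truth, pcoa_labels=list(truth.strata), pcoa_coords=coords
        )
        assert rep["stratum_separation"] < 0.7

    def test_identifier_mismatch_raises(self, small_config):
        res = simulate_collection(small_config, seed=9)
        with pytest.raises(ValueError):
            truth_report(
                res.truth,
                pcoa_labels=["ghost"],
                pcoa_coords=np.zeros((1, 2)),
            )


def test_infeasible_config_rejected():
    with pytest.raises(ValueError, match="block"):
        SimulationConfig(block_length=80_000_000).validate()
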