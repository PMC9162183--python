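"""Shared fixtures: tiny hand-built matrices and scaled-down simulations."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from popkit.genotype_io import GenotypeMatrix
from popkit.synthetic_data import SimulationConfig

DATA = Path(__file__).parent / "data"


def make_matrix(
    calls,
    pos=None,
    chrom=None,
    qual=None,
    samples=None,
    gq=None,
) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a 2D call list (samples x loci)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    pos = list(pos) if pos is not None else list(range(100, 100 + 100 * m, 100))
    chrom = list(chrom) if chrom is not None else ["chr1"] * m
    qual = list(qual) if qual is not None else [100.0] * m
    samples = samples or [f"s{i+1}" for i in range(n)]
    loci = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "ref": ["A"] * m, "alt": ["G"] * m, "qual": qual}
    )
    gq_arr = np.asarray(gq, dtype=np.float32) if gq is not None else None
    return GenotypeMatrix(samples, loci, calls, gq_arr)


@pytest.fixture
def fixture_vcf() -> str:
    return str(DATA / "fixture.vcf")


@pytest.fixture
def fixture_samples_tsv() -> str:
    return str(DATA / "fixture_samples.tsv")


def small_sim_config(**overrides) -> SimulationConfig:
    """A scaled-down collection for fast end-to-end tests.

    Keeps the default stratum proportions and locus density per Mb while
    shrinking the genome and sample counts.
    """
    params = dict(
        n_wild=15,
        n_semidom=15,
        n_traditional=60,
        n_modern=20,
        n_chromosomes=4,
        chromosome_length=30_000_000,
        n_loci=4_000,
        n_polymorphic=80,
        n_donor_blocks=4,
        n_backbone_blocks=2,
        blocks_per_sample=3,
        block_length=4_000_000,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return small_sim_config()
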