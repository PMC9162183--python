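"""Synthetic genotype collections emulating a low-diversity crop germplasm.

The generator produces a four-stratum collection shaped like a traditional
tomato germplasm panel:

* **wild** — high-diversity outgroup; locus frequencies drift from a shared
  ancestral distribution under the Balding–Nichols F-model
  (p' ~ Beta(p(1-F)/F, (1-p)(1-F)/F)) with a small F.
* **semi-domesticated** — the same model with a larger F (stronger drift).
* **traditional** — a near-desert of variation: almost every locus is fixed
  on the drifted major allele with only singleton-scale private variants
  (minor frequency ~ U(eps_lo, eps_hi), realised as heterozygous carriers),
  plus a small number of clustered, common polymorphic loci ("diversity-rich
  islands").  Genotypes at the polymorphic loci are built from a small pool
  of founder haplotypes by segmental mosaic inheritance, which creates the
  long-range haplotype blocks a real landrace panel shows; traditional
  sub-groups differ in their founder-usage weights, giving the
  group-differentiated frequencies the distance and heatmap analyses need.
* **modern** — traditional-like genomes carrying discrete homozygous donor
  introgression blocks (divergent fixed alleles) pasted at recorded
  intervals, emulating wild-species introgressions in modern cultivars.

Samples are drawn as (mostly) selfed diploids: the two gametes of a sample
are identical with probability ``inbreeding`` (tomato is autogamous), so
observed heterozygosity stays low enough for the standard GBS het filter to
make sense.  Traits are linear in the dosages of designated causal loci
(drawn from the traditional polymorphic set) plus Gaussian noise; binary
traits threshold the liability.  All randomness flows from the single seed.

The ground truth (strata, frequencies, introgressed intervals, causal loci,
closed-form He expectations) is returned alongside the data so recovery can
be scored without re-deriving anything.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, MISSING, SampleTable

logger = logging.getLogger("popkit")

STRATA = ("wild", "semidom", "traditional", "modern")


@dataclass
class TraitSpec:
    """One simulated trait: causal-locus effects plus Gaussian noise.

    ``effects`` are in residual-SD units when ``noise_sd`` is 1.  The
    ``transform`` makes the raw quantitative scale skewed (``exp``) or
    leaves it linear; binary traits threshold the liability at its median.
    """

    name: str
    kind: str = "quantitative"  # or "binary"
    effects: tuple[float, ...] = (1.0,)
    noise_sd: float = 1.0
    transform: str = "linear"  # or "exp"
    offset: float = 10.0


def default_traits() -> list[TraitSpec]:
    return [
        TraitSpec("fruit_weight", "quantitative", (1.0, 0.6), 1.0, "exp", 0.0),
        TraitSpec("locule_number", "quantitative", (1.0,), 1.0, "linear", 10.0),
        TraitSpec("pink_skin", "binary", (2.0,), 1.0, "linear", 0.0),
    ]


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic collection.

    Defaults are sized for desk scale (400 samples x 20 000 loci x 12
    chromosomes) and emulate the diversity contrasts of a European
    traditional crop collection: wild >> semi-domesticated >> modern >
    traditional.
    """

    # collection layout
    n_wild: int = 40
    n_semidom: int = 40
    n_traditional: int = 240
    n_modern: int = 80
    n_chromosomes: int = 12
    chromosome_length: int = 65_000_000
    n_loci: int = 20_000

    # frequency model
    ancestral_low: float = 0.05
    ancestral_high: float = 0.95
    f_wild: float = 0.1
    f_semidom: float = 0.3
    f_traditional: float = 0.3  # drift before near-fixation is imposed
    inbreeding: float = 0.95  # per-sample selfing coefficient

    # traditional near-fixation and residual polymorphism
    n_polymorphic: int = 300
    polymorphic_cluster_size: int = 10  # consecutive loci per island
    polymorphic_maf_low: float = 0.1
    polymorphic_maf_high: float = 0.5
    rare_minor_low: float = 0.005
    rare_minor_high: float = 0.02

    # founder-mosaic model for traditional/modern genomes
    n_founders: int = 8
    founder_switch_rate: float = 3e-6  # per bp per gamete
    n_traditional_groups: int = 6
    founder_weight_concentration: float = 3.0

    # introgressions carried by the modern stratum: a backbone of blocks
    # shared by every modern sample (the near-universal resistance-gene
    # introgressions of real modern cultivars) plus variable blocks drawn
    # per sample from the rest of the catalog
    n_donor_blocks: int = 6  # catalog size
    n_backbone_blocks: int = 2
    blocks_per_sample: int = 3
    block_length: int = 5_000_000

    # noise layers
    missing_rate: float = 0.03
    low_callrate_fraction: float = 0.01
    low_callrate_missing: float = 0.55
    low_qual_fraction: float = 0.01
    low_gq_rate: float = 0.02  # calls whose GQ falls below the mask threshold

    traits: list[TraitSpec] = field(default_factory=default_traits)

    def stratum_sizes(self) -> dict[str, int]:
        return {
            "wild": self.n_wild,
            "semidom": self.n_semidom,
            "traditional": self.n_traditional,
            "modern": self.n_modern,
        }

    def validate(self) -> None:
        if min(self.stratum_sizes().values()) <= 0:
            raise ValueError("stratum sizes must be positive")
        if not 0 < self.f_wild < 1 or not 0 < self.f_semidom < 1:
            raise ValueError("drift parameters must lie in (0, 1)")
        if self.block_length >= self.chromosome_length:
            raise ValueError("introgression blocks longer than a chromosome")
        if self.n_donor_blocks > self.n_chromosomes:
            raise ValueError("at most one donor block per chromosome")
        if not 0 <= self.n_backbone_blocks <= self.blocks_per_sample:
            raise ValueError("backbone blocks must not exceed blocks per sample")
        if self.blocks_per_sample > self.n_donor_blocks:
            raise ValueError("blocks per sample exceeds the donor catalog")
        if self.n_polymorphic > self.n_loci // 2:
            raise ValueError("too many polymorphic loci requested")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated collection."""

    seed: int
    strata: dict[str, str]  # sample -> stratum
    subgroup: dict[str, str]  # traditional-like samples -> rank2 group
    stratum_freqs: dict[str, np.ndarray]  # alt-allele frequency per locus
    polymorphic_idx: np.ndarray
    causal: dict[str, list[tuple[int, float]]]  # trait -> (locus index, effect)
    introgressions: dict[str, list[tuple[str, int, int]]]  # sample -> intervals
    donor_blocks: list[tuple[str, int, int]]
    config: SimulationConfig

    def expected_missing(self) -> float:
        c = self.config
        base = c.missing_rate
        boosted = c.low_callrate_fraction * (c.low_callrate_missing - base)
        return base + boosted

    def expected_he(self, stratum: str, n_draw: int | None = None) -> float:
        """Closed-form expectation of mean He over all loci.

        Includes the founder-quantisation factor (1 - 1/K), the
        founder-weight dispersion factor, and — when ``n_draw`` is given —
        the plug-in bias factor of frequencies estimated from n samples
        under the configured selfing coefficient.
        """
        c = self.config
        m = self.expected_missing()

        def plugin(f_equiv: float) -> float:
            if n_draw is None:
                return 1.0
            n_eff = n_draw * (1.0 - m)
            return 1.0 - (1.0 + f_equiv) / (2.0 * n_eff)

        a, b = c.ancestral_low, c.ancestral_high
        mean_p = (a + b) / 2.0
        var_p = (b - a) ** 2 / 12.0
        e_pq_anc = mean_p - var_p - mean_p**2

        if stratum == "wild":
            return 2.0 * e_pq_anc * (1.0 - c.f_wild) * plugin(c.inbreeding)
        if stratum == "semidom":
            return 2.0 * e_pq_anc * (1.0 - c.f_semidom) * plugin(c.inbreeding)

        frac_poly = c.n_polymorphic / c.n_loci
        qa, qb = c.polymorphic_maf_low, c.polymorphic_maf_high
        k = c.n_founders
        # founder allele counts are Binomial(K, q) conditioned on 1..K-1:
        # E[2 (j/K)(1-j/K)] = (1 - 1/K) q(1-q) / P(1 <= j <= K-1), then
        # averaged over q ~ U(qa, qb) numerically
        qs = np.linspace(qa, qb, 2001)
        p_keep = 1.0 - qs**k - (1.0 - qs) ** k
        e_qq = float(np.mean(qs * (1.0 - qs) / p_keep))
        dirichlet_shrink = 1.0 - 1.0 / (
            (c.founder_weight_concentration * k + 1.0) * c.n_traditional_groups
        )
        common = 2.0 * e_qq * (1.0 - 1.0 / k) * dirichlet_shrink * plugin(c.inbreeding)

        ea, eb = c.rare_minor_low, c.rare_minor_high
        e_eps = (ea + eb) / 2.0
        e_eps2 = (ea**2 + ea * eb + eb**2) / 3.0
        # rare carriers are single heterozygotes: plug-in factor with F = 0
        rare = 2.0 * (e_eps - e_eps2) * plugin(0.0)
        he_trad = frac_poly * common + (1.0 - frac_poly) * rare
        if stratum == "traditional":
            return he_trad
        if stratum == "modern":
            genome = c.n_chromosomes * c.chromosome_length
            per_block = c.block_length / genome
            frac_backbone = c.n_backbone_blocks * per_block
            n_var = c.n_donor_blocks - c.n_backbone_blocks
            frac_var = n_var * per_block
            pv = (c.blocks_per_sample - c.n_backbone_blocks) / n_var if n_var else 0.0
            # homozygous block presence ~ Bernoulli(pv): F-equivalent 1;
            # backbone blocks are fixed donor, He 0
            he_var = 2.0 * pv * (1.0 - pv) * plugin(1.0)
            return (
                (1.0 - frac_backbone - frac_var) * he_trad + frac_var * he_var
            )
        raise KeyError(f"unknown stratum {stratum!r}")

    def introgressed_samples(self) -> set[str]:
        return {s for s, blocks in self.introgressions.items() if blocks}

    def to_json(self, path: str) -> None:
        payload = {
            "seed": self.seed,
            "strata": self.strata,
            "subgroup": self.subgroup,
            "stratum_freqs": {k: v.tolist() for k, v in self.stratum_freqs.items()},
            "polymorphic_idx": self.polymorphic_idx.tolist(),
            "causal": self.causal,
            "introgressions": self.introgressions,
            "donor_blocks": self.donor_blocks,
            "config": {
                **{k: v for k, v in asdict(self.config).items() if k != "traits"},
                "traits": [asdict(t) for t in self.config.traits],
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        cfg_d = payload["config"]
        cfg_d["traits"] = [TraitSpec(**t) for t in cfg_d["traits"]]
        return cls(
            seed=payload["seed"],
            strata=payload["strata"],
            subgroup=payload["subgroup"],
            stratum_freqs={k: np.asarray(v) for k, v in payload["stratum_freqs"].items()},
            polymorphic_idx=np.asarray(payload["polymorphic_idx"], dtype=int),
            causal={k: [(int(i), float(e)) for i, e in v] for k, v in payload["causal"].items()},
            introgressions={
                k: [(c, int(s), int(e)) for c, s, e in v]
                for k, v in payload["introgressions"].items()
            },
            donor_blocks=[(c, int(s), int(e)) for c, s, e in payload["donor_blocks"]],
            config=SimulationConfig(**cfg_d),
        )


@dataclass
class SimulationResult:
    matrix: GenotypeMatrix
    samples: SampleTable
    genetic_map: pd.DataFrame
    traits: pd.DataFrame
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# building blocks


def drift_frequencies(p_anc: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    """Balding–Nichols drifted frequencies around ancestral values."""
    theta = (1.0 - f) / f
    return rng.beta(np.maximum(p_anc * theta, 1e-9), np.maximum((1 - p_anc) * theta, 1e-9))


def sample_inbred_genotypes(
    p: np.ndarray, n: int, inbreeding: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw n diploid dosage rows from allele frequencies with selfing.

    With probability ``inbreeding`` the two gametes of a sample are copies
    of a single allele draw (homozygote), otherwise independent draws.
    """
    a1 = (rng.random((n, len(p))) < p).astype(np.int8)
    a2 = (rng.random((n, len(p))) < p).astype(np.int8)
    selfed = rng.random((n, len(p))) < inbreeding
    a2 = np.where(selfed, a1, a2)
    return (a1 + a2).astype(np.int8)


def _mosaic_founder_path(
    pos: np.ndarray, length: int, weights: np.ndarray, rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Founder id per locus position for one gamete on one chromosome."""
    n_switch = rng.poisson(rate * length)
    cuts = np.sort(rng.uniform(0, length, size=n_switch))
    founders = rng.choice(len(weights), size=n_switch + 1, p=weights)
    return founders[np.searchsorted(cuts, pos)]


def _layout_loci(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    per_chrom = np.full(config.n_chromosomes, config.n_loci // config.n_chromosomes)
    per_chrom[: config.n_loci % config.n_chromosomes] += 1
    chroms, poss = [], []
    for c in range(config.n_chromosomes):
        m = per_chrom[c]
        # sorted draws plus an index offset guarantee strictly increasing ints
        raw = np.sort(rng.random(m)) * (config.chromosome_length - m)
        pos = raw.astype(np.int64) + np.arange(m) + 1
        chroms.extend([f"chr{c + 1:02d}"] * m)
        poss.append(pos)
    return pd.DataFrame({"chrom": chroms, "pos": np.concatenate(poss)})


# ---------------------------------------------------------------------------
# the generator


def simulate_collection(
    config: SimulationConfig | None = None, seed: int = 0
) -> SimulationResult:
    """Simulate the full collection, metadata, map, traits, and truth.

    Identical seeds give bit-identical outputs.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    loci = _layout_loci(config, rng)
    L = len(loci)
    chrom_arr = loci["chrom"].to_numpy()
    pos_arr = loci["pos"].to_numpy()

    p_anc = rng.uniform(config.ancestral_low, config.ancestral_high, L)
    p_wild = drift_frequencies(p_anc, config.f_wild, rng)
    p_semidom = drift_frequencies(p_anc, config.f_semidom, rng)
    p_drift = drift_frequencies(p_anc, config.f_traditional, rng)

    # traditional locus classes: clustered common polymorphic islands +
    # near-fixed remainder with singleton-scale private minors
    n_clusters = max(config.n_polymorphic // config.polymorphic_cluster_size, 1)
    cluster_size = config.polymorphic_cluster_size
    starts = rng.choice(L - cluster_size, size=n_clusters * 4, replace=False)
    poly_idx: list[int] = []
    taken = np.zeros(L, dtype=bool)
    for s in np.sort(starts):
        run = np.arange(s, s + cluster_size)
        if len(poly_idx) >= config.n_polymorphic:
            break
        if taken[run].any() or len(np.unique(chrom_arr[run])) > 1:
            continue
        taken[run] = True
        poly_idx.extend(run.tolist())
    poly_idx = np.asarray(poly_idx[: config.n_polymorphic], dtype=int)
    is_poly = np.zeros(L, dtype=bool)
    is_poly[poly_idx] = True

    fixed_allele = (p_drift >= 0.5).astype(np.int8)
    eps = rng.uniform(config.rare_minor_low, config.rare_minor_high, L)
    q_common = rng.uniform(config.polymorphic_maf_low, config.polymorphic_maf_high, L)
    p_trad = np.where(
        fixed_allele == 1, 1.0 - eps, eps
    )  # alt-allele frequency at near-fixed loci
    p_trad[poly_idx] = np.where(
        fixed_allele[poly_idx] == 1, 1.0 - q_common[poly_idx], q_common[poly_idx]
    )

    # founder haplotypes over the polymorphic loci (elsewhere = fixed allele);
    # the alt-allele count per locus is Binomial(K, p) conditioned on
    # 1..K-1 so every island locus truly segregates in the founder pool
    K = config.n_founders
    p_poly = p_trad[poly_idx]
    k_counts = rng.binomial(K, p_poly)
    stuck = (k_counts == 0) | (k_counts == K)
    while stuck.any():
        k_counts[stuck] = rng.binomial(K, p_poly[stuck])
        stuck = (k_counts == 0) | (k_counts == K)
    founder_alleles = np.zeros((K, len(poly_idx)), dtype=np.int8)
    for j, k in enumerate(k_counts):
        founder_alleles[rng.permutation(K)[:k], j] = 1
    group_weights = rng.dirichlet(
        np.full(K, config.founder_weight_concentration), size=config.n_traditional_groups
    )

    # donor introgression catalog: one block on each of the first chromosomes
    donor_allele = 1 - fixed_allele
    donor_blocks: list[tuple[str, int, int]] = []
    for b in range(config.n_donor_blocks):
        chrom = f"chr{b + 1:02d}"
        start = int(rng.integers(1, config.chromosome_length - config.block_length))
        donor_blocks.append((chrom, start, start + config.block_length))

    sizes = config.stratum_sizes()
    sample_ids: list[str] = []
    strata: dict[str, str] = {}
    subgroup: dict[str, str] = {}
    calls = np.zeros((sum(sizes.values()), L), dtype=np.int8)
    introgressions: dict[str, list[tuple[str, int, int]]] = {}

    row = 0
    prefix = {"wild": "W", "semidom": "S", "traditional": "T", "modern": "M"}
    chrom_lengths = {f"chr{c + 1:02d}": config.chromosome_length for c in range(config.n_chromosomes)}
    poly_pos_by_chrom = {
        c: (np.flatnonzero(is_poly & (chrom_arr == c)), pos_arr[is_poly & (chrom_arr == c)])
        for c in chrom_lengths
    }

    def traditional_like_genome(weights: np.ndarray) -> np.ndarray:
        g = (2 * fixed_allele).astype(np.int8).copy()
        for chrom, (idx, ppos) in poly_pos_by_chrom.items():
            if len(idx) == 0:
                continue
            path1 = _mosaic_founder_path(
                ppos, chrom_lengths[chrom], weights, config.founder_switch_rate, rng
            )
            local = np.searchsorted(poly_idx, idx)
            gam1 = founder_alleles[path1, local]
            if rng.random() < config.inbreeding:
                gam2 = gam1
            else:
                path2 = _mosaic_founder_path(
                    ppos, chrom_lengths[chrom], weights, config.founder_switch_rate, rng
                )
                gam2 = founder_alleles[path2, local]
            g[idx] = gam1 + gam2
        # private rare variants: heterozygous carriers at near-fixed loci
        rare_mask = ~is_poly & (rng.random(L) < 2.0 * eps)
        g[rare_mask] = 1
        return g

    for stratum in STRATA:
        n = sizes[stratum]
        if stratum == "wild":
            calls[row:row + n] = sample_inbred_genotypes(p_wild, n, config.inbreeding, rng)
        elif stratum == "semidom":
            calls[row:row + n] = sample_inbred_genotypes(p_semidom, n, config.inbreeding, rng)
        for i in range(n):
            sid = f"{prefix[stratum]}{i + 1:04d}"
            sample_ids.append(sid)
            strata[sid] = stratum
            if stratum in ("traditional", "modern"):
                g_idx = int(rng.integers(config.n_traditional_groups))
                subgroup[sid] = f"trad_g{g_idx + 1}"
                g = traditional_like_genome(group_weights[g_idx])
                if stratum == "modern":
                    n_bb = config.n_backbone_blocks
                    variable = rng.choice(
                        np.arange(n_bb, config.n_donor_blocks),
                        size=config.blocks_per_sample - n_bb, replace=False,
                    )
                    chosen = np.concatenate([np.arange(n_bb), variable])
                    blocks = [donor_blocks[b] for b in sorted(chosen)]
                    introgressions[sid] = blocks
                    for chrom, start, end in blocks:
                        in_block = (chrom_arr == chrom) & (pos_arr >= start) & (pos_arr < end)
                        g[in_block] = (2 * donor_allele[in_block]).astype(np.int8)
                else:
                    introgressions[sid] = []
                calls[row + i] = g
            else:
                subgroup[sid] = stratum
                introgressions[sid] = []
        row += n

    n_samples = len(sample_ids)

    # traits before masking, from true dosages
    traits = _simulate_traits(config, calls, poly_idx, n_clusters, cluster_size, rng)
    causal = traits.pop("_causal")
    trait_df = pd.DataFrame(traits, index=pd.Index(sample_ids, name="sample"))

    # missingness and genotype/site qualities
    miss_rate = np.full(L, config.missing_rate)
    low_cr = rng.random(L) < config.low_callrate_fraction
    miss_rate[low_cr] = config.low_callrate_missing
    missing = rng.random((n_samples, L)) < miss_rate
    calls[missing] = MISSING
    gq = rng.integers(6, 61, size=(n_samples, L)).astype(np.float32)
    low_gq = rng.random((n_samples, L)) < config.low_gq_rate
    gq[low_gq] = rng.integers(0, 5, size=int(low_gq.sum())).astype(np.float32)
    gq[missing] = np.nan
    qual = rng.uniform(50.0, 3000.0, L)
    low_q = rng.random(L) < config.low_qual_fraction
    qual[low_q] = rng.uniform(10.0, 49.9, size=int(low_q.sum()))

    ref = np.asarray(["A"] * L)
    alt = np.asarray(["G"] * L)
    loci_df = pd.DataFrame(
        {
            "chrom": chrom_arr,
            "pos": pos_arr,
            "ref": ref,
            "alt": alt,
            "qual": np.round(qual, 2),
        }
    )
    matrix = GenotypeMatrix(sample_ids, loci_df, calls, gq)

    countries = {"wild": "PER", "semidom": "MEX", "modern": "NLD"}
    trad_country = ["ESP", "ITA", "GRC", "FRA", "ESP", "ITA"]
    rows = []
    for sid in sample_ids:
        st = strata[sid]
        if st == "traditional":
            gi = int(subgroup[sid].split("_g")[1]) - 1
            country = trad_country[gi % len(trad_country)]
        else:
            country = countries.get(st, "UNK")
        rows.append(
            {
                "sample": sid,
                "status": "SLC" if st == "semidom" else st,
                "country": country,
                "group_rank1": st,
                "group_rank2": subgroup[sid],
            }
        )
    sample_table = SampleTable(pd.DataFrame(rows))

    genetic_map = make_genetic_map(config, seed=int(rng.integers(2**31)))

    # expected modern alt frequencies per locus: donor-fixed in backbone
    # blocks, donor at the per-sample presence probability in variable blocks
    p_modern = p_trad.copy()
    n_var = config.n_donor_blocks - config.n_backbone_blocks
    pv = (config.blocks_per_sample - config.n_backbone_blocks) / n_var if n_var else 0.0
    for b, (chrom, start, end) in enumerate(donor_blocks):
        in_block = (chrom_arr == chrom) & (pos_arr >= start) & (pos_arr < end)
        presence = 1.0 if b < config.n_backbone_blocks else pv
        p_modern[in_block] = (
            presence * donor_allele[in_block]
            + (1.0 - presence) * p_trad[in_block]
        )
    truth = SyntheticTruth(
        seed=seed,
        strata=strata,
        subgroup=subgroup,
        stratum_freqs={
            "wild": p_wild, "semidom": p_semidom,
            "traditional": p_trad, "modern": p_modern,
        },
        polymorphic_idx=poly_idx,
        causal=causal,
        introgressions=introgressions,
        donor_blocks=donor_blocks,
        config=config,
    )
    logger.info(
        "simulate_collection: %d samples x %d loci (seed %d)", n_samples, L, seed
    )
    return SimulationResult(matrix, sample_table, genetic_map, trait_df, truth)


def _simulate_traits(
    config: SimulationConfig,
    calls: np.ndarray,
    poly_idx: np.ndarray,
    n_clusters: int,
    cluster_size: int,
    rng: np.random.Generator,
) -> dict:
    """Trait columns plus the causal-locus map (under key ``_causal``)."""
    out: dict = {}
    causal: dict[str, list[tuple[int, float]]] = {}
    # one candidate causal locus per island, so causal loci are unlinked
    n_islands = len(poly_idx) // cluster_size
    island_reps = [int(poly_idx[i * cluster_size + cluster_size // 2]) for i in range(n_islands)]
    pool = list(island_reps)
    for spec in config.traits:
        chosen = []
        for e in spec.effects:
            if not pool:
                raise ValueError("not enough polymorphic islands for causal loci")
            locus = pool.pop(0)
            chosen.append((locus, float(e)))
        causal[spec.name] = chosen
        dose = calls[:, [l for l, _ in chosen]].astype(float)
        liability = dose @ np.array([e for _, e in chosen])
        liability = liability + rng.normal(0.0, spec.noise_sd, size=len(liability))
        if spec.kind == "binary":
            out[spec.name] = (liability > np.median(liability)).astype(int)
        elif spec.transform == "exp":
            out[spec.name] = np.exp(0.5 * (liability - liability.mean()))
        else:
            out[spec.name] = liability + spec.offset
    out["_causal"] = causal
    return out


def make_genetic_map(
    config: SimulationConfig | None = None,
    seed: int | None = None,
    points_per_chromosome: int = 40,
    arm_slope_cm_per_mb: float = 2.5,
    plateau_slope_cm_per_mb: float = 0.05,
    plateau: tuple[float, float] = (0.25, 0.70),
    noise_sd_cm: float = 0.5,
) -> pd.DataFrame:
    """Simulate a genetic map with a low-recombination plateau per chromosome.

    The cM profile is 3-segment piecewise linear: recombining arms around a
    plateau spanning the configured fractional interval of the chromosome.
    A zero-length plateau degenerates to a single slope.  Gaussian noise of
    ``noise_sd_cm`` is added to the cM values.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    lo_f, hi_f = plateau
    records = []
    length = config.chromosome_length
    b1, b2 = lo_f * length, hi_f * length
    s_arm = arm_slope_cm_per_mb / 1e6
    s_mid = plateau_slope_cm_per_mb / 1e6
    for c in range(config.n_chromosomes):
        x = np.linspace(0, length, points_per_chromosome)
        cm = np.where(
            x < b1,
            s_arm * x,
            np.where(
                x < b2,
                s_arm * b1 + s_mid * (x - b1),
                s_arm * b1 + s_mid * (b2 - b1) + s_arm * (x - b2),
            ),
        )
        if noise_sd_cm > 0:
            cm = cm + rng.normal(0.0, noise_sd_cm, size=len(cm))
        records.append(
            pd.DataFrame({"chrom": f"chr{c + 1:02d}", "bp": x.astype(np.int64), "cM": cm})
        )
    return pd.concat(records, ignore_index=True)


# ---------------------------------------------------------------------------
# recovery scoring


def truth_report(
    truth: SyntheticTruth,
    pcoa_labels: list[str] | None = None,
    pcoa_coords: np.ndarray | None = None,
    resampled: pd.DataFrame | None = None,
    reclassification: pd.DataFrame | None = None,
    gwas_table: pd.DataFrame | None = None,
    flagged_windows: dict[str, pd.DataFrame] | None = None,
) -> dict[str, float]:
    """Score analysis outputs against the generator's ground truth.

    Each supplied output contributes its recovery metrics; identifier
    mismatches raise.  Returns a flat name -> value dict.
    """
    report: dict[str, float] = {}

    if pcoa_coords is not None:
        if pcoa_labels is None or len(pcoa_labels) != len(pcoa_coords):
            raise ValueError("pcoa labels/coords misaligned")
        unknown = [s for s in pcoa_labels if s not in truth.strata]
        if unknown:
            raise ValueError(f"unknown samples in PCoA output: {unknown[:5]}")
        labels = np.array([truth.strata[s] for s in pcoa_labels])
        centroids = {g: pcoa_coords[labels == g].mean(axis=0) for g in np.unique(labels)}
        correct = 0
        for i, g in enumerate(labels):
            dists = {h: np.linalg.norm(pcoa_coords[i] - c) for h, c in centroids.items()}
            if min(dists, key=dists.get) == g:
                correct += 1
        report["stratum_separation"] = correct / len(labels)

    if resampled is not None:
        for rec in resampled.itertuples():
            expected = truth.expected_he(rec.group, n_draw=rec.n_drawn)
            report[f"he_expected_{rec.group}"] = expected
            report[f"he_observed_{rec.group}"] = rec.he_all_mean
            report[f"he_abs_error_{rec.group}"] = abs(rec.he_all_mean - expected)

    if reclassification is not None:
        truth_pos = truth.introgressed_samples()
        rec = reclassification.set_index("sample")
        unknown = [s for s in rec.index if s not in truth.strata]
        if unknown:
            raise ValueError(f"unknown samples in reclassification: {unknown[:5]}")
        called = set(rec.index[rec["proposed_status"] == "modern-like"])
        pos = truth_pos & set(rec.index)
        neg = set(rec.index) - truth_pos
        tp = len(called & pos)
        report["introgression_sensitivity"] = tp / len(pos) if pos else np.nan
        report["introgression_specificity"] = (
            len(neg - called) / len(neg) if neg else np.nan
        )

    if flagged_windows is not None:
        hits = total = 0
        for sample, bed in flagged_windows.items():
            for chrom, start, end in truth.introgressions.get(sample, []):
                total += 1
                overlap = (
                    (bed["chrom"] == chrom)
                    & (bed["end"] + 1 > start)
                    & (bed["start"] + 1 < end)
                )
                if overlap.any():
                    hits += 1
        report["introgression_block_recall"] = hits / total if total else np.nan

    if gwas_table is not None:
        causal_all = {l for lst in truth.causal.values() for l, _ in lst}
        hit = n_traits = 0
        sig_true = sig_all = 0
        for trait, sub in gwas_table.groupby("trait"):
            truth_loci = {l for l, _ in truth.causal.get(trait, [])}
            if not truth_loci:
                continue
            n_traits += 1
            finite = sub[np.isfinite(sub["p"])]
            if not len(finite):
                continue
            top = finite.loc[finite["p"].idxmin()]
            top_idx = int(top.get("locus_index", -1))
            if top_idx in truth_loci:
                hit += 1
            sig = finite[finite["significant"]]
            sig_all += len(sig)
            if "locus_index" in sig.columns:
                sig_true += int(sig["locus_index"].isin(truth_loci | causal_all).sum())
        if n_traits:
            report["gwas_top_hit_rate"] = hit / n_traits
        if sig_all:
            report["gwas_hit_precision"] = sig_true / sig_all
    return report
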