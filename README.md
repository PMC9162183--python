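# popkit

Population-genomic analysis of low-diversity crop collections from
genotyping-by-sequencing (GBS) SNP data.

Traditional crop varieties — landraces maintained by farmers before
systematic breeding — often combine striking phenotypic diversity with very
little molecular variation, and gene banks hold thousands of accessions
whose "traditional" labels can hide modern breeding material.  `popkit` is
a tested, reusable implementation of the analysis such a collection needs:

* **Genotype filtering** — the tier1 cascade (genotype quality masking,
  variant quality ≥ 50, observed heterozygosity ≤ 0.1, call rate ≥ 0.6,
  minor allele in ≥ 3 samples) plus pericentromere masking by segmented
  regression of the genetic map (cM vs bp, two breakpoints delimiting the
  low-recombination plateau).
* **Structure** — pairwise Kosman distances (per-locus shared-allele
  similarity, `1 − |d₁−d₂|/2` on dosages, pairwise-deleted) and classical
  PCoA, with hierarchical re-analysis on sample subsets.
* **Diversity** — expected/observed heterozygosity, percent polymorphic at
  the 95% major-allele-frequency threshold, the 100×20 resampling scheme,
  rarefaction curves with an exact hypergeometric closed form, and
  minor-allele-frequency spectra.
* **LD** — Rogers–Huff composite r² for unphased genotypes, binned decay
  curves per genetic group.
* **Introgression scanning** — windowed haplotype comparison against a
  traditional reference panel: a window is flagged when the query's minimum
  Kosman distance to every panel haplotype is non-zero (threshold
  configurable), and samples with too many flagged windows are proposed as
  modern-like.
* **Group distances** — Nei (1972) standard distance and Jost's
  D<sub>est</sub>, neighbor-joining trees, and Nexus export for
  split-network software.
* **GWAS** — Box–Cox normalisation, principal-component structure
  correction (0.3 LD-pruning threshold), Wald tests for quantitative and
  Rao score tests for binary traits, exact Bonferroni bookkeeping.
* **Synthetic collections** — a generator that emulates the study design
  (wild / semi-domesticated / traditional / modern strata, diversity-rich
  polymorphic islands in a near-fixed traditional background, founder-
  mosaic haplotype blocks, planted donor introgressions, trait-driving
  loci) together with a machine-readable ground truth, so every stage can
  be validated by recovery.

## Worked example

```python
import popkit as pk

res = pk.simulate_collection(pk.SimulationConfig(), seed=1)
tier1 = pk.create_tier1(res.matrix)
print(f"tier1: {tier1.n_loci} / {res.matrix.n_loci} loci retained")

markers = pk.select_structure_markers(tier1)
coords = pk.pcoa(pk.pairwise_distances(markers), k=3)
print(f"markers: {markers.n_loci}, PCoA axis1 explains "
      f"{coords.explained[0]:.1%} of variance")

div = pk.resampled_diversity(res.matrix, res.samples.groups("group_rank1"),
                             draw_size=20, replicates=100, seed=2)
for rec in div.itertuples():
    print(f"{rec.group:12s} He={rec.he_all_mean:.4f} (SD {rec.he_all_sd:.4f}) "
          f"%P={rec.pct_polymorphic_mean:5.1f}")

report = pk.reclassify(tier1, res.samples)
cult = report[report.status.isin(["traditional", "modern"])]
n_mod = (cult.proposed_status == "modern-like").sum()
print(f"reclassification: {n_mod} of {len(cult)} cultivated samples "
      f"carry non-traditional haplotypes")
```

prints

```
tier1: 19580 / 20000 loci retained
markers: 2000, PCoA axis1 explains 44.4% of variance
modern       He=0.0371 (SD 0.0004) %P= 31.1
semidom      He=0.2413 (SD 0.0004) %P= 98.6
traditional  He=0.0289 (SD 0.0002) %P= 26.5
wild         He=0.3134 (SD 0.0004) %P= 99.1
reclassification: 80 of 320 cultivated samples carry non-traditional haplotypes
```

The tier1 cascade drops the low-quality and under-called loci layered into
the simulation.  The first PCoA axis separates the wild outgroup from the
cultivated material.  The resampled diversity indices (100 draws of 20
samples each) recover the designed contrast — the wild stratum is far more
diverse than the cultivated ones, and the traditional stratum is the
poorest, with mean expected heterozygosity under 0.03 because almost all
of its variants sit at near-fixation.  The haplotype scan proposes exactly
the 80 modern samples (the ones carrying planted donor blocks) as
modern-like, and none of the 240 traditional samples.

## Command-line pipeline

```bash
popkit simulate --seed 1 --out run/          # or point inputs at your VCF
popkit all --seed 1 --out run/
```

Stages (`filter → structure → diversity → ld → introgression → distances →
gwas`) write TSV/VCF/Newick/Nexus artifacts plus a `manifest.json` with the
resolved configuration and seed; identical config + seed reproduce every
artifact byte for byte.  A YAML config file (`--config run.yaml`) overrides
any stage parameter; see `popkit --help`.

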