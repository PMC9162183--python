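"""Composite linkage disequilibrium for unphased genotypes.

With unknown gametic phase the Rogers–Huff composite estimator applies: the
LD correlation r between two loci is the Pearson correlation of their 0/1/2
genotype dosage vectors over the samples called at both loci.  r^2 is its
square.  Decay curves bin intra-chromosomal pairwise r^2 by physical
distance, separately per genetic group, after restricting each group to its
loci with a within-group major-allele frequency strictly below a ceiling
(default 0.98) — LD among near-fixed loci is dominated by estimation noise.

For truly independent loci the expected r^2 is approximately 1/n (the
finite-sample bias of the squared correlation), which is the baseline any
decay curve should be read against.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .diversity_stats import allele_frequencies
from .genotype_io import MISSING, GenotypeMatrix, subset

logger = logging.getLogger("popkit")

#: Default distance-bin edges in bp: (0,5], (5,25], (25,100], (100,1000] kb.
DEFAULT_BIN_EDGES = (0, 5_000, 25_000, 100_000, 1_000_000)


def rogers_huff_r(dosage_i: np.ndarray, dosage_j: np.ndarray) -> float:
    """Composite LD correlation of two dosage vectors (pairwise-complete).

    Missing dosages may be coded -1 or nan.  Returns nan when fewer than two
    pairwise-complete samples remain or either locus is constant on the
    complete set.
    """
    a = np.asarray(dosage_i, dtype=float)
    b = np.asarray(dosage_j, dtype=float)
    a[a == MISSING] = np.nan
    b[b == MISSING] = np.nan
    both = np.isfinite(a) & np.isfinite(b)
    if both.sum() < 2:
        return np.nan
    a = a[both]
    b = b[both]
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def _pairwise_r2(calls: np.ndarray) -> np.ndarray:
    """r^2 between all column pairs with pairwise-complete deletion.

    ``calls`` is samples x loci int8 with -1 missing.  Returns an m x m
    matrix with nan where r is undefined.
    """
    mask = (calls != MISSING).astype(np.float64)
    x = np.where(calls == MISSING, 0, calls).astype(np.float64)
    n = mask.T @ mask  # pairwise-complete counts
    sx = x.T @ mask  # sum of locus-i dosage over samples complete for (i,j)
    sy = sx.T
    sxy = x.T @ x
    sxx = (x * x).T @ mask
    syy = sxx.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        var_x = sxx - sx**2 / n
        var_y = syy - sy**2 / n
        r2 = cov**2 / (var_x * var_y)
    r2[(n < 2) | ~np.isfinite(r2)] = np.nan
    return r2


def ld_decay(
    matrix: GenotypeMatrix,
    grouping: dict[str, list[str]],
    maf_ceiling: float = 0.98,
    max_distance_bp: int = 1_000_000,
    bin_edges: tuple[int, ...] = DEFAULT_BIN_EDGES,
    max_pairs_per_group: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Distance-binned mean r^2 per genetic group.

    Within each group, loci are restricted to those with a within-group
    major-allele frequency strictly below ``maf_ceiling``; r^2 is computed
    for every intra-chromosomal pair up to ``max_distance_bp`` apart and
    averaged per distance bin.  ``max_pairs_per_group`` caps the pair count
    by random subsampling for large matrices.  Groups with fewer than two
    eligible loci yield an empty curve with a log entry.
    """
    rng = np.random.default_rng(seed)
    edges = np.asarray(bin_edges)
    records = []
    for group in sorted(grouping):
        ids = grouping[group]
        sub = subset(matrix, sample_ids=ids)
        freqs = allele_frequencies(sub, {group: ids})
        major = freqs.major_freq()[0]
        eligible = np.isfinite(major) & (major < maf_ceiling)
        if eligible.sum() < 2:
            logger.warning("ld_decay: group %r has <2 eligible loci", group)
            continue
        sub = subset(sub, locus_predicate=eligible)
        dist_list = []
        r2_list = []
        for _, chrom_loci in sub.loci.groupby("chrom", sort=False):
            idx = chrom_loci.index.to_numpy()
            if len(idx) < 2:
                continue
            pos = chrom_loci["pos"].to_numpy()
            r2 = _pairwise_r2(sub.calls[:, idx])
            iu, ju = np.triu_indices(len(idx), k=1)
            d = pos[ju] - pos[iu]
            keep = d <= max_distance_bp
            dist_list.append(d[keep])
            r2_list.append(r2[iu[keep], ju[keep]])
        if not dist_list:
            continue
        dists = np.concatenate(dist_list)
        r2s = np.concatenate(r2_list)
        ok = np.isfinite(r2s)
        dists, r2s = dists[ok], r2s[ok]
        if max_pairs_per_group is not None and len(dists) > max_pairs_per_group:
            pick = rng.choice(len(dists), size=max_pairs_per_group, replace=False)
            dists, r2s = dists[pick], r2s[pick]
        for b in range(len(edges) - 1):
            lo, hi = edges[b], edges[b + 1]
            in_bin = (dists > lo) & (dists <= hi)
            records.append(
                {
                    "group": group,
                    "bin_lo": int(lo),
                    "bin_hi": int(hi),
                    "mean_r2": float(r2s[in_bin].mean()) if in_bin.any() else np.nan,
                    "n_pairs": int(in_bin.sum()),
                }
            )
    return pd.DataFrame(records)
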