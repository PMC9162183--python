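"""Per-group allele frequencies, heterozygosity, %polymorphic, rarefaction.

All estimators are plug-in (frequency substitution, no small-sample
correction).  Frequencies are always computed from non-missing calls only.
A locus is *variable* within a group when both alleles were observed there,
and *polymorphic at threshold t* when its major-allele frequency does not
exceed t (the boundary is inclusive: a major frequency of exactly 0.95 counts
as polymorphic at the 95% threshold).

The resampling scheme draws a fixed number of samples per group without
replacement, many times, and reports the replicate mean and SD of each index
— the device that makes diversity comparable across groups of very different
sizes.  Rarefaction curves additionally report the expected number of
segregating loci as a function of subsample size; an exact hypergeometric
closed form is provided alongside the Monte-Carlo estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger("popkit")


@dataclass
class GroupFrequencyTable:
    """Per-group, per-locus reference-allele frequencies.

    ``p_ref`` is the reference-allele frequency (nan where a group has no
    called genotype at the locus); ``n_alleles`` is twice the number of
    non-missing calls.
    """

    groups: list[str]
    loci: pd.DataFrame = field(repr=False)
    p_ref: np.ndarray = field(repr=False)  # (n_groups, n_loci)
    n_alleles: np.ndarray = field(repr=False)  # (n_groups, n_loci) int

    def __post_init__(self) -> None:
        if self.p_ref.shape != (len(self.groups), len(self.loci)):
            raise ValueError("frequency array shape mismatch")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def major_freq(self) -> np.ndarray:
        """Major-allele frequency per (group, locus); nan where undefined."""
        return np.maximum(self.p_ref, 1.0 - self.p_ref)

    def variable_mask(self) -> np.ndarray:
        """True where both alleles were observed within the group."""
        with np.errstate(invalid="ignore"):
            return (self.p_ref > 0.0) & (self.p_ref < 1.0)

    def row(self, group: str) -> int:
        try:
            return self.groups.index(group)
        except ValueError:
            raise KeyError(f"unknown group {group!r}") from None


def _group_counts(
    calls: np.ndarray, rows: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    sub = calls[rows]
    called = sub != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, sub, 0).sum(axis=0)
    return alt.astype(np.int64), (2 * n_called).astype(np.int64)


def allele_frequencies(
    matrix: GenotypeMatrix, grouping: dict[str, list[str]]
) -> GroupFrequencyTable:
    """Reference-allele frequency per group and locus.

    ``grouping`` maps group label -> sample ids.  Loci invariant within a
    group (frequency 0 or 1) remain in the table and are flagged through
    :meth:`GroupFrequencyTable.variable_mask`; loci with no called genotype
    in a group get frequency nan.
    """
    groups = sorted(grouping)
    p = np.full((len(groups), matrix.n_loci), np.nan)
    n = np.zeros((len(groups), matrix.n_loci), dtype=np.int64)
    for gi, g in enumerate(groups):
        ids = grouping[g]
        if not ids:
            raise ValueError(f"group {g!r} has no samples")
        rows = matrix.sample_index(ids)
        alt, n_alleles = _group_counts(matrix.calls, rows)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[gi] = np.where(n_alleles > 0, 1.0 - alt / np.maximum(n_alleles, 1), np.nan)
        n[gi] = n_alleles
    return GroupFrequencyTable(groups, matrix.loci, p, n)


def expected_heterozygosity(freqs: GroupFrequencyTable) -> np.ndarray:
    """Per-locus expected heterozygosity He = 1 - p^2 - (1-p)^2.

    Returns an (n_groups, n_loci) array; nan where the frequency is
    undefined.  He is invariant to the allele-label swap p <-> 1-p and is at
    most 0.5 for a biallelic locus.
    """
    p = freqs.p_ref
    return 1.0 - p**2 - (1.0 - p) ** 2


def percent_polymorphic(
    freqs: GroupFrequencyTable, threshold: float = 0.95, variable_only: bool = False
) -> pd.Series:
    """Percentage of loci polymorphic at the major-allele-frequency threshold.

    A locus counts as polymorphic iff its major-allele frequency is <= the
    threshold.  The denominator is every locus with a defined frequency, or
    only the within-group variable loci when ``variable_only`` is set.
    """
    major = freqs.major_freq()
    defined = np.isfinite(major)
    poly = defined & (major <= threshold)
    denom = freqs.variable_mask() if variable_only else defined
    poly = poly & denom
    out = {}
    for gi, g in enumerate(freqs.groups):
        total = int(denom[gi].sum())
        out[g] = 100.0 * poly[gi].sum() / total if total else np.nan
    return pd.Series(out, name=f"pct_polymorphic_{threshold:g}")


def observed_heterozygosity(
    matrix: GenotypeMatrix, rows: np.ndarray
) -> np.ndarray:
    """Per-locus observed heterozygosity (hets / non-missing) for a sample set."""
    sub = matrix.calls[rows]
    called = sub != MISSING
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_called > 0, (sub == 1).sum(axis=0) / np.maximum(n_called, 1), np.nan)


def _diversity_indices(
    matrix: GenotypeMatrix, rows: np.ndarray, threshold: float
) -> dict[str, float]:
    """He / Ho / %P / variant count for one sample set.

    ``he_all`` averages He over every locus with a defined frequency (fixed
    loci contribute 0); ``he_variable`` restricts to loci variable in the
    set; ``he_polymorphic`` restricts further to the polymorphic loci at the
    threshold.  ``pct_polymorphic`` uses the variable loci as denominator.
    """
    alt, n_alleles = _group_counts(matrix.calls, rows)
    defined = n_alleles > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(defined, alt / np.maximum(n_alleles, 1), np.nan)
    he = 2.0 * p * (1.0 - p)
    variable = defined & (alt > 0) & (alt < n_alleles)
    major = np.maximum(p, 1.0 - p)
    poly = variable & (major <= threshold)
    ho = observed_heterozygosity(matrix, rows)

    def _mean(values: np.ndarray, mask: np.ndarray) -> float:
        return float(values[mask].mean()) if mask.any() else np.nan

    return {
        "he_all": _mean(he, defined),
        "he_variable": _mean(he, variable),
        "he_polymorphic": _mean(he, poly),
        "ho": _mean(ho, defined),
        "pct_polymorphic": 100.0 * poly.sum() / variable.sum() if variable.any() else np.nan,
        "n_variants": int(variable.sum()),
    }


_INDEX_COLS = ("he_all", "he_variable", "he_polymorphic", "ho", "pct_polymorphic", "n_variants")


def resampled_diversity(
    matrix: GenotypeMatrix,
    grouping: dict[str, list[str]],
    draw_size: int = 20,
    replicates: int = 100,
    seed: int | None = None,
    threshold: float = 0.95,
) -> pd.DataFrame:
    """Diversity indices per group from repeated fixed-size subsampling.

    For each replicate, ``draw_size`` samples are drawn without replacement
    from the group, frequencies are recomputed on the draw, and He/Ho/%P are
    computed with the %P and variable-locus restrictions applied within the
    draw.  Groups smaller than ``draw_size`` are skipped with a warning.  A
    single seeded generator drives all draws, so identical seeds give
    identical reports.
    """
    rng = np.random.default_rng(seed)
    records = []
    for g in sorted(grouping):
        ids = grouping[g]
        if len(ids) < draw_size:
            logger.warning(
                "resampled_diversity: group %r has %d < %d samples; skipped",
                g, len(ids), draw_size,
            )
            continue
        rows = matrix.sample_index(ids)
        reps = []
        for _ in range(replicates):
            draw = rng.choice(rows, size=draw_size, replace=False)
            reps.append(_diversity_indices(matrix, draw, threshold))
        rep_df = pd.DataFrame(reps)
        rec: dict[str, object] = {"group": g, "n_drawn": draw_size, "replicates": replicates}
        for col in _INDEX_COLS:
            rec[f"{col}_mean"] = rep_df[col].mean()
            rec[f"{col}_sd"] = rep_df[col].std(ddof=1) if replicates > 1 else 0.0
        records.append(rec)
    return pd.DataFrame(records)


def group_diversity(
    matrix: GenotypeMatrix, grouping: dict[str, list[str]], threshold: float = 0.95
) -> pd.DataFrame:
    """Plain (non-resampled) diversity indices per group."""
    records = []
    for g in sorted(grouping):
        rows = matrix.sample_index(grouping[g])
        rec = {"group": g, "n_samples": len(rows)}
        rec.update(_diversity_indices(matrix, rows, threshold))
        records.append(rec)
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# rarefaction


def _log_comb(n: np.ndarray, k: int) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    out = np.full(n.shape, -np.inf)
    ok = n >= k
    out[ok] = gammaln(n[ok] + 1) - gammaln(k + 1) - gammaln(n[ok] - k + 1)
    return out


def rarefaction_expected(matrix: GenotypeMatrix, sample_ids: list[str], n: int) -> float:
    """Exact expected number of segregating loci in a random n-subset.

    A locus segregates in a subset when both alleles are observed among its
    called genotypes.  With genotype-class counts (hom-ref n0, het n1,
    hom-alt n2, missing nm) out of N samples, the subset fails to segregate
    exactly when it is drawn entirely from hom-ref+missing or entirely from
    hom-alt+missing (all-missing subsets are in both), so

        P(not segregating) = [C(n0+nm, n) + C(n2+nm, n) - C(nm, n)] / C(N, n)
    """
    rows = matrix.sample_index(sample_ids)
    sub = matrix.calls[rows]
    N = len(rows)
    if not 1 <= n <= N:
        raise ValueError(f"subset size {n} outside [1, {N}]")
    n0 = (sub == 0).sum(axis=0)
    n1 = (sub == 1).sum(axis=0)
    n2 = (sub == 2).sum(axis=0)
    nm = N - n0 - n1 - n2
    log_total = _log_comb(np.array([N]), n)[0]
    p_not = (
        np.exp(_log_comb(n0 + nm, n) - log_total)
        + np.exp(_log_comb(n2 + nm, n) - log_total)
        - np.exp(_log_comb(nm, n) - log_total)
    )
    return float(np.sum(1.0 - p_not))


def rarefaction_variants(
    matrix: GenotypeMatrix,
    sample_ids: list[str],
    n_grid: list[int],
    replicates: int = 20,
    seed: int | None = None,
) -> pd.DataFrame:
    """Monte-Carlo rarefaction curve: segregating-locus count vs subset size.

    Points with n greater than the group size are skipped.  At n equal to
    the group size the count is exact and the SD is zero.
    """
    rng = np.random.default_rng(seed)
    rows = matrix.sample_index(sample_ids)
    records = []
    for n in n_grid:
        if n > len(rows) or n < 1:
            logger.warning("rarefaction: n=%d outside group size %d; skipped", n, len(rows))
            continue
        counts = []
        reps = 1 if n == len(rows) else replicates
        for _ in range(reps):
            draw = rng.choice(rows, size=n, replace=False)
            sub = matrix.calls[draw]
            called = sub != MISSING
            alt = np.where(called, sub, 0).sum(axis=0)
            n_alleles = 2 * called.sum(axis=0)
            counts.append(int(((alt > 0) & (alt < n_alleles)).sum()))
        records.append(
            {
                "n": n,
                "mean_variants": float(np.mean(counts)),
                "sd_variants": float(np.std(counts, ddof=1)) if len(counts) > 1 else 0.0,
            }
        )
    return pd.DataFrame(records)


def maf_spectrum(freqs: GroupFrequencyTable, bins: int = 20) -> pd.DataFrame:
    """Histogram of minor-allele frequency per group over [0, 0.5].

    Bin totals sum to the number of loci with a defined frequency in the
    group.  Near-fixed collections pile their mass in the lowest bin.
    """
    edges = np.linspace(0.0, 0.5, bins + 1)
    maf = 1.0 - freqs.major_freq()
    records = []
    for gi, g in enumerate(freqs.groups):
        vals = maf[gi][np.isfinite(maf[gi])]
        counts, _ = np.histogram(vals, bins=edges)
        # np.histogram's last bin is closed on the right, so 0.5 is included
        for b in range(bins):
            records.append(
                {"group": g, "maf_lo": edges[b], "maf_hi": edges[b + 1], "count": int(counts[b])}
            )
    return pd.DataFrame(records)
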