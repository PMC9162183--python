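"""Tier1 variant filtering, pericentromere detection, and marker selection.

The tier1 cascade keeps loci that pass four independent per-locus filters
(variant quality, observed heterozygosity, call rate, minor-allele carrier
count).  Each filter is evaluated on the input matrix, so the cascade is
order-independent and idempotent by construction.

Pericentromeres — the low-recombination chromosome interiors — are located by
a continuous 3-segment (2-breakpoint) piecewise-linear regression of genetic
position (cM) on physical position (bp), fitted per chromosome by a coarse
breakpoint grid search followed by local refinement.  The interval between
the two breakpoints is the pericentromeric plateau.  A fixture with the
tomato SL2.50 pericentromere coordinates ships with the package.

Marker selection for structure analysis keeps up to a target number of loci
on an even physical grid across the genome and prunes consecutive markers in
near-complete LD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .genotype_io import MISSING, GenotypeMatrix, subset

logger = logging.getLogger("popkit")


@dataclass
class FilterParams:
    """Thresholds for the tier1 cascade.

    Defaults follow the GBS filtering regime for a selfing crop: variant
    quality >= 50, observed heterozygosity <= 0.1, call rate >= 0.6, and the
    minor allele carried by at least 3 samples ("more than two").
    """

    min_variant_quality: float = 50.0
    max_observed_het: float = 0.1
    min_call_rate: float = 0.6
    min_minor_samples: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_observed_het <= 1.0:
            raise ValueError("max_observed_het must lie in [0, 1]")
        if not 0.0 <= self.min_call_rate <= 1.0:
            raise ValueError("min_call_rate must lie in [0, 1]")
        if self.min_variant_quality < 0 or self.min_minor_samples < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class PericentromereSet:
    """Per-chromosome pericentromeric interval, half-open on 1-based bp."""

    intervals: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, (start, end) in self.intervals.items():
            if not 0 <= start < end:
                raise ValueError(f"bad interval for {chrom}: [{start}, {end})")

    def contains(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Boolean mask: position falls inside its chromosome's interval."""
        inside = np.zeros(len(pos), dtype=bool)
        for c, (start, end) in self.intervals.items():
            on = chrom == c
            inside |= on & (pos >= start) & (pos < end)
        return inside


def load_packaged_pericentromeres() -> PericentromereSet:
    """The pericentromeric intervals of the tomato SL2.50 assembly.

    The packaged table stores 1-based inclusive start/end coordinates; they
    are converted to the internal half-open convention here.
    """
    with resources.files("popkit.data").joinpath(
        "pericentromeres_sl250.tsv"
    ).open() as fh:
        table = pd.read_csv(fh, sep="\t")
    return PericentromereSet(
        {r.chrom: (int(r.start), int(r.end) + 1) for r in table.itertuples()}
    )


# ---------------------------------------------------------------------------
# per-locus statistics


def locus_stats(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus call rate, observed heterozygosity, minor-allele carriers.

    Observed heterozygosity = hets / non-missing calls; call rate =
    non-missing / total samples.  The minor allele is the globally rarer
    allele at the locus; a carrier is any sample with at least one copy
    (het or hom).
    """
    calls = matrix.calls
    n = matrix.n_samples
    called = calls != MISSING
    n_called = called.sum(axis=0)
    n_het = (calls == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        het = np.where(n_called > 0, n_het / np.maximum(n_called, 1), 0.0)
        alt_dose = np.where(called, calls, 0).sum(axis=0)
        p_alt = np.where(n_called > 0, alt_dose / (2.0 * np.maximum(n_called, 1)), 0.0)
    minor_is_alt = p_alt <= 0.5
    carriers_alt = ((calls >= 1) & called).sum(axis=0)
    carriers_ref = ((calls <= 1) & called).sum(axis=0)
    minor_carriers = np.where(minor_is_alt, carriers_alt, carriers_ref)
    # a locus with no minor allele at all has zero carriers
    minor_freq = np.minimum(p_alt, 1.0 - p_alt)
    minor_carriers = np.where(minor_freq > 0, minor_carriers, 0)
    return pd.DataFrame(
        {
            "call_rate": n_called / n if n else np.zeros(matrix.n_loci),
            "obs_het": het,
            "minor_carriers": minor_carriers,
            "p_alt": p_alt,
        }
    )


def create_tier1(
    matrix: GenotypeMatrix, params: FilterParams | None = None
) -> GenotypeMatrix:
    """Apply the tier1 filter cascade; returns the retained loci.

    Keeps exactly the loci with QUAL >= ``min_variant_quality``, observed
    heterozygosity <= ``max_observed_het``, call rate >= ``min_call_rate``,
    and minor allele carried by >= ``min_minor_samples`` samples.  Per-filter
    drop counts are logged (the audit trail of the cascade).
    """
    params = params or FilterParams()
    if matrix.n_loci == 0:
        return matrix
    stats = locus_stats(matrix)
    qual = matrix.loci["qual"].to_numpy(dtype=float)
    pass_qual = qual >= params.min_variant_quality
    pass_het = stats["obs_het"].to_numpy() <= params.max_observed_het
    pass_rate = stats["call_rate"].to_numpy() >= params.min_call_rate
    pass_minor = stats["minor_carriers"].to_numpy() >= params.min_minor_samples
    keep = pass_qual & pass_het & pass_rate & pass_minor
    logger.info(
        "tier1: %d/%d loci kept (drops: qual=%d het=%d call_rate=%d minor=%d)",
        int(keep.sum()), matrix.n_loci,
        int((~pass_qual).sum()), int((~pass_het).sum()),
        int((~pass_rate).sum()), int((~pass_minor).sum()),
    )
    return subset(matrix, locus_predicate=keep)


# ---------------------------------------------------------------------------
# pericentromere detection


def _piecewise_design(x: np.ndarray, b1: float, b2: float) -> np.ndarray:
    # continuous 3-segment linear model: basis {1, x, (x-b1)+, (x-b2)+}
    return np.column_stack(
        [np.ones_like(x), x, np.maximum(x - b1, 0.0), np.maximum(x - b2, 0.0)]
    )


def _piecewise_sse(x: np.ndarray, y: np.ndarray, b1: float, b2: float) -> float:
    design = _piecewise_design(x, b1, b2)
    _, res, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1] or res.size == 0:
        fit = design @ np.linalg.lstsq(design, y, rcond=None)[0]
        return float(np.sum((y - fit) ** 2))
    return float(res[0])


def fit_chromosome_breakpoints(
    bp: np.ndarray, cm: np.ndarray, n_grid: int = 30
) -> tuple[float, float, np.ndarray]:
    """Fit a continuous 2-breakpoint segmented regression of cM on bp.

    Returns (b1, b2, slopes) with b1 < b2 and the three segment slopes.
    Breakpoints are found by an exhaustive coarse grid over interior
    candidate pairs followed by Nelder-Mead refinement of the least-squares
    objective.
    """
    order = np.argsort(bp)
    x = bp[order].astype(float)
    y = cm[order].astype(float)
    if len(x) < 8:
        raise ValueError("too few map points for segmented regression")
    lo, hi = np.quantile(x, [0.02, 0.98])
    candidates = np.linspace(lo, hi, n_grid)
    best = (np.inf, lo, hi)
    for i in range(n_grid - 1):
        for j in range(i + 1, n_grid):
            sse = _piecewise_sse(x, y, candidates[i], candidates[j])
            if sse < best[0]:
                best = (sse, candidates[i], candidates[j])
    span = x[-1] - x[0]

    def objective(b: np.ndarray) -> float:
        b1, b2 = sorted(b)
        if b1 <= x[0] or b2 >= x[-1] or (b2 - b1) < span * 1e-3:
            return np.inf
        return _piecewise_sse(x, y, b1, b2)

    result = minimize(
        objective, x0=[best[1], best[2]], method="Nelder-Mead",
        options={"xatol": span * 1e-5, "fatol": 1e-12, "maxiter": 400},
    )
    b1, b2 = sorted(result.x) if np.isfinite(result.fun) else (best[1], best[2])
    beta = np.linalg.lstsq(_piecewise_design(x, b1, b2), y, rcond=None)[0]
    slopes = np.array([beta[1], beta[1] + beta[2], beta[1] + beta[2] + beta[3]])
    return float(b1), float(b2), slopes


def fit_pericentromeres(
    map_points: pd.DataFrame, slope_contrast: float = 0.5
) -> PericentromereSet:
    """Locate the pericentromeric plateau of each chromosome.

    ``map_points`` has columns ``chrom, bp, cM``.  For each chromosome a
    3-segment model is fitted; the interval between the two breakpoints is
    returned when the middle-segment slope is below ``slope_contrast`` times
    the mean arm slope (otherwise the chromosome has no detectable plateau
    and is omitted with a warning).
    """
    intervals: dict[str, tuple[int, int]] = {}
    for chrom, sub in map_points.groupby("chrom", sort=False):
        bp = sub["bp"].to_numpy(dtype=float)
        cm = sub["cM"].to_numpy(dtype=float)
        b1, b2, slopes = fit_chromosome_breakpoints(bp, cm)
        arm_slope = (abs(slopes[0]) + abs(slopes[2])) / 2.0
        if arm_slope <= 0 or abs(slopes[1]) >= slope_contrast * arm_slope:
            logger.warning(
                "fit_pericentromeres: no low-recombination plateau on %s "
                "(slopes %.4g/%.4g/%.4g)", chrom, *slopes
            )
            continue
        logger.info(
            "fit_pericentromeres: %s plateau [%d, %d) slopes %.4g/%.4g/%.4g",
            chrom, int(b1), int(b2), *slopes,
        )
        intervals[str(chrom)] = (int(round(b1)), int(round(b2)))
    return PericentromereSet(intervals)


def mask_pericentromeres(
    matrix: GenotypeMatrix, regions: PericentromereSet
) -> GenotypeMatrix:
    """Drop loci inside any pericentromeric interval (half-open test).

    Chromosomes absent from ``regions`` keep all their loci, with a warning.
    """
    if not regions.intervals:
        return matrix
    chrom = matrix.loci["chrom"].to_numpy()
    pos = matrix.loci["pos"].to_numpy()
    unknown = set(chrom) - set(regions.intervals)
    if unknown:
        logger.warning(
            "mask_pericentromeres: no interval for chromosomes %s; loci kept",
            sorted(unknown),
        )
    keep = ~regions.contains(chrom, pos)
    logger.info(
        "mask_pericentromeres: %d/%d euchromatic loci kept",
        int(keep.sum()), matrix.n_loci,
    )
    return subset(matrix, locus_predicate=keep)


# ---------------------------------------------------------------------------
# structure-marker selection


def dosage_correlation(col_a: np.ndarray, col_b: np.ndarray) -> float:
    """Pearson correlation of two 0/1/2 dosage columns, pairwise-complete."""
    both = (col_a != MISSING) & (col_b != MISSING)
    if both.sum() < 2:
        return np.nan
    a = col_a[both].astype(float)
    b = col_b[both].astype(float)
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def select_structure_markers(
    matrix: GenotypeMatrix,
    target_count: int = 2000,
    call_rate_floor: float = 0.95,
    min_minor_samples: int = 3,
    prune_r: float = 0.95,
) -> GenotypeMatrix:
    """Select well-called, evenly spread, LD-pruned markers for PCoA.

    Keeps loci with call rate >= ``call_rate_floor`` and the minor allele in
    at least ``min_minor_samples`` samples, then picks up to ``target_count``
    loci on an even physical grid spanning the whole genome (chromosomes
    concatenated; the locus nearest each grid point is chosen, ties to the
    lower position).  Finally consecutive retained loci whose absolute dosage
    correlation exceeds ``prune_r`` are collapsed to the first of each run.
    """
    stats = locus_stats(matrix)
    eligible = (
        (stats["call_rate"].to_numpy() >= call_rate_floor)
        & (stats["minor_carriers"].to_numpy() >= min_minor_samples)
    )
    if not eligible.any():
        raise ValueError("no informative markers after call-rate/minor filters")
    cand = subset(matrix, locus_predicate=eligible)

    if cand.n_loci > target_count:
        # global coordinate = chromosome offset + position
        offsets: dict[str, float] = {}
        running = 0.0
        for chrom, sub in cand.loci.groupby("chrom", sort=False):
            offsets[chrom] = running
            running += float(sub["pos"].max()) + 1.0
        gpos = np.array(
            [offsets[c] + p for c, p in zip(cand.loci["chrom"], cand.loci["pos"])]
        )
        span = gpos[-1] - gpos[0]
        step = span / target_count
        grid = gpos[0] + (np.arange(target_count) + 0.5) * step
        picked = np.searchsorted(gpos, grid)
        chosen: list[int] = []
        for g, idx in zip(grid, picked):
            lo = max(idx - 1, 0)
            hi = min(idx, len(gpos) - 1)
            # ties go to the lower position
            best = lo if abs(gpos[lo] - g) <= abs(gpos[hi] - g) else hi
            if not chosen or chosen[-1] != best:
                chosen.append(best)
        keep = np.zeros(cand.n_loci, dtype=bool)
        keep[chosen] = True
        cand = subset(cand, locus_predicate=keep)

    # prune consecutive markers in near-complete LD
    kept_idx: list[int] = []
    for j in range(cand.n_loci):
        if not kept_idx:
            kept_idx.append(j)
            continue
        prev = kept_idx[-1]
        same_chrom = cand.loci["chrom"].iat[j] == cand.loci["chrom"].iat[prev]
        if same_chrom:
            r = dosage_correlation(cand.calls[:, prev], cand.calls[:, j])
            if np.isfinite(r) and abs(r) > prune_r:
                continue
        kept_idx.append(j)
    keep = np.zeros(cand.n_loci, dtype=bool)
    keep[kept_idx] = True
    out = subset(cand, locus_predicate=keep)
    logger.info(
        "select_structure_markers: %d markers selected (target %d)",
        out.n_loci, target_count,
    )
    return out


def read_genetic_map(path: str) -> pd.DataFrame:
    """Read a genetic map TSV with columns ``chrom  bp  cM``."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in ("chrom", "bp", "cM") if c not in table.columns]
    if missing:
        raise ValueError(f"genetic map missing columns: {missing}")
    return table
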