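"""Windowed haplotype scan for segments absent from a reference panel.

The genome is tiled into fixed-size windows.  Within each window, every
reference-panel sample's genotype vector over the in-window loci is one
"haplotype" (the data are near-homozygous GBS calls, so the unphased vector
stands in for a haplotype; missing positions act as wildcards).  A query
sample is compared window by window: its minimum Kosman distance to the
catalog haplotypes is computed with pairwise deletion, and the window is
flagged when that minimum exceeds a threshold.  The strict reading —
flag on any non-zero distance — is the default of :func:`scan_sample`; the
reclassification layer defaults to a tolerant threshold (0.25) so that a
single private variant in a window does not mimic a wild-donor introgression
block, whose windows sit near distance 1.

A sample whose flagged-window fraction exceeds a cutoff is proposed as
"modern-like" (carrying haplotypes absent from the traditional panel);
original status labels are reported alongside, never overwritten.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, SampleTable, subset

logger = logging.getLogger("popkit")

DEFAULT_WINDOW_BP = 1_000_000
DEFAULT_MIN_INFORMATIVE_LOCI = 3
#: Tolerant flag threshold used by reclassification: isolated private
#: variants give min distances of order 1/(2 * loci-per-window), introgressed
#: windows sit near 1.
DEFAULT_FLAG_THRESHOLD = 0.25
DEFAULT_SAMPLE_CUTOFF = 0.005


@dataclass
class WindowCatalog:
    """Reference-panel haplotypes per genomic window.

    ``windows`` has columns chrom/start/end (half-open, 1-based) plus the
    locus index range [lo, hi) into the locus table; per window the distinct
    reference genotype vectors are stored with their carrier counts and the
    per-reference-sample assignment to those vectors (needed for
    leave-one-out scans).
    """

    windows: pd.DataFrame = field(repr=False)
    haplotypes: list[np.ndarray] = field(repr=False)  # per window: (u, w) int8
    counts: list[np.ndarray] = field(repr=False)  # per window: (u,) int
    assignment: list[np.ndarray] = field(repr=False)  # per window: (n_ref,) int
    reference_samples: list[str] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def informative(self) -> np.ndarray:
        return self.windows["informative"].to_numpy(dtype=bool)


@dataclass
class ScanResult:
    """Per-window minimum distances and flags for one query sample."""

    sample: str
    min_distance: np.ndarray = field(repr=False)  # nan = uninformative window
    flagged: np.ndarray = field(repr=False)

    @property
    def n_informative(self) -> int:
        return int(np.isfinite(self.min_distance).sum())

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())

    @property
    def fraction_flagged(self) -> float:
        n = self.n_informative
        return self.n_flagged / n if n else np.nan


def tile_windows(loci: pd.DataFrame, window_bp: int) -> pd.DataFrame:
    """Tile each chromosome with half-open fixed-size windows.

    Windows start at position 1 and cover every locus exactly once; the
    locus index range [lo, hi) of each window is recorded.
    """
    records = []
    for chrom, sub in loci.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        idx = sub.index.to_numpy()
        last = int(pos.max())
        n_windows = (last - 1) // window_bp + 1
        for w in range(n_windows):
            start = 1 + w * window_bp
            end = start + window_bp
            in_w = (pos >= start) & (pos < end)
            lo_hi = idx[in_w]
            records.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "lo": int(lo_hi.min()) if in_w.any() else -1,
                    "hi": int(lo_hi.max()) + 1 if in_w.any() else -1,
                    "n_loci": int(in_w.sum()),
                }
            )
    return pd.DataFrame(records)


def build_catalog(
    reference: GenotypeMatrix,
    window_bp: int = DEFAULT_WINDOW_BP,
    min_informative_loci: int = DEFAULT_MIN_INFORMATIVE_LOCI,
) -> WindowCatalog:
    """Collect the distinct reference genotype vectors of every window.

    Windows with fewer than ``min_informative_loci`` loci are marked
    uninformative and never contribute flags.
    """
    if reference.n_samples < 2:
        raise ValueError("reference panel needs at least 2 samples")
    windows = tile_windows(reference.loci, window_bp)
    windows["informative"] = windows["n_loci"] >= min_informative_loci
    haplotypes: list[np.ndarray] = []
    counts: list[np.ndarray] = []
    assignment: list[np.ndarray] = []
    for w in windows.itertuples():
        if not w.informative:
            haplotypes.append(np.zeros((0, 0), dtype=np.int8))
            counts.append(np.zeros(0, dtype=np.int64))
            assignment.append(np.full(reference.n_samples, -1))
            continue
        block = reference.calls[:, w.lo:w.hi]
        uniq, inverse, cnt = np.unique(
            block, axis=0, return_inverse=True, return_counts=True
        )
        haplotypes.append(uniq.astype(np.int8))
        counts.append(cnt)
        assignment.append(inverse.astype(np.int64))
    n_hap = sum(len(c) for c in counts)
    logger.info(
        "build_catalog: %d windows (%d informative), %d distinct haplotypes",
        len(windows), int(windows["informative"].sum()), n_hap,
    )
    return WindowCatalog(windows, haplotypes, counts, assignment, list(reference.samples))


def _window_min_distance(
    query_block: np.ndarray, haps: np.ndarray, exclude: int = -1
) -> float:
    """Minimum Kosman distance from one query vector to catalog haplotypes.

    ``exclude`` removes one haplotype row (leave-one-out support).  Missing
    positions in either vector are wildcards; haplotypes with no co-called
    locus against the query are skipped.  Returns nan when nothing is
    comparable.
    """
    if exclude >= 0:
        keep = np.arange(len(haps)) != exclude
        haps = haps[keep]
    if len(haps) == 0:
        return np.nan
    q = query_block.astype(np.float64)
    q[query_block == MISSING] = np.nan
    h = haps.astype(np.float64)
    h[haps == MISSING] = np.nan
    diff = np.abs(h - q)  # (u, w), nan where either missing
    n_ok = np.isfinite(diff).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dists = np.nansum(diff, axis=1) / (2.0 * n_ok)
    dists[n_ok == 0] = np.nan
    if not np.isfinite(dists).any():
        return np.nan
    return float(np.nanmin(dists))


def scan_sample(
    query: GenotypeMatrix | np.ndarray,
    catalog: WindowCatalog,
    flag_threshold: float = 0.0,
    sample_id: str | None = None,
    leave_one_out: str | None = None,
) -> ScanResult:
    """Scan one query sample against the window catalog.

    ``query`` is either a single-sample matrix aligned with the catalog's
    loci or a raw call vector.  A window is flagged when the minimum Kosman
    distance from the query's in-window genotype vector to every catalog
    haplotype strictly exceeds ``flag_threshold`` (default 0: the strict
    non-zero-distance rule).  ``leave_one_out`` names a reference sample
    whose singleton haplotypes are excluded — used when the query itself is
    part of the reference panel.
    """
    if isinstance(query, GenotypeMatrix):
        if query.n_samples != 1:
            raise ValueError("scan_sample expects a single-sample matrix")
        calls = query.calls[0]
        sample_id = sample_id or query.samples[0]
    else:
        calls = np.asarray(query, dtype=np.int8)
    n_loci_catalog = int(catalog.windows["hi"].max()) if catalog.n_windows else 0
    if len(calls) < n_loci_catalog:
        raise ValueError("query loci not aligned with catalog loci")
    loo_idx = (
        catalog.reference_samples.index(leave_one_out)
        if leave_one_out is not None
        else -1
    )
    n_w = catalog.n_windows
    min_d = np.full(n_w, np.nan)
    informative = catalog.informative()
    for wi, w in enumerate(catalog.windows.itertuples()):
        if not informative[wi]:
            continue
        block = calls[w.lo:w.hi]
        if np.all(block == MISSING):
            continue
        exclude = -1
        if loo_idx >= 0:
            own = catalog.assignment[wi][loo_idx]
            if own >= 0 and catalog.counts[wi][own] == 1:
                exclude = int(own)
        min_d[wi] = _window_min_distance(block, catalog.haplotypes[wi], exclude)
    flagged = np.isfinite(min_d) & (min_d > flag_threshold)
    return ScanResult(sample_id or "query", min_d, flagged)


def scan_matrix(
    queries: GenotypeMatrix,
    catalog: WindowCatalog,
    flag_threshold: float = 0.0,
    leave_one_out: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Scan many query samples at once.

    Returns (min_distance, flagged) arrays of shape (n_queries, n_windows);
    nan marks uninformative windows.  With ``leave_one_out`` any query that
    is also a reference sample has its own singleton haplotypes excluded
    from the catalog minima.
    """
    n_q = queries.n_samples
    n_w = catalog.n_windows
    min_d = np.full((n_q, n_w), np.nan)
    informative = catalog.informative()
    ref_index = {s: i for i, s in enumerate(catalog.reference_samples)}
    query_ref_row = np.array(
        [ref_index.get(s, -1) for s in queries.samples], dtype=np.int64
    )
    for wi, w in enumerate(catalog.windows.itertuples()):
        if not informative[wi]:
            continue
        haps = catalog.haplotypes[wi].astype(np.float64)
        haps[catalog.haplotypes[wi] == MISSING] = np.nan
        block = queries.calls[:, w.lo:w.hi].astype(np.float64)
        block[queries.calls[:, w.lo:w.hi] == MISSING] = np.nan
        # (q, u, w) pairwise-deleted mean |dosage difference| / 2
        diff = np.abs(block[:, None, :] - haps[None, :, :])
        n_ok = np.isfinite(diff).sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.nansum(diff, axis=2) / (2.0 * n_ok)
        d[n_ok == 0] = np.nan
        if leave_one_out:
            singleton = catalog.counts[wi] == 1
            for qi, r in enumerate(query_ref_row):
                if r >= 0:
                    own = catalog.assignment[wi][r]
                    if own >= 0 and singleton[own]:
                        d[qi, own] = np.nan
        all_nan = ~np.isfinite(d).any(axis=1)
        with np.errstate(invalid="ignore"):
            col = np.nanmin(np.where(np.isfinite(d), d, np.inf), axis=1)
        col[all_nan] = np.nan
        col[np.isinf(col)] = np.nan
        min_d[:, wi] = col
    flagged = np.isfinite(min_d) & (min_d > flag_threshold)
    return min_d, flagged


def reclassify(
    matrix: GenotypeMatrix,
    samples: SampleTable,
    reference_status: str = "traditional",
    window_bp: int = DEFAULT_WINDOW_BP,
    flag_threshold: float = DEFAULT_FLAG_THRESHOLD,
    sample_cutoff: float = DEFAULT_SAMPLE_CUTOFF,
    min_informative_loci: int = DEFAULT_MIN_INFORMATIVE_LOCI,
) -> pd.DataFrame:
    """Propose modern-like reclassification for every sample.

    The catalog is built from the samples whose status equals
    ``reference_status``.  Reference-labelled queries are scanned
    leave-one-out (their own singleton haplotypes removed from the catalog)
    so they are not trivially at distance zero.  A query is proposed
    "modern-like" when its flagged-window fraction exceeds
    ``sample_cutoff``; the original status is reported, never overwritten.
    """
    ref_ids = samples.samples_with_status(reference_status)
    if not set(ref_ids) & set(matrix.samples):
        raise ValueError(f"no samples with status {reference_status!r} in matrix")
    ref_ids = [s for s in ref_ids if s in set(matrix.samples)]
    catalog = build_catalog(
        subset(matrix, sample_ids=ref_ids), window_bp, min_informative_loci
    )
    status = samples.status_of()
    min_d, flagged = scan_matrix(
        matrix, catalog, flag_threshold, leave_one_out=True
    )
    records = []
    for i, sample in enumerate(matrix.samples):
        informative = int(np.isfinite(min_d[i]).sum())
        n_flag = int(flagged[i].sum())
        frac = n_flag / informative if informative else np.nan
        proposed = "modern-like" if np.isfinite(frac) and frac > sample_cutoff else "consistent"
        records.append(
            {
                "sample": sample,
                "status": status.get(sample, "unknown"),
                "windows_informative": informative,
                "windows_flagged": n_flag,
                "fraction": frac,
                "proposed_status": proposed,
            }
        )
    report = pd.DataFrame(records)
    n_prop = int((report["proposed_status"] == "modern-like").sum())
    logger.info("reclassify: %d/%d samples proposed modern-like", n_prop, len(report))
    return report


def flagged_windows_bed(result: ScanResult, catalog: WindowCatalog) -> pd.DataFrame:
    """Flagged windows as BED rows (0-based half-open)."""
    w = catalog.windows.loc[result.flagged]
    return pd.DataFrame(
        {
            "chrom": w["chrom"].to_numpy(),
            "start": w["start"].to_numpy() - 1,
            "end": w["end"].to_numpy() - 1,
            "name": result.sample,
            "score": result.min_distance[result.flagged.nonzero()[0]],
        }
    )
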