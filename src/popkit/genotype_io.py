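"""Genotype matrix I/O and the shared in-memory representation.

The whole pipeline operates on a :class:`GenotypeMatrix`: an ordered set of
samples crossed with an ordered set of biallelic SNP loci, each call being an
unordered diploid genotype stored as an alternate-allele dosage
(0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing).  Missing is a distinct
state and is never conflated with hom-ref.  Positions are 1-based, as in VCF;
every genomic window used downstream is half-open ``[start, end)`` on those
1-based coordinates.

Genotypes are unphased throughout: the data model targets
genotyping-by-sequencing calls, and every downstream statistic (Kosman
distances, Rogers–Huff LD) is defined for unknown phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger("popkit")

MISSING = -1

LOCUS_COLUMNS = ("chrom", "pos", "ref", "alt", "qual")

SAMPLE_TABLE_COLUMNS = ("sample", "status", "country", "group_rank1", "group_rank2")

#: Recognised passport status labels; unknown labels are preserved verbatim.
KNOWN_STATUSES = frozenset(
    {"traditional", "modern", "wild", "SLC", "hybrid", "unknown"}
)


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


class UndefinedDistanceError(ValueError):
    """Raised when two samples share no co-called locus."""


@dataclass
class GenotypeMatrix:
    """Samples x biallelic-SNP loci diploid calls with missing states.

    Attributes
    ----------
    samples : list of str
        Ordered sample identifiers.
    loci : pandas.DataFrame
        One row per locus with columns ``chrom, pos, ref, alt, qual``; ``pos``
        is strictly increasing within each chromosome.
    calls : ndarray of int8, shape (n_samples, n_loci)
        Alt-allele dosage per call; ``-1`` marks a missing call.
    gq : ndarray of float32 or None
        Per-call genotype quality, aligned with ``calls``; ``nan`` where the
        VCF carried no GQ.
    """

    samples: list[str]
    loci: pd.DataFrame
    calls: np.ndarray
    gq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.loci = self.loci.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        for col in LOCUS_COLUMNS:
            if col not in self.loci.columns:
                raise ValueError(f"loci table missing column {col!r}")
        if len(self.loci):
            for chrom, sub in self.loci.groupby("chrom", sort=False):
                pos = sub["pos"].to_numpy()
                if not np.all(np.diff(pos) > 0):
                    raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def dosages(self) -> np.ndarray:
        """Calls as float with ``nan`` for missing (samples x loci)."""
        d = self.calls.astype(np.float64)
        d[self.calls == MISSING] = np.nan
        return d

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def sample_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None


@dataclass
class SampleTable:
    """Passport metadata: one row per sample.

    ``status`` carries traditional/modern/wild/... labels; ``group_rank1`` and
    ``group_rank2`` hold the coarse and fine genetic-group assignments (these
    are curated metadata, never inferred here).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_TABLE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"sample table missing columns: {missing}")
        dups = self.table["sample"][self.table["sample"].duplicated()].tolist()
        if dups:
            raise ValueError(f"duplicate sample ids: {sorted(set(dups))}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def status_of(self) -> pd.Series:
        return self.table.set_index("sample")["status"]

    def samples_with_status(self, status: str) -> list[str]:
        t = self.table
        return t.loc[t["status"] == status, "sample"].tolist()

    def groups(self, rank: str = "group_rank1") -> dict[str, list[str]]:
        """Mapping group label -> sample ids, skipping unassigned rows."""
        t = self.table.dropna(subset=[rank])
        return {g: sub["sample"].tolist() for g, sub in t.groupby(rank, sort=True)}


def read_vcf(path: str, min_genotype_quality: float = 5.0) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF 4.2 file into a :class:`GenotypeMatrix`.

    Calls with a genotype quality strictly below ``min_genotype_quality`` are
    set to missing ("lower than" is a strict inequality: a call at exactly the
    threshold is kept).  Calls without a GQ value are kept as-is — absence of
    evidence is not grounds to mask — and a single warning is logged per file.
    Non-SNP and multiallelic records are skipped with a warning counter.
    """
    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    quals: list[float] = []
    call_rows: list[np.ndarray] = []
    gq_rows: list[np.ndarray] = []
    n_skipped = 0
    any_gq = False
    try:
        for rec in vcf:
            if not rec.is_snp or len(rec.ALT) != 1:
                n_skipped += 1
                continue
            gt = rec.gt_types.astype(np.int8)  # 0/1/2, 3 = unknown
            gt[gt == 3] = MISSING
            gq = np.asarray(rec.gt_quals, dtype=np.float32)
            chroms.append(rec.CHROM)
            poss.append(rec.POS)
            refs.append(rec.REF)
            alts.append(rec.ALT[0])
            quals.append(rec.QUAL if rec.QUAL is not None else 0.0)
            call_rows.append(gt)
            gq_rows.append(gq)
    except Exception as exc:  # cyvcf2 raises on malformed records
        raise VcfParseError(f"malformed VCF {path!r}: {exc}") from exc

    if n_skipped:
        logger.warning("read_vcf: skipped %d non-SNP/multiallelic records", n_skipped)

    if call_rows:
        calls = np.stack(call_rows, axis=1)  # samples x loci
        gq_arr = np.stack(gq_rows, axis=1)
        gq_arr[gq_arr < 0] = np.nan  # cyvcf2 encodes absent GQ as negative
        any_gq = bool(np.any(np.isfinite(gq_arr)))
        if not any_gq:
            logger.warning("read_vcf: no GQ values in %s; no GQ masking applied", path)
    else:
        calls = np.zeros((len(samples), 0), dtype=np.int8)
        gq_arr = np.zeros((len(samples), 0), dtype=np.float32)

    loci = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts, "qual": quals}
    ) if call_rows else pd.DataFrame(
        {c: pd.Series(dtype=t) for c, t in
         zip(LOCUS_COLUMNS, (str, np.int64, str, str, float))}
    )
    matrix = GenotypeMatrix(samples, loci, calls, gq_arr if any_gq else None)
    matrix, n_masked = mask_low_gq(matrix, min_genotype_quality)
    logger.info(
        "read_vcf: %d samples, %d loci, %d calls masked at GQ<%g",
        matrix.n_samples, matrix.n_loci, n_masked, min_genotype_quality,
    )
    return matrix


def mask_low_gq(
    matrix: GenotypeMatrix, min_genotype_quality: float
) -> tuple[GenotypeMatrix, int]:
    """Set calls with GQ strictly below the threshold to missing.

    Returns the masked matrix and the number of newly masked calls.  Calls
    with no GQ value pass unconditionally.
    """
    if matrix.gq is None or min_genotype_quality <= 0:
        return matrix, 0
    low = np.isfinite(matrix.gq) & (matrix.gq < min_genotype_quality)
    to_mask = low & (matrix.calls != MISSING)
    calls = matrix.calls.copy()
    calls[to_mask] = MISSING
    return replace(matrix, calls=calls), int(to_mask.sum())


_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n'
)

_GT_CODES = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str) -> None:
    """Write the matrix as an uncompressed VCF 4.2 file.

    The header is fixed so that the body is byte-stable for a given matrix;
    ``read_vcf(write_vcf(m))`` reproduces samples, loci, and calls exactly.
    """
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        if len(matrix.loci):
            for chrom, sub in matrix.loci.groupby("chrom", sort=False):
                length = int(sub["pos"].max()) + 1
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        has_gq = matrix.gq is not None
        loci = matrix.loci.itertuples(index=False)
        for j, loc in enumerate(loci):
            fields = [
                str(loc.chrom), str(int(loc.pos)), ".", loc.ref, loc.alt,
                format(float(loc.qual), "g"), ".", ".", "GT:GQ" if has_gq else "GT",
            ]
            col = matrix.calls[:, j]
            if has_gq:
                gqcol = matrix.gq[:, j]
                cells = [
                    _GT_CODES[int(c)]
                    + (":." if not np.isfinite(q) else f":{int(round(float(q)))}")
                    for c, q in zip(col, gqcol)
                ]
            else:
                cells = [_GT_CODES[int(c)] for c in col]
            fh.write("\t".join(fields + cells) + "\n")


def read_sample_table(path: str) -> SampleTable:
    """Read passport metadata from a TSV with a header line.

    Expected columns: ``sample  status  country  group_rank1  group_rank2``.
    Unknown status labels are preserved verbatim.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    return SampleTable(table)


def write_sample_table(table: SampleTable, path: str) -> None:
    table.table.to_csv(path, sep="\t", index=False)


def subset(
    matrix: GenotypeMatrix,
    sample_ids: Sequence[str] | None = None,
    locus_predicate: Callable[[pd.DataFrame], np.ndarray] | np.ndarray | None = None,
) -> GenotypeMatrix:
    """Restrict a matrix to selected samples and/or loci.

    ``locus_predicate`` is either a boolean mask over loci or a callable that
    maps the locus table to one.  Order of retained samples and loci is
    preserved; an unknown sample id raises ``KeyError`` naming it.
    """
    if sample_ids is None:
        rows = np.arange(matrix.n_samples)
        samples = list(matrix.samples)
    else:
        rows = matrix.sample_index(sample_ids)
        samples = list(sample_ids)
    if locus_predicate is None:
        keep = np.ones(matrix.n_loci, dtype=bool)
    elif callable(locus_predicate):
        keep = np.asarray(locus_predicate(matrix.loci), dtype=bool)
    else:
        keep = np.asarray(locus_predicate, dtype=bool)
    if keep.shape != (matrix.n_loci,):
        raise ValueError("locus mask length does not match locus count")
    calls = matrix.calls[np.ix_(rows, np.flatnonzero(keep))]
    gq = None if matrix.gq is None else matrix.gq[np.ix_(rows, np.flatnonzero(keep))]
    return GenotypeMatrix(samples, matrix.loci.loc[keep], calls, gq)
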