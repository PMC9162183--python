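"""Kosman distances, classical PCoA, and group frequency clustering.

The Kosman dissimilarity between two unordered diploid genotypes counts
shared alleles: per locus the similarity is (size of the multiset
intersection of the two allele pairs)/2, i.e. 1 for identical genotypes,
0.5 when exactly one allele is shared (hom vs het, or opposite hets at a
multiallelic locus — here always hom vs het), and 0 for opposite
homozygotes.  For biallelic dosage-coded genotypes this reduces to
|d1 - d2| / 2.  The distance between two samples is one minus the mean
similarity over the loci called in both (pairwise deletion).

PCoA is plain classical metric scaling: double-centre -D^2/2,
eigendecompose, keep the top non-negative eigenpairs, and scale each
eigenvector by the square root of its eigenvalue.  Negative eigenvalues
(non-Euclidean distance matrices) are dropped and their mass reported — no
Cailliez or Lingoes correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

from .diversity_stats import GroupFrequencyTable
from .genotype_io import MISSING, GenotypeMatrix, UndefinedDistanceError, subset

logger = logging.getLogger("popkit")


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal pairwise distances with labels.

    Entries may be nan where a distance is undefined (no co-called loci for
    the pair); defined entries are non-negative.
    """

    labels: list[str]
    d: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")
        finite = np.isfinite(self.d)
        if not np.array_equal(self.d[finite & finite.T], self.d.T[finite & finite.T]):
            raise ValueError("matrix must be symmetric")
        if np.any(self.d[finite] < -1e-12):
            raise ValueError("negative distances")

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass
class PcoaResult:
    """Principal-coordinate embedding of a distance matrix.

    ``coordinates`` is samples x k with axes ordered by decreasing
    eigenvalue; ``explained`` holds the fraction of positive-eigenvalue
    variance per axis; ``negative_eigenvalue_mass`` is the summed magnitude
    of the dropped negative eigenvalues relative to the total absolute
    eigenvalue mass.
    """

    labels: list[str]
    coordinates: np.ndarray = field(repr=False)
    explained: np.ndarray = field(repr=False)
    negative_eigenvalue_mass: float = 0.0


def kosman_distance(g1: np.ndarray, g2: np.ndarray) -> float:
    """Kosman dissimilarity between two dosage-coded genotype vectors.

    Missing calls (code -1) are dropped pairwise; raises
    :class:`UndefinedDistanceError` if no locus is called in both vectors.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    if g1.shape != g2.shape:
        raise ValueError("genotype vectors differ in length")
    both = (g1 != MISSING) & (g2 != MISSING)
    if not both.any():
        raise UndefinedDistanceError("no co-called loci between the two samples")
    sim = 1.0 - np.abs(g1[both].astype(float) - g2[both].astype(float)) / 2.0
    return float(1.0 - sim.mean())


def pairwise_distances(matrix: GenotypeMatrix) -> DistanceMatrix:
    """All-pairs Kosman distances between samples.

    Pairs with no co-called loci are reported as nan with a warning.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least two samples")
    dose = matrix.dosages()  # nan for missing
    n = matrix.n_samples
    d = np.zeros((n, n))
    n_undefined = 0
    for i in range(n - 1):
        diff = np.abs(dose[i + 1:] - dose[i])  # nan where either missing
        counts = np.sum(np.isfinite(diff), axis=1)
        with np.errstate(invalid="ignore"):
            row = np.nansum(diff, axis=1) / (2.0 * counts)
        undef = counts == 0
        n_undefined += int(undef.sum())
        row[undef] = np.nan
        d[i, i + 1:] = row
        d[i + 1:, i] = row
    if n_undefined:
        logger.warning("pairwise_distances: %d pairs with no co-called loci", n_undefined)
    return DistanceMatrix(list(matrix.samples), d)


def pcoa(dist: DistanceMatrix, k: int = 3) -> PcoaResult:
    """Classical metric scaling of a distance matrix.

    Requires k <= n-1; if the matrix rank is lower than k the returned axes
    are truncated with a warning.  Axis signs are fixed by making the
    largest-magnitude loading of each axis positive, so repeated runs are
    reproducible.
    """
    n = dist.n
    if k > n - 1:
        raise ValueError(f"k={k} exceeds n-1={n - 1}")
    if np.any(~np.isfinite(dist.d)):
        raise ValueError("distance matrix contains undefined entries")
    d2 = dist.d**2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centering @ d2 @ centering
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    tol = max(abs(eigval[0]), 1.0) * 1e-12
    positive = eigval > tol
    neg_mass = float(np.abs(eigval[eigval < -tol]).sum())
    total_abs = float(np.abs(eigval).sum())
    n_pos = int(positive.sum())
    if n_pos < k:
        logger.warning("pcoa: rank %d below requested k=%d; axes truncated", n_pos, k)
    k_eff = min(k, n_pos)
    vals = eigval[:k_eff]
    vecs = eigvec[:, :k_eff]
    # deterministic sign: largest-magnitude loading positive
    for a in range(k_eff):
        idx = int(np.argmax(np.abs(vecs[:, a])))
        if vecs[idx, a] < 0:
            vecs[:, a] = -vecs[:, a]
    coords = vecs * np.sqrt(vals)
    pos_sum = float(eigval[positive].sum()) if n_pos else 1.0
    explained = vals / pos_sum if n_pos else np.zeros(0)
    if k_eff == 0:
        coords = np.zeros((n, k))
        explained = np.zeros(k)
    return PcoaResult(
        list(dist.labels), coords, explained,
        neg_mass / total_abs if total_abs > 0 else 0.0,
    )


def hierarchical_pcoa(
    matrix: GenotypeMatrix,
    sample_ids: list[str],
    k: int = 3,
    **marker_kwargs,
) -> PcoaResult:
    """Re-run marker selection and PCoA on a subset of samples.

    Frequencies, call-rate filters, and LD pruning are all recomputed
    relative to the subset, which is what lets nested analyses resolve
    structure invisible at the top level.
    """
    from .variant_filtering import select_structure_markers

    if len(sample_ids) < 3:
        raise ValueError("hierarchical PCoA needs at least 3 samples")
    sub = subset(matrix, sample_ids=sample_ids)
    markers = select_structure_markers(sub, **marker_kwargs)
    return pcoa(pairwise_distances(markers), k=k)


def maf_heatmap_cluster(
    freqs: GroupFrequencyTable,
) -> tuple[list[str], pd.DataFrame, np.ndarray]:
    """Order groups by average-linkage clustering of major-allele frequencies.

    Groups are clustered on the Euclidean distance between their
    major-allele-frequency vectors (loci with an undefined frequency in any
    group are excluded); loci keep genomic order.  Returns (ordered group
    labels, locus table, frequency matrix in that group order) ready for
    heatmap plotting.
    """
    major = freqs.major_freq()
    usable = np.all(np.isfinite(major), axis=0)
    mat = major[:, usable]
    if len(freqs.groups) < 2:
        return list(freqs.groups), freqs.loci.loc[usable], mat
    linkage = average(pdist(mat, metric="euclidean"))
    order = leaves_list(linkage)
    ordered = [freqs.groups[i] for i in order]
    return ordered, freqs.loci.loc[usable], mat[order]


def write_coordinates(result: PcoaResult, path: str) -> None:
    """Write PCoA coordinates as TSV: sample, dim1..dimk, explained1..k."""
    k = result.coordinates.shape[1]
    df = pd.DataFrame(result.coordinates, columns=[f"dim{i+1}" for i in range(k)])
    df.insert(0, "sample", result.labels)
    for i in range(k):
        df[f"explained{i+1}"] = result.explained[i]
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_phylip(dist: DistanceMatrix, path: str) -> None:
    """Write a distance matrix in PHYLIP square format."""
    with open(path, "w") as fh:
        fh.write(f"{dist.n}\n")
        for label, row in zip(dist.labels, dist.d):
            fh.write(label + "\t" + "\t".join(format(x, ".10g") for x in row) + "\n")
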