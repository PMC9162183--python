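"""Between-group differentiation: Nei (1972) D, Jost's Dest, NJ tree, Nexus.

Nei's standard genetic distance uses the gene-identity terms
J_A = mean over loci of sum(p_A^2), J_B likewise, and
J_AB = mean of sum(p_A * p_B) (sums over both alleles of a biallelic
locus); D = -ln( J_AB / sqrt(J_A * J_B) ).  Loci monomorphic in both groups
contribute identity 1 to every J term and are retained.

Jost's Dest for a pair of demes uses the plug-in (frequency-substitution)
estimators: per locus H_S is the mean within-group expected heterozygosity,
H_T the expected heterozygosity of the pooled (mean) frequencies, and
Dest = ((H_T - H_S) / (1 - H_S)) * n/(n-1) with n = 2 demes; locus values
are averaged over the loci polymorphic in at least one of the two groups
(jointly monomorphic loci carry no differentiation signal and are
excluded).  Dest is 0 for identical frequency profiles and 1 for demes
fixed for alternative alleles.

The neighbor-joining tree and the Nexus DISTANCES export are the bridge to
external tree/split-network viewers.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import nj

from .diversity_stats import GroupFrequencyTable

logger = logging.getLogger("popkit")


@dataclass
class GroupDistanceMatrix:
    """Pairwise Nei D and Dest between groups, with per-pair locus counts."""

    labels: list[str]
    nei: np.ndarray = field(repr=False)
    dest: np.ndarray = field(repr=False)
    n_loci: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        for name, m in (("nei", self.nei), ("dest", self.dest)):
            if m.shape != (len(self.labels), len(self.labels)):
                raise ValueError(f"{name} matrix shape mismatch")
            if not np.allclose(np.diag(m), 0.0):
                raise ValueError(f"{name} diagonal must be zero")


def nei_distance(p_a: np.ndarray, p_b: np.ndarray) -> float:
    """Nei (1972) standard genetic distance from two ref-allele frequency vectors.

    Only loci with defined frequencies in both groups enter.  Returns inf
    when the between-group identity J_AB is zero (groups fixed for
    alternative alleles everywhere).
    """
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    ok = np.isfinite(p_a) & np.isfinite(p_b)
    if not ok.any():
        raise ValueError("no shared loci with defined frequencies")
    pa, pb = p_a[ok], p_b[ok]
    j_a = float(np.mean(pa**2 + (1 - pa) ** 2))
    j_b = float(np.mean(pb**2 + (1 - pb) ** 2))
    j_ab = float(np.mean(pa * pb + (1 - pa) * (1 - pb)))
    if j_ab == 0.0:
        return np.inf
    return float(-np.log(j_ab / np.sqrt(j_a * j_b)))


def pairwise_dest(p_a: np.ndarray, p_b: np.ndarray) -> float:
    """Jost's Dest between two demes (plug-in estimator, n = 2).

    Averaged over loci polymorphic in at least one deme; loci with
    H_S = 1 would be excluded (cannot occur for biallelic loci).
    """
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    ok = np.isfinite(p_a) & np.isfinite(p_b)
    pa, pb = p_a[ok], p_b[ok]
    he_a = 1 - pa**2 - (1 - pa) ** 2
    he_b = 1 - pb**2 - (1 - pb) ** 2
    hs = (he_a + he_b) / 2.0
    pm = (pa + pb) / 2.0
    ht = 1 - pm**2 - (1 - pm) ** 2
    informative = ((he_a > 0) | (he_b > 0) | (pa != pb)) & (hs < 1.0)
    if not informative.any():
        return 0.0
    dest = (ht[informative] - hs[informative]) / (1.0 - hs[informative]) * 2.0
    return float(dest.mean())


def group_distance_matrix(freqs: GroupFrequencyTable) -> GroupDistanceMatrix:
    """All-pairs Nei D and Dest from a group frequency table."""
    g = len(freqs.groups)
    if g < 2:
        raise ValueError("need at least two groups")
    nei = np.zeros((g, g))
    dest = np.zeros((g, g))
    n_loci = np.zeros((g, g), dtype=np.int64)
    for i in range(g - 1):
        for j in range(i + 1, g):
            pa, pb = freqs.p_ref[i], freqs.p_ref[j]
            ok = np.isfinite(pa) & np.isfinite(pb)
            nei[i, j] = nei[j, i] = nei_distance(pa, pb)
            dest[i, j] = dest[j, i] = pairwise_dest(pa, pb)
            n_loci[i, j] = n_loci[j, i] = int(ok.sum())
    return GroupDistanceMatrix(list(freqs.groups), nei, dest, n_loci)


def neighbor_joining(labels: list[str], d: np.ndarray) -> str:
    """Neighbor-joining tree in Newick format with branch lengths.

    Requires at least 3 groups and finite distances (an infinite Nei D means
    the identity ratio hit zero; add a pseudocount upstream).  Negative
    branch lengths are clamped to zero.
    """
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 groups")
    if not np.all(np.isfinite(d)):
        raise ValueError(
            "distance matrix has infinite entries; use a pseudocount on the "
            "gene identities before tree building"
        )
    tree = nj(SkbioDM(d, ids=list(labels)), neg_as_zero=True)
    out = io.StringIO()
    tree.write(out, format="newick")
    return out.getvalue().strip()


_NEEDS_QUOTE = re.compile(r"[\s'(){}\[\]/\\,;:=*`\"+<>-]")


def _nexus_label(label: str) -> str:
    if _NEEDS_QUOTE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def export_network_input(labels: list[str], d: np.ndarray, path: str) -> None:
    """Write a Nexus file (TAXA + DISTANCES blocks) for split-network software.

    Labels containing whitespace or Nexus punctuation are quoted (single
    quotes, doubled internally) so they round-trip safely.
    """
    if not np.all(np.isfinite(d)):
        raise ValueError("cannot export infinite distances")
    n = len(labels)
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN TAXA;\n")
        fh.write(f"  DIMENSIONS NTAX={n};\n  TAXLABELS\n")
        for lab in labels:
            fh.write(f"    {_nexus_label(lab)}\n")
        fh.write("  ;\nEND;\n\nBEGIN DISTANCES;\n")
        fh.write(f"  DIMENSIONS NTAX={n};\n")
        fh.write("  FORMAT TRIANGLE=BOTH DIAGONAL LABELS;\n  MATRIX\n")
        for lab, row in zip(labels, d):
            cells = " ".join(format(x, ".10g") for x in row)
            fh.write(f"    {_nexus_label(lab)} {cells}\n")
        fh.write("  ;\nEND;\n")


def read_nexus_labels(path: str) -> list[str]:
    """Parse the taxa labels back out of a Nexus distances file."""
    labels = []
    in_taxlabels = False
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s.upper() == "TAXLABELS":
                in_taxlabels = True
                continue
            if in_taxlabels:
                if s == ";":
                    break
                if s.startswith("'"):
                    labels.append(s[1:-1].replace("''", "'"))
                else:
                    labels.append(s)
    return labels
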