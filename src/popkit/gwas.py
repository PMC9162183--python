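"""Structure-corrected single-locus association testing.

Quantitative traits are Box–Cox normalised (maximum-likelihood lambda, with
an offset when values are not strictly positive) and tested locus by locus
with a Wald test in the linear model

    trait ~ intercept + structure PCs + dosage

against the t reference with the residual degrees of freedom.  Binary
traits are tested with the Rao score test of the dosage term evaluated at
the null logistic fit (covariates only), chi-square with 1 df.  Genetic
structure is corrected with the top principal components of the LD-pruned
dosage matrix (greedy pruning at an r^2 threshold, default 0.3, within a
sliding physical window); no kinship/mixed model is used.  Multiple testing
is controlled by Bonferroni: a locus is significant iff p <= alpha / m with
m the number of loci actually tested for the trait.

Dosages are additive 0/1/2; missing dosages are mean-imputed per locus for
the PCA only and excluded (complete-case) in per-locus tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger("popkit")

DEFAULT_LD_THRESHOLD = 0.3
DEFAULT_N_PCS = 5
DEFAULT_ALPHA = 0.05
PRUNE_WINDOW_BP = 500_000


@dataclass
class TransformedTrait:
    """A Box-Cox-normalised quantitative trait."""

    trait: str
    values: np.ndarray = field(repr=False)  # nan where missing
    lmbda: float = 0.0
    offset: float = 0.0
    #: correlation of sorted values with normal quantiles (qq diagnostic)
    normality_r: float = np.nan


@dataclass
class StructureCovariates:
    """Per-sample principal components of the LD-pruned dosage matrix."""

    samples: list[str]
    components: np.ndarray = field(repr=False)  # (n_samples, q)
    explained: np.ndarray = field(repr=False)
    ld_threshold: float = DEFAULT_LD_THRESHOLD
    n_markers: int = 0


def boxcox_normalize(values: np.ndarray, trait: str = "trait") -> TransformedTrait:
    """Box-Cox transform with maximum-likelihood lambda.

    Values must be strictly positive after an optional offset shift; when
    the minimum is <= 0 an offset of 1 - min is applied and logged.  Missing
    values (nan) are carried through untouched.
    """
    values = np.asarray(values, dtype=float)
    obs = values[np.isfinite(values)]
    if len(obs) < 3:
        raise ValueError("too few observed values")
    if np.ptp(obs) == 0:
        raise ValueError(f"trait {trait!r} has no variance")
    offset = 0.0
    if obs.min() <= 0:
        offset = 1.0 - obs.min()
        logger.info("boxcox_normalize: %s shifted by offset %.6g", trait, offset)
    transformed_obs, lmbda = stats.boxcox(obs + offset)
    out = np.full_like(values, np.nan)
    out[np.isfinite(values)] = transformed_obs
    # qq-plot summary: correlation between order statistics and their
    # expected normal quantiles
    srt = np.sort(transformed_obs)
    qq = stats.norm.ppf((np.arange(len(srt)) + 0.5) / len(srt))
    normality_r = float(np.corrcoef(srt, qq)[0, 1])
    return TransformedTrait(trait, out, float(lmbda), offset, normality_r)


def boxcox_fixed(values: np.ndarray, lmbda: float) -> np.ndarray:
    """Box-Cox with a fixed lambda (lambda = 0 is the natural log)."""
    values = np.asarray(values, dtype=float)
    if lmbda == 0.0:
        return np.log(values)
    return (values**lmbda - 1.0) / lmbda


# ---------------------------------------------------------------------------
# structure covariates


def ld_prune(
    matrix: GenotypeMatrix,
    r2_threshold: float = DEFAULT_LD_THRESHOLD,
    window_bp: int = PRUNE_WINDOW_BP,
) -> np.ndarray:
    """Greedy LD pruning: boolean mask of retained loci.

    Scans loci in genomic order; a locus is dropped when its dosage r^2
    with any already-kept locus within ``window_bp`` on the same chromosome
    exceeds the threshold (first-kept-wins).  Constant loci are dropped.
    """
    dose = matrix.dosages()
    means = np.nanmean(dose, axis=0)
    chrom = matrix.loci["chrom"].to_numpy()
    pos = matrix.loci["pos"].to_numpy()
    filled = np.where(np.isnan(dose), means, dose)
    centred = filled - filled.mean(axis=0)
    sd = centred.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, centred / sd, 0.0)  # r = z_k . z_j / n
    n = matrix.n_samples
    keep: list[int] = []
    kept_mask = np.zeros(matrix.n_loci, dtype=bool)
    for j in range(matrix.n_loci):
        if sd[j] == 0:
            continue
        drop = False
        for k in reversed(keep):
            if chrom[k] != chrom[j] or pos[j] - pos[k] > window_bp:
                break
            r = float(z[:, k] @ z[:, j]) / n
            if r * r > r2_threshold:
                drop = True
                break
        if not drop:
            keep.append(j)
            kept_mask[j] = True
    return kept_mask


def structure_pcs(
    matrix: GenotypeMatrix,
    ld_threshold: float = DEFAULT_LD_THRESHOLD,
    q: int = DEFAULT_N_PCS,
    window_bp: int = PRUNE_WINDOW_BP,
) -> StructureCovariates:
    """Top-q principal components of the LD-pruned, mean-imputed dosages.

    PCs are returned in decreasing-variance order with a deterministic sign
    convention (largest-magnitude loading positive).  ``q = 0`` yields an
    empty covariate set (unadjusted analysis).
    """
    if q >= matrix.n_samples:
        raise ValueError("q must be smaller than the number of samples")
    if q == 0:
        return StructureCovariates(
            list(matrix.samples), np.zeros((matrix.n_samples, 0)), np.zeros(0),
            ld_threshold, 0,
        )
    kept = ld_prune(matrix, ld_threshold, window_bp)
    if not kept.any():
        raise ValueError("all loci pruned; no markers for PCA")
    dose = matrix.dosages()[:, kept]
    means = np.nanmean(dose, axis=0)
    filled = np.where(np.isnan(dose), means, dose)
    centred = filled - filled.mean(axis=0)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    pcs = u[:, :q] * s[:q]
    for a in range(pcs.shape[1]):
        idx = int(np.argmax(np.abs(pcs[:, a])))
        if pcs[idx, a] < 0:
            pcs[:, a] = -pcs[:, a]
    var = s**2
    explained = var[:q] / var.sum() if var.sum() > 0 else np.zeros(q)
    logger.info(
        "structure_pcs: %d pruned markers, %d PCs (%.1f%% variance)",
        int(kept.sum()), q, 100 * explained.sum(),
    )
    return StructureCovariates(
        list(matrix.samples), pcs, explained, ld_threshold, int(kept.sum())
    )


# ---------------------------------------------------------------------------
# per-locus tests


def wald_test_quantitative(
    dosage: np.ndarray, trait: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float, float, float]:
    """Wald test of the dosage term in a linear model.

    Returns (beta, se, t statistic, p).  Complete cases only; raises
    ``ValueError`` for constant or collinear dosage (callers skip the locus
    with the reason).
    """
    dosage = np.asarray(dosage, dtype=float)
    dosage = np.where(dosage == MISSING, np.nan, dosage)
    trait = np.asarray(trait, dtype=float)
    cov = covariates if covariates is not None else np.zeros((len(trait), 0))
    ok = np.isfinite(dosage) & np.isfinite(trait) & np.all(np.isfinite(cov), axis=1)
    n = int(ok.sum())
    p_par = 2 + cov.shape[1]
    if n < p_par + 1:
        raise ValueError("too few complete observations")
    x = np.column_stack([np.ones(n), cov[ok], dosage[ok]])
    y = trait[ok]
    if np.ptp(dosage[ok]) == 0:
        raise ValueError("constant dosage")
    q, r = np.linalg.qr(x)
    if np.abs(np.diag(r)).min() < 1e-10 * np.abs(np.diag(r)).max():
        raise ValueError("collinear dosage/covariates")
    beta_all = np.linalg.solve(r, q.T @ y)
    resid = y - x @ beta_all
    df = n - x.shape[1]
    sigma2 = float(resid @ resid) / df
    xtx_inv_last = np.linalg.inv(r.T @ r)[-1, -1]
    beta = float(beta_all[-1])
    se = float(np.sqrt(sigma2 * xtx_inv_last))
    tstat = beta / se
    p = float(2.0 * stats.t.sf(abs(tstat), df))
    return beta, se, tstat, max(p, np.finfo(float).tiny)


def score_test_binary(
    dosage: np.ndarray, trait: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Rao score test of the dosage term at the null logistic fit.

    The null model (intercept + covariates) is fitted once on the complete
    cases; the score statistic U^2 / V for the dosage term is chi-square
    with 1 df.  Raises ``ValueError`` on separation or missing trait class.
    """
    dosage = np.asarray(dosage, dtype=float)
    dosage = np.where(dosage == MISSING, np.nan, dosage)
    trait = np.asarray(trait, dtype=float)
    cov = covariates if covariates is not None else np.zeros((len(trait), 0))
    ok = np.isfinite(dosage) & np.isfinite(trait) & np.all(np.isfinite(cov), axis=1)
    y = trait[ok]
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("binary trait must be coded 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both trait classes must be present")
    x0 = np.column_stack([np.ones(int(ok.sum())), cov[ok]])
    g = dosage[ok]
    if np.ptp(g) == 0:
        raise ValueError("constant dosage")
    try:
        null = sm.Logit(y, x0).fit(disp=0, maxiter=100)
    except Exception as exc:
        raise ValueError(f"null logistic model failed: {exc}") from exc
    if not np.all(np.isfinite(null.params)) or np.abs(null.params).max() > 30:
        raise ValueError("separation in null model")
    mu = null.predict(x0)
    w = mu * (1.0 - mu)
    u = float(g @ (y - mu))
    gw_x0 = (g * w) @ x0
    x0w_x0 = x0.T @ (x0 * w[:, None])
    v = float(g @ (g * w) - gw_x0 @ np.linalg.solve(x0w_x0, gw_x0))
    if v <= 0:
        raise ValueError("degenerate score variance")
    stat = u * u / v
    p = float(stats.chi2.sf(stat, df=1))
    return stat, max(p, np.finfo(float).tiny)


# ---------------------------------------------------------------------------
# the full scan


def polymorphic_mask(matrix: GenotypeMatrix, threshold: float = 0.95) -> np.ndarray:
    """Loci whose major-allele frequency among the samples is <= threshold."""
    calls = matrix.calls
    called = calls != MISSING
    n_alleles = 2 * called.sum(axis=0)
    alt = np.where(called, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    major = np.maximum(p, 1.0 - p)
    return np.isfinite(major) & (major <= threshold)


def bonferroni_threshold(alpha: float, m: int) -> float:
    return alpha / m if m else np.nan


def run_gwas(
    matrix: GenotypeMatrix,
    traits: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    q: int = DEFAULT_N_PCS,
    ld_threshold: float = DEFAULT_LD_THRESHOLD,
    maf_threshold: float = 0.95,
    covariates: StructureCovariates | None = None,
) -> pd.DataFrame:
    """Association scan of every trait column over the polymorphic loci.

    ``traits`` is indexed by sample id (or carries a ``sample`` column);
    columns whose observed values are all in {0, 1} are tested with the
    score test, the rest are Box-Cox normalised and tested with the Wald
    test.  Structure PCs are built once from the full matrix unless a
    prebuilt covariate set is supplied.  The output table has one row per
    (trait, locus) with the Bonferroni flag at alpha / m, m being the loci
    tested for that trait.
    """
    if "sample" in traits.columns:
        traits = traits.set_index("sample")
    missing_samples = [s for s in matrix.samples if s not in traits.index]
    if missing_samples:
        raise ValueError(f"traits missing for samples: {missing_samples[:5]}")
    traits = traits.loc[matrix.samples]

    poly = polymorphic_mask(matrix, maf_threshold)
    loci_idx = np.flatnonzero(poly)
    logger.info("run_gwas: %d polymorphic loci at the %g threshold", len(loci_idx), maf_threshold)
    if covariates is None:
        covariates = structure_pcs(matrix, ld_threshold=ld_threshold, q=q)
    cov = covariates.components

    results = []
    for trait_name in traits.columns:
        raw = pd.to_numeric(traits[trait_name], errors="coerce").to_numpy(dtype=float)
        observed = raw[np.isfinite(raw)]
        if len(observed) < 30:
            logger.warning("run_gwas: trait %r has %d (<30) complete samples", trait_name, len(observed))
        is_binary = np.all(np.isin(observed, (0.0, 1.0)))
        if is_binary:
            y = raw
            test_type = "score"
        else:
            y = boxcox_normalize(raw, trait_name).values
            test_type = "wald"
        rows = []
        for j in loci_idx:
            dosage = matrix.calls[:, j]
            rec = {
                "trait": trait_name,
                "chrom": matrix.loci["chrom"].iat[j],
                "pos": int(matrix.loci["pos"].iat[j]),
                "test": test_type,
            }
            try:
                if is_binary:
                    stat, p = score_test_binary(dosage, y, cov)
                    rec.update(beta=np.nan, se=np.nan, stat=stat, p=p)
                else:
                    beta, se, tstat, p = wald_test_quantitative(dosage, y, cov)
                    rec.update(beta=beta, se=se, stat=tstat, p=p)
            except ValueError as exc:
                rec.update(beta=np.nan, se=np.nan, stat=np.nan, p=np.nan, skipped=str(exc))
            rows.append(rec)
        table = pd.DataFrame(rows)
        m = int(np.isfinite(table["p"]).sum())
        thr = bonferroni_threshold(alpha, m)
        table["significant"] = np.isfinite(table["p"]) & (table["p"] <= thr)
        table["m_tested"] = m
        results.append(table)
        n_sig = int(table["significant"].sum())
        logger.info("run_gwas: %s — %d/%d loci significant at %.3g", trait_name, n_sig, m, thr)
    return pd.concat(results, ignore_index=True)


def genomic_inflation(pvalues: np.ndarray) -> float:
    """Genomic-control lambda: median association chi-square / 0.4549."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    chi2 = stats.chi2.ppf(1.0 - p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
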