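"""Structure-corrected single-SNP association scan with genomic control.

The scan residualizes both the trait and each SNP dosage on the top
eigenvectors of the genomic kinship (the EIGENSTRAT-style adjustment used
by GenABEL's ``egscore``) and tests the residual-residual correlation with
a 1-df score statistic

    chi2 = (n - n_axes - 1) * r^2 .

Residual population structure inflates the genome-wide chi2 distribution by
a factor lambda, estimated either as median(chi2)/median(chi2_1df) or as the
through-the-origin regression slope of sorted observed chi2 on expected
chi2_1df quantiles; corrected statistics are chi2/lambda (lambda clipped at
1 by default so correction never inflates significance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .popgen import genomic_pca

__all__ = [
    "AssocScan",
    "ThresholdResult",
    "kinship_ibs",
    "score_scan",
    "estimate_lambda",
    "apply_threshold",
    "variance_explained",
]

_CHI2_MEDIAN_1DF = stats.chi2.ppf(0.5, df=1)  # ~0.4549


@dataclass
class AssocScan:
    """Per-locus association statistics plus scan-level genomic control."""

    loci: pd.DataFrame  # contig,pos,chi2,p,chi2_gc,p_gc,r2,excluded,monomorphic
    lam: float
    lambda_method: str
    lambda_clipped: bool
    n_axes_used: int
    n_individuals: int
    alpha: float | None = None
    n_excluded_mac: int = 0

    def tested(self) -> pd.DataFrame:
        return self.loci[~self.loci["excluded"]]


@dataclass
class ThresholdResult:
    significant: pd.DataFrame
    alpha: float
    bonferroni_bound: float
    n_loci_tested: int


def kinship_ibs(genotypes: GenotypeMatrix, weighted: bool = False) -> np.ndarray:
    """Pairwise identity-by-state allele sharing among individuals.

    The unweighted value for a pair is the mean over loci non-missing in
    both of ``1 - |g_i - g_j| / 2`` (1 = identical genotypes, 0 = opposite
    homozygotes).  ``weighted=True`` returns the frequency-weighted
    (centered by 2p, scaled by 2p(1-p)) genomic relationship matrix whose
    top eigenvectors are the PCA axes used for structure correction.
    """
    D = genotypes.dosage
    all_missing = np.isnan(D).all(axis=1)
    if all_missing.any():
        bad = [genotypes.samples[i] for i in np.flatnonzero(all_missing)]
        raise ValueError(f"individuals with all-missing genotypes: {bad}")

    M = (~np.isnan(D)).astype(float)
    if weighted:
        X = genotypes.mean_imputed()
        p = X.mean(axis=0) / 2.0
        poly = (p > 0) & (p < 1)
        Xc = (X[:, poly] - 2.0 * p[poly]) / np.sqrt(2.0 * p[poly] * (1.0 - p[poly]))
        return Xc @ Xc.T / poly.sum()

    X = np.where(np.isnan(D), 0.0, D)
    H = (D == 1.0).astype(float)  # zero at missing
    shared = M @ M.T
    sq = (X**2) @ M.T + M @ (X**2).T - 2.0 * (X @ X.T)
    one_het = H @ M.T + M @ H.T - 2.0 * (H @ H.T)
    abs_sum = 0.5 * (sq + one_het)  # sum over shared loci of |g_i - g_j|
    with np.errstate(invalid="ignore", divide="ignore"):
        K = 1.0 - abs_sum / (2.0 * shared)
    K[shared == 0] = np.nan
    return K


def _residualize(V: np.ndarray, axes: np.ndarray) -> np.ndarray:
    """Residualize columns of V on an intercept plus orthonormal axes."""
    Vc = V - V.mean(axis=0, keepdims=True)
    if axes.size:
        Vc = Vc - axes @ (axes.T @ Vc)
    return Vc


def score_scan(
    genotypes: GenotypeMatrix,
    trait,
    n_axes: int = 3,
    min_mac: int = 2,
    lambda_method: str = "regression",
    clip_lambda: bool = True,
    alpha: float | None = None,
) -> AssocScan:
    """Genome scan of trait-genotype association adjusted for structure.

    Missing dosages are mean-imputed per locus for the test; loci with
    minor-allele count below ``min_mac`` are excluded from both the scan and
    the inflation-factor estimate.  Monomorphic loci get chi2 = 0 with a
    flag.  Individuals with a missing trait value are dropped.
    """
    y = np.asarray(trait, dtype=float)
    if y.size != genotypes.n_individuals:
        raise ValueError("one trait value per individual required")
    keep = ~np.isnan(y)
    gm = genotypes.take_individuals(keep) if not keep.all() else genotypes
    y = y[keep]
    n = y.size
    if np.allclose(y, y[0]):
        raise ValueError("trait is constant; association undefined")
    if n_axes >= n - 2:
        raise ValueError(f"n_axes={n_axes} too large for n={n} individuals")

    mac = gm.minor_allele_count()
    excluded = mac < min_mac
    monomorphic = mac == 0

    if n_axes > 0:
        axes = genomic_pca(gm, n_axes=n_axes).eigenvectors
    else:
        axes = np.empty((n, 0))

    X = gm.mean_imputed()
    yr = _residualize(y[:, None], axes)[:, 0]
    Xr = _residualize(X, axes)

    sy = float(yr @ yr)
    sx = np.einsum("ij,ij->j", Xr, Xr)
    sxy = yr @ Xr
    with np.errstate(invalid="ignore", divide="ignore"):
        r2_resid = np.where(sx > 0, sxy**2 / (sx * sy), 0.0)
    chi2 = (n - n_axes - 1) * r2_resid
    chi2[monomorphic] = 0.0
    chi2[excluded] = np.nan

    lam = estimate_lambda(chi2[~excluded], method=lambda_method)
    lam_for_corr = max(lam, 1.0) if clip_lambda else lam
    chi2_gc = chi2 / lam_for_corr
    p = stats.chi2.sf(chi2, df=1)
    p_gc = stats.chi2.sf(chi2_gc, df=1)

    # plain per-locus variance explained on complete cases
    D = gm.dosage
    Mv = ~np.isnan(D)
    Xz = np.where(Mv, D, 0.0)
    nv = Mv.sum(axis=0)
    sx1 = Xz.sum(axis=0)
    sx2 = (Xz**2).sum(axis=0)
    sy1 = y @ Mv
    sy2 = (y**2) @ Mv
    sxy1 = y @ Xz
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy1 - sx1 * sy1 / nv
        vx = sx2 - sx1**2 / nv
        vy = sy2 - sy1**2 / nv
        r2_plain = np.where((vx > 0) & (vy > 0), cov**2 / (vx * vy), np.nan)

    loci = gm.loci.copy()
    loci["chi2"] = chi2
    loci["p"] = p
    loci["chi2_gc"] = chi2_gc
    loci["p_gc"] = p_gc
    loci["r2"] = r2_plain
    loci["excluded"] = excluded
    loci["monomorphic"] = monomorphic

    return AssocScan(
        loci=loci,
        lam=float(lam),
        lambda_method=lambda_method,
        lambda_clipped=clip_lambda,
        n_axes_used=n_axes,
        n_individuals=n,
        alpha=alpha,
        n_excluded_mac=int(excluded.sum()),
    )


def estimate_lambda(chi2_values, method: str = "regression") -> float:
    """Genomic-control inflation factor of a set of 1-df chi2 statistics.

    ``"median"``: median(chi2) divided by the median of the chi2_1df
    distribution (0.4549...).  ``"regression"``: slope through the origin of
    the sorted observed values on the expected chi2_1df order-statistic
    quantiles.  Returned unclipped; clipping at 1 happens at correction time.
    """
    x = np.asarray(chi2_values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("cannot estimate lambda from an empty scan")
    if x.size < 100:
        warnings.warn(
            f"lambda estimated from only {x.size} loci; unstable below ~100",
            stacklevel=2,
        )
    if method == "median":
        return float(np.median(x) / _CHI2_MEDIAN_1DF)
    if method == "regression":
        obs = np.sort(x)
        exp = stats.chi2.ppf((np.arange(1, x.size + 1) - 0.5) / x.size, df=1)
        return float((exp @ obs) / (exp @ exp))
    raise ValueError("method must be 'median' or 'regression'")


def apply_threshold(scan: AssocScan, alpha: float) -> ThresholdResult:
    """Loci whose corrected p falls below alpha, plus the Bonferroni bound.

    The reference Bonferroni bound is 0.05 / n_loci_tested; it is reported
    alongside, not applied.
    """
    tested = scan.tested()
    n_loci = len(tested)
    sig = tested[tested["p_gc"] < alpha].copy()
    return ThresholdResult(
        significant=sig,
        alpha=alpha,
        bonferroni_bound=0.05 / n_loci if n_loci else np.nan,
        n_loci_tested=n_loci,
    )


def variance_explained(dosage, trait) -> float:
    """Squared Pearson correlation of dosage and trait on complete cases."""
    g = np.asarray(dosage, dtype=float)
    y = np.asarray(trait, dtype=float)
    ok = ~(np.isnan(g) | np.isnan(y))
    g, y = g[ok], y[ok]
    if g.size < 3:
        raise ValueError("need >= 3 complete cases")
    if np.allclose(g, g[0]):
        raise ValueError("locus is monomorphic on complete cases")
    if np.allclose(y, y[0]):
        raise ValueError("trait is constant on complete cases")
    r = np.corrcoef(g, y)[0, 1]
    return float(r**2)
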