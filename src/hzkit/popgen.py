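"""Weir-Cockerham differentiation scans and genomic PCA.

Per-SNP F_ST uses the Weir & Cockerham (1984) two-level estimator with its
three variance components: ``a`` among populations, ``b`` among individuals
within populations, and ``c`` within individuals (heterozygosity).  The
per-locus estimate is theta = a / (a + b + c); the genome-wide weighted
average is the ratio of sums sum(a) / sum(a + b + c), which is also the
default windowed summary.  Negative per-locus theta values are retained
(an estimator, not a parameter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "FstScan",
    "GenomicPca",
    "wc_fst",
    "windowed_fst",
    "flag_outliers",
    "genomic_pca",
]


@dataclass
class FstScan:
    """Per-locus W&C variance components and the weighted genome-wide theta."""

    loci: pd.DataFrame  # contig, pos, a, b, c, theta, n_used per pop
    genome_wide_weighted: float
    n_skipped: int
    populations: tuple[str, str]

    def weighted_mean(self) -> float:
        return self.genome_wide_weighted


@dataclass
class GenomicPca:
    scores: np.ndarray  # individuals x axes (eigenvector * sqrt(eigenvalue))
    eigenvectors: np.ndarray  # individuals x axes, orthonormal
    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    samples: list[str]


def wc_fst(
    genotypes: GenotypeMatrix,
    population_labels,
    populations: tuple[str, str] | None = None,
    min_per_pop: int = 2,
) -> FstScan:
    """Weir-Cockerham (1984) per-SNP theta between two populations.

    Parameters
    ----------
    genotypes
        Dosage matrix (missing calls allowed).
    population_labels
        One label per individual.  Individuals whose label is not one of the
        two analysis populations are ignored.
    populations
        The two population labels to contrast; default: the two unique
        labels present (error if not exactly two).
    min_per_pop
        A locus is skipped (and counted) unless both populations have at
        least this many non-missing diploid calls there.
    """
    labels = np.asarray(population_labels)
    if labels.size != genotypes.n_individuals:
        raise ValueError("one population label per individual required")
    if populations is None:
        uniq = sorted(pd.unique(labels))
        if len(uniq) != 2:
            raise ValueError(f"need exactly two populations, found {uniq}")
        populations = (uniq[0], uniq[1])
    groups = [np.flatnonzero(labels == p) for p in populations]
    if any(g.size == 0 for g in groups):
        raise ValueError(f"empty population among {populations}")

    r = 2  # two sampled populations
    D = genotypes.dosage
    # per-population per-locus summaries
    n_i, p_i, h_i = [], [], []
    for g in groups:
        sub = D[g]
        called = ~np.isnan(sub)
        n = called.sum(axis=0).astype(float)  # diploid individuals called
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.nansum(sub, axis=0) / (2.0 * n)
            h = np.nansum(sub == 1.0, axis=0) / n
        n_i.append(n)
        p_i.append(p)
        h_i.append(h)
    n_i = np.vstack(n_i)  # (2, L)
    p_i = np.vstack(p_i)
    h_i = np.vstack(h_i)

    usable = (n_i >= min_per_pop).all(axis=0)
    n_skipped = int((~usable).sum())

    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n_i.mean(axis=0)
        nc = (r * nbar - (n_i**2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / (r * nbar)

        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        theta = np.where(denom != 0.0, a / np.where(denom == 0.0, np.nan, denom), np.nan)

    a = np.where(usable, a, np.nan)
    b = np.where(usable, b, np.nan)
    c = np.where(usable, c, np.nan)
    theta = np.where(usable, theta, np.nan)

    loci = genotypes.loci.copy()
    loci["a"] = a
    loci["b"] = b
    loci["c"] = c
    loci["theta"] = theta
    loci["used"] = usable

    denom_sum = np.nansum(a + b + c)
    gw = float(np.nansum(a) / denom_sum) if denom_sum != 0 else np.nan
    return FstScan(
        loci=loci,
        genome_wide_weighted=gw,
        n_skipped=n_skipped,
        populations=populations,
    )


def windowed_fst(
    scan: FstScan, window_bp: int = 10_000, method: str = "ratio"
) -> pd.DataFrame:
    """Non-overlapping fixed-span window summaries of a per-SNP scan.

    Windows tile each contig from position 1 in half-open
    ``[start, start + window_bp)`` intervals (1-based positions), so a locus
    at position 10000 falls in the first 10-kb window.  The default window
    statistic is the ratio of sums sum(a)/sum(a+b+c); ``method="mean"``
    averages per-locus theta instead.  Windows with no usable loci are
    omitted.
    """
    if method not in ("ratio", "mean"):
        raise ValueError("method must be 'ratio' or 'mean'")
    df = scan.loci[scan.loci["used"]].copy()
    df = df.dropna(subset=["a"])
    if df.empty:
        return pd.DataFrame(columns=["contig", "start", "end", "theta", "n_loci"])
    df["start"] = ((df["pos"] - 1) // window_bp) * window_bp + 1
    rows = []
    for (contig, start), grp in df.groupby(["contig", "start"], sort=True):
        denom = (grp["a"] + grp["b"] + grp["c"]).sum()
        if method == "ratio":
            theta = grp["a"].sum() / denom if denom != 0 else np.nan
        else:
            theta = grp["theta"].mean()
        rows.append(
            {
                "contig": contig,
                "start": int(start),
                "end": int(start + window_bp),
                "theta": theta,
                "n_loci": len(grp),
            }
        )
    return pd.DataFrame(rows)


def flag_outliers(table, threshold: float, column: str = "theta"):
    """Rows (loci or windows) with differentiation strictly above threshold."""
    if isinstance(table, FstScan):
        table = table.loci
    return table[table[column] > threshold].copy()


def genomic_pca(
    genotypes: GenotypeMatrix,
    n_axes: int = 10,
    standardize: bool = True,
    occidentalis_index=None,
) -> GenomicPca:
    """PCA of the genomic covariance among individuals.

    Loci are centered at twice the counted-allele frequency and (by default)
    standardized by sqrt(2 p (1 - p)); missing calls are mean-imputed before
    decomposition, so monomorphic loci carry no signal and are dropped.  If
    ``occidentalis_index`` (row indices of occidentalis-labelled reference
    individuals) is given, axis 1 is oriented so those individuals score low;
    other axes get a deterministic sign (largest-magnitude score positive).
    """
    if genotypes.n_individuals < 3:
        raise ValueError("PCA needs at least 3 individuals")
    X = genotypes.mean_imputed()
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all loci monomorphic; PCA undefined")
    X = X[:, poly]
    p = p[poly]
    Xc = X - 2.0 * p
    if standardize:
        Xc = Xc / np.sqrt(2.0 * p * (1.0 - p))
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    n_axes = min(n_axes, S.size)
    total = float((S**2).sum())
    eigvals = (S**2)[:n_axes]
    pct = 100.0 * eigvals / total
    U = U[:, :n_axes]
    for j in range(n_axes):
        col = U[:, j]
        if occidentalis_index is not None and j == 0:
            occ = np.asarray(occidentalis_index)
            flip = col[occ].mean() > np.delete(col, occ).mean()
        else:
            flip = col[np.argmax(np.abs(col))] < 0
        if flip:
            U[:, j] = -col
    scores = U * S[:n_axes]
    return GenomicPca(
        scores=scores,
        eigenvectors=U,
        eigenvalues=eigvals,
        pct_variance=pct,
        samples=list(genotypes.samples),
    )
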