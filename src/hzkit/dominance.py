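"""Dominance coefficient of the O allele from genotype-class trait means.

With Z_OO, Z_OT, Z_TT the mean phenotypes of the three genotype classes at
the focal SNP, the dominance coefficient of the O allele is

    h = (Z_TT - Z_OT) / (Z_TT - Z_OO),

so h = 0.5 is complete additivity, h = 0 complete recessivity of the O
allele (heterozygotes look like TT), and h = 1 complete dominance
(heterozygotes look like OO).  h is not clamped to [0, 1].  Confidence
intervals come from bootstrap resampling of individuals from the pooled
sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DominanceEstimate", "estimate_h", "bootstrap_h", "CLASSES"]

CLASSES = ("OO", "OT", "TT")
_DOSE_TO_CLASS = {0: "OO", 1: "OT", 2: "TT"}


@dataclass
class DominanceEstimate:
    h: float
    class_means: dict
    class_counts: dict
    ci95: tuple[float, float] | None = None
    n_bootstrap: int = 0
    n_degenerate: int = 0
    draws: np.ndarray | None = None


def _as_classes(genotype_classes) -> np.ndarray:
    arr = np.asarray(genotype_classes)
    if arr.dtype.kind in "ifu":  # T-allele dosage coding
        vals = arr.astype(float)
        if not np.isin(vals[~np.isnan(vals)], (0.0, 1.0, 2.0)).all():
            raise ValueError("numeric genotype classes must be dosages 0/1/2")
        out = np.full(arr.shape, None, dtype=object)
        ok = ~np.isnan(vals)
        out[ok] = [_DOSE_TO_CLASS[int(v)] for v in vals[ok]]
        return out
    return arr.astype(object)


def _h_from_means(m: dict) -> float:
    return (m["TT"] - m["OT"]) / (m["TT"] - m["OO"])


def estimate_h(genotype_classes, trait, tol: float = 1e-12) -> DominanceEstimate:
    """Point estimate of the dominance coefficient of the O allele.

    ``genotype_classes`` may be labels {"OO", "OT", "TT"} or T-allele
    dosages {0, 1, 2}; individuals with a missing class or trait value are
    dropped (complete cases).
    """
    cls = _as_classes(genotype_classes)
    y = np.asarray(trait, dtype=float)
    ok = np.array([c in CLASSES for c in cls]) & ~np.isnan(y)
    cls, y = cls[ok], y[ok]

    means, counts = {}, {}
    for c in CLASSES:
        sel = cls == c
        counts[c] = int(sel.sum())
        if counts[c] == 0:
            raise ValueError(f"genotype class {c} is empty; h undefined")
        means[c] = float(y[sel].mean())
    scale = max(abs(means["TT"]), abs(means["OO"]), 1.0)
    if abs(means["TT"] - means["OO"]) <= tol * scale:
        raise ValueError("homozygote class means are equal; h undefined")
    return DominanceEstimate(h=_h_from_means(means), class_means=means, class_counts=counts)


def bootstrap_h(
    genotype_classes,
    trait,
    n_iter: int = 10_000,
    seed: int | None = None,
    stratified: bool = False,
    keep_draws: bool = False,
) -> DominanceEstimate:
    """Dominance coefficient with a percentile 95% bootstrap CI.

    Individuals are resampled with replacement from the pooled sample
    (``stratified=True`` resamples within genotype classes instead, as a
    sensitivity analysis).  Iterations that empty a genotype class or leave
    the homozygote means equal are redrawn, counted, and capped at 10 x
    ``n_iter`` total attempts; if more than half of all attempts are
    degenerate the run aborts.
    """
    point = estimate_h(genotype_classes, trait)
    cls = _as_classes(genotype_classes)
    y = np.asarray(trait, dtype=float)
    ok = np.array([c in CLASSES for c in cls]) & ~np.isnan(y)
    cls, y = cls[ok], y[ok]
    n = y.size
    class_idx = {c: np.flatnonzero(cls == c) for c in CLASSES}

    rng = np.random.default_rng(seed)
    draws = np.empty(n_iter)
    got, attempts, degenerate = 0, 0, 0
    max_attempts = 10 * max(n_iter, 1)
    while got < n_iter:
        if attempts >= max_attempts or (
            attempts >= 2 * n_iter and degenerate > 0.5 * attempts
        ):
            raise RuntimeError(
                f"bootstrap degenerate in {degenerate}/{attempts} attempts; "
                "classes too small for resampling"
            )
        attempts += 1
        if stratified:
            idx = np.concatenate(
                [rng.choice(class_idx[c], size=class_idx[c].size) for c in CLASSES]
            )
        else:
            idx = rng.integers(0, n, size=n)
        c_b, y_b = cls[idx], y[idx]
        m = {}
        empty = False
        for c in CLASSES:
            sel = c_b == c
            if not sel.any():
                empty = True
                break
            m[c] = y_b[sel].mean()
        if empty or abs(m["TT"] - m["OO"]) <= 1e-12 * max(
            abs(m["TT"]), abs(m["OO"]), 1.0
        ):
            degenerate += 1
            continue
        draws[got] = _h_from_means(m)
        got += 1

    lo, hi = np.percentile(draws, [2.5, 97.5]) if n_iter else (point.h, point.h)
    return DominanceEstimate(
        h=point.h,
        class_means=point.class_means,
        class_counts=point.class_counts,
        ci95=(float(lo), float(hi)),
        n_bootstrap=n_iter,
        n_degenerate=degenerate,
        draws=draws if keep_draws else None,
    )
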