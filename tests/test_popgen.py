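"""Weir-Cockerham F_ST estimator, windowing, outliers, and genomic PCA."""

import numpy as np
import pandas as pd
import pytest

from hzkit import GenotypeMatrix, flag_outliers, genomic_pca, wc_fst, windowed_fst
from hzkit.association import kinship_ibs


def wc_theta_oracle(geno_pop1, geno_pop2):
    """Independent transcription of the Weir & Cockerham (1984) two-level
    estimator for one biallelic locus, written as explicit scalar arithmetic
    over diploid genotype lists (dosages 0/1/2, None = missing)."""
    pops = []
    for g in (geno_pop1, geno_pop2):
        g = [v for v in g if v is not None]
        n = len(g)
        p = sum(g) / (2 * n)
        het = sum(1 for v in g if v == 1) / n
        pops.append((n, p, het))
    r = 2
    n1, p1, h1 = pops[0]
    n2, p2, h2 = pops[1]
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def _random_two_pop(rng, n1, n2, n_loci, missing=0.0):
    p1 = rng.uniform(0.05, 0.95, n_loci)
    p2 = np.clip(p1 + rng.normal(0, 0.2, n_loci), 0.02, 0.98)
    g1 = rng.binomial(2, p1, size=(n1, n_loci)).astype(float)
    g2 = rng.binomial(2, p2, size=(n2, n_loci)).astype(float)
    D = np.vstack([g1, g2])
    if missing:
        D[rng.random(D.shape) < missing] = np.nan
    labels = np.array(["A"] * n1 + ["B"] * n2)
    return GenotypeMatrix(D, [f"i{k}" for k in range(n1 + n2)]), labels


class TestWcFst:
    def test_matches_independent_oracle_on_random_instances(self, rng):
        """25 random two-population instances agree with the scalar
        transcription of the 1984 formulas to 1e-12."""
        for rep in range(25):
            n1, n2 = rng.integers(4, 21, size=2)
            gm, labels = _random_two_pop(rng, n1, n2, n_loci=50, missing=0.1)
            scan = wc_fst(gm, labels)
            D = gm.dosage
            for j in range(gm.n_loci):
                g1 = [None if np.isnan(v) else int(v) for v in D[:n1, j]]
                g2 = [None if np.isnan(v) else int(v) for v in D[n1:, j]]
                n1v = sum(v is not None for v in g1)
                n2v = sum(v is not None for v in g2)
                if n1v < 2 or n2v < 2:
                    assert not scan.loci["used"].iloc[j]
                    continue
                a, b, c = wc_theta_oracle(g1, g2)
                assert scan.loci["a"].iloc[j] == pytest.approx(a, abs=1e-12)
                assert scan.loci["b"].iloc[j] == pytest.approx(b, abs=1e-12)
                assert scan.loci["c"].iloc[j] == pytest.approx(c, abs=1e-12)

    def test_fixed_opposite_alleles_gives_theta_one(self):
        D = np.vstack([np.zeros((8, 5)), np.full((8, 5), 2.0)])
        gm = GenotypeMatrix(D, [f"i{k}" for k in range(16)])
        scan = wc_fst(gm, ["A"] * 8 + ["B"] * 8)
        np.testing.assert_allclose(scan.loci["theta"], 1.0)
        assert scan.genome_wide_weighted == pytest.approx(1.0)

    def test_identical_populations_near_zero(self, rng):
        p = rng.uniform(0.3, 0.7, 400)
        D = rng.binomial(2, p, size=(120, 400)).astype(float)
        gm = GenotypeMatrix(D, [f"i{k}" for k in range(120)])
        scan = wc_fst(gm, ["A"] * 60 + ["B"] * 60)
        assert abs(scan.genome_wide_weighted) < 0.01

    def test_weighted_average_invariant_to_split_and_pool(self, rng):
        gm, labels = _random_two_pop(rng, 12, 9, n_loci=60)
        scan = wc_fst(gm, labels)
        half1 = wc_fst(gm.take_loci(np.arange(30)), labels)
        half2 = wc_fst(gm.take_loci(np.arange(30, 60)), labels)
        num = np.nansum(half1.loci["a"]) + np.nansum(half2.loci["a"])
        den = sum(
            np.nansum(h.loci[["a", "b", "c"]].to_numpy()) for h in (half1, half2)
        )
        assert scan.genome_wide_weighted == pytest.approx(num / den, abs=1e-12)

    def test_locus_order_invariance(self, rng):
        gm, labels = _random_two_pop(rng, 10, 10, n_loci=40)
        perm = rng.permutation(40)
        assert wc_fst(gm, labels).genome_wide_weighted == pytest.approx(
            wc_fst(gm.take_loci(perm), labels).genome_wide_weighted, abs=1e-12
        )

    def test_single_population_rejected(self, rng):
        gm, _ = _random_two_pop(rng, 5, 5, n_loci=10)
        with pytest.raises(ValueError):
            wc_fst(gm, ["A"] * 10)

    def test_underpowered_locus_skipped_and_counted(self, rng):
        gm, labels = _random_two_pop(rng, 5, 5, n_loci=3)
        gm.dosage[5:9, 0] = np.nan  # pop B has 1 call at locus 0
        scan = wc_fst(gm, labels)
        assert scan.n_skipped == 1
        assert np.isnan(scan.loci["theta"].iloc[0])


class TestWindowedFst:
    def _scan(self, rng, positions, contig="chr1"):
        n = len(positions)
        gm, labels = _random_two_pop(rng, 10, 10, n_loci=n)
        gm.loci["pos"] = positions
        gm.loci["contig"] = contig
        return wc_fst(gm, labels)

    def test_single_window_equals_genome_wide(self, rng):
        scan = self._scan(rng, np.arange(1, 31) * 100)  # all within [1, 10001)
        win = windowed_fst(scan, 10_000)
        assert len(win) == 1
        assert win["theta"].iloc[0] == pytest.approx(scan.genome_wide_weighted)

    def test_boundary_position_10000_in_first_window(self, rng):
        scan = self._scan(rng, [10_000, 10_001])
        win = windowed_fst(scan, 10_000).sort_values("start").reset_index(drop=True)
        assert list(win["start"]) == [1, 10_001]
        assert list(win["n_loci"]) == [1, 1]

    def test_mean_method_differs_from_ratio(self, rng):
        scan = self._scan(rng, np.arange(1, 41) * 200)
        ratio = windowed_fst(scan, 10_000, method="ratio")
        mean = windowed_fst(scan, 10_000, method="mean")
        assert mean["theta"].iloc[0] == pytest.approx(
            scan.loci.loc[scan.loci["used"], "theta"].iloc[:40].mean(), abs=1e-9
        )
        assert len(ratio) == len(mean)


class TestFlagOutliers:
    def test_thresholds(self, rng):
        gm, labels = _random_two_pop(rng, 10, 10, n_loci=30)
        scan = wc_fst(gm, labels)
        assert flag_outliers(scan, 1.0).empty
        n_used = int(scan.loci["used"].sum())
        assert len(flag_outliers(scan, -1.0)) == n_used - scan.loci["theta"].isna().sum() + (
            ~scan.loci["used"]
        ).sum() * 0  # all used, non-NaN loci exceed -1
        assert len(flag_outliers(scan, -1.0)) == scan.loci["theta"].notna().sum()

    def test_near_fixed_locus_flagged(self, rng):
        g1 = rng.binomial(2, 0.02, size=(20, 1)).astype(float)
        g2 = rng.binomial(2, 0.98, size=(20, 1)).astype(float)
        gm = GenotypeMatrix(np.vstack([g1, g2]), [f"i{k}" for k in range(40)])
        scan = wc_fst(gm, ["A"] * 20 + ["B"] * 20)
        assert len(flag_outliers(scan, 0.6)) == 1


class TestGenomicPca:
    def _two_cluster(self, rng, n_per=20, n_loci=200):
        p1 = rng.uniform(0.05, 0.3, n_loci)
        p2 = rng.uniform(0.7, 0.95, n_loci)
        D = np.vstack(
            [
                rng.binomial(2, p1, size=(n_per, n_loci)),
                rng.binomial(2, p2, size=(n_per, n_loci)),
            ]
        ).astype(float)
        return GenotypeMatrix(D, [f"i{k}" for k in range(2 * n_per)])

    def test_separated_populations_bimodal_ev1_with_orientation(self, rng):
        gm = self._two_cluster(rng)
        occ = np.arange(20)
        res = genomic_pca(gm, n_axes=2, occidentalis_index=occ)
        ev1 = res.scores[:, 0]
        assert ev1[:20].mean() < ev1[20:].mean()  # occidentalis low
        assert ev1[:20].max() < ev1[20:].min()  # clean separation
        assert res.pct_variance[0] > 50

    def test_eigenvectors_orthonormal_scores_centered(self, rng):
        gm = self._two_cluster(rng)
        res = genomic_pca(gm, n_axes=3)
        np.testing.assert_allclose(res.eigenvectors.T @ res.eigenvectors, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(res.scores.mean(axis=0), 0.0, atol=1e-9)
        assert res.pct_variance.sum() <= 100 + 1e-9

    def test_matches_weighted_kinship_eigenvectors(self, rng):
        """PCA axes are the top eigenvectors of the frequency-weighted
        kinship: the single source of structure used by the GWAS scan."""
        gm = self._two_cluster(rng, n_per=12, n_loci=80)
        res = genomic_pca(gm, n_axes=3)
        K = kinship_ibs(gm, weighted=True)
        vals, vecs = np.linalg.eigh(K)
        top = vecs[:, ::-1][:, :3]
        for j in range(3):
            dot = abs(top[:, j] @ res.eigenvectors[:, j])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_all_monomorphic_rejected(self):
        gm = GenotypeMatrix(np.full((5, 4), 2.0), [f"i{k}" for k in range(5)])
        with pytest.raises(ValueError):
            genomic_pca(gm)
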