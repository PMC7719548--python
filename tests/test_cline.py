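"""Cline model, maximum-likelihood fitting, and the width-change test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hzkit import (
    ClineFitError,
    ClineParams,
    SiteSeries,
    bootstrap_clines,
    cline_value,
    fit_cline,
    simulate_allele_counts,
    width_change_test,
)
from hzkit.cline import EpochDraws, site_series_from_index


class TestClineValue:
    def test_half_at_center_and_tail_limits(self):
        p = ClineParams(1216.0, 42.0)
        assert cline_value(p, 1216.0) == pytest.approx(0.5)
        assert cline_value(p, -1e7) == pytest.approx(0.0, abs=1e-12)
        assert cline_value(p, 1e7) == pytest.approx(1.0, abs=1e-12)

    def test_max_slope_is_inverse_width(self):
        """Numerical derivative at the center equals 1/w (width convention)."""
        p = ClineParams(1216.0, 42.0)
        eps = 1e-4
        deriv = (cline_value(p, p.center + eps) - cline_value(p, p.center - eps)) / (2 * eps)
        assert deriv == pytest.approx(1.0 / p.width, rel=1e-6)

    @given(
        c=st.floats(-1e3, 1e3),
        w=st.floats(1.0, 500.0),
        x=st.floats(-2e3, 2e3),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_logistic_reparameterization_identity(self, c, w, x):
        """tanh form agrees with the logistic form 1/(1+exp(-4(x-c)/w))."""
        p = ClineParams(c, w)
        logistic = 1.0 / (1.0 + np.exp(-4.0 * (x - c) / w))
        assert cline_value(p, x) == pytest.approx(logistic, abs=1e-12)

    def test_monotone_in_x(self):
        p = ClineParams(0.0, 30.0)
        xs = np.linspace(-200, 200, 500)
        assert np.all(np.diff(cline_value(p, xs)) > 0)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            ClineParams(0.0, 0.0)


def _quasi_noise_free_series(c=1216.0, w=42.0, n=40, n_sites=30):
    x = np.linspace(1000.0, 1480.0, n_sites)
    p = cline_value(ClineParams(c, w), x)
    k = np.round(n * p).astype(int)
    return SiteSeries(position=x, epoch=np.ones(n_sites), n=np.full(n_sites, n), k=k)


class TestFitCline:
    def test_recovers_quasi_noise_free_parameters(self):
        """Rounded expected counts at 30 sites recover c within 2 km, w within 10%."""
        series = _quasi_noise_free_series()
        fit = fit_cline(series)
        assert fit.params.center == pytest.approx(1216.0, abs=2.0)
        assert fit.params.width == pytest.approx(42.0, rel=0.10)

    def test_mirror_symmetry_width_invariant(self):
        series = _quasi_noise_free_series()
        mirrored = SiteSeries(
            position=-series.position,
            epoch=series.epoch,
            n=series.n,
            k=series.n - series.k,  # re-orient so frequency still rises with x
        )
        f1, f2 = fit_cline(series), fit_cline(mirrored)
        assert f2.params.width == pytest.approx(f1.params.width, rel=1e-4)
        assert f2.params.center == pytest.approx(-f1.params.center, abs=0.1)

    def test_position_shift_moves_center_not_width(self):
        series = _quasi_noise_free_series()
        shifted = SiteSeries(
            position=series.position + 500.0, epoch=series.epoch, n=series.n, k=series.k
        )
        f1, f2 = fit_cline(series), fit_cline(shifted)
        assert f2.params.center == pytest.approx(f1.params.center + 500.0, abs=0.1)
        assert f2.params.width == pytest.approx(f1.params.width, rel=1e-4)

    def test_gaussian_likelihood_matches_grid_least_squares(self):
        """With the noise variance profiled out, the gaussian MLE is the
        least-squares fit; check against a brute-force (c, w) grid."""
        rng = np.random.default_rng(3)
        x = np.linspace(0.0, 200.0, 20)
        truth = ClineParams(105.0, 38.0)
        y = np.asarray(cline_value(truth, x)) + rng.normal(0, 0.03, x.size)
        series = SiteSeries(position=x, epoch=np.ones(20), n=np.full(20, 10), value=y)
        fit = fit_cline(series, likelihood="gaussian")

        cs = np.linspace(80, 130, 161)
        ws = np.linspace(10, 90, 241)
        rss = np.array(
            [
                [np.sum((y - cline_value(ClineParams(c, w), x)) ** 2) for w in ws]
                for c in cs
            ]
        )
        ci, wi = np.unravel_index(np.argmin(rss), rss.shape)
        assert fit.params.center == pytest.approx(cs[ci], abs=0.5)
        assert fit.params.width == pytest.approx(ws[wi], abs=0.5)
        fit_rss = np.sum((y - cline_value(fit.params, x)) ** 2)
        assert fit_rss <= rss.min() + 1e-9

    def test_monomorphic_input_fails(self):
        x = np.linspace(0, 100, 10)
        series = SiteSeries(position=x, epoch=np.ones(10), n=np.full(10, 20), k=np.zeros(10, int))
        with pytest.raises(ClineFitError):
            fit_cline(series)

    def test_narrow_frequency_span_warns_but_fits(self):
        x = np.linspace(0, 100, 12)
        k = np.round(20 * (0.45 + 0.1 * x / 100)).astype(int)
        series = SiteSeries(position=x, epoch=np.ones(12), n=np.full(12, 20), k=k)
        with pytest.warns(UserWarning, match="weakly"):
            fit = fit_cline(series)
        assert fit.degenerate_span

    def test_too_few_sites_rejected(self):
        series = SiteSeries(
            position=[0.0, 1.0], epoch=[1, 1], n=[10, 10], k=[0, 10]
        )
        with pytest.raises(ClineFitError):
            fit_cline(series)

    def test_bootstrap_deterministic_under_seed(self, rng):
        series = simulate_allele_counts(ClineParams(50.0, 20.0), np.linspace(0, 100, 15), 30, rng)
        f1 = fit_cline(series, bootstrap=30, seed=42)
        f2 = fit_cline(series, bootstrap=30, seed=42)
        assert f1.ci95_width == f2.ci95_width
        assert f1.ci95_center == f2.ci95_center
        assert [(d.center, d.width) for d in f1.bootstrap_draws] == [
            (d.center, d.width) for d in f2.bootstrap_draws
        ]

    def test_point_estimate_inside_own_ci(self, rng):
        series = simulate_allele_counts(ClineParams(50.0, 20.0), np.linspace(0, 100, 20), 40, rng)
        fit = fit_cline(series, bootstrap=100, seed=9)
        assert fit.ci95_center[0] <= fit.params.center <= fit.ci95_center[1]
        assert fit.ci95_width[0] <= fit.params.width <= fit.ci95_width[1]


def _two_epoch_series(rng, c=1216.0, w1=42.0, w2=42.0, n=24):
    pos = np.arange(1000.0, 1481.0, 20.0)
    s1 = simulate_allele_counts(ClineParams(c, w1), pos, n, rng, epoch=1)
    s2 = simulate_allele_counts(ClineParams(c, w2), pos, n, rng, epoch=2)
    return SiteSeries(
        position=np.r_[s1.position, s2.position],
        epoch=np.r_[s1.epoch, s2.epoch],
        n=np.r_[s1.n, s2.n],
        k=np.r_[s1.k, s2.k],
    )


class TestBootstrapClines:
    def test_zero_replicates_keeps_point_estimates(self, rng):
        series = _two_epoch_series(rng)
        draws = bootstrap_clines(series, replicates=0, seed=1)
        assert draws.delta_w2.size == 0
        assert draws.fits[1].params.width == pytest.approx(
            fit_cline(series, epoch=1).params.width
        )

    def test_same_seed_same_draw_sequence(self, rng):
        series = _two_epoch_series(rng)
        d1 = bootstrap_clines(series, replicates=20, seed=5)
        d2 = bootstrap_clines(series, replicates=20, seed=5)
        np.testing.assert_array_equal(d1.delta_w2, d2.delta_w2)

    def test_requires_two_epochs(self, rng):
        series = simulate_allele_counts(ClineParams(50.0, 20.0), np.linspace(0, 100, 15), 30, rng)
        with pytest.raises(ClineFitError):
            bootstrap_clines(series, replicates=5, seed=1)


class TestWidthChangeTest:
    def test_constant_draws_collapse_ci(self):
        fits = {
            1: fit_cline(_quasi_noise_free_series(w=42.0)),
            2: fit_cline(_quasi_noise_free_series(w=50.0)),
        }
        d = 50.0**2 - 42.0**2
        draws = EpochDraws(
            epochs=[1, 2],
            fits=fits,
            draws={1: [], 2: []},
            delta_w2=np.full(100, d),
        )
        t = width_change_test(draws, sigma=20.0, delta_t=3.0)
        assert t.ci95 == (pytest.approx(d), pytest.approx(d))
        assert t.neutral_expectation == pytest.approx(2 * np.pi * 400 * 3)
        assert t.less_than_neutral  # d = 736 << 7540
        assert not t.includes_zero

    def test_invalid_sigma_or_delta_t_rejected(self, rng):
        series = _two_epoch_series(rng)
        draws = bootstrap_clines(series, replicates=10, seed=2)
        with pytest.raises(ValueError):
            width_change_test(draws, sigma=0.0, delta_t=3.0)
        with pytest.raises(ValueError):
            width_change_test(draws, sigma=20.0, delta_t=-1.0)

    def test_verdict_flags_follow_ci(self, rng):
        series = _two_epoch_series(rng)
        draws = bootstrap_clines(series, replicates=50, seed=3)
        t = width_change_test(draws, sigma=20.0, delta_t=3.0)
        lo, hi = t.ci95
        assert t.less_than_neutral == (hi < t.neutral_expectation)
        assert t.includes_zero == (lo <= 0.0 <= hi)


class TestIndexSeries:
    def test_rescaled_to_unit_interval_and_site_means(self):
        import pandas as pd

        transect = pd.DataFrame(
            {
                "individual_id": ["a", "b", "c", "d"],
                "site_id": ["s0", "s0", "s1", "s1"],
                "distance_km": [0.0, 0.0, 10.0, 10.0],
                "epoch": [1, 1, 1, 1],
            }
        )
        series = site_series_from_index([2.0, 4.0, 6.0, 10.0], ["a", "b", "c", "d"], transect)
        # min-max rescale: (0, .25, .5, 1) -> site means (.125, .75)
        np.testing.assert_allclose(series.value, [0.125, 0.75])
        np.testing.assert_array_equal(series.n, [2, 2])
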