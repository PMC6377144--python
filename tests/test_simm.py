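import math

import numpy as np
import pandas as pd
import pytest

from isoforage.core_io import (IsotopeSample, McmcConfig, SourceGroup,
                               TrophicEnrichment, ValidationError)
from isoforage.simm import (MixingModelSpec, MixingPosterior, ilr_basis,
                            ilr_forward, ilr_inverse, log_likelihood,
                            mixture_moments, run_paired_models,
                            sample_posterior, summarize_posterior)

LOG_2PI = math.log(2 * math.pi)


def _consumer(d13C, d15N, sid="c1", site="X"):
    return IsotopeSample(sample_id=sid, site=site, habitat_status="natural",
                         category="Armases", d13C=d13C, d15N=d15N,
                         pctC=40.0, pctN=10.0)


class TestMixtureMoments:
    def test_single_source_identity_with_tef(self, tef):
        src = [SourceGroup("A", "X", (-26.0, 3.0), (0.5, 0.4), (40.0, 2.0), 3)]
        mean, _ = mixture_moments(np.array([1.0]), src, tef, "d13C")
        assert mean == pytest.approx(-26.0 + 4.6)   # = -21.4

    def test_equal_concentration_midpoint(self, tef):
        srcs = [
            SourceGroup("A", "X", (-20.0 - 4.6, 0.0), (0.0, 0.0), (10.0, 5.0), 3),
            SourceGroup("B", "X", (-10.0 - 4.6, 0.0), (0.0, 0.0), (10.0, 5.0), 3),
        ]
        mean, var = mixture_moments(np.array([0.5, 0.5]), srcs, tef, "d13C")
        assert mean == pytest.approx(-15.0)

    def test_concentration_weighting(self, tef):
        # conc 2 vs 4 at p = (0.5, 0.5): weights 1/3, 2/3
        srcs = [
            SourceGroup("A", "X", (-20.0 - 4.6, 0.0), (0.0, 0.0), (2.0, 5.0), 3),
            SourceGroup("B", "X", (-10.0 - 4.6, 0.0), (0.0, 0.0), (4.0, 5.0), 3),
        ]
        mean, _ = mixture_moments(np.array([0.5, 0.5]), srcs, tef, "d13C")
        assert mean == pytest.approx((1 * -20.0 + 2 * -10.0) / 3.0)

    def test_variance_formula(self, tef):
        srcs = [
            SourceGroup("A", "X", (-26.0, 3.0), (0.8, 0.5), (40.0, 2.0), 3),
            SourceGroup("B", "X", (-14.0, 7.0), (0.6, 0.4), (40.0, 2.0), 3),
        ]
        p = np.array([0.3, 0.7])
        mean, var = mixture_moments(p, srcs, tef, "d15N")
        # equal concentrations -> w = p
        expect_var = 0.3 ** 2 * (0.5 ** 2 + 0.28 ** 2) \
            + 0.7 ** 2 * (0.4 ** 2 + 0.28 ** 2)
        assert var == pytest.approx(expect_var)

    def test_off_simplex_rejected(self, tef, two_sources):
        with pytest.raises(ValueError, match="simplex"):
            mixture_moments(np.array([0.6, 0.6]), two_sources, tef, "d13C")

    def test_concentration_off_ignores_conc(self, tef):
        srcs = [
            SourceGroup("A", "X", (-20.0 - 4.6, 0.0), (0.0, 0.0), (2.0, 5.0), 3),
            SourceGroup("B", "X", (-10.0 - 4.6, 0.0), (0.0, 0.0), (4.0, 5.0), 3),
        ]
        mean, _ = mixture_moments(np.array([0.5, 0.5]), srcs, tef, "d13C",
                                  concentration_dependent=False)
        assert mean == pytest.approx(-15.0)


class TestLogLikelihood:
    def _spec(self, tef, x=None, error_model="residual_only"):
        srcs = [
            SourceGroup("A", "X", (-26.0, 3.0), (0.8, 0.5), (40.0, 2.0), 3),
            SourceGroup("B", "X", (-14.0, 7.0), (0.9, 0.6), (40.0, 2.0), 3),
        ]
        consumers = [x] if x is not None else []
        return MixingModelSpec(srcs, consumers, tef, error_model=error_model)

    def test_peak_density_at_mixture_mean(self, tef):
        p = np.array([[0.4, 0.6]])
        srcs = [
            SourceGroup("A", "X", (-26.0, 3.0), (0.8, 0.5), (40.0, 2.0), 3),
            SourceGroup("B", "X", (-14.0, 7.0), (0.9, 0.6), (40.0, 2.0), 3),
        ]
        m13, _ = mixture_moments(p[0], srcs, tef, "d13C")
        m15, _ = mixture_moments(p[0], srcs, tef, "d15N")
        spec = self._spec(tef, _consumer(m13, m15))
        ll = log_likelihood(spec, p, np.array([1.0, 1.0]))
        assert ll == pytest.approx(2 * (-0.5 * LOG_2PI))

    def test_doubling_variance_lowers_peak(self, tef):
        p = np.array([[0.4, 0.6]])
        srcs = self._spec(tef).sources
        m13, _ = mixture_moments(p[0], list(srcs), tef, "d13C")
        m15, _ = mixture_moments(p[0], list(srcs), tef, "d15N")
        spec = self._spec(tef, _consumer(m13, m15))
        ll1 = log_likelihood(spec, p, np.array([1.0, 1.0]))
        ll2 = log_likelihood(spec, p, np.array([math.sqrt(2.0)] * 2))
        assert ll2 < ll1

    def test_nonpositive_sd_rejected(self, tef):
        spec = self._spec(tef, _consumer(-20.0, 9.0))
        assert log_likelihood(spec, np.array([[0.5, 0.5]]),
                              np.array([0.0, 1.0])) == -math.inf

    def test_off_simplex_raises(self, tef):
        spec = self._spec(tef, _consumer(-20.0, 9.0))
        with pytest.raises(ValueError, match="simplex"):
            log_likelihood(spec, np.array([[0.7, 0.7]]), np.array([1.0, 1.0]))

    def test_process_error_model_adds_variance(self, tef):
        p = np.array([[0.4, 0.6]])
        c = _consumer(-18.0, 9.0)
        ll_res = log_likelihood(self._spec(tef, c, "residual_only"), p,
                                np.array([1.0, 1.0]))
        ll_proc = log_likelihood(
            self._spec(tef, c, "residual_plus_process"), p,
            np.array([1.0, 1.0]))
        assert ll_res != ll_proc


class TestIlr:
    def test_round_trip(self):
        rng = np.random.default_rng(0)
        for k in (2, 3, 5):
            basis = ilr_basis(k)
            # orthonormal columns orthogonal to 1
            assert np.allclose(basis.T @ basis, np.eye(k - 1), atol=1e-12)
            assert np.allclose(basis.sum(axis=0), 0.0, atol=1e-12)
            p = rng.dirichlet(np.ones(k))
            z = ilr_forward(p, basis)
            p2 = ilr_inverse(z, basis)
            assert np.allclose(p, p2, atol=1e-12)


def _grid_oracle_mean_p1(srcs, consumer, tef, resid_sd, n_grid=1001):
    """Numerically integrated posterior mean of p1 (uniform prior),
    computed from explicit formulas independent of the package moments."""
    p1 = np.linspace(0.0, 1.0, n_grid)[1:-1]
    x = np.array([consumer.d13C, consumer.d15N])
    f = np.array(tef.mean)
    fv = np.square(np.array(tef.sd))
    dens = np.ones_like(p1)
    for t in range(2):
        c1, c2 = srcs[0].conc[t], srcs[1].conc[t]
        w1 = p1 * c1
        w2 = (1 - p1) * c2
        s = w1 + w2
        w1, w2 = w1 / s, w2 / s
        m = w1 * (srcs[0].mu[t] + f[t]) + w2 * (srcs[1].mu[t] + f[t])
        v = (w1 ** 2 * (srcs[0].sigma[t] ** 2 + fv[t])
             + w2 ** 2 * (srcs[1].sigma[t] ** 2 + fv[t])
             + resid_sd[t] ** 2)
        dens *= np.exp(-0.5 * (x[t] - m) ** 2 / v) / np.sqrt(v)
    return float(np.sum(p1 * dens) / np.sum(dens))


class TestSamplePosterior:
    def test_grid_integration_oracle(self, tef, two_sources):
        consumer = _consumer(-18.0, 10.5)
        spec = MixingModelSpec(two_sources, [consumer], tef)
        fixed_sd = np.array([0.5, 0.5])
        oracle = _grid_oracle_mean_p1(two_sources, consumer, tef, fixed_sd)
        mc = McmcConfig(chains=3, iterations=8000, burn_in=3000, thin=5,
                        seed=11)
        post = sample_posterior(spec, mc, fixed_resid_sd=fixed_sd)
        ki = post.source_names.index("A")
        mcmc_mean = float(post.flat_draws()[:, 0, ki].mean())
        assert abs(mcmc_mean - oracle) < 0.02
        assert post.max_rhat < 1.05

    def test_symmetric_midpoint(self, tef):
        srcs = [
            SourceGroup("A", "X", (-26.0, 3.0), (0.7, 0.7), (40.0, 5.0), 3),
            SourceGroup("B", "X", (-14.0, 9.0), (0.7, 0.7), (40.0, 5.0), 3),
        ]
        mid = _consumer((-26.0 - 14.0) / 2 + tef.delta_d13C_mean,
                        (3.0 + 9.0) / 2 + tef.delta_d15N_mean)
        spec = MixingModelSpec(srcs, [mid], tef)
        mc = McmcConfig(chains=2, iterations=6000, burn_in=2000, thin=4,
                        seed=2)
        post = sample_posterior(spec, mc)
        means = post.flat_draws().mean(axis=0)[0]
        assert np.allclose(means, 0.5, atol=0.05)

    def test_seed_determinism(self, tef, two_sources, fast_mcmc):
        spec = MixingModelSpec(two_sources, [_consumer(-18.0, 10.0)], tef)
        p1 = sample_posterior(spec, fast_mcmc)
        p2 = sample_posterior(spec, fast_mcmc)
        assert np.array_equal(p1.draws, p2.draws)
        assert np.array_equal(p1.resid_sd, p2.resid_sd)

    def test_draws_on_simplex(self, tef, two_sources, fast_mcmc):
        spec = MixingModelSpec(two_sources, [_consumer(-18.0, 10.0)], tef)
        post = sample_posterior(spec, fast_mcmc)
        sums = post.draws.sum(axis=-1)
        assert np.abs(sums - 1.0).max() < 1e-9
        assert (post.draws >= 0).all()

    def test_parameter_recovery_two_sources(self, tef):
        rng = np.random.default_rng(42)
        srcs = [
            SourceGroup("A", "X", (-26.0, 2.0), (0.5, 0.5), (40.0, 5.0), 3),
            SourceGroup("B", "X", (-16.0, 12.0), (0.5, 0.5), (40.0, 5.0), 3),
        ]
        p_true = np.array([0.7, 0.3])
        mu = np.array([[-26.0, 2.0], [-16.0, 12.0]])
        mean = p_true @ (mu + np.array(tef.mean))
        consumers = [
            _consumer(float(mean[0] + rng.normal(0, 0.7)),
                      float(mean[1] + rng.normal(0, 0.7)), sid=f"c{i}")
            for i in range(30)
        ]
        spec = MixingModelSpec(srcs, consumers, tef)
        mc = McmcConfig(chains=3, iterations=4000, burn_in=2000, thin=2,
                        seed=3)
        post = sample_posterior(spec, mc)
        ki = post.source_names.index("A")
        m = float(post.flat_draws()[:, 0, ki].mean())
        assert 0.6 <= m <= 0.8
        assert post.max_rhat < 1.05

    def test_prior_predictive_uniform(self, tef):
        srcs = [SourceGroup(n, "X", mu, (0.8, 0.5), (40.0, 5.0), 3)
                for n, mu in (("A", (-26.0, 3.0)), ("B", (-14.0, 7.0)),
                              ("C", (-20.0, 10.0)))]
        spec = MixingModelSpec(srcs, [], tef)
        mc = McmcConfig(chains=2, iterations=22_000, burn_in=2000, thin=2,
                        seed=5)
        post = sample_posterior(spec, mc, fixed_resid_sd=np.array([1.0, 1.0]))
        means = post.flat_draws().mean(axis=0)[0]
        assert np.abs(means - 1.0 / 3.0).max() < 0.03

    def test_concentration_off_equals_equal_conc(self, tef):
        rng = np.random.default_rng(6)
        consumers = [_consumer(-18.0 + float(rng.normal(0, 0.3)),
                               10.0 + float(rng.normal(0, 0.3)), sid=f"c{i}")
                     for i in range(10)]
        srcs_eq = [
            SourceGroup("A", "X", (-26.0, 3.0), (0.8, 0.5), (30.0, 4.0), 3),
            SourceGroup("B", "X", (-14.0, 12.0), (0.9, 0.6), (30.0, 4.0), 3),
        ]
        mc = McmcConfig(chains=2, iterations=6000, burn_in=2000, thin=4,
                        seed=8)
        spec_on = MixingModelSpec(srcs_eq, consumers, tef,
                                  concentration_dependent=True)
        spec_off = MixingModelSpec(srcs_eq, consumers, tef,
                                   concentration_dependent=False)
        m_on = sample_posterior(spec_on, mc).flat_draws().mean(axis=0)
        m_off = sample_posterior(spec_off, mc).flat_draws().mean(axis=0)
        assert np.abs(m_on - m_off).max() < 0.05   # MCMC noise only

    def test_mismatched_source_menus_rejected(self, tef):
        srcs = [
            SourceGroup("A", "X", (-26.0, 3.0), (0.5, 0.5), (40.0, 5.0), 3),
            SourceGroup("B", "X", (-14.0, 7.0), (0.5, 0.5), (40.0, 5.0), 3),
            SourceGroup("A", "Y", (-26.0, 3.0), (0.5, 0.5), (40.0, 5.0), 3),
        ]
        consumers = [_consumer(-20.0, 8.0, site="X"),
                     _consumer(-20.0, 8.0, sid="c2", site="Y")]
        with pytest.raises(ValidationError, match="menu"):
            MixingModelSpec(srcs, consumers, tef)


class TestSummarize:
    def _degenerate_posterior(self):
        draws = np.full((2, 10, 1, 2), 0.5)
        return MixingPosterior(
            draws=draws, resid_sd=np.full((2, 10, 2), 1.0),
            sites=["X"], source_names=["A", "B"],
            diagnostics=pd.DataFrame([{"parameter": "p", "rhat": 1.0,
                                       "ess": 20.0}]),
            acceptance_rate=0.3, seed=0)

    def test_degenerate_sd_zero(self):
        summary = summarize_posterior(self._degenerate_posterior())
        assert (summary["sd"] == 0.0).all()
        assert (summary["mean"] == 0.5).all()

    def test_means_sum_to_one(self, tef, two_sources, fast_mcmc):
        spec = MixingModelSpec(two_sources, [_consumer(-18.0, 10.0)], tef)
        post = sample_posterior(spec, fast_mcmc)
        summary = summarize_posterior(post)
        assert summary.groupby("site")["mean"].sum().iloc[0] == pytest.approx(
            1.0, abs=1e-9)

    def test_percentiles_match_sorted_draw_oracle(self, tef, two_sources,
                                                  fast_mcmc):
        spec = MixingModelSpec(two_sources, [_consumer(-18.0, 10.0)], tef)
        post = sample_posterior(spec, fast_mcmc)
        summary = summarize_posterior(post).set_index("source")
        d = np.sort(post.flat_draws()[:, 0, post.source_names.index("A")])

        def quantile(sorted_v, q):
            # linear interpolation between closest ranks (matches the
            # default definition)
            h = (len(sorted_v) - 1) * q
            lo = int(math.floor(h))
            hi = min(lo + 1, len(sorted_v) - 1)
            return sorted_v[lo] + (h - lo) * (sorted_v[hi] - sorted_v[lo])

        assert summary.loc["A", "q2.5"] == pytest.approx(
            quantile(d, 0.025), rel=1e-12)
        assert summary.loc["A", "median"] == pytest.approx(
            quantile(d, 0.5), rel=1e-12)

    def test_empty_draws_rejected(self):
        post = self._degenerate_posterior()
        post.draws = np.empty((0, 0, 0, 0))
        with pytest.raises(ValueError, match="draws"):
            summarize_posterior(post)


class TestPairedModels:
    def _specs(self, tef, drop_source=False):
        rng = np.random.default_rng(13)

        def make(menu, site):
            return [SourceGroup(n, site, mu, (0.6, 0.5), (40.0, 5.0), 3)
                    for n, mu in menu]

        menu_full = [("A", (-26.0, 3.0)), ("B", (-14.0, 9.0)),
                     ("C", (-20.0, 12.0))]
        menu_dist = menu_full[:-1] if drop_source else menu_full
        cons_n = [_consumer(-18.0 + float(rng.normal(0, 0.4)),
                            10.0 + float(rng.normal(0, 0.4)), sid=f"n{i}",
                            site="N") for i in range(6)]
        cons_d = [_consumer(-18.0 + float(rng.normal(0, 0.4)),
                            10.0 + float(rng.normal(0, 0.4)), sid=f"d{i}",
                            site="D") for i in range(6)]
        spec_n = MixingModelSpec(make(menu_full, "N"), cons_n, tef)
        spec_d = MixingModelSpec(make(menu_dist, "D"), cons_d, tef)
        return spec_n, spec_d

    def test_missing_source_shrinks_table(self, tef, fast_mcmc):
        spec_n, spec_d = self._specs(tef, drop_source=True)
        post_n, post_d, comparison = run_paired_models(spec_n, spec_d,
                                                       fast_mcmc)
        assert len(post_d.source_names) == len(post_n.source_names) - 1
        shared = set(post_n.source_names) & set(post_d.source_names)
        assert set(comparison["source"]) == shared
        assert len(comparison) == 2 * len(shared)

    def test_identical_populations_overlap(self, tef):
        spec_n, spec_d = self._specs(tef, drop_source=False)
        mc = McmcConfig(chains=2, iterations=5000, burn_in=2000, thin=3,
                        seed=4)
        _, _, comparison = run_paired_models(spec_n, spec_d, mc)
        for src, grp in comparison.groupby("source"):
            nat = grp[grp["population"] == "natural"].iloc[0]
            dist = grp[grp["population"] == "disturbed"].iloc[0]
            assert nat["q2.5"] <= dist["q97.5"]
            assert dist["q2.5"] <= nat["q97.5"]
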