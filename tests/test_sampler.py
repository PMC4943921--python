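"""Independence Metropolis chain mechanics, ESS/MCSE estimation and
posterior functionals, validated on analytic Gaussian targets."""

import math

import numpy as np
import pytest
from scipy import stats

import epbayes as ep
from epbayes.laplace import LaplaceFit

from conftest import GaussianTarget


def gaussian_proposal(target):
    return LaplaceFit(
        mode=target.mean.copy(), names=list(target.names), covariance=target.cov.copy()
    )


class TestImChain:
    def test_target_equals_proposal_accepts_everything(self, gaussian_target):
        chain = ep.run_im_chain(
            gaussian_target, gaussian_proposal(gaussian_target),
            iterations=2000, thinning=1, seed=0,
        )
        assert chain.acceptance_rate == 1.0
        # accepted proposals are i.i.d. from the target: KS against the
        # known Gaussian marginals
        for j in range(2):
            sd = math.sqrt(gaussian_target.cov[j, j])
            ks = stats.kstest(
                chain.draws[:, j], lambda x: stats.norm.cdf(x, gaussian_target.mean[j], sd)
            )
            assert ks.pvalue > 0.01

    def test_correlated_gaussian_mean_recovery(self, gaussian_target):
        # deliberately mismatched proposal: wider and offset
        proposal = LaplaceFit(
            mode=gaussian_target.mean + 0.3,
            names=list(gaussian_target.names),
            covariance=1.5 * gaussian_target.cov,
        )
        chain = ep.run_im_chain(
            gaussian_target, proposal, iterations=20000, thinning=2, seed=5
        )
        summary = ep.summarize_chain(chain)
        for j, name in enumerate(gaussian_target.names):
            err = abs(summary.loc[name, "Mean"] - gaussian_target.mean[j])
            assert err < 3 * summary.loc[name, "MCSE"] + 1e-12

    def test_bit_reproducible(self, table1_logpost, table1_laplace):
        kw = dict(iterations=500, thinning=5, seed=123)
        for rule in ("exact", "reference"):
            a = ep.run_im_chain(table1_logpost, table1_laplace,
                                acceptance_rule=rule, **kw)
            b = ep.run_im_chain(table1_logpost, table1_laplace,
                                acceptance_rule=rule, **kw)
            np.testing.assert_array_equal(a.draws, b.draws)
            np.testing.assert_array_equal(a.deviance, b.deviance)

    def test_rules_differ(self, table1_logpost, table1_laplace):
        kw = dict(iterations=2000, thinning=2, seed=7)
        exact = ep.run_im_chain(table1_logpost, table1_laplace,
                                acceptance_rule="exact", **kw)
        ref = ep.run_im_chain(table1_logpost, table1_laplace,
                              acceptance_rule="reference", **kw)
        # the reference rule concentrates around the mode
        assert ref.draws[:, 0].std() < exact.draws[:, 0].std()

    def test_student_proposal_still_targets_posterior(self, gaussian_target):
        proposal = gaussian_proposal(gaussian_target)
        chain = ep.run_im_chain(
            gaussian_target, proposal, iterations=8000, thinning=2,
            seed=11, proposal_df=5.0,
        )
        summary = ep.summarize_chain(chain)
        for j, name in enumerate(gaussian_target.names):
            err = abs(summary.loc[name, "Mean"] - gaussian_target.mean[j])
            assert err < 4 * summary.loc[name, "MCSE"]

    def test_kept_count_and_thinning(self, table1_logpost, table1_laplace):
        chain = ep.run_im_chain(table1_logpost, table1_laplace,
                                iterations=1005, thinning=10, seed=1)
        assert chain.n_kept == 100
        assert chain.thinning == 10

    def test_nonfinite_start_raises(self, table1_logpost):
        bad = LaplaceFit(
            mode=np.array([800.0, -800.0]),  # exp overflow: posterior -inf
            names=["log.gamma", "log.alpha"],
            covariance=np.diag([1e-6, 1e-6]),
        )
        with pytest.raises(ValueError, match="chain start"):
            ep.run_im_chain(table1_logpost, bad, iterations=100, thinning=1, seed=0)

    def test_low_acceptance_warns(self):
        # a sharply concentrated target probed with a far-too-broad
        # proposal: almost no proposal lands in the high-density ball
        target = GaussianTarget([0.0, 0.0], 1e-4 * np.eye(2))
        proposal = LaplaceFit(
            mode=np.zeros(2), names=list(target.names),
            covariance=100.0 * np.eye(2),
        )
        with pytest.warns(RuntimeWarning, match="acceptance rate"):
            ep.run_im_chain(target, proposal, iterations=300, thinning=1, seed=1)

    def test_invalid_arguments(self, table1_logpost, table1_laplace):
        with pytest.raises(ValueError):
            ep.run_im_chain(table1_logpost, table1_laplace, iterations=5,
                            thinning=10, seed=0)
        with pytest.raises(ValueError):
            ep.run_im_chain(table1_logpost, table1_laplace,
                            acceptance_rule="metropolis", seed=0)


class TestEss:
    def test_iid_normal(self):
        x = np.random.default_rng(0).standard_normal(1000)
        ess = ep.geyer_ess(x)
        assert 700 <= ess <= 1000
        assert abs(x.mean()) < 3 / math.sqrt(1000)

    def test_ar1_integrated_autocorrelation(self):
        rho, n = 0.9, 40000
        rng = np.random.default_rng(42)
        x = np.empty(n)
        x[0] = rng.standard_normal()
        eps = rng.standard_normal(n) * math.sqrt(1 - rho**2)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        expected = n * (1 - rho) / (1 + rho)
        assert ep.geyer_ess(x) == pytest.approx(expected, rel=0.30)

    def test_cross_check_against_arviz(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(1)
        x = np.convolve(rng.standard_normal(5200), np.ones(5) / 5, mode="valid")
        ours = ep.geyer_ess(x)
        theirs = float(az.ess(np.asarray(x)[None, :]))
        assert ours == pytest.approx(theirs, rel=0.25)

    def test_constant_column_warns(self):
        with pytest.warns(RuntimeWarning, match="constant"):
            assert ep.geyer_ess(np.ones(50)) == 50


class TestSummaries:
    def test_order_statistics_and_mcse(self, table1_reference_chain):
        summary = ep.summarize_chain(table1_reference_chain)
        assert np.all(summary["LB"] <= summary["Median"])
        assert np.all(summary["Median"] <= summary["UB"])
        assert np.all(summary["ESS"] <= table1_reference_chain.n_kept + 1e-9)
        np.testing.assert_allclose(
            summary["MCSE"], summary["SD"] / np.sqrt(summary["ESS"]), rtol=1e-12
        )

    def test_burnin_fraction(self, table1_reference_chain):
        full = ep.summarize_chain(table1_reference_chain)
        trimmed = ep.summarize_chain(table1_reference_chain, burnin=0.5)
        assert not np.allclose(full["Mean"], trimmed["Mean"])
        with pytest.raises(ValueError):
            ep.summarize_chain(table1_reference_chain, burnin=1.5)


class TestPosteriorFunctionals:
    def test_identity_reproduces_parameter_summary(self, table1_reference_chain):
        chain = table1_reference_chain
        ep.posterior_functional(chain, lambda nat: np.log(nat["alpha"]), "ident")
        summary = ep.summarize_chain(chain)
        assert summary.loc["ident", "Mean"] == pytest.approx(
            summary.loc["log.alpha", "Mean"], rel=1e-12
        )

    def test_reliability_plus_cdf_is_one(self, table1_reference_chain):
        chain = table1_reference_chain
        r = ep.posterior_functional(chain, ep.reliability_monitor(23.13), "R")
        f = ep.posterior_functional(
            chain,
            lambda nat: 1.0
            - np.exp(1.0 - np.exp((23.13 / nat["alpha"]) ** nat["gamma"])),
            "F",
        )
        np.testing.assert_allclose(r.to_numpy() + f.to_numpy(), 1.0, rtol=1e-12)

    def test_changepoint_undefined_draws_flagged(self, table1_reference_chain):
        chain = table1_reference_chain
        nat = chain.natural()
        frac_defined = float((nat["gamma"] < 1).mean())
        if frac_defined == 1.0:  # pragma: no cover - depends on the chain
            pytest.skip("no monotone-hazard draws in this chain")
        with pytest.warns(RuntimeWarning, match="undefined"):
            ep.posterior_functional(chain, ep.changepoint_monitor(), "t0")
        summary = ep.summarize_chain(chain)
        assert summary.loc["t0", "Defined"] == pytest.approx(frac_defined, abs=1e-12)

    def test_hazard_threshold_monitors_solve_the_equation(self):
        # a small chain of draws guaranteed to be bathtub-shaped
        layout = ep.ParameterLayout("null")
        rng = np.random.default_rng(2)
        draws = np.column_stack(
            [np.log(rng.uniform(0.4, 0.8, 50)), np.log(rng.uniform(5.0, 15.0, 50))]
        )
        chain = ep.PosteriorDraws(
            draws=draws, names=layout.names, layout=layout,
            deviance=np.zeros(50), thinning=1,
        )
        rate = 0.5
        lo = ep.posterior_functional(chain, ep.burnin_time_monitor(rate), "tb")
        hi = ep.posterior_functional(chain, ep.replacement_time_monitor(rate), "tc")
        nat = chain.natural()
        for i in range(50):
            params = ep.EPParams(nat["gamma"][i], nat["alpha"][i])
            for root in (lo[i], hi[i]):
                if np.isfinite(root):
                    assert float(ep.ep_hazard(root, params)) == pytest.approx(
                        rate, rel=1e-8
                    )
            if np.isfinite(lo[i]) and np.isfinite(hi[i]):
                t0 = ep.hazard_changepoint(params)
                assert lo[i] <= t0 <= hi[i]

    def test_wrong_length_functional_raises(self, table1_reference_chain):
        with pytest.raises(ValueError):
            ep.posterior_functional(
                table1_reference_chain, lambda nat: np.ones(3), "bad"
            )
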