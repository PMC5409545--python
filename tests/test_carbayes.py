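import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln

import radonmap as rm
from radonmap.carbayes import (
    CARModelSpec,
    ChainState,
    MCMCConfig,
    MCMCSamples,
    build_design,
    effective_sample_size,
    gelman_rubin,
    log_posterior,
    mcmc_run,
    quintile_groups,
    summarize_posterior,
)


def chain3_spec(**kwargs):
    """Three regions in a chain graph 1-2-3; tiny hand-checkable data."""
    defaults = dict(
        observed=np.array([3.0, 5.0, 2.0]),
        expected=np.array([4.0, 4.0, 4.0]),
        design=np.array([[1.0], [2.0], [3.0]]),
        colnames=["radon_per10"],
        region_ids=[1, 2, 3],
        adjacency=frozenset({(1, 2), (2, 3)}),
    )
    defaults.update(kwargs)
    return CARModelSpec(**defaults)


class TestQuintilesAndDesign:
    def test_234_zscores_split_47_47_47_47_46(self):
        z = np.random.default_rng(1).standard_normal(234)
        q = quintile_groups(z)
        assert np.bincount(q)[1:].tolist() == [47, 47, 47, 47, 46]
        # groups respect the ordering of z
        order = np.argsort(z)
        assert (np.diff(q[order]) >= 0).all()

    def test_radon_scaling_per_10(self):
        cov = pd.DataFrame({"region_id": [1], "deprivation_z": [0.0],
                            "smoking_male": [50.0]})
        x, names = build_design(np.array([57.0]), cov, adjusted=False)
        assert x[0, 0] == pytest.approx(5.7)
        assert names == ["radon_per10"]

    def test_adjusted_design_columns(self):
        rng = np.random.default_rng(2)
        cov = pd.DataFrame({
            "region_id": np.arange(20),
            "deprivation_z": rng.standard_normal(20),
            "smoking_male": rng.uniform(30, 60, 20),
        })
        x, names = build_design(rng.uniform(20, 200, 20), cov,
                                sex="male", adjusted=True)
        assert names == ["radon_per10", "smoking_centered",
                         "di_q2", "di_q3", "di_q4", "di_q5"]
        assert x[:, 1].mean() == pytest.approx(0.0, abs=1e-12)
        assert set(np.unique(x[:, 2:])) <= {0.0, 1.0}

    def test_empty_quintile_flagged_then_rank_checked(self, caplog):
        # 4 regions: quintile 5 is necessarily empty under the rank rule; the
        # empty indicator is flagged and dropped, after which the remaining
        # one-hot columns span too much of a 4-row design and rank fails
        cov = pd.DataFrame({
            "region_id": [1, 2, 3, 4],
            "deprivation_z": [0.1, -0.5, 1.2, 0.7],
            "smoking_male": [40.0, 45.0, 50.0, 55.0],
        })
        assert 5 not in quintile_groups(cov["deprivation_z"])
        with caplog.at_level("WARNING"), pytest.raises(ValueError, match="rank"):
            build_design(np.array([30, 40, 50, 60.0]), cov,
                         sex="male", adjusted=True)
        assert any("quintile 5 is empty" in r.message for r in caplog.records)

    def test_rank_deficiency_rejected(self):
        spec_kwargs = dict(design=np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]]),
                           colnames=["a", "b"])
        with pytest.raises(ValueError, match="rank deficient"):
            chain3_spec(**spec_kwargs)


class TestLogPosterior:
    def test_closed_form_reduction_at_zero_state(self):
        spec = chain3_spec(include_u=False, include_v=False)
        state = ChainState(0.0, np.zeros(1), np.zeros(3), np.zeros(3), 1.0, 1.0)
        o, e = spec.observed, spec.expected
        expect = float(np.sum(o * np.log(e) - e - gammaln(o + 1)))
        # alpha normal prior contributes 0 at alpha=0, beta likewise
        assert log_posterior(state, spec) == pytest.approx(expect, abs=1e-12)

    def test_hand_summed_three_region_oracle(self):
        spec = chain3_spec()
        state = ChainState(
            alpha=0.3, beta=np.array([-0.1]),
            u=np.array([0.2, -0.3, 0.1]), v=np.array([0.05, 0.0, -0.05]),
            tau_u=2.0, tau_v=3.0,
        )
        # independent term-by-term evaluation
        lp = 0.0
        for i in range(3):
            eta = (state.alpha + spec.design[i, 0] * state.beta[0]
                   + state.u[i] + state.v[i])
            lam = spec.expected[i] * np.exp(eta)
            o = spec.observed[i]
            lp += o * np.log(lam) - lam - gammaln(o + 1)
        s2 = spec.beta_prior_sd**2
        lp -= state.alpha**2 / (2 * s2) + state.beta[0]**2 / (2 * s2)
        ss = (state.u[0] - state.u[1])**2 + (state.u[1] - state.u[2])**2
        lp += (3 - 1) / 2 * np.log(state.tau_u) - state.tau_u / 2 * ss
        lp += (spec.tau_shape - 1) * np.log(state.tau_u) - spec.tau_rate * state.tau_u
        lp += 3 / 2 * np.log(state.tau_v) - state.tau_v / 2 * np.sum(state.v**2)
        lp += (spec.tau_shape - 1) * np.log(state.tau_v) - spec.tau_rate * state.tau_v
        assert log_posterior(state, spec) == pytest.approx(lp, rel=1e-12)

    def test_icar_term_invariant_to_constant_shift(self):
        """Adding c to every u changes the likelihood but not the pairwise term."""
        spec = chain3_spec(include_v=False)
        u = np.array([0.2, -0.3, 0.1])
        s_a = ChainState(0.0, np.zeros(1), u, np.zeros(3), 2.0, 1.0)
        s_b = ChainState(0.0, np.zeros(1), u + 0.7, np.zeros(3), 2.0, 1.0)
        o, e = spec.observed, spec.expected
        # likelihood-only difference from the shift
        def loglik(uu):
            lam = e * np.exp(uu)
            return float(np.sum(o * np.log(lam) - lam - gammaln(o + 1)))
        expected_delta = loglik(u + 0.7) - loglik(u)
        assert (log_posterior(s_b, spec) - log_posterior(s_a, spec)
                == pytest.approx(expected_delta, rel=1e-12))

    def test_non_finite_state_returns_minus_inf(self):
        spec = chain3_spec()
        state = ChainState(1e5, np.zeros(1), np.zeros(3), np.zeros(3), 1.0, 1.0)
        assert log_posterior(state, spec) == -np.inf


class TestDetailedBalance:
    def test_acceptance_log_ratio_is_reciprocal(self):
        """log r(a->b) = -log r(b->a) for a symmetric proposal pair."""
        spec = chain3_spec()
        rng = np.random.default_rng(3)
        a = ChainState(0.1, rng.normal(size=1), rng.normal(size=3) * 0.1,
                       rng.normal(size=3) * 0.1, 1.5, 2.5)
        a.u -= a.u.mean()
        b = ChainState(a.alpha + 0.05, a.beta + 0.02, a.u.copy(), a.v.copy(),
                       a.tau_u, a.tau_v)
        fwd = log_posterior(b, spec) - log_posterior(a, spec)
        rev = log_posterior(a, spec) - log_posterior(b, spec)
        assert fwd == pytest.approx(-rev, abs=1e-12)


class TestGelmanRubin:
    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(11)
        chains = rng.standard_normal((5, 10_000))
        assert 0.99 <= gelman_rubin(chains) <= 1.01

    def test_separated_chains_match_direct_formula(self):
        rng = np.random.default_rng(12)
        n = 1000
        chains = np.vstack([rng.standard_normal(n), rng.standard_normal(n) + 100])
        rhat = gelman_rubin(chains)
        w = np.mean([chains[0].var(ddof=1), chains[1].var(ddof=1)])
        b = n * np.var([chains[0].mean(), chains[1].mean()], ddof=1)
        direct = np.sqrt(((n - 1) / n * w + b / n) / w)
        assert rhat == pytest.approx(direct, rel=1e-12)
        assert rhat > 1.1

    def test_duplicated_chain_gives_sub_unity(self):
        c = np.random.default_rng(13).standard_normal(500)
        rhat = gelman_rubin(np.vstack([c, c]))
        assert rhat == pytest.approx(np.sqrt(499 / 500), rel=1e-12)

    def test_degenerate_chains_error(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.ones((2, 100)))


class TestMCMC:
    def test_conjugate_gamma_oracle(self):
        """2-region intercept-only model: posterior of exp(alpha) is Gamma."""
        o = np.array([40.0, 70.0])
        e = np.array([50.0, 60.0])
        spec = CARModelSpec(
            observed=o, expected=e, design=np.empty((2, 0)), colnames=[],
            region_ids=[1, 2], adjacency=frozenset({(1, 2)}),
            include_u=False, include_v=False, alpha_prior="flat_exp",
        )
        cfg = MCMCConfig(n_chains=2, n_iter=20_000, burn_in=5_000, thin=5, seed=7)
        lam = np.exp(mcmc_run(spec, cfg).pooled("alpha"))
        g = stats.gamma(a=o.sum() + 1, scale=1 / e.sum())
        assert lam.mean() == pytest.approx(g.mean(), rel=0.02)
        assert np.quantile(lam, 0.025) == pytest.approx(g.ppf(0.025), rel=0.02)
        assert np.quantile(lam, 0.975) == pytest.approx(g.ppf(0.975), rel=0.02)

    def test_same_seed_reproduces_chains(self):
        spec = chain3_spec()
        cfg = MCMCConfig(n_chains=2, n_iter=400, burn_in=100, thin=2, seed=42)
        a = mcmc_run(spec, cfg)
        b = mcmc_run(spec, cfg)
        for name in a.draws:
            assert np.array_equal(a.draws[name], b.draws[name])

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            MCMCConfig(thin=0)


class TestCrudeVsAdjusted:
    def test_no_covariate_effects_crude_equals_adjusted(self):
        """With zero covariate effects and covariates independent of radon,
        crude and adjusted radon coefficients are statistically
        indistinguishable: the mean paired difference across replicates lies
        within the 95% Monte-Carlo band (2 standard errors) around zero."""
        import radonmap.geostat as gs
        from radonmap import synthetic as syn

        grid = rm.GridSpec(nx=25, ny=25)
        params = rm.calibrate_field_params()
        rates = syn.default_reference_rates("nhl")
        cfg = MCMCConfig(n_chains=3, n_iter=2000, burn_in=500, thin=5, seed=0)
        diffs = []
        for rep, ss in enumerate(np.random.SeedSequence(77).spawn(8)):
            s_f, s_r, s_c, s_n, s_m = ss.spawn(5)
            f = rm.simulate_log_field(grid, params, s_f)
            regs = rm.make_regions(grid, 60, seed=s_r)
            radon = rm.aggregate_to_regions(np.exp(f), regs)["radon_bqm3"].to_numpy()
            cov = syn.make_region_covariates(regs, radon, seed=s_c)
            truth = rm.TruthRecord(beta_radon=np.log(1.07), sigma_u=0.1,
                                   sigma_v=0.05)
            strata = rm.simulate_strata_and_counts(
                regs, cov, truth, reference_rates=rates, seed=s_n)
            st = rm.sir_from_strata(strata, sex="female")
            betas = {}
            for adjusted in (False, True):
                x, names = build_design(radon, cov, sex="female",
                                        adjusted=adjusted)
                spec = CARModelSpec(
                    observed=st["observed"].to_numpy(),
                    expected=st["expected"].to_numpy(),
                    design=x, colnames=names,
                    region_ids=st["region_id"].tolist(),
                    adjacency=regs.adjacency,
                )
                seed = int(s_m.generate_state(1)[0] % 2**31) + int(adjusted)
                s = mcmc_run(spec, MCMCConfig(n_chains=3, n_iter=2000,
                                              burn_in=500, thin=5, seed=seed))
                summ = summarize_posterior(s)
                betas[adjusted] = float(
                    summ.loc[summ.parameter == "radon_per10", "mean"].iloc[0]
                )
            diffs.append(betas[True] - betas[False])
        diffs = np.asarray(diffs)
        mc_se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < max(2 * mc_se, 1e-4), (diffs.mean(), mc_se)


class TestSummaries:
    def test_point_mass_draws(self):
        draws = np.full((2, 200), np.log(1.07))
        samples = MCMCSamples(draws={"radon_per10": draws}, colnames=["radon_per10"])
        with pytest.raises(ValueError):
            # degenerate chains have no within-chain variance for R-hat
            summarize_posterior(samples)
        out = summarize_posterior(
            MCMCSamples(draws={"radon_per10": draws[:1]}, colnames=["radon_per10"])
        )
        r = out.iloc[0]
        assert r["rr_mean"] == pytest.approx(1.07)
        assert r["rr_q025"] == pytest.approx(1.07)
        assert r["rr_q975"] == pytest.approx(1.07)

    def test_normal_draws_credible_interval_closed_form(self):
        rng = np.random.default_rng(21)
        draws = rng.normal(0.0, 0.01, size=(1, 100_000))
        out = summarize_posterior(MCMCSamples(draws={"b": draws}, colnames=["b"]))
        r = out.iloc[0]
        assert r["rr_q025"] == pytest.approx(np.exp(-0.0196), abs=2e-4)
        assert r["rr_q975"] == pytest.approx(np.exp(0.0196), abs=2e-4)

    def test_rr_quantiles_are_exp_of_log_quantiles(self):
        rng = np.random.default_rng(22)
        draws = rng.normal(size=(3, 500))
        out = summarize_posterior(MCMCSamples(draws={"b": draws}, colnames=["b"]))
        r = out.iloc[0]
        assert r["rr_q025"] == np.exp(r["q025"])
        assert r["rr_q975"] == np.exp(r["q975"])
        assert r["q025"] <= r["median"] <= r["q975"]

    def test_too_few_draws_refused(self):
        draws = np.empty((2, 0))
        samples = MCMCSamples(draws={"b": draws}, colnames=["b"])
        with pytest.raises(ValueError, match="need >= 100"):
            summarize_posterior(samples)

    def test_ess_of_iid_draws_near_n(self):
        rng = np.random.default_rng(30)
        c = rng.standard_normal((2, 5000))
        assert effective_sample_size(c) > 5000 * 2 * 0.8
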