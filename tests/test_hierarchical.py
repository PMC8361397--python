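"""Model graph construction, likelihood, MCMC sampler and diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from antdrift import cohort, ddm, hierarchical as hm


def toy_table(n_subjects=2, n_trials=8, conditions=("congruent",), seed=0,
              group="G", covariates=()):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        for k in range(n_trials):
            row = {
                "subject_id": f"{group}-{i}",
                "group": group,
                "run": 0,
                "condition": conditions[k % len(conditions)],
                "response": int(rng.random() < 0.8),
                "rt": float(rng.uniform(0.4, 1.8)),
            }
            for cov in covariates:
                row[cov] = float(rng.standard_normal())
            rows.append(row)
    return pd.DataFrame(rows)


class TestBuildModel:
    def test_minimal_graph_nodes(self):
        """One subject, one condition, no covariates: subject nodes plus
        their group hyper-nodes only."""
        data = toy_table(n_subjects=1)
        model = hm.build_model(hm.ModelSpec(varies_by_condition=("v",)), data)
        assert sorted(model.params) == sorted(
            ["v[G-0]", "a[G-0]", "t0[G-0]",
             "mu_v[G]", "sigma_v[G]", "mu_a[G]", "sigma_a[G]",
             "mu_t0[G]", "sigma_t0[G]"])

    def test_condition_effects_only_for_varying_parameters(self):
        data = toy_table(conditions=ddm.CONDITIONS)
        m1 = hm.build_model(hm.ModelSpec(varies_by_condition=("v",)), data)
        assert any(p.startswith("b_v[") for p in m1.params)
        assert not any(p.startswith("b_a[") for p in m1.params)

    def test_full_variant_adds_boundary_effects(self):
        """The both-vary variant has exactly two extra boundary-effect
        coefficients per group over the drift-only variant."""
        tables = [toy_table(conditions=ddm.CONDITIONS, group=g, seed=i)
                  for i, g in enumerate(("Control", "AD", "LBD"))]
        data = pd.concat(tables, ignore_index=True)
        m1 = hm.build_model(hm.ModelSpec(varies_by_condition=("v",)), data)
        m3 = hm.build_model(hm.ModelSpec(varies_by_condition=("v", "a")), data)
        assert m3.n_parameters - m1.n_parameters == 2 * 3

    def test_unknown_condition_rejected(self):
        data = toy_table()
        data.loc[0, "condition"] = "neutral"
        with pytest.raises(ValueError, match="schema|task"):
            hm.build_model(hm.ModelSpec(), data)

    def test_missing_covariate_rejected(self):
        with pytest.raises(ValueError, match="covariate"):
            hm.build_model(hm.ModelSpec(covariates=("beta_x",)), toy_table())

    def test_censored_rows_rejected(self):
        data = toy_table()
        data.loc[0, "response"] = -1
        with pytest.raises(ValueError, match="censored|filter"):
            hm.build_model(hm.ModelSpec(), data)


class TestLogLikelihood:
    def _state(self, model, v=1.5, a=1.6, t0=0.3):
        state = {}
        for g in model.groups:
            state.update({f"mu_v[{g}]": v, f"sigma_v[{g}]": 0.5,
                          f"mu_a[{g}]": a, f"sigma_a[{g}]": 0.3,
                          f"mu_t0[{g}]": t0, f"sigma_t0[{g}]": 0.1})
        for p in model.params:
            if p.startswith("b_"):
                state[p] = 0.1
        for s in model.subjects:
            state.update({f"v[{s}]": v, f"a[{s}]": a, f"t0[{s}]": t0})
        return state

    def test_single_trial_reduces_to_wfpt_density(self):
        data = toy_table(n_subjects=1, n_trials=1)
        model = hm.build_model(hm.ModelSpec(varies_by_condition=()), data)
        state = self._state(model)
        expected = ddm.wfpt_log_density(
            data["rt"].iloc[0], int(data["response"].iloc[0]),
            ddm.DDMParams(v=1.5, a=1.6, t0=0.3, p_outlier=0.05))
        assert model.log_likelihood(state) == pytest.approx(float(expected), rel=1e-9)

    def test_trial_order_invariance(self):
        data = toy_table(n_trials=20, conditions=ddm.CONDITIONS)
        model = hm.build_model(hm.ModelSpec(varies_by_condition=("v", "a")), data)
        state = self._state(model)
        shuffled = data.sample(frac=1, random_state=3).reset_index(drop=True)
        model2 = hm.build_model(hm.ModelSpec(varies_by_condition=("v", "a")), shuffled)
        assert model.log_likelihood(state) == pytest.approx(
            model2.log_likelihood(state), rel=1e-12)

    def test_five_trial_term_by_term_oracle(self):
        """Total log-likelihood equals the sum of per-trial densities with
        condition- and covariate-resolved drift, computed independently."""
        data = toy_table(n_subjects=1, n_trials=5, conditions=ddm.CONDITIONS,
                         covariates=("beta_net",), seed=4)
        spec = hm.ModelSpec(varies_by_condition=("v", "a"), covariates=("beta_net",))
        model = hm.build_model(spec, data)
        state = self._state(model)
        state["b_v[G,incongruent-EASY]"] = 0.3
        state["b_v[G,incongruent-HARD]"] = -0.2
        state["b_a[G,incongruent-EASY]"] = 0.15
        state["b_a[G,incongruent-HARD]"] = 0.25
        state["b_beta_net[G]"] = 0.4
        total = 0.0
        for _, tr in data.iterrows():
            dv = {"congruent": 0.0, "incongruent-EASY": 0.3,
                  "incongruent-HARD": -0.2}[tr["condition"]]
            da = {"congruent": 0.0, "incongruent-EASY": 0.15,
                  "incongruent-HARD": 0.25}[tr["condition"]]
            params = ddm.DDMParams(v=1.5 + dv + 0.4 * tr["beta_net"],
                                   a=1.6 + da, t0=0.3, p_outlier=0.05)
            total += float(ddm.wfpt_log_density(tr["rt"], int(tr["response"]), params))
        assert model.log_likelihood(state) == pytest.approx(total, rel=1e-9)


class TestSampler:
    def test_conjugate_normal_mean_recovered(self):
        """Sampler matches the closed-form conjugate posterior of a
        normal mean with known variance."""
        rng = np.random.default_rng(0)
        data = rng.normal(1.2, 1.0, 40)
        model = hm.NormalMeanModel(data, sigma=1.0, prior_mu=0.0, prior_sd=2.0)
        cfg = hm.MCMCConfig(n_samples=6000, n_burn_in=1000, n_chains=2, seed=1)
        s = hm.sample_posterior(model, cfg)
        mean_true, sd_true = model.conjugate_posterior()
        draws = s.get("mu").ravel()
        assert draws.mean() == pytest.approx(mean_true, abs=4 * sd_true / np.sqrt(200))
        assert draws.std() == pytest.approx(sd_true, rel=0.1)

    def test_no_data_posterior_matches_prior(self):
        """With no observations the posterior equals the prior
        (Kolmogorov–Smirnov at alpha = 0.01 vs direct prior draws)."""
        model = hm.NormalMeanModel(np.empty(0), sigma=1.0, prior_mu=0.5, prior_sd=1.5)
        cfg = hm.MCMCConfig(n_samples=9000, n_burn_in=1000, thin=4, n_chains=2, seed=2)
        s = hm.sample_posterior(model, cfg)
        draws = s.get("mu").ravel()
        prior = np.random.default_rng(3).normal(0.5, 1.5, draws.size)
        assert stats.ks_2samp(draws, prior).pvalue > 0.01

    def test_identical_seed_identical_chains(self):
        data = toy_table(n_trials=12, conditions=ddm.CONDITIONS)
        model = hm.build_model(hm.ModelSpec(varies_by_condition=("v",)), data)
        cfg = hm.MCMCConfig(n_samples=120, n_burn_in=60, n_chains=2, seed=7)
        s1 = hm.sample_posterior(model, cfg)
        model2 = hm.build_model(hm.ModelSpec(varies_by_condition=("v",)), data)
        s2 = hm.sample_posterior(model2, cfg)
        np.testing.assert_array_equal(s1.draws, s2.draws)
        np.testing.assert_array_equal(s1.loglik, s2.loglik)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            hm.MCMCConfig(n_samples=100, n_burn_in=100)
        with pytest.raises(ValueError):
            hm.MCMCConfig(n_chains=1)

    def test_paper_preset_settings(self):
        cfg = hm.MCMCConfig.paper_preset()
        assert (cfg.n_samples, cfg.n_burn_in, cfg.thin) == (95_000, 35_000, 5)

    def test_shrinkage_toward_group_mean(self, small_fit):
        """Partial pooling: subject drift estimates sit between the
        single-subject (unpooled) estimate and the group mean."""
        model, samples, data, _ = small_fit
        g = "LBD"
        mu = samples.get(f"mu_v[{g}]").mean()
        toward = 0
        checked = 0
        for s in model.group_subjects[g]:
            sub = data[data["subject_id"] == s]
            solo_model = hm.build_model(
                hm.ModelSpec(varies_by_condition=("v", "a")), sub)
            solo = hm.sample_posterior(solo_model, hm.MCMCConfig(
                n_samples=800, n_burn_in=400, n_chains=2, seed=13))
            unpooled = solo.get(f"v[{s}]").mean()
            pooled = samples.get(f"v[{s}]").mean()
            if abs(unpooled - mu) > 0.05:
                checked += 1
                toward += abs(pooled - mu) < abs(unpooled - mu) + 0.02
        assert checked > 0 and toward >= 0.8 * checked


class TestPosteriorSamples:
    def test_save_load_round_trip(self, small_fit, tmp_path):
        _, samples, _, _ = small_fit
        samples.save(tmp_path / "draws")
        back = hm.PosteriorSamples.load(tmp_path / "draws")
        assert back.params == samples.params
        np.testing.assert_allclose(back.draws, samples.draws, rtol=1e-6)
        np.testing.assert_allclose(back.loglik, samples.loglik, rtol=1e-6)


class TestReconstruct:
    def test_congruent_equals_baseline_and_linearity(self, small_fit):
        model, samples, _, _ = small_fit
        rec = hm.reconstruct_condition_posteriors(samples)
        g = model.groups[0]
        np.testing.assert_array_equal(rec[("v", g, "congruent")],
                                      samples.get(f"mu_v[{g}]"))
        easy = rec[("v", g, "incongruent-EASY")]
        assert easy.mean() == pytest.approx(
            samples.get(f"mu_v[{g}]").mean()
            + samples.get(f"b_v[{g},incongruent-EASY]").mean(), rel=1e-12)

    def test_matches_brute_force_recomputation(self, small_fit):
        model, samples, _, _ = small_fit
        rec = hm.reconstruct_condition_posteriors(samples)
        g = model.groups[1]
        i = samples.params.index(f"mu_a[{g}]")
        j = samples.params.index(f"b_a[{g},incongruent-HARD]")
        brute = samples.draws[:, :, i] + samples.draws[:, :, j]
        np.testing.assert_allclose(rec[("a", g, "incongruent-HARD")], brute)


class TestGelmanRubin:
    def _samples(self, chains):
        arr = np.asarray(chains)[:, :, None]
        return hm.PosteriorSamples(params=["x"], draws=arr,
                                   loglik=np.zeros(arr.shape[:2]))

    def test_common_distribution_near_one(self):
        rng = np.random.default_rng(5)
        s = self._samples(rng.normal(size=(2, 4000)))
        assert hm.gelman_rubin(s)["x"] == pytest.approx(1.0, abs=0.05)

    def test_shifted_chain_flags_nonconvergence(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=2000)
        s = self._samples([a, a + 10.0])
        assert hm.gelman_rubin(s)["x"] > 3.0

    def test_never_below_small_sample_floor(self):
        rng = np.random.default_rng(7)
        for seed in range(5):
            s = self._samples(rng.normal(size=(2, 100)))
            assert hm.gelman_rubin(s)["x"] >= np.sqrt((50 - 1) / 50) - 1e-12

    def test_degenerate_chains_reported_not_raised(self):
        s = self._samples(np.ones((2, 100)))
        assert np.isnan(hm.gelman_rubin(s)["x"])

    def test_agrees_with_arviz(self, small_fit):
        arviz = pytest.importorskip("arviz")
        _, samples, _, _ = small_fit
        mine = hm.gelman_rubin(samples)
        for name in ("mu_v[Control]", "mu_a[AD]", "mu_t0[LBD]"):
            ref = float(arviz.rhat(
                arviz.convert_to_dataset(samples.get(name)),
                method="split")["x"].values)
            assert mine[name] == pytest.approx(ref, abs=0.02)
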