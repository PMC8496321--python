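import numpy as np
import pandas as pd
import pytest

from mtgp import (
    GRM,
    MCMCSettings,
    ModelSpec,
    PhenotypeTable,
    PriorSpec,
    SimulationConfig,
    closed_form_gblup,
    compute_grm,
    estimate_heritability,
    fit_multitrait,
    fit_singletrait,
    predict_lines,
    simulate_dataset,
    simulate_genotypes,
)
from tests.conftest import single_env_phenotypes


def _identity_grm(n):
    return GRM(np.eye(n), [f"l{i}" for i in range(n)])


class TestClosedFormGblup:
    def test_identity_grm_is_ridge_shrinkage(self, rng):
        n = 12
        y = rng.standard_normal(n)
        phen = single_env_phenotypes(y, [f"l{i}" for i in range(n)])
        b = closed_form_gblup(phen, "T1", _identity_grm(n), 1.0, 3.0)
        np.testing.assert_allclose(b.values, (y - y.mean()) / 4.0, atol=1e-10)

    def test_vanishing_residual_interpolates(self, rng):
        n = 10
        y = rng.standard_normal(n)
        phen = single_env_phenotypes(y, [f"l{i}" for i in range(n)])
        b = closed_form_gblup(phen, "T1", _identity_grm(n), 1.0, 1e-10)
        np.testing.assert_allclose(b.values, y - y.mean(), atol=1e-6)

    def test_two_closed_forms_agree(self, rng):
        # MME-style solve vs direct joint-covariance formula
        geno = simulate_genotypes(15, 60, (0.1, 0.5), seed=2)
        G = compute_grm(geno)
        y = rng.standard_normal(15)
        phen = single_env_phenotypes(y, geno.line_ids)
        sg, se = 0.7, 1.3
        b = closed_form_gblup(phen, "T1", G, sg, se)
        V = sg * G.values + se * np.eye(15)
        Vi = np.linalg.inv(V)
        mu = np.ones(15) @ Vi @ y / (np.ones(15) @ Vi @ np.ones(15))
        b2 = sg * G.values @ Vi @ (y - mu)
        np.testing.assert_allclose(b.values, b2, atol=1e-8)


class TestSampler:
    def test_noiseless_interpolation_limit(self, rng):
        # fixed variances, G = I, e = 0: posterior mean of mu + b1 equals y
        n = 20
        y = rng.standard_normal(n)
        phen = single_env_phenotypes(y, [f"l{i}" for i in range(n)])
        spec = ModelSpec(
            grm=_identity_grm(n), traits=["T1"], environments=["cycle1"],
            include_gxe=False,
            priors=PriorSpec(fixed_sigma_T=1.0, fixed_R=1e-12),
            mcmc=MCMCSettings(n_iter=2500, burn_in=500, thin=1, seed=1),
            ridge=0.0,
        )
        post = fit_singletrait(phen, "T1", spec)
        fitted = post.mu[0] + post.b1[:, 0]
        np.testing.assert_allclose(fitted, y, atol=1e-6)
        # predicting a phenotyped line returns its phenotype
        preds = predict_lines(post, post.line_ids, "cycle1")
        np.testing.assert_allclose(preds.total["T1"].to_numpy(), y, atol=1e-6)

    def test_matches_closed_form_gblup_at_fixed_variances(self):
        rng = np.random.default_rng(5)
        geno = simulate_genotypes(50, 200, (0.05, 0.5), seed=11)
        G = compute_grm(geno)
        A = np.linalg.cholesky(G.values + 1e-6 * np.eye(50))
        y = A @ rng.standard_normal(50) + rng.standard_normal(50)
        phen = single_env_phenotypes(y, geno.line_ids)
        blup = closed_form_gblup(phen, "T1", G, 1.0, 1.0)
        spec = ModelSpec(
            grm=G, traits=["T1"], environments=["cycle1"], include_gxe=False,
            priors=PriorSpec(fixed_sigma_T=1.0, fixed_R=1.0),
            mcmc=MCMCSettings(n_iter=6000, burn_in=1000, thin=1, seed=7),
        )
        post = fit_singletrait(phen, "T1", spec)
        rms = np.sqrt(np.mean((post.b1[:, 0] - blup.values) ** 2))
        assert rms < 0.02

    def test_seed_determinism(self, small_dataset, fast_mcmc):
        ds = small_dataset
        spec = ModelSpec(
            grm=ds.grm, traits=["T1", "T2"], environments=["cycle1", "cycle2"],
            mcmc=fast_mcmc,
        )
        a = fit_multitrait(ds.phenotypes, spec)
        b = fit_multitrait(ds.phenotypes, spec)
        np.testing.assert_array_equal(a.draws["sigma_T"], b.draws["sigma_T"])
        np.testing.assert_array_equal(a.b1, b.b1)

    def test_posterior_means_are_draw_means(self, small_dataset, fast_mcmc):
        ds = small_dataset
        spec = ModelSpec(
            grm=ds.grm, traits=["T1", "T2"], environments=["cycle1", "cycle2"],
            mcmc=fast_mcmc,
        )
        post = fit_multitrait(ds.phenotypes, spec)
        np.testing.assert_allclose(post.sigma_T, post.draws["sigma_T"].mean(axis=0))
        np.testing.assert_allclose(post.mu, post.draws["mu"].mean(axis=0))

    def test_every_covariance_draw_is_pd(self, small_dataset, fast_mcmc):
        ds = small_dataset
        spec = ModelSpec(
            grm=ds.grm, traits=["T1", "T2"], environments=["cycle1", "cycle2"],
            mcmc=fast_mcmc,
        )
        post = fit_multitrait(ds.phenotypes, spec)
        for name in ("sigma_T", "sigma_TE", "R"):
            for S in post.draws[name]:
                assert np.linalg.eigvalsh(S).min() > 0, name

    def test_singletrait_equals_multitrait_restriction(self, small_dataset, fast_mcmc):
        ds = small_dataset
        spec = ModelSpec(
            grm=ds.grm, traits=["T1"], environments=["cycle1", "cycle2"],
            mcmc=fast_mcmc,
        )
        a = fit_singletrait(ds.phenotypes, "T1", spec)
        b = fit_multitrait(ds.phenotypes, spec, _allow_single=True)
        np.testing.assert_array_equal(a.draws["sigma_T"], b.draws["sigma_T"])

    def test_zero_variance_trait_rejected(self):
        phen = single_env_phenotypes(np.ones(8), [f"l{i}" for i in range(8)])
        spec = ModelSpec(grm=_identity_grm(8), traits=["T1"], environments=["cycle1"])
        with pytest.raises(ValueError, match="zero variance"):
            fit_singletrait(phen, "T1", spec)

    def test_multienv_line_rejected(self):
        df = pd.DataFrame(
            {
                "line": ["l0", "l0", "l1"],
                "env": ["cycle1", "cycle2", "cycle1"],
                "trait": "T1",
                "value": [1.0, 2.0, 0.5],
            }
        )
        spec = ModelSpec(
            grm=_identity_grm(2), traits=["T1"], environments=["cycle1", "cycle2"]
        )
        with pytest.raises(ValueError, match="more than one environment"):
            fit_singletrait(PhenotypeTable(df), "T1", spec)

    def test_burnin_validation(self):
        with pytest.raises(ValueError, match="burn_in"):
            MCMCSettings(n_iter=100, burn_in=100)


class TestPrediction:
    def test_correlation_invariant_to_predictor_choice(self, small_dataset, fast_mcmc):
        ds = small_dataset
        masked = ds.phenotypes.mask_lines(ds.test_lines)
        spec = ModelSpec(
            grm=ds.grm, traits=["T1", "T2"], environments=["cycle1", "cycle2"],
            mcmc=fast_mcmc,
        )
        post = fit_multitrait(masked, spec)
        preds = predict_lines(post, ds.test_lines, "cycle2")
        obs = ds.phenotypes.values_for(ds.test_lines, "cycle2", "T1").to_numpy()
        r_tot = np.corrcoef(obs, preds.total["T1"])[0, 1]
        r_gen = np.corrcoef(obs, preds.genetic["T1"])[0, 1]
        assert r_tot == pytest.approx(r_gen, abs=1e-10)
        # within one environment the two predictors differ by a constant
        diff = preds.total["T1"] - preds.genetic["T1"]
        assert diff.std() == pytest.approx(0.0, abs=1e-12)

    def test_unknown_env_and_line(self, small_dataset, fast_mcmc):
        ds = small_dataset
        spec = ModelSpec(
            grm=ds.grm, traits=["T1"], environments=["cycle1", "cycle2"],
            mcmc=fast_mcmc,
        )
        post = fit_singletrait(ds.phenotypes, "T1", spec)
        with pytest.raises(KeyError, match="environment"):
            predict_lines(post, ds.test_lines, "cycle9")
        with pytest.raises(KeyError, match="not modelled"):
            predict_lines(post, ds.test_lines, "cycle1")

    def test_accuracy_grows_with_training_size(self):
        # larger training cycles should predict the testing cycle better
        from mtgp import true_accuracy

        wins = 0
        for rep in range(6):
            accs = []
            for n_train in (150, 700):
                cfg = SimulationConfig(
                    n_train_lines=n_train, n_test_lines=80, n_markers=400,
                    n_traits=1, sigma_T=0.5, sigma_TE=0.0, residual_cov=0.5,
                    seed=100 + rep,
                )
                ds = simulate_dataset(cfg)
                masked = ds.phenotypes.mask_lines(ds.test_lines)
                spec = ModelSpec(
                    grm=ds.grm, traits=["T1"], environments=["cycle1", "cycle2"],
                    include_gxe=False,
                    mcmc=MCMCSettings(n_iter=800, burn_in=300, thin=2, seed=rep),
                )
                post = fit_singletrait(masked, "T1", spec)
                preds = predict_lines(post, ds.test_lines, "cycle2")
                accs.append(true_accuracy(ds, preds.genetic, "T1", ds.test_lines))
            assert accs[1] > 0
            if accs[1] > accs[0]:
                wins += 1
        assert wins >= 5


class TestHeritability:
    def test_noiseless_data_gives_h2_near_one(self):
        cfg = SimulationConfig(
            n_train_lines=150, n_test_lines=0, n_markers=300, n_traits=1,
            sigma_T=1.0, sigma_TE=0.0, residual_cov=1e-6, seed=3,
        )
        ds = simulate_dataset(cfg)
        spec = ModelSpec(
            grm=ds.grm, traits=["T1"], environments=["cycle1"], include_gxe=False,
            mcmc=MCMCSettings(n_iter=1200, burn_in=400, thin=2, seed=4),
        )
        h2 = estimate_heritability(ds.phenotypes, "T1", spec)
        assert h2 > 0.9

    def test_h2_recovery(self):
        cfg = SimulationConfig(
            n_train_lines=500, n_test_lines=0, n_markers=500, n_traits=1,
            sigma_T=0.5, sigma_TE=0.0, residual_cov=0.5, seed=9,
        )
        ds = simulate_dataset(cfg)
        spec = ModelSpec(
            grm=ds.grm, traits=["T1"], environments=["cycle1"], include_gxe=False,
            mcmc=MCMCSettings(n_iter=1500, burn_in=500, thin=2, seed=10),
        )
        h2 = estimate_heritability(ds.phenotypes, "T1", spec)
        assert abs(h2 - 0.5) < 0.1

    def test_pure_noise_h2_small(self):
        cfg = SimulationConfig(
            n_train_lines=800, n_test_lines=0, n_markers=500, n_traits=1,
            sigma_T=1e-8, sigma_TE=0.0, residual_cov=1.0, seed=21,
        )
        ds = simulate_dataset(cfg)
        spec = ModelSpec(
            grm=ds.grm, traits=["T1"], environments=["cycle1"], include_gxe=False,
            mcmc=MCMCSettings(n_iter=1500, burn_in=500, thin=2, seed=22),
        )
        h2 = estimate_heritability(ds.phenotypes, "T1", spec)
        assert h2 < 0.15
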