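"""Likelihood, CAR conditionals, sampler contracts, convergence diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import smrmap as sm
from smrmap.graph import build_adjacency_from_edgelist, generate_lattice_graph
from smrmap.model import (
    McmcConfig,
    ModelSpec,
    PosteriorChains,
    Priors,
    car_full_conditional,
    gelman_rubin,
    log_likelihood,
    sample_posterior,
    standard_models,
)
from smrmap.simulate import assign_covariates


def null_params(n_units, n_periods, **kw):
    params = dict(
        alpha=0.0,
        beta_period=np.zeros(n_periods),
        beta_language=np.zeros(3),
        beta_urban=np.zeros(2),
        phi=np.zeros(n_units),
        theta=np.zeros(n_units),
    )
    params.update(kw)
    return params


def flat_covariates(units):
    return pd.DataFrame(
        {"language": "German", "urbanisation": "rural"},
        index=pd.Index(units, name="unit_id"),
    )


class TestLogLikelihood:
    def test_matches_poisson_pmf_oracle(self):
        # one cell, y = 2, E = 2, all effects zero
        cov = flat_covariates(["u"])
        got = log_likelihood(
            np.array([[2.0]]), np.array([[2.0]]), cov,
            ModelSpec("poisson", "spatial"), null_params(1, 1),
        )
        assert got == pytest.approx(float(stats.poisson.logpmf(2, 2)), abs=1e-12)

    def test_negbin_limit_agrees_with_poisson_per_cell(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(3.0, size=(5, 4)).astype(float)
        e = rng.uniform(0.5, 5.0, size=(5, 4))
        cov = flat_covariates([f"u{i}" for i in range(5)])
        params = null_params(5, 4, kappa=1e8)
        ll_nb = log_likelihood(y, e, cov, ModelSpec("negbin", "spatial"), params)
        ll_p = log_likelihood(y, e, cov, ModelSpec("poisson", "spatial"), params)
        assert abs(ll_nb - ll_p) < 1e-6 * y.size

    def test_reference_constraint_breaks_shift_invariance(self):
        # with beta_t[0] pinned at 0, moving mass between alpha and the period
        # factor changes the fit for the reference period's cells
        rng = np.random.default_rng(1)
        y = rng.poisson(2.0, size=(3, 3)).astype(float)
        e = np.full((3, 3), 2.0)
        cov = flat_covariates(["a", "b", "c"])
        spec = ModelSpec("poisson", "spatial")
        base = null_params(3, 3)
        ll0 = log_likelihood(y, e, cov, spec, base)
        shifted = null_params(3, 3, alpha=0.3)
        shifted["beta_period"] = np.array([0.0, -0.3, -0.3])
        ll1 = log_likelihood(y, e, cov, spec, shifted)
        assert ll0 != pytest.approx(ll1)

    def test_zero_expected_with_deaths_rejected(self):
        cov = flat_covariates(["u"])
        with pytest.raises(ValueError, match="impossible"):
            log_likelihood(
                np.array([[1.0]]), np.array([[0.0]]), cov,
                ModelSpec(), null_params(1, 1),
            )

    def test_zero_expected_zero_deaths_contributes_nothing(self):
        cov = flat_covariates(["a", "b"])
        y = np.array([[2.0], [0.0]])
        e = np.array([[2.0], [0.0]])
        got = log_likelihood(y, e, cov, ModelSpec(), null_params(2, 1))
        assert got == pytest.approx(float(stats.poisson.logpmf(2, 2)))


class TestCarFullConditional:
    def test_path_middle_node(self):
        g = build_adjacency_from_edgelist([("a", "b"), ("b", "c")], list("abc"))
        phi = np.array([1.0, 0.0, -1.0])
        mean, var = car_full_conditional(g.index("b"), phi, 0.5, g)
        assert mean == pytest.approx(0.0)
        assert var == pytest.approx(0.25 / 2)

    def test_end_node_single_neighbour(self):
        g = build_adjacency_from_edgelist([("a", "b"), ("b", "c")], list("abc"))
        phi = np.array([0.0, 0.7, 0.0])
        mean, var = car_full_conditional(g.index("a"), phi, 1.3, g)
        assert mean == pytest.approx(0.7)
        assert var == pytest.approx(1.3**2)

    def test_island_raises(self):
        g = build_adjacency_from_edgelist([("a", "b")], list("abc"))
        with pytest.raises(ValueError, match="island"):
            car_full_conditional(g.index("c"), np.zeros(3), 1.0, g)

    def test_matches_dense_gaussian_conditional(self):
        # oracle: conditional of N(0, (Q/sigma^2)^-) via precision algebra
        g = build_adjacency_from_edgelist(
            [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a"), ("a", "c")],
            list("abcd"),
        )
        a = g.adjacency_matrix().toarray()
        q = np.diag(a.sum(axis=1)) - a
        sigma = 0.8
        rng = np.random.default_rng(2)
        phi = rng.standard_normal(4)
        for i in range(4):
            mean, var = car_full_conditional(i, phi, sigma, g)
            cond_var = sigma**2 / q[i, i]
            cond_mean = -np.dot(q[i], phi) / q[i, i] + phi[i]
            assert mean == pytest.approx(cond_mean)
            assert var == pytest.approx(cond_var)


class TestSampler:
    def test_same_seed_bit_identical(self, small_study, small_prepared):
        _, expected, grouped = small_prepared
        cfg = McmcConfig(chains=2, iterations=120, burn_in=60, seed=77)
        kw = dict(
            covariates=small_study.covariates, graph=small_study.graph,
            spec=ModelSpec("negbin", "spatial_plus_unstructured"),
            config=cfg, age_group="75+",
        )
        a = sample_posterior(grouped, expected, **kw)
        b = sample_posterior(grouped, expected, **kw)
        for name in a.draws:
            np.testing.assert_array_equal(a.draws[name], b.draws[name])

    def test_phi_centred_and_deviance_finite(self, small_fit, small_study):
        small_fit.validate(small_study.graph)
        phi = small_fit.stacked("phi")
        assert np.abs(phi.sum(axis=1)).max() < 1e-8

    def test_prior_only_field_matches_forward_simulation(self):
        # with the likelihood switched off (no observed cells) and sigma_phi
        # held fixed, the sampled field must reproduce the ICAR prior moments
        g = generate_lattice_graph(2, 3)
        cov = flat_covariates(g.units)
        sigma = 0.5
        y = np.zeros((6, 1))
        e = np.zeros((6, 1))
        cfg = McmcConfig(chains=2, iterations=4000, burn_in=500, seed=21)
        chains = sample_posterior(
            y, e, cov, g, ModelSpec("poisson", "spatial"), config=cfg,
            fixed={"sigma_phi": sigma, "alpha": 0.0},
        )
        draws = chains.stacked("phi")
        a = g.adjacency_matrix().toarray()
        q = np.diag(a.sum(axis=1)) - a
        oracle = sigma**2 * np.linalg.pinv(q)
        emp = np.cov(draws.T)
        assert np.abs(emp - oracle).max() < 0.06

    def test_negbin_kappa_limit_reproduces_poisson_chain(
        self, small_study, small_prepared
    ):
        _, expected, grouped = small_prepared
        cfg = McmcConfig(chains=2, iterations=300, burn_in=150, seed=5)
        kw = dict(
            covariates=small_study.covariates, graph=small_study.graph,
            config=cfg, age_group="75+",
        )
        pois = sample_posterior(grouped, expected, spec=ModelSpec("poisson", "spatial"), **kw)
        nb = sample_posterior(
            grouped, expected, spec=ModelSpec("negbin", "spatial"),
            fixed={"kappa": 1e8}, **kw
        )
        # identical proposal streams + likelihoods equal to ~1e-6: the chains
        # coincide, so the posteriors match to far within MC error
        np.testing.assert_allclose(
            pois.stacked("beta_period"), nb.stacked("beta_period"), atol=1e-3
        )

    def test_effective_parameters_of_plain_glm(self):
        # Poisson GLM with 3 identified fixed effects: pd ~ 3
        g = generate_lattice_graph(8, 8)
        cov = flat_covariates(g.units)
        rng = np.random.default_rng(3)
        e = np.full((64, 3), 20.0)
        truth_eta = np.tile([0.0, -0.2, -0.5], (64, 1))
        y = rng.poisson(e * np.exp(truth_eta)).astype(float)
        cfg = McmcConfig(chains=2, iterations=3000, burn_in=1000, seed=13)
        chains = sample_posterior(
            y, e, cov, g, ModelSpec("poisson", "none"), config=cfg
        )
        dic = sm.compute_dic(chains, y, e, cov)
        assert dic.pd == pytest.approx(3.0, abs=0.5)

    def test_deviance_improves_with_spatial_effects_on_structured_data(
        self, main_study, main_prepared
    ):
        _, expected, grouped = main_prepared
        cfg = McmcConfig(chains=2, iterations=800, burn_in=400, seed=17)
        kw = dict(
            covariates=main_study.covariates, graph=main_study.graph,
            config=cfg, age_group="75+",
        )
        with_re = sample_posterior(
            grouped, expected, spec=ModelSpec("poisson", "spatial"), **kw
        )
        without = sample_posterior(
            grouped, expected, spec=ModelSpec("poisson", "none"), **kw
        )
        assert with_re.stacked("deviance").mean() < without.stacked("deviance").mean()

    def test_nonpositive_expected_with_deaths_rejected(self, small_study):
        cov = small_study.covariates
        g = small_study.graph
        y = np.ones((g.n_units, 2))
        e = np.zeros((g.n_units, 2))
        with pytest.raises(ValueError, match="impossible"):
            sample_posterior(y, e, cov, g, ModelSpec(), config=McmcConfig(
                chains=2, iterations=20, burn_in=10, seed=0))


class TestModelSpec:
    def test_four_standard_models_enumerated_in_order(self):
        labels = [m.label for m in standard_models()]
        assert labels == ["P/1re", "NB/1re", "P/2re", "NB/2re"]

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("gamma", "spatial")
        with pytest.raises(ValueError):
            ModelSpec("poisson", "temporal")
        with pytest.raises(ValueError):
            Priors(beta_sd=-1)
        with pytest.raises(ValueError):
            McmcConfig(chains=1)
        with pytest.raises(ValueError):
            McmcConfig(burn_in=100, iterations=100)


def synthetic_chains(arrays: dict) -> PosteriorChains:
    draws = {k: np.asarray(v, dtype=float) for k, v in arrays.items()}
    n_chains, n_kept = draws["alpha"].shape[:2]
    draws.setdefault("deviance", np.zeros((n_chains, n_kept)))
    return PosteriorChains(draws=draws)


class TestGelmanRubin:
    def test_identical_chains_at_most_one(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(500)
        chains = synthetic_chains({"alpha": np.stack([x, x])})
        psrf = gelman_rubin(chains)["psrf"]["alpha"]
        assert psrf <= 1 + 1e-6

    def test_same_distribution_approaches_one(self):
        rng = np.random.default_rng(5)
        chains = synthetic_chains({"alpha": rng.standard_normal((2, 10_000))})
        psrf = gelman_rubin(chains)["psrf"]["alpha"]
        assert psrf == pytest.approx(1.0, abs=0.05)

    def test_divergent_chains_flagged(self):
        rng = np.random.default_rng(6)
        a = rng.standard_normal((1, 2000))
        b = rng.standard_normal((1, 2000)) + 10.0
        df = gelman_rubin(synthetic_chains({"alpha": np.vstack([a, b])}))
        assert df["psrf"]["alpha"] > 1.1
        assert bool(df["flagged"]["alpha"])

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="2 chains"):
            gelman_rubin(synthetic_chains({"alpha": np.zeros((1, 100))}))
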