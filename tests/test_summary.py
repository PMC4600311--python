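"""DIC decomposition, model selection, SMR-ratio and smoothing summaries."""

import numpy as np
import pandas as pd
import pytest

import smrmap as sm
from smrmap.graph import build_adjacency_from_edgelist
from smrmap.model import McmcConfig, ModelSpec, PosteriorChains
from smrmap.summary import (
    DicResult,
    compute_dic,
    select_model,
    smoothed_unit_smr,
    summarize_effects,
)


def chains_from(draws, **meta):
    draws = {k: np.asarray(v, dtype=float) for k, v in draws.items()}
    return PosteriorChains(draws=draws, **meta)


def constant_chains(n_units=2, n_periods=2, n_kept=150, **overrides):
    shape = (2, n_kept)
    draws = {
        "alpha": np.zeros(shape),
        "beta_period": np.zeros(shape + (n_periods,)),
        "beta_language": np.zeros(shape + (3,)),
        "beta_urban": np.zeros(shape + (2,)),
        "phi": np.zeros(shape + (n_units,)),
        "sigma_phi": np.full(shape, 0.3),
        "deviance": np.full(shape, 100.0),
    }
    draws.update({k: np.asarray(v, dtype=float) for k, v in overrides.items()})
    return draws


class TestDic:
    def test_degenerate_chain_has_zero_pd(self):
        units = ("a", "b")
        draws = constant_chains()
        chains = chains_from(draws, units=units, period_labels=("P0", "P1"))
        y = np.array([[1.0, 2.0], [3.0, 1.0]])
        e = np.array([[1.5, 1.5], [2.0, 2.0]])
        cov = pd.DataFrame(
            {"language": "German", "urbanisation": "rural"},
            index=pd.Index(units, name="unit_id"),
        )
        # make the stored deviance consistent with the constant parameters
        ll = sm.log_likelihood(y, e, cov, ModelSpec(), {
            "alpha": 0.0, "beta_period": np.zeros(2),
            "beta_language": np.zeros(3), "beta_urban": np.zeros(2),
            "phi": np.zeros(2), "theta": np.zeros(2)})
        draws["deviance"][:] = -2 * ll
        chains = chains_from(draws, units=units, period_labels=("P0", "P1"))
        dic = compute_dic(chains, y, e, cov)
        assert dic.pd == pytest.approx(0.0, abs=1e-9)
        assert dic.dic == pytest.approx(dic.dbar)

    def test_decomposition_identity(self):
        d = DicResult(dbar=120.0, dhat=110.0)
        assert d.pd == 10.0
        assert d.dic == d.dbar + d.pd
        assert not d.negative_pd
        assert DicResult(dbar=100.0, dhat=105.0).negative_pd

    def test_empty_chains_rejected(self):
        chains = chains_from(
            {"alpha": np.zeros((2, 0)), "deviance": np.zeros((2, 0))}
        )
        with pytest.raises(ValueError, match="empty"):
            compute_dic(chains, np.zeros((1, 1)), np.ones((1, 1)),
                        pd.DataFrame({"language": ["German"],
                                      "urbanisation": ["rural"]},
                                     index=pd.Index(["a"], name="unit_id")))


class TestSelectModel:
    def specs(self):
        return [
            ModelSpec("poisson", "spatial"),
            ModelSpec("negbin", "spatial"),
            ModelSpec("poisson", "spatial_plus_unstructured"),
            ModelSpec("negbin", "spatial_plus_unstructured"),
        ]

    def test_lowest_dic_wins(self):
        dics = [13_430.0, 13_462.0, 13_457.0, 13_494.0]
        results = [
            (spec, DicResult(dbar=v, dhat=v)) for spec, v in zip(self.specs(), dics)
        ]
        assert select_model(results) == ModelSpec("poisson", "spatial")

    def test_tie_broken_toward_simpler_model(self):
        m1, _, m3, _ = self.specs()
        results = [
            (m3, DicResult(dbar=100.0, dhat=100.0)),
            (m1, DicResult(dbar=100.0, dhat=100.0)),
        ]
        assert select_model(results) == m1
        # family tie-break: Poisson preferred at equal complexity and DIC
        m2 = ModelSpec("negbin", "spatial")
        assert select_model(
            [(m2, DicResult(100.0, 100.0)), (m1, DicResult(100.0, 100.0))]
        ) == m1

    def test_single_entry_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            select_model([(ModelSpec(), DicResult(1.0, 1.0))])


class TestSummarizeEffects:
    def test_zero_draws_give_unit_ratio_not_significant(self):
        chains = chains_from(
            constant_chains(), units=("a", "b"), period_labels=("P0", "P1")
        )
        summ = summarize_effects(chains)
        row = summ.effects.set_index(["effect", "level"]).loc[("period", "P1")]
        assert row["smr_ratio"] == pytest.approx(1.0)
        assert not row["significant"]

    def test_reference_levels_exactly_one(self):
        chains = chains_from(
            constant_chains(), units=("a", "b"), period_labels=("P0", "P1")
        )
        eff = summarize_effects(chains).effects.set_index(["effect", "level"])
        for key in [("period", "P0"), ("language", "German"),
                    ("urbanisation", "rural")]:
            row = eff.loc[key]
            assert (row["smr_ratio"], row["ci_low"], row["ci_high"]) == (1, 1, 1)
            assert row["reference"]

    def test_narrow_negative_effect_flagged_significant(self):
        rng = np.random.default_rng(0)
        draws = constant_chains()
        draws["beta_urban"][:, :, 1] = np.log(0.89) + 0.01 * rng.standard_normal(
            (2, 150)
        )
        chains = chains_from(draws, units=("a", "b"), period_labels=("P0", "P1"))
        row = summarize_effects(chains).effects.set_index(
            ["effect", "level"]
        ).loc[("urbanisation", "urban")]
        assert row["smr_ratio"] == pytest.approx(0.89, abs=0.01)
        assert row["significant"]
        assert row["ci_high"] < 1.0

    def test_spatial_variation_reported(self):
        chains = chains_from(
            constant_chains(), units=("a", "b"), period_labels=("P0", "P1")
        )
        med, lo, hi = summarize_effects(chains).spatial_variation
        assert med == pytest.approx(0.3)

    def test_too_few_draws_rejected(self):
        chains = chains_from(
            constant_chains(n_kept=50), units=("a", "b"), period_labels=("P0", "P1")
        )
        with pytest.raises(ValueError, match="100"):
            summarize_effects(chains)


class TestSmoothedUnitSmr:
    def flat_cov(self, units):
        return pd.DataFrame(
            {"language": "German", "urbanisation": "rural"},
            index=pd.Index(units, name="unit_id"),
        )

    def test_all_zero_effects_give_unit_smr_one(self):
        units = ("a", "b")
        chains = chains_from(
            constant_chains(), units=units, period_labels=("P0", "P1")
        )
        out = smoothed_unit_smr(chains, self.flat_cov(units))
        assert len(out) == 4
        np.testing.assert_allclose(out["smr"], 1.0)

    def test_identical_units_identical_smr(self):
        units = ("a", "b")
        draws = constant_chains()
        rng = np.random.default_rng(1)
        shared = rng.standard_normal((2, 150))
        draws["phi"] = np.stack([shared, shared], axis=-1) * 0.2
        chains = chains_from(draws, units=units, period_labels=("P0", "P1"))
        out = smoothed_unit_smr(chains, self.flat_cov(units))
        a = out[out.unit_id == "a"].set_index("period")["smr"]
        b = out[out.unit_id == "b"].set_index("period")["smr"]
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy())

    def test_small_unit_shrinks_toward_neighbourhood(self):
        # star graph: tiny-population centre with one noisy death, leaves with
        # large expected counts and elevated risk
        edges = [("centre", f"leaf{k}") for k in range(4)]
        units = ["centre"] + [f"leaf{k}" for k in range(4)]
        g = build_adjacency_from_edgelist(edges, units)
        cov = self.flat_cov(g.units)
        e = np.array([[50.0] if u != "centre" else [0.4] for u in g.units])
        rng = np.random.default_rng(7)
        risk = np.array([[1.6] if u != "centre" else [1.0] for u in g.units])
        y = rng.poisson(e * risk).astype(float)
        ci = g.units.index("centre")
        y[ci, 0] = 2.0  # raw SMR = 5: wildly high for half an expected death
        chains = sm.sample_posterior(
            y, e, cov, g, ModelSpec("poisson", "spatial"),
            config=McmcConfig(chains=2, iterations=1500, burn_in=500, seed=3),
        )
        out = smoothed_unit_smr(chains, cov)
        post = out.set_index("unit_id")["smr"]
        raw_centre = np.log(y[ci, 0] / e[ci, 0])
        nbhd = np.mean([np.log(post[u]) for u in units[1:]])
        assert abs(np.log(post["centre"]) - nbhd) < abs(raw_centre - nbhd)

    def test_unit_without_covariates_rejected(self):
        units = ("a", "b")
        chains = chains_from(
            constant_chains(), units=units, period_labels=("P0", "P1")
        )
        with pytest.raises(ValueError, match="without covariates"):
            smoothed_unit_smr(chains, self.flat_cov(["a"]))
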