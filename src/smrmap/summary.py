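"""DIC model comparison and posterior summaries on the SMR scale.

Produces the quantities a disease-mapping analysis reports: SMR ratios
(exp of the fixed effects) with 95% credible intervals and a
CI-excludes-1 significance flag, the spatial variation (posterior of the
CAR field's standard deviation), the DIC table over candidate models, and
smoothed per-unit SMRs for mapping.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph import LANGUAGE_LEVELS, URBANISATION_LEVELS
from .model import (
    ModelSpec,
    PosteriorChains,
    _encode_covariates,
    _extract_group,
    _Likelihood,
)

__all__ = [
    "DicResult",
    "SmrSummary",
    "compute_dic",
    "select_model",
    "summarize_effects",
    "smoothed_unit_smr",
]

MIN_DRAWS_FOR_SUMMARY = 100


@dataclass(frozen=True)
class DicResult:
    """Deviance information criterion decomposition.

    dbar: posterior mean deviance; dhat: deviance at the (elementwise)
    posterior mean of all parameters including the latent fields;
    pd = dbar - dhat (effective number of parameters); dic = dbar + pd.
    A negative pd indicates a poorly identified or badly mixing fit and is
    flagged, never hidden.
    """

    dbar: float
    dhat: float

    @property
    def pd(self) -> float:
        return self.dbar - self.dhat

    @property
    def dic(self) -> float:
        return self.dbar + self.pd

    @property
    def negative_pd(self) -> bool:
        return self.pd < 0


def compute_dic(
    chains: PosteriorChains,
    deaths,
    expected,
    covariates: pd.DataFrame,
    spec: ModelSpec | None = None,
    age_group: str | None = None,
) -> DicResult:
    """DIC with the plug-in at posterior means of ALL latent quantities."""
    spec = spec or chains.spec
    dev = chains.stacked("deviance")
    if dev.size == 0:
        raise ValueError("empty chains")
    dbar = float(dev.mean())

    y, e, units, _ = _extract_group(deaths, expected, age_group)
    if units is None:
        units = list(chains.units)
    lang, urb = _encode_covariates(covariates, units)
    lik = _Likelihood(y, e, spec.family)

    point = {
        name: chains.stacked(name).mean(axis=0)
        for name in chains.draws
        if name != "deviance"
    }
    n = len(lang)
    alpha = float(point.get("alpha", 0.0))
    beta_t = np.asarray(point.get("beta_period", np.zeros(lik.n_periods)))
    beta_l = np.asarray(point.get("beta_language", np.zeros(3)))
    beta_u = np.asarray(point.get("beta_urban", np.zeros(2)))
    phi = np.asarray(point.get("phi", np.zeros(n)))
    theta = np.asarray(point.get("theta", np.zeros(n)))
    unit_eff = beta_l[lang] + beta_u[urb] + phi + theta
    eta = lik.eta(alpha, beta_t, unit_eff)
    kappa = float(point["kappa"]) if spec.family == "negbin" else None
    dhat = float(-2.0 * lik.cells(eta, kappa).sum())
    return DicResult(dbar=dbar, dhat=dhat)


def select_model(
    results: Sequence[tuple[ModelSpec, DicResult]],
) -> ModelSpec:
    """Lowest-DIC model; ties go to the simpler model.

    Tie-break order: fewer random-effect sets first, then Poisson over
    negative binomial.  Requires at least two candidates.
    """
    results = list(results)
    if len(results) < 2:
        raise ValueError("model selection needs at least 2 fitted models")

    def key(item):
        spec, dic = item
        return (
            round(dic.dic, 9),
            spec.n_random_effect_sets,
            0 if spec.family == "poisson" else 1,
        )

    return min(results, key=key)[0]


@dataclass
class SmrSummary:
    """Posterior SMR-ratio table plus spatial variation and unit SMRs.

    ``effects``: one row per (effect, level) with columns smr_ratio
    (posterior median of exp(beta)), ci_low, ci_high (central 95%), and
    significant (CI excludes 1).  Reference levels are exactly 1.
    ``spatial_variation``: (median, ci_low, ci_high) of sigma_phi, or None.
    ``unit_smr``: per-(unit, period) smoothed SMR frame, when computed.
    """

    effects: pd.DataFrame
    spatial_variation: tuple[float, float, float] | None = None
    unit_smr: pd.DataFrame | None = None

    def write_effects_csv(self, path) -> None:
        self.effects.to_csv(path, index=False)


def _ratio_row(effect, level, draws=None, reference=False):
    if reference:
        return {
            "effect": effect,
            "level": level,
            "smr_ratio": 1.0,
            "ci_low": 1.0,
            "ci_high": 1.0,
            "significant": False,
            "reference": True,
        }
    ratio = np.exp(draws)
    lo, med, hi = np.quantile(ratio, [0.025, 0.5, 0.975])
    return {
        "effect": effect,
        "level": level,
        "smr_ratio": float(med),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "significant": bool(lo > 1.0 or hi < 1.0),
        "reference": False,
    }


def summarize_effects(
    chains: PosteriorChains, spec: ModelSpec | None = None
) -> SmrSummary:
    """SMR ratios (posterior medians, 95% CI, significance) per effect level."""
    spec = spec or chains.spec
    n_total = chains.n_chains * chains.n_kept
    if chains.n_kept < MIN_DRAWS_FOR_SUMMARY:
        raise ValueError(
            f"need >= {MIN_DRAWS_FOR_SUMMARY} retained draws per chain for a summary, "
            f"got {chains.n_kept}"
        )
    rows = []
    bt = chains.stacked("beta_period")
    labels = chains.period_labels or tuple(f"P{k}" for k in range(bt.shape[1]))
    rows.append(_ratio_row("period", labels[0], reference=True))
    for t in range(1, bt.shape[1]):
        rows.append(_ratio_row("period", labels[t], bt[:, t]))
    bl = chains.stacked("beta_language")
    rows.append(_ratio_row("language", LANGUAGE_LEVELS[0], reference=True))
    for k in range(1, bl.shape[1]):
        rows.append(_ratio_row("language", LANGUAGE_LEVELS[k], bl[:, k]))
    bu = chains.stacked("beta_urban")
    rows.append(_ratio_row("urbanisation", URBANISATION_LEVELS[0], reference=True))
    rows.append(_ratio_row("urbanisation", URBANISATION_LEVELS[1], bu[:, 1]))
    effects = pd.DataFrame(rows)

    spatial = None
    if "sigma_phi" in chains.draws:
        s = chains.stacked("sigma_phi")
        lo, med, hi = np.quantile(s, [0.025, 0.5, 0.975])
        spatial = (float(med), float(lo), float(hi))
    return SmrSummary(effects=effects, spatial_variation=spatial)


def smoothed_unit_smr(
    chains: PosteriorChains,
    covariates: pd.DataFrame,
    spec: ModelSpec | None = None,
) -> pd.DataFrame:
    """Posterior median smoothed SMR per (unit, period), with 95% CI.

    The per-draw unit SMR is exp(alpha + beta_t + covariate terms + phi
    (+ theta)), so estimates for small units borrow strength from their
    neighbours through the CAR field.
    """
    spec = spec or chains.spec
    if chains.n_kept < MIN_DRAWS_FOR_SUMMARY:
        raise ValueError(
            f"need >= {MIN_DRAWS_FOR_SUMMARY} retained draws per chain for a summary"
        )
    units = chains.units
    lang, urb = _encode_covariates(covariates, units)
    n = len(units)
    a = chains.stacked("alpha")
    bt = chains.stacked("beta_period")
    bl = chains.stacked("beta_language")
    bu = chains.stacked("beta_urban")
    phi = chains.stacked("phi") if "phi" in chains.draws else np.zeros((len(a), n))
    theta = (
        chains.stacked("theta") if "theta" in chains.draws else np.zeros((len(a), n))
    )
    unit_part = a[:, None] + bl[:, lang] + bu[:, urb] + phi + theta  # (draws, units)

    labels = chains.period_labels or tuple(f"P{k}" for k in range(bt.shape[1]))
    frames = []
    for t, label in enumerate(labels):
        log_smr = unit_part + bt[:, t][:, None]
        lo, med, hi = np.quantile(np.exp(log_smr), [0.025, 0.5, 0.975], axis=0)
        frames.append(
            pd.DataFrame(
                {
                    "unit_id": units,
                    "period": label,
                    "smr": med,
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
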