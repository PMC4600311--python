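"""Hierarchical spatio-temporal count models fitted by Metropolis-within-Gibbs.

The observation model for one coarse age group is

    y_it ~ Poisson(E_it r_it)            or NB with mean E_it r_it,
    log r_it = alpha + beta_t + beta_l(i) + beta_u(i) + phi_i (+ theta_i),

where E_it is the indirectly standardized expected count, beta_t a period
factor (first period = reference), beta_l / beta_u the language and
urbanisation factors, phi an intrinsic CAR (spatially structured) random
effect with conditional variance sigma_phi^2 / n_i, and theta an optional
exchangeable (unstructured) effect — the Besag-York-Mollié convolution.
The negative binomial uses mean mu and variance mu (1 + mu/kappa), so
kappa -> infinity recovers the Poisson.

The intrinsic CAR prior is improper; identifiability comes from a
sum-to-zero constraint per graph component (the intercept absorbs the
field's level).  Degree-0 units (islands) have phi fixed at 0.  Sampling is
adaptive random-walk Metropolis on every scalar, with the structured field
updated one graph-colour class at a time: units of one colour share no
edge, so their CAR full conditionals are mutually independent given the
rest and an entire colour class can be proposed and accepted as a vector.
Proposal scales adapt toward 0.44 acceptance during burn-in and are frozen
afterwards to preserve detailed balance.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln

from .graph import AdjacencyGraph, LANGUAGE_LEVELS, URBANISATION_LEVELS
from .tables import ExpectedCounts, GroupedDeaths, align_covariates

__all__ = [
    "ModelSpec",
    "Priors",
    "McmcConfig",
    "PosteriorChains",
    "standard_models",
    "log_likelihood",
    "car_full_conditional",
    "sample_posterior",
    "gelman_rubin",
]

FAMILIES = ("poisson", "negbin")
RANDOM_EFFECTS = ("none", "spatial", "spatial_plus_unstructured")


@dataclass(frozen=True)
class ModelSpec:
    """Family x random-effect structure of one candidate model.

    ``random_effects="none"`` gives the plain (non-spatial) GLM used for
    preliminary analysis; the DIC comparison runs over the four
    family x {spatial, spatial_plus_unstructured} combinations.
    """

    family: str = "poisson"
    random_effects: str = "spatial"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.random_effects not in RANDOM_EFFECTS:
            raise ValueError(f"random_effects must be one of {RANDOM_EFFECTS}")

    @property
    def has_spatial(self) -> bool:
        return self.random_effects in ("spatial", "spatial_plus_unstructured")

    @property
    def has_unstructured(self) -> bool:
        return self.random_effects == "spatial_plus_unstructured"

    @property
    def n_random_effect_sets(self) -> int:
        return int(self.has_spatial) + int(self.has_unstructured)

    @property
    def label(self) -> str:
        fam = "P" if self.family == "poisson" else "NB"
        return f"{fam}/{self.n_random_effect_sets}re"


def standard_models() -> list[ModelSpec]:
    """The four models of the DIC comparison, in table order.

    1: Poisson + spatial RE; 2: NB + spatial RE; 3: Poisson + spatial and
    unstructured REs; 4: NB + spatial and unstructured REs.
    """
    return [
        ModelSpec("poisson", "spatial"),
        ModelSpec("negbin", "spatial"),
        ModelSpec("poisson", "spatial_plus_unstructured"),
        ModelSpec("negbin", "spatial_plus_unstructured"),
    ]


@dataclass(frozen=True)
class Priors:
    """Weakly informative defaults; every scale is configurable.

    Gaussian(0, beta_sd^2) on the intercept and all fixed effects,
    half-normal on the random-effect SDs, Gaussian on log kappa.
    """

    beta_sd: float = 10.0
    sigma_phi_scale: float = 1.0
    sigma_theta_scale: float = 1.0
    log_kappa_mean: float = 0.0
    log_kappa_sd: float = 2.0

    def __post_init__(self) -> None:
        for name in ("beta_sd", "sigma_phi_scale", "sigma_theta_scale", "log_kappa_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class McmcConfig:
    chains: int = 4
    iterations: int = 5000
    burn_in: int = 2500
    thin: int = 1
    seed: int = 0
    adapt_interval: int = 50

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("at least 2 chains are required")
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("need 0 <= burn_in < iterations")
        if self.thin < 1 or self.adapt_interval < 1:
            raise ValueError("thin and adapt_interval must be >= 1")

    @property
    def n_kept(self) -> int:
        return (self.iterations - self.burn_in + self.thin - 1) // self.thin


@dataclass
class PosteriorChains:
    """Retained MCMC draws, shape (chains, kept, ...) per parameter.

    Keys: alpha, beta_period (incl. the reference 0 column), beta_language,
    beta_urban, phi, theta, sigma_phi, sigma_theta, kappa (as present), and
    deviance (-2 log-likelihood, stored per draw for DIC).
    """

    draws: dict[str, np.ndarray] = field(repr=False)
    spec: ModelSpec = field(default_factory=ModelSpec)
    priors: Priors = field(default_factory=Priors)
    config: McmcConfig = field(default_factory=McmcConfig)
    units: tuple[str, ...] = ()
    period_labels: tuple[str, ...] = ()
    accept_rates: dict[str, float] = field(default_factory=dict, repr=False)

    @property
    def n_chains(self) -> int:
        return self.draws["alpha"].shape[0]

    @property
    def n_kept(self) -> int:
        return self.draws["alpha"].shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated along the draw axis."""
        arr = self.draws[name]
        return arr.reshape(arr.shape[0] * arr.shape[1], *arr.shape[2:])

    def validate(self, graph: AdjacencyGraph | None = None) -> None:
        if not np.all(np.isfinite(self.stacked("deviance"))):
            raise ValueError("non-finite deviance in retained draws")
        if "phi" in self.draws and graph is not None:
            phi = self.stacked("phi")
            for comp in graph.components():
                if len(comp) >= 2 and np.abs(phi[:, comp].sum(axis=1)).max() > 1e-6:
                    raise ValueError("phi violates per-component sum-to-zero")


# -- likelihood ----------------------------------------------------------


class _Likelihood:
    """Flattened per-cell log pmf over cells with expected > 0.

    Cells with expected = 0 must have y = 0 (checked) and contribute 0, so
    they are dropped from the flat arrays entirely.
    """

    def __init__(self, y: np.ndarray, expected: np.ndarray, family: str):
        y = np.asarray(y, dtype=float)
        expected = np.asarray(expected, dtype=float)
        if y.shape != expected.shape or y.ndim != 2:
            raise ValueError(
                "deaths and expected must be matching (units, periods) arrays"
            )
        if np.any((expected == 0) & (y > 0)):
            raise ValueError(
                "deaths > 0 in a cell with expected = 0 is impossible under the model"
            )
        if np.any(y < 0) or np.any(expected < 0):
            raise ValueError("negative counts or expected values")
        self.n_units, self.n_periods = y.shape
        keep = expected > 0
        self.unit_idx, self.period_idx = np.nonzero(keep)
        self.y = y[keep]
        self.e = expected[keep]
        self.log_e = np.log(self.e)
        self.gln_y1 = gammaln(self.y + 1.0)
        self.family = family
        self._kappa_cache: tuple[float, np.ndarray] | None = None
        self.cells_by_period = [
            np.flatnonzero(self.period_idx == t) for t in range(self.n_periods)
        ]

    def _gln_yk(self, kappa: float) -> np.ndarray:
        if self._kappa_cache is None or self._kappa_cache[0] != kappa:
            self._kappa_cache = (kappa, gammaln(self.y + kappa))
        return self._kappa_cache[1]

    def eta(self, alpha, beta_t, unit_eff) -> np.ndarray:
        return alpha + beta_t[self.period_idx] + unit_eff[self.unit_idx]

    def cells(self, eta: np.ndarray, kappa: float | None = None) -> np.ndarray:
        """Per-cell log pmf at flat linear predictor ``eta``."""
        if self.family == "poisson":
            return self.y * (self.log_e + eta) - self.e * np.exp(eta) - self.gln_y1
        if kappa is None or kappa <= 0:
            raise ValueError("negative binomial needs kappa > 0")
        mu = self.e * np.exp(eta)
        return (
            self._gln_yk(kappa)
            - gammaln(kappa)
            - self.gln_y1
            + kappa * math.log(kappa)
            - (self.y + kappa) * np.log(kappa + mu)
            + self.y * (self.log_e + eta)
        )

    def cells_at(
        self, eta_sub: np.ndarray, idx: np.ndarray, kappa: float | None = None
    ) -> np.ndarray:
        """Per-cell log pmf on the flat-cell subset ``idx``."""
        y, e, log_e, g1 = self.y[idx], self.e[idx], self.log_e[idx], self.gln_y1[idx]
        if self.family == "poisson":
            return y * (log_e + eta_sub) - e * np.exp(eta_sub) - g1
        mu = e * np.exp(eta_sub)
        return (
            self._gln_yk(kappa)[idx]
            - gammaln(kappa)
            - g1
            + kappa * math.log(kappa)
            - (y + kappa) * np.log(kappa + mu)
            + y * (log_e + eta_sub)
        )

    def per_unit(self, cells: np.ndarray) -> np.ndarray:
        return np.bincount(self.unit_idx, weights=cells, minlength=self.n_units)


def _encode_covariates(covariates: pd.DataFrame, units: Sequence[str]):
    cov = align_covariates(covariates, units)
    lang = cov["language"].map({lv: k for k, lv in enumerate(LANGUAGE_LEVELS)})
    urb = cov["urbanisation"].map({lv: k for k, lv in enumerate(URBANISATION_LEVELS)})
    if lang.isna().any() or urb.isna().any():
        raise ValueError("unknown covariate level")
    return lang.to_numpy(dtype=np.int64), urb.to_numpy(dtype=np.int64)


def _params_eta(
    params: Mapping[str, np.ndarray | float],
    lang: np.ndarray,
    urb: np.ndarray,
    n_periods: int,
) -> np.ndarray:
    """(units, periods) linear predictor from one parameter point."""
    alpha = float(params.get("alpha", 0.0))
    beta_t = np.asarray(params.get("beta_period", np.zeros(n_periods)), dtype=float)
    beta_l = np.asarray(params.get("beta_language", np.zeros(3)), dtype=float)
    beta_u = np.asarray(params.get("beta_urban", np.zeros(2)), dtype=float)
    n = len(lang)
    phi = np.asarray(params.get("phi", np.zeros(n)), dtype=float)
    theta = np.asarray(params.get("theta", np.zeros(n)), dtype=float)
    unit_eff = beta_l[lang] + beta_u[urb] + phi + theta
    return beta_t[np.newaxis, :n_periods] + (alpha + unit_eff)[:, np.newaxis]


def _extract_group(deaths, expected, age_group):
    if isinstance(deaths, GroupedDeaths):
        if not isinstance(expected, ExpectedCounts):
            raise TypeError("expected must be ExpectedCounts when deaths is grouped")
        deaths.require_same_index(expected, "deaths and expected")
        if age_group is None:
            if len(deaths.age_groups) != 1:
                raise ValueError("age_group required for multi-group tables")
            gi = 0
        else:
            gi = deaths.age_groups.index(age_group)
        return (
            deaths.values[:, :, gi],
            expected.values[:, :, gi],
            deaths.units,
            deaths.periods,
        )
    y = np.asarray(deaths, dtype=float)
    e = np.asarray(expected, dtype=float)
    return y, e, None, None


def log_likelihood(
    deaths: GroupedDeaths | np.ndarray,
    expected: ExpectedCounts | np.ndarray,
    covariates: pd.DataFrame,
    spec: ModelSpec,
    params: Mapping[str, np.ndarray | float],
    age_group: str | None = None,
) -> float:
    """Total log-likelihood of one age group's counts at one parameter point.

    ``deaths``/``expected`` may be (units, periods) arrays or grouped cubes
    (then ``age_group`` selects the slice).  ``params`` holds alpha,
    beta_period/beta_language/beta_urban (full vectors, reference entries
    0), phi, theta, and kappa for the negative binomial.  ``covariates`` is
    indexed by unit_id in the table's unit order.
    """
    y, e, units, _ = _extract_group(deaths, expected, age_group)
    if units is None:
        units = list(covariates.index)
    lang, urb = _encode_covariates(covariates, units)
    lik = _Likelihood(y, e, spec.family)
    eta = _params_eta(params, lang, urb, y.shape[1])
    kappa = float(params["kappa"]) if spec.family == "negbin" else None
    flat_eta = eta[lik.unit_idx, lik.period_idx]
    return float(lik.cells(flat_eta, kappa).sum())


def car_full_conditional(
    i: int, phi: np.ndarray, sigma_phi: float, graph: AdjacencyGraph
) -> tuple[float, float]:
    """Intrinsic-CAR prior full conditional of phi_i given the rest.

    mean = average of the neighbours' phi, variance = sigma_phi^2 / n_i.
    Raises for degree-0 units: an island carries no spatial information and
    its phi is fixed at 0 by the sampler.
    """
    ns = graph.neighbors[i]
    if not ns:
        raise ValueError(f"unit {graph.units[i]!r} has degree 0 (island)")
    mean = float(np.mean([phi[j] for j in ns]))
    return mean, sigma_phi**2 / len(ns)


# -- sampler -------------------------------------------------------------


def _coloring(graph: AdjacencyGraph, active: np.ndarray) -> list[np.ndarray]:
    g = nx.Graph()
    g.add_nodes_from(int(i) for i in active)
    for i in active:
        for j in graph.neighbors[int(i)]:
            g.add_edge(int(i), int(j))
    colors = nx.greedy_color(g, strategy="largest_first")
    out: dict[int, list[int]] = {}
    for i in active:
        out.setdefault(colors[int(i)], []).append(int(i))
    return [np.array(sorted(v), dtype=np.int64) for _, v in sorted(out.items())]


class _AdaptiveScale:
    """Per-parameter random-walk scale targeting 0.44 acceptance."""

    def __init__(self, shape, init=0.3):
        self.log_scale = np.full(shape, math.log(init))
        self.accepts = np.zeros(shape)
        self.proposals = np.zeros(shape)
        self.batch = 0
        self.frozen = False

    @property
    def scale(self):
        return np.exp(self.log_scale)

    def record(self, accepted) -> None:
        self.accepts += accepted
        self.proposals += 1

    def adapt(self) -> None:
        if self.frozen:
            return
        self.batch += 1
        mask = self.proposals > 0
        rate = np.where(mask, self.accepts / np.maximum(self.proposals, 1), 0.44)
        step = min(0.25, 2.0 / math.sqrt(self.batch))
        self.log_scale = np.clip(
            self.log_scale + step * (rate - 0.44) * mask, -12.0, 4.0
        )
        self.accepts = np.zeros_like(self.accepts)
        self.proposals = np.zeros_like(self.proposals)


_HALF_NORMAL_MEDIAN = 0.6744897501960817  # Phi^{-1}(0.75)


def _log_half_normal(x: float, scale: float) -> float:
    if x <= 0:
        return -np.inf
    return -0.5 * (x / scale) ** 2  # unnormalized


def sample_posterior(
    deaths: GroupedDeaths | np.ndarray,
    expected: ExpectedCounts | np.ndarray,
    covariates: pd.DataFrame,
    graph: AdjacencyGraph,
    spec: ModelSpec = ModelSpec(),
    priors: Priors = Priors(),
    config: McmcConfig = McmcConfig(),
    age_group: str | None = None,
    fixed: Mapping[str, float] | None = None,
) -> PosteriorChains:
    """Fit one age group's model by adaptive Metropolis-within-Gibbs.

    Runs ``config.chains`` independent chains (over-dispersed fixed-effect
    starts), re-centres the CAR field per graph component each sweep with
    the level transferred to the intercept, and stores the deviance at
    every retained draw.  Bit-reproducible for a given config seed.

    ``fixed`` pins named scalars (``sigma_phi``, ``sigma_theta``,
    ``kappa``, ``alpha``) at given values — useful for prior-only checks
    and the kappa -> infinity Poisson limit.
    """
    y, e, table_units, table_periods = _extract_group(deaths, expected, age_group)
    if table_units is not None and tuple(table_units) != tuple(graph.units):
        raise ValueError("table units do not match graph units")
    if y.shape[0] != graph.n_units:
        raise ValueError("row count does not match graph units")
    lang, urb = _encode_covariates(covariates, graph.units)
    fixed = dict(fixed or {})

    lik = _Likelihood(y, e, spec.family)
    n, p = y.shape

    degrees = graph.degrees
    active = np.flatnonzero(degrees > 0)  # islands keep phi = 0
    colors = _coloring(graph, active) if (spec.has_spatial and len(active)) else []
    edge_list = graph.edges()
    edge_arr = np.array(edge_list, dtype=np.int64).reshape(-1, 2)
    adj = graph.adjacency_matrix()
    comps = [c for c in graph.components() if len(c) >= 2]
    icar_rank = sum(len(c) - 1 for c in comps)

    period_cells = lik.cells_by_period
    lang_cells = [np.flatnonzero(lang[lik.unit_idx] == k) for k in range(3)]
    urb_cells = [np.flatnonzero(urb[lik.unit_idx] == k) for k in range(2)]

    n_kept = config.n_kept
    shapes = {
        "alpha": (),
        "beta_period": (p,),
        "beta_language": (3,),
        "beta_urban": (2,),
    }
    if spec.has_spatial:
        shapes.update({"phi": (n,), "sigma_phi": ()})
    if spec.has_unstructured:
        shapes.update({"theta": (n,), "sigma_theta": ()})
    if spec.family == "negbin":
        shapes["kappa"] = ()
    store = {
        name: np.empty((config.chains, n_kept) + shp) for name, shp in shapes.items()
    }
    store["deviance"] = np.empty((config.chains, n_kept))
    acc_totals: dict[str, list[float]] = {}

    for chain in range(config.chains):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(config.seed) % (2**31), 11, chain])
        )
        _run_chain(
            chain, rng, lik, spec, priors, config, fixed, lang, urb,
            degrees, active, colors, edge_arr, adj, comps, icar_rank,
            period_cells, lang_cells, urb_cells, store, acc_totals,
        )

    labels = (
        tuple(table_periods)
        if table_periods is not None
        else tuple(f"P{k}" for k in range(p))
    )
    chains = PosteriorChains(
        draws=store,
        spec=spec,
        priors=priors,
        config=config,
        units=tuple(graph.units),
        period_labels=labels,
        accept_rates={k: float(np.mean(v)) for k, v in acc_totals.items()},
    )
    chains.validate(graph)
    return chains


def _run_chain(
    chain, rng, lik, spec, priors, config, fixed, lang, urb,
    degrees, active, colors, edge_arr, adj, comps, icar_rank,
    period_cells, lang_cells, urb_cells, store, acc_totals,
):
    n = len(lang)
    p = lik.n_periods
    all_cells = np.arange(len(lik.y))

    # --- initialization: intercept near the crude log-SMR, over-dispersed betas
    tot_y, tot_e = lik.y.sum(), lik.e.sum()
    alpha = math.log((tot_y + 0.5) / (tot_e + 0.5)) if tot_e > 0 else 0.0
    alpha += 0.25 * rng.standard_normal()
    if "alpha" in fixed:
        alpha = float(fixed["alpha"])
    beta_t = np.zeros(p)
    beta_t[1:] = 0.25 * rng.standard_normal(max(p - 1, 0))
    beta_l = np.zeros(3)
    beta_l[1:] = 0.25 * rng.standard_normal(2)
    beta_u = np.zeros(2)
    beta_u[1] = 0.25 * rng.standard_normal()
    phi = np.zeros(n)
    theta = np.zeros(n)
    sigma_phi = float(
        fixed.get("sigma_phi", priors.sigma_phi_scale * _HALF_NORMAL_MEDIAN)
    )
    sigma_theta = float(
        fixed.get("sigma_theta", priors.sigma_theta_scale * _HALF_NORMAL_MEDIAN)
    )
    kappa = float(fixed.get("kappa", math.exp(priors.log_kappa_mean)))
    kap = kappa if spec.family == "negbin" else None

    def unit_eff():
        return beta_l[lang] + beta_u[urb] + phi + theta

    eta = lik.eta(alpha, beta_t, unit_eff())
    cur_cells = lik.cells(eta, kap)
    cur_ll = float(cur_cells.sum())
    if not np.isfinite(cur_ll):
        raise ValueError("non-finite posterior at initialization")

    sc_alpha = _AdaptiveScale((), 0.1)
    sc_bt = _AdaptiveScale((p,), 0.1)
    sc_bl = _AdaptiveScale((3,), 0.1)
    sc_bu = _AdaptiveScale((2,), 0.1)
    sc_phi = _AdaptiveScale((n,), 0.3)
    sc_theta = _AdaptiveScale((n,), 0.3)
    sc_lsphi = _AdaptiveScale((), 0.3)
    sc_lstheta = _AdaptiveScale((), 0.3)
    sc_lkappa = _AdaptiveScale((), 0.3)
    all_scales = [sc_alpha, sc_bt, sc_bl, sc_bu, sc_phi, sc_theta,
                  sc_lsphi, sc_lstheta, sc_lkappa]

    beta_prec = 1.0 / priors.beta_sd**2
    acc_count = {k: [0, 0] for k in ("alpha", "beta", "phi", "theta")}
    kept = 0

    def try_shift(cells_idx, delta, val_old, val_new):
        """RWM accept for an additive shift on a flat-cell subset with a
        Gaussian(0, beta_sd^2) prior on the shifted coefficient."""
        nonlocal cur_ll
        sub_eta = eta[cells_idx] + delta
        new_sub = lik.cells_at(sub_eta, cells_idx, kap)
        d_ll = float(new_sub.sum() - cur_cells[cells_idx].sum())
        d_prior = -0.5 * beta_prec * (val_new**2 - val_old**2)
        if math.log(rng.uniform()) < d_ll + d_prior:
            eta[cells_idx] = sub_eta
            cur_cells[cells_idx] = new_sub
            cur_ll += d_ll
            return True
        return False

    for it in range(config.iterations):
        # ---- intercept
        if "alpha" not in fixed:
            d = float(sc_alpha.scale) * rng.standard_normal()
            ok = try_shift(all_cells, d, alpha, alpha + d)
            if ok:
                alpha += d
            sc_alpha.record(float(ok))
            acc_count["alpha"][0] += ok
            acc_count["alpha"][1] += 1

        # ---- period factors (first period reference, fixed at 0)
        for t in range(1, p):
            d = sc_bt.scale[t] * rng.standard_normal()
            ok = try_shift(period_cells[t], d, beta_t[t], beta_t[t] + d)
            if ok:
                beta_t[t] += d
            sc_bt.accepts[t] += float(ok)
            sc_bt.proposals[t] += 1
            acc_count["beta"][0] += ok
            acc_count["beta"][1] += 1

        # ---- language factors (German reference)
        for k in range(1, 3):
            d = sc_bl.scale[k] * rng.standard_normal()
            ok = try_shift(lang_cells[k], d, beta_l[k], beta_l[k] + d)
            if ok:
                beta_l[k] += d
            sc_bl.accepts[k] += float(ok)
            sc_bl.proposals[k] += 1
            acc_count["beta"][0] += ok
            acc_count["beta"][1] += 1

        # ---- urbanisation factor (rural reference)
        d = sc_bu.scale[1] * rng.standard_normal()
        ok = try_shift(urb_cells[1], d, beta_u[1], beta_u[1] + d)
        if ok:
            beta_u[1] += d
        sc_bu.accepts[1] += float(ok)
        sc_bu.proposals[1] += 1
        acc_count["beta"][0] += ok
        acc_count["beta"][1] += 1

        # ---- structured field, one colour class at a time
        if spec.has_spatial and len(active) and sigma_phi > 0:
            inv_two_s2 = 1.0 / (2.0 * sigma_phi**2)
            for cls in colors:
                prop = sc_phi.scale[cls] * rng.standard_normal(len(cls))
                nbr_sum = adj.dot(phi)[cls]
                deg = degrees[cls]
                m = nbr_sum / deg
                old = phi[cls]
                d_prior = -deg * inv_two_s2 * ((old + prop - m) ** 2 - (old - m) ** 2)

                dvec = np.zeros(n)
                dvec[cls] = prop
                eta_new = eta + dvec[lik.unit_idx]
                new_cells = lik.cells(eta_new, kap)
                d_unit = lik.per_unit(new_cells - cur_cells)
                accept = np.log(rng.uniform(size=len(cls))) < d_unit[cls] + d_prior
                if accept.any():
                    acc_units = cls[accept]
                    phi[acc_units] += prop[accept]
                    mask_units = np.zeros(n, dtype=bool)
                    mask_units[acc_units] = True
                    sel = mask_units[lik.unit_idx]
                    eta[sel] = eta_new[sel]
                    cur_cells[sel] = new_cells[sel]
                    cur_ll = float(cur_cells.sum())
                sc_phi.accepts[cls] += accept
                sc_phi.proposals[cls] += 1
                acc_count["phi"][0] += int(accept.sum())
                acc_count["phi"][1] += len(cls)

        # ---- unstructured effects (conditionally independent across units)
        if spec.has_unstructured and sigma_theta > 0:
            prop = sc_theta.scale * rng.standard_normal(n)
            inv2 = 1.0 / (2.0 * sigma_theta**2)
            d_prior = -inv2 * ((theta + prop) ** 2 - theta**2)
            eta_new = eta + prop[lik.unit_idx]
            new_cells = lik.cells(eta_new, kap)
            d_unit = lik.per_unit(new_cells - cur_cells)
            accept = np.log(rng.uniform(size=n)) < d_unit + d_prior
            if accept.any():
                theta = np.where(accept, theta + prop, theta)
                sel = accept[lik.unit_idx]
                eta[sel] = eta_new[sel]
                cur_cells[sel] = new_cells[sel]
                cur_ll = float(cur_cells.sum())
            sc_theta.accepts += accept
            sc_theta.proposals += 1
            acc_count["theta"][0] += int(accept.sum())
            acc_count["theta"][1] += n

        # ---- random-effect SDs (random walk on the log scale)
        if spec.has_spatial and "sigma_phi" not in fixed and icar_rank > 0:
            s_quad = (
                float(np.sum((phi[edge_arr[:, 0]] - phi[edge_arr[:, 1]]) ** 2))
                if len(edge_arr)
                else 0.0
            )

            def lp_sphi(ls):
                s = math.exp(ls)
                return (
                    -icar_rank * ls
                    - s_quad / (2.0 * s * s)
                    + _log_half_normal(s, priors.sigma_phi_scale)
                    + ls  # Jacobian of s = exp(ls)
                )

            ls = math.log(sigma_phi) if sigma_phi > 0 else -6.0
            ls_new = ls + float(sc_lsphi.scale) * rng.standard_normal()
            ok = math.log(rng.uniform()) < lp_sphi(ls_new) - lp_sphi(ls)
            if ok:
                sigma_phi = math.exp(ls_new)
            sc_lsphi.record(float(ok))

        if spec.has_unstructured and "sigma_theta" not in fixed:
            t_quad = float(np.sum(theta**2))

            def lp_stheta(ls):
                s = math.exp(ls)
                return (
                    -n * ls
                    - t_quad / (2.0 * s * s)
                    + _log_half_normal(s, priors.sigma_theta_scale)
                    + ls
                )

            ls = math.log(sigma_theta) if sigma_theta > 0 else -6.0
            ls_new = ls + float(sc_lstheta.scale) * rng.standard_normal()
            ok = math.log(rng.uniform()) < lp_stheta(ls_new) - lp_stheta(ls)
            if ok:
                sigma_theta = math.exp(ls_new)
            sc_lstheta.record(float(ok))

        # ---- NB dispersion (Gaussian prior directly on log kappa)
        if spec.family == "negbin" and "kappa" not in fixed:
            lk = math.log(kappa)
            lk_new = lk + float(sc_lkappa.scale) * rng.standard_normal()
            new_cells = lik.cells(eta, math.exp(lk_new))
            d_ll = float(new_cells.sum()) - cur_ll
            d_prior = 0.5 * (
                ((lk - priors.log_kappa_mean) / priors.log_kappa_sd) ** 2
                - ((lk_new - priors.log_kappa_mean) / priors.log_kappa_sd) ** 2
            )
            ok = math.log(rng.uniform()) < d_ll + d_prior
            if ok:
                kappa = math.exp(lk_new)
                kap = kappa
                cur_cells = new_cells
                cur_ll += d_ll
            sc_lkappa.record(float(ok))

        # ---- re-centre the field per component; the intercept absorbs the level
        if spec.has_spatial and comps:
            shift = 0.0
            for comp in comps:
                mc = float(phi[comp].mean())
                phi[comp] -= mc
                shift += mc * len(comp)
            if "alpha" not in fixed:
                alpha += shift / n
            eta = lik.eta(alpha, beta_t, unit_eff())
            cur_cells = lik.cells(eta, kap)
            cur_ll = float(cur_cells.sum())

        # ---- adaptation (burn-in only, then frozen)
        if it < config.burn_in and (it + 1) % config.adapt_interval == 0:
            for sc in all_scales:
                sc.adapt()
        elif it == config.burn_in:
            for sc in all_scales:
                sc.frozen = True

        # ---- record
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            store["alpha"][chain, kept] = alpha
            store["beta_period"][chain, kept] = beta_t
            store["beta_language"][chain, kept] = beta_l
            store["beta_urban"][chain, kept] = beta_u
            if spec.has_spatial:
                store["phi"][chain, kept] = phi
                store["sigma_phi"][chain, kept] = sigma_phi
            if spec.has_unstructured:
                store["theta"][chain, kept] = theta
                store["sigma_theta"][chain, kept] = sigma_theta
            if spec.family == "negbin":
                store["kappa"][chain, kept] = kappa
            store["deviance"][chain, kept] = -2.0 * cur_ll
            kept += 1

    for key, (a, m) in acc_count.items():
        if m:
            acc_totals.setdefault(key, []).append(a / m)


# -- convergence ----------------------------------------------------------


def gelman_rubin(chains: PosteriorChains, threshold: float = 1.1) -> pd.DataFrame:
    """Classic potential scale reduction factor per scalar parameter.

    PSRF = sqrt(((n-1)/n W + B/n) / W) over the retained draws of >= 2
    chains; parameters with PSRF above ``threshold`` are flagged.  Identical
    chains give sqrt((n-1)/n) < 1.
    """
    if chains.n_chains < 2:
        raise ValueError("gelman_rubin needs at least 2 chains")
    rows = []
    for name, arr in chains.draws.items():
        if name == "deviance":
            continue
        flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
        _, n_draws, k = flat.shape
        if n_draws < 2:
            raise ValueError("need at least 2 retained draws per chain")
        means = flat.mean(axis=1)
        w = flat.var(axis=1, ddof=1).mean(axis=0)
        b_over_n = means.var(axis=0, ddof=1)
        var_plus = (n_draws - 1) / n_draws * w + b_over_n
        with np.errstate(divide="ignore", invalid="ignore"):
            psrf = np.sqrt(var_plus / w)
        psrf = np.where(w > 0, psrf, 1.0)  # constant-everywhere parameters
        for j in range(k):
            label = name if k == 1 else f"{name}[{j}]"
            rows.append((label, float(psrf[j])))
    df = pd.DataFrame(rows, columns=["parameter", "psrf"]).set_index("parameter")
    df["flagged"] = df["psrf"] > threshold
    return df
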