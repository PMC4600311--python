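"""End-to-end pipeline: data -> standardization -> fits -> DIC -> summaries -> maps.

Driven by a YAML run configuration.  Every artifact is delimited text (or
GeoJSON for maps) and every run writes a manifest recording the seed, a
hash of the effective configuration, and package versions, so a run can be
reproduced byte-for-byte from the manifest alone.
"""

from __future__ import annotations

import hashlib
import logging
import time
from collections.abc import Mapping, Sequence
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .graph import (
    AdjacencyGraph,
    build_adjacency_from_edgelist,
    build_adjacency_from_polygons,
    geometry_to_geojson,
    read_edgelist,
    read_geojson_polygons,
    write_edgelist,
)
from .model import (
    McmcConfig,
    ModelSpec,
    Priors,
    gelman_rubin,
    sample_posterior,
    standard_models,
)
from .simulate import GroundTruth, simulate_study
from .standardize import (
    CorrectionFactors,
    aggregate_age_groups,
    aggregate_periods,
    apply_coding_correction,
    compute_expected,
    compute_reference_rates,
    raw_smr,
)
from .summary import (
    DicResult,
    compute_dic,
    select_model,
    smoothed_unit_smr,
    summarize_effects,
)
from .tables import (
    COARSE_AGE_GROUPS,
    MortalityTable,
    PopulationTable,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "export_maps"]

logger = logging.getLogger(__name__)

MODEL_BY_NAME = {
    "1": ModelSpec("poisson", "spatial"),
    "2": ModelSpec("negbin", "spatial"),
    "3": ModelSpec("poisson", "spatial_plus_unstructured"),
    "4": ModelSpec("negbin", "spatial_plus_unstructured"),
}
NAME_BY_MODEL = {v: k for k, v in MODEL_BY_NAME.items()}


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Validated run configuration; see ``template()`` for all defaults.

    Either ``simulate`` is true (synthetic inputs are generated from the
    seed) or the four input paths must point at existing files.
    """

    out_dir: str = "smrmap_run"
    seed: int = 0
    simulate: bool = True
    # synthetic scenario
    lattice_rows: int = 20
    lattice_cols: int = 20
    periods: int = 5
    size_range: tuple[float, float] = (500.0, 50_000.0)
    # file inputs (used when simulate is false)
    deaths_path: str | None = None
    population_path: str | None = None
    covariates_path: str | None = None
    adjacency_path: str | None = None  # edge list (.csv) or polygons (.geojson)
    geometry_path: str | None = None  # optional polygons for map export
    # standardization
    period_windows: list[tuple[int, int]] | None = None  # aggregate annual input
    correction_factors_path: str | None = None
    round_corrected_counts: bool = True
    # modelling
    age_groups: list[str] = field(default_factory=lambda: list(COARSE_AGE_GROUPS))
    models: list[str] = field(default_factory=lambda: ["1", "2", "3", "4"])
    chains: int = 4
    iterations: int = 2000
    burn_in: int = 1000
    thin: int = 1
    adapt_interval: int = 50
    beta_prior_sd: float = 10.0
    sigma_phi_prior_scale: float = 1.0
    sigma_theta_prior_scale: float = 1.0
    log_kappa_prior_mean: float = 0.0
    log_kappa_prior_sd: float = 2.0

    def __post_init__(self) -> None:
        self.models = [str(m) for m in self.models]
        unknown = [m for m in self.models if m not in MODEL_BY_NAME]
        if unknown:
            raise ValueError(f"unknown model names {unknown}; use 1-4")
        bad_groups = [g for g in self.age_groups if g not in COARSE_AGE_GROUPS]
        if bad_groups:
            raise ValueError(f"unknown age groups {bad_groups}")
        if not self.simulate:
            for name in ("deaths_path", "population_path", "covariates_path",
                         "adjacency_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"{name} is required when simulate is false")
                if not Path(p).exists():
                    raise ValueError(f"{name}={p!r} does not exist")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        doc = asdict(self)
        doc["size_range"] = list(self.size_range)
        if self.period_windows is not None:
            doc["period_windows"] = [list(w) for w in self.period_windows]
        return doc

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        if "size_range" in doc:
            doc["size_range"] = tuple(doc["size_range"])
        if doc.get("period_windows") is not None:
            doc["period_windows"] = [tuple(w) for w in doc["period_windows"]]
        return cls(**doc)

    @classmethod
    def template(cls) -> str:
        """YAML template with every key at its default."""
        return yaml.safe_dump(cls().to_dict(), sort_keys=True)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def mcmc_config(self) -> McmcConfig:
        return McmcConfig(
            chains=self.chains,
            iterations=self.iterations,
            burn_in=self.burn_in,
            thin=self.thin,
            seed=self.seed,
            adapt_interval=self.adapt_interval,
        )

    def priors(self) -> Priors:
        return Priors(
            beta_sd=self.beta_prior_sd,
            sigma_phi_scale=self.sigma_phi_prior_scale,
            sigma_theta_scale=self.sigma_theta_prior_scale,
            log_kappa_mean=self.log_kappa_prior_mean,
            log_kappa_sd=self.log_kappa_prior_sd,
        )


@dataclass
class _Data:
    graph: AdjacencyGraph
    population: PopulationTable
    deaths: MortalityTable
    covariates: pd.DataFrame
    truth: GroundTruth | None = None


def _load_graph(config: RunConfig) -> AdjacencyGraph:
    path = Path(config.adjacency_path)
    if path.suffix.lower() in (".geojson", ".json"):
        return build_adjacency_from_polygons(read_geojson_polygons(path))
    units, edges = read_edgelist(path)
    return build_adjacency_from_edgelist(edges, units)


def _stage_data(config: RunConfig) -> _Data:
    if config.simulate:
        study = simulate_study(
            seed=config.seed,
            rows=config.lattice_rows,
            cols=config.lattice_cols,
            periods=config.periods,
            size_range=config.size_range,
        )
        return _Data(
            study.graph, study.population, study.deaths, study.covariates,
            truth=study.truth,
        )
    graph = _load_graph(config)
    population = PopulationTable.read_csv(config.population_path)
    deaths = MortalityTable.read_csv(
        config.deaths_path,
        units=population.units,
        periods=None,
        ages=population.age_bands,
    )
    covariates = pd.read_csv(config.covariates_path).set_index("unit_id")
    return _Data(graph, population, deaths, covariates)


def _stage_prepare_counts(data: _Data, config: RunConfig) -> MortalityTable:
    deaths = data.deaths
    if config.correction_factors_path:
        factors = CorrectionFactors.read_csv(config.correction_factors_path)
        deaths = apply_coding_correction(
            deaths, factors, round_counts=config.round_corrected_counts
        )
    if config.period_windows:
        deaths = aggregate_periods(deaths, config.period_windows)
    if deaths.periods != data.population.periods:
        raise ValueError(
            "death-table periods do not match population periods after aggregation"
        )
    return deaths


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute every configured stage; returns a dict of output paths.

    Stage order: data (simulate/load) -> coding correction & period
    aggregation -> reference rates & expected counts -> per-age-group model
    fits -> DIC table -> effect summaries and smoothed SMRs for the
    DIC-best model -> manifest.  Deterministic given (config, seed); any
    stage failure aborts with the stage name and leaves an INCOMPLETE
    marker.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "INCOMPLETE"
    marker.write_text("run in progress\n", encoding="utf-8")
    artifacts: dict[str, str] = {}
    t_start = time.time()

    def _write_frame(name: str, frame: pd.DataFrame) -> None:
        path = out / name
        frame.to_csv(path, index=False)
        artifacts[name] = str(path)

    stage = "data"
    try:
        data = _stage_data(config)
        logger.info("stage data: %d units, %d periods", data.graph.n_units,
                    len(data.population.periods))
        data.population.write_csv(out / "population.csv")
        artifacts["population.csv"] = str(out / "population.csv")
        data.deaths.write_csv(out / "deaths_raw.csv")
        artifacts["deaths_raw.csv"] = str(out / "deaths_raw.csv")
        data.covariates.to_csv(out / "covariates.csv")
        artifacts["covariates.csv"] = str(out / "covariates.csv")
        write_edgelist(data.graph, out / "adjacency.csv")
        artifacts["adjacency.csv"] = str(out / "adjacency.csv")
        if data.truth is not None:
            data.truth.to_yaml(out / "truth.yaml")
            artifacts["truth.yaml"] = str(out / "truth.yaml")

        stage = "correction_aggregation"
        deaths = _stage_prepare_counts(data, config)
        deaths.write_csv(out / "deaths_analysis.csv")
        artifacts["deaths_analysis.csv"] = str(out / "deaths_analysis.csv")

        stage = "standardization"
        rates = compute_reference_rates(deaths, data.population)
        _write_frame(
            "reference_rates.csv",
            pd.DataFrame(
                {"age_band": data.population.age_bands, "rate": rates}
            ),
        )
        expected = compute_expected(data.population, rates)
        expected.write_csv(out / "expected.csv")
        artifacts["expected.csv"] = str(out / "expected.csv")
        grouped = aggregate_age_groups(deaths)
        smr, defined = raw_smr(grouped, expected)
        raw_frame = expected.to_frame().rename(columns={"expected": "smr"})
        raw_frame["smr"] = smr.reshape(-1)
        raw_frame["defined"] = defined.reshape(-1)
        _write_frame("raw_smr.csv", raw_frame)

        stage = "fit"
        mcmc = config.mcmc_config()
        priors = config.priors()
        dic_rows = []
        fits: dict[str, dict[str, object]] = {}
        for group in config.age_groups:
            fits[group] = {}
            for name in config.models:
                spec = MODEL_BY_NAME[name]
                logger.info("fitting model %s (%s), age group %s", name,
                            spec.label, group)
                chains = sample_posterior(
                    grouped, expected, data.covariates, data.graph,
                    spec=spec, priors=priors, config=mcmc, age_group=group,
                )
                dic = compute_dic(chains, grouped, expected, data.covariates,
                                  age_group=group)
                fits[group][name] = chains
                dic_rows.append(
                    {
                        "age_group": group,
                        "model": name,
                        "label": spec.label,
                        "dbar": dic.dbar,
                        "pd": dic.pd,
                        "dic": dic.dic,
                        "negative_pd": dic.negative_pd,
                    }
                )

        stage = "dic"
        dic_frame = pd.DataFrame(dic_rows)
        best_by_group: dict[str, str] = {}
        for group in config.age_groups:
            sub = dic_frame[dic_frame.age_group == group]
            pairs = [
                (
                    MODEL_BY_NAME[row["model"]],
                    DicResult(dbar=row["dbar"], dhat=row["dbar"] - row["pd"]),
                )
                for _, row in sub.iterrows()
            ]
            best = (
                select_model(pairs) if len(pairs) >= 2 else pairs[0][0]
            )
            best_by_group[group] = NAME_BY_MODEL[best]
        dic_frame["best"] = [
            row["model"] == best_by_group[row["age_group"]]
            for _, row in dic_frame.iterrows()
        ]
        _write_frame("dic_table.csv", dic_frame)

        stage = "summaries"
        for group in config.age_groups:
            best = best_by_group[group]
            chains = fits[group][best]
            summ = summarize_effects(chains)
            if summ.spatial_variation is not None:
                med, lo, hi = summ.spatial_variation
                extra = pd.DataFrame(
                    [
                        {
                            "effect": "spatial_variation",
                            "level": "sigma_phi",
                            "smr_ratio": med,
                            "ci_low": lo,
                            "ci_high": hi,
                            "significant": False,
                            "reference": False,
                        }
                    ]
                )
                table = pd.concat([summ.effects, extra], ignore_index=True)
            else:
                table = summ.effects
            _write_frame(f"effects_{_slug(group)}.csv", table)
            unit_smr = smoothed_unit_smr(chains, data.covariates)
            _write_frame(f"unit_smr_{_slug(group)}.csv", unit_smr)
            psrf = gelman_rubin(chains)
            scalars = psrf[~psrf.index.str.startswith(("phi[", "theta["))]
            scalars.reset_index().to_csv(
                out / f"convergence_{_slug(group)}.csv", index=False
            )
            artifacts[f"convergence_{_slug(group)}.csv"] = str(
                out / f"convergence_{_slug(group)}.csv"
            )
            _save_scalar_chains(chains, out, group, artifacts)

        stage = "manifest"
        manifest = {
            "package": "smrmap",
            "version": __version__,
            "seed": int(config.seed),
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "library_versions": _library_versions(),
            "artifacts": sorted(artifacts),
            "runtime_seconds": round(time.time() - t_start, 2),
        }
        with open(out / "manifest.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
        artifacts["manifest.yaml"] = str(out / "manifest.yaml")
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError(stage, exc) from exc
    marker.unlink(missing_ok=True)
    return artifacts


def _library_versions() -> dict[str, str]:
    import scipy

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
    }


def _slug(group: str) -> str:
    return group.replace("<", "lt").replace("+", "plus").replace("-", "_")


def _save_scalar_chains(chains, out: Path, group: str, artifacts: dict) -> None:
    """Persist scalar and factor chains as delimited text (latent fields as
    posterior summaries; the full per-unit chains are disproportionate as text)."""
    n_chains, n_kept = chains.n_chains, chains.n_kept
    cols = {"chain": np.repeat(np.arange(n_chains), n_kept),
            "draw": np.tile(np.arange(n_kept), n_chains)}
    for name, arr in chains.draws.items():
        if name in ("phi", "theta"):
            continue
        if arr.ndim == 2:
            cols[name] = arr.reshape(-1)
        else:
            labels = (
                chains.period_labels
                if name == "beta_period"
                else range(arr.shape[2])
            )
            for j, lab in enumerate(labels):
                cols[f"{name}[{lab}]"] = arr[:, :, j].reshape(-1)
    path = out / f"chains_{_slug(group)}.csv"
    pd.DataFrame(cols).to_csv(path, index=False)
    artifacts[path.name] = str(path)
    for name in ("phi", "theta"):
        if name in chains.draws:
            flat = chains.stacked(name)
            frame = pd.DataFrame(
                {
                    "unit_id": chains.units,
                    "mean": flat.mean(axis=0),
                    "median": np.median(flat, axis=0),
                    "sd": flat.std(axis=0, ddof=1),
                }
            )
            path = out / f"{name}_summary_{_slug(group)}.csv"
            frame.to_csv(path, index=False)
            artifacts[path.name] = str(path)


def export_maps(
    unit_smr: pd.DataFrame,
    geometries: Mapping | None = None,
    out_prefix: str | Path = "smr_map",
) -> list[str]:
    """Write smoothed-SMR map exports.

    Always writes ``<prefix>.csv`` (unit_id, period, smr, ci_low, ci_high);
    with polygon ``geometries`` also writes ``<prefix>.geojson`` carrying
    the same values as feature properties (one feature per unit, SMRs keyed
    by period).
    """
    needed = {"unit_id", "period", "smr"}
    if not needed <= set(unit_smr.columns):
        raise ValueError(f"unit_smr frame needs columns {sorted(needed)}")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    csv_path = out_prefix.with_suffix(".csv")
    cols = [c for c in ("unit_id", "period", "smr", "ci_low", "ci_high")
            if c in unit_smr.columns]
    unit_smr[cols].to_csv(csv_path, index=False)
    written.append(str(csv_path))

    if geometries is not None:
        ids = set(unit_smr["unit_id"].astype(str))
        geo_ids = {str(k) for k in geometries}
        missing = sorted(ids - geo_ids)
        if missing:
            raise ValueError(f"units without geometry: {missing[:10]}")
        features = []
        for uid in sorted(ids):
            sub = unit_smr[unit_smr["unit_id"].astype(str) == uid]
            props = {"unit_id": uid}
            for _, row in sub.iterrows():
                props[f"smr_{row['period']}"] = float(row["smr"])
            features.append(
                {
                    "type": "Feature",
                    "properties": props,
                    "geometry": geometry_to_geojson(geometries[uid]),
                }
            )
        import json

        geo_path = out_prefix.with_suffix(".geojson")
        with open(geo_path, "w", encoding="utf-8") as fh:
            json.dump(
                {"type": "FeatureCollection", "features": features},
                fh,
                sort_keys=True,
            )
        written.append(str(geo_path))
    return written
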