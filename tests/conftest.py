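"""Shared fixtures: synthetic studies and fitted chains reused across tests.

Expensive fits are session-scoped so each is computed once per run.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import smrmap as sm
from smrmap.model import McmcConfig, ModelSpec, sample_posterior

settings.register_profile("ci", derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """6x6 lattice, 3 periods: cheap dataset for unit tests."""
    return sm.simulate_study(seed=42, rows=6, cols=6, periods=3)


@pytest.fixture(scope="session")
def small_prepared(small_study):
    rates = sm.compute_reference_rates(small_study.deaths, small_study.population)
    expected = sm.compute_expected(small_study.population, rates)
    grouped = sm.aggregate_age_groups(small_study.deaths)
    return rates, expected, grouped


@pytest.fixture(scope="session")
def small_fit(small_study, small_prepared):
    """Short spatial-Poisson fit on the small dataset (>=100 kept per chain)."""
    _, expected, grouped = small_prepared
    cfg = McmcConfig(chains=2, iterations=400, burn_in=200, seed=9)
    return sample_posterior(
        grouped, expected, small_study.covariates, small_study.graph,
        ModelSpec("poisson", "spatial"), config=cfg, age_group="75+",
    )


@pytest.fixture(scope="session")
def main_study():
    """The documented 20x20 / 5-period study scenario."""
    return sm.simulate_study(seed=7)


@pytest.fixture(scope="session")
def main_prepared(main_study):
    rates = sm.compute_reference_rates(main_study.deaths, main_study.population)
    expected = sm.compute_expected(main_study.population, rates)
    grouped = sm.aggregate_age_groups(main_study.deaths)
    return rates, expected, grouped


@pytest.fixture(scope="session")
def main_fit(main_study, main_prepared):
    """Full-length spatial-Poisson fit (4 chains x 5000) on the 75+ group."""
    _, expected, grouped = main_prepared
    cfg = McmcConfig(chains=4, iterations=5000, burn_in=2500, seed=11)
    return sample_posterior(
        grouped, expected, main_study.covariates, main_study.graph,
        ModelSpec("poisson", "spatial"), config=cfg, age_group="75+",
    )


def bfs_components(n: int, neighbors) -> np.ndarray:
    """Brute-force component labelling oracle."""
    label = -np.ones(n, dtype=int)
    comp = 0
    for start in range(n):
        if label[start] >= 0:
            continue
        stack = [start]
        label[start] = comp
        while stack:
            i = stack.pop()
            for j in neighbors[i]:
                if label[j] < 0:
                    label[j] = comp
                    stack.append(j)
        comp += 1
    return label
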