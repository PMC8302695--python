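"""Shared fixtures.

The heavyweight replication studies (multi-seed knockout and community
null-model comparisons) are computed once per session and shared between
the module-level property tests and the acceptance tests.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pytest

import syntrobn as sb
from syntrobn.studies import community_null_study, gene_knockout_study

logging.getLogger("syntrobn").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def knockout_study() -> pd.DataFrame:
    """Knockout experiment at the study's contrast conditions.

    50 seeds, n=200 samples, iht_effect=0.8 vs diet_effect=0.2, noise 0.2;
    scenarios complete / delta_IHT / delta_DIET / delta_distractor.
    """
    return gene_knockout_study(n_seeds=50, base_seed=0, iht_effect=0.8,
                               diet_effect=0.2, noise_sd=0.2, n_samples=200)


@pytest.fixture(scope="session")
def community_studies() -> dict[str, pd.DataFrame]:
    """BN-vs-null Bray-Curtis across 20 seeds, dependent and independent."""
    return {
        "dependent": community_null_study(n_seeds=20, base_seed=0,
                                          independent_taxa=False),
        "independent": community_null_study(n_seeds=20, base_seed=0,
                                            independent_taxa=True),
    }


@pytest.fixture()
def default_config() -> sb.ScenarioConfig:
    return sb.ScenarioConfig()


@pytest.fixture()
def template_sem(default_config) -> sb.GroundTruthSEM:
    return sb.build_template_sem(default_config)


@pytest.fixture()
def small_gene_matrix() -> sb.FeatureTable:
    """Normalized template-SEM expression table at a modest depth."""
    config = sb.ScenarioConfig(n_samples=80, seed=7)
    sem = sb.build_template_sem(config)
    expression = sb.simulate_expression(sem, config.n_samples, config.seed)
    normalized, _ = sb.minmax_normalize(expression)
    return normalized


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
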