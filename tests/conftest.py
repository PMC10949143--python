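"""Shared fixtures: a default synthetic city and a fitted risk model.

Session-scoped so the expensive pieces (generation, LightGBM fit) are
built once and shared; tests must not mutate fixture frames in place.
"""

from __future__ import annotations

import numpy as np
import pytest

import leadwater as lw
from leadwater.config import (
    ConcentrationConfig,
    ContaminationConfig,
    GeneratorConfig,
    RiskModelConfig,
    ScreeningConfig,
)

N_BLOCKS = 2000


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def city(default_config):
    """Default-condition synthetic city: (blocks, tests, survey)."""
    blocks = lw.generate_blocks(N_BLOCKS, default_config, seed=1)
    tests = lw.generate_tests(blocks, default_config, seed=2)
    survey = lw.generate_survey(blocks, default_config, seed=3)
    blocks = blocks.copy()
    blocks["tested"] = blocks["block_id"].isin(tests["block_id"])
    return blocks, tests, survey


@pytest.fixture(scope="session")
def city_labels(city):
    _, tests, _ = city
    return lw.label_blocks(tests)


@pytest.fixture(scope="session")
def labeled_blocks(city, city_labels):
    blocks, _, _ = city
    return blocks.merge(city_labels[["block_id", "contaminated"]], on="block_id",
                        how="inner")


@pytest.fixture(scope="session")
def risk_fit(labeled_blocks):
    return lw.fit_risk_model(labeled_blocks, RiskModelConfig(tune=False), seed=5)


@pytest.fixture(scope="session")
def predictions(risk_fit, city):
    blocks, _, _ = city
    return lw.predict_blocks(risk_fit, blocks)


def high_fidelity_concentrations() -> ConcentrationConfig:
    """Widely separated clean/contaminated mixtures: the majority-rule
    label then recovers the latent state essentially without error."""
    return ConcentrationConfig(
        contaminated_median_ppb=(6.0, 8.0, 5.0), contaminated_sigma=0.6,
        clean_median_ppb=(0.06, 0.08, 0.05), clean_sigma=0.4)


def separable_generator() -> GeneratorConfig:
    """Latent contamination nearly deterministic in covariates, labels
    nearly noise-free: a classifier should reach very high held-out AUROC."""
    return GeneratorConfig(
        contamination=ContaminationConfig(
            intercept=-15.0, b_minority=30.0, b_building_age=0.0,
            b_log_population=0.0, b_buildings=0.0, sigma_community=3.0),
        concentrations=high_fidelity_concentrations(),
        screening=ScreeningConfig(intercept=0.5, b_white=0.0),
        mean_tests_per_block=5.0)


def make_city(cfg: GeneratorConfig, n_blocks: int, seed: int):
    blocks = lw.generate_blocks(n_blocks, cfg, seed)
    tests = lw.generate_tests(blocks, cfg, seed + 50_000)
    blocks["tested"] = blocks["block_id"].isin(tests["block_id"])
    return blocks, tests


@pytest.fixture(scope="session")
def exposure_response() -> lw.ExposureResponse:
    # illustrative slope; the true exposure-response value is an external input
    return lw.ExposureResponse(slope_point=0.25, slope_ci_low=0.10,
                               slope_ci_high=0.40)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
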