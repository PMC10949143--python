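"""Synthetic city generator.

Emulates the statistical structure of a municipal household lead-testing
program: a four-level nested geography (community area > tract > block
group > block), block-level race/age composition and building stock, a
latent per-block contamination state, race-correlated voluntary screening,
and per-test lead concentrations across three sequential draws with a
1 ppb limit of detection.

Ground-truth columns are prefixed ``truth_`` and must never be consumed by
inference modules; they exist so tests can compare estimates with reality.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import RACE_GROUPS, GeneratorConfig

GEO_COLUMNS = ["block_id", "block_group_id", "tract_id", "community_area_id"]
TRUTH_COLUMNS = ["truth_p_contaminated", "truth_contaminated", "truth_screening_propensity"]
DRAW_COLUMNS = ["draw1_ppb", "draw2_ppb", "draw3_ppb"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _geo_ids(n_blocks: int, cfg: GeneratorConfig) -> pd.DataFrame:
    h = cfg.hierarchy
    block = np.arange(n_blocks)
    bg = block // h.blocks_per_block_group
    tract = bg // h.block_groups_per_tract
    ca = tract // h.tracts_per_community_area
    return pd.DataFrame({
        "block_id": [f"CA{c:03d}-T{t:03d}-BG{g:04d}-B{b:05d}"
                     for c, t, g, b in zip(ca, tract, bg, block)],
        "block_group_id": [f"CA{c:03d}-T{t:03d}-BG{g:04d}" for c, t, g in zip(ca, tract, bg)],
        "tract_id": [f"CA{c:03d}-T{t:03d}" for c, t in zip(ca, tract)],
        "community_area_id": [f"CA{c:03d}" for c in ca],
    })


def generate_blocks(n_blocks: int, config: GeneratorConfig | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Generate ``n_blocks`` census-block records.

    Race composition is drawn hierarchically (a Dirichlet per community
    area, then a tighter Dirichlet per block around its area's mix), which
    produces residential segregation: blocks within an area resemble each
    other and areas differ strongly.  The latent contamination probability
    follows a logistic model on block covariates plus a community-area
    random effect; the screening propensity increases with White
    population share.  Both are recorded as ``truth_`` columns.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    geo = _geo_ids(n_blocks, config)
    ca_codes, ca_idx = np.unique(geo["community_area_id"], return_inverse=True)
    n_ca = len(ca_codes)

    # population: log-normal around the configured median
    population = np.maximum(
        1, np.round(rng.lognormal(np.log(config.population_median),
                                  config.population_sigma, n_blocks))).astype(int)

    # hierarchical race mixture
    city = np.array([config.race_city_proportions[r] for r in RACE_GROUPS], dtype=float)
    city = city / city.sum()
    ca_props = rng.dirichlet(config.race_concentration_area * city, size=n_ca)
    block_props = np.empty((n_blocks, 4))
    for j in range(n_ca):
        mask = ca_idx == j
        alpha = np.maximum(config.race_concentration_block * ca_props[j], 1e-3)
        block_props[mask] = rng.dirichlet(alpha, size=int(mask.sum()))

    # integer race counts; a small "other" share keeps sums <= population
    probs = np.column_stack([block_props * (1 - config.other_race_share),
                             np.full(n_blocks, config.other_race_share)])
    race_counts = rng.multinomial(population, probs)
    pop_by_race = {f"pop_{r.lower()}": race_counts[:, k] for k, r in enumerate(RACE_GROUPS)}

    n_under5 = rng.binomial(population, config.frac_under5)
    n_5to9 = rng.binomial(population, config.frac_age5to9)

    n_buildings = np.maximum(1, rng.poisson(config.buildings_mean, n_blocks))
    building_age = np.maximum(
        0.0, rng.normal(config.building_age_mean, config.building_age_sd, n_blocks))

    # latent contamination: logistic on covariates + community-area effect
    cm = config.contamination
    minority = (pop_by_race["pop_black"] + pop_by_race["pop_hispanic"]) / population
    z_age = (building_age - config.building_age_mean) / config.building_age_sd
    z_logpop = (np.log(population) - np.log(config.population_median)) / config.population_sigma
    z_bld = (n_buildings - config.buildings_mean) / np.sqrt(config.buildings_mean)
    ca_effect = rng.normal(0.0, cm.sigma_community, n_ca)
    logit_p = (cm.intercept + cm.b_minority * minority + cm.b_building_age * z_age
               + cm.b_log_population * z_logpop + cm.b_buildings * z_bld
               + ca_effect[ca_idx])
    for race, beta in cm.b_race.items():
        logit_p = logit_p + beta * (pop_by_race[f"pop_{race.lower()}"] / population)
    p_contaminated = _sigmoid(logit_p)
    contaminated = rng.random(n_blocks) < p_contaminated

    white = pop_by_race["pop_white"] / population
    sc = config.screening
    propensity = _sigmoid(sc.intercept + sc.b_white * white)

    blocks = pd.DataFrame({
        **{c: geo[c] for c in GEO_COLUMNS},
        "population": population,
        **pop_by_race,
        "n_children_under5": n_under5,
        "n_children_5to9": n_5to9,
        "n_buildings": n_buildings,
        "median_building_age": np.round(building_age, 1),
        "truth_p_contaminated": p_contaminated,
        "truth_contaminated": contaminated,
        "truth_screening_propensity": propensity,
    })
    return blocks


def generate_tests(blocks: pd.DataFrame, config: GeneratorConfig | None = None,
                   seed: int = 0) -> pd.DataFrame:
    """Generate the household lead-test file for a synthetic city.

    Each block enters the testing program with probability equal to its
    screening propensity; a tested block receives ``1 + Poisson(mean - 1)``
    tests.  Each test has three draws (stagnant first draw, 2-minute
    flush, 5-minute flush) from a log-normal whose median depends on the
    block's latent contamination state; draws below the detection limit
    are reported as 0 ppb with a per-draw below-detection flag.
    """
    if len(blocks) == 0:
        raise ValueError("blocks must be nonempty")
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    tested = rng.random(len(blocks)) < blocks["truth_screening_propensity"].to_numpy()
    lam = max(config.mean_tests_per_block - 1.0, 0.0)
    n_tests = np.where(tested, 1 + rng.poisson(lam, len(blocks)), 0)

    block_idx = np.repeat(np.arange(len(blocks)), n_tests)
    total = len(block_idx)
    state = blocks["truth_contaminated"].to_numpy()[block_idx]

    cc = config.concentrations
    out = {"block_id": blocks["block_id"].to_numpy()[block_idx]}
    for d in range(3):
        mu = np.where(state, np.log(cc.contaminated_median_ppb[d]),
                      np.log(cc.clean_median_ppb[d]))
        sigma = np.where(state, cc.contaminated_sigma, cc.clean_sigma)
        raw = rng.lognormal(mu, sigma, total) if total else np.empty(0)
        below = raw < cc.detection_limit_ppb
        out[f"draw{d+1}_ppb"] = np.where(below, 0.0, np.round(raw, 2))
        out[f"below_detection_draw{d+1}"] = below
    return pd.DataFrame(out)


def generate_survey(blocks: pd.DataFrame, config: GeneratorConfig | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Generate primary-drinking-water-source aggregates.

    Returns one row per race group (exact configured proportions) and one
    row per community area (population-weighted mixture of the race-level
    rows with mild Dirichlet noise, emulating survey sampling error).
    Every row lies on the 4-simplex: unfiltered + filtered + bottled +
    other = 1.
    """
    config = config or GeneratorConfig()
    config.validate()
    sv = config.survey
    rng = np.random.default_rng(seed)

    def simplex_row(p_unf: float) -> np.ndarray:
        rest = 1.0 - p_unf
        return np.array([p_unf, rest * sv.filtered_share, rest * sv.bottled_share,
                         rest * sv.other_share])

    rows = []
    for race in RACE_GROUPS:
        p = simplex_row(sv.p_unfiltered_by_race[race])
        rows.append({"group_or_area": race, "p_unfiltered_tap": p[0],
                     "p_filtered_tap": p[1], "p_bottled": p[2], "p_other": p[3]})

    race_cols = [f"pop_{r.lower()}" for r in RACE_GROUPS]
    for ca, sub in blocks.groupby("community_area_id", sort=True):
        weights = sub[race_cols].sum().to_numpy(dtype=float)
        weights = weights / weights.sum() if weights.sum() > 0 else np.full(4, 0.25)
        base = sum(w * simplex_row(sv.p_unfiltered_by_race[r])
                   for w, r in zip(weights, RACE_GROUPS))
        noisy = rng.dirichlet(np.maximum(sv.area_noise_concentration * base, 1e-3))
        rows.append({"group_or_area": ca, "p_unfiltered_tap": noisy[0],
                     "p_filtered_tap": noisy[1], "p_bottled": noisy[2],
                     "p_other": noisy[3]})
    return pd.DataFrame(rows)


def write_city(out_dir, blocks: pd.DataFrame, tests: pd.DataFrame,
               survey: pd.DataFrame) -> dict[str, str]:
    """Write blocks/tests/survey CSVs; returns {name: path}."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (("blocks", blocks), ("tests", tests), ("survey", survey)):
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = str(path)
    return paths
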