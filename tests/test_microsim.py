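"""Microsimulation: child accounting, misclassification adjustment,
resampling, uncertainty summaries and conservation."""

import numpy as np
import pandas as pd
import pytest

import leadwater as lw
from leadwater.config import GeneratorConfig
from leadwater.microsim import build_concentration_pools

from .conftest import make_city


# ---------------------------------------------------------------------- units
@pytest.mark.parametrize("under5, b5to9, expected", [(50, 20, 54.0), (0, 0, 0.0)])
def test_child_population_arithmetic(under5, b5to9, expected):
    frame = pd.DataFrame({"n_children_under5": [under5], "n_children_5to9": [b5to9]})
    assert lw.child_population(frame).iloc[0] == expected


def test_child_population_citywide_sum_matches_loop(city):
    blocks, _, _ = city
    total = lw.child_population(blocks).sum()
    oracle = sum(row.n_children_under5 + row.n_children_5to9 / 5
                 for row in blocks.itertuples())
    assert total == pytest.approx(oracle)


def test_child_population_rejects_negative_counts():
    frame = pd.DataFrame({"n_children_under5": [-1], "n_children_5to9": [0]})
    with pytest.raises(ValueError, match="nonnegative"):
        lw.child_population(frame)


def test_misclassification_identity_when_ppv_npv_perfect(rng):
    predicted = rng.random(500) < 0.6
    adjusted = lw.misclassification_adjust(predicted, 1.0, 1.0, rng)
    assert (adjusted == predicted).all()


def test_misclassification_binomial_concentration(rng):
    # mean over replicates concentrates at ppv*P (resp. (1-npv)*N)
    predicted = np.ones(10_000, dtype=bool)
    counts = [lw.misclassification_adjust(predicted, 0.8, 1.0, rng).sum()
              for _ in range(100)]
    assert abs(np.mean(counts) - 8000) <= 3 * np.sqrt(10_000 * 0.8 * 0.2 / 100)
    negatives = np.zeros(10_000, dtype=bool)
    flips = [lw.misclassification_adjust(negatives, 1.0, 0.5, rng).sum()
             for _ in range(100)]
    assert abs(np.mean(flips) - 5000) <= 3 * np.sqrt(10_000 * 0.25 / 100)


def test_misclassification_never_touches_observed_blocks(rng):
    predicted = np.zeros(200, dtype=bool)
    observed_mask = np.arange(200) < 100
    observed = np.ones(200, dtype=bool)
    adjusted = lw.misclassification_adjust(predicted, 1.0, 1.0, rng,
                                           observed_mask, observed)
    assert adjusted[:100].all() and not adjusted[100:].any()
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        lw.misclassification_adjust(predicted, 1.2, 0.5, rng)


def test_sample_concentration_top_coding_and_mean(rng):
    assert lw.sample_concentration(np.array([25.0]), 10.0, rng)[0] == 10.0
    assert (lw.sample_concentration(np.array([3.0]), 10.0, rng, size=50) == 3.0).all()
    draws = lw.sample_concentration(np.array([2.0, 4.0, 6.0]), 10.0, rng, size=10_000)
    se = np.std([2, 4, 6]) / np.sqrt(10_000)
    assert abs(draws.mean() - 4.0) <= 3 * se
    with pytest.raises(ValueError, match="empty"):
        lw.sample_concentration(np.array([]), 10.0, rng)


def test_sample_slope_support_and_mean(rng):
    er = lw.ExposureResponse(1.0, 1.0, 1.0)
    assert (lw.sample_slope(er, rng, size=20) == 1.0).all()
    er = lw.ExposureResponse(1.0, 0.0, 2.0)
    draws = lw.sample_slope(er, rng, size=10_000)
    assert draws.min() >= 0.0 and draws.max() <= 2.0
    assert abs(draws.mean() - 1.0) <= 3 * (2 / np.sqrt(12)) / np.sqrt(10_000)
    with pytest.raises(ValueError):
        lw.ExposureResponse(1.0, 2.0, 0.5)


def test_summarize_ui_percentile_definition():
    s = lw.summarize_ui(np.arange(1.0, 101.0))
    assert s.ui_low == pytest.approx(5.95)
    assert s.ui_high == pytest.approx(95.05)
    const = lw.summarize_ui(np.full(10, 7.0))
    assert const.ui_low == const.ui_high == const.point == 7.0
    assert lw.summarize_ui(np.array([1.0, 2.0, 3.0])).point == 2.0
    with pytest.raises(ValueError, match="empty"):
        lw.summarize_ui(np.array([]))


# ------------------------------------------------------------------ pool logic
def test_concentration_pool_fallback_chain(city):
    blocks, tests, _ = city
    values, start, length = build_concentration_pools(tests, blocks, "block_group")
    assert (length > 0).all()
    assert (values > 0).all()
    # a block whose block group has nonzero results gets exactly that pool
    nz = tests[tests["draw2_ppb"] > 0].merge(
        blocks[["block_id", "block_group_id"]], on="block_id")
    bg_counts = nz.groupby("block_group_id").size()
    bg = bg_counts.index[0]
    i = blocks.index[blocks["block_group_id"] == bg][0]
    pool = values[start[i]:start[i] + length[i]]
    expected = np.sort(nz.loc[nz["block_group_id"] == bg, "draw2_ppb"].to_numpy())
    assert np.array_equal(np.sort(pool), expected)


def test_empty_citywide_pool_raises(city):
    blocks, tests, _ = city
    dry = tests.assign(draw2_ppb=0.0)
    with pytest.raises(ValueError, match="citywide"):
        build_concentration_pools(dry, blocks, "block_group")


# ------------------------------------------------------------------- full runs
def _tiny_city_inputs(seed=17, n=300):
    cfg = GeneratorConfig()
    blocks, tests = make_city(cfg, n, seed)
    survey = lw.generate_survey(blocks, cfg, seed + 1)
    labels = lw.label_blocks(tests)
    predicted = blocks["truth_contaminated"].to_numpy()
    predictions = blocks[["block_id"]].assign(
        p_contaminated=np.where(predicted, 0.9, 0.1), predicted_label=predicted)
    return blocks, tests, survey, labels, predictions


def test_degenerate_run_is_fully_deterministic():
    blocks, tests, survey, labels, predictions = _tiny_city_inputs()
    single = tests.copy()
    single["draw2_ppb"] = 4.0  # one-value citywide pool
    er = lw.ExposureResponse(0.3, 0.3, 0.3)
    res = lw.run_microsim(blocks, labels, predictions, 1.0, 1.0, survey, er,
                          single, n_reps=50, seed=0)
    total = res.summary.set_index("group").loc["Total"]
    assert total["bll_increase_affected"] == pytest.approx(0.3 * 4.0)
    assert total["bll_increase_affected_ui_low"] == \
        total["bll_increase_affected_ui_high"]
    assert res.draws["n_exposed_total"].nunique() == 1  # ppv=npv=1: no resampling


def test_full_determinism_under_fixed_seed(city, city_labels, predictions,
                                           exposure_response):
    blocks, tests, survey = city
    kw = dict(n_reps=60, seed=9)
    a = lw.run_microsim(blocks, city_labels, predictions, 0.9, 0.8, survey,
                        exposure_response, tests, **kw)
    b = lw.run_microsim(blocks, city_labels, predictions, 0.9, 0.8, survey,
                        exposure_response, tests, **kw)
    pd.testing.assert_frame_equal(a.draws, b.draws)
    pd.testing.assert_frame_equal(a.summary, b.summary)


def test_race_counts_conserve_total_each_replicate(city, city_labels, predictions,
                                                   exposure_response):
    blocks, tests, survey = city
    res = lw.run_microsim(blocks, city_labels, predictions, 0.85, 0.7, survey,
                          exposure_response, tests, n_reps=100, seed=3)
    races = res.draws[[f"n_exposed_{r}" for r in
                       ("asian", "black", "hispanic", "white")]].sum(axis=1)
    assert np.allclose(races, res.draws["n_exposed_total"], rtol=1e-9)
    assert (res.draws["n_exposed_total"]
            <= lw.child_population(blocks).sum() + 1e-9).all()
    # overall-population increase never exceeds the affected-children increase
    assert (res.draws["bll_overall"] <= res.draws["bll_affected"] + 1e-12).all()


def test_raising_top_code_never_lowers_affected_increase(city, city_labels,
                                                          predictions):
    blocks, tests, survey = city
    means = []
    for top in (5.0, 10.0):
        er = lw.ExposureResponse(0.25, 0.10, 0.40, max_concentration_ppb=top)
        res = lw.run_microsim(blocks, city_labels, predictions, 0.9, 0.8, survey,
                              er, tests, n_reps=150, seed=11)
        means.append(res.summary.set_index("group")
                     .loc["Total", "bll_increase_affected"])
    assert means[1] >= means[0]


def test_replicate_count_stability_of_ui_endpoints(city, city_labels, predictions,
                                                    exposure_response):
    blocks, tests, survey = city
    runs = {}
    for reps in (1000, 10_000):
        res = lw.run_microsim(blocks, city_labels, predictions, 0.9, 0.8, survey,
                              exposure_response, tests, n_reps=reps, seed=13)
        total = res.summary.set_index("group").loc["Total"]
        runs[reps] = (total["affected_ui_low"], total["affected_ui_high"])
    for lo_hi_1k, lo_hi_10k in [(runs[1000], runs[10_000])]:
        for a, b in zip(lo_hi_1k, lo_hi_10k):
            assert abs(a - b) / abs(b) < 0.05


def test_missing_survey_group_and_missing_predictions_error(city, city_labels,
                                                            predictions,
                                                            exposure_response):
    blocks, tests, survey = city
    with pytest.raises(ValueError, match="survey"):
        lw.run_microsim(blocks, city_labels, predictions, 0.9, 0.8,
                        survey[survey["group_or_area"] != "Black"],
                        exposure_response, tests, n_reps=2, seed=0)
    with pytest.raises(ValueError, match="predictions"):
        lw.run_microsim(blocks, city_labels, predictions.iloc[:10], 0.9, 0.8,
                        survey, exposure_response, tests, n_reps=2, seed=0)
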