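"""Risk model: determinism, leakage, discrimination, PPV/NPV and
additive attributions."""

import numpy as np
import pandas as pd
import pytest

import leadwater as lw
from leadwater.config import GeneratorConfig, RiskModelConfig
from leadwater.riskmodel import (
    AttributionUnavailableError,
    PpvUndefinedError,
    SchemaError,
    _confusion_ppv_npv,
    _make_lgbm,
    _prepare,
    make_test_unit_frame,
)

from .conftest import high_fidelity_concentrations, make_city, separable_generator


def test_refit_same_seed_gives_identical_predictions(labeled_blocks, city, risk_fit):
    blocks, _, _ = city
    refit = lw.fit_risk_model(labeled_blocks, RiskModelConfig(tune=False), seed=5)
    pd.testing.assert_frame_equal(lw.predict_blocks(refit, blocks),
                                  lw.predict_blocks(risk_fit, blocks))
    assert refit.auroc_heldout == risk_fit.auroc_heldout


def test_heldout_rows_never_influence_training(labeled_blocks, risk_fit):
    """Retraining on exactly the recorded training rows reproduces the
    booster byte for byte: the held-out rows left no trace in the fit."""
    cfg = RiskModelConfig(tune=False)
    train = labeled_blocks[labeled_blocks["block_id"].isin(risk_fit.train_ids)]
    # same row order as the internal split
    train = train.set_index("block_id").loc[risk_fit.train_ids].reset_index()
    X, _ = _prepare(train)
    manual = _make_lgbm(cfg, 5, cfg.learning_rate_grid[0], cfg.num_leaves_grid[0])
    manual.fit(X, train["contaminated"].astype(bool).to_numpy(),
               categorical_feature=["community_area_id", "tract_id", "block_group_id"])
    assert manual.booster_.model_to_string() == risk_fit.model.booster_.model_to_string()


def test_separable_city_reaches_high_heldout_auroc():
    blocks, tests = make_city(separable_generator(), 2000, seed=11)
    labeled = blocks.merge(lw.label_blocks(tests)[["block_id", "contaminated"]],
                           on="block_id")
    fit = lw.fit_risk_model(labeled, RiskModelConfig(tune=False), seed=3)
    assert fit.auroc_heldout > 0.95


def test_permuted_labels_give_chance_level_auroc():
    cfg = separable_generator()
    cfg.screening.intercept = 1.5  # most blocks labeled -> large held-out set
    blocks, tests = make_city(cfg, 4000, seed=12)
    labeled = blocks.merge(lw.label_blocks(tests)[["block_id", "contaminated"]],
                           on="block_id")
    rng = np.random.default_rng(4)
    labeled = labeled.assign(
        contaminated=rng.permutation(labeled["contaminated"].to_numpy()))
    fit = lw.fit_risk_model(labeled, RiskModelConfig(tune=False), seed=3)
    assert 0.45 <= fit.auroc_heldout <= 0.55


def test_ppv_npv_confusion_arithmetic():
    y_true = np.array([True] * 8 + [False] * 2 + [False] * 9 + [True])
    y_pred = np.array([True] * 10 + [False] * 10)
    assert _confusion_ppv_npv(y_true, y_pred) == (0.8, 0.9)
    perfect = np.array([True, True, False, False])
    assert _confusion_ppv_npv(perfect, perfect) == (1.0, 1.0)
    with pytest.raises(PpvUndefinedError):
        _confusion_ppv_npv(y_true, np.zeros_like(y_true, dtype=bool))


def test_estimate_ppv_npv_matches_bruteforce_confusion(risk_fit, labeled_blocks):
    held = labeled_blocks[labeled_blocks["block_id"].isin(risk_fit.heldout_ids)]
    ppv, npv = lw.estimate_ppv_npv(risk_fit, held)
    X, _ = _prepare(held, risk_fit.categories)
    pred = risk_fit.model.predict_proba(X)[:, 1] >= risk_fit.threshold
    y = held["contaminated"].to_numpy(dtype=bool)
    tp = fp = tn = fn = 0
    for pi, yi in zip(pred, y):
        tp += pi and yi
        fp += pi and not yi
        tn += not pi and not yi
        fn += not pi and yi
    assert ppv == pytest.approx(tp / (tp + fp))
    assert npv == pytest.approx(tn / (tn + fn))
    assert (ppv, npv) == (risk_fit.ppv, risk_fit.npv)
    assert risk_fit.heldout_confusion == (tp, fp, tn, fn)


def test_predictions_cover_all_blocks_and_probability_range(predictions, city):
    blocks, _, _ = city
    assert len(predictions) == len(blocks)
    assert predictions["p_contaminated"].between(0, 1).all()
    assert (predictions["predicted_label"]
            == (predictions["p_contaminated"] >= 0.5)).all()


def test_predicted_prevalence_tracks_ground_truth(predictions, city):
    blocks, _, _ = city
    assert abs(predictions["predicted_label"].mean()
               - blocks["truth_contaminated"].mean()) <= 0.05


def test_predict_empty_frame(risk_fit):
    out = lw.predict_blocks(risk_fit, pd.DataFrame(columns=["block_id"]))
    assert len(out) == 0


def test_auroc_equals_pairwise_concordance(risk_fit, labeled_blocks):
    held = labeled_blocks[labeled_blocks["block_id"].isin(risk_fit.heldout_ids)]
    X, _ = _prepare(held, risk_fit.categories)
    score = risk_fit.model.predict_proba(X)[:, 1]
    y = held["contaminated"].to_numpy(dtype=bool)
    assert len(held) <= 500
    pos, neg = score[y], score[~y]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    assert risk_fit.auroc_heldout == pytest.approx(wins / (len(pos) * len(neg)))


def test_attributions_are_additive_on_margin_scale(risk_fit, city):
    blocks, _, _ = city
    sample = blocks.head(50)
    attr = lw.feature_attributions(risk_fit, sample)
    X, _ = _prepare(sample, risk_fit.categories)
    margin = risk_fit.model.booster_.predict(X, raw_score=True)
    assert np.abs(attr.sum(axis=1).to_numpy() - margin).max() < 1e-6


def test_constant_feature_gets_zero_attribution():
    cfg = separable_generator()
    cfg.frac_age5to9 = 0.0  # n_children_5to9 identically zero -> never split on
    blocks, tests = make_city(cfg, 1000, seed=13)
    labeled = blocks.merge(lw.label_blocks(tests)[["block_id", "contaminated"]],
                           on="block_id")
    fit = lw.fit_risk_model(labeled, RiskModelConfig(tune=False), seed=3)
    attr = lw.feature_attributions(fit, blocks)
    assert (attr["n_children_5to9"] == 0).all()


def test_geography_dominates_importance_when_it_drives_contamination():
    cfg = GeneratorConfig()
    cfg.contamination.sigma_community = 4.0
    cfg.contamination.b_minority = 0.0
    cfg.contamination.b_building_age = 0.0
    cfg.contamination.b_log_population = 0.0
    cfg.contamination.b_buildings = 0.0
    cfg.concentrations = high_fidelity_concentrations()
    blocks, tests = make_city(cfg, 2000, seed=14)
    labeled = blocks.merge(lw.label_blocks(tests)[["block_id", "contaminated"]],
                           on="block_id")
    fit = lw.fit_risk_model(labeled, RiskModelConfig(tune=False), seed=3)
    importance = lw.global_importance(lw.feature_attributions(fit, blocks))
    assert importance.index[0] in {"community_area_id", "tract_id", "block_group_id"}


def test_logistic_fallback_fits_and_refuses_attributions(labeled_blocks):
    fit = lw.fit_risk_model(labeled_blocks, RiskModelConfig(model="logistic"), seed=5)
    assert 0.0 <= fit.auroc_heldout <= 1.0
    with pytest.raises(AttributionUnavailableError, match="attribution unavailable"):
        lw.feature_attributions(fit, labeled_blocks.head(5))


def test_single_class_and_missing_covariates_raise(labeled_blocks):
    single = labeled_blocks.assign(contaminated=True)
    with pytest.raises(ValueError, match="single class"):
        lw.fit_risk_model(single, RiskModelConfig(tune=False), seed=0)
    with pytest.raises(SchemaError, match="population"):
        lw.fit_risk_model(labeled_blocks.drop(columns=["population"]),
                          RiskModelConfig(tune=False), seed=0)


def test_test_unit_frame_has_one_row_per_test(city):
    blocks, tests, _ = city
    frame = make_test_unit_frame(tests, blocks)
    assert len(frame) == len(tests)
    assert (frame["contaminated"].to_numpy()
            == (tests["draw2_ppb"] >= 1.0).to_numpy()).all()
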