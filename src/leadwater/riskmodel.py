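"""Block-level contamination risk model.

A gradient-boosted decision-tree classifier (LightGBM) predicts whether a
block's drinking water is lead contaminated from sociodemographic and
building covariates plus its position in the geographic hierarchy
(encoded as raw categorical levels, never target-encoded).  Performance
(AUROC, PPV, NPV at a fixed threshold) is measured on a stratified
held-out split that never touches training or tuning.  A penalized
logistic regression is available as a pluggable fallback; any estimator
with fit/predict_proba satisfies the contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.compose import ColumnTransformer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder, StandardScaler

from .config import RiskModelConfig

CATEGORICAL_FEATURES = ["community_area_id", "tract_id", "block_group_id"]
NUMERIC_FEATURES = [
    "population", "pop_asian", "pop_black", "pop_hispanic", "pop_white",
    "n_children_under5", "n_children_5to9", "n_buildings", "median_building_age",
]
ALL_FEATURES = CATEGORICAL_FEATURES + NUMERIC_FEATURES
LABEL_COLUMN = "contaminated"


class SchemaError(ValueError):
    """Input frame is missing required columns."""


class AttributionUnavailableError(TypeError):
    """Feature attributions require a tree-ensemble model."""


class PpvUndefinedError(ZeroDivisionError):
    """No predicted positives (or negatives) on the held-out set."""


@dataclass
class RiskModelFit:
    model: Any
    model_type: str
    threshold: float
    auroc_heldout: float
    ppv: float
    npv: float
    feature_names: list[str]
    categories: dict[str, pd.Index]
    heldout_confusion: tuple[int, int, int, int] = (0, 0, 0, 0)  # tp, fp, tn, fn
    train_ids: list[str] = field(repr=False, default_factory=list)
    heldout_ids: list[str] = field(repr=False, default_factory=list)
    params: dict[str, Any] = field(default_factory=dict)


def _check_schema(df: pd.DataFrame, required: list[str]) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")


def _prepare(df: pd.DataFrame, categories: dict[str, pd.Index] | None = None
             ) -> tuple[pd.DataFrame, dict[str, pd.Index]]:
    """Cast geography to pandas categoricals with a frozen level set."""
    X = df[ALL_FEATURES].copy()
    out_categories = {}
    for col in CATEGORICAL_FEATURES:
        if categories is None:
            cat = pd.Categorical(X[col])
            out_categories[col] = cat.categories
            X[col] = cat
        else:
            X[col] = pd.Categorical(X[col], categories=categories[col])
            out_categories[col] = categories[col]
    X[NUMERIC_FEATURES] = X[NUMERIC_FEATURES].astype(float)
    return X, out_categories


def _make_lgbm(cfg: RiskModelConfig, seed: int, learning_rate: float, num_leaves: int):
    import lightgbm as lgb

    return lgb.LGBMClassifier(
        n_estimators=cfg.n_estimators, learning_rate=learning_rate,
        num_leaves=num_leaves, random_state=seed, deterministic=True,
        n_jobs=1, force_row_wise=True, verbose=-1)


def _make_logistic(seed: int):
    return Pipeline([
        ("prep", ColumnTransformer([
            ("cat", OneHotEncoder(handle_unknown="ignore"), CATEGORICAL_FEATURES),
            ("num", StandardScaler(), NUMERIC_FEATURES)])),
        ("clf", LogisticRegression(C=1.0, max_iter=2000, random_state=seed)),
    ])


def fit_risk_model(labeled: pd.DataFrame, config: RiskModelConfig | None = None,
                   seed: int = 0) -> RiskModelFit:
    """Fit the contamination classifier on labeled blocks.

    ``labeled`` must contain the feature columns plus a boolean
    ``contaminated`` outcome (one row per labeled block, or per test when
    the unit-of-analysis robustness switch built the frame).  The data are
    split 80/20 stratified by label; hyperparameters are tuned by k-fold
    cross-validation inside the training split only; AUROC/PPV/NPV come
    from the untouched held-out split.
    """
    config = config or RiskModelConfig()
    config.validate()
    _check_schema(labeled, ALL_FEATURES + [LABEL_COLUMN])
    y = labeled[LABEL_COLUMN].astype(bool).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training data contain a single class; cannot fit a classifier")

    train_df, held_df = train_test_split(
        labeled, test_size=config.test_size, stratify=y, random_state=seed)
    X_train, categories = _prepare(train_df)
    y_train = train_df[LABEL_COLUMN].astype(bool).to_numpy()

    if config.model == "lightgbm":
        params = _tune_lgbm(X_train, y_train, config, seed) if config.tune else {
            "learning_rate": config.learning_rate_grid[0],
            "num_leaves": config.num_leaves_grid[0]}
        model = _make_lgbm(config, seed, **params)
        model.fit(X_train, y_train, categorical_feature=CATEGORICAL_FEATURES)
    else:
        params = {}
        model = _make_logistic(seed)
        model.fit(X_train, y_train)

    X_held, _ = _prepare(held_df, categories)
    y_held = held_df[LABEL_COLUMN].astype(bool).to_numpy()
    p_held = model.predict_proba(X_held)[:, 1]
    auroc = float(roc_auc_score(y_held, p_held))
    pred_held = p_held >= config.threshold
    ppv, npv = _confusion_ppv_npv(y_held, pred_held)
    confusion = (int(np.sum(pred_held & y_held)), int(np.sum(pred_held & ~y_held)),
                 int(np.sum(~pred_held & ~y_held)), int(np.sum(~pred_held & y_held)))

    id_col = "block_id" if "block_id" in labeled.columns else None
    return RiskModelFit(
        model=model, model_type=config.model, threshold=config.threshold,
        auroc_heldout=auroc, ppv=ppv, npv=npv,
        feature_names=list(ALL_FEATURES), categories=categories,
        heldout_confusion=confusion,
        train_ids=list(train_df[id_col]) if id_col else [],
        heldout_ids=list(held_df[id_col]) if id_col else [],
        params=params)


def _tune_lgbm(X: pd.DataFrame, y: np.ndarray, cfg: RiskModelConfig,
               seed: int) -> dict[str, Any]:
    """Grid search (learning rate x leaves) by stratified k-fold AUROC."""
    splitter = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=seed)
    best, best_score = None, -np.inf
    for lr in cfg.learning_rate_grid:
        for leaves in cfg.num_leaves_grid:
            scores = []
            for tr, va in splitter.split(X, y):
                m = _make_lgbm(cfg, seed, lr, leaves)
                m.fit(X.iloc[tr], y[tr], categorical_feature=CATEGORICAL_FEATURES)
                scores.append(roc_auc_score(y[va], m.predict_proba(X.iloc[va])[:, 1]))
            score = float(np.mean(scores))
            if score > best_score:  # first-best tie-break: grid order
                best, best_score = {"learning_rate": lr, "num_leaves": leaves}, score
    return best


def predict_blocks(fit: RiskModelFit, blocks: pd.DataFrame) -> pd.DataFrame:
    """Predict contamination probability for every block (tested or not).

    Downstream stages keep observed labels for tested blocks; predictions
    fill in the unobserved remainder.
    """
    if len(blocks) == 0:
        return pd.DataFrame(columns=["block_id", "p_contaminated", "predicted_label"])
    _check_schema(blocks, ALL_FEATURES + ["block_id"])
    X, _ = _prepare(blocks, fit.categories)
    p = fit.model.predict_proba(X)[:, 1]
    return pd.DataFrame({
        "block_id": blocks["block_id"].to_numpy(),
        "p_contaminated": p,
        "predicted_label": p >= fit.threshold,
    })


def _confusion_ppv_npv(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    tp = int(np.sum(y_pred & y_true))
    fp = int(np.sum(y_pred & ~y_true))
    tn = int(np.sum(~y_pred & ~y_true))
    fn = int(np.sum(~y_pred & y_true))
    if tp + fp == 0:
        raise PpvUndefinedError("no predicted positives: PPV undefined")
    if tn + fn == 0:
        raise PpvUndefinedError("no predicted negatives: NPV undefined")
    return tp / (tp + fp), tn / (tn + fn)


def estimate_ppv_npv(fit: RiskModelFit, heldout: pd.DataFrame) -> tuple[float, float]:
    """PPV/NPV at the fit's fixed threshold on a disjoint labeled set."""
    _check_schema(heldout, ALL_FEATURES + [LABEL_COLUMN])
    X, _ = _prepare(heldout, fit.categories)
    y = heldout[LABEL_COLUMN].astype(bool).to_numpy()
    pred = fit.model.predict_proba(X)[:, 1] >= fit.threshold
    return _confusion_ppv_npv(y, pred)


def feature_attributions(fit: RiskModelFit, blocks: pd.DataFrame) -> pd.DataFrame:
    """Per-block additive feature contributions (TreeSHAP) on the margin scale.

    Returns one column per feature plus ``base_value``; each row sums to
    the model's raw-margin output for that block.  Only available for the
    tree-ensemble model.
    """
    if fit.model_type != "lightgbm":
        raise AttributionUnavailableError(
            f"attribution unavailable for model type {fit.model_type!r}; "
            "requires the tree-ensemble model")
    _check_schema(blocks, ALL_FEATURES)
    X, _ = _prepare(blocks, fit.categories)
    contrib = fit.model.booster_.predict(X, pred_contrib=True)
    return pd.DataFrame(contrib, columns=fit.feature_names + ["base_value"],
                        index=blocks.index)


def global_importance(attributions: pd.DataFrame) -> pd.Series:
    """Mean absolute contribution per feature, sorted descending."""
    contribs = attributions.drop(columns=["base_value"])
    return contribs.abs().mean(axis=0).sort_values(ascending=False)


def make_test_unit_frame(tests: pd.DataFrame, blocks: pd.DataFrame,
                         draw: str = "second") -> pd.DataFrame:
    """Robustness path: one row per household test instead of per block.

    The outcome is whether that single test's chosen draw is at or above
    the 1 ppb detection limit; block covariates are joined on.
    """
    from .labels import DETECTION_LIMIT_PPB, _draw_column

    col = _draw_column(draw)
    merged = tests[["block_id", col]].merge(blocks, on="block_id", how="inner")
    merged[LABEL_COLUMN] = merged[col] >= DETECTION_LIMIT_PPB
    return merged.drop(columns=[col])
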