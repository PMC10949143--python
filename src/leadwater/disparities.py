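"""Disparity regressions and E-value sensitivity analysis.

For each racial/ethnic group separately, logistic regressions quantify
(1) screening disparities — whether a block was tested, regressed on the
group's block-level population proportion with the predicted contamination
risk as an adjustment covariate — and (2) exposure disparities — whether a
block's water is lead contaminated, regressed on the group proportion and
total block population.

Coefficients are log-odds per unit change in proportion (0 -> 1).  The
reported "increase" rescales the full-range odds ratio to a
per-10-percentage-point percentage change:

    increase = 100 * (exp(b) - 1) / 10

(The naive alternative ``100 * (exp(b / 10) - 1)`` is NOT used; it is the
per-10pp odds change under the model, but it does not match the reporting
convention of published block-level disparity tables, which divide the
full-range percentage change by ten.)

E-values use the common-outcome odds-ratio approximation: RR* = sqrt(OR)
(inverting protective ORs first), then E = RR* + sqrt(RR* * (RR* - 1)).
An E-value of, say, 2 means an unmeasured confounder would need
risk-ratio associations of at least 2 with both the group proportion and
the outcome to explain the association away entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import RACE_GROUPS

Z_95 = float(stats.norm.ppf(0.975))


class DegenerateDesignError(ValueError):
    """A regressor is constant (or the outcome is single-valued)."""


@dataclass
class DisparityResult:
    group: str
    outcome: str               # "screening" or "exposure"
    coefficient: float         # log-odds per unit proportion (0 -> 1 scale)
    se: float
    increase_per_10pp: float   # percent
    ci_low: float
    ci_high: float
    p_value: float
    e_value: float
    n_obs: int
    warnings: tuple[str, ...] = ()


def coef_to_increase(coefficient: float) -> float:
    """Percent odds change per 10-percentage-point increase in group share."""
    if not np.isfinite(coefficient):
        raise ValueError("coefficient must be finite")
    return 100.0 * np.expm1(coefficient) / 10.0


def evalue_from_or(odds_ratio: float) -> float:
    """E-value for an odds ratio with a common outcome.

    The OR is first mapped to an approximate risk ratio RR* = sqrt(OR)
    (after inverting protective ORs so RR* >= 1), then
    E = RR* + sqrt(RR* * (RR* - 1)).  Returns 1.0 exactly when OR = 1.
    """
    if not (np.isfinite(odds_ratio) and odds_ratio > 0):
        raise ValueError(f"odds_ratio must be a positive finite number, got {odds_ratio!r}")
    if odds_ratio < 1.0:
        odds_ratio = 1.0 / odds_ratio
    rr = np.sqrt(odds_ratio)
    return float(rr + np.sqrt(rr * (rr - 1.0)))


def _fit_logit(y: np.ndarray, X: pd.DataFrame, focal: str,
               robust_se: bool) -> tuple[float, float, float, tuple[str, ...]]:
    """Fit a logit and return (coef, se, p) for the focal column."""
    msgs: list[str] = []
    for col in X.columns:
        if np.ptp(X[col].to_numpy(dtype=float)) == 0:
            raise DegenerateDesignError(f"regressor {col!r} is constant across observations")
    if len(np.unique(y)) < 2:
        raise DegenerateDesignError("outcome takes a single value")
    design = sm.add_constant(X.astype(float), has_constant="add")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.Logit(y.astype(float), design)
        try:
            res = model.fit(disp=0, cov_type="HC1" if robust_se else "nonrobust",
                            maxiter=200)
        except Exception as exc:  # e.g. perfect separation raised as error
            raise DegenerateDesignError(f"logit fit failed: {exc}") from exc
    for w in caught:
        if "separation" in str(w.message).lower() or "converge" in str(w.message).lower():
            msgs.append(str(w.message))
    return (float(res.params[focal]), float(res.bse[focal]),
            float(res.pvalues[focal]), tuple(msgs))


def _build_result(group: str, outcome: str, coef: float, se: float, p: float,
                  n_obs: int, msgs: tuple[str, ...]) -> DisparityResult:
    lo, hi = coef - Z_95 * se, coef + Z_95 * se
    return DisparityResult(
        group=group, outcome=outcome, coefficient=coef, se=se,
        increase_per_10pp=coef_to_increase(coef),
        ci_low=coef_to_increase(lo), ci_high=coef_to_increase(hi),
        p_value=p, e_value=evalue_from_or(float(np.exp(coef))),
        n_obs=n_obs, warnings=msgs)


def _group_proportion(blocks: pd.DataFrame, group: str) -> pd.Series:
    col = f"pop_{group.lower()}"
    if col not in blocks.columns:
        raise KeyError(f"blocks frame lacks column {col!r} for group {group!r}")
    return blocks[col] / blocks["population"]


def fit_screening_regression(blocks: pd.DataFrame, predictions: pd.DataFrame | None,
                             group: str, adjust_risk: bool = True,
                             robust_se: bool = False) -> DisparityResult:
    """Screening disparity for one group.

    Outcome: the block's ``tested`` flag.  Covariates: the group's
    population proportion and, when ``adjust_risk``, the model-predicted
    contamination probability (so the disparity is measured net of
    genuine risk differences).  The unadjusted variant is the stated
    robustness check.
    """
    if "tested" not in blocks.columns:
        raise KeyError("blocks frame must carry a boolean 'tested' column")
    X = pd.DataFrame({"proportion": _group_proportion(blocks, group)})
    if adjust_risk:
        if predictions is None:
            raise ValueError("risk adjustment requested but predictions missing")
        merged = blocks[["block_id"]].merge(
            predictions[["block_id", "p_contaminated"]], on="block_id", how="left")
        if merged["p_contaminated"].isna().any():
            raise ValueError("predictions missing for some blocks")
        X["estimated_risk"] = merged["p_contaminated"].to_numpy()
    y = blocks["tested"].astype(bool).to_numpy()
    coef, se, p, msgs = _fit_logit(y, X, "proportion", robust_se)
    return _build_result(group, "screening", coef, se, p, len(blocks), msgs)


def fit_exposure_regression(blocks: pd.DataFrame, labels: pd.DataFrame,
                            group: str, robust_se: bool = False) -> DisparityResult:
    """Exposure disparity for one group.

    Outcome: the block-level contamination label (available for tested
    blocks).  Covariates: the group's population proportion and total
    block population.
    """
    merged = blocks.merge(labels[["block_id", "contaminated"]], on="block_id",
                          how="inner")
    X = pd.DataFrame({
        "proportion": _group_proportion(merged, group),
        "population": merged["population"].astype(float),
    })
    y = merged["contaminated"].astype(bool).to_numpy()
    coef, se, p, msgs = _fit_logit(y, X, "proportion", robust_se)
    return _build_result(group, "exposure", coef, se, p, len(merged), msgs)


def disparity_table(blocks: pd.DataFrame, labels: pd.DataFrame,
                    predictions: pd.DataFrame | None, adjust_risk: bool = True,
                    robust_se: bool = False,
                    groups: tuple[str, ...] = RACE_GROUPS) -> pd.DataFrame:
    """All groups x {screening, exposure} in a flat table.

    Layout: one row per (group, outcome) with coefficient, SE,
    per-10pp increase and its 95% CI, p-value and E-value.
    """
    rows = []
    for group in groups:
        for res in (fit_screening_regression(blocks, predictions, group,
                                             adjust_risk, robust_se),
                    fit_exposure_regression(blocks, labels, group, robust_se)):
            rows.append({
                "group": res.group, "outcome": res.outcome,
                "coefficient": res.coefficient, "se": res.se,
                "increase_per_10pp": res.increase_per_10pp,
                "ci_low": res.ci_low, "ci_high": res.ci_high,
                "p_value": res.p_value, "e_value": res.e_value,
                "n_obs": res.n_obs, "warnings": "; ".join(res.warnings),
            })
    return pd.DataFrame(rows)
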