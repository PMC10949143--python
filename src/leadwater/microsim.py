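"""Monte Carlo microsimulation of childhood exposure and relative BLL increase.

Each replicate (default 10,000):

1. classifies every block as exposed or not — tested blocks keep their
   observed label (authoritative, never resampled); untested blocks start
   from the model prediction and are resampled binomially using the
   classifier's held-out PPV/NPV, so prevalence is unbiased with respect
   to classifier error;
2. counts exposed children younger than 6 (per block:
   ``n_under5 + n_5to9 / 5``, assuming a uniform age distribution) and
   allocates them across race groups by block composition and across
   water sources by survey proportions;
3. draws, for each exposed block, one water-lead concentration by
   resampling with replacement from the nonzero 2-minute-flush results of
   the block's geographic region (falling back block group -> tract ->
   community area -> citywide), top-coded at 10 ppb, and one
   exposure-response slope from a uniform distribution over the slope's
   95% CI;
4. averages slope x concentration over exposed children (the "affected"
   relative BLL increase) and rescales by the unfiltered-tap-using share
   for the overall-population figure.

Uncertainty intervals are the 5th-95th percentiles over replicates
(linear interpolation between order statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RACE_GROUPS


@dataclass
class ExposureResponse:
    """External exposure-response association: % BLL increase per ppb of
    lead in drinking water after ``exposure_days`` days of exposure.

    The packaged defaults are deliberately absent: the slope comes from an
    external epidemiological study and must be supplied.  Concentrations
    are top-coded at ``max_concentration_ppb`` because the association is
    unsupported beyond that range.
    """

    slope_point: float
    slope_ci_low: float
    slope_ci_high: float
    max_concentration_ppb: float = 10.0
    exposure_days: int = 150

    def __post_init__(self):
        if not (self.slope_ci_low <= self.slope_point <= self.slope_ci_high):
            raise ValueError("require slope_ci_low <= slope_point <= slope_ci_high")
        if self.max_concentration_ppb <= 0:
            raise ValueError("max_concentration_ppb must be > 0")


@dataclass
class UncertaintySummary:
    point: float    # mean over replicates
    ui_low: float   # 5th percentile
    ui_high: float  # 95th percentile

    def __post_init__(self):
        if self.ui_low > self.ui_high + 1e-12:
            raise ValueError("ui_low must be <= ui_high")


@dataclass
class MicrosimResult:
    draws: pd.DataFrame                       # one row per replicate
    summary: pd.DataFrame                     # Table-layout point (5th-95th pct)
    child_population: dict[str, float] = field(default_factory=dict)


def child_population(blocks: pd.DataFrame) -> pd.Series:
    """Children younger than 6 per block: ``n_under5 + n_5to9 / 5``.

    The under-10 age bin is assumed uniform across single years of age, so
    one fifth of the 5-9 bin is 5 years old.
    """
    u5 = blocks["n_children_under5"].to_numpy(dtype=float)
    b59 = blocks["n_children_5to9"].to_numpy(dtype=float)
    if (u5 < 0).any() or (b59 < 0).any():
        raise ValueError("child counts must be nonnegative")
    return pd.Series(u5 + b59 / 5.0, index=blocks.index, name="n_under6")


def misclassification_adjust(predicted_labels: np.ndarray, ppv: float, npv: float,
                             rng: np.random.Generator,
                             observed_mask: np.ndarray | None = None,
                             observed_labels: np.ndarray | None = None) -> np.ndarray:
    """One replicate of binomial misclassification adjustment.

    Predicted positives stay exposed with probability PPV; predicted
    negatives become exposed with probability 1 - NPV.  Blocks flagged in
    ``observed_mask`` keep ``observed_labels`` untouched.
    """
    if not (0.0 <= ppv <= 1.0 and 0.0 <= npv <= 1.0):
        raise ValueError("ppv and npv must lie in [0, 1]")
    predicted = np.asarray(predicted_labels, dtype=bool)
    u = rng.random(predicted.shape[0])
    adjusted = np.where(predicted, u < ppv, u < (1.0 - npv))
    if observed_mask is not None:
        observed_mask = np.asarray(observed_mask, dtype=bool)
        adjusted = np.where(observed_mask, np.asarray(observed_labels, dtype=bool),
                            adjusted)
    return adjusted


def sample_concentration(pool: np.ndarray, top_code: float,
                         rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Resample concentrations with replacement from ``pool``, top-coded."""
    pool = np.asarray(pool, dtype=float)
    if pool.size == 0:
        raise ValueError("concentration pool is empty")
    picks = pool[rng.integers(0, pool.size, size=size)]
    return np.minimum(picks, top_code)


def sample_slope(er: ExposureResponse, rng: np.random.Generator,
                 size: int = 1) -> np.ndarray:
    """Uniform draw over the slope's 95% CI (degenerate CI -> constant)."""
    if er.slope_ci_low == er.slope_ci_high:
        return np.full(size, er.slope_ci_low)
    return rng.uniform(er.slope_ci_low, er.slope_ci_high, size=size)


def summarize_ui(values: np.ndarray) -> UncertaintySummary:
    """Mean with 5th-95th percentile interval (linear interpolation)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarize an empty replicate vector")
    lo, hi = np.percentile(values, [5, 95])
    return UncertaintySummary(point=float(np.mean(values)), ui_low=float(lo),
                              ui_high=float(hi))


_LEVEL_CHAIN = ["block", "block_group", "tract", "community_area", "city"]
_LEVEL_COLUMN = {"block": "block_id", "block_group": "block_group_id",
                 "tract": "tract_id", "community_area": "community_area_id"}


def build_concentration_pools(tests: pd.DataFrame, blocks: pd.DataFrame,
                              region_level: str = "block_group"
                              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-block resampling pools of nonzero 2-min-flush concentrations.

    Starting at ``region_level``, each block is assigned the pool of its
    smallest enclosing region that has at least one nonzero result,
    falling back through coarser levels to the citywide pool.  Returns
    ``(values, start, length)`` where block *i*'s pool is
    ``values[start[i]:start[i]+length[i]]``.
    """
    if region_level not in _LEVEL_CHAIN:
        raise ValueError(f"unknown region level {region_level!r}")
    nz = tests.loc[tests["draw2_ppb"] > 0, ["block_id", "draw2_ppb"]]
    if len(nz) == 0:
        raise ValueError("citywide concentration pool is empty: no nonzero results")
    nz = nz.merge(blocks[["block_id", "block_group_id", "tract_id",
                          "community_area_id"]], on="block_id", how="left")

    chain = _LEVEL_CHAIN[_LEVEL_CHAIN.index(region_level):]
    pools_by_level: dict[str, dict] = {}
    for level in chain:
        if level == "city":
            continue
        col = _LEVEL_COLUMN[level]
        pools_by_level[level] = {
            key: grp["draw2_ppb"].to_numpy(dtype=float)
            for key, grp in nz.groupby(col, sort=True)}
    citywide = nz["draw2_ppb"].to_numpy(dtype=float)

    segments, start, length = [], np.zeros(len(blocks), dtype=np.int64), \
        np.zeros(len(blocks), dtype=np.int64)
    offset = 0
    for i, row in enumerate(blocks.itertuples(index=False)):
        pool = citywide
        for level in chain:
            if level == "city":
                break
            key = getattr(row, _LEVEL_COLUMN[level])
            candidate = pools_by_level[level].get(key)
            if candidate is not None and candidate.size > 0:
                pool = candidate
                break
        segments.append(pool)
        start[i], length[i] = offset, pool.size
        offset += pool.size
    return np.concatenate(segments), start, length


def run_microsim(blocks: pd.DataFrame, labels: pd.DataFrame,
                 predictions: pd.DataFrame, ppv: float, npv: float,
                 survey: pd.DataFrame, er: ExposureResponse,
                 tests: pd.DataFrame, n_reps: int = 10_000, seed: int = 0,
                 region_level: str = "block_group",
                 ppv_npv_counts: tuple[int, int, int, int] | None = None
                 ) -> MicrosimResult:
    """Run the full microsimulation; see the module docstring for the model.

    By default PPV/NPV are treated as known constants.  When
    ``ppv_npv_counts = (tp, fp, tn, fn)`` — the held-out confusion counts
    the estimates came from — each replicate instead draws PPV ~
    Beta(tp + 1/2, fp + 1/2) and NPV ~ Beta(tn + 1/2, fn + 1/2) (Jeffreys)
    so the uncertainty interval also reflects the sampling error of the
    predictive-value estimates, not just binomial misclassification noise.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not (0.0 <= ppv <= 1.0 and 0.0 <= npv <= 1.0):
        raise ValueError("ppv and npv must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_blocks = len(blocks)

    n_under6 = child_population(blocks).to_numpy()
    race_pops = np.column_stack([
        blocks[f"pop_{r.lower()}"].to_numpy(dtype=float) for r in RACE_GROUPS])
    race_tot = race_pops.sum(axis=1, keepdims=True)
    race_props = np.divide(race_pops, race_tot, out=np.full_like(race_pops, 0.25),
                           where=race_tot > 0)
    children_by_race = n_under6[:, None] * race_props

    survey_race = survey.set_index("group_or_area")
    missing = [r for r in RACE_GROUPS if r not in survey_race.index]
    if missing:
        raise ValueError(f"survey aggregates missing race groups: {missing}")
    p_unf_race = np.array([survey_race.loc[r, "p_unfiltered_tap"] for r in RACE_GROUPS])
    p_unf_block = race_props @ p_unf_race

    labeled = labels.set_index("block_id")["contaminated"]
    observed_mask = blocks["block_id"].isin(labeled.index).to_numpy()
    observed = np.zeros(n_blocks, dtype=bool)
    observed[observed_mask] = labeled.loc[
        blocks.loc[observed_mask, "block_id"]].to_numpy(dtype=bool)
    pred = (blocks[["block_id"]]
            .merge(predictions[["block_id", "predicted_label"]], on="block_id",
                   how="left"))
    if pred["predicted_label"].isna().any():
        raise ValueError("predictions missing for some blocks")
    predicted = pred["predicted_label"].to_numpy(dtype=bool)

    pool_values, pool_start, pool_len = build_concentration_pools(
        tests, blocks, region_level)

    total_children = float(n_under6.sum())
    total_children_race = children_by_race.sum(axis=0)

    cols = (["n_exposed_total", "n_exposed_unfiltered", "bll_affected", "bll_overall"]
            + [f"n_exposed_{r.lower()}" for r in RACE_GROUPS]
            + [f"n_exposed_unfiltered_{r.lower()}" for r in RACE_GROUPS]
            + [f"bll_affected_{r.lower()}" for r in RACE_GROUPS]
            + [f"bll_overall_{r.lower()}" for r in RACE_GROUPS])
    draws = np.zeros((n_reps, len(cols)))

    for rep in range(n_reps):
        if ppv_npv_counts is not None:
            tp, fp, tn, fn = ppv_npv_counts
            rep_ppv = rng.beta(tp + 0.5, fp + 0.5)
            rep_npv = rng.beta(tn + 0.5, fn + 0.5)
        else:
            rep_ppv, rep_npv = ppv, npv
        exposed = misclassification_adjust(predicted, rep_ppv, rep_npv, rng,
                                           observed_mask, observed)
        idx = np.flatnonzero(exposed)
        n_exp_race = children_by_race[idx].sum(axis=0)
        n_exp_unf_race = (children_by_race[idx] * p_unf_race[None, :]).sum(axis=0)
        n_exp_total = float(n_under6[idx].sum())
        n_exp_unf = float((n_under6[idx] * p_unf_block[idx]).sum())

        if idx.size > 0:
            u = rng.random(idx.size)
            pick = pool_start[idx] + np.floor(u * pool_len[idx]).astype(np.int64)
            conc = np.minimum(pool_values[pick], er.max_concentration_ppb)
            slope = sample_slope(er, rng, size=idx.size)
            inc = slope * conc  # % BLL increase for children in that block
            w = n_under6[idx]
            bll_aff = float((w * inc).sum() / w.sum()) if w.sum() > 0 else 0.0
            wr = children_by_race[idx]
            denom = wr.sum(axis=0)
            bll_aff_race = np.divide((wr * inc[:, None]).sum(axis=0), denom,
                                     out=np.zeros(4), where=denom > 0)
        else:
            bll_aff, bll_aff_race = 0.0, np.zeros(4)

        bll_overall = bll_aff * n_exp_unf / total_children if total_children > 0 else 0.0
        bll_overall_race = np.divide(bll_aff_race * n_exp_unf_race, total_children_race,
                                     out=np.zeros(4), where=total_children_race > 0)
        draws[rep] = np.concatenate([
            [n_exp_total, n_exp_unf, bll_aff, bll_overall],
            n_exp_race, n_exp_unf_race, bll_aff_race, bll_overall_race])

    draws_df = pd.DataFrame(draws, columns=cols)
    child_pop = {"Total": total_children,
                 **{r: float(total_children_race[k]) for k, r in enumerate(RACE_GROUPS)}}
    summary = _summary_table(draws_df, child_pop)
    return MicrosimResult(draws=draws_df, summary=summary, child_population=child_pop)


def format_summary(summary: pd.DataFrame) -> pd.DataFrame:
    """Render the numeric summary as ``point (ui_low-ui_high)`` strings,
    one row per group, matching the conventional stratified table layout."""
    out = pd.DataFrame({"group": summary["group"]})
    out["child_population"] = summary["child_population"].map(lambda v: f"{v:.0f}")
    for col, digits in (("affected", 0), ("affected_unfiltered", 0),
                        ("bll_increase_affected", 1), ("bll_increase_overall", 1)):
        out[col] = [f"{p:.{digits}f} ({lo:.{digits}f}-{hi:.{digits}f})"
                    for p, lo, hi in zip(summary[col], summary[f"{col}_ui_low"],
                                         summary[f"{col}_ui_high"])]
    return out


def _summary_table(draws: pd.DataFrame, child_pop: dict[str, float]) -> pd.DataFrame:
    rows = []
    for group in ["Total"] + list(RACE_GROUPS):
        suffix = "" if group == "Total" else f"_{group.lower()}"
        row = {"group": group, "child_population": child_pop[group]}
        for label, col in (("affected", f"n_exposed{'_total' if group == 'Total' else suffix}"),
                           ("affected_unfiltered", f"n_exposed_unfiltered{suffix}"),
                           ("bll_increase_affected", f"bll_affected{suffix}"),
                           ("bll_increase_overall", f"bll_overall{suffix}")):
            s = summarize_ui(draws[col].to_numpy())
            row[label], row[f"{label}_ui_low"], row[f"{label}_ui_high"] = \
                s.point, s.ui_low, s.ui_high
        rows.append(row)
    return pd.DataFrame(rows)
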