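"""Block-level contamination labels and draw summaries.

A block counts as lead contaminated when at least half of its household
tests show a 2-minute-flush (second draw) concentration at or above the
1 ppb detection limit.  Ties at exactly 50% count as contaminated.
Values reported as 0 with a below-detection flag are below 1 ppb by
construction and never count toward detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

DETECTION_LIMIT_PPB = 1.0
MAJORITY_THRESHOLD = 0.5

_DRAW_SELECTORS = {"first": "draw1_ppb", "second": "draw2_ppb", "third": "draw3_ppb"}
_DRAW_NAMES = {"draw1_ppb": "first", "draw2_ppb": "flush2min", "draw3_ppb": "flush5min"}


@dataclass(frozen=True)
class BlockLabel:
    block_id: str
    n_tests: int
    n_detect: int
    contaminated: bool | None  # None when the block has no tests

    def __post_init__(self):
        if self.n_tests == 0 and self.contaminated is not None:
            raise ValueError("contaminated must be undefined when n_tests == 0")


def percent(count: int, total: int) -> float:
    """Percentage ``100 * count / total`` rounded half-up to 2 decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    frac = Decimal(100 * count) / Decimal(total)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def label_block(tests_for_block: pd.DataFrame, draw: str = "second") -> BlockLabel:
    """Label a single block from its tests (all rows must share one block_id)."""
    col = _draw_column(draw)
    if len(tests_for_block) == 0:
        return BlockLabel(block_id="", n_tests=0, n_detect=0, contaminated=None)
    ids = tests_for_block["block_id"].unique()
    if len(ids) != 1:
        raise ValueError(f"tests span multiple blocks: {sorted(ids)[:5]}")
    values = tests_for_block[col].to_numpy(dtype=float)
    n_detect = int((values >= DETECTION_LIMIT_PPB).sum())
    n = len(values)
    return BlockLabel(block_id=str(ids[0]), n_tests=n, n_detect=n_detect,
                      contaminated=bool(n_detect / n >= MAJORITY_THRESHOLD))


def label_blocks(tests: pd.DataFrame, draw: str = "second") -> pd.DataFrame:
    """Vectorized majority-rule labels for every tested block.

    Returns columns block_id, n_tests, n_detect, contaminated.  Untested
    blocks do not appear (their label is undefined).
    """
    col = _draw_column(draw)
    if len(tests) == 0:
        return pd.DataFrame(columns=["block_id", "n_tests", "n_detect", "contaminated"])
    detect = tests[col].to_numpy(dtype=float) >= DETECTION_LIMIT_PPB
    grouped = (pd.DataFrame({"block_id": tests["block_id"], "detect": detect})
               .groupby("block_id", sort=True)["detect"].agg(["size", "sum"])
               .reset_index())
    grouped.columns = ["block_id", "n_tests", "n_detect"]
    grouped["n_detect"] = grouped["n_detect"].astype(int)
    grouped["contaminated"] = grouped["n_detect"] / grouped["n_tests"] >= MAJORITY_THRESHOLD
    return grouped


def alternative_outcome_labels(tests: pd.DataFrame, draw: str) -> pd.DataFrame:
    """Majority-rule labels using the first or third draw (robustness path).

    ``draw='second'`` reproduces :func:`label_blocks` exactly.
    """
    return label_blocks(tests, draw=draw)


def summarize_draws(tests: pd.DataFrame) -> pd.DataFrame:
    """Per-draw median, IQR and >=1/>=5/>=15 ppb counts and percentages.

    Medians and IQRs are over all tests (censored values enter as 0 ppb);
    percentages are rounded half-up to 2 decimals.
    """
    if len(tests) == 0:
        raise ValueError("tests must be nonempty")
    total = len(tests)
    rows = []
    for col, name in _DRAW_NAMES.items():
        v = tests[col].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        counts = {thr: int((v >= thr).sum()) for thr in (1, 5, 15)}
        rows.append({
            "draw_name": name,
            "median_ppb": med,
            "iqr_ppb": q3 - q1,
            "n_ge1": counts[1], "n_ge5": counts[5], "n_ge15": counts[15],
            "pct_ge1": percent(counts[1], total),
            "pct_ge5": percent(counts[5], total),
            "pct_ge15": percent(counts[15], total),
        })
    return pd.DataFrame(rows)


def _draw_column(draw: str) -> str:
    if draw not in _DRAW_SELECTORS:
        raise ValueError(f"draw must be one of {sorted(_DRAW_SELECTORS)}, got {draw!r}")
    return _DRAW_SELECTORS[draw]
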