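"""Nonparametric between-group comparison of metric distributions.

Each pair of groups is compared per metric with a two-sided
Wilcoxon-Mann-Whitney test: exact enumeration when the combined sample
is small (n_x + n_y <= 12) and tie-free, otherwise the normal
approximation with tie and continuity corrections.  No multiple-testing
correction is applied by default (each test at its own 5% level); Holm
correction is available behind a flag.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .matrices import GROUP_LABELS as GROUP_ORDER
from .metrics import METRIC_NAMES

logger = logging.getLogger(__name__)

EXACT_MAX_N = 12


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    group_x: str
    group_y: str
    U: float
    p_value: float
    significant: bool
    stars: str


def mann_whitney(x, y, method: str | None = None) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U, p).

    ``method`` is chosen automatically: exact when n_x + n_y <= 12 with
    no ties across the pooled sample, else the tie-corrected normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if method is None:
        pooled = np.concatenate([x, y])
        tie_free = len(np.unique(pooled)) == len(pooled)
        method = "exact" if (x.size + y.size <= EXACT_MAX_N and tie_free) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def compare_all(
    cohort_metrics: pd.DataFrame,
    alpha: float = 0.05,
    holm: bool = False,
) -> pd.DataFrame:
    """All group pairs x all six metrics; one row per comparison.

    Groups with fewer than 2 defined values for a metric are skipped
    with a warning.  With ``holm=True`` the p-values are Holm-adjusted
    across the whole table before the significance call.
    """
    canonical = {g: i for i, g in enumerate(GROUP_ORDER)}
    groups = sorted(
        cohort_metrics["group"].unique(),
        key=lambda g: (canonical.get(g, len(canonical)), g),
    )
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for gx, gy in itertools.combinations(groups, 2):
        for metric in METRIC_NAMES:
            x = cohort_metrics.loc[cohort_metrics["group"] == gx, metric].dropna()
            y = cohort_metrics.loc[cohort_metrics["group"] == gy, metric].dropna()
            if len(x) < 2 or len(y) < 2:
                logger.warning("skipping %s %s-%s: degenerate group sizes (%d, %d)", metric, gx, gy, len(x), len(y))
                continue
            U, p = mann_whitney(x, y)
            rows.append({"group_x": gx, "group_y": gy, "metric": metric, "U": U, "p_value": p})
    out = pd.DataFrame(rows)
    p_eff = out["p_value"].to_numpy()
    if holm:
        p_eff = multipletests(p_eff, alpha=alpha, method="holm")[1]
        out["p_holm"] = p_eff
    out["significant"] = p_eff < alpha
    out["stars"] = [_stars(p) for p in p_eff]
    return out


def comparison_grid(comparisons: pd.DataFrame) -> pd.DataFrame:
    """Pivot to the familiar layout: rows = group pairs, columns = metrics.

    Non-significant cells are NA; significant ones hold the p-value.
    """
    df = comparisons.copy()
    df["pair"] = df["group_x"] + "-" + df["group_y"]
    df["cell"] = np.where(df["significant"], df["p_value"], np.nan)
    grid = df.pivot(index="pair", columns="metric", values="cell")
    return grid.reindex(columns=[m for m in METRIC_NAMES if m in grid.columns])
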