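"""Cross-level association: activity vs transcription vs origin distance.

Simple ordinary least-squares regressions tie the three measurement layers
together per strain: LacS activity (kinetic slope), relative lacS
transcription (ddCT fold change) and the site's distance to the nearest
replication origin.  Each pair is summarized by slope, R^2 and the two-tailed
p value for slope != 0 (t distribution, n - 2 df).  Values enter on the raw
scale by default; a log10 transform of activity and fold change is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RegressionResult", "fit_linear", "correlation_report"]


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_two_tailed: float
    n: int


def fit_linear(x, y) -> RegressionResult:
    """OLS fit of y on x with R^2 and a two-tailed slope test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("regression needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope is undefined")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_two_tailed=float(res.pvalue),
        n=len(x),
    )


PAIRS = [
    ("activity_vs_expression", "fold_change", "geo_mean_slope"),
    ("expression_vs_ori_distance", "ori_distance", "fold_change"),
    ("activity_vs_ori_distance", "ori_distance", "geo_mean_slope"),
]


def correlation_report(
    site_table: pd.DataFrame,
    activity: pd.DataFrame,
    expression: pd.DataFrame,
    log_scale: bool = False,
) -> tuple[dict, pd.DataFrame]:
    """The three pairwise regressions on a complete-case strain join.

    ``site_table`` needs columns site/ori_distance, ``activity``
    strain/geo_mean_slope, ``expression`` strain/fold_change; strains missing
    from any layer are dropped (count recorded in the scatter frame's attrs).
    Returns ({name: RegressionResult}, scatter data frame).
    """
    ctx = site_table.rename(columns={"site": "strain"})[["strain", "ori_distance"]]
    act = activity[["strain", "geo_mean_slope"]]
    expr = expression[["strain", "fold_change"]]
    merged = ctx.merge(act, on="strain").merge(expr, on="strain")
    n_dropped = len(set(ctx["strain"]) | set(act["strain"]) | set(expr["strain"])) - len(merged)
    if len(merged) < 3:
        raise ValueError(f"only {len(merged)} strains present in all three layers; need >= 3")
    data = merged.copy()
    if log_scale:
        data["geo_mean_slope"] = np.log10(data["geo_mean_slope"])
        data["fold_change"] = np.log10(data["fold_change"])
    results = {name: fit_linear(data[xc], data[yc]) for name, xc, yc in PAIRS}
    data.attrs["n_dropped"] = n_dropped
    return results, data
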