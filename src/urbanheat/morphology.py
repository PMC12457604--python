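"""LCZ morphology comparison between niche-exceeding and cooler cities.

Cities are split into < 29 degC and > 29 degC groups on their terminal
period (2071-2100) MAT, and each LCZ group share is compared between the
two with Welch's two-sample t-test (no equal-variance assumption,
Welch-Satterthwaite degrees of freedom, two-sided p), both pooled over the
whole city set and stratified by continent.  Raw p < alpha earns the
significance flag; no multiple-testing correction is applied by default
(a Benjamini-Hochberg mode is available for sensitivity use).

Also provides the median-position diagnostic: the fraction of exceeding
cities whose share of a given LCZ group lies strictly above (or below) the
median share of all cities of their continent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("urbanheat")

ALL_STRATUM = "ALL"


@dataclass
class ComparisonResult:
    continent: str
    lcz_group: str
    n_below: int
    n_above: int
    mean_below: float
    mean_above: float
    t_stat: float
    df: float
    p_value: float
    significant: bool


def split_groups(
    cities: pd.DataFrame, mat_col: str = "mat", threshold: float = 29.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition cities by terminal-period MAT: (below-or-at, strictly above)."""
    above = cities[cities[mat_col] > threshold]
    below = cities[~(cities[mat_col] > threshold)]
    if above.empty:
        logger.warning("split_groups: no city above %.1f degC; comparison degenerate", threshold)
    return below, above


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch's two-sample t statistic, Welch-Satterthwaite df, two-sided p.

    t = (mean_x - mean_y) / sqrt(s2x/nx + s2y/ny) with unbiased variances;
    p from the Student-t survival function.  Requires n >= 2 per sample.
    Two degenerate cases: both variances zero with equal means -> (0, nan, 1);
    both variances zero with different means -> (+-inf, nan, 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("welch_t needs at least 2 observations per sample")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    diff = x.mean() - y.mean()
    se2 = vx / nx + vy / ny
    if se2 == 0.0:
        if diff == 0.0:
            return 0.0, float("nan"), 1.0
        return math.copysign(float("inf"), diff), float("nan"), 0.0
    t = diff / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), p


def compare_all(
    cities: pd.DataFrame,
    group_labels: Iterable[str],
    mat_col: str = "mat",
    threshold: float = 29.0,
    alpha: float = 0.05,
    correction: str | None = None,
) -> pd.DataFrame:
    """Welch comparisons of LCZ group shares per (continent + pooled) stratum.

    ``cities`` needs columns continent, ``mat_col`` and one share column per
    label in ``group_labels``.  One output row per stratum x group; strata
    where either temperature group has fewer than two cities get missing
    t/df/p and ``significant = False``.  ``correction='bh'`` applies
    Benjamini-Hochberg across the emitted p-values before flagging.
    """
    group_labels = list(group_labels)
    strata = [ALL_STRATUM] + sorted(cities["continent"].unique())
    rows: list[ComparisonResult] = []
    for stratum in strata:
        sub = cities if stratum == ALL_STRATUM else cities[cities["continent"] == stratum]
        below, above = split_groups(sub, mat_col, threshold)
        for label in group_labels:
            nb, na = len(below), len(above)
            mb = float(below[label].mean()) if nb else float("nan")
            ma = float(above[label].mean()) if na else float("nan")
            if nb < 2 or na < 2:
                rows.append(
                    ComparisonResult(stratum, label, nb, na, mb, ma,
                                     float("nan"), float("nan"), float("nan"), False)
                )
                continue
            t, df, p = welch_t(below[label].to_numpy(), above[label].to_numpy())
            rows.append(ComparisonResult(stratum, label, nb, na, mb, ma, t, df, p, p < alpha))
    out = pd.DataFrame([r.__dict__ for r in rows])
    if correction == "bh":
        mask = out["p_value"].notna()
        adj = _benjamini_hochberg(out.loc[mask, "p_value"].to_numpy())
        out.loc[mask, "p_adjusted"] = adj
        out["significant"] = out.get("p_adjusted", out["p_value"]) < alpha
        out["significant"] = out["significant"].fillna(False)
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def median_position_diagnostic(
    cities: pd.DataFrame,
    group_label: str,
    direction: str,
    mat_col: str = "mat",
    threshold: float = 29.0,
    median_population: str = "all",
) -> float:
    """Fraction of exceeders on the stated side of their continent median.

    For each city with MAT > ``threshold``, its ``group_label`` share is
    compared to the median share over cities of its continent (all cities by
    default, only non-exceeders with ``median_population='nonexceeders'``).
    Strict comparison: ties count as not satisfying the condition.
    """
    if direction not in ("above", "below"):
        raise ValueError("direction must be 'above' or 'below'")
    exceed = cities[cities[mat_col] > threshold]
    if exceed.empty:
        raise ValueError("no exceeding cities; diagnostic undefined")
    if median_population == "all":
        base = cities
    elif median_population == "nonexceeders":
        base = cities[~(cities[mat_col] > threshold)]
    else:
        raise ValueError("median_population must be 'all' or 'nonexceeders'")
    medians = base.groupby("continent")[group_label].median()
    hits = 0
    for _, row in exceed.iterrows():
        med = medians.get(row["continent"], float("nan"))
        if math.isnan(med):
            continue
        if direction == "above":
            hits += bool(row[group_label] > med)
        else:
            hits += bool(row[group_label] < med)
    return hits / len(exceed)
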