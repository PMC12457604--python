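"""Climate-niche threshold screening and exposure accounting.

Cities are classified per scenario x period against the human-climate-niche
mean annual temperature (MAT) thresholds: 29 degC as the upper habitability
benchmark and 27 degC as a conservative sensitivity cut.  "Exceed" is
strict: a city with MAT exactly at a threshold is not an exceeder.

Each future period maps to a single population year (2011-2040 -> 2025,
2041-2070 -> 2070, 2071-2100 -> 2100); exposed population is taken from the
mapped year only, with no within-period averaging.  Warming is reported as
delta MAT against the 1981-2010 reference span.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("urbanheat")

DEFAULT_LOW = 27.0
DEFAULT_HIGH = 29.0


def band_labels(low: float = DEFAULT_LOW, high: float = DEFAULT_HIGH) -> tuple[str, str, str]:
    """The three band names for a threshold pair, e.g. below_27 / 27_to_29 / above_29."""
    return (f"below_{low:g}", f"{low:g}_to_{high:g}", f"above_{high:g}")


def classify_band(
    mat: float, low: float = DEFAULT_LOW, high: float = DEFAULT_HIGH
) -> str | None:
    """Band of one MAT value: above iff mat > high (strict), middle iff
    low < mat <= high, else below.  Non-finite MAT returns None (logged)."""
    if low >= high:
        raise ValueError("low threshold must be < high threshold")
    if mat is None or not math.isfinite(mat):
        logger.warning("classify_band: non-finite MAT %r", mat)
        return None
    below, mid, above = band_labels(low, high)
    if mat > high:
        return above
    if mat > low:
        return mid
    return below


def delta_mat(mat_future: float, mat_reference: float) -> float:
    """Warming vs the reference span: exact difference (degC)."""
    if not (math.isfinite(mat_future) and math.isfinite(mat_reference)):
        raise ValueError("both MAT values must be finite")
    return mat_future - mat_reference


def validate_popmap(popmap: Mapping[str, int], periods) -> None:
    for p in periods:
        if p not in popmap:
            raise ValueError(f"popmap has no population year for period {p!r}")


def screen(
    mat_records: pd.DataFrame,
    populations: pd.DataFrame,
    popmap: Mapping[str, int],
    low: float = DEFAULT_LOW,
    high: float = DEFAULT_HIGH,
) -> pd.DataFrame:
    """Exposure summary per scenario x period x band x continent.

    Parameters
    ----------
    mat_records:
        long table with columns city_id, continent, scenario, period, mat.
    populations:
        long table with columns city_id, year, population.
    popmap:
        period label -> population year.

    Returns a table with columns scenario, period, band, continent,
    n_cities, population, where population is the sum over cities in the
    band of the mapped-year city population.  Cities with non-finite MAT
    are excluded with a logged warning; a missing population year raises,
    listing the offending cities.
    """
    validate_popmap(popmap, mat_records["period"].unique())
    recs = mat_records.copy()
    bad = ~np.isfinite(recs["mat"].to_numpy(dtype=float))
    if bad.any():
        logger.warning(
            "screen: dropping %d records with non-finite MAT (%s)",
            int(bad.sum()),
            ", ".join(recs.loc[bad, "city_id"].unique()[:5]),
        )
        recs = recs[~bad]
    recs = recs.assign(
        band=[classify_band(m, low, high) for m in recs["mat"]],
        year=[popmap[p] for p in recs["period"]],
    )
    pop = populations.set_index(["city_id", "year"])["population"]
    key = pd.MultiIndex.from_frame(recs[["city_id", "year"]])
    missing = ~key.isin(pop.index)
    if missing.any():
        offenders = recs.loc[missing, ["city_id", "year"]].drop_duplicates()
        raise ValueError(
            "missing population for city/year pairs: "
            + ", ".join(f"{c}@{y}" for c, y in offenders.itertuples(index=False))
        )
    recs = recs.assign(population=pop.loc[key].to_numpy())
    out = (
        recs.groupby(["scenario", "period", "band", "continent"], as_index=False)
        .agg(n_cities=("city_id", "size"), population=("population", "sum"))
        .sort_values(["scenario", "period", "band", "continent"])
        .reset_index(drop=True)
    )
    return out


def exceeders(
    mat_records: pd.DataFrame, threshold: float = DEFAULT_HIGH
) -> pd.DataFrame:
    """Rows of ``mat_records`` with MAT strictly above ``threshold``."""
    return mat_records[mat_records["mat"] > threshold]


def continental_summary(delta_records: pd.DataFrame) -> pd.DataFrame:
    """Median and quartiles of delta MAT per continent x scenario x period.

    ``delta_records`` needs columns continent, scenario, period, delta_mat.
    Quartiles use linear interpolation between order statistics.  Continents
    with zero cities are simply absent (upstream logs the omission).
    """
    if delta_records.empty:
        logger.warning("continental_summary: no records")
        return pd.DataFrame(
            columns=["scenario", "period", "continent", "n_cities", "q1", "median", "q3"]
        )
    out = (
        delta_records.groupby(["scenario", "period", "continent"], as_index=False)
        .agg(
            n_cities=("delta_mat", "size"),
            q1=("delta_mat", lambda v: float(np.percentile(v, 25))),
            median=("delta_mat", "median"),
            q3=("delta_mat", lambda v: float(np.percentile(v, 75))),
        )
        .sort_values(["scenario", "period", "continent"])
        .reset_index(drop=True)
    )
    return out
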