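"""Economic-capacity overlay: per-city GDP (PPP) totals vs terminal-period MAT.

Adaptive capacity is proxied by the total gridded GDP (purchasing power
parity, 2020) summed over each city footprint — fixed at the 2020 grid for
all periods, with no GDP projection.  The summary restricts to cities whose
terminal-period MAT strictly exceeds the niche threshold and reports
per-continent quartiles; continents with no qualifying city are emitted
with n = 0 (they simply have nothing to plot).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_geo import CityBoundary, GeoGrid
from .zonal import zonal_sum

logger = logging.getLogger("urbanheat")


def capacity_table(
    boundaries: Sequence[CityBoundary],
    gdp_grid: GeoGrid,
    mat_by_city: Mapping[str, float],
) -> pd.DataFrame:
    """Join per-city GDP totals with terminal-period MAT.

    Columns: city_id, continent, gdp_ppp_total, mat_2071_2100, above_29.
    A city whose footprint contains no GDP cell gets total 0 with a warning.
    """
    rows = []
    for b in boundaries:
        total = zonal_sum(gdp_grid, b)
        if total is None:
            logger.warning("capacity_table: no GDP cells for %s; total set to 0", b.city_id)
            total = 0.0
        mat = mat_by_city.get(b.city_id, float("nan"))
        rows.append(
            {
                "city_id": b.city_id,
                "continent": b.continent,
                "gdp_ppp_total": total,
                "mat_2071_2100": mat,
                "above_29": bool(mat > 29.0) if np.isfinite(mat) else False,
            }
        )
    return pd.DataFrame(rows)


def capacity_summary(records: pd.DataFrame, threshold: float = 29.0) -> pd.DataFrame:
    """Per-continent GDP quartiles over cities with MAT strictly above threshold.

    Every continent present in ``records`` gets a row; continents with no
    qualifying city have n = 0 and missing quartiles.
    """
    out = []
    for cont in sorted(records["continent"].unique()):
        sub = records[
            (records["continent"] == cont) & (records["mat_2071_2100"] > threshold)
        ]
        if sub.empty:
            out.append(
                {"continent": cont, "n": 0, "q1": np.nan, "median": np.nan, "q3": np.nan}
            )
            continue
        g = sub["gdp_ppp_total"].to_numpy(dtype=float)
        out.append(
            {
                "continent": cont,
                "n": len(g),
                "q1": float(np.percentile(g, 25)),
                "median": float(np.percentile(g, 50)),
                "q3": float(np.percentile(g, 75)),
            }
        )
    return pd.DataFrame(out)
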