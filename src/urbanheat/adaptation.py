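"""Adaptation-measure scoring from LCZ composition.

Each city's responsiveness to an adaptation measure is the dot product of
its LCZ share vector with a binary suitability column::

    Score(measure) = sum_LCZ S_LCZ * w(LCZ, measure)

where S_LCZ is the share of the LCZ in the classified city area and the
weights w come from an expert-curated measure x LCZ matrix covering built
classes 1, 2, 3, 4, 8 and 10.  LCZ classes absent from the matrix (5, 6, 7,
9 and the natural classes A-G) carry weight 0, so scores lie in [0, 1]: a
score of 1 means the whole classified city area lies in zones where the
measure applies.  Scores are not renormalised by built-area fraction.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_geo import LCZ_CODES
from .zonal import LCZProfile

logger = logging.getLogger("urbanheat")

#: LCZ classes the expert matrix assigns weights to, in column order.
MATRIX_LCZ_COLUMNS = (1, 2, 3, 4, 8, 10)

#: The ten measures with their binary suitability over MATRIX_LCZ_COLUMNS.
DEFAULT_MEASURE_WEIGHTS: dict[str, tuple[int, ...]] = {
    "Optimize Urban Openness": (1, 1, 1, 0, 0, 0),
    "Regulate Densification": (1, 1, 1, 0, 0, 0),
    "Restrict Building Height": (1, 0, 0, 1, 0, 0),
    "Raise Pervious Surface Fraction Ratio": (1, 1, 1, 0, 1, 0),
    "Use Reflective Building Materials": (1, 1, 1, 1, 1, 1),
    "Increase Green Space and Vegetation Cover": (1, 1, 1, 1, 1, 1),
    "Increase Water Bodies": (1, 1, 1, 1, 1, 1),
    "Reduce Environmental Pollution": (1, 0, 0, 0, 1, 1),
    "Control Heat Emissions from Factories": (1, 0, 0, 0, 1, 1),
    "Promote Sustainable Urban Forms": (0, 0, 0, 0, 1, 1),
}


@dataclass
class MeasureMatrix:
    """Binary measure x LCZ weight matrix, total over all 17 LCZ codes."""

    measures: tuple[str, ...]
    lcz_columns: tuple[int, ...] = MATRIX_LCZ_COLUMNS
    weights: dict[tuple[str, int], int] = field(default_factory=dict)

    def weight(self, measure: str, lcz: int) -> int:
        """Weight for any LCZ code; codes outside the matrix columns are 0."""
        return self.weights.get((measure, lcz), 0)

    def as_array(self) -> np.ndarray:
        """Dense (n_measures x 17) weight array over all LCZ codes."""
        return np.array(
            [[self.weight(m, c) for c in LCZ_CODES] for m in self.measures],
            dtype=float,
        )


def default_measure_matrix() -> MeasureMatrix:
    weights = {
        (m, c): w
        for m, row in DEFAULT_MEASURE_WEIGHTS.items()
        for c, w in zip(MATRIX_LCZ_COLUMNS, row)
    }
    return MeasureMatrix(measures=tuple(DEFAULT_MEASURE_WEIGHTS), weights=weights)


def load_measure_matrix(path: str | Path | None = None) -> MeasureMatrix:
    """The default expert matrix, or a validated CSV override.

    Override CSV header: ``measure,LCZ1,LCZ2,LCZ3,LCZ4,LCZ8,LCZ10``;
    entries must be 0 or 1.
    """
    if path is None:
        return default_measure_matrix()
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header[0].strip().lower() != "measure":
            raise ValueError("override CSV must start with a 'measure' column")
        cols = []
        for name in header[1:]:
            name = name.strip().upper().replace(" ", "")
            if not name.startswith("LCZ"):
                raise ValueError(f"unknown column {name!r}; expected LCZ<code>")
            code = int(name[3:])
            if code not in LCZ_CODES:
                raise ValueError(f"unknown LCZ column {name!r}")
            cols.append(code)
        measures: list[str] = []
        weights: dict[tuple[str, int], int] = {}
        for r, row in enumerate(reader):
            measure = row[0]
            measures.append(measure)
            for code, cell in zip(cols, row[1:]):
                if cell.strip() not in ("0", "1"):
                    raise ValueError(
                        f"non-binary entry {cell!r} at row {r + 2}, LCZ {code}"
                    )
                weights[(measure, code)] = int(cell)
    return MeasureMatrix(measures=tuple(measures), lcz_columns=tuple(cols), weights=weights)


def score_city(
    profile: LCZProfile, matrix: MeasureMatrix | None = None
) -> dict[str, float]:
    """Per-measure adaptation scores for one city (the share/weight dot product)."""
    if matrix is None:
        matrix = default_measure_matrix()
    shares = np.array([profile.shares.get(c, 0.0) for c in LCZ_CODES])
    scores = matrix.as_array() @ shares
    return dict(zip(matrix.measures, scores.tolist()))


def score_cities(
    profiles: Mapping[str, LCZProfile | None], matrix: MeasureMatrix | None = None
) -> pd.DataFrame:
    """Score a city set; cities with a missing profile are logged and skipped."""
    if matrix is None:
        matrix = default_measure_matrix()
    rows = []
    for city_id, profile in profiles.items():
        if profile is None:
            logger.warning("score_cities: missing LCZ profile for %s", city_id)
            continue
        rows.append({"city_id": city_id, **score_city(profile, matrix)})
    return pd.DataFrame(rows)


def aggregate_scores(
    scores: pd.DataFrame,
    continents: Mapping[str, str] | pd.Series,
    mode: str = "mean",
    measures: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-continent aggregate of city scores.

    ``mode='sum'`` gives the continent's total adaptation potential,
    ``mode='mean'`` the per-city potential.  ``continents`` maps city_id to
    continent.  Continents with no scored city are simply absent.
    """
    if mode not in ("sum", "mean"):
        raise ValueError("mode must be 'sum' or 'mean'")
    if measures is None:
        measures = [c for c in scores.columns if c != "city_id"]
    df = scores.assign(continent=scores["city_id"].map(dict(continents)))
    if df["continent"].isna().any():
        missing = df.loc[df["continent"].isna(), "city_id"].tolist()
        raise ValueError(f"no continent for cities: {missing}")
    agg = df.groupby("continent")[list(measures)].agg(mode)
    return agg.reset_index()
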