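"""Synthetic study region with planted ground truth.

Generates a complete fake "world" — coarse continuous rasters (mean annual
temperature per scenario x period, population per mapping year, GDP),
a fine categorical LCZ raster, city boundary polygons and a truth table —
with the statistical structure the downstream analysis assumes, so the whole
pipeline is testable without any external gridded datasets.

Planted quantities are exact by construction:

* each city's MAT raster is constant at the planted value (plus optional
  cell noise, off by default);
* population and GDP totals are integers allocated evenly over the city's
  coarse cells with the remainder assigned to the first (row-major) cell,
  so zonal sums recover them exactly;
* the LCZ composition is realised over the city's fine cells by
  largest-remainder allocation of a Dirichlet draw, so class shares are
  recovered exactly from cell counts (a multinomial mode exists behind
  ``lcz_multinomial`` for stochastic tests).

Cities are axis-aligned rectangles snapped to coarse cell edges on a slot
lattice, so footprints never overlap, every city contains at least four
coarse cell centers, and no cell center ever falls on a city edge.

All randomness flows from one ``numpy`` generator seeded with
``WorldConfig.seed``; draws happen in a fixed documented order (continents,
baselines, warming increments, city sizes, populations, GDP, LCZ shares,
optional noise), so the same config is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box

from .core_geo import (
    LCZ_CODE_TABLE,
    LCZ_CODES,
    CityBoundary,
    ClassGrid,
    GeoGrid,
)

SCENARIOS = ("SSP1-2.6", "SSP3-7.0", "SSP5-8.5")
PERIODS = ("2011-2040", "2041-2070", "2071-2100")
REFERENCE_PERIOD = "1981-2010"
TERMINAL_PERIOD = "2071-2100"

#: period -> population mapping year
DEFAULT_POPMAP = {"2011-2040": 2025, "2041-2070": 2070, "2071-2100": 2100}


def _default_continent_weights() -> dict[str, float]:
    return {
        "Africa": 0.22,
        "Asia": 0.38,
        "Europe": 0.12,
        "North America": 0.12,
        "South America": 0.10,
        "Oceania": 0.06,
    }


def _default_baseline_mat() -> dict[str, tuple[float, float]]:
    # (mean, sd) degC of the 1981-2010 reference MAT per continent; hot
    # continents sit near the upper end of the habitable niche.
    return {
        "Africa": (25.5, 2.5),
        "Asia": (22.0, 4.5),
        "Europe": (10.5, 3.0),
        "North America": (13.0, 4.5),
        "South America": (22.5, 3.0),
        "Oceania": (18.0, 3.0),
    }


def _default_warming() -> dict[tuple[str, str], tuple[float, float]]:
    # (mean, sd) degC warming vs reference per scenario x period; magnitudes
    # follow low / intermediate / high emission pathways through the century.
    means = {
        "SSP1-2.6": (0.8, 1.2, 1.3),
        "SSP3-7.0": (0.9, 2.1, 3.4),
        "SSP5-8.5": (1.0, 2.5, 4.0),
    }
    return {
        (s, p): (means[s][i], 0.3) for s in SCENARIOS for i, p in enumerate(PERIODS)
    }


def _default_population() -> dict[int, tuple[float, float]]:
    # log-normal (mu, sigma) of city population per mapping year; cities of
    # interest are > 300k, medians grow through the century.
    return {2025: (13.6, 0.7), 2070: (13.9, 0.8), 2100: (14.0, 0.9)}


def _default_gdp() -> dict[str, tuple[float, float]]:
    # gamma (shape, scale) of city total GDP PPP (2020 currency units).
    return {
        "Africa": (1.5, 4.0e9),
        "Asia": (2.0, 2.5e10),
        "Europe": (3.0, 4.0e10),
        "North America": (3.0, 5.0e10),
        "South America": (2.0, 1.5e10),
        "Oceania": (2.5, 3.0e10),
    }


def _dirichlet_conc(shares: dict[int, float], strength: float) -> np.ndarray:
    vec = np.array([shares.get(c, 0.002) for c in LCZ_CODES], dtype=float)
    vec = vec / vec.sum()
    return vec * strength


def _default_hot_conc() -> np.ndarray:
    # Hot regime: more bare natural surface (E=15, F=16), less vegetation
    # (A-D = 11-14); built fabric skewed to compact/open low-rise.
    return _dirichlet_conc(
        {
            1: 0.01, 2: 0.04, 3: 0.10, 4: 0.01, 5: 0.04, 6: 0.12,
            7: 0.06, 8: 0.07, 9: 0.06, 10: 0.02,
            11: 0.02, 12: 0.04, 13: 0.03, 14: 0.10,
            15: 0.08, 16: 0.18, 17: 0.02,
        },
        strength=120.0,
    )


def _default_cool_conc() -> np.ndarray:
    # Cool regime: vegetated classes dominate the non-built area.
    return _dirichlet_conc(
        {
            1: 0.01, 2: 0.05, 3: 0.09, 4: 0.02, 5: 0.06, 6: 0.14,
            7: 0.03, 8: 0.07, 9: 0.08, 10: 0.02,
            11: 0.08, 12: 0.08, 13: 0.05, 14: 0.14,
            15: 0.03, 16: 0.02, 17: 0.03,
        },
        strength=120.0,
    )


@dataclass
class WorldConfig:
    """Parameters of the synthetic world generator."""

    n_cities: int = 120
    n_hot_cities: int = 20
    continent_weights: dict[str, float] = field(default_factory=_default_continent_weights)
    scenarios: tuple[str, ...] = SCENARIOS
    periods: tuple[str, ...] = PERIODS
    reference_period: str = REFERENCE_PERIOD
    popmap: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_POPMAP))
    baseline_mat: dict[str, tuple[float, float]] = field(default_factory=_default_baseline_mat)
    warming: dict[tuple[str, str], tuple[float, float]] = field(default_factory=_default_warming)
    population: dict[int, tuple[float, float]] = field(default_factory=_default_population)
    gdp: dict[str, tuple[float, float]] = field(default_factory=_default_gdp)
    lcz_hot_conc: np.ndarray = field(default_factory=_default_hot_conc)
    lcz_cool_conc: np.ndarray = field(default_factory=_default_cool_conc)
    hot_threshold: float = 29.0
    hot_rule_scenario: str = "SSP5-8.5"
    coarse_cell_size: float = 0.1
    fine_cell_size: float = 0.01
    mat_noise_sd: float = 0.0
    lcz_multinomial: bool = False
    n_slot_cols: int | None = None
    n_slot_rows: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        ratio = self.coarse_cell_size / self.fine_cell_size
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("fine_cell_size must divide coarse_cell_size exactly")
        if np.any(np.asarray(self.lcz_hot_conc) <= 0) or np.any(
            np.asarray(self.lcz_cool_conc) <= 0
        ):
            raise ValueError("Dirichlet concentrations must be > 0")
        for (mu, sd) in self.baseline_mat.values():
            if sd < 0:
                raise ValueError("baseline MAT sd must be >= 0")
        if self.mat_noise_sd < 0:
            raise ValueError("mat_noise_sd must be >= 0")
        if self.hot_rule_scenario not in self.scenarios:
            raise ValueError("hot_rule_scenario must be one of scenarios")

    @property
    def fine_per_coarse(self) -> int:
        return round(self.coarse_cell_size / self.fine_cell_size)


@dataclass
class SyntheticWorld:
    """Bundle of generated layers, boundaries and planted truth."""

    config: WorldConfig
    mat: dict[tuple[str, str], GeoGrid]          # (scenario, period) -> grid
    mat_reference: GeoGrid
    population: dict[int, GeoGrid]               # mapping year -> grid
    gdp: GeoGrid
    lcz: ClassGrid
    boundaries: list[CityBoundary]
    truth: pd.DataFrame


# slot lattice: each city occupies w x h coarse cells inside a
# (_SLOT + 1)-cell pitch, leaving at least a one-cell gap between cities.
_SLOT = 4          # max city side, in coarse cells
_MIN_SIDE = 2      # min city side, guarantees >= 4 coarse centers


def _dyadic(x: np.ndarray, bits: int = 10) -> np.ndarray:
    """Round to a multiple of 2**-bits (exactly representable in float64)."""
    scale = 2.0**bits
    return np.round(np.asarray(x) * scale) / scale


def largest_remainder_counts(shares: np.ndarray, total: int) -> np.ndarray:
    """Integer counts summing to ``total`` closest to ``shares * total``.

    Hamilton / largest-remainder apportionment: floor every quota, then give
    the leftover units to the largest fractional remainders (ties broken by
    lower index, deterministically).
    """
    shares = np.asarray(shares, dtype=float)
    if shares.size == 0 or total < 0:
        raise ValueError("need >= 1 share and total >= 0")
    quota = shares / shares.sum() * total
    counts = np.floor(quota).astype(int)
    short = total - counts.sum()
    if short > 0:
        remainders = quota - counts
        order = np.lexsort((np.arange(len(shares)), -remainders))
        counts[order[:short]] += 1
    return counts


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate rasters, boundaries and the truth table for ``config``.

    Exactly ``config.n_hot_cities`` cities are planted with terminal-period
    MAT above ``hot_threshold`` under ``hot_rule_scenario``; those cities
    draw their LCZ composition from the hot regime, the rest from the cool
    regime.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cities
    if cfg.n_hot_cities > n:
        raise ValueError("n_hot_cities cannot exceed n_cities")

    pitch = _SLOT + 1
    slot_cols = cfg.n_slot_cols or math.ceil(math.sqrt(n))
    slot_rows = cfg.n_slot_rows or math.ceil(n / slot_cols)
    if slot_cols * slot_rows < n:
        raise ValueError(
            f"{slot_cols}x{slot_rows} slots cannot fit {n} cities without "
            "overlap; increase n_slot_cols/n_slot_rows"
        )
    n_cols_c = slot_cols * pitch + 1
    n_rows_c = slot_rows * pitch + 1
    r = cfg.fine_per_coarse
    n_cols_f, n_rows_f = n_cols_c * r, n_rows_c * r
    origin_lon = 0.0
    origin_lat = n_rows_c * cfg.coarse_cell_size  # grid spans lat 0..origin_lat

    # --- per-city draws, in fixed order ---------------------------------
    continents = list(cfg.continent_weights)
    weights = np.array([cfg.continent_weights[c] for c in continents], float)
    weights /= weights.sum()
    city_cont = rng.choice(len(continents), size=n, p=weights)
    base_draw = np.array(
        [rng.normal(*cfg.baseline_mat[continents[c]]) for c in city_cont]
    )
    # planted temperatures are quantized to 2^-10 degC so that cell values,
    # zonal means over identical cells and reference deltas are all exact in
    # float64 (dyadic rationals; no last-ulp drift in downstream recovery)
    inc = {
        (s, p): _dyadic(rng.normal(*cfg.warming[(s, p)], size=n))
        for s in cfg.scenarios
        for p in cfg.periods
    }
    hot_idx = rng.permutation(n)[: cfg.n_hot_cities]
    is_hot = np.zeros(n, dtype=bool)
    is_hot[hot_idx] = True

    # force baselines so that exactly the chosen cities exceed the threshold
    # in the terminal period of the rule scenario (strict >)
    term_inc = inc[(cfg.hot_rule_scenario, cfg.periods[-1])]
    margin_hot = rng.uniform(0.2, 2.5, size=n)
    margin_cool = rng.uniform(0.3, 4.0, size=n)
    baseline = base_draw.copy()
    lim = cfg.hot_threshold - term_inc
    baseline[is_hot] = np.maximum(base_draw[is_hot], lim[is_hot] + margin_hot[is_hot])
    baseline[~is_hot] = np.minimum(
        base_draw[~is_hot], lim[~is_hot] - margin_cool[~is_hot]
    )
    baseline = _dyadic(baseline)

    widths = rng.integers(_MIN_SIDE, _SLOT + 1, size=n)
    heights = rng.integers(_MIN_SIDE, _SLOT + 1, size=n)
    pops = {
        yr: np.rint(rng.lognormal(mu, sigma, size=n)).astype(np.int64)
        for yr, (mu, sigma) in cfg.population.items()
    }
    gdps = np.rint(
        [rng.gamma(*cfg.gdp[continents[c]]) for c in city_cont]
    ).astype(np.int64)
    shares_drawn = np.empty((n, len(LCZ_CODES)))
    for i in range(n):
        conc = cfg.lcz_hot_conc if is_hot[i] else cfg.lcz_cool_conc
        shares_drawn[i] = rng.dirichlet(conc)

    # --- rasters ---------------------------------------------------------
    nodata = -9999.0
    mat_layers = {
        key: np.full((n_rows_c, n_cols_c), nodata) for key in inc
    }
    mat_ref = np.full((n_rows_c, n_cols_c), nodata)
    pop_layers = {yr: np.zeros((n_rows_c, n_cols_c)) for yr in pops}
    gdp_layer = np.zeros((n_rows_c, n_cols_c))
    lcz_layer = np.zeros((n_rows_f, n_cols_f), dtype=np.int64)

    boundaries: list[CityBoundary] = []
    rows: list[dict] = []
    city_names = _city_names(n)
    for i in range(n):
        sr, sc = divmod(i, slot_cols)
        row0 = sr * pitch + 1
        col0 = sc * pitch + 1
        h, w = int(heights[i]), int(widths[i])
        ncell = h * w
        sl = (slice(row0, row0 + h), slice(col0, col0 + w))

        mat_ref[sl] = baseline[i]
        for key, arr in inc.items():
            mat_layers[key][sl] = baseline[i] + arr[i]
        if cfg.mat_noise_sd > 0:
            for key in inc:
                mat_layers[key][sl] += rng.normal(0, cfg.mat_noise_sd, (h, w))
            mat_ref[sl] += rng.normal(0, cfg.mat_noise_sd, (h, w))

        for yr in pops:
            _allocate_total(pop_layers[yr], sl, int(pops[yr][i]))
        _allocate_total(gdp_layer, sl, int(gdps[i]))

        n_fine = ncell * r * r
        if cfg.lcz_multinomial:
            counts = rng.multinomial(n_fine, shares_drawn[i])
        else:
            counts = largest_remainder_counts(shares_drawn[i], n_fine)
        codes = np.repeat(np.array(LCZ_CODES), counts)
        lcz_layer[row0 * r:(row0 + h) * r, col0 * r:(col0 + w) * r] = codes.reshape(
            h * r, w * r
        )
        realized = counts / n_fine

        # polygon: rectangle exactly covering the city's coarse cells
        west = origin_lon + col0 * cfg.coarse_cell_size
        east = origin_lon + (col0 + w) * cfg.coarse_cell_size
        north = origin_lat - row0 * cfg.coarse_cell_size
        south = origin_lat - (row0 + h) * cfg.coarse_cell_size
        cid = f"city_{i:04d}"
        boundaries.append(
            CityBoundary(cid, city_names[i], continents[city_cont[i]], box(west, south, east, north))
        )

        rec: dict = {
            "city_id": cid,
            "name": city_names[i],
            "continent": continents[city_cont[i]],
            "baseline_mat": baseline[i],
            "gdp_total": int(gdps[i]),
            "n_coarse_cells": ncell,
            "n_fine_cells": n_fine,
        }
        for (s, p), arr in inc.items():
            rec[f"mat_{s}_{p}"] = baseline[i] + arr[i]
        for yr in pops:
            rec[f"population_{yr}"] = int(pops[yr][i])
        for j, code in enumerate(LCZ_CODES):
            rec[f"lcz_share_{code}"] = realized[j]
        for s in cfg.scenarios:
            rec[f"exceeds_29_{s}"] = bool(
                baseline[i] + inc[(s, cfg.periods[-1])][i] > cfg.hot_threshold
            )
        rows.append(rec)

    def _grid(arr: np.ndarray, fine: bool = False) -> GeoGrid:
        size = cfg.fine_cell_size if fine else cfg.coarse_cell_size
        return GeoGrid(origin_lon, origin_lat, size, size, arr, nodata=nodata)

    world = SyntheticWorld(
        config=cfg,
        mat={key: _grid(mat_layers[key]) for key in mat_layers},
        mat_reference=_grid(mat_ref),
        population={yr: _grid(pop_layers[yr]) for yr in pop_layers},
        gdp=_grid(gdp_layer),
        lcz=ClassGrid(
            origin_lon, origin_lat, cfg.fine_cell_size, cfg.fine_cell_size,
            lcz_layer, nodata_code=0, code_table=dict(LCZ_CODE_TABLE),
        ),
        boundaries=boundaries,
        truth=pd.DataFrame(rows),
    )
    return world


def _allocate_total(layer: np.ndarray, sl: tuple[slice, slice], total: int) -> None:
    """Spread an integer total evenly over a block, remainder to first cell."""
    block = layer[sl]
    ncell = block.size
    per = total // ncell
    block[...] = per
    block.flat[0] += total - per * ncell


def _city_names(n: int) -> list[str]:
    return [f"Synthville-{i:04d}" for i in range(n)]


def perturb_group_shares(
    config: WorldConfig, delta: float, target_class: int
) -> WorldConfig:
    """Shift the hot regime's expected share of ``target_class`` by +delta.

    The compensating mass is removed from the remaining classes
    proportionally; total Dirichlet concentration (and hence draw
    variability) is preserved.  ``delta`` = 0 returns the config unchanged.
    """
    if target_class not in LCZ_CODES:
        raise ValueError(f"unknown LCZ code {target_class}")
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if delta == 0:
        return config
    conc = np.asarray(config.lcz_hot_conc, dtype=float)
    strength = conc.sum()
    p = conc / strength
    t = LCZ_CODES.index(target_class)
    if p[t] + delta > 1:
        raise ValueError(
            f"delta {delta} infeasible: expected share would exceed 1"
        )
    p_new = p * (1 - p[t] - delta) / (1 - p[t])
    p_new[t] = p[t] + delta
    return dataclasses.replace(config, lcz_hot_conc=p_new * strength)
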