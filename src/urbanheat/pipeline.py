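"""End-to-end orchestration: simulate, run, report.

The pipeline operates on an on-disk data directory using a fixed layout so
synthetic and real-data modes are format-identical:

* ``boundaries.geojson`` — city polygons with city_id/name/continent,
* ``mat_<scenario>_<period>.tif`` — coarse MAT GeoTIFF per scenario x period,
* ``mat_reference.tif`` — reference-span (1981-2010) MAT,
* ``population_<year>.tif`` — population count grid per mapping year,
* ``gdp.tif`` — gridded GDP PPP (2020),
* ``lcz.tif`` — fine categorical LCZ grid,
* ``truth.csv`` — planted truth (synthetic mode only).

``run`` executes the stages in dependency order (zonal aggregation ->
niche screening -> morphology comparison -> adaptation scoring -> capacity
overlay), writes every result table as CSV and a manifest recording the
config hash, seed, package versions, per-file content hashes and the list
of cities excluded by per-city failures (never silently dropped).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adaptation import aggregate_scores, load_measure_matrix, score_cities
from .capacity import capacity_summary, capacity_table
from .core_geo import (
    read_boundaries,
    read_raster,
    write_boundaries,
    write_raster,
)
from .morphology import compare_all, median_position_diagnostic
from .niche import continental_summary, delta_mat, screen
from .synthetic_world import (
    DEFAULT_POPMAP,
    PERIODS,
    REFERENCE_PERIOD,
    SCENARIOS,
    WorldConfig,
    generate_world,
)
from .zonal import DEFAULT_GROUPING, class_shares, group_shares, zonal_mean, zonal_sum

logger = logging.getLogger("urbanheat")


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration (flat key tree).

    Precedence when loading: CLI overrides > config file > these defaults.
    """

    data_dir: str = "data"
    out_dir: str = "results"
    scenarios: tuple[str, ...] = SCENARIOS
    periods: tuple[str, ...] = PERIODS
    reference_period: str = REFERENCE_PERIOD
    popmap: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_POPMAP))
    threshold_low: float = 27.0
    threshold_high: float = 29.0
    alpha: float = 0.05
    correction: str | None = None          # None or 'bh'
    median_population: str = "all"         # 'all' or 'nonexceeders'
    aggregation: str = "mean"              # 'sum' or 'mean'
    report_scenario: str = "SSP5-8.5"      # scenario used for Fig-6-style tables
    grouping: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: {k: tuple(sorted(v)) for k, v in DEFAULT_GROUPING.items()}
    )
    measure_matrix_csv: str | None = None
    seed: int = 0
    # synthetic-world knobs (simulate only)
    n_cities: int = 120
    n_hot_cities: int = 20
    mat_noise_sd: float = 0.0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.report_scenario not in cfg.scenarios:
            raise ValueError("report_scenario must be one of scenarios")
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grouping"] = {k: list(v) for k, v in d["grouping"].items()}
        d["scenarios"] = list(d["scenarios"])
        d["periods"] = list(d["periods"])
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _mat_path(data_dir: Path, scenario: str, period: str) -> Path:
    return data_dir / f"mat_{scenario}_{period}.tif"


def cmd_simulate(config: PipelineConfig) -> Path:
    """Generate a synthetic world and write it to ``config.data_dir``."""
    data_dir = Path(config.data_dir)
    data_dir.mkdir(parents=True, exist_ok=True)
    wc = WorldConfig(
        n_cities=config.n_cities,
        n_hot_cities=config.n_hot_cities,
        scenarios=tuple(config.scenarios),
        periods=tuple(config.periods),
        popmap=dict(config.popmap),
        mat_noise_sd=config.mat_noise_sd,
        seed=config.seed,
    )
    world = generate_world(wc)
    for (s, p), grid in world.mat.items():
        write_raster(_mat_path(data_dir, s, p), grid)
    write_raster(data_dir / "mat_reference.tif", world.mat_reference)
    for yr, grid in world.population.items():
        write_raster(data_dir / f"population_{yr}.tif", grid)
    write_raster(data_dir / "gdp.tif", world.gdp)
    write_raster(data_dir / "lcz.tif", world.lcz)
    write_boundaries(data_dir / "boundaries.geojson", world.boundaries)
    world.truth.to_csv(data_dir / "truth.csv", index=False)
    logger.info("simulate: wrote %d cities to %s", len(world.boundaries), data_dir)
    return data_dir


def cmd_run(config: PipelineConfig) -> Path:
    """Run the full analysis on ``config.data_dir``; write CSVs + manifest."""
    data_dir = Path(config.data_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    excluded: list[dict] = []

    bpath = data_dir / "boundaries.geojson"
    if not bpath.exists():
        raise FileNotFoundError(f"run: missing boundaries layer: {bpath}")
    boundaries = read_boundaries(bpath)
    continent_of = {b.city_id: b.continent for b in boundaries}
    name_of = {b.city_id: b.name for b in boundaries}

    # --- stage: zonal MAT -------------------------------------------------
    for s in config.scenarios:
        for p in config.periods:
            if not _mat_path(data_dir, s, p).exists():
                raise FileNotFoundError(
                    f"run: missing MAT layer for {s} {p}: {_mat_path(data_dir, s, p)}"
                )
    ref_grid = read_raster(data_dir / "mat_reference.tif", categorical=False)
    ref_mat = {b.city_id: zonal_mean(ref_grid, b) for b in boundaries}
    mat_rows = []
    for s in config.scenarios:
        for p in config.periods:
            grid = read_raster(_mat_path(data_dir, s, p), categorical=False)
            for b in boundaries:
                m = zonal_mean(grid, b)
                if m is None or ref_mat[b.city_id] is None:
                    excluded.append(
                        {"stage": "zonal_mat", "city_id": b.city_id,
                         "scenario": s, "period": p, "reason": "no valid MAT cells"}
                    )
                    continue
                mat_rows.append(
                    {
                        "city_id": b.city_id,
                        "name": name_of[b.city_id],
                        "continent": b.continent,
                        "scenario": s,
                        "period": p,
                        "mat": m,
                        "delta_mat": delta_mat(m, ref_mat[b.city_id]),
                    }
                )
    mat_records = pd.DataFrame(mat_rows)
    mat_records.to_csv(out_dir / "city_mat.csv", index=False)

    # --- stage: populations ----------------------------------------------
    pop_rows = []
    for yr in sorted(set(config.popmap.values())):
        ppath = data_dir / f"population_{yr}.tif"
        if not ppath.exists():
            raise FileNotFoundError(f"run: missing population layer: {ppath}")
        pgrid = read_raster(ppath, categorical=False)
        for b in boundaries:
            total = zonal_sum(pgrid, b)
            if total is None:
                excluded.append(
                    {"stage": "population", "city_id": b.city_id,
                     "scenario": "", "period": str(yr), "reason": "no cells"}
                )
                continue
            pop_rows.append({"city_id": b.city_id, "year": yr, "population": total})
    populations = pd.DataFrame(pop_rows)

    # --- stage: niche screening ------------------------------------------
    exposure = screen(
        mat_records, populations, config.popmap,
        low=config.threshold_low, high=config.threshold_high,
    )
    exposure.to_csv(out_dir / "exposure.csv", index=False)
    delta_summary = continental_summary(mat_records)
    delta_summary.to_csv(out_dir / "delta_mat_summary.csv", index=False)

    # --- stage: LCZ profiles ---------------------------------------------
    lcz_path = data_dir / "lcz.tif"
    if not lcz_path.exists():
        raise FileNotFoundError(f"run: missing LCZ layer: {lcz_path}")
    lcz_grid = read_raster(lcz_path, categorical=True)
    grouping = {k: frozenset(v) for k, v in config.grouping.items()}
    profiles = {}
    for b in boundaries:
        prof = class_shares(lcz_grid, b)
        if prof is None:
            excluded.append(
                {"stage": "lcz", "city_id": b.city_id,
                 "scenario": "", "period": "", "reason": "no classified cells"}
            )
            profiles[b.city_id] = None
            continue
        group_shares(prof, grouping)
        profiles[b.city_id] = prof
    prof_rows = []
    for cid, prof in profiles.items():
        if prof is None:
            continue
        row = {"city_id": cid, "name": name_of[cid], "continent": continent_of[cid],
               "n_cells": prof.n_cells}
        row.update({f"lcz_{c}": v for c, v in prof.shares.items()})
        row.update(prof.grouped_shares)
        prof_rows.append(row)
    lcz_profiles = pd.DataFrame(prof_rows)
    lcz_profiles.to_csv(out_dir / "lcz_profiles.csv", index=False)

    # --- stage: morphology comparison ------------------------------------
    terminal = config.periods[-1]
    comp_frames = []
    diag_rows = []
    for s in config.scenarios:
        term = mat_records[
            (mat_records["scenario"] == s) & (mat_records["period"] == terminal)
        ][["city_id", "continent", "mat"]]
        table = term.merge(lcz_profiles.drop(columns=["name", "continent"]), on="city_id")
        comp = compare_all(
            table, grouping, threshold=config.threshold_high,
            alpha=config.alpha, correction=config.correction,
        )
        comp.insert(0, "scenario", s)
        comp_frames.append(comp)
        if (table["mat"] > config.threshold_high).any():
            for label, direction in (
                ("bare_natural", "above"), ("green", "below"), ("low_plants", "below"),
            ):
                if label in grouping:
                    frac = median_position_diagnostic(
                        table, label, direction,
                        threshold=config.threshold_high,
                        median_population=config.median_population,
                    )
                    diag_rows.append(
                        {"scenario": s, "lcz_group": label,
                         "direction": direction, "fraction": frac}
                    )
    comparison = pd.concat(comp_frames, ignore_index=True)
    comparison.to_csv(out_dir / "lcz_comparison.csv", index=False)
    pd.DataFrame(diag_rows).to_csv(out_dir / "median_diagnostics.csv", index=False)

    # --- stage: adaptation scores ----------------------------------------
    matrix = load_measure_matrix(config.measure_matrix_csv)
    scores = score_cities(profiles, matrix)
    scores.insert(1, "name", scores["city_id"].map(name_of))
    scores.insert(2, "continent", scores["city_id"].map(continent_of))
    scores.to_csv(out_dir / "adaptation_scores.csv", index=False)
    term_rs = mat_records[
        (mat_records["scenario"] == config.report_scenario)
        & (mat_records["period"] == terminal)
    ].set_index("city_id")["mat"]
    hot_ids = set(term_rs[term_rs > config.threshold_high].index)
    hot_scores = scores[scores["city_id"].isin(hot_ids)]
    if hot_scores.empty:
        logger.warning("run: no exceeding city to aggregate scores over")
        agg = pd.DataFrame()
    else:
        agg = aggregate_scores(
            hot_scores.drop(columns=["name", "continent"]),
            continent_of, mode=config.aggregation, measures=list(matrix.measures),
        )
    agg.to_csv(out_dir / "adaptation_scores_by_continent.csv", index=False)

    # --- stage: capacity overlay -----------------------------------------
    gdp_path = data_dir / "gdp.tif"
    if not gdp_path.exists():
        raise FileNotFoundError(f"run: missing GDP layer: {gdp_path}")
    gdp_grid = read_raster(gdp_path, categorical=False)
    cap = capacity_table(boundaries, gdp_grid, dict(term_rs))
    cap.to_csv(out_dir / "capacity.csv", index=False)
    capacity_summary(cap, threshold=config.threshold_high).to_csv(
        out_dir / "capacity_summary.csv", index=False
    )

    # --- manifest ---------------------------------------------------------
    outputs = sorted(p for p in out_dir.glob("*.csv"))
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {
            "urbanheat": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "excluded": excluded,
        "files": {p.name: _sha256(p) for p in outputs},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("run: wrote %d tables to %s (%d exclusions)",
                len(outputs), out_dir, len(excluded))
    return out_dir


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def cmd_report(out_dir: str | Path) -> str:
    """Render a markdown summary from a completed result bundle."""
    out_dir = Path(out_dir)
    lines = ["# Urban heat screening report", ""]

    def _load(name: str) -> pd.DataFrame | None:
        p = out_dir / name
        if not p.exists():
            lines.append(f"*Missing table: {name}*")
            lines.append("")
            return None
        try:
            return pd.read_csv(p)
        except pd.errors.EmptyDataError:
            return pd.DataFrame()

    exposure = _load("exposure.csv")
    if exposure is not None:
        lines.append("## Cities beyond the climate niche")
        for s in sorted(exposure["scenario"].unique()):
            lines.append(f"### {s}")
            sub = exposure[exposure["scenario"] == s]
            above = sub[sub["band"].str.startswith("above")]
            if above.empty:
                lines.append("No city exceeds the upper threshold in any period.")
            for p in sorted(sub["period"].unique()):
                pv = above[above["period"] == p]
                n = int(pv["n_cities"].sum())
                pop = float(pv["population"].sum())
                lines.append(
                    f"- {p}: {n} exceeding cities, {pop / 1e6:.1f} M residents exposed"
                )
            lines.append("")

    delta = _load("delta_mat_summary.csv")
    if delta is not None and not delta.empty:
        lines.append("## Median warming vs reference (terminal period)")
        term = delta[delta["period"] == delta["period"].max()]
        for _, r in term.sort_values(["scenario", "median"], ascending=[True, False]).iterrows():
            lines.append(
                f"- {r['scenario']} {r['continent']}: median +{r['median']:.1f} degC "
                f"(IQR {r['q1']:.1f}-{r['q3']:.1f})"
            )
        lines.append("")

    comp = _load("lcz_comparison.csv")
    if comp is not None and not comp.empty:
        lines.append("## Significant LCZ contrasts (exceeders vs others)")
        sig = comp[comp["significant"] == True]  # noqa: E712
        if sig.empty:
            lines.append("No significant contrast at the configured alpha.")
        for _, r in sig.iterrows():
            lines.append(
                f"- {r['scenario']} / {r['continent']} / {r['lcz_group']}: "
                f"mean share {r['mean_below']:.3f} (cooler) vs {r['mean_above']:.3f} "
                f"(exceeders), p = {r['p_value']:.2g} *"
            )
        lines.append("")

    agg = _load("adaptation_scores_by_continent.csv")
    if agg is not None and not agg.empty:
        lines.append("## Top adaptation measures per continent (exceeding cities)")
        measures = [c for c in agg.columns if c != "continent"]
        for _, r in agg.iterrows():
            ranked = sorted(measures, key=lambda m: -r[m])[:3]
            top = ", ".join(f"{m} ({r[m]:.2f})" for m in ranked)
            lines.append(f"- {r['continent']}: {top}")
        lines.append("")

    cap = _load("capacity_summary.csv")
    if cap is not None and not cap.empty:
        lines.append("## GDP (PPP) of exceeding cities per continent")
        for _, r in cap.iterrows():
            if r["n"] == 0:
                lines.append(f"- {r['continent']}: no exceeding city")
            else:
                lines.append(
                    f"- {r['continent']}: n = {int(r['n'])}, median GDP "
                    f"{r['median']:.3g} (IQR {r['q1']:.3g}-{r['q3']:.3g})"
                )
        lines.append("")

    report = "\n".join(lines)
    (out_dir / "report.md").write_text(report)
    return report
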