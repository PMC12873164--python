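"""End-to-end driver: weather → GDD → trends → scenarios → sensitivity →
evaluation, reproducible from a single config + master seed.

``run_pipeline`` writes a bundle of CSV/JSON artifacts to an output
directory together with a run manifest (canonical config, seed, package
version, SHA-256 of every output file).  Identical config + seed yields a
byte-identical bundle.

The demo phenology stage derives per-season days-to-anthesis/maturity by
inverting cumulative thermal time (days until fixed GDD targets are reached)
and simulates grain yield with the sensitivity module's surrogate driven by
each season's temperature anomaly — a self-contained, clearly synthetic
stand-in for observed phenology/yield records.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import PairedSeries, evaluate
from .gdd import default_schedule, season_gdd, days_to_reach, NonAttainment
from .scenarios import (
    SITE_DTA,
    scenario_table,
    stage_rainfall,
    standard_scenarios,
)
from .sensitivity import run_grid, surrogate_preset
from .synthetic import generate_series, preset
from .trends import decadal_summary, describe, fit_polynomial, pearson_matrix
from .weather import (
    WHEAT_SEASON,
    season_bounds,
    seasonal_table,
    write_weather_table,
    write_wth,
)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("wheatclim")

#: Site-typical long-term mean days to maturity.
SITE_DTM = {"islamabad": 135, "chakwal": 127}


@dataclass
class RunConfig:
    """Validated configuration of an end-to-end run."""

    site: str = "islamabad"
    seed: int | None = None
    start_year: int = 1980
    end_year: int = 2021
    climate: dict = field(default_factory=dict)  # ClimateGenConfig overrides
    dta_days: int | None = None
    dtm_days: int | None = None
    flowering_duration: int = 10
    anthesis_gdd_target: float = 1365.0
    maturity_gdd_target: float = 1585.0
    heat_zero_threshold: float = 35.0
    decades: list = field(
        default_factory=lambda: [(1981, 1990), (1991, 2000), (2001, 2010), (2011, 2021)]
    )
    rainfall_aggregate: str = "mean"
    trend_degree: int = 2
    sensitivity_replicates: int = 200
    log_level: str = "INFO"

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a master seed is mandatory for synthetic runs")
        if self.site not in SITE_DTA:
            raise ValueError(f"unknown site {self.site!r}; known: {sorted(SITE_DTA)}")
        if self.dta_days is None:
            self.dta_days = SITE_DTA[self.site]
        if self.dtm_days is None:
            self.dtm_days = SITE_DTM[self.site]
        if not self.dta_days < self.dtm_days:
            raise ValueError("need dta_days < dtm_days")
        if self.end_year <= self.start_year:
            raise ValueError("end_year must exceed start_year")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "decades" in d:
            d["decades"] = [tuple(pair) for pair in d["decades"]]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["decades"] = [list(pair) for pair in d["decades"]]
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _write_csv(df: pd.DataFrame, path: Path, index=False) -> None:
    df.to_csv(path, index=index, float_format="%.6g")


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage and write the report bundle to *outdir*.

    Returns a dict with the output paths and the in-memory stage results.
    Any stage failure is re-raised annotated with the stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    results: dict = {"paths": {}}
    stage = "setup"

    def _tick(name):
        nonlocal stage
        stage = name
        log.info("stage %s ...", name)
        return time.perf_counter()

    try:
        # ------------------------------------------------------------ weather
        t0 = _tick("weather")
        clim = preset(
            config.site,
            seed=config.seed,
            start_year=config.start_year,
            end_year=config.end_year,
            **config.climate,
        )
        series = generate_series(clim)
        write_weather_table(series, outdir / "weather.csv")
        write_wth(series, outdir / "weather.wth")
        seasons = seasonal_table(series)
        results["series"] = series
        results["seasonal"] = seasons
        log.info("stage weather done (%.2fs, %d seasons)",
                 time.perf_counter() - t0, len(seasons))

        # ---------------------------------------------------------------- gdd
        t0 = _tick("gdd")
        schedule = default_schedule(
            config.dta_days, config.flowering_duration, config.heat_zero_threshold
        )
        gdd_rows = []
        phen_rows = []
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
        long_term_tmean = float(seasons["tmean"].mean())
        surrogate = surrogate_preset(config.site, noise_sd=0.15)
        for year in seasons.index:
            sowing, end = season_bounds(WHEAT_SEASON, int(year))
            res = season_gdd(series, sowing, schedule, end)
            gdd_rows.append(
                {
                    "harvest_year": int(year),
                    "total_gdd": res.total_gdd,
                    "n_ceiling_days": res.n_ceiling_days,
                    "n_days_above_35": res.n_days_above_35,
                }
            )
            dta = days_to_reach(series, sowing, config.anthesis_gdd_target,
                                schedule, end)
            dtm = days_to_reach(series, sowing, config.maturity_gdd_target,
                                schedule, end)
            if isinstance(dta, NonAttainment) or isinstance(dtm, NonAttainment):
                continue
            anomaly = seasons.loc[year, "tmean"] - long_term_tmean
            gy = float(
                surrogate.simulate(anomaly, surrogate.co2_reference, 1, rng)[0]
            )
            phen_rows.append(
                {"harvest_year": int(year), "dta": dta, "dtm": dtm,
                 "grain_yield": gy}
            )
        gdd_table = pd.DataFrame(gdd_rows)
        phen = pd.DataFrame(phen_rows)
        _write_csv(gdd_table, outdir / "gdd_summary.csv")
        _write_csv(phen, outdir / "phenology.csv")
        results["gdd"] = gdd_table
        results["phenology"] = phen
        log.info("stage gdd done (%.2fs)", time.perf_counter() - t0)

        # ------------------------------------------------------------- trends
        t0 = _tick("trends")
        table = seasons.join(gdd_table.set_index("harvest_year")["total_gdd"])
        table = table.join(phen.set_index("harvest_year"))
        desc = {
            name: describe(table[name].dropna()).to_dict()
            for name in ("tmean", "tmax", "tmin", "rain", "total_gdd",
                         "dta", "dtm", "grain_yield")
            if table[name].notna().sum() >= 2
        }
        desc_df = pd.DataFrame(desc).T
        desc_df.index.name = "variable"
        _write_csv(desc_df, outdir / "descriptive_stats.csv", index=True)

        fits = {}
        years = table.index.to_numpy(dtype=float)
        for name in ("tmean", "dta", "dtm", "grain_yield"):
            col = table[name]
            ok = col.notna()
            if ok.sum() > config.trend_degree + 1:
                fits[name] = fit_polynomial(
                    years[ok.to_numpy()], col[ok].to_numpy(), config.trend_degree
                ).to_dict()
        _write_json(outdir / "trend_fits.json", fits)

        dec = decadal_summary(table.index, table["tmean"], config.decades)
        _write_csv(dec, outdir / "decadal_tmean.csv")
        corr = pearson_matrix(table.dropna())
        _write_csv(corr.round(6), outdir / "correlation.csv", index=True)
        results["descriptive"] = desc_df
        results["trend_fits"] = fits
        results["correlation"] = corr
        log.info("stage trends done (%.2fs)", time.perf_counter() - t0)

        # ---------------------------------------------------------- scenarios
        t0 = _tick("scenarios")
        scens = standard_scenarios(config.dta_days, config.flowering_duration)
        rows = scenario_table(series, scens)
        scen_df = pd.DataFrame([r.to_dict() for r in rows])
        _write_csv(scen_df, outdir / "scenario_table.csv")
        rain_df = stage_rainfall(
            series, config.dta_days, config.decades,
            aggregate=config.rainfall_aggregate,
        )
        _write_csv(rain_df, outdir / "stage_rainfall.csv")
        results["scenarios"] = rows
        results["stage_rainfall"] = rain_df
        log.info("stage scenarios done (%.2fs)", time.perf_counter() - t0)

        # -------------------------------------------------------- sensitivity
        t0 = _tick("sensitivity")
        model = surrogate_preset(config.site, noise_sd=0.2, seed=config.seed)
        grid = run_grid(model, replicates=config.sensitivity_replicates)
        _write_csv(grid.boxplot_summary(), outdir / "sensitivity_cells.csv")
        _write_json(outdir / "sensitivity_summary.json", grid.summary())
        results["sensitivity"] = grid
        log.info("stage sensitivity done (%.2fs)", time.perf_counter() - t0)

        # --------------------------------------------------------- evaluation
        t0 = _tick("evaluation")
        eval_out = {}
        for name in ("dta", "dtm", "grain_yield"):
            col = phen.set_index("harvest_year")[name].dropna()
            if len(col) <= config.trend_degree + 1:
                continue
            fit = fit_polynomial(
                col.index.to_numpy(dtype=float), col.to_numpy(), config.trend_degree
            )
            pairs = PairedSeries(
                col.to_numpy(), fit.predict(col.index.to_numpy(dtype=float)),
                label=name,
            )
            eval_out[name] = evaluate(pairs).to_dict()
        _write_json(outdir / "evaluation.json", eval_out)
        results["evaluation"] = eval_out
        log.info("stage evaluation done (%.2fs)", time.perf_counter() - t0)

        # ----------------------------------------------------------- manifest
        _tick("manifest")
        files = sorted(
            p.name for p in outdir.iterdir()
            if p.is_file() and p.name != "manifest.json"
        )
        manifest = {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "wheatclim_version": __version__,
            "outputs": {
                name: hashlib.sha256((outdir / name).read_bytes()).hexdigest()
                for name in files
            },
        }
        _write_json(outdir / "manifest.json", manifest)
        results["paths"] = {p.name: outdir / p.name for p in outdir.iterdir()}
        results["manifest"] = manifest
        return results
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
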