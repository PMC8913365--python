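"""End-to-end orchestration of the analysis stages from a single config.

``run_pipeline`` executes simulate (optional) -> PWS estimation ->
burned-area/VPD sensitivity -> trait attribution -> VPD trends and double
hazard -> WUI exposure, writing per-stage outputs under ``out_dir`` and a
machine-readable ``report.json`` with every fitted coefficient, the config
hash and all seeds. Stages resume from on-disk intermediates when
``resume`` is set.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import io as pio
from .drivers import fit_trait_importance
from .pws import LagConfig, estimate_pws_map
from .sensitivity import (
    bin_annual_series,
    classify_hazard,
    equal_area_bins,
    ols_slope,
    sensitivity_curve,
)
from .preprocess import AnnualFireSeries
from .synthetic import (
    simulate_annual_vpd,
    simulate_fire,
    simulate_traits,
    simulate_wui,
    standard_fixture,
)
from .trends import double_hazard, vpd_trend_map, wui_exposure

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Pipeline configuration; numeric defaults follow the study design."""

    out_dir: str = "pwsfire_run"
    seed: int = 42
    simulate: bool = True
    lfmc_path: str | None = None
    dfmc_path: str | None = None
    max_lag_days: int = 150
    step_days: int = 15
    years: tuple[int, ...] = (2016, 2017, 2018, 2019, 2020)
    min_valid_fraction: float = 0.5
    n_bins: int = 15
    hazard_thresholds: tuple[float, float] = (1.0, 1.5)
    fire_years: tuple[int, int] = (2001, 2020)
    trend_years: tuple[int, int] = (1980, 2020)
    vpd_trend: float = 0.05
    n_trees: int = 50
    n_folds: int = 3
    resume: bool = True
    stages: tuple[str, ...] = ("simulate", "pws", "sensitivity", "drivers", "trends", "exposure")

    def lag_config(self) -> LagConfig:
        return LagConfig(
            max_lag_days=self.max_lag_days,
            step_days=self.step_days,
            years=tuple(self.years),
            min_valid_fraction=self.min_valid_fraction,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for k in ("years", "hazard_thresholds", "fire_years", "trend_years", "stages"):
            if k in raw and raw[k] is not None:
                raw[k] = tuple(raw[k])
        return cls(**raw)

    def digest(self) -> str:
        payload = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured stages; returns the report dict (also on disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not cfg.simulate:
        for p in (cfg.lfmc_path, cfg.dfmc_path):
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"input stack not found: {p}")
    report: dict = {"config_hash": cfg.digest(), "seed": cfg.seed, "stages": {}}
    lag_cfg = cfg.lag_config()

    fixture = None
    lfmc_file = out / "lfmc.nc"
    dfmc_file = out / "dfmc.nc"
    if "simulate" in cfg.stages and cfg.simulate:
        if not (cfg.resume and lfmc_file.exists() and dfmc_file.exists()):
            fixture = standard_fixture(seed=cfg.seed)
            pio.write_epoch_series(fixture.lfmc, lfmc_file, "lfmc")
            pio.write_epoch_series(fixture.climate.dfmc, dfmc_file, "dfmc")
            pio.write_map(fixture.truth.pws, fixture.grid, out / "pws_true.tif")
            report["stages"]["simulate"] = {"noise_sd": fixture.noise_sd}
        else:
            report["stages"]["simulate"] = {"resumed": True}
    if fixture is None and "simulate" in cfg.stages and cfg.simulate:
        fixture = standard_fixture(seed=cfg.seed)  # truth needed downstream

    # --- PWS stage ---
    pws_file = out / "pws.tif"
    if "pws" in cfg.stages:
        if cfg.resume and pws_file.exists():
            pws_arr, grid = pio.read_map(pws_file)
            r2_arr, _ = pio.read_map(out / "pws_r2.tif")
            from .pws import PWSMap

            pws_map = PWSMap(pws_arr, r2_arr, grid)
            report["stages"]["pws"] = {"resumed": True}
        else:
            lfmc = pio.read_epoch_series(
                lfmc_file if cfg.simulate else cfg.lfmc_path, "lfmc" if cfg.simulate else "value"
            )
            dfmc = pio.read_epoch_series(
                dfmc_file if cfg.simulate else cfg.dfmc_path, "dfmc" if cfg.simulate else "value"
            )
            pws_map = estimate_pws_map(lfmc, dfmc, lag_cfg)
            grid = pws_map.grid
            pio.write_map(pws_map.pws, grid, pws_file)
            pio.write_map(pws_map.r2, grid, out / "pws_r2.tif")
            report["stages"]["pws"] = {
                "n_valid": int(pws_map.valid.sum()),
                "median_r2": float(np.nanmedian(pws_map.r2)),
            }
    else:
        raise ValueError("the pws stage is required by all downstream stages")

    veg = np.isfinite(pws_map.pws)

    if "sensitivity" in cfg.stages:
        if fixture is None:
            raise ValueError("sensitivity stage needs the simulate stage (synthetic truth)")
        fy = list(range(cfg.fire_years[0], cfg.fire_years[1] + 1))
        years_arr, vpd_annual = simulate_annual_vpd(pws_map.grid, fy, cfg.seed + 10)
        ba = simulate_fire(fixture.truth, years_arr, vpd_annual, cfg.seed + 11,
                           noise_sd=5.0, n_bins=cfg.n_bins)
        fire = AnnualFireSeries(years_arr, ba, vpd_annual, pws_map.grid)
        bins = equal_area_bins(pws_map, veg, pws_map.grid.pixel_area, cfg.n_bins)
        yrs, ba_bins, vpd_bins = bin_annual_series(fire, bins, pws_map.grid.pixel_area)
        slopes = [ols_slope(ba_bins[:, b], vpd_bins[:, b]) for b in range(cfg.n_bins)]
        curve = sensitivity_curve(bins, slopes)
        import pandas as pd

        table = pd.DataFrame(
            {
                "bin": range(cfg.n_bins),
                "pws": bins.rep_pws,
                "slope": [s.slope for s in slopes],
                "stderr": [s.stderr for s in slopes],
                "r2": [s.r2 for s in slopes],
                "p": [s.p_value for s in slopes],
            }
        ).set_index("bin")
        pio.write_table(table, out / "sensitivity_bins.csv")
        report["stages"]["sensitivity"] = {
            "slope_vs_pws": curve.slope,
            "intercept": curve.intercept,
            "r2": curve.r2,
            "p": curve.p_value,
            "true_b": fixture.truth.slope_b if fixture else None,
        }

    if "drivers" in cfg.stages:
        if fixture is None:
            raise ValueError("drivers stage needs the simulate stage (synthetic truth)")
        traits = simulate_traits(fixture.truth, seed=cfg.seed + 20)
        imp = fit_trait_importance(traits, pws_map, seed=cfg.seed + 21,
                                   n_folds=cfg.n_folds, n_estimators=cfg.n_trees)
        pio.write_table(imp.importance.rename("importance").to_frame(),
                        out / "trait_importance.csv")
        report["stages"]["drivers"] = {
            "cv_r2": imp.mean_cv_r2,
            "top_trait": str(imp.importance.idxmax()),
        }

    trend = None
    if "trends" in cfg.stages:
        ty = list(range(cfg.trend_years[0], cfg.trend_years[1] + 1))
        t_years, t_vpd = simulate_annual_vpd(pws_map.grid, ty, cfg.seed + 30,
                                             trend=cfg.vpd_trend)
        trend = vpd_trend_map(t_vpd, t_years)
        pio.write_map(trend.trend, pws_map.grid, out / "vpd_trend.tif")
        mask, frac = double_hazard(pws_map, trend, "joint_median")
        report["stages"]["trends"] = {
            "mean_trend": float(np.nanmean(trend.trend)),
            "rising_fraction": float(np.nanmean(trend.trend > 0)),
            "double_hazard_fraction": frac,
        }

    if "exposure" in cfg.stages:
        hazard = classify_hazard(pws_map, cfg.hazard_thresholds)
        wui, pop90, pop10 = simulate_wui(hazard, cfg.seed + 40)
        table = wui_exposure(wui, pop90, pop10, hazard)
        pio.write_table(table, out / "wui_exposure.csv")
        report["stages"]["exposure"] = {
            "total_pct_change": float(table.loc["total", "pct_change"]),
            "high_share_1990": float(table.loc["high", "share_1990"]),
            "high_share_2010": float(table.loc["high", "share_2010"]),
        }

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    cfg.to_yaml(out / "config.yaml")
    return report
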