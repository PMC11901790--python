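"""Run configuration and end-to-end orchestration.

``run_pipeline`` chains the stages simulate -> separate -> analyze for
one plot over one or more growing seasons, optionally scoring the
simulation against observations (calibration year first, further years
as validation) and optionally calibrating free parameters.  Inputs come
either from CSV files or from the synthetic generator; every run writes
its outputs plus a manifest (config echo, package version, seed,
mass-balance summary) under the configured output directory and mutates
nothing else.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .analysis import cumulative_threshold, gwa_change_stats, gwi_regression
from .calibrate import ObservationSet, calibrate, classify_nse, nse, read_observations
from .canopy import interpolate_lai, read_lai
from .forward import CalibrationRunner, ForwardResult, run_forward
from .meteo import SeasonCalendar, read_weather
from .richards import RichardsNonConvergence, SolverConfig
from .synth import WeatherGenSpec, gen_lai, gen_weather, make_truth_run
from .templates import species_templates

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """Structured stage failure (stage name + cause)."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    species: str = "R. pseudoacacia"
    params: dict = field(default_factory=dict)          # template overrides
    weather_csv: str | None = None
    lai_csv: str | None = None
    observations_csv: str | None = None
    synth: bool = True
    years: tuple = (2019,)
    season_total_mm: float = 560.0
    sigma_theta: float = 0.0
    partition_convention: str = "conventional"          # or "as_printed"
    evap_form: str = "increasing"                       # or "as_printed"
    dz: float = 2.0
    picard_tol: float = 1e-6
    theta_init_frac_fc: float = 0.85
    calibrate_enabled: bool = False
    calibrate_free: tuple = ("n1", "n2")
    calibrate_n_screen: int = 16
    output_dir: str = "gw_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat: dict = {}
        for block in ("plot", "meteo", "canopy", "soilwater", "calibrate", "synth", "output"):
            flat.update(raw.pop(block, None) or {})
        flat.update(raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise PipelineError("config", f"unknown config keys {sorted(unknown)}")
        if "years" in flat:
            flat["years"] = tuple(flat["years"])
        if "calibrate_free" in flat:
            flat["calibrate_free"] = tuple(flat["calibrate_free"])
        return cls(**flat)

    def validate(self) -> None:
        if self.species not in species_templates():
            raise PipelineError("config", f"unknown species template {self.species!r}")
        if self.partition_convention not in ("conventional", "as_printed"):
            raise PipelineError("config", f"bad partition convention {self.partition_convention!r}")
        if not self.synth:
            for name in ("weather_csv", "lai_csv"):
                p = getattr(self, name)
                if p is None:
                    raise PipelineError("config", f"{name} required when synth is disabled")
                if not Path(p).exists():
                    raise PipelineError("config", f"missing input file {p}")
        if self.observations_csv is not None and not Path(self.observations_csv).exists():
            raise PipelineError("config", f"missing input file {self.observations_csv}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> separate -> analyze and write all artefacts.

    Returns a dict with per-year ForwardResult objects, NSE tables,
    optional calibration result and the analysis summaries.
    """
    config.validate()
    template = species_templates()[config.species].with_params(**config.params)
    solver = SolverConfig(picard_tol=config.picard_tol, evap_form=config.evap_form)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    seasons: dict[int, dict] = {}
    for i, year in enumerate(config.years):
        cal = SeasonCalendar(year)
        try:
            if config.synth:
                weather = gen_weather(WeatherGenSpec(
                    seed=config.seed + i, year=year,
                    season_total_mm=config.season_total_mm))
                lai = gen_lai(template, cal)
                obs = None
                if config.sigma_theta > 0:
                    truth = make_truth_run(template, weather,
                                           sigma_theta=config.sigma_theta,
                                           seed=config.seed + 1000 + i, solver=solver)
                    obs = truth.observations
            else:
                weather = read_weather(config.weather_csv)
                lai = interpolate_lai(read_lai(config.lai_csv), weather.index)
                obs = (read_observations(config.observations_csv)
                       if config.observations_csv else None)
        except (ValueError, OSError) as exc:
            raise PipelineError("ingest", str(exc)) from exc

        try:
            fwd = run_forward(template, weather, lai, solver=solver,
                              partition_convention=config.partition_convention)
        except RichardsNonConvergence as exc:
            raise PipelineError("simulate", str(exc)) from exc
        except ValueError as exc:
            raise PipelineError("simulate", str(exc)) from exc

        nse_table = None
        if obs is not None:
            nse_table = _score(fwd, obs)
        seasons[year] = {"forward": fwd, "observations": obs, "nse": nse_table,
                         "calendar": cal}
        _write_gwc(fwd, outdir / f"gwc_{year}.csv")

    calib = None
    if config.calibrate_enabled:
        year0 = config.years[0]
        s0 = seasons[year0]
        if s0["observations"] is None:
            raise PipelineError("calibrate", "no observations available for calibration")
        runner = CalibrationRunner(template, s0["forward"].weather, s0["forward"].lai,
                                   solver=solver)
        from .templates import PARAM_RANGES
        bounds = {k: PARAM_RANGES[k] for k in config.calibrate_free}
        calib = calibrate(runner, s0["observations"], bounds,
                          nominal=template.param_dict(), n_screen=config.calibrate_n_screen,
                          seed=config.seed + 7)

    analyses = {}
    for year, s in seasons.items():
        gwc = s["forward"].gwc
        entry = {"box_stats": gwa_change_stats(gwc, s["calendar"]),
                 "threshold": cumulative_threshold(gwc)}
        try:
            entry["gwi_regression"] = gwi_regression(gwc.assign(LAI=s["forward"].lai))
        except ValueError:
            entry["gwi_regression"] = None
        analyses[year] = entry
        _write_analysis(entry, outdir / f"analysis_{year}")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "mass_balance": {str(y): seasons[y]["forward"].sim.mass_balance_error()
                         for y in seasons},
        "nse": {str(y): seasons[y]["nse"] for y in seasons if seasons[y]["nse"]},
    }
    if calib is not None:
        manifest["calibration"] = {"params": calib.params, "nse": calib.nse_theta,
                                   "bands": calib.bands}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    return {"seasons": seasons, "calibration": calib, "analyses": analyses,
            "manifest": manifest}


def _score(fwd: ForwardResult, obs: ObservationSet) -> dict:
    out = {}
    for col in obs.theta.columns:
        sim = fwd.theta[col].reindex(obs.theta.index)
        v = nse(obs.theta[col], sim)
        out[f"theta_{col:g}cm"] = {"nse": v, "band": classify_nse(v)}
    if len(obs.evap) >= 2 and obs.evap.nunique() > 1:
        v = nse(obs.evap, fwd.evap.reindex(obs.evap.index))
        out["evap"] = {"nse": v, "band": classify_nse(v)}
    return out


def _write_gwc(fwd: ForwardResult, path: Path) -> None:
    out = fwd.gwc.copy()
    out.insert(0, "date", out.index.strftime("%Y-%m-%d"))
    out.to_csv(path, index=False, float_format="%.6f")


def _write_analysis(entry: dict, stem: Path) -> None:
    box = pd.DataFrame([dataclasses.asdict(b) for b in entry["box_stats"]])
    box["outliers"] = box["outliers"].apply(lambda t: ";".join(f"{v:.4f}" for v in t))
    box.to_csv(f"{stem}_gwa_boxstats.csv", index=False, float_format="%.4f")
    th = entry["threshold"]
    pd.DataFrame([dataclasses.asdict(th)]).to_csv(f"{stem}_threshold.csv", index=False,
                                                  float_format="%.4f")
    if entry["gwi_regression"]:
        reg = pd.DataFrame([dataclasses.asdict(r) for r in entry["gwi_regression"].values()])
        reg.to_csv(f"{stem}_gwi_regression.csv", index=False, float_format="%.4f")
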