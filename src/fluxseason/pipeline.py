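"""End-to-end analysis pipeline and the parameter-table report.

Chains simulation (or CSV input), the three response-model fits, the annual
flux upscaling with bootstrap CI, seasonal summaries, the correlation
screen, and the variable-importance ranking, writing one JSON artifact per
stage plus a Markdown summary table.  Every JSON artifact embeds the seed
and a hash of the run configuration; logging goes to stderr and results only
ever to files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from fluxseason import envstats
from fluxseason.data import (
    monthly_mean,
    read_chemistry,
    read_climate,
    read_measurements,
)
from fluxseason.models import (
    compute_q10,
    fit_moisture_linear,
    fit_temperature_exponential,
    fit_temperature_moisture,
    significance_stars,
)
from fluxseason.simulate import StudyConfig, generate_study
from fluxseason.upscale import bootstrap_flux, fit_calibration, predict_daily_soil_temp

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and inputs."""


def _json_default(obj):
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj).__name__}")


@dataclasses.dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str
    seed: int = 0
    simulate: bool = False
    measurements_path: str | None = None
    climate_path: str | None = None
    chemistry_path: str | None = None
    sim_config: StudyConfig | None = None
    method: str = "nls"
    n_boot: int = 1000
    importance_trees: int = 150
    importance_permutations: int = 60

    def digest(self) -> str:
        payload = dataclasses.asdict(self)
        if self.sim_config is not None:
            payload["sim_config"] = self.sim_config.to_dict()
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()


def _substream_seeds(seed: int, n: int):
    return [int(s.generate_state(1)[0]) for s in np.random.SeedSequence(seed).spawn(n)]


def fit_stand_models(records: pd.DataFrame, method: str = "nls") -> dict:
    """All three response-model fits for one stand, parameter-table shaped."""
    exp_fit = fit_temperature_exponential(records, method=method)
    biv_fit = fit_temperature_moisture(records, method=method)
    lin_fit = fit_moisture_linear(records)
    return {
        "exponential": {
            "a": exp_fit.a,
            "b": exp_fit.b,
            "r2": exp_fit.r2,
            "p_value": exp_fit.p_value,
            "star": significance_stars(exp_fit.p_value),
            "q10": exp_fit.q10,
        },
        "bivariate": {
            "a": biv_fit.a,
            "b": biv_fit.b,
            "c": biv_fit.c,
            "r2": biv_fit.r2,
            "p_value": biv_fit.p_value,
            "star": significance_stars(biv_fit.p_value),
        },
        "linear": {
            "m": lin_fit.m,
            "n": lin_fit.n,
            "r2": lin_fit.r2,
            "p_value": lin_fit.p_value,
            "star": significance_stars(lin_fit.p_value),
        },
        "n_obs": exp_fit.n_obs,
    }


def upscale_stand(
    records: pd.DataFrame,
    climate: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    stand_id: str = "",
) -> dict:
    """Calibrate monthly soil-from-air temperature and integrate to annual flux."""
    soil_monthly = monthly_mean(records, "soil_temp_10cm").set_index("month")["mean"]
    clim = climate.copy()
    clim["month"] = pd.to_datetime(clim["date"]).dt.strftime("%Y-%m")
    air_monthly = clim.groupby("month")["air_temp"].mean()
    shared = soil_monthly.index.intersection(air_monthly.index)
    calib = fit_calibration(
        soil_monthly.loc[shared], air_monthly.loc[shared], stand_id=stand_id
    )
    daily_soil = pd.Series(
        predict_daily_soil_temp(calib, clim["air_temp"].to_numpy()),
        index=pd.DatetimeIndex(clim["date"]),
    )
    est = bootstrap_flux(records, daily_soil, n_boot=n_boot, seed=seed, stand_id=stand_id)
    return {
        "calibration": {
            "slope": calib.slope,
            "intercept": calib.intercept,
            "r2": calib.r2,
            "p_value": calib.p_value,
            "n_months": calib.n_months,
            "direction": calib.direction,
        },
        "flux": est.flux,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "n_days": est.n_days,
        "a": est.a,
        "b": est.b,
    }


def parameter_table(
    measurements: pd.DataFrame,
    climate: pd.DataFrame,
    method: str = "nls",
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Per-stand fit parameters, Q10, and annual flux (the report's core)."""
    stands = sorted(measurements["stand_id"].unique())
    seeds = _substream_seeds(seed, len(stands))
    out = {}
    for sid, s in zip(stands, seeds):
        recs = measurements[measurements["stand_id"] == sid]
        clim = climate[climate["stand_id"] == sid]
        entry = fit_stand_models(recs, method=method)
        entry["upscaling"] = upscale_stand(recs, clim, n_boot=n_boot, seed=s, stand_id=sid)
        out[sid] = entry
    return out


def render_markdown_report(table: dict, seed: int, digest: str) -> str:
    """Markdown report with a parameter-table-shaped per-stand summary."""
    lines = [
        "# Soil respiration analysis report",
        "",
        f"seed: {seed}; config: `{digest[:16]}`",
        "",
        "| Stand | a | b | R2(T) | a' | b' | c | R2(T,W) | m | n | R2(W) | Q10 | Annual flux (gC m-2 a-1) |",
        "|---|---|---|---|---|---|---|---|---|---|---|---|---|",
    ]
    for sid, e in sorted(table.items()):
        ex, bv, ln, up = e["exponential"], e["bivariate"], e["linear"], e["upscaling"]
        lines.append(
            f"| {sid} | {ex['a']:.3f} | {ex['b']:.3f} | {ex['r2']:.3f}{ex['star']} "
            f"| {bv['a']:.3f} | {bv['b']:.3f} | {bv['c']:.3f} | {bv['r2']:.3f}{bv['star']} "
            f"| {ln['m']:.3f} | {ln['n']:.3f} | {ln['r2']:.3f}{ln['star']} "
            f"| {compute_q10(ex['b']):.2f} "
            f"| {up['flux']:.2f} [{up['ci_low']:.2f}, {up['ci_high']:.2f}] |"
        )
    lines.append("")
    lines.append("Stars: **P < 0.01, *P < 0.05.")
    lines.append("")
    return "\n".join(lines)


def run_full_pipeline(config: RunConfig) -> dict:
    """Run every stage, writing artifacts under ``config.out_dir``.

    Returns a mapping of stage name to output path.  On any stage failure
    the partially written outputs are removed and a :class:`StageError`
    naming the stage propagates.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    provenance = {"seed": config.seed, "config_sha256": digest}
    written: list[Path] = []
    outputs: dict[str, str] = {}

    def emit(name: str, payload) -> None:
        path = out_dir / name
        path.write_text(
            json.dumps(
                {"provenance": provenance, "results": payload},
                indent=1,
                sort_keys=True,
                default=_json_default,
            )
        )
        written.append(path)
        outputs[name] = str(path)

    stage = "load"
    try:
        t0 = time.perf_counter()
        if config.simulate:
            stage = "simulate"
            bundle = generate_study(config.sim_config, seed=config.seed)
            bundle.write(out_dir / "data")
            for name in ("measurements.csv", "climate_daily.csv", "chemistry.csv", "truth.json"):
                written.append(out_dir / "data" / name)
            measurements, climate, chemistry = (
                bundle.measurements,
                bundle.climate,
                bundle.chemistry,
            )
            outputs["data"] = str(out_dir / "data")
        else:
            if not (config.measurements_path and config.climate_path):
                raise ValueError("measurements and climate paths are required unless simulating")
            measurements = read_measurements(config.measurements_path)
            climate = read_climate(config.climate_path)
            chemistry = (
                read_chemistry(config.chemistry_path) if config.chemistry_path else None
            )
        log.info("stage %-12s %6.2fs", stage, time.perf_counter() - t0)

        stage = "fit+upscale"
        t0 = time.perf_counter()
        table = parameter_table(
            measurements, climate, method=config.method, n_boot=config.n_boot, seed=config.seed
        )
        emit("fits.json", {sid: {k: v for k, v in e.items() if k != "upscaling"} for sid, e in table.items()})
        emit("flux.json", {sid: e["upscaling"] for sid, e in table.items()})
        log.info("stage %-12s %6.2fs", stage, time.perf_counter() - t0)

        stage = "seasonal"
        t0 = time.perf_counter()
        seasonal = {
            var: envstats.seasonal_summary(measurements, var).to_dict(orient="records")
            for var in ("rs", "soil_temp_10cm", "soil_moisture")
        }
        seasonal["wet_dry_ratio_rs"] = envstats.wet_dry_ratio(measurements, "rs").to_dict()
        emit("seasonal.json", seasonal)
        log.info("stage %-12s %6.2fs", stage, time.perf_counter() - t0)

        if chemistry is not None:
            stage = "correlate"
            t0 = time.perf_counter()
            table_env = envstats.season_table(measurements, chemistry, climate)
            screens = {
                "pooled": envstats.pearson_screen(table_env).to_dict(orient="records")
            }
            for season in ("dry", "wet"):
                sub = table_env[table_env["season"] == season]
                if len(sub) >= 3:
                    screens[season] = envstats.pearson_screen(sub).to_dict(orient="records")
            emit("correlations.json", screens)
            log.info("stage %-12s %6.2fs", stage, time.perf_counter() - t0)

            stage = "importance"
            t0 = time.perf_counter()
            if len(table_env) >= 8:
                imp = envstats.rank_variable_importance(
                    table_env[list(envstats.ENV_FACTORS)],
                    table_env["rs"],
                    n_trees=config.importance_trees,
                    n_permutations=config.importance_permutations,
                    seed=config.seed,
                )
                emit("importance.json", imp.to_dict(orient="records"))
            else:
                log.warning("importance skipped: fewer than 8 stand-season rows")
            log.info("stage %-12s %6.2fs", stage, time.perf_counter() - t0)

        stage = "report"
        report = out_dir / "report.md"
        report.write_text(render_markdown_report(table, config.seed, digest))
        written.append(report)
        outputs["report.md"] = str(report)
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise StageError(f"stage '{stage}' failed: {exc}") from exc
    return outputs
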