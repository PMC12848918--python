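"""Synthetic study generator.

Produces a full collar campaign — daily climate, soil microclimate, collar
measurements, and per-season soil chemistry — with the statistical structure
the downstream analysis assumes, so every stage is testable without any
field data.

The generative respiration law is the bivariate response
``rs = a * exp(b*T) * W**c``; the univariate temperature and moisture models
emerge as (mis)specified fits of the same data.  Observed rates carry
multiplicative lognormal noise (mean 1), observed temperature and moisture
carry additive Gaussian noise.  All randomness flows from a single integer
seed via named :class:`numpy.random.SeedSequence` substreams, so identical
(config, seed) pairs yield byte-identical bundles.

Note on the default truth set: the printed bivariate temperature coefficient
for stand SF (0.01) is almost certainly a typographical truncation of its
univariate value 0.102; the default truth uses 0.102.  Default air->soil
calibration lines are chosen so that the seasonal soil-temperature swings
they imply are consistent with the stands' observed seasonal contrasts.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from fluxseason.data import (
    CHEMISTRY_COLUMNS,
    WET_MONTHS,
    write_chemistry,
    write_climate,
    write_measurements,
)

log = logging.getLogger(__name__)

_CHEM_VARS = ("ph", "som", "soc", "tn", "tp", "an", "ap")

# Day-of-year anchors for the annual temperature sinusoid and moisture dips.
_DOY_PEAK = 196  # mid July: warmest
_DOY_DRY_DIP = 15  # mid January
_DOY_WET_DIP = 196  # mid July
_DIP_WIDTH_DAYS = 22.0


@dataclasses.dataclass(frozen=True)
class StandTruth:
    """Generative parameters for one stand.

    ``calib_slope``/``calib_intercept`` are stored in the printed direction
    ``air = slope * soil + intercept`` and inverted when simulating soil
    temperature from air temperature, mirroring how such calibrations are
    used for upscaling.
    """

    stand_id: str
    # bivariate respiration law rs = a * exp(b*T) * W**c
    a_true: float
    b_true: float  # degC^-1
    c_true: float  # unitless moisture exponent
    # monthly soil<->air temperature line, printed direction air-on-soil
    calib_slope: float
    calib_intercept: float
    # noise scales
    rs_noise_cv: float = 0.25  # CV of mean-1 multiplicative lognormal noise
    collar_sd: float = 0.10  # CV of persistent per-collar lognormal offsets
    temp_noise_sd: float = 0.25  # degC, additive
    moist_noise_sd: float = 0.5  # volumetric points, additive
    air_noise_sd: float = 0.8  # degC day-to-day weather noise
    rh_noise_sd: float = 1.5
    # seasonal moisture baselines (volumetric %)
    moist_dry_mean: float = 20.0
    moist_wet_mean: float = 24.0
    moist_dip_depth: float = 3.0  # depth of the two seasonal dips (W shape)
    moist_pulse_gain: float = 0.02  # volumetric points per mm precip anomaly
    # climate envelope (seasonal means)
    air_temp_dry: float = 22.6
    air_temp_wet: float = 27.2
    precip_wet_monthly: float = 260.0  # mm per wet-season month
    wet_precip_share: float = 0.80  # wet-season share of annual precipitation
    rh_dry: float = 81.0
    rh_wet: float = 83.0
    rain_prob_wet: float = 0.55
    rain_prob_dry: float = 0.25
    # per-season chemistry truth: {"dry": {var: (mean, sd)}, "wet": {...}}
    chemistry: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if self.a_true <= 0:
            raise ValueError("a_true must be > 0")
        if self.calib_slope == 0:
            raise ValueError("calib_slope must be nonzero")
        for name in ("moist_dry_mean", "moist_wet_mean"):
            v = getattr(self, name)
            if not 0 < v < 100:
                raise ValueError(f"{name} must lie in (0, 100)")
        if self.air_temp_wet <= self.air_temp_dry:
            raise ValueError("wet-season air temperature must exceed dry-season")


@dataclasses.dataclass
class StudyConfig:
    """Configuration of a synthetic campaign (defaults: 4 stands, a
    September-August study year, monthly sampling, 18 collars per stand)."""

    stands: tuple = ()
    start: dt.date = dt.date(2023, 9, 1)
    n_days: int = 366
    sample_day: int = 15  # day of month for the monthly campaign
    n_collars: int = 18

    def __post_init__(self):
        if not self.stands:
            self.stands = tuple(default_truths().values())
        if isinstance(self.start, str):
            self.start = dt.date.fromisoformat(self.start)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        """Load a config whose ``stands`` section maps stand ids to
        StandTruth field overrides (unset fields keep package defaults)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        defaults = default_truths()
        stands = []
        for sid, overrides in (raw.get("stands") or {}).items():
            base = defaults.get(sid)
            fields = dataclasses.asdict(base) if base else {"stand_id": sid}
            fields.update(overrides or {})
            fields["stand_id"] = sid
            stands.append(StandTruth(**fields))
        kwargs = {k: raw[k] for k in ("start", "n_days", "sample_day", "n_collars") if k in raw}
        return cls(stands=tuple(stands), **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["start"] = self.start.isoformat()
        return d


@dataclasses.dataclass
class StudyBundle:
    """A complete synthetic study plus the truth that generated it."""

    measurements: pd.DataFrame
    climate: pd.DataFrame
    chemistry: pd.DataFrame
    truth: dict  # stand_id -> StandTruth
    seed: int
    # realized daily soil microclimate (kept for truth-recovery checks;
    # not part of the written study tables)
    microclimate: pd.DataFrame | None = None

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_measurements(self.measurements, out / "measurements.csv")
        write_climate(self.climate, out / "climate_daily.csv")
        write_chemistry(self.chemistry, out / "chemistry.csv")
        payload = {
            "seed": self.seed,
            "stands": {sid: dataclasses.asdict(t) for sid, t in self.truth.items()},
        }
        (out / "truth.json").write_text(json.dumps(payload, indent=1, sort_keys=True))


def _chem(dry: dict, wet: dict) -> dict:
    return {"dry": dry, "wet": wet}


def default_truths() -> dict:
    """Default four-stand truth set (CA, CO, MF, SF).

    Respiration parameters come from the bivariate columns of the study's
    fitted-model table (with SF's truncated b restored to 0.102); climate
    envelopes and chemistry means/sds from its environmental-factor table.
    Calibration lines are derived from the seasonal air means together with
    the observed seasonal soil-temperature means so that simulated soil
    temperature reproduces the stands' seasonal contrasts.
    """
    # (air_dry, air_wet, soil_dry, soil_wet) seasonal mean temperatures
    temps = {
        "CA": (22.85, 27.65, 21.92, 27.55),
        "CO": (22.90, 27.28, 22.11, 29.21),
        "MF": (22.77, 27.27, 22.41, 28.69),
        "SF": (22.28, 26.87, 20.00, 25.12),
    }
    resp = {  # a, b, c of the generative bivariate law
        "CA": (0.132, 0.101, 0.094),
        "CO": (0.307, 0.066, 0.118),
        "MF": (0.128, 0.092, 0.199),
        "SF": (0.290, 0.102, 0.052),
    }
    moist = {  # dry/wet season mean volumetric moisture (%)
        "CA": (13.59, 15.55),
        "CO": (18.51, 23.22),
        "MF": (14.11, 15.04),
        "SF": (30.00, 35.18),
    }
    climate = {  # wet monthly precip (mm), rh dry, rh wet
        "CA": (244.65, 80.48, 82.95),
        "CO": (283.26, 79.78, 81.50),
        "MF": (255.08, 80.73, 83.43),
        "SF": (254.56, 82.47, 85.32),
    }
    chemistry = {
        "CA": _chem(
            {"ph": (5.65, 0.16), "som": (6.60, 0.65), "soc": (3.83, 0.38),
             "tn": (0.37, 0.04), "tp": (0.08, 0.01), "an": (3.98, 0.22),
             "ap": (5.26, 0.04)},
            {"ph": (4.19, 0.03), "som": (7.23, 0.22), "soc": (4.19, 0.13),
             "tn": (0.27, 0.03), "tp": (0.10, 0.02), "an": (6.10, 0.26),
             "ap": (1.36, 0.04)},
        ),
        "CO": _chem(
            {"ph": (5.32, 0.05), "som": (11.11, 0.70), "soc": (6.44, 0.40),
             "tn": (0.68, 0.07), "tp": (0.51, 0.06), "an": (9.33, 0.39),
             "ap": (67.86, 2.84)},
            {"ph": (5.16, 0.04), "som": (9.10, 0.61), "soc": (5.28, 0.08),
             "tn": (0.49, 0.04), "tp": (0.59, 0.07), "an": (4.20, 0.06),
             "ap": (67.97, 2.26)},
        ),
        "MF": _chem(
            {"ph": (4.92, 0.04), "som": (9.82, 0.50), "soc": (5.70, 0.29),
             "tn": (0.47, 0.04), "tp": (0.25, 0.03), "an": (4.04, 0.10),
             "ap": (21.49, 1.04)},
            {"ph": (4.56, 0.04), "som": (9.94, 0.40), "soc": (5.77, 0.07),
             "tn": (0.42, 0.02), "tp": (0.25, 0.04), "an": (6.55, 0.14),
             "ap": (26.62, 0.71)},
        ),
        "SF": _chem(
            {"ph": (5.27, 0.11), "som": (39.76, 1.44), "soc": (23.06, 0.84),
             "tn": (2.41, 0.08), "tp": (0.91, 0.12), "an": (33.52, 0.59),
             "ap": (9.80, 0.95)},
            {"ph": (5.43, 0.03), "som": (34.20, 0.54), "soc": (19.84, 0.31),
             "tn": (1.97, 0.07), "tp": (0.86, 0.16), "an": (10.98, 0.22),
             "ap": (4.05, 0.08)},
        ),
    }
    out = {}
    for sid in ("CA", "CO", "MF", "SF"):
        air_d, air_w, soil_d, soil_w = temps[sid]
        slope = (air_w - air_d) / (soil_w - soil_d)
        intercept = air_d - slope * soil_d
        a, b, c = resp[sid]
        md, mw = moist[sid]
        pw, rh_d, rh_w = climate[sid]
        out[sid] = StandTruth(
            stand_id=sid,
            a_true=a,
            b_true=b,
            c_true=c,
            calib_slope=slope,
            calib_intercept=intercept,
            moist_dry_mean=md,
            moist_wet_mean=mw,
            air_temp_dry=air_d,
            air_temp_wet=air_w,
            precip_wet_monthly=pw,
            rh_dry=rh_d,
            rh_wet=rh_w,
            chemistry=chemistry[sid],
        )
    return out


def noise_free(truth: StandTruth) -> StandTruth:
    """Copy of a truth with every noise scale set to zero."""
    return dataclasses.replace(
        truth,
        rs_noise_cv=0.0,
        collar_sd=0.0,
        temp_noise_sd=0.0,
        moist_noise_sd=0.0,
        air_noise_sd=0.0,
        rh_noise_sd=0.0,
    )


def _lognormal_factors(rng, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(-sigma2 / 2.0, math.sqrt(sigma2), size)


def _annual_sinusoid(dates: pd.DatetimeIndex) -> np.ndarray:
    """Unit annual temperature wave: maximum mid-July, minimum mid-January."""
    doy = dates.dayofyear.to_numpy(dtype=float)
    return np.cos(2.0 * np.pi * (doy - _DOY_PEAK) / 365.25)


def simulate_daily_climate(stand: StandTruth, start_date, n_days: int, seed: int) -> pd.DataFrame:
    """Daily air temperature, precipitation, and relative humidity.

    Air temperature is an annual sinusoid (minimum in January, maximum in
    July) scaled so the dry- and wet-season means match the stand's seasonal
    envelope exactly in the noise-free case, plus Gaussian day-to-day noise.
    Precipitation is a seeded wet-day process whose expected wet-season total
    is ``wet_precip_share`` (default 80%) of the annual sum.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if isinstance(start_date, str):
        start_date = dt.date.fromisoformat(start_date)
    rng = np.random.default_rng(seed)
    dates = pd.date_range(start_date, periods=n_days, freq="D")
    month = dates.month.to_numpy()
    wet = np.isin(month, list(WET_MONTHS))

    s = _annual_sinusoid(dates)
    if wet.any() and (~wet).any():
        s_w, s_d = s[wet].mean(), s[~wet].mean()
        amp = (stand.air_temp_wet - stand.air_temp_dry) / (s_w - s_d)
        mean = stand.air_temp_dry - amp * s_d
    else:  # degenerate span inside one season: nominal amplitude
        amp = math.pi * (stand.air_temp_wet - stand.air_temp_dry) / 4.0
        target = stand.air_temp_wet if wet.all() else stand.air_temp_dry
        mean = target - amp * s.mean()
    air = mean + amp * s + rng.normal(0.0, stand.air_noise_sd, n_days)

    # expected monthly totals: wet months at the envelope value, dry months
    # scaled so the wet season carries `wet_precip_share` of the annual sum
    share = stand.wet_precip_share
    dry_monthly = stand.precip_wet_monthly * (1.0 - share) / share
    monthly = np.where(wet, stand.precip_wet_monthly, dry_monthly)
    p_rain = np.where(wet, stand.rain_prob_wet, stand.rain_prob_dry)
    daily_mean = monthly / 30.44
    rainy = rng.random(n_days) < p_rain
    # gamma(shape 2) amounts with mean daily_mean / p_rain on rainy days
    amounts = rng.gamma(2.0, daily_mean / (p_rain * 2.0), n_days)
    precip = np.where(rainy, amounts, 0.0)

    rh_base = np.where(wet, stand.rh_wet, stand.rh_dry)
    rh = np.clip(rh_base + rng.normal(0.0, stand.rh_noise_sd, n_days), 0.0, 100.0)

    return pd.DataFrame(
        {
            "stand_id": stand.stand_id,
            "date": dates,
            "air_temp": air,
            "precip": precip,
            "rh": rh,
        }
    )


def simulate_soil_microclimate(climate: pd.DataFrame, stand: StandTruth, seed: int) -> pd.DataFrame:
    """Daily soil temperature and moisture for one stand.

    Soil temperature inverts the stand's printed air-on-soil calibration
    line, ``soil = (air - intercept) / slope``, plus Gaussian noise.  Soil
    moisture is a seasonal baseline with two mean-preserving mid-season dips
    (producing the W-shaped annual trajectory) and precipitation-anomaly
    pulses, clipped to (0, 100).
    """
    if climate.empty:
        raise ValueError("climate series is empty")
    if stand.calib_slope == 0:
        raise ValueError("degenerate calibration: slope is zero")
    rng = np.random.default_rng(seed)
    dates = pd.DatetimeIndex(climate["date"])
    n = len(dates)
    air = climate["air_temp"].to_numpy(dtype=float)
    soil_temp = (air - stand.calib_intercept) / stand.calib_slope
    soil_temp = soil_temp + rng.normal(0.0, stand.temp_noise_sd, n)

    month = dates.month.to_numpy()
    wet = np.isin(month, list(WET_MONTHS))
    base = np.where(wet, stand.moist_wet_mean, stand.moist_dry_mean)

    doy = dates.dayofyear.to_numpy(dtype=float)
    dip = np.zeros(n)
    for center in (_DOY_DRY_DIP, _DOY_WET_DIP):
        delta = np.minimum(np.abs(doy - center), 365.25 - np.abs(doy - center))
        dip -= stand.moist_dip_depth * np.exp(-0.5 * (delta / _DIP_WIDTH_DAYS) ** 2)
    precip = climate["precip"].to_numpy(dtype=float)
    pulse = stand.moist_pulse_gain * precip
    anomaly = dip + pulse
    # center anomalies within each season so seasonal means stay on baseline
    for mask in (wet, ~wet):
        if mask.any():
            anomaly[mask] -= anomaly[mask].mean()
    moisture = base + anomaly + rng.normal(0.0, stand.moist_noise_sd, n)
    moisture = np.clip(moisture, 0.1, 99.9)

    return pd.DataFrame(
        {
            "stand_id": stand.stand_id,
            "date": dates,
            "soil_temp": soil_temp,
            "soil_moisture": moisture,
        }
    )


def simulate_campaign(
    stand: StandTruth,
    microclimate: pd.DataFrame,
    schedule,
    n_collars: int,
    seed: int,
) -> pd.DataFrame:
    """Collar-level flux measurements on the scheduled dates.

    Per collar and date the true rate is the bivariate law evaluated at that
    day's soil microclimate times a persistent collar-level lognormal offset;
    the observed rate multiplies in mean-1 lognormal noise and the observed
    temperature/moisture receive additive Gaussian noise.
    """
    if n_collars < 1:
        raise ValueError("n_collars must be >= 1")
    rng = np.random.default_rng(seed)
    schedule = pd.DatetimeIndex(pd.to_datetime(list(schedule))).sort_values()
    micro = microclimate.set_index(pd.DatetimeIndex(microclimate["date"]))
    missing = schedule.difference(micro.index)
    if len(missing):
        raise ValueError(f"schedule dates outside microclimate series: {list(missing.date)}")

    t_true = micro.loc[schedule, "soil_temp"].to_numpy(dtype=float)
    w_true = micro.loc[schedule, "soil_moisture"].to_numpy(dtype=float)
    if stand.c_true != 0 and np.any(w_true <= 0):
        raise ValueError("soil moisture <= 0 with nonzero moisture exponent")

    collar_f = _lognormal_factors(rng, stand.collar_sd, n_collars)
    n_dates = len(schedule)
    shape = (n_dates, n_collars)
    rate = (
        stand.a_true
        * np.exp(stand.b_true * t_true)[:, None]
        * np.power(w_true, stand.c_true)[:, None]
        * collar_f[None, :]
    )
    rs = rate * _lognormal_factors(rng, stand.rs_noise_cv, shape)
    t_obs = t_true[:, None] + rng.normal(0.0, stand.temp_noise_sd, shape)
    w_obs = np.clip(w_true[:, None] + rng.normal(0.0, stand.moist_noise_sd, shape), 0.0, 100.0)

    collar_idx = np.tile(np.arange(n_collars), n_dates)
    return pd.DataFrame(
        {
            "stand_id": stand.stand_id,
            "plot_id": [f"P{i // 6 + 1}" for i in collar_idx],
            "collar_id": [f"C{i + 1:02d}" for i in collar_idx],
            "date": np.repeat(schedule, n_collars),
            "rs": rs.ravel(),
            "soil_temp_10cm": t_obs.ravel(),
            "soil_moisture": w_obs.ravel(),
        }
    )


def simulate_chemistry(stand: StandTruth, seed: int) -> pd.DataFrame:
    """One dry- and one wet-season chemistry record drawn from the stand's
    Normal(mean, sd) truth, truncated to the schema invariants."""
    if not stand.chemistry:
        raise ValueError(f"stand {stand.stand_id} has no chemistry defaults")
    rng = np.random.default_rng(seed)
    rows = []
    for season in ("dry", "wet"):
        params = stand.chemistry[season]
        row = {"stand_id": stand.stand_id, "season": season}
        for var in _CHEM_VARS:
            mean, sd = params[var]
            row[var] = float(rng.normal(mean, sd))
        row["ph"] = float(np.clip(row["ph"], 0.01, 13.99))
        for var in _CHEM_VARS[1:]:
            row[var] = max(row[var], 1e-3)
        if row["soc"] >= row["som"]:
            log.warning("%s/%s: truncating soc below som", stand.stand_id, season)
            row["soc"] = 0.95 * row["som"]
        rows.append(row)
    return pd.DataFrame(rows, columns=CHEMISTRY_COLUMNS)


def monthly_schedule(start: dt.date, n_days: int, sample_day: int) -> list:
    """One sampling date per calendar month in the span, on ``sample_day``
    (clamped to the month's length)."""
    end = start + dt.timedelta(days=n_days - 1)
    months = pd.period_range(start, end, freq="M")
    out = []
    for m in months:
        day = min(sample_day, m.days_in_month)
        d = dt.date(m.year, m.month, day)
        if start <= d <= end:
            out.append(d)
    return out


def generate_study(config: StudyConfig | None = None, seed: int = 0) -> StudyBundle:
    """Simulate the full campaign for every configured stand.

    Each stand draws climate, microclimate, campaign, and chemistry from
    independent seed substreams spawned from ``seed``.
    """
    config = config or StudyConfig()
    if not config.stands:
        raise ValueError("config names no stands")
    schedule = monthly_schedule(config.start, config.n_days, config.sample_day)
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(config.stands))
    meas, clim, chem, micros = [], [], [], []
    truth = {}
    for stand, child in zip(config.stands, children):
        s_climate, s_micro, s_campaign, s_chem = (c.generate_state(1)[0] for c in child.spawn(4))
        climate = simulate_daily_climate(stand, config.start, config.n_days, s_climate)
        micro = simulate_soil_microclimate(climate, stand, s_micro)
        meas.append(simulate_campaign(stand, micro, schedule, config.n_collars, s_campaign))
        clim.append(climate)
        chem.append(simulate_chemistry(stand, s_chem))
        micros.append(micro)
        truth[stand.stand_id] = stand
    return StudyBundle(
        measurements=pd.concat(meas, ignore_index=True),
        climate=pd.concat(clim, ignore_index=True),
        chemistry=pd.concat(chem, ignore_index=True),
        truth=truth,
        seed=seed,
        microclimate=pd.concat(micros, ignore_index=True),
    )


def simulate_driver_table(
    n_rows: int,
    driver: str = "som",
    effect: float = 1.0,
    noise_sd: float = 0.25,
    seed: int = 0,
) -> tuple:
    """Synthetic environmental-factor table with a planted response signal.

    Returns ``(features, response)`` where ``features`` has the ten standard
    environmental columns drawn independently at realistic scales and
    ``response`` is ``effect`` times the standardized driver column plus
    Gaussian noise (``effect=0`` gives a pure-noise response).  Used to
    calibrate the variable-importance screen.
    """
    rng = np.random.default_rng(seed)
    scales = {
        "ph": (5.0, 0.5),
        "som": (15.0, 8.0),
        "soc": (8.0, 4.0),
        "tn": (0.8, 0.5),
        "tp": (0.4, 0.25),
        "an": (10.0, 6.0),
        "ap": (25.0, 15.0),
        "prcp": (140.0, 80.0),
        "temp": (25.0, 2.0),
        "rh": (82.0, 2.0),
    }
    features = pd.DataFrame(
        {name: rng.normal(mu, sd, n_rows) for name, (mu, sd) in scales.items()}
    )
    if effect != 0.0:
        z = features[driver].to_numpy()
        z = (z - z.mean()) / z.std()
        response = effect * z + rng.normal(0.0, noise_sd, n_rows)
    else:
        response = rng.normal(0.0, 1.0, n_rows)
    return features, pd.Series(response, name="rs")
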