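import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from fluxseason.data import WET_MONTHS
from fluxseason.envstats import seasonal_summary, wet_dry_ratio
from fluxseason.models import (
    fit_moisture_linear,
    fit_temperature_exponential,
    fit_temperature_moisture,
)
from fluxseason.simulate import (
    StandTruth,
    StudyConfig,
    default_truths,
    generate_study,
    monthly_schedule,
    noise_free,
    simulate_campaign,
    simulate_chemistry,
    simulate_daily_climate,
    simulate_soil_microclimate,
)


def wet_mask(df):
    return pd.to_datetime(df["date"]).dt.month.isin(WET_MONTHS)


class TestDailyClimate:
    def test_noise_free_seasonal_air_contrast(self, truths):
        # seasonal mean difference must land in the observed 4.38-4.80 degC band
        for truth in truths.values():
            clim = simulate_daily_climate(noise_free(truth), "2023-09-01", 365, seed=0)
            wet = wet_mask(clim)
            diff = clim.loc[wet, "air_temp"].mean() - clim.loc[~wet, "air_temp"].mean()
            assert 4.38 <= diff <= 4.80

    def test_wet_season_precip_share(self, truths):
        clim = simulate_daily_climate(truths["SF"], "2023-09-01", 366, seed=11)
        wet = wet_mask(clim)
        share = clim.loc[wet, "precip"].sum() / clim["precip"].sum()
        assert 0.75 <= share <= 0.85

    def test_same_seed_identical(self, truths):
        a = simulate_daily_climate(truths["CA"], "2023-09-01", 100, seed=5)
        b = simulate_daily_climate(truths["CA"], "2023-09-01", 100, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_n_days_validation(self, truths):
        with pytest.raises(ValueError, match="n_days"):
            simulate_daily_climate(truths["CA"], "2023-09-01", 0, seed=0)

    def test_rh_within_bounds(self, truths):
        clim = simulate_daily_climate(truths["MF"], "2023-09-01", 366, seed=3)
        assert clim["rh"].between(0, 100).all()
        assert (clim["precip"] >= 0).all()


class TestSoilMicroclimate:
    def _constant_air(self, temp, n=30):
        return pd.DataFrame(
            {
                "stand_id": "CA",
                "date": pd.date_range("2024-01-01", periods=n),
                "air_temp": temp,
                "precip": 0.0,
                "rh": 80.0,
            }
        )

    def test_printed_ca_line_inversion(self, ca_printed_calib_truth):
        # soil = (25 + 1.078) / 1.067 = 24.44
        micro = simulate_soil_microclimate(self._constant_air(25.0), ca_printed_calib_truth, seed=0)
        assert micro["soil_temp"].to_numpy() == pytest.approx((25 + 1.078) / 1.067)
        assert round(float(micro["soil_temp"].iloc[0]), 2) == 24.44

    def test_identity_line(self, truths):
        truth = dataclasses.replace(noise_free(truths["CA"]), calib_slope=1.0, calib_intercept=0.0)
        micro = simulate_soil_microclimate(self._constant_air(18.5), truth, seed=0)
        assert micro["soil_temp"].to_numpy() == pytest.approx(18.5)

    def test_sf_moisture_seasonal_offset(self, truths):
        truth = noise_free(truths["SF"])
        clim = simulate_daily_climate(truth, "2023-09-01", 366, seed=2)
        micro = simulate_soil_microclimate(clim, truth, seed=2)
        wet = wet_mask(micro)
        offset = micro.loc[wet, "soil_moisture"].mean() - micro.loc[~wet, "soil_moisture"].mean()
        assert offset == pytest.approx(5.18, abs=1e-9)

    def test_moisture_stays_in_open_interval(self, truths):
        for truth in truths.values():
            clim = simulate_daily_climate(truth, "2023-09-01", 366, seed=4)
            micro = simulate_soil_microclimate(clim, truth, seed=4)
            assert (micro["soil_moisture"] > 0).all()
            assert (micro["soil_moisture"] < 100).all()

    def test_w_shape_has_two_troughs(self, truths):
        # mid-January and mid-July dips below their season baselines
        truth = noise_free(truths["CA"])
        clim = simulate_daily_climate(truth, "2023-09-01", 366, seed=0)
        micro = simulate_soil_microclimate(clim, truth, seed=0).set_index("date")
        jan = micro.loc["2024-01-10":"2024-01-20", "soil_moisture"].mean()
        jul = micro.loc["2024-07-10":"2024-07-20", "soil_moisture"].mean()
        assert jan < truth.moist_dry_mean
        assert jul < truth.moist_wet_mean

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            StandTruth(
                stand_id="X", a_true=0.2, b_true=0.1, c_true=0.0,
                calib_slope=0.0, calib_intercept=1.0,
            )

    def test_empty_climate_rejected(self, truths):
        with pytest.raises(ValueError, match="empty"):
            simulate_soil_microclimate(self._constant_air(25.0).iloc[:0], truths["CA"], seed=0)


class TestCampaign:
    def _micro(self, temps, moistures):
        return pd.DataFrame(
            {
                "stand_id": "X",
                "date": pd.date_range("2024-01-01", periods=len(temps)),
                "soil_temp": temps,
                "soil_moisture": moistures,
            }
        )

    def test_noise_free_law_with_zero_exponent(self):
        truth = StandTruth(
            stand_id="X", a_true=0.5, b_true=0.08, c_true=0.0,
            calib_slope=1.0, calib_intercept=0.0, rs_noise_cv=0.0,
            collar_sd=0.0, temp_noise_sd=0.0, moist_noise_sd=0.0,
        )
        micro = self._micro([20.0, 25.0, 30.0], [10.0, 20.0, 30.0])
        out = simulate_campaign(truth, micro, micro["date"], n_collars=4, seed=0)
        expected = 0.5 * np.exp(0.08 * out["soil_temp_10cm"].to_numpy())
        np.testing.assert_allclose(out["rs"].to_numpy(), expected, rtol=1e-12)

    def test_sf_exponential_point_value(self):
        # a=0.331, b=0.102, c=0, T=25 -> rs = 0.331 * e^2.55
        truth = StandTruth(
            stand_id="SF", a_true=0.331, b_true=0.102, c_true=0.0,
            calib_slope=1.0, calib_intercept=0.0, rs_noise_cv=0.0,
            collar_sd=0.0, temp_noise_sd=0.0, moist_noise_sd=0.0,
        )
        micro = self._micro([25.0], [42.0])
        out = simulate_campaign(truth, micro, micro["date"], n_collars=1, seed=0)
        assert out["rs"].iloc[0] == pytest.approx(0.331 * math.exp(2.55), rel=1e-12)

    def test_cardinality(self, truths):
        truth = truths["CA"]
        micro = self._micro(list(np.linspace(18, 30, 12)), [15.0] * 12)
        out = simulate_campaign(truth, micro, micro["date"], n_collars=18, seed=1)
        assert len(out) == 12 * 18
        assert out["collar_id"].nunique() == 18
        assert out["plot_id"].nunique() == 3

    def test_outputs_satisfy_invariants(self, default_bundle):
        m = default_bundle.measurements
        assert (m["rs"] >= 0).all() and np.isfinite(m["rs"]).all()
        assert m["soil_moisture"].between(0, 100).all()
        assert m["soil_temp_10cm"].between(-10, 60).all()
        assert not m.duplicated(subset=["stand_id", "collar_id", "date"]).any()

    def test_nonpositive_moisture_domain_error(self, truths):
        micro = self._micro([20.0], [0.0])
        with pytest.raises(ValueError, match="moisture"):
            simulate_campaign(truths["CA"], micro, micro["date"], n_collars=2, seed=0)

    def test_schedule_outside_series_rejected(self, truths):
        micro = self._micro([20.0, 21.0], [15.0, 15.0])
        with pytest.raises(ValueError, match="schedule"):
            simulate_campaign(
                truths["CA"], micro, [pd.Timestamp("2030-01-01")], n_collars=2, seed=0
            )


class TestChemistry:
    def test_zero_sd_gives_exact_means(self, truths):
        truth = truths["SF"]
        frozen = dataclasses.replace(
            truth,
            chemistry={
                season: {var: (mean, 0.0) for var, (mean, _) in params.items()}
                for season, params in truth.chemistry.items()
            },
        )
        chem = simulate_chemistry(frozen, seed=0).set_index("season")
        assert chem.loc["dry", "som"] == pytest.approx(39.76)
        assert chem.loc["wet", "som"] == pytest.approx(34.20)

    def test_soc_below_som(self, truths):
        for seed in range(5):
            for truth in truths.values():
                chem = simulate_chemistry(truth, seed=seed)
                assert (chem["soc"] < chem["som"]).all()

    def test_same_seed_identical(self, truths):
        a = simulate_chemistry(truths["CO"], seed=9)
        b = simulate_chemistry(truths["CO"], seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestGenerateStudy:
    def test_default_cardinality(self, default_bundle):
        assert len(default_bundle.measurements) == 4 * 12 * 18
        assert sorted(default_bundle.truth) == ["CA", "CO", "MF", "SF"]
        assert len(default_bundle.chemistry) == 8

    def test_wet_exceeds_dry_respiration_everywhere(self, default_bundle):
        summary = seasonal_summary(default_bundle.measurements, "rs")
        wide = summary.pivot(index="stand_id", columns="season", values="mean")
        assert (wide["wet"] > wide["dry"]).all()

    def test_wet_dry_ratio_band(self):
        # bracketing the observed 1.69-2.04 range
        for seed in (0, 3, 11, 21, 42):
            bundle = generate_study(seed=seed)
            ratios = wet_dry_ratio(bundle.measurements, "rs")
            assert ((ratios > 1.5) & (ratios < 2.3)).all(), (seed, ratios)

    def test_determinism(self):
        a = generate_study(seed=123)
        b = generate_study(seed=123)
        pd.testing.assert_frame_equal(a.measurements, b.measurements)
        pd.testing.assert_frame_equal(a.climate, b.climate)
        pd.testing.assert_frame_equal(a.chemistry, b.chemistry)

    def test_two_seeds_same_truth_different_noise(self):
        a = generate_study(seed=1)
        b = generate_study(seed=2)
        assert a.truth == b.truth
        assert not np.allclose(a.measurements["rs"], b.measurements["rs"])

    def test_empty_config_rejected(self):
        cfg = StudyConfig()
        cfg.stands = ()
        with pytest.raises(ValueError, match="stands"):
            generate_study(cfg, seed=0)

    def test_monthly_schedule_clamps_to_month_length(self):
        import datetime as dt

        dates = monthly_schedule(dt.date(2024, 1, 1), 60, sample_day=31)
        assert dates == [dt.date(2024, 1, 31), dt.date(2024, 2, 29)]

    def test_bundle_write_round_trip(self, tmp_path, default_bundle):
        from fluxseason.data import read_chemistry, read_climate, read_measurements

        default_bundle.write(tmp_path)
        assert len(read_measurements(tmp_path / "measurements.csv")) == 864
        assert len(read_climate(tmp_path / "climate_daily.csv")) == 4 * 366
        assert len(read_chemistry(tmp_path / "chemistry.csv")) == 8
        assert (tmp_path / "truth.json").exists()


class TestNoiseFreeRecovery:
    def test_downstream_fits_recover_truth(self, noise_free_bundle):
        for sid, records in noise_free_bundle.measurements.groupby("stand_id"):
            truth = noise_free_bundle.truth[sid]
            fit = fit_temperature_moisture(records)
            assert fit.a == pytest.approx(truth.a_true, rel=1e-6)
            assert fit.b == pytest.approx(truth.b_true, rel=1e-6)
            assert fit.c == pytest.approx(truth.c_true, rel=1e-6)

    def test_config_from_yaml_overrides(self, tmp_path):
        cfg_path = tmp_path / "study.yaml"
        cfg_path.write_text(
            "n_days: 90\nstands:\n  CA:\n    rs_noise_cv: 0.0\n  SF: {}\n"
        )
        cfg = StudyConfig.from_yaml(cfg_path)
        assert cfg.n_days == 90
        by_id = {t.stand_id: t for t in cfg.stands}
        assert by_id["CA"].rs_noise_cv == 0.0
        assert by_id["SF"].rs_noise_cv == 0.25
        assert by_id["CA"].a_true == default_truths()["CA"].a_true
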