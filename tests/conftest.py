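import numpy as np
import pandas as pd
import pytest

from fluxseason.simulate import (
    StandTruth,
    StudyConfig,
    default_truths,
    generate_study,
    noise_free,
)

BUNDLE_SEED = 7


@pytest.fixture(scope="session")
def default_bundle():
    """Default four-stand synthetic study at a fixed seed."""
    return generate_study(seed=BUNDLE_SEED)


@pytest.fixture(scope="session")
def noise_free_bundle():
    """Default study with every noise scale zeroed."""
    stands = tuple(noise_free(t) for t in default_truths().values())
    return generate_study(StudyConfig(stands=stands), seed=BUNDLE_SEED)


@pytest.fixture(scope="session")
def truths():
    return default_truths()


@pytest.fixture
def ca_printed_calib_truth(truths):
    """CA truth carrying the printed air-on-soil line air = 1.067*soil - 1.078."""
    import dataclasses

    return dataclasses.replace(
        noise_free(truths["CA"]), calib_slope=1.067, calib_intercept=-1.078
    )


@pytest.fixture
def small_measurements():
    """Hand-built six-record fixture spanning both seasons and two stands."""
    return pd.DataFrame(
        {
            "stand_id": ["A", "A", "A", "B", "B", "B"],
            "plot_id": ["P1"] * 6,
            "collar_id": ["C1", "C2", "C3", "C1", "C2", "C3"],
            "date": pd.to_datetime(
                ["2024-01-10", "2024-01-10", "2024-07-10",
                 "2024-01-10", "2024-07-10", "2024-07-10"]
            ),
            "rs": [1.0, 3.0, 4.0, 2.0, 4.0, 4.0],
            "soil_temp_10cm": [20.0, 21.0, 28.0, 20.5, 27.0, 28.0],
            "soil_moisture": [12.0, 14.0, 18.0, 20.0, 25.0, 24.0],
        }
    )


def exp_records(a, b, temps, moisture=20.0):
    """Noise-free records following rs = a*exp(b*T) at fixed moisture."""
    temps = np.asarray(temps, dtype=float)
    return pd.DataFrame(
        {
            "stand_id": "X",
            "plot_id": "P1",
            "collar_id": [f"C{i}" for i in range(len(temps))],
            "date": pd.Timestamp("2024-01-15"),
            "rs": a * np.exp(b * temps),
            "soil_temp_10cm": temps,
            "soil_moisture": moisture,
        }
    )


def bivariate_records(a, b, c, temps, moistures):
    """Noise-free records following rs = a*exp(b*T)*W**c."""
    temps = np.asarray(temps, dtype=float)
    moistures = np.asarray(moistures, dtype=float)
    return pd.DataFrame(
        {
            "stand_id": "X",
            "plot_id": "P1",
            "collar_id": [f"C{i}" for i in range(len(temps))],
            "date": pd.Timestamp("2024-01-15"),
            "rs": a * np.exp(b * temps) * moistures**c,
            "soil_temp_10cm": temps,
            "soil_moisture": moistures,
        }
    )
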