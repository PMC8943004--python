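"""Shared fixtures: small synthetic tracks and sensor streams."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from nocmig import synthetic as syn


@pytest.fixture(scope="session")
def small_config():
    return syn.SimulationConfig(seed=11, n_days=50, stopover_schedule=((10, 3),))


@pytest.fixture(scope="session")
def small_track(small_config):
    return syn.simulate_track(small_config)


@pytest.fixture(scope="session")
def small_sensors(small_track):
    return syn.simulate_sensor_series(small_track)


def make_twilight_frame(lon, lat, d0, n_days, zenith, delay_fn=None):
    """Noise-free (or delayed) twilight events for a stationary position."""
    from nocmig import solar

    rows = []
    for k in range(n_days):
        d = (pd.Timestamp(d0) + pd.Timedelta(days=k)).date()
        day64 = np.datetime64(d.isoformat())
        for rising, typ in ((True, "sunrise"), (False, "sunset")):
            m = float(solar.event_time_minutes(day64, lon, lat, zenith, rising))
            if np.isnan(m):
                continue
            if delay_fn is not None:
                dl = delay_fn()
                m = m + dl if rising else m - dl
            rows.append(
                {
                    "date": d,
                    "type": typ,
                    "time": pd.Timestamp(d) + pd.Timedelta(minutes=m),
                    "excluded": False,
                }
            )
    return pd.DataFrame(rows)
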