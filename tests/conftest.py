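import numpy as np
import pandas as pd
import pytest

import fullcycle as fc


@pytest.fixture(scope="session")
def wa_year():
    """One West-Africa bird-year at a coarse 60-min interval (fast)."""
    return fc.generate_bird_year("WestAfrica", 60, seed=11)


@pytest.fixture(scope="session")
def fruk_year():
    return fc.generate_bird_year("FRUK", 60, seed=7)


@pytest.fixture(scope="session")
def wa_processed(wa_year):
    return fc.process_bird_year(wa_year, seed=0)


@pytest.fixture(scope="session")
def fruk_processed(fruk_year):
    return fc.process_bird_year(fruk_year, seed=0)


def make_day_fixes(modes, dbas=None, floating=None, date="2018-06-02",
                   t_air=20.0, wind=1.0, solar=0.0):
    """A minimal one-day fix table for energetics unit tests."""
    n = len(modes)
    t = pd.date_range(date, periods=n, freq=f"{int(24 * 60 / n)}min")
    return pd.DataFrame({
        "t": t,
        "lat": 52.0, "lon": 4.0,
        "mode": modes,
        "floating": floating if floating is not None else [False] * n,
        "dba": dbas if dbas is not None else [0.0] * n,
        "t_air": t_air, "wind": wind, "solar": solar,
        "simulated": False,
    })
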