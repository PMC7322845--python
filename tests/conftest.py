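import numpy as np
import pandas as pd
import pytest

from plasmascape.tracks import Trip


def make_trip(lons, lats, interval_s=3600.0, t0="2016-12-01T00:00:00",
              individual_id="bird", species="sp", guild="flying", **cols):
    """Build a Trip from coordinate arrays at a regular interval."""
    n = len(lons)
    times = (np.datetime64(t0)
             + (np.arange(n) * interval_s * 1e9).astype("timedelta64[ns]"))
    df = pd.DataFrame({"time": times, "lon": np.asarray(lons, float),
                       "lat": np.asarray(lats, float), **cols})
    return Trip(individual_id, species, guild, df, interval_s)


@pytest.fixture(scope="session")
def flying_bundle():
    """Small synthetic flying-guild study shared across tests."""
    from plasmascape.synth import make_study_bundle
    return make_study_bundle(n_per_species=8, guild="flying", seed=3)
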