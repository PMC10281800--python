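import numpy as np
import pandas as pd
import pytest

from cuculus.io import read_regions
from cuculus.mcmc import MCMCSettings
from cuculus.segmentation import segment
from cuculus.synthetic import (SimConfig, metadata_table, noise_free,
                               render_population, simulate_schedules)


@pytest.fixture(scope="session")
def regions():
    return read_regions()


@pytest.fixture(scope="session")
def fast_mcmc():
    """Short chains for unit tests; conclusions never hinge on tail
    quantiles of these runs."""
    return MCMCSettings(chains=2, burn_in=300, draws=700, seed=7)


@pytest.fixture(scope="session")
def clean_population():
    """Small noise-free population: truth records, fixes, segmentation."""
    cfg = noise_free(SimConfig(n_birds=8, n_years=2, seed=12,
                               mortality_enabled=False))
    records = simulate_schedules(cfg)
    fixes = render_population(records, cfg)
    cycles, best, stopovers = segment(fixes)
    return dict(config=cfg, records=records, fixes=fixes, cycles=cycles,
                best=best, stopovers=stopovers, meta=metadata_table(records))


@pytest.fixture(scope="session")
def mortal_population():
    """Population with mortality and duty-cycle dropouts switched on."""
    cfg = SimConfig(n_birds=25, n_years=3, seed=21)
    records = simulate_schedules(cfg)
    return dict(config=cfg, records=records, meta=metadata_table(records))


def make_fix_frame(times_hours, lats, lons, lcs=None, bird="B1",
                   t0="2015-06-01T00:00:00Z"):
    """Helper: build a fix table from hour offsets."""
    t0 = pd.Timestamp(t0)
    n = len(times_hours)
    return pd.DataFrame({
        "bird_id": [bird] * n,
        "t": [t0 + pd.Timedelta(hours=float(h)) for h in times_hours],
        "lat": np.asarray(lats, dtype=float),
        "lon": np.asarray(lons, dtype=float),
        "lc": lcs if lcs is not None else ["3"] * n,
    })
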