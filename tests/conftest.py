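import numpy as np
import pandas as pd
import pytest

from sealforage import synthetic as syn
from sealforage.dives import Dive, split_phases


@pytest.fixture(scope="session")
def small_config():
    return syn.SimConfig(seed=11, n_seals=1, track_steps=60)


@pytest.fixture(scope="session")
def small_deployment(small_config):
    """One-seal synthetic deployment reused across modules."""
    tr, st = syn.simulate_track(small_config, "S0")
    rec, truth = syn.simulate_dive_records(small_config, tr, "S0")
    gps = syn.simulate_gps_fixes(small_config, tr, "S0")
    return {"track": tr, "states": st, "records": rec, "dive_truth": truth, "gps": gps}


def make_dive(depths, temps=None, lls=None, seal_id="S0", t0="2014-07-01T15:00:00Z",
              dt_s=10.0):
    """Construct a Dive directly from a depth profile (10-s cadence)."""
    depths = np.asarray(depths, float)
    n = len(depths)
    samples = pd.DataFrame(
        {
            "seal_id": seal_id,
            "timestamp": pd.Timestamp(t0) + pd.to_timedelta(np.arange(n) * dt_s, unit="s"),
            "depth_m": depths,
            "temp_c": np.asarray(temps, float) if temps is not None else np.full(n, 8.0),
            "ll": np.asarray(lls, float) if lls is not None else np.full(n, 150.0),
            "wet": True,
        }
    )
    d = Dive(seal_id=seal_id, samples=samples)
    d.i_bottom_start, d.i_bottom_end = split_phases(d)
    return d
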