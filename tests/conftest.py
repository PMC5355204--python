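from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd
import pytest

T0 = datetime(2000, 10, 1, tzinfo=timezone.utc)


def make_track(lonlat, hours=None, lc=None, animal="A1", hauled=None):
    """Small helper building a location table from (lon, lat) pairs."""
    n = len(lonlat)
    hours = hours if hours is not None else list(range(n))
    lc = lc if lc is not None else ["3"] * n
    hauled = hauled if hauled is not None else [0] * n
    return pd.DataFrame({
        "animal_id": animal,
        "timestamp": [T0 + timedelta(hours=float(h)) for h in hours],
        "lon": [p[0] for p in lonlat],
        "lat": [p[1] for p in lonlat],
        "lc": lc,
        "hauled_out": hauled,
    })


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_tracks(rng, n_tracks=100, max_fixes=50):
    """Random jittery tracks exercising all three SDA rules."""
    tracks = []
    for k in range(n_tracks):
        n = int(rng.integers(5, max_fixes + 1))
        t = np.cumsum(rng.exponential(3600.0, n))        # seconds
        lon = np.cumsum(rng.normal(0.0, 0.05, n)) - 157.0
        lat = np.cumsum(rng.normal(0.0, 0.03, n)) + 58.0
        # inject spikes to trigger speed/angle rules
        n_spikes = int(rng.integers(0, 4))
        for _ in range(n_spikes):
            i = int(rng.integers(1, n))
            lon[i] += rng.normal(0, 0.5)
            lat[i] += rng.normal(0, 0.3)
        lc = rng.choice(list("3210ABZ"), n,
                        p=[0.05, 0.08, 0.13, 0.1, 0.25, 0.34, 0.05])
        tracks.append(make_track(list(zip(lon, lat)), hours=t / 3600.0,
                                 lc=list(lc), animal=f"T{k:03d}"))
    return tracks
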