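"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from ravenrange import synth, trackprep

FIELD_LON = synth.FIELD_SITE_LON
FIELD_LAT = synth.FIELD_SITE_LAT


def make_fixes(times, lons, lats, individual_id="B001") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual_id": individual_id,
            "timestamp": pd.to_datetime(times),
            "lon": np.asarray(lons, float),
            "lat": np.asarray(lats, float),
        }
    )


@pytest.fixture(scope="session")
def small_population():
    """A compact multi-season population shared by read-only tests."""
    cfg = synth.SyntheticConfig.scaled(n_individuals=4, n_sites=5, n_days=40, seed=101)
    tracks, attrs, truth = synth.simulate_population(cfg)
    return cfg, tracks, attrs, truth


@pytest.fixture(scope="session")
def small_segments(small_population):
    _, tracks, attrs, _ = small_population
    individuals = {r["id"]: trackprep.Individual(**r) for r in attrs.to_dict("records")}
    day = trackprep.filter_daytime(tracks)
    return trackprep.segment(day, individuals), individuals


@pytest.fixture()
def brownian_segment_factory():
    """Pure 2-D Brownian motion tracks with known motion variance."""

    def factory(sigma2=2.0, n=200, dt_s=300.0, delta=5.0, seed=0):
        rng = np.random.default_rng(seed)
        steps = rng.normal(0.0, np.sqrt(sigma2 * dt_s), (n - 1, 2))
        xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        xy = xy + rng.normal(0.0, delta, xy.shape)  # GPS location error
        proj = synth.LocalProjection(FIELD_LON, FIELD_LAT)
        lon, lat = proj.inverse(xy[:, 0], xy[:, 1])
        t0 = dt.datetime(2018, 7, 1, 8, 0, 0)
        times = [t0 + dt.timedelta(seconds=i * dt_s) for i in range(n)]
        fixes = make_fixes(times, lon, lat)
        return trackprep.SeasonYearSegment(
            individual_id="B001", season="summer", year_label=2018, fixes=fixes, age_class="adult"
        )

    return factory


@pytest.fixture()
def planted_sites_fixture():
    """Five well-separated sites with >= 12 subsampled fixes each plus noise.

    Returns (fixes, true site centres as (lon, lat) tuples).  Fix times are
    spaced 20 min apart so the 15-min subsampling keeps everything.
    """
    rng = np.random.default_rng(42)
    proj = synth.LocalProjection(FIELD_LON, FIELD_LAT)
    centres_xy = [(0.0, 0.0), (4000.0, 0.0), (0.0, 4000.0), (-5000.0, -2000.0), (6000.0, 5000.0)]
    rows = []
    t = dt.datetime(2018, 7, 1, 6, 0, 0)
    for cx, cy in centres_xy:
        for _ in range(14):
            x = cx + rng.normal(0, 30.0)
            y = cy + rng.normal(0, 30.0)
            lon, lat = proj.inverse(x, y)
            rows.append((t, float(lon), float(lat)))
            t += dt.timedelta(minutes=20)
    for _ in range(60):  # sparse uniform noise, far less dense than the sites
        x, y = rng.uniform(-9000, 9000, 2)
        lon, lat = proj.inverse(x, y)
        rows.append((t, float(lon), float(lat)))
        t += dt.timedelta(minutes=20)
    fixes = make_fixes([r[0] for r in rows], [r[1] for r in rows], [r[2] for r in rows])
    centres_ll = [tuple(map(float, proj.inverse(cx, cy))) for cx, cy in centres_xy]
    return fixes, centres_ll
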