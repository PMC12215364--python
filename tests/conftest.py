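import datetime as dt

import numpy as np
import pandas as pd
import pytest

from mothtraj import (OccurrenceTable, ScenarioSpec, Trajectory,
                      TrajectoryEnsemble, WindField, make_windfield)


def uniform_field(u=10.0, v=0.0, lat_bounds=(-10.0, 10.0),
                  lon_bounds=(-10.0, 40.0), t0="2022-04-01", days=10):
    lats = np.arange(lat_bounds[0], lat_bounds[1] + 0.5, 1.0)
    lons = np.arange(lon_bounds[0], lon_bounds[1] + 0.5, 1.0)
    times = pd.date_range(t0, periods=days, freq="D")
    shape = (len(times), len(lats), len(lons))
    return WindField(lats, lons, times.to_numpy(),
                     np.full(shape, float(u)), np.full(shape, float(v)))


@pytest.fixture
def equator_field():
    return uniform_field(u=10.0, v=0.0)


@pytest.fixture
def jet_field():
    return make_windfield(ScenarioSpec(wind_kind="westerly_jet"))


@pytest.fixture
def rotation_field():
    return make_windfield(ScenarioSpec(
        wind_kind="solid_rotation", center=(35.0, 120.0),
        omega=2 * np.pi / (24 * 3600.0),          # one revolution per day
        lat_bounds=(28.0, 42.0), lon_bounds=(110.0, 130.0)))


def make_traj(points, site_id="S1", init="2022-04-04", direction="forward"):
    """Trajectory from a list of (lat, lon) pairs at hourly cadence."""
    pts = np.array([(float(i), la, lo, 1000.0)
                    for i, (la, lo) in enumerate(points)])
    return Trajectory(site_id, pd.Timestamp(init), direction, pts)


def make_ensemble(trajs, direction="forward"):
    return TrajectoryEnsemble(list(trajs), direction)


def occ_table(records):
    """OccurrenceTable from (site_id, period_id, count) triples."""
    return OccurrenceTable(
        pd.DataFrame(records, columns=["site_id", "period_id", "count"]))
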