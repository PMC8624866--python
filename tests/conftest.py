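import numpy as np
import pytest

from gwmap import marinduque_fixture
from gwmap.geostat import VariogramModel
from gwmap.synthetic import FieldSpec, make_survey


@pytest.fixture(scope="session")
def stations():
    """The 36-station Marinduque geometry, projected to UTM 51N."""
    return marinduque_fixture()


@pytest.fixture(scope="session")
def survey():
    """One seeded synthetic survey on the Marinduque geometry."""
    sv, truth, aux = make_survey(FieldSpec(seed=42))
    return sv, truth, aux


@pytest.fixture()
def toy_survey():
    """Tiny deterministic survey on a unit-ish grid for oracle checks."""
    import pandas as pd

    from gwmap import SampleSet

    xy = np.array([
        [0.0, 0.0], [1000.0, 0.0], [0.0, 1000.0], [1000.0, 1000.0],
        [500.0, 500.0], [250.0, 750.0], [800.0, 300.0],
    ])
    z = np.array([0.0, 1.0, 2.0, 3.0, 1.5, 1.2, 0.9])
    df = pd.DataFrame({
        "station_id": [f"T{i}" for i in range(len(xy))],
        "lon": 121.0, "lat": 13.0, "season": "dry",
        "x": xy[:, 0], "y": xy[:, 1], "Cd": z,
    })
    return SampleSet(df)


def spherical_vm(nugget=0.0, sill=1.0, range_=800.0):
    return VariogramModel("spherical", nugget=nugget, partial_sill=sill,
                          range_=range_)
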