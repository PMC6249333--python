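import io

import numpy as np
import pandas as pd
import pytest

from morphokey.measurement_io import MEASUREMENT_CODES, MeasurementTable
from morphokey.synth import SyntheticSpec, simulate_measurements


def make_table(values, species=None, ids=None, variables=None, side=None):
    """Build a MeasurementTable from a plain nested list."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    ids = ids or [f"sp{i + 1}" for i in range(n)]
    variables = variables or list(MEASUREMENT_CODES[:p])
    species = species or ["X"] * n
    side = side or ["left"] * n
    return MeasurementTable(
        data=pd.DataFrame(values, index=ids, columns=variables),
        species=pd.Series(species, index=ids),
        side=pd.Series(side, index=ids),
    )


@pytest.fixture
def small_table():
    return make_table(
        [
            [100, 200, 400, 80],
            [110, 210, 390, 82],
            [95, 190, 410, 79],
            [105, 205, 405, 81],
        ],
        species=["X", "X", "Y", "Y"],
        variables=["ant.l", "eye.d", "gst.b", "pol.l"],
    )


@pytest.fixture
def planted_spec():
    """Two groups of 30, contrast of +/-3 noise SD planted on (ant.l, ool.l)."""
    return SyntheticSpec(
        groups=(("A", 30), ("B", 30)),
        planted_pair=("ant.l", "ool.l"),
        planted_delta=0.06,
        noise_sd=0.02,
        seed=11,
    )


@pytest.fixture
def planted_table(planted_spec):
    return simulate_measurements(planted_spec)


def csv_stream(text: str) -> io.StringIO:
    return io.StringIO(text)
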