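import numpy as np
import pandas as pd
import pytest

from wormtrace import EmbryoTable, SimulationParams, simulate_embryo


def make_table(rows, embryo_id="emb", units="pixel", time_units="ordinal",
               expr_columns=None):
    """Build an EmbryoTable from a list of row dicts."""
    df = pd.DataFrame(rows)
    return EmbryoTable(data=df, embryo_id=embryo_id, units=units,
                       time_units=time_units, expr_columns=expr_columns)


def rowd(cell, time, x=0.0, y=0.0, z=0.0, **expr):
    return {"cell": cell, "time": time, "x": x, "y": y, "z": z, **expr}


@pytest.fixture(scope="session")
def sim_default():
    """One default synthetic embryo (acquired table + ground truth), shared
    read-only across tests."""
    return simulate_embryo(SimulationParams(), seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


# A hand-constructed embryo already in canonical pose: centroid at the
# origin, covariance exactly diagonal (z/y values come in +- pairs at equal
# x), the default landmark groups exactly on their target half-axes.  The
# orientation fit on it must be the identity.
CANONICAL_POINTS = [
    ("ABal", 17.2, 0.0, 0.0),
    ("ABpl", 7.2, 0.0, 0.0),
    ("Cap", -7.8, 0.0, 0.0),
    ("Cpp", -11.8, 0.0, 0.0),
    ("Caaa", -0.8, 0.0, 5.0),
    ("Cpaa", -2.8, 0.0, 5.0),
    ("Eaa", -0.8, 0.0, -5.0),
    ("Epa", -2.8, 0.0, -5.0),
    ("MSap", 1.2, -5.0, 0.0),
    ("MSpp", 1.2, 5.0, 0.0),
]


@pytest.fixture()
def canonical_table():
    rows = [rowd(c, 1, x, y, z) for c, x, y, z in CANONICAL_POINTS]
    return make_table(rows, units="micron", expr_columns=())
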