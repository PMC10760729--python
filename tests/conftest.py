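import numpy as np
import pytest

from hospisite import ODMatrix, generate_city


def line_od(demand_pos, facility_pos, cutoff_h=None):
    """OD matrix for points on a line where travel time equals distance.

    The simplest geometry where shortest paths are known in closed form;
    used as the hand-checkable substrate for the solver examples.
    """
    times = np.abs(
        np.asarray(demand_pos, dtype=float)[:, None]
        - np.asarray(facility_pos, dtype=float)[None, :]
    )
    return ODMatrix(
        demand_ids=list(range(len(demand_pos))),
        facility_ids=list(range(len(facility_pos))),
        times=times,
        cutoff_h=cutoff_h,
    )


@pytest.fixture(scope="session")
def city200():
    """A 200-node synthetic city reused by read-only tests."""
    return generate_city(n_nodes=200, n_districts=50, n_facilities=5, seed=7)


@pytest.fixture(scope="session")
def city_remote():
    """110-district city where exactly 16 districts sit beyond a 6 h cut-off."""
    return generate_city(n_nodes=200, n_districts=110, n_facilities=5,
                         n_remote=16, seed=11)
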