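import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from decyto import (
    AcquisitionConfig,
    ChannelGeometry,
    PopulationSpec,
    TransitSimulation,
    coordinate_frame,
    default_strip_acquisition,
    estimate_background,
    measure_stack,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def geom():
    return ChannelGeometry()


@pytest.fixture(scope="session")
def strip_acq():
    return default_strip_acquisition()


@pytest.fixture(scope="session")
def strip_coord(geom, strip_acq):
    return coordinate_frame(geom, strip_acq)


@pytest.fixture(scope="session")
def bead_sim(geom, strip_acq):
    """A short rigid-bead recording (~30 transits), rendered once."""
    return TransitSimulation(
        PopulationSpec.beads(), geom, strip_acq, duration_s=0.3, seed=11
    )


@pytest.fixture(scope="session")
def bead_measured(bead_sim, geom, strip_acq):
    records, tracks, counts = measure_stack(bead_sim, geom, strip_acq, "beads")
    return records, tracks, counts


@pytest.fixture(scope="session")
def cell_sim(geom, strip_acq):
    """A short deformable-cell recording (~50 transits), rendered once."""
    return TransitSimulation(
        PopulationSpec.cells(), geom, strip_acq, duration_s=0.5, seed=5
    )


@pytest.fixture(scope="session")
def cell_measured(cell_sim, geom, strip_acq):
    records, tracks, counts = measure_stack(cell_sim, geom, strip_acq, "cells")
    return records, tracks, counts


@pytest.fixture(scope="session")
def cell_background(cell_sim):
    return estimate_background(cell_sim)
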