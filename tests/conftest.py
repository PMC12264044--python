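"""Shared fixtures: small synthetic tissues generated once per session."""

import numpy as np
import pandas as pd
import pytest

from spleenniche import synthgeom as sg


@pytest.fixture(scope="session")
def bare_disk():
    """Disk with 500 μm capsule-free core, no internal structures, 2 μm px.

    The analytic reference geometry: distances to the capsule's inner edge
    follow the annulus-area law of a disk of radius 500.
    """
    params = sg.GeometryParams(shape="disk", a=502.0, b=502.0,
                               capsule_width=2.0, pixel_size=2.0,
                               n_trabeculae=0, n_wp_discs=0,
                               vessel_density_rp=0.0, vessel_density_wp=0.0,
                               lymph_density_rp=0.0, seed=0)
    return sg.make_tissue(params)


@pytest.fixture(scope="session")
def steady_tissue():
    """Default ellipse cross-section of the steady-state scenario."""
    geom, _, _ = sg.scenario("steady_female")
    return sg.make_tissue(geom)


@pytest.fixture(scope="session")
def steady_cells(steady_tissue):
    """Three images of pHSC-profile cells under the steady female law."""
    _, place, _ = sg.scenario("steady_female")
    tables = [sg.plant_cells(steady_tissue, place, seed=100 + i,
                             image_id=f"img{i}", animal_id=f"m{i}")
              for i in range(3)]
    return pd.concat(tables, ignore_index=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
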