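"""Shared fixtures: a scaled-down slab geometry and meshes sized for tests."""

import numpy as np
import pytest

from cortistim.scenario_geometry import (
    ElectrodeSpec,
    SlabParams,
    build_slab_geometry,
    generate_mesh,
    place_electrodes,
)


@pytest.fixture(scope="session")
def small_params():
    """Slab shrunk for test speed; same topology as the default geometry."""
    return SlabParams(
        sulcal_depth=10.0,
        crown_to_crown_path_length=40.0,
        extrusion_length_z=20.0,
        x_half_extent=16.0,
        wm_margin=6.0,
    )


@pytest.fixture(scope="session")
def small_geom(small_params):
    return build_slab_geometry(small_params)


@pytest.fixture(scope="session")
def small_geom_electrodes(small_geom):
    specs = [
        ElectrodeSpec(center_x=-6.0, center_z=-6.5, role="active"),
        ElectrodeSpec(center_x=-6.0, center_z=6.5, role="return"),
    ]
    return place_electrodes(small_geom, specs)


@pytest.fixture(scope="session")
def small_mesh(small_geom_electrodes):
    return generate_mesh(small_geom_electrodes, resolution=1.5)


@pytest.fixture(scope="session")
def homogeneous_box_mesh():
    """Electrode-free box mesh used for the analytic point-source oracle."""
    params = SlabParams(
        sulcal_depth=6.0,
        crown_to_crown_path_length=18.0,
        extrusion_length_z=24.0,
        x_half_extent=12.0,
        wm_margin=10.0,
    )
    geom = build_slab_geometry(params)
    return generate_mesh(geom, resolution=1.5, coarse_factor=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20160607)
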