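import warnings

import numpy as np
import pytest
import trimesh

from osteoplan import phantom


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def study_case_coarse():
    """Study-case phantom at coarse meshing: fast, still sub-0.1 mm
    accurate for registration-level checks."""
    return phantom.fixture("study_case", mesh_pitch=0.8)


@pytest.fixture(scope="session")
def clean_case_coarse():
    return phantom.fixture("clean", mesh_pitch=0.8)


@pytest.fixture(scope="session")
def ellipsoid():
    """Generic asymmetric watertight test solid."""
    m = trimesh.creation.icosphere(subdivisions=3, radius=12.0)
    m.vertices[:, 1] *= 1.4
    m.vertices[:, 2] *= 0.8
    return trimesh.Trimesh(m.vertices, m.faces)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
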