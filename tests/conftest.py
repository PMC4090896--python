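import pytest

from skinslide import (RoiGeometry, build_roi_mesh, build_verification_mesh)


@pytest.fixture(scope="session")
def roi_mesh_coarse():
    """A small but complete region-of-interest mesh (fast fixture density)."""
    from skinslide.experiments import density_ladder
    return build_roi_mesh(RoiGeometry(), density_ladder(3)[0])


@pytest.fixture(scope="session")
def patch_fixture():
    return build_verification_mesh("patch_test")


@pytest.fixture(scope="session")
def strip_fixture():
    return build_verification_mesh("uniaxial_strip")
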