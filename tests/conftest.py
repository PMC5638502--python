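import numpy as np
import pytest

from hemoradar import dielectrics as dl, fields, phantom as ph


@pytest.fixture(scope="session")
def blood_1ghz():
    return dl.tissue_properties("blood", 1e9)


@pytest.fixture(scope="session")
def wm_1ghz():
    return dl.tissue_properties("white_matter", 1e9)


@pytest.fixture
def calibrated_dipole(wm_1ghz):
    """Near-field dipole source in white matter, calibrated at 1 GHz."""
    src = fields.SourceModel(kind="short_dipole", position=(0.0, 0.0, -0.095),
                             background_props=wm_1ghz)
    return fields.calibrate_source(src, 1e9)


def local_phantom(lesion_radius, center, spacing, margin=2,
                  background_label=4):
    """Uniform white-matter grid just covering a lesion neighborhood.

    Keeps voxel counts small for refinement/convergence tests that do
    not need the full layered head.
    """
    n = int(np.ceil(2 * (lesion_radius + margin * spacing) / spacing))
    origin = np.asarray(center) - spacing * n / 2.0
    labels = np.full((n, n, n), background_label, dtype=np.int8)
    return ph.VoxelPhantom(spacing, origin, labels)
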