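import numpy as np
import pytest

from flexbuild import load_library, make_fixture
from flexbuild.density import RingerTrace


@pytest.fixture(scope="session")
def library():
    return load_library()


@pytest.fixture(scope="session")
def serine_fixture(tmp_path_factory):
    return make_fixture("serine_70_30", tmp_path_factory.mktemp("fx_ser"),
                        seed=1)


@pytest.fixture(scope="session")
def met_fixture(tmp_path_factory):
    return make_fixture("methionine_chi3_split",
                        tmp_path_factory.mktemp("fx_met"), seed=1)


@pytest.fixture(scope="session")
def single_fixture(tmp_path_factory):
    return make_fixture("single_conformer",
                        tmp_path_factory.mktemp("fx_one"), seed=1)


def make_trace(values, step=10.0, residue_id=("A", 1, " ", "SER"),
               chi_index=1, probe="OG"):
    """Helper: wrap raw sample values into a RingerTrace."""
    values = np.asarray(values, dtype=float)
    angles = np.arange(0.0, 360.0, step)
    assert len(angles) == len(values)
    return RingerTrace(residue_id, chi_index, angles, values, probe)


def gaussian_bump(centre, height, width_deg=25.0, step=10.0, baseline=0.0):
    """Circular Gaussian bump trace values on a [0, 360) grid."""
    angles = np.arange(0.0, 360.0, step)
    d = np.abs((angles - centre + 180.0) % 360.0 - 180.0)
    return baseline + height * np.exp(-0.5 * (d / width_deg) ** 2)
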