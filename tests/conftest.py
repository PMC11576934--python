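import numpy as np
import pytest

from hypoparc.lut_io import LookupTable, LutEntry, Volume, default_lut, toy_lut


@pytest.fixture(scope="session")
def lut24():
    return default_lut()


@pytest.fixture(scope="session")
def lut_toy():
    return toy_lut()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_volume(data, voxel_size=(1.0, 1.0, 1.0), modality="T1"):
    data = np.asarray(data)
    affine = np.diag(list(voxel_size) + [1.0])
    # RAS diag affine -> axis codes (R, A, S); conform will reorient
    return Volume(data, voxel_size, affine, modality)


@pytest.fixture()
def pairless_lut():
    return LookupTable(
        [
            LutEntry(1, "A", "others", None, (10, 10, 10)),
            LutEntry(2, "B", "optic", None, (20, 20, 20)),
        ]
    )
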