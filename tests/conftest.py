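import numpy as np
import pytest

from fragsite.structure_io import Triplet
from fragsite.synthetic_fixtures import (
    FixtureSpec,
    generate_ideal_backbone,
    make_toy_dataset,
)


@pytest.fixture(autouse=True)
def _quiet_triplet_warnings():
    """Noisy synthetic triplets legitimately violate ideal bond lengths."""
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="unusual .* bond length")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def ideal_triplet():
    return Triplet(
        n_coord=np.array([1.458, 0.0, 0.0]),
        ca_coord=np.array([0.0, 0.0, 0.0]),
        c_coord=np.array([-0.546, 1.424, 0.0]),
    )


def random_triplet(rng):
    """A validly bonded triplet at a random pose."""
    from scipy.spatial.transform import Rotation

    base = np.array(
        [[1.458, 0.0, 0.0], [0.0, 0.0, 0.0], [-0.546, 1.424, 0.0]]
    )
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-20, 20, 3)
    coords = base @ R.T + t
    return Triplet(*coords)


@pytest.fixture
def helix_chain():
    spec = FixtureSpec(20, "H" * 20, "A" * 20, 0.0, 7)
    return generate_ideal_backbone(spec)


@pytest.fixture
def strand_chain():
    spec = FixtureSpec(20, "E" * 20, "A" * 20, 0.0, 7)
    return generate_ideal_backbone(spec)


@pytest.fixture(scope="session")
def toy_small():
    """A 4-protein toy dataset shared across tests (cheap, deterministic)."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_toy_dataset(4, seed=11)


GLY_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.004   1.424   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def gly_pdb_text():
    return GLY_PDB
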