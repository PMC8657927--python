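import numpy as np
import pytest

from grindqsar.compounds import Molecule3D
from grindqsar.syndata import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 12-compound synthetic dataset shared by tests that only need
    'some realistic molecules + activities' (generated once per session)."""
    cfg = GeneratorConfig(n_compounds=12, seed=7)
    molecules, records, truth, dm = generate_dataset(cfg)
    return {"config": cfg, "molecules": molecules, "records": records,
            "truth": truth, "dm": dm}


@pytest.fixture
def toy_molecule():
    """A small hand-built fragment: carbonyl C=O with a clear approach
    direction, plus a hydroxyl O-H on the other side."""
    return Molecule3D(
        compound_id="toy",
        elements=["C", "O", "C", "O", "H", "C"],
        coords=np.array([
            [0.0, 0.0, 0.0],    # carbonyl C
            [1.2, 0.0, 0.0],    # carbonyl O (points +x, unobstructed)
            [-1.5, 0.0, 0.0],   # carrier C
            [-2.2, 1.2, 0.0],   # hydroxyl O
            [-2.0, 2.1, 0.3],   # hydroxyl H
            [-1.8, -1.4, 0.0],  # lone carbon
        ]),
        charges=np.array([0.3, -0.4, 0.0, -0.3, 0.25, 0.0]),
        bonds=[(0, 1, 2), (0, 2, 1), (2, 3, 1), (3, 4, 1), (2, 5, 1)],
    )


def random_rotation(seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
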