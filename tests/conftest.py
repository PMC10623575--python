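import numpy as np
import pytest

from lrip.synthetic import ToyComplexSpec, make_toy_complex


@pytest.fixture(scope="session")
def toy_spec() -> ToyComplexSpec:
    return ToyComplexSpec(
        n_residues=8,
        atoms_per_residue=3,
        n_ligand_atoms=6,
        n_snapshots=5,
        jitter_sd=0.15,
        seed=1,
    )


@pytest.fixture(scope="session")
def toy_ensemble(toy_spec):
    return make_toy_complex(toy_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
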