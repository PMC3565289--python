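import numpy as np
import pytest

from mqsar.structio import MolecularSystem, perceive_bonds
from mqsar.surrogate_qsar import GAConfig
from mqsar.synthetic import make_toy_pocket, simulate_qsar_dataset


def chain_molecule(elements, spacing=1.5, hetero=True, resname="LIG",
                   chain="L", resseq=1):
    """Linear test molecule with the given elements, bonds perceived."""
    n = len(elements)
    coords = np.zeros((n, 3))
    coords[:, 0] = np.arange(n) * spacing
    system = MolecularSystem(
        serials=np.arange(1, n + 1),
        names=[f"{el}{i}" for i, el in enumerate(elements, 1)],
        elements=elements, residue_names=[resname] * n,
        chain_ids=[chain] * n, residue_seqs=[resseq] * n,
        insertion_codes=[""] * n, coords=coords, is_hetero=[hetero] * n)
    return perceive_bonds(system)


@pytest.fixture(scope="session")
def toy_pocket():
    return make_toy_pocket(n_residues=10, seed=1)


@pytest.fixture(scope="session")
def small_dataset():
    """Small ground-truth QSAR dataset for fast GA exercises."""
    dataset, true_model, manifest = simulate_qsar_dataset(
        n_ligands=20, poses_per_ligand=2, noise_sd=0.0, seed=5,
        envelope_spacing=6.0)
    return dataset, true_model, manifest


@pytest.fixture(scope="session")
def fast_ga_config():
    return GAConfig(population=30, generations=20, family_size=5)
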