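import numpy as np
import pytest

from tfrewire import BindingTensor, BranchPartition, GeneModule
from tfrewire.synthetic import PlantSpec, module51_fixture, plant_tensor


def make_tensor(P, present=None, tfs=None, genes=None, species=None):
    """Small tensor from an explicit (n_tf, n_gene, n_species) array."""
    P = np.asarray(P, dtype=float)
    nt, ng, ns = P.shape
    return BindingTensor(
        tfs or [f"TF{i + 1:03d}" for i in range(nt)],
        genes or [f"g{i + 1:03d}" for i in range(ng)],
        species or [f"sp{i + 1:02d}" for i in range(ns)],
        np.round(P, 8),
        present,
    )


def module_of(tensor, module_id="mod"):
    return GeneModule(module_id, frozenset(tensor.gene_ids))


def split_branch(tensor, k, label=None):
    return BranchPartition.from_members(
        label or str(k), tensor.species_ids[:k], tensor.species_ids
    )


@pytest.fixture(scope="session")
def planted():
    """Default planted fixture: (3,1,19)-block, delta 1.0, noise 0.05."""
    return plant_tensor(PlantSpec(seed=11))


@pytest.fixture(scope="session")
def m51():
    """The flagship-shaped fixture: FHL1/RAP1/SFP1 vs TBF1 on branch 10."""
    return module51_fixture(seed=0)
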