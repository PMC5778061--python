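import numpy as np
import pytest

from ecrscan import build_nss, load_qij
from ecrscan.phylo import RootedTree, TreeNode
from ecrscan.seqio import SequenceRecord


@pytest.fixture(scope="session")
def qij():
    return load_qij()


@pytest.fixture(scope="session")
def nss(qij):
    return build_nss(qij)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_records(rows: dict[str, str]) -> list[SequenceRecord]:
    return [SequenceRecord(id=k, residues=v) for k, v in rows.items()]


def star_tree(labels) -> RootedTree:
    root = TreeNode()
    for label in labels:
        root.add_child(TreeNode(label=label))
    return RootedTree(root)


def random_binary_tree(n_leaves: int, rng: np.random.Generator) -> RootedTree:
    from ecrscan.simulate import sample_yule_tree

    return sample_yule_tree(n_leaves, rng)


@pytest.fixture()
def make_family():
    """Factory for small simulated families with fixed defaults."""
    from ecrscan import SimulationConfig, simulate_family

    def _make(seed=0, **overrides):
        return simulate_family(SimulationConfig(seed=seed, **overrides))

    return _make
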