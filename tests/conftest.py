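import numpy as np
import pytest

from mycophylo import hominid_tree_fixture
from mycophylo.cophylogeny import Alignment
from mycophylo.synthetic_data import SimulationConfig, simulate_cospeciating_sequences


@pytest.fixture
def host_tree():
    return hominid_tree_fixture()


def merge_genus_alignment(alns: dict, genus: str = "GenusSim") -> Alignment:
    """Concatenate per-OTU alignments into one genus-level alignment."""
    ids, seqs, hosts, otus = [], [], [], []
    for a in alns.values():
        ids += a.ids
        seqs += a.seqs
        hosts += a.hosts
        otus += a.otus
    return Alignment(ids, seqs, hosts, genus, otus)


@pytest.fixture
def cospeciating_otus():
    """Five perfectly cospeciating OTU alignments (pi = 0)."""
    cfg = SimulationConfig(seed=11, host_independence=0.0)
    return simulate_cospeciating_sequences(cfg, n_otus=5)


def random_binary_tree(rng: np.random.Generator, n_leaves: int,
                       prefix: str = "t"):
    """Random rooted binary tree with positive branch lengths (newick str)."""
    nodes = [f"{prefix}{i}" for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False), reverse=True)
        a, b = nodes.pop(i), nodes.pop(j)
        la, lb = rng.uniform(0.1, 1.0, 2).round(3)
        nodes.append(f"({a}:{la},{b}:{lb})")
    from skbio import TreeNode

    return TreeNode.read([nodes[0] + ";"], convert_underscores=False)
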