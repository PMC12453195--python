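"""Topological congruence between host phylogeny and mycobiome dendrogram.

Phylosymbiosis is assessed as the matching-cluster (MC) distance between the
rooted host tree and the rooted community dendrogram, normalized by the mean
MC distance to random trees (nMC; 0 = perfect congruence). Significance comes
from the same random-tree null; the companion intraspecific/interspecific
permutation test works directly on the sample distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from skbio import DistanceMatrix, TreeNode


# ---------------------------------------------------------------------------
# matching cluster distance
# ---------------------------------------------------------------------------

def _cluster_masks(tree: TreeNode, bit_of: dict[str, int]) -> list[int]:
    """Bitmask leaf sets of internal, non-root nodes (non-trivial clusters)."""
    masks = []
    memo: dict[int, int] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            memo[id(node)] = 1 << bit_of[node.name]
        else:
            m = 0
            for ch in node.children:
                m |= memo[id(ch)]
            memo[id(node)] = m
            if node.parent is not None:  # exclude the root cluster
                masks.append(m)
    return masks


def _mc_from_masks(m1: list[int], m2: list[int]) -> int:
    """Minimum-cost perfect matching between two cluster sets.

    Cost of pairing clusters is the size of their symmetric difference;
    clusters left unmatched (unequal counts) pair with the empty set at cost
    equal to their size.
    """
    k = max(len(m1), len(m2))
    if k == 0:
        return 0
    a = np.array(m1 + [0] * (k - len(m1)), dtype=object)
    b = np.array(m2 + [0] * (k - len(m2)), dtype=object)
    cost = np.zeros((k, k), dtype=np.int64)
    for i, ci in enumerate(a):
        for j, cj in enumerate(b):
            cost[i, j] = (int(ci) ^ int(cj)).bit_count()
    ri, cj = linear_sum_assignment(cost)
    return int(cost[ri, cj].sum())


def matching_cluster_distance(t1: TreeNode, t2: TreeNode) -> int:
    """MC distance between two rooted trees on the same leaf set.

    Topology-only: branch lengths are ignored. Identical topologies give 0.
    """
    leaves1 = sorted(t.name for t in t1.tips())
    leaves2 = sorted(t.name for t in t2.tips())
    if leaves1 != leaves2:
        diff = sorted(set(leaves1) ^ set(leaves2))
        raise ValueError(f"leaf sets differ: {diff}")
    bit_of = {name: i for i, name in enumerate(leaves1)}
    return _mc_from_masks(_cluster_masks(t1, bit_of), _cluster_masks(t2, bit_of))


# ---------------------------------------------------------------------------
# random-tree null
# ---------------------------------------------------------------------------

def _random_topology_masks(
    bits: list[int], rng: np.random.Generator, model: str,
    include_root: bool = False,
) -> list[int]:
    """Cluster bitmasks of one random rooted binary topology on ``bits``.

    ``yule``: random coalescent/labeled-history merging (equals the Yule
    topology distribution). ``uniform``: uniform over rooted labeled binary
    topologies via sequential attachment to a uniformly chosen edge.
    ``include_root`` keeps the all-leaf cluster (used when the generated tree
    is a subtree of a larger rooted tree).
    """
    n_leaves = len(bits)
    if model == "yule":
        lineages = [1 << b for b in bits]
        masks = []
        while len(lineages) > 1:
            i, j = rng.choice(len(lineages), size=2, replace=False)
            merged = lineages[i] | lineages[j]
            for idx in sorted((int(i), int(j)), reverse=True):
                lineages.pop(idx)
            lineages.append(merged)
            masks.append(merged)
        if not include_root:
            masks.pop()
        return masks
    if model == "uniform":
        # grow by splitting a uniformly chosen edge (edge above any non-root
        # node); uniform over rooted labeled binary topologies
        parent = [-1, 0, 0]            # node 0 = root; 1, 2 = first two leaves
        mask = [0, 1 << bits[0], 1 << bits[1]]
        for leaf in range(2, n_leaves):
            # splitting the root's virtual edge (target = current root)
            # creates a new root, so every topology stays reachable
            target = int(rng.integers(0, len(parent)))
            new_internal = len(parent)
            parent.append(parent[target])
            mask.append(0)
            parent[target] = new_internal
            parent.append(new_internal)
            mask.append(1 << bits[leaf])
        # accumulate leaf masks up to ancestors
        total = [0] * len(parent)
        for i, m in enumerate(mask):
            if m:
                j = i
                while j != -1:
                    total[j] |= m
                    j = parent[j]
        out = [total[i] for i in range(len(parent))
               if mask[i] == 0 and parent[i] != -1]
        if include_root:
            full = 0
            for b in bits:
                full |= 1 << b
            out.append(full)
        return out
    raise ValueError(f"unknown random-tree model {model!r}")


def random_tree_null(
    leaves: list[str],
    reference: TreeNode,
    n: int = 100_000,
    model: str = "yule",
    seed: int | None = None,
    outgroup: str | None = None,
) -> np.ndarray:
    """MC distances from ``n`` random rooted topologies to ``reference``.

    With ``outgroup`` set, random trees are conditioned on that leaf being
    sister to all others (a random ingroup topology attached at the root).
    Use this when both compared trees were deliberately rooted on the same
    outgroup: unconditioned random trees place the outgroup anywhere, which
    makes the test anti-conservative in that design.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if len(leaves) < 4:
        raise ValueError("need at least 4 leaves for a meaningful null")
    rng = np.random.default_rng(seed)
    bit_of = {name: i for i, name in enumerate(sorted(leaves))}
    if outgroup is None:
        bits = list(bit_of.values())
        include_root = False
    else:
        if outgroup not in bit_of:
            raise ValueError(f"outgroup {outgroup!r} not among leaves")
        bits = [b for name, b in bit_of.items() if name != outgroup]
        include_root = True  # the ingroup root is a non-root internal node
    ref_masks = _cluster_masks(reference, bit_of)
    out = np.empty(n, dtype=np.int64)
    for i in range(n):
        out[i] = _mc_from_masks(
            _random_topology_masks(bits, rng, model, include_root=include_root),
            ref_masks)
    return out


@dataclass
class CongruenceResult:
    mc_raw: int
    nmc: float
    p_value: float
    n_random: int
    normalization_constant: float
    model: str


def congruence_test(
    host: TreeNode,
    dendrogram: TreeNode,
    n: int = 100_000,
    model: str = "yule",
    seed: int | None = None,
    outgroup: str | None = None,
) -> CongruenceResult:
    """nMC congruence of a community dendrogram with the host phylogeny.

    The observed MC distance is compared with MC distances between random
    topologies and the dendrogram; p = (1 + #{null <= obs}) / (1 + n), and
    nMC = obs / mean(null). nMC is reported unclipped and may slightly exceed
    1 for trees worse than the random expectation. When both trees were
    rooted on the same outgroup, pass ``outgroup`` to condition the null on
    that rooting; the unconditioned null is anti-conservative there because
    random trees place the outgroup anywhere.
    """
    obs = matching_cluster_distance(host, dendrogram)
    leaves = [t.name for t in dendrogram.tips()]
    null = random_tree_null(leaves, dendrogram, n=n, model=model, seed=seed,
                            outgroup=outgroup)
    norm = float(null.mean())
    p = (1 + int((null <= obs).sum())) / (1 + n)
    nmc = obs / norm if norm > 0 else 0.0
    return CongruenceResult(obs, nmc, p, n, norm, model)


# ---------------------------------------------------------------------------
# intraspecific / interspecific permutation test
# ---------------------------------------------------------------------------

@dataclass
class PermutationTestResult:
    observed_diff: float
    p_two_tailed: float
    nperm: int


def intra_inter_permutation_test(
    dm: DistanceMatrix,
    groups: dict[str, str] | pd.Series,
    nperm: int = 999,
    seed: int | None = None,
) -> PermutationTestResult:
    """Mean interspecific minus mean intraspecific distance, two-tailed.

    Group labels are shuffled ``nperm`` times; the two-tailed p-value counts
    permuted |differences in means| at least as large as the observed one,
    with the add-one correction.
    """
    labels = pd.Series(groups).loc[list(dm.ids)]
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        raise ValueError(f"groups need >=2 members: {dict(counts)}")
    rng = np.random.default_rng(seed)
    d = dm.data
    iu = np.triu_indices(d.shape[0], 1)
    vals = d[iu]
    codes, _ = pd.factorize(labels)

    def diff(code_arr):
        same = code_arr[iu[0]] == code_arr[iu[1]]
        return vals[~same].mean() - vals[same].mean()

    obs = diff(codes)
    hits = 0
    for _ in range(nperm):
        if abs(diff(rng.permutation(codes))) >= abs(obs):
            hits += 1
    return PermutationTestResult(float(obs), (1 + hits) / (1 + nperm), nperm)
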