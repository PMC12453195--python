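"""Beta diversity, jackknife beta-rarefaction, UPGMA dendrograms, PERMANOVA.

Distance matrices are :class:`skbio.DistanceMatrix` objects throughout (which
enforce symmetry, a zero diagonal, and unique labels). Trees are
:class:`skbio.TreeNode`.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.tree import upgma as _skbio_upgma
from statsmodels.stats.multitest import multipletests

from .feature_table import FeatureTable

logger = logging.getLogger(__name__)


def _as_frame(table) -> pd.DataFrame:
    if isinstance(table, FeatureTable):
        return table.counts
    return table


def _check_zero_pairs(df: pd.DataFrame) -> None:
    zero = list(df.columns[df.sum(axis=0) == 0])
    if len(zero) >= 2:
        raise ValueError(
            f"Bray-Curtis/Jaccard undefined for all-zero sample pair: "
            f"{zero[0]!r}, {zero[1]!r}"
        )


def bray_curtis(table) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples (columns).

    BC(x, y) = 1 - 2 sum(min(x_i, y_i)) / (sum x + sum y), in [0, 1].
    """
    df = _as_frame(table)
    _check_zero_pairs(df)
    d = pdist(df.to_numpy().T, metric="braycurtis")
    return DistanceMatrix(squareform(d), ids=list(df.columns))


def jaccard_binary(table) -> DistanceMatrix:
    """Binary Jaccard distance on presence/absence of OTUs."""
    df = _as_frame(table)
    _check_zero_pairs(df)
    presence = df.to_numpy().T > 0
    d = pdist(presence, metric="jaccard")
    return DistanceMatrix(squareform(d), ids=list(df.columns))


_METRICS = {"bray_curtis": bray_curtis, "braycurtis": bray_curtis,
            "jaccard": jaccard_binary}


def beta_rarefaction(
    ft: FeatureTable,
    metric: str = "bray_curtis",
    depth: int = 2000,
    iters: int = 10,
    seed: int | None = None,
) -> DistanceMatrix:
    """Jackknife beta diversity: average the metric over repeated rarefactions.

    Each iteration subsamples every qualifying sample (total >= depth) to
    ``depth`` reads without replacement and computes the metric; the returned
    matrix is the element-wise mean across iterations.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    fn = _METRICS[metric]
    rng = np.random.default_rng(seed)
    c = ft.counts
    totals = c.sum(axis=0)
    kept = [s for s in c.columns if totals[s] >= depth]
    if len(kept) < 2:
        raise ValueError(f"fewer than 2 samples meet depth {depth}")
    sub = c[kept]
    acc = np.zeros((len(kept), len(kept)))
    for _ in range(iters):
        draw = np.empty_like(sub.to_numpy(), dtype=np.int64)
        for j, s in enumerate(kept):
            col = sub[s].to_numpy().astype(np.int64)
            if col.sum() == depth:
                draw[:, j] = col
            else:
                draw[:, j] = rng.multivariate_hypergeometric(col, depth)
        acc += fn(pd.DataFrame(draw, index=sub.index, columns=kept)).data
    return DistanceMatrix(acc / iters, ids=kept)


def upgma(dm: DistanceMatrix) -> TreeNode:
    """Average-linkage (UPGMA) dendrogram; rooted and ultrametric."""
    if np.isnan(dm.data).any():
        raise ValueError("distance matrix contains NaN")
    tree = _skbio_upgma(dm)
    return tree


def outgroup_root(tree: TreeNode, outgroup: str) -> TreeNode:
    """Root a tree on the midpoint of the outgroup's pendant edge.

    If the tree is already rooted with the outgroup as a direct child of the
    root, it is returned unchanged (as a copy). Total branch length is
    preserved.
    """
    names = {t.name for t in tree.tips()}
    if outgroup not in names:
        raise ValueError(f"outgroup {outgroup!r} not among tips {sorted(names)}")
    root_children = [c.name for c in tree.children]
    if outgroup in root_children and len(tree.children) == 2:
        return tree.copy()
    return tree.root_at(outgroup, above=True)


@dataclass
class PermanovaResult:
    F: float
    R2: float
    p_value: float
    n_permutations: int
    df_between: int
    df_within: int


def _permanova_ss(sqd: np.ndarray, group_idx: list[np.ndarray]) -> tuple[float, float]:
    n = sqd.shape[0]
    ss_total = sqd[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for idx in group_idx:
        sub = sqd[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total, ss_within


def permanova(
    dm: DistanceMatrix,
    groups: dict[str, str] | pd.Series,
    nperm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA (Anderson's pseudo-F) with label permutations.

    p = (1 + #{F_perm >= F_obs}) / (1 + nperm).
    """
    labels = pd.Series(groups)
    labels = labels.loc[list(dm.ids)]
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if (counts < 2).any():
        bad = list(counts.index[counts < 2])
        raise ValueError(f"singleton group(s): {bad}")
    rng = np.random.default_rng(seed)
    sqd = dm.data**2
    n = len(labels)
    k = len(counts)
    codes = labels.to_numpy()

    def f_stat(code_arr):
        idx = [np.flatnonzero(code_arr == g) for g in counts.index]
        ss_t, ss_w = _permanova_ss(sqd, idx)
        ss_a = ss_t - ss_w
        return (ss_a / (k - 1)) / (ss_w / (n - k)), ss_a / ss_t

    f_obs, r2 = f_stat(codes)
    hits = 0
    for _ in range(nperm):
        f_perm, _ = f_stat(rng.permutation(codes))
        if f_perm >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + nperm)
    return PermanovaResult(f_obs, r2, p, nperm, k - 1, n - k)


def pairwise_permanova(
    dm: DistanceMatrix,
    groups: dict[str, str] | pd.Series,
    nperm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """PERMANOVA for every group pair, Benjamini-Hochberg adjusted."""
    labels = pd.Series(groups).loc[list(dm.ids)]
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in itertools.combinations(sorted(labels.unique()), 2):
        ids = list(labels.index[labels.isin([a, b])])
        sub = dm.filter(ids)
        res = permanova(sub, labels.loc[ids], nperm=nperm,
                        seed=int(rng.integers(2**31)))
        rows.append({"group_a": a, "group_b": b, "F": res.F, "R2": res.R2,
                     "p_value": res.p_value})
    out = pd.DataFrame(rows)
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
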