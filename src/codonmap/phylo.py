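"""Signal-based phylogenetics.

Equal-length amino-acid signals are compared by the *proportional
deviation*

    d = 1/M * sum_n |a1[n]/20 - a2[n]/20|,

the mean absolute difference of the 20-normalized signals (no alignment
is performed; sequences must already be colinear).  All pairwise
deviations form a distance matrix, trees are built with the Saitou-Nei
neighbor-joining algorithm (scikit-bio's implementation, negative branch
lengths clamped to zero), and topologies are compared with the
Robinson-Foulds distance, normalized by its maximum: the symmetric
difference of non-trivial clade sets over 2(n-2) for rooted trees, of
bipartition sets over 2(n-3) for unrooted trees.

Branch robustness is assessed by bootstrapping signal *columns*: per
replicate the same M positions (sampled with replacement) are taken from
every signal, the distance matrix and NJ tree are rebuilt, and each
internal edge of the full-data tree is annotated with the percentage of
replicates that contain it.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .exceptions import SignalError, TreeError
from .maps import Signal

__all__ = [
    "proportional_deviation",
    "pairwise_distance_matrix",
    "neighbor_joining",
    "rooted_clades",
    "unrooted_bipartitions",
    "normalized_rf_distance",
    "bootstrap_support",
]


def proportional_deviation(a1: Signal | np.ndarray, a2: Signal | np.ndarray) -> float:
    """Mean absolute difference of two 20-normalized amino-acid signals."""
    x = np.asarray(a1, dtype=float)
    y = np.asarray(a2, dtype=float)
    if x.shape != y.shape:
        raise SignalError(
            f"signal length mismatch ({x.shape[0]} vs {y.shape[0]}): "
            "signals must be pre-aligned to equal length"
        )
    if x.size == 0:
        raise SignalError("proportional deviation requires non-empty signals")
    return float(np.mean(np.abs(x / 20.0 - y / 20.0)))


def _signal_arrays(signals: Mapping[str, Signal | np.ndarray]) -> dict[str, np.ndarray]:
    arrays = {str(k): np.asarray(v, dtype=float) for k, v in signals.items()}
    if len(arrays) != len(signals):
        raise SignalError("duplicate taxon labels in signal set")
    lengths = {k: a.shape[0] for k, a in arrays.items()}
    if len(set(lengths.values())) > 1:
        raise SignalError(f"signals have unequal lengths: {lengths}")
    return arrays


def pairwise_distance_matrix(
    signals: Mapping[str, Signal | np.ndarray]
) -> DistanceMatrix:
    """Symmetric matrix of proportional deviations over all signal pairs."""
    arrays = _signal_arrays(signals)
    if len(arrays) < 3:
        raise SignalError("need at least 3 signals to build a distance matrix")
    labels = list(arrays)
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = proportional_deviation(arrays[labels[i]], arrays[labels[j]])
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids=labels)


def neighbor_joining(
    dm: DistanceMatrix, outgroup: str | None = None
) -> TreeNode:
    """Saitou-Nei NJ tree; negative branch lengths are clamped to zero.

    The result is unrooted (trifurcating root node) unless ``outgroup``
    names a taxon, in which case the tree is rooted on that taxon's
    pendant edge.
    """
    if np.allclose(dm.data, 0):
        warnings.warn("all pairwise distances are zero; returning a star tree")
        tree = TreeNode(children=[TreeNode(name=i, length=0.0) for i in dm.ids])
    else:
        tree = nj(dm, neg_as_zero=True)
        for node in tree.traverse():
            if node.length is not None and node.length < 0:  # pragma: no cover
                node.length = 0.0
    if outgroup is not None:
        if outgroup not in dm.ids:
            raise TreeError(f"outgroup {outgroup!r} is not among the taxa")
        tree = tree.root_by_outgroup([outgroup])
    return tree


def _tip_names(tree: TreeNode) -> frozenset[str]:
    names = [t.name for t in tree.tips()]
    if len(set(names)) != len(names):
        raise TreeError("tree has duplicate leaf labels")
    return frozenset(names)


def rooted_clades(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial clades: leaf sets of internal nodes below the root."""
    all_tips = _tip_names(tree)
    clades = set()
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        if 1 < len(clade) < len(all_tips):
            clades.add(clade)
    return clades


def unrooted_bipartitions(tree: TreeNode) -> set[frozenset[frozenset[str]]]:
    """Non-trivial bipartitions induced by the internal edges of a tree."""
    all_tips = _tip_names(tree)
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_tips) - 1:
            parts.add(frozenset({side, all_tips - side}))
    return parts


def normalized_rf_distance(t1: TreeNode, t2: TreeNode, rooted: bool = True) -> float:
    """Robinson-Foulds distance normalized to [0, 1].

    Rooted mode (default) compares clade sets and divides the symmetric
    difference by 2(n-2); unrooted mode compares bipartitions and
    divides by 2(n-3).
    """
    tips1, tips2 = _tip_names(t1), _tip_names(t2)
    if tips1 != tips2:
        raise TreeError(
            f"leaf sets differ: only in first {sorted(tips1 - tips2)}, "
            f"only in second {sorted(tips2 - tips1)}"
        )
    n = len(tips1)
    if rooted:
        if any(len(t.root().children) != 2 for t in (t1, t2)):
            raise TreeError(
                "rooted RF distance requires bifurcating roots; "
                "root the trees (e.g. on an outgroup) first"
            )
        sets1, sets2 = rooted_clades(t1), rooted_clades(t2)
        denom = 2 * (n - 2)
    else:
        sets1, sets2 = unrooted_bipartitions(t1), unrooted_bipartitions(t2)
        denom = 2 * (n - 3)
    if denom <= 0:
        return 0.0
    return len(sets1 ^ sets2) / denom


def bootstrap_support(
    signals: Mapping[str, Signal | np.ndarray],
    replicates: int = 1000,
    seed: int | np.random.Generator = 0,
    outgroup: str | None = None,
) -> TreeNode:
    """NJ tree with bootstrap support percentages on its internal nodes.

    Each replicate resamples the M signal positions with replacement
    (the same column choice for every taxon), rebuilds the distance
    matrix and NJ tree, and scores every internal edge of the full-data
    tree by the percentage of replicates containing it (as a clade when
    an outgroup roots the trees, as a bipartition otherwise).  Supports
    are stored as integer-percent internal node names, so they appear as
    standard node labels in Newick output.
    """
    if replicates < 1:
        raise ValueError("bootstrap requires at least one replicate")
    arrays = _signal_arrays(signals)
    if len(arrays) < 4:
        raise SignalError("bootstrap support requires at least 4 signals")
    rng = np.random.default_rng(seed)
    m = next(iter(arrays.values())).shape[0]

    tree = neighbor_joining(pairwise_distance_matrix(arrays), outgroup=outgroup)
    rooted = outgroup is not None
    splits_of = rooted_clades if rooted else unrooted_bipartitions
    reference = splits_of(tree)
    counts = dict.fromkeys(reference, 0)
    for _ in range(replicates):
        columns = rng.integers(0, m, size=m)
        resampled = {k: a[columns] for k, a in arrays.items()}
        rep_tree = neighbor_joining(
            pairwise_distance_matrix(resampled), outgroup=outgroup
        )
        rep_splits = splits_of(rep_tree)
        for split in reference:
            if split in rep_splits:
                counts[split] += 1

    all_tips = _tip_names(tree)
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        if rooted:
            key = clade if 1 < len(clade) < len(all_tips) else None
        else:
            key = (
                frozenset({clade, all_tips - clade})
                if 1 < len(clade) < len(all_tips) - 1
                else None
            )
        if key is not None and key in counts:
            node.name = str(round(100.0 * counts[key] / replicates))
    return tree
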