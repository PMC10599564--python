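"""Dendrograms from model two-site probabilities and tree comparisons.

Species are compared through the Euclidean distance between their models'
vectorized two-site probability tables P_ij (36 pairs x 16 letter pairs = 576
entries), clustered by complete linkage.  The resulting dendrogram is compared
with a reference (time) tree via cophenetic correlation, Fowlkes-Mallows Bk
indices with a permutation null, and tanglegram entanglement after a two-sided
stepwise untangling heuristic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

from .model import PottsModel, model_marginals


def pij_feature_vector(model: PottsModel) -> np.ndarray:
    """Model two-site probabilities flattened in the fixed pair order (576,)."""
    return model_marginals(model).f2.ravel().copy()


@dataclass
class Dendrogram:
    """Agglomerative merge tree over labelled leaves (scipy linkage format)."""

    linkage: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.linkage.shape != (n - 1, 4):
            raise ValueError("linkage shape inconsistent with label count")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def cophenetic_matrix(self) -> np.ndarray:
        """Pairwise merge-height distances, square form, label order."""
        return squareform(hierarchy.cophenet(self.linkage))

    def cut(self, k: int) -> dict[str, int]:
        """Partition the leaves into k clusters (cut across merge heights)."""
        if not 1 <= k <= self.n_leaves:
            raise ValueError(f"k must be in [1, {self.n_leaves}], got {k}")
        assignment = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in assignment)))


def complete_linkage(dist: np.ndarray, labels: list[str]) -> Dendrogram:
    """Complete-linkage agglomeration of a symmetric distance matrix.

    Labels are sorted internally so that distance ties resolve toward the
    lexicographically smallest pair.
    """
    dist = np.asarray(dist, dtype=float)
    if np.isnan(dist).any():
        raise ValueError("distance matrix contains NaN")
    if dist.shape != (len(labels), len(labels)):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(dist, dist.T) or np.abs(np.diag(dist)).max(initial=0) > 0:
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    order = np.argsort(np.asarray(labels, dtype=object))
    labels_sorted = [labels[k] for k in order]
    dist = dist[np.ix_(order, order)]
    Z = hierarchy.linkage(squareform(dist, checks=False), method="complete")
    return Dendrogram(Z, labels_sorted)


def panel_distance_matrix(models: dict[str, PottsModel]) -> tuple[np.ndarray, list[str]]:
    """Euclidean distances between species' vectorized P_ij tables."""
    labels = sorted(models)
    X = np.stack([pij_feature_vector(models[sp]) for sp in labels])
    return squareform(pdist(X, metric="euclidean")), labels


def pij_dendrogram(models: dict[str, PottsModel]) -> Dendrogram:
    """Complete-linkage dendrogram of species from model P_ij distances."""
    dist, labels = panel_distance_matrix(models)
    return complete_linkage(dist, labels)


def _tree_cophenetic(tree: dendropy.Tree, labels: list[str]) -> np.ndarray:
    """Patristic (path-length) distance matrix of a tree in label order."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    missing = [lab for lab in labels if lab not in taxa]
    if missing:
        raise ValueError(f"labels missing from tree: {missing}")
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return D


def _leaf_labels(obj) -> list[str]:
    if isinstance(obj, Dendrogram):
        return list(obj.labels)
    return [lf.taxon.label for lf in obj.leaf_node_iter() if lf.taxon is not None]


def _cophenetic_in_order(obj, labels: list[str]) -> np.ndarray:
    if isinstance(obj, Dendrogram):
        D = obj.cophenetic_matrix()
        pos = {lab: k for k, lab in enumerate(obj.labels)}
        idx = [pos[lab] for lab in labels]
        return D[np.ix_(idx, idx)]
    return _tree_cophenetic(obj, labels)


def as_dendrogram(obj) -> Dendrogram:
    """View a tree as a dendrogram (complete linkage on patristic distances).

    For an ultrametric time tree the cophenetic matrix is itself ultrametric,
    so the linkage reproduces the tree's hierarchy exactly.
    """
    if isinstance(obj, Dendrogram):
        return obj
    labels = sorted(_leaf_labels(obj))
    return complete_linkage(_tree_cophenetic(obj, labels), labels)


def cophenetic_correlation(a, b) -> float:
    """Pearson correlation of the two cophenetic distance matrices.

    Accepts Dendrograms and/or dendropy Trees (patristic distances); the leaf
    label sets must match.
    """
    la, lb = set(_leaf_labels(a)), set(_leaf_labels(b))
    if la != lb:
        raise ValueError(
            f"label mismatch: only in first {sorted(la - lb)}, "
            f"only in second {sorted(lb - la)}"
        )
    labels = sorted(la)
    Da = _cophenetic_in_order(a, labels)
    Db = _cophenetic_in_order(b, labels)
    iu = np.triu_indices(len(labels), k=1)
    return float(pearsonr(Da[iu], Db[iu])[0])


def bk_index(va: np.ndarray, vb: np.ndarray) -> float:
    """Fowlkes-Mallows index Bk = Tk / sqrt(Pk * Qk) of two flat partitions."""
    va = np.asarray(va)
    vb = np.asarray(vb)
    n = va.size
    _, ia = np.unique(va, return_inverse=True)
    _, ib = np.unique(vb, return_inverse=True)
    N = np.zeros((ia.max() + 1, ib.max() + 1))
    np.add.at(N, (ia, ib), 1.0)
    tk = float((N**2).sum() - n)
    pk = float((N.sum(axis=1) ** 2).sum() - n)
    qk = float((N.sum(axis=0) ** 2).sum() - n)
    if pk <= 0 or qk <= 0:
        return 0.0
    return tk / math.sqrt(pk * qk)


def fowlkes_mallows_bk(
    a,
    b,
    k_range,
    n_perm: int = 10000,
    seed: int = 0,
) -> dict[int, dict[str, float]]:
    """Fowlkes-Mallows Bk between k-cluster cuts, with a relabelling null.

    For each k both hierarchies are cut into k clusters and
    Bk = Tk / sqrt(Pk * Qk) computed; the null shuffles one side's labels
    n_perm times (vectorized), p = (1 + #{null >= Bk}) / (1 + n_perm).
    """
    da, db = as_dendrogram(a), as_dendrogram(b)
    if set(da.labels) != set(db.labels):
        raise ValueError("label mismatch between the two hierarchies")
    labels = sorted(da.labels)
    n = len(labels)
    rng = np.random.default_rng(seed)
    out: dict[int, dict[str, float]] = {}
    for k in k_range:
        k = int(k)
        if not 2 <= k <= n - 1:
            raise ValueError(f"k must be in [2, {n - 1}], got {k}")
        ca = da.cut(k)
        cb = db.cut(k)
        va = np.array([ca[lab] for lab in labels]) - 1
        vb = np.array([cb[lab] for lab in labels]) - 1
        bk = bk_index(va, vb)
        ka, kb = int(va.max()) + 1, int(vb.max()) + 1
        perms = rng.permuted(np.tile(vb, (n_perm, 1)), axis=1)
        N = np.zeros((n_perm, ka, kb))
        np.add.at(
            N,
            (np.repeat(np.arange(n_perm), n), np.tile(va, n_perm), perms.ravel()),
            1.0,
        )
        tk = (N**2).sum(axis=(1, 2)) - n
        pk = (N.sum(axis=2) ** 2).sum(axis=1) - n
        qk = (N.sum(axis=1) ** 2).sum(axis=1) - n
        denom = np.sqrt(np.maximum(pk * qk, 0.0))
        null = np.where(denom > 0, tk / np.where(denom > 0, denom, 1.0), 0.0)
        p = (1.0 + float(np.sum(null >= bk - 1e-12))) / (1.0 + n_perm)
        out[k] = {"bk": bk, "p": p}
    return out


# -- tanglegram entanglement -------------------------------------------------

class _RotatableTree:
    """Binary merge tree from a linkage matrix whose nodes can be flipped."""

    def __init__(self, dendro: Dendrogram):
        n = dendro.n_leaves
        self.n = n
        self.left = {}
        self.right = {}
        for k, row in enumerate(dendro.linkage):
            self.left[n + k] = int(row[0])
            self.right[n + k] = int(row[1])
        self.root = 2 * n - 2 if n > 1 else 0
        self.labels = dendro.labels
        self.flipped: set[int] = set()

    def leaf_order(self) -> list[str]:
        order = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node < self.n:
                order.append(self.labels[node])
                continue
            a, b = self.left[node], self.right[node]
            if node in self.flipped:
                a, b = b, a
            stack.append(b)
            stack.append(a)
        return order

    def internal_nodes(self) -> list[int]:
        return list(range(self.n, 2 * self.n - 1))

    def flip(self, node: int) -> None:
        self.flipped.symmetric_difference_update({node})


def _entanglement_of_orders(order_a, order_b, L: float) -> float:
    n = len(order_a)
    if n < 2:
        return 0.0
    pos_b = {lab: k + 1 for k, lab in enumerate(order_b)}
    ra = np.arange(1, n + 1, dtype=float)
    rb = np.array([pos_b[lab] for lab in order_a], dtype=float)
    worst = np.abs(np.arange(1, n + 1) - np.arange(n, 0, -1)) ** L
    denom = worst.sum()
    if denom == 0:
        return 0.0
    return float((np.abs(ra - rb) ** L).sum() / denom)


def entanglement(
    a: Dendrogram,
    b: Dendrogram,
    *,
    L: float = 1.5,
    untangle: bool = True,
    max_passes: int = 8,
) -> float:
    """Tanglegram entanglement in [0, 1] after two-sided stepwise untangling.

    Leaf rotations (child flips at internal nodes) are searched greedily on
    one side then the other, repeating until no flip improves the layout.
    0 means the two leaf orders can be made identical by rotations alone.
    """
    if set(a.labels) != set(b.labels):
        raise ValueError("label mismatch between dendrograms")
    ta, tb = _RotatableTree(a), _RotatableTree(b)
    best = _entanglement_of_orders(ta.leaf_order(), tb.leaf_order(), L)
    if not untangle:
        return best
    for _ in range(max_passes):
        improved = False
        for tree in (ta, tb):
            for node in tree.internal_nodes():
                tree.flip(node)
                cand = _entanglement_of_orders(ta.leaf_order(), tb.leaf_order(), L)
                if cand < best - 1e-15:
                    best = cand
                    improved = True
                else:
                    tree.flip(node)
        if not improved:
            break
    return best


def comparison_report(
    models: dict[str, PottsModel],
    reference_tree: dendropy.Tree,
    k_range=None,
    n_perm: int = 10000,
    seed: int = 0,
) -> dict:
    """Full dendrogram-vs-tree comparison for a fitted species panel."""
    dend = pij_dendrogram(models)
    n = dend.n_leaves
    if k_range is None:
        k_range = range(2, n)
    bk = fowlkes_mallows_bk(dend, reference_tree, k_range, n_perm=n_perm, seed=seed)
    return {
        "cophenetic_r": cophenetic_correlation(dend, reference_tree),
        "bk": bk,
        "entanglement": entanglement(dend, as_dendrogram(reference_tree)),
        "dendrogram_leaf_order": dend.labels,
    }


def distance_frame(models: dict[str, PottsModel]) -> pd.DataFrame:
    """P_ij distance matrix as a labelled DataFrame (TSV-ready)."""
    dist, labels = panel_distance_matrix(models)
    return pd.DataFrame(dist, index=labels, columns=labels)
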