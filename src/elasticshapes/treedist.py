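"""Class-average shape distances, metric comparison and shape trees.

Mean between-class distances condense an object-level distance matrix into
a K x K class matrix; Pearson correlation between two such matrices says
whether two shape metrics place the classes similarly in shape space; and
neighbour joining on a class matrix yields a tree that, when classes are
taxa, can be read against known higher-level groupings (monophyly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix as _SkbioDM
from skbio import TreeNode
from skbio.tree import nj as _skbio_nj

__all__ = [
    "ClassDistanceMatrix",
    "PhyloTree",
    "class_mean_distances",
    "metric_correlation",
    "neighbour_joining",
    "root_at",
    "monophyly_check",
]


@dataclass
class ClassDistanceMatrix:
    """K x K matrix of mean between-class pairwise distances.

    Off-diagonal entry (a, b) averages all object distances across the two
    classes; the diagonal holds the mean within-class distance, which is
    reported but excluded from correlations and tree building.
    """

    values: np.ndarray
    class_ids: list
    method_tag: str = ""

    def __post_init__(self):
        V = np.asarray(self.values, dtype=float)
        if V.ndim != 2 or V.shape[0] != V.shape[1] or V.shape[0] != len(self.class_ids):
            raise ValueError("values must be K x K matching class_ids")
        if not np.allclose(V, V.T, atol=1e-9):
            raise ValueError("class distance matrix must be symmetric")
        self.values = 0.5 * (V + V.T)

    @property
    def k(self) -> int:
        return self.values.shape[0]

    def off_diagonal(self) -> np.ndarray:
        """Upper-triangular off-diagonal entries, row-major order."""
        iu = np.triu_indices(self.k, 1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.class_ids, columns=self.class_ids)


@dataclass
class PhyloTree:
    """Unrooted or rooted tree over class leaves (scikit-bio TreeNode)."""

    tree: TreeNode
    class_ids: list
    root_taxon: str | None = None

    def leaf_names(self) -> set:
        return {t.name for t in self.tree.tips()}

    def to_newick(self) -> str:
        return str(self.tree).strip()

    def write(self, path) -> None:
        self.tree.write(str(path), format="newick")

    def tip_distances(self) -> pd.DataFrame:
        dm = self.tree.tip_tip_distances()
        return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))


def class_mean_distances(D, labels, method_tag: str = "") -> ClassDistanceMatrix:
    """Average the object distance matrix within and between classes."""
    V = D.values if hasattr(D, "values") and not isinstance(D, np.ndarray) else np.asarray(D, float)
    labels = np.asarray(list(labels))
    if len(labels) != V.shape[0]:
        raise ValueError("labels must cover all objects")
    classes = sorted(np.unique(labels).tolist())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    K = len(classes)
    M = np.zeros((K, K))
    idx = {c: np.flatnonzero(labels == c) for c in classes}
    for a in range(K):
        ia = idx[classes[a]]
        if len(ia) > 1:
            block = V[np.ix_(ia, ia)]
            M[a, a] = block[np.triu_indices(len(ia), 1)].mean()
        for b in range(a + 1, K):
            ib = idx[classes[b]]
            M[a, b] = M[b, a] = V[np.ix_(ia, ib)].mean()
    tag = method_tag or getattr(D, "method_tag", "")
    return ClassDistanceMatrix(M, classes, tag)


def metric_correlation(M1: ClassDistanceMatrix, M2: ClassDistanceMatrix) -> float:
    """Pearson r between two metrics' between-class distances.

    Computed over the K(K-1)/2 off-diagonal entries; the matrices must
    describe the same classes in the same order.
    """
    if M1.class_ids != M2.class_ids:
        raise ValueError("class ids differ between the two matrices")
    if M1.k < 3:
        raise ValueError("correlation needs at least 3 classes")
    r, _ = stats.pearsonr(M1.off_diagonal(), M2.off_diagonal())
    return float(r)


def neighbour_joining(M: ClassDistanceMatrix) -> PhyloTree:
    """Neighbour-joining tree on the between-class distances.

    Standard Q-matrix agglomeration (negative branch-length estimates are
    clamped to zero); within-class diagonal entries are ignored.  Class ids
    are passed in sorted order so ties resolve deterministically.
    """
    if M.k < 3:
        raise ValueError("need at least 3 classes for a tree")
    if not np.all(np.isfinite(M.values)):
        raise ValueError("non-finite distances")
    V = M.values.copy()
    np.fill_diagonal(V, 0.0)
    order = np.argsort(np.asarray(M.class_ids, dtype=object))
    ids = [str(M.class_ids[i]) for i in order]
    dm = _SkbioDM(V[np.ix_(order, order)], ids)
    tree = _skbio_nj(dm, neg_as_zero=True)
    return PhyloTree(tree, list(ids))


def root_at(tree: PhyloTree, taxon: str) -> PhyloTree:
    """Re-root on the edge leading to ``taxon`` (leaf-to-leaf path lengths
    are preserved)."""
    if taxon not in tree.leaf_names():
        raise ValueError(f"unknown taxon {taxon!r}")
    rooted = tree.tree.root_at(taxon, above=True)
    return PhyloTree(rooted, list(tree.class_ids), root_taxon=taxon)


def monophyly_check(tree: PhyloTree, groups: dict) -> dict:
    """Which families form complete subtrees?

    ``groups`` maps every leaf (class) to a family.  A family is
    monophyletic iff some edge of the tree separates exactly that family's
    leaves from all others.
    """
    leaves = tree.leaf_names()
    missing = leaves - set(groups)
    if missing:
        raise ValueError(f"leaves without a family assignment: {sorted(missing)}")
    bipartitions = set()
    for node in tree.tree.traverse(include_self=False):
        side = frozenset(t.name for t in node.tips()) if not node.is_tip() else frozenset({node.name})
        bipartitions.add(side)
        bipartitions.add(frozenset(leaves - side))
    families = sorted({groups[l] for l in leaves})
    return {
        fam: frozenset(l for l in leaves if groups[l] == fam) in bipartitions
        for fam in families
    }
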