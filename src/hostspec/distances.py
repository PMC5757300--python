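"""Host distance machinery.

Four building blocks feed the specificity analysis:

* scaled patristic distances on the host phylogeny (``PDist``),
* Abouheif's C and its topology-derived proximity matrix, used to weight
  niche variables by the inverse of their phylogenetic autocorrelation,
* a mixed-variable weighted Gower distance over continuous, binary and
  fuzzy-composition traits, and
* an ensemble of eight agglomerative dendrograms per niche matrix, whose
  max-scaled cophenetic distances serve as the ecological distance
  (``FDist``) draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .io import DistanceMatrix, HostTree, TraitTable, ValidationError, DEFAULT_LINKAGE_METHODS

logger = logging.getLogger("hostspec")

__all__ = [
    "patristic_distances",
    "abouheif_proximity",
    "abouheif_C",
    "autocorrelation_weights",
    "weighted_gower",
    "Dendrogram",
    "build_dendrogram_ensemble",
]


# ---------------------------------------------------------------------------
# Phylogenetic distances
# ---------------------------------------------------------------------------


def patristic_distances(tree: HostTree, scale: bool = True) -> DistanceMatrix:
    """Pairwise sums of branch lengths between tips, optionally divided by
    the maximum so entries span [0, 1]. Labels are sorted."""
    pdm = tree.dendropy_tree.phylogenetic_distance_matrix()
    labels = tree.tips
    taxa = {t.label: t for t in tree.dendropy_tree.taxon_namespace if t.label in set(labels)}
    n = len(labels)
    vals = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[a], taxa[labels[j]])
            vals[i, j] = vals[j, i] = d
    dm = DistanceMatrix(labels, vals, scaled=False)
    return dm.max_scaled() if scale else dm


def _tip_ancestor_chains(tree: HostTree):
    """Per tip: list of (ancestor id, 1/child-count) from parent up to root."""
    t = tree.dendropy_tree
    chains = {}
    for leaf in t.leaf_node_iter():
        chain = []
        node = leaf.parent_node
        while node is not None:
            chain.append((id(node), 1.0 / len(node.child_nodes())))
            node = node.parent_node
        chains[leaf.taxon.label] = chain
    return chains


def abouheif_proximity(tree: HostTree) -> tuple[list, np.ndarray]:
    """Abouheif's topology-only proximity matrix.

    Off-diagonal ``a_ij`` is the product, over interior nodes on the path
    between tips i and j (most recent common ancestor included), of one over
    that node's number of direct descendants; the diagonal absorbs the
    remainder so every row sums to 1. Branch lengths play no role.
    """
    labels = tree.tips
    chains = _tip_ancestor_chains(tree)
    n = len(labels)
    A = np.zeros((n, n))
    for i in range(n):
        ci = chains[labels[i]]
        anc_i = {nid: k for k, (nid, _) in enumerate(ci)}
        for j in range(i + 1, n):
            cj = chains[labels[j]]
            # walk j's ancestors until the MRCA (first shared node)
            prod = 1.0
            for nid, inv in cj:
                prod *= inv
                if nid in anc_i:
                    mrca = nid
                    break
            # i's ancestors strictly below the MRCA
            for k in range(anc_i[mrca]):
                prod *= ci[k][1]
            A[i, j] = A[j, i] = prod
    np.fill_diagonal(A, 1.0 - A.sum(axis=1))
    if A.min() < 0:
        raise ValidationError("Abouheif proximity produced a negative entry")
    return labels, A


def abouheif_C(tree: HostTree, trait) -> float:
    """Abouheif's C: proximity-weighted cross-product of the centred trait
    over its sum of squares. Positive values indicate closely related tips
    share similar values.

    ``trait`` may be a mapping / pandas Series keyed by tip label, or an
    array ordered like ``tree.tips``.
    """
    labels, A = abouheif_proximity(tree)
    if isinstance(trait, Mapping) or isinstance(trait, pd.Series):
        x = np.array([float(trait[l]) for l in labels])
    else:
        x = np.asarray(trait, dtype=float)
        if x.size != len(labels):
            raise ValidationError("trait length does not match tip count")
    z = x - x.mean()
    ss = float(z @ z)
    if ss == 0:
        raise ValidationError("constant trait: Abouheif's C is undefined")
    off = A.copy()
    np.fill_diagonal(off, 0.0)
    return float(z @ off @ z / ss)


def autocorrelation_weights(
    tree: HostTree,
    table: TraitTable,
    columns: Sequence[str],
    clip: float = 0.01,
) -> dict:
    """Inverse-autocorrelation weights ``w = 1 / max(C, clip)`` per variable.

    Negative or near-zero C values are clipped so weights stay positive and
    finite. Fuzzy groups named in ``columns`` receive one weight from the
    mean C across their member columns.
    """
    sub = table.data.loc[list(tree.tips)]
    weights = {}
    for col in columns:
        if col in table.fuzzy_groups:
            cs = []
            for member in table.fuzzy_groups[col]:
                try:
                    cs.append(abouheif_C(tree, sub[member]))
                except ValidationError:
                    continue  # constant category carries no signal
            c = float(np.mean(cs)) if cs else clip
        else:
            try:
                c = abouheif_C(tree, sub[col])
            except ValidationError:
                # constant column: weight is moot, Gower will drop it anyway
                logger.warning("autocorrelation_weights: %r is constant", col)
                c = clip
        weights[col] = 1.0 / max(c, clip)
    return weights


# ---------------------------------------------------------------------------
# Mixed-variable Gower distance
# ---------------------------------------------------------------------------


def weighted_gower(
    table: TraitTable,
    weights: Mapping[str, float],
    species: Sequence[str] | None = None,
) -> DistanceMatrix:
    """Weighted Gower distance over mixed variable types.

    Per-variable contributions all lie in [0, 1]:

    * continuous -- |x_i - x_j| after SD-scaling, divided by the maximum
      observed pairwise difference;
    * binary -- simple 0/1 mismatch;
    * fuzzy group -- half the L1 distance between compositions (total
      variation).

    The combined distance is the weight-normalised sum. Keys of ``weights``
    are continuous/binary column names or fuzzy group names; variables with
    no pairwise variation are dropped with a warning. Requires a complete
    (imputed) table.
    """
    sp = list(species) if species is not None else list(table.data.index)
    df = table.data.loc[sp]
    if df.isna().any().any():
        raise ValidationError("weighted_gower requires a complete table; impute first")
    n = len(sp)
    num = np.zeros((n, n))
    wsum = 0.0
    for var, w in weights.items():
        if w <= 0:
            raise ValidationError(f"non-positive weight for {var!r}")
        if var in table.fuzzy_groups:
            P = df[list(table.fuzzy_groups[var])].to_numpy(dtype=float)
            d = 0.5 * np.abs(P[:, None, :] - P[None, :, :]).sum(axis=2)
        else:
            typ = table.types.get(var)
            x = df[var].to_numpy(dtype=float)
            if typ == "binary":
                d = (x[:, None] != x[None, :]).astype(float)
            elif typ == "continuous":
                sd = x.std(ddof=0)
                if sd > 0:
                    x = (x - x.mean()) / sd
                d = np.abs(x[:, None] - x[None, :])
                mx = d.max()
                if mx == 0:
                    logger.warning("weighted_gower: dropping constant column %r", var)
                    continue
                d = d / mx
            else:
                raise ValidationError(f"unknown Gower variable {var!r}")
        num += w * d
        wsum += w
    if wsum == 0:
        raise ValidationError("no informative variables left for Gower distance")
    D = num / wsum
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(sp, D, scaled=False)


# ---------------------------------------------------------------------------
# Dendrogram ensemble
# ---------------------------------------------------------------------------


@dataclass
class Dendrogram:
    """One agglomerative clustering of a niche distance matrix.

    ``cophenetic`` is max-scaled to [0, 1] so it is directly comparable with
    the scaled phylogenetic distances.
    """

    linkage_method: str
    labels: list
    merge_matrix: np.ndarray  # scipy linkage encoding
    cophenetic: DistanceMatrix

    def to_newick(self) -> str:
        """Serialise merge structure as Newick with heights as node depths."""
        root = sch.to_tree(self.merge_matrix)

        def rec(node, parent_height):
            # branch length = parent merge height - own merge height (0 at leaves);
            # clamped at 0 for non-monotone linkages with inversions
            bl = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id].replace(' ', '_')}:{bl:.10g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{bl:.10g}"

        return rec(root, root.dist) + ";"


def _linkage(condensed: np.ndarray, method: str) -> np.ndarray:
    """scipy linkage plus a 'ward_squared' variant run on squared distances
    (heights mapped back to the distance scale by a square root)."""
    if method == "ward_squared":
        Z = sch.linkage(condensed**2, method="ward")
        Z = Z.copy()
        Z[:, 2] = np.sqrt(Z[:, 2])
        return Z
    return sch.linkage(condensed, method=method)


def build_dendrogram_ensemble(
    matrix: DistanceMatrix,
    methods: Sequence[str] = DEFAULT_LINKAGE_METHODS,
) -> list[Dendrogram]:
    """Cluster one niche distance matrix with eight agglomerative schemes.

    Different linkage rules imply different dendrograms from the same
    distances; drawing among them propagates that topological uncertainty
    into the specificity nulls.
    """
    if matrix.n < 3:
        raise ValidationError("need >= 3 species to build dendrograms")
    methods = list(methods)
    if len(set(methods)) < 8:
        raise ValidationError(
            f"ensemble requires 8 distinct linkage methods, got {sorted(set(methods))}"
        )
    condensed = squareform(matrix.values, checks=False)
    out = []
    for method in methods:
        Z = _linkage(condensed, method)
        coph = squareform(sch.cophenet(Z), checks=False)
        dm = DistanceMatrix(list(matrix.labels), coph).max_scaled()
        out.append(Dendrogram(method, list(matrix.labels), Z, dm))
    return out
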