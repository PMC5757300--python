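"""Distance machinery checked against independent oracles.

Patristic distances are compared with Bio.Phylo's path sums, the Abouheif
proximity with a networkx shortest-path enumeration, and the weighted Gower
distance with a brute-force double loop.
"""

import io as _io
import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from Bio import Phylo

from hostspec import (
    DistanceMatrix,
    HostTree,
    TraitTable,
    ValidationError,
    abouheif_C,
    abouheif_proximity,
    build_dendrogram_ensemble,
    patristic_distances,
    weighted_gower,
)
from hostspec.distances import autocorrelation_weights
from hostspec.simulate import simulate_tree


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def biopython_patristic(newick: str, labels):
    """Independent patristic oracle via Bio.Phylo path sums."""
    tree = Phylo.read(_io.StringIO(newick), "newick")
    n = len(labels)
    out = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = tree.distance(a, labels[j])
    return out


def networkx_abouheif(tree: HostTree):
    """Brute-force proximity oracle: enumerate the tip-to-tip path with
    networkx and multiply 1/#children over its interior nodes."""
    g = nx.Graph()
    names = {}
    children = {}
    for node in tree.dendropy_tree.preorder_node_iter():
        names[id(node)] = (
            node.taxon.label if node.is_leaf() else f"int{id(node)}"
        )
        children[names[id(node)]] = len(node.child_nodes())
        if node.parent_node is not None:
            g.add_edge(names[id(node.parent_node)], names[id(node)])
    labels = tree.tips
    n = len(labels)
    A = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        path = nx.shortest_path(g, labels[i], labels[j])
        prod = 1.0
        for name in path[1:-1]:
            prod *= 1.0 / children[name]
        A[i, j] = A[j, i] = prod
    np.fill_diagonal(A, 1.0 - A.sum(axis=1))
    return labels, A


def brute_force_gower(table: TraitTable, weights):
    """Double-loop Gower oracle mirroring the documented dialect."""
    df = table.data
    sp = list(df.index)
    n = len(sp)

    prepared = {}
    for var in weights:
        if var in table.fuzzy_groups:
            prepared[var] = ("fuzzy", df[list(table.fuzzy_groups[var])].to_numpy())
        elif table.types[var] == "binary":
            prepared[var] = ("binary", df[var].to_numpy())
        else:
            x = df[var].to_numpy(dtype=float)
            if x.std(ddof=0) > 0:
                x = (x - x.mean()) / x.std(ddof=0)
            rng = max(abs(x[i] - x[j]) for i in range(n) for j in range(n))
            prepared[var] = ("continuous", x / 1.0) if rng == 0 else ("cont_scaled", (x, rng))

    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = den = 0.0
            for var, w in weights.items():
                kind, payload = prepared[var]
                if kind == "fuzzy":
                    d = 0.5 * np.abs(payload[i] - payload[j]).sum()
                elif kind == "binary":
                    d = float(payload[i] != payload[j])
                elif kind == "cont_scaled":
                    x, rng = payload
                    d = abs(x[i] - x[j]) / rng
                else:  # constant continuous column: dropped
                    continue
                num += w * d
                den += w
            D[i, j] = num / den
    return D


# ---------------------------------------------------------------------------
# Patristic distances
# ---------------------------------------------------------------------------


class TestPatristicDistances:
    def test_path_sums(self, three_tip_tree):
        dm = patristic_distances(three_tip_tree, scale=False)
        f = dm.to_frame()
        assert f.loc["A", "B"] == 2
        assert f.loc["A", "C"] == 4
        assert f.loc["B", "C"] == 4

    def test_scaling_divides_by_max(self, three_tip_tree):
        dm = patristic_distances(three_tip_tree, scale=True)
        f = dm.to_frame()
        assert f.loc["A", "B"] == 0.5
        assert f.loc["A", "C"] == 1.0

    def test_two_tip_tree_scaled(self):
        t = HostTree.from_newick("(A:1,B:3);")
        assert patristic_distances(t, scale=True).to_frame().loc["A", "B"] == 1.0

    def test_matches_biopython_oracle(self):
        tree = simulate_tree(10, seed=4)
        dm = patristic_distances(tree, scale=False)
        oracle = biopython_patristic(tree.to_newick(), dm.labels)
        assert np.abs(dm.values - oracle).max() < 1e-10

    def test_four_point_condition(self):
        tree = simulate_tree(12, seed=9)
        d = patristic_distances(tree, scale=False).to_frame()
        labels = list(d.index)
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, e = rng.choice(labels, size=4, replace=False)
            sums = sorted([
                d.loc[a, b] + d.loc[c, e],
                d.loc[a, c] + d.loc[b, e],
                d.loc[a, e] + d.loc[b, c],
            ])
            assert sums[2] - sums[1] < 1e-8


# ---------------------------------------------------------------------------
# Abouheif proximity and C
# ---------------------------------------------------------------------------


class TestAbouheif:
    def test_balanced_four_tip_values(self, balanced_four_tip_tree):
        labels, A = abouheif_proximity(balanced_four_tip_tree)
        f = pd.DataFrame(A, index=labels, columns=labels)
        assert f.loc["A", "B"] == pytest.approx(0.5)
        assert f.loc["A", "C"] == pytest.approx(1 / 8)
        assert f.loc["A", "A"] == pytest.approx(0.25)

    def test_two_tip_tree(self):
        t = HostTree.from_newick("(A:1,B:1);")
        labels, A = abouheif_proximity(t)
        assert A[0, 1] == pytest.approx(0.5)
        assert A[0, 0] == pytest.approx(0.5)

    @pytest.mark.parametrize("n,seed", [(5, 0), (8, 1), (8, 2)])
    def test_matches_path_enumeration_oracle(self, n, seed):
        tree = simulate_tree(n, seed=seed)
        labels, A = abouheif_proximity(tree)
        olabels, O = networkx_abouheif(tree)
        assert labels == olabels
        assert np.abs(A - O).max() < 1e-12

    def test_rows_sum_to_one(self):
        tree = simulate_tree(15, seed=5)
        _, A = abouheif_proximity(tree)
        assert np.abs(A.sum(axis=1) - 1).max() < 1e-10
        assert A.min() >= 0

    def test_polytomy_uses_child_count(self):
        t = HostTree.from_newick("((A:1,B:1,C:1):1,D:2);")
        labels, A = abouheif_proximity(t)
        f = pd.DataFrame(A, index=labels, columns=labels)
        assert f.loc["A", "B"] == pytest.approx(1 / 3)
        assert f.loc["A", "D"] == pytest.approx(1 / 6)

    def test_C_clade_trait(self, balanced_four_tip_tree):
        c = abouheif_C(balanced_four_tip_tree, {"A": 1, "B": 1, "C": -1, "D": -1})
        assert c == pytest.approx(0.25)

    def test_C_anti_clade_is_negative(self, balanced_four_tip_tree):
        assert abouheif_C(balanced_four_tip_tree, {"A": 1, "B": -1, "C": 1, "D": -1}) < 0

    def test_C_constant_trait_rejected(self, balanced_four_tip_tree):
        with pytest.raises(ValidationError, match="constant"):
            abouheif_C(balanced_four_tip_tree, {"A": 1, "B": 1, "C": 1, "D": 1})

    def test_C_permutation_null_mean(self):
        # E[C] under random permutation is -1/(n-1)
        tree = simulate_tree(12, seed=8)
        n = 12
        rng = np.random.default_rng(42)
        base = rng.standard_normal(n)
        cs = []
        for _ in range(999):
            cs.append(abouheif_C(tree, rng.permutation(base)))
        mean, se = np.mean(cs), np.std(cs) / np.sqrt(len(cs))
        assert abs(mean - (-1 / (n - 1))) < 3 * se + 1e-3


# ---------------------------------------------------------------------------
# Weighted Gower
# ---------------------------------------------------------------------------


def _mixed_table(n=8, seed=0):
    rng = np.random.default_rng(seed)
    fz = rng.dirichlet(np.ones(4), size=n)
    data = pd.DataFrame(
        {
            "mass": rng.standard_normal(n) * 3 + 5,
            "lat": rng.uniform(-60, 60, n),
            "urban": rng.integers(0, 2, n).astype(float),
            **{f"d{i}": fz[:, i] for i in range(4)},
        },
        index=[f"s{i}" for i in range(n)],
    )
    types = {"mass": "continuous", "lat": "continuous", "urban": "binary",
             **{f"d{i}": "fuzzy" for i in range(4)}}
    return TraitTable(data, types, {"diet": [f"d{i}" for i in range(4)]})


class TestWeightedGower:
    def test_identical_rows_zero(self):
        table = _mixed_table(4, seed=1)
        df = pd.concat([table.data.iloc[[0]]] * 3)
        df.index = ["a", "b", "c"]
        dup = TraitTable(df, dict(table.types), dict(table.fuzzy_groups))
        dm = weighted_gower(dup, {"urban": 1.0, "diet": 1.0})
        assert dm.values.max() == 0

    def test_single_binary_mismatch_is_one(self):
        df = pd.DataFrame({"urban": [0.0, 1.0]}, index=["a", "b"])
        table = TraitTable(df, {"urban": "binary"})
        dm = weighted_gower(table, {"urban": 1.0})
        assert dm.values[0, 1] == 1.0

    def test_weighted_mean_of_contributions(self):
        df = pd.DataFrame({"u1": [0.0, 1.0], "u2": [1.0, 1.0]}, index=["a", "b"])
        table = TraitTable(df, {"u1": "binary", "u2": "binary"})
        dm = weighted_gower(table, {"u1": 3.0, "u2": 1.0})
        assert dm.values[0, 1] == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", [0, 3])
    def test_matches_brute_force_oracle(self, seed):
        table = _mixed_table(8, seed=seed)
        weights = {"mass": 2.0, "lat": 0.5, "urban": 1.0, "diet": 1.5}
        dm = weighted_gower(table, weights)
        oracle = brute_force_gower(table, weights)
        assert np.abs(dm.values - oracle).max() < 1e-12

    def test_invariant_to_variable_ordering(self):
        table = _mixed_table(6, seed=2)
        w1 = {"mass": 2.0, "urban": 1.0, "diet": 1.5}
        w2 = {"diet": 1.5, "urban": 1.0, "mass": 2.0}
        a = weighted_gower(table, w1).values
        b = weighted_gower(table, w2).values
        assert np.abs(a - b).max() < 1e-15

    def test_constant_column_dropped_with_warning(self, caplog):
        df = pd.DataFrame({"c": [2.0, 2.0, 2.0], "urban": [0.0, 1.0, 0.0]},
                          index=["a", "b", "c"])
        table = TraitTable(df, {"c": "continuous", "urban": "binary"})
        with caplog.at_level("WARNING", logger="hostspec"):
            dm = weighted_gower(table, {"c": 5.0, "urban": 1.0})
        assert "dropping" in caplog.text
        assert dm.values[0, 1] == 1.0  # only the binary variable remains


# ---------------------------------------------------------------------------
# Dendrogram ensemble
# ---------------------------------------------------------------------------


class TestDendrogramEnsemble:
    def _matrix(self):
        vals = np.array([[0, 1, 2], [1, 0, 1.0], [2, 1, 0]])
        return DistanceMatrix(["a", "b", "c"], vals)

    def test_requires_eight_methods(self):
        with pytest.raises(ValidationError, match="8"):
            build_dendrogram_ensemble(self._matrix(), methods=["single", "complete"])

    def test_three_point_hand_clustering(self):
        # distances: d(a,b)=1, d(b,c)=1, d(a,c)=2 -> single linkage merges at
        # heights 1 then 1; complete at 1 then 2; max-scaled cophenetic max = 1
        ens = build_dendrogram_ensemble(self._matrix())
        by_method = {d.linkage_method: d for d in ens}
        single = by_method["single"]
        assert single.merge_matrix.shape == (2, 4)
        assert single.cophenetic.values.max() == 1.0
        complete = by_method["complete"]
        assert complete.merge_matrix[:, 2].tolist() == [1.0, 2.0]

    def test_every_dendrogram_has_n_minus_one_merges(self, medium_dataset):
        from hostspec.distances import patristic_distances

        dm = patristic_distances(medium_dataset.tree.prune_to(
            medium_dataset.tree.tips[:12]), scale=True)
        ens = build_dendrogram_ensemble(dm)
        assert len(ens) == 8
        assert all(d.merge_matrix.shape[0] == 11 for d in ens)

    def test_average_linkage_cophenetic_is_ultrametric(self):
        rng = np.random.default_rng(1)
        pts = rng.standard_normal((9, 3))
        from scipy.spatial.distance import cdist

        dm = DistanceMatrix([f"s{i}" for i in range(9)], cdist(pts, pts))
        ens = build_dendrogram_ensemble(dm)
        coph = next(d for d in ens if d.linkage_method == "average").cophenetic.values
        n = coph.shape[0]
        for i, j, k in itertools.combinations(range(n), 3):
            assert max(coph[i, j], coph[j, k]) >= coph[i, k] - 1e-10

    def test_newick_serialization_parses(self):
        ens = build_dendrogram_ensemble(self._matrix())
        t = HostTree.from_newick(ens[0].to_newick())
        assert t.tips == ["a", "b", "c"]


def test_autocorrelation_weights_clip_and_invert():
    tree = simulate_tree(20, seed=3)
    rng = np.random.default_rng(0)
    df = pd.DataFrame(
        {"noise": rng.standard_normal(20)}, index=tree.tips
    )
    from hostspec.simulate import simulate_bm_trait

    df["signal"] = simulate_bm_trait(tree, 1.0, seed=1)
    table = TraitTable(df, {"noise": "continuous", "signal": "continuous"})
    w = autocorrelation_weights(tree, table, ["noise", "signal"], clip=0.01)
    assert all(v > 0 for v in w.values())
    assert w["noise"] <= 1.0 / 0.01 + 1e-9
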