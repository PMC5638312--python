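import numpy as np
import pytest

from genoclim.clustering import (
    DistanceMatrix,
    Tree,
    TreeNode,
    bootstrap_support,
    nei_li_distance,
    neighbor_joining,
    pca_genotypes,
    shared_allele_distance,
)
from genoclim.genotype_data import (
    GenotypeTable,
    binary_presence_matrix,
    dosage_matrix,
)
from genoclim.synthetic_data import GenotypeSimSpec, simulate_genotypes


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """Random unrooted binary tree with positive lengths; returns
    (distance matrix, set of bipartitions as frozensets of leaf names)."""
    names = [f"t{i}" for i in range(n_taxa)]
    # start from a 3-star, attach remaining leaves to random edges
    nodes = {0: TreeNode(name=names[0]), 1: TreeNode(name=names[1]),
             2: TreeNode(name=names[2])}
    adj: dict[int, dict[int, float]] = {3: {}}
    center = 3
    next_id = 4
    edges = []
    for i in range(3):
        w = rng.uniform(0.5, 2.0)
        adj.setdefault(i, {})[center] = w
        adj[center][i] = w
        edges.append((i, center))
    leaf_ids = {0: names[0], 1: names[1], 2: names[2]}
    for k in range(3, n_taxa):
        u, v = edges[rng.integers(len(edges))]
        w_uv = adj[u][v]
        split = rng.uniform(0.2, 0.8) * w_uv
        mid = next_id
        next_id += 1
        leaf = next_id
        next_id += 1
        del adj[u][v]
        del adj[v][u]
        adj.setdefault(mid, {})[u] = split
        adj[u][mid] = split
        adj[mid][v] = w_uv - split
        adj.setdefault(v, {})[mid] = w_uv - split
        w_leaf = rng.uniform(0.5, 2.0)
        adj.setdefault(leaf, {})[mid] = w_leaf
        adj[mid][leaf] = w_leaf
        leaf_ids[leaf] = names[k]
        edges.remove((u, v))
        edges += [(u, mid), (mid, v), (mid, leaf)]
    # all-pairs path lengths between leaves (Dijkstra-free: BFS w/ weights)
    ids = sorted(leaf_ids)
    index = {names[i]: i for i in range(n_taxa)}
    d = np.zeros((n_taxa, n_taxa))

    def paths_from(src: int) -> dict[int, float]:
        dist = {src: 0.0}
        stack = [src]
        while stack:
            cur = stack.pop()
            for nb, w in adj[cur].items():
                if nb not in dist:
                    dist[nb] = dist[cur] + w
                    stack.append(nb)
        return dist

    for src in ids:
        dist = paths_from(src)
        for dst in ids:
            d[index[leaf_ids[src]], index[leaf_ids[dst]]] = dist[dst]

    # bipartitions: remove each internal edge, collect leaves on one side
    ref = min(names)
    splits = set()
    for u, v in edges:
        if u in leaf_ids or v in leaf_ids:
            continue
        seen = {u}
        stack = [u]
        while stack:
            cur = stack.pop()
            for nb in adj[cur]:
                if nb != v and nb not in seen and (cur, nb) != (u, v):
                    if not (cur == u and nb == v):
                        seen.add(nb)
                        stack.append(nb)
        side = {leaf_ids[x] for x in seen if x in leaf_ids}
        if 1 < len(side) < n_taxa - 1:
            splits.add(frozenset(side if ref not in side else set(names) - side))
    return names, d, splits


class TestSharedAlleleDistance:
    def test_identical_zero(self, toy_table):
        d = shared_allele_distance(toy_table)
        assert np.allclose(np.diag(d.matrix), 0)

    def test_disjoint_one(self):
        gt = GenotypeTable(["a", "b"], ["L1", "L2"],
                           np.array([[[1, 2], [5, 6]], [[3, 4], [7, 8]]]))
        assert shared_allele_distance(gt).matrix[0, 1] == pytest.approx(1.0)

    def test_single_locus_half(self):
        gt = GenotypeTable(["a", "b"], ["L"], np.array([[[1, 2]], [[1, 3]]]))
        assert shared_allele_distance(gt).matrix[0, 1] == pytest.approx(0.5)

    def test_metric_properties_random(self, bn_table):
        gt, _ = bn_table
        sub = gt.subset(np.arange(0, 30))
        d = shared_allele_distance(sub).matrix
        assert np.allclose(d, d.T)
        assert (d >= -1e-12).all() and (d <= 1 + 1e-12).all()


class TestNeiLiDistance:
    def test_identical_zero(self):
        gt = GenotypeTable(["a", "b"], ["L"], np.array([[[1, 2]], [[1, 2]]]))
        assert nei_li_distance(binary_presence_matrix(gt)).matrix[0, 1] == 0

    def test_disjoint_one(self):
        gt = GenotypeTable(["a", "b"], ["L"], np.array([[[1, 2]], [[3, 4]]]))
        assert nei_li_distance(binary_presence_matrix(gt)).matrix[0, 1] == 1

    def test_hand_counts(self):
        from genoclim.genotype_data import BinaryMatrix

        m = np.array([[1, 1, 1, 0, 0, 0], [1, 1, 0, 1, 1, 1]], dtype=np.uint8)
        bm = BinaryMatrix(["x", "y"], [("L", i) for i in range(6)], m,
                          np.ones((2, 1), bool))
        # n_x=3, n_y=5, n_xy=2 -> 1 - 4/8 = 0.5
        assert nei_li_distance(bm).matrix[0, 1] == pytest.approx(0.5)


class TestNeighborJoining:
    def test_four_taxon_additive(self):
        ids = ["A", "B", "C", "D"]
        d = np.array([[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]],
                     float)
        tree = neighbor_joining(DistanceMatrix(ids, d))
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        # recovered path lengths reproduce the input distances
        assert _tree_distances(tree) == pytest.approx(d)

    def test_three_taxon_star(self):
        d = np.full((3, 3), 2.0)
        np.fill_diagonal(d, 0)
        tree = neighbor_joining(DistanceMatrix(["x", "y", "z"], d))
        assert sorted(c.length for c in tree.root.children) == [1, 1, 1]

    def test_taxon_order_invariance(self, bn_table):
        gt, _ = bn_table
        sub = gt.subset(np.arange(12))
        dm = shared_allele_distance(sub)
        t1 = neighbor_joining(dm)
        perm = np.random.default_rng(0).permutation(12)
        dm2 = DistanceMatrix([dm.ids[i] for i in perm],
                             dm.matrix[np.ix_(perm, perm)])
        t2 = neighbor_joining(dm2)
        assert t1.bipartitions() == t2.bipartitions()

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_additive_tree_oracle(self, n_taxa):
        rng = np.random.default_rng(n_taxa * 13)
        for _ in range(10):
            names, d, splits = random_additive_tree(n_taxa, rng)
            tree = neighbor_joining(DistanceMatrix(names, d))
            assert tree.bipartitions() == splits
            assert _tree_distances(tree) == pytest.approx(d, abs=1e-8)

    def test_missing_entries_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            neighbor_joining(DistanceMatrix(["a", "b", "c"], d))


def _tree_distances(tree: Tree) -> np.ndarray:
    """Leaf-to-leaf path lengths, ordered by sorted leaf name."""
    leaves = sorted(tree.leaf_names())
    idx = {n: i for i, n in enumerate(leaves)}
    n = len(leaves)
    d = np.zeros((n, n))

    def walk(node, acc):
        if node.is_leaf:
            return {node.name: acc}
        out = {}
        for c in node.children:
            out.update(walk(c, acc + c.length))
        return out

    # distances via paths through each internal node
    def pairs(node):
        if node.is_leaf:
            return {node.name: node.length}
        below = []
        for c in node.children:
            below.append(walk(c, c.length))
        for i in range(len(below)):
            for j in range(i + 1, len(below)):
                for a, da in below[i].items():
                    for b, db in below[j].items():
                        d[idx[a], idx[b]] = d[idx[b], idx[a]] = da + db
        merged = {}
        for sub in below:
            merged.update(sub)
        return merged

    def recurse(node):
        for c in node.children:
            recurse(c)
        pairs(node)

    recurse(tree.root)
    return d


class TestBootstrap:
    def test_separated_clusters_high_support(self):
        gt, _ = simulate_genotypes(GenotypeSimSpec(
            seed=1, fst=0.6, group_sizes=(5, 5), n_loci=40, n_alleles=8))
        tree = bootstrap_support(gt, n_reps=100, seed=2)
        labels = dict(zip(gt.accession_ids, gt.groups))
        cluster_split = frozenset(
            a for a in gt.accession_ids if labels[a] == "G2"
        )
        supports = _collect_supports(tree)
        assert cluster_split in supports
        assert supports[cluster_split] >= 95

    def test_supports_bounded_and_deterministic(self, bn_table):
        gt, _ = bn_table
        sub = gt.subset(np.arange(10))
        t1 = bootstrap_support(sub, n_reps=30, seed=5)
        t2 = bootstrap_support(sub, n_reps=30, seed=5)
        s1, s2 = _collect_supports(t1), _collect_supports(t2)
        assert s1 == s2
        assert all(0 <= v <= 100 for v in s1.values())

    def test_nreps_validation(self, bn_table):
        gt, _ = bn_table
        with pytest.raises(ValueError):
            bootstrap_support(gt, n_reps=0)


def _collect_supports(tree: Tree) -> dict[frozenset, float]:
    all_leaves = set(tree.leaf_names())
    ref = min(all_leaves)
    out = {}

    def walk(node):
        if node.is_leaf:
            return {node.name}
        below = set()
        for c in node.children:
            below |= walk(c)
        if node.support is not None:
            side = below if ref not in below else all_leaves - below
            out[frozenset(side)] = node.support
        return below

    walk(tree.root)
    return out


class TestPCA:
    def test_duplicates_coincide(self):
        gt, _ = simulate_genotypes(GenotypeSimSpec(seed=4, group_sizes=(6,),
                                                   n_loci=6))
        doubled = GenotypeTable(
            gt.accession_ids + ["dup"],
            gt.loci,
            np.vstack([gt.calls, gt.calls[:1]]),
        )
        res = pca_genotypes(dosage_matrix(doubled))
        assert np.allclose(res["scores"][0], res["scores"][-1], atol=1e-8)

    def test_known_covariance_eigenvalues(self):
        rng = np.random.default_rng(0)
        # 2-D data with known sample covariance: eigenvalues of X^T X / 1
        x = rng.standard_normal((200, 2)) @ np.array([[2.0, 0.0], [0.0, 0.5]])
        from genoclim.genotype_data import DosageMatrix

        dm = DosageMatrix([str(i) for i in range(200)],
                          [("L", 1), ("L", 2)], x, np.zeros_like(x, bool))
        res = pca_genotypes(dm)
        xc = x - x.mean(axis=0)
        eig = np.sort(np.linalg.eigvalsh(xc.T @ xc))[::-1]
        assert res["explained"] == pytest.approx(eig / eig.sum())

    def test_fractions_non_increasing(self, bn_table):
        gt, _ = bn_table
        res = pca_genotypes(dosage_matrix(gt))
        assert (np.diff(res["explained"]) <= 1e-12).all()
        assert res["explained"].sum() <= 1 + 1e-9

    def test_constant_matrix_rejected(self):
        from genoclim.genotype_data import DosageMatrix

        dm = DosageMatrix(["a", "b"], [("L", 1)], np.ones((2, 1)),
                          np.zeros((2, 1), bool))
        with pytest.raises(ValueError, match="constant"):
            pca_genotypes(dm)
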