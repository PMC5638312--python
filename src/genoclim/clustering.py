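"""Distance-based relationships: genotype distances, neighbor joining, PCA."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from genoclim.genotype_data import BinaryMatrix, DosageMatrix, GenotypeTable
from genoclim.differentiation import _shared_pairs

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "Tree",
    "shared_allele_distance",
    "nei_li_distance",
    "neighbor_joining",
    "bootstrap_support",
    "pca_genotypes",
]


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray
    n_compared: np.ndarray | None = None  # loci compared per pair

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.matrix, self.matrix.T, equal_nan=True):
            raise ValueError("distance matrix not symmetric")


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    """Unrooted tree stored with an arbitrary (trifurcating) root."""

    root: TreeNode

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def bipartitions(self) -> set[frozenset[str]]:
        """Canonical leaf-set bipartitions of internal edges.

        Each internal (non-root, non-leaf) edge is identified by the
        side of the split not containing the lexicographically smallest
        leaf; trivial splits are excluded.
        """
        all_leaves = set(self.leaf_names())
        ref = min(all_leaves)
        splits: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> set[str]:
            if node.is_leaf:
                return {node.name}
            below: set[str] = set()
            for c in node.children:
                below |= walk(c)
            if node is not self.root and 1 < len(below) < len(all_leaves) - 1:
                side = below if ref not in below else all_leaves - below
                splits.add(frozenset(side))
            return below

        walk(self.root)
        return splits

    def newick(self, include_support: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if include_support and node.support is not None:
                label = f"{node.support:g}"
            return f"({inner}){label}:{node.length:.6g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"


def shared_allele_distance(gt: GenotypeTable) -> DistanceMatrix:
    """1 minus the proportion of alleles shared over jointly typed loci.

    Per shared locus the contribution is the multiset intersection size
    of the two allele pairs (0, 1 or 2); d = 1 - sum/(2 * L_shared).
    Pairs with no jointly typed locus get NaN with a warning.
    """
    n, L = gt.n_accessions, gt.n_loci
    shared_sum = np.zeros((n, n))
    n_comp = np.zeros((n, n), dtype=np.int64)
    for j in range(L):
        t = gt.typed[:, j]
        valid = t[:, None] & t[None, :]
        s = _shared_pairs(gt.calls[:, j, 0], gt.calls[:, j, 1])
        shared_sum += np.where(valid, s, 0)
        n_comp += valid
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - shared_sum / (2.0 * n_comp)
    if (n_comp == 0).any():
        logger.warning("%d pairs share no typed loci (distance NaN)",
                       int(((n_comp == 0).sum() - n) // 2))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(gt.accession_ids), d, n_comp)


def nei_li_distance(bm: BinaryMatrix) -> DistanceMatrix:
    """Nei & Li distance on presence/absence rows: 1 - 2*n_xy/(n_x + n_y)."""
    m = bm.matrix.astype(float)
    n_x = m.sum(axis=1)
    if (n_x == 0).any():
        raise ValueError("accession with all-zero presence row")
    n_xy = m @ m.T
    denom = n_x[:, None] + n_x[None, :]
    d = 1.0 - 2.0 * n_xy / denom
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(bm.accession_ids), d)


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining; Q-criterion ties broken by lowest index pair.

    Returns an unrooted tree represented with a trifurcating root.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if np.isnan(dm.matrix).any():
        raise ValueError("distance matrix has missing entries")
    d = dm.matrix.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie break: argmin over flattened row-major order
        flat = np.argmin(q)
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = li
        child_j.length = lj
        if li < 0 or lj < 0:
            logger.debug("negative NJ branch length at join (%s,%s)", i, j)
        new = TreeNode(children=[child_i, child_j])
        # distances from the new node to remaining actives
        d_new = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.pad(d, ((0, 1), (0, 1)), constant_values=0.0)
        d[-1, : len(d_new)] = d_new
        d[: len(d_new), -1] = d_new
        d[-1, -1] = 0.0
        nodes.append(new)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for idx, length in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = length
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return Tree(root)


def bootstrap_support(gt: GenotypeTable, n_reps: int = 100, seed: int | None = None,
                      distance: str = "shared_allele") -> Tree:
    """NJ tree with bootstrap support from resampling loci with replacement.

    Support on an internal edge is the percentage of replicate trees
    containing the same leaf bipartition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if gt.n_loci < 2:
        raise ValueError("bootstrap needs at least 2 loci")

    def build(table: GenotypeTable) -> Tree:
        if distance == "shared_allele":
            return neighbor_joining(shared_allele_distance(table))
        raise ValueError(f"unknown distance {distance!r}")

    ref = build(gt)
    ref_splits = ref.bipartitions()
    tally = {s: 0 for s in ref_splits}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        loci_idx = rng.integers(0, gt.n_loci, size=gt.n_loci)
        rep = GenotypeTable(
            accession_ids=list(gt.accession_ids),
            loci=[f"L{k}" for k in range(gt.n_loci)],
            calls=gt.calls[:, loci_idx, :].copy(),
            groups=gt.groups,
        )
        rep_splits = build(rep).bipartitions()
        for s in ref_splits & rep_splits:
            tally[s] += 1

    def annotate(node: TreeNode, all_leaves: set[str], ref_leaf: str) -> set[str]:
        if node.is_leaf:
            return {node.name}
        below: set[str] = set()
        for c in node.children:
            below |= annotate(c, all_leaves, ref_leaf)
        if node is not ref.root and 1 < len(below) < len(all_leaves) - 1:
            side = below if ref_leaf not in below else all_leaves - below
            node.support = 100.0 * tally[frozenset(side)] / n_reps
        return below

    leaves = set(ref.leaf_names())
    annotate(ref.root, leaves, min(leaves))
    return ref


def pca_genotypes(dm: DosageMatrix, n_components: int | None = None
                  ) -> dict[str, np.ndarray]:
    """Column-centered (unscaled) PCA of the dosage matrix.

    Returns ``scores`` (accessions x axes) and ``explained`` — the
    fraction of total variance per axis (non-increasing, sums to <= 1).
    """
    x = dm.matrix - dm.matrix.mean(axis=0, keepdims=True)
    if np.allclose(x, 0):
        raise ValueError("constant dosage matrix")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    total_var = (s**2).sum()
    k = n_components or len(s)
    scores = u[:, :k] * s[:k]
    explained = (s[:k] ** 2) / total_var
    return {"scores": scores, "explained": explained}
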