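"""Phylogenetic tree container and covariance utilities.

Wraps a rooted :class:`dendropy.Tree` and exposes the quantities the
comparative machinery needs: the tip-tip phylogenetic covariance matrix
``C`` (``C_ij`` = shared path length from the root, in the tree's time
units), covariances involving internal nodes (for ancestral-state
estimation), and a few deterministic tree constructors used by the
synthetic-data generators and the test suite.
"""
from __future__ import annotations

import io
from typing import Sequence

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "star_tree",
    "balanced_tree",
    "random_coalescent_tree",
]


def _normalize_label(label: str) -> str:
    """Species-name reconciliation: strip and map spaces to underscores."""
    return str(label).strip().replace(" ", "_")


class PhyloTree:
    """A rooted, labelled phylogenetic tree with branch lengths.

    Tip labels must be unique. Branch lengths must be non-negative;
    a missing root edge length is treated as zero.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        # depth of every node from the root, and stable node identifiers
        self._depth: dict[int, float] = {}
        self._parent: dict[int, int | None] = {}
        self._nodes = []
        for i, node in enumerate(tree.preorder_node_iter()):
            node._ormine_index = i
            self._nodes.append(node)
            edge = node.edge.length
            if edge is None:
                edge = 0.0
            if edge < -1e-12:
                raise ValueError(f"negative branch length {edge!r} in tree")
            parent = node.parent_node
            if parent is None:
                self._depth[i] = float(max(edge, 0.0))
                self._parent[i] = None
            else:
                self._depth[i] = self._depth[parent._ormine_index] + float(max(edge, 0.0))
                self._parent[i] = parent._ormine_index
        self.tips: list[str] = []
        self._tip_index: dict[str, int] = {}
        for node in tree.leaf_node_iter():
            label = _normalize_label(node.taxon.label)
            if label in self._tip_index:
                raise ValueError(f"duplicate tip label {label!r}")
            self._tip_index[label] = node._ormine_index
            self.tips.append(label)
        # internal node labels: root is "root", others nd<preorder index>
        self.internal_labels: list[str] = []
        self._internal_index: dict[str, int] = {}
        for node in self._nodes:
            if node.is_leaf():
                continue
            name = "root" if node.parent_node is None else f"nd{node._ormine_index}"
            self.internal_labels.append(name)
            self._internal_index[name] = node._ormine_index

    # ------------------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls(tree)

    def write_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    # ------------------------------------------------------------------
    def _path_from_root(self, idx: int) -> list[int]:
        path = []
        cur: int | None = idx
        while cur is not None:
            path.append(cur)
            cur = self._parent[cur]
        return path[::-1]

    def _mrca_depth(self, i: int, j: int) -> float:
        if i == j:
            return self._depth[i]
        pi, pj = self._path_from_root(i), self._path_from_root(j)
        d = 0.0
        for a, b in zip(pi, pj):
            if a != b:
                break
            d = self._depth[a]
        return d

    # ------------------------------------------------------------------
    def vcv(self, order: Sequence[str] | None = None) -> tuple[list[str], np.ndarray]:
        """Tip-tip phylogenetic covariance matrix.

        Returns ``(labels, C)`` with ``C[i, j]`` the depth of the MRCA of
        tips ``i`` and ``j`` (shared path length from the root).
        """
        labels = list(order) if order is not None else list(self.tips)
        idx = []
        for lab in labels:
            key = _normalize_label(lab)
            if key not in self._tip_index:
                raise KeyError(f"tip {lab!r} not found in tree")
            idx.append(self._tip_index[key])
        n = len(idx)
        C = np.zeros((n, n))
        for a in range(n):
            C[a, a] = self._depth[idx[a]]
            for b in range(a + 1, n):
                C[a, b] = C[b, a] = self._mrca_depth(idx[a], idx[b])
        return labels, C

    def node_tip_cov(self, tip_order: Sequence[str] | None = None) -> tuple[
        list[str], np.ndarray, np.ndarray
    ]:
        """Covariances of internal nodes with tips and with themselves.

        Returns ``(internal_labels, C_nt, c_nn)`` where ``C_nt[u, i]`` is
        the shared path length of internal node ``u`` and tip ``i`` and
        ``c_nn[u]`` is the depth of node ``u``.
        """
        tips = list(tip_order) if tip_order is not None else list(self.tips)
        tip_idx = [self._tip_index[_normalize_label(t)] for t in tips]
        node_idx = [self._internal_index[l] for l in self.internal_labels]
        C_nt = np.zeros((len(node_idx), len(tip_idx)))
        for a, u in enumerate(node_idx):
            for b, i in enumerate(tip_idx):
                C_nt[a, b] = self._mrca_depth(u, i)
        c_nn = np.array([self._depth[u] for u in node_idx])
        return list(self.internal_labels), C_nt, c_nn

    # ------------------------------------------------------------------
    def depth(self) -> float:
        """Maximum root-to-tip distance."""
        return max(self._depth[self._tip_index[t]] for t in self.tips)

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        depths = [self._depth[self._tip_index[t]] for t in self.tips]
        return (max(depths) - min(depths)) <= tol * max(max(depths), 1.0)

    def patristic_distances(self, order: Sequence[str] | None = None) -> tuple[
        list[str], np.ndarray
    ]:
        """Tip-tip path-length distances (used by the stationary OU kernel)."""
        labels, C = self.vcv(order)
        d = np.diag(C)
        return labels, d[:, None] + d[None, :] - 2.0 * C

    def __len__(self) -> int:
        return len(self.tips)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PhyloTree(n_tips={len(self.tips)}, depth={self.depth():.4g})"


# ----------------------------------------------------------------------
# deterministic constructors


def star_tree(labels: Sequence[str], branch: float = 1.0) -> PhyloTree:
    """A star phylogeny: every tip attached to the root by ``branch``."""
    inner = ",".join(f"{_normalize_label(l)}:{branch}" for l in labels)
    return PhyloTree.from_newick(f"({inner});")


def balanced_tree(n_tips: int, branch: float = 1.0, prefix: str = "t") -> PhyloTree:
    """A fully balanced binary tree with unit-length branches.

    ``n_tips`` must be a power of two; tree depth is ``log2(n) * branch``.
    """
    if n_tips < 2 or (n_tips & (n_tips - 1)) != 0:
        raise ValueError("n_tips must be a power of two >= 2")
    labels = [f"{prefix}{i}" for i in range(n_tips)]

    def build(lo: int, hi: int) -> str:
        if hi - lo == 1:
            return f"{labels[lo]}:{branch}"
        mid = (lo + hi) // 2
        return f"({build(lo, mid)},{build(mid, hi)}):{branch}"

    mid = n_tips // 2
    return PhyloTree.from_newick(f"({build(0, mid)},{build(mid, n_tips)});")


def random_coalescent_tree(
    n_tips: int, seed: int, prefix: str = "t", scale: float = 1.0
) -> PhyloTree:
    """A random ultrametric tree from a Kingman-style coalescent.

    Pairs of lineages merge at exponentially distributed waiting times;
    the result is ultrametric with expected depth of order ``scale``.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    # (newick fragment, height of fragment root)
    lineages: list[tuple[str, float]] = [(f"{prefix}{i}", 0.0) for i in range(n_tips)]
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t += float(rng.exponential(scale / (k * (k - 1) / 2.0) * 2.0))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (na, ha), (nb, hb) = lineages[i], lineages[j]
        merged = f"({na}:{t - ha},{nb}:{t - hb})"
        lineages = [lineages[m] for m in range(k) if m not in (i, j)]
        lineages.append((merged, t))
    root, _ = lineages[0]
    return PhyloTree.from_newick(root + ";")
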