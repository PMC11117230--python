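"""Rooted, time-calibrated phylogenies with array-based access.

The container stores a tree as flat parent/branch-length arrays in
preorder, which keeps the comparative methods (shared-path covariances,
ancestral reconstruction, branch interpolation) vectorizable.  Newick
parsing and serialization are delegated to dendropy.
"""

from __future__ import annotations

import logging
from typing import Sequence

import dendropy
import numpy as np

log = logging.getLogger(__name__)

ULTRAMETRIC_TOL = 1e-6


class Phylogeny:
    """A rooted tree with branch lengths in Myr.

    Nodes are indexed ``0..n_nodes-1`` in preorder (root first).  Tips
    carry labels; internal nodes may be unlabeled.  Node *depths* are
    measured from the root, node *times* in Myr before present
    (``height - depth``), so tips of an ultrametric tree sit at time 0.

    Parameters
    ----------
    parent
        Parent index per node, ``-1`` for the root.
    edge_length
        Length of the edge above each node (ignored for the root).
    labels
        Label per node; ``None`` for unlabeled internal nodes.
    """

    def __init__(
        self,
        parent: Sequence[int],
        edge_length: Sequence[float],
        labels: Sequence[str | None],
    ):
        self.parent = np.asarray(parent, dtype=int)
        self.edge_length = np.asarray(edge_length, dtype=float)
        self.labels = list(labels)
        n = len(self.parent)
        if not (len(self.edge_length) == len(self.labels) == n):
            raise ValueError("parent, edge_length and labels must have equal length")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            if i != self.root:
                if self.parent[i] >= i:
                    raise ValueError("nodes must be in preorder (parent before child)")
                self.children[self.parent[i]].append(i)
        self.edge_length = self.edge_length.copy()
        self.edge_length[self.root] = 0.0
        if np.any(self.edge_length[np.arange(n) != self.root] <= 0):
            raise ValueError("branch lengths must be positive")
        self.tip_indices = np.array(
            [i for i in range(n) if not self.children[i]], dtype=int
        )
        tip_labels = [self.labels[i] for i in self.tip_indices]
        if any(lb is None for lb in tip_labels):
            raise ValueError("every tip must be labeled")
        if len(set(tip_labels)) != len(tip_labels):
            raise ValueError("tip labels must be unique")
        # depths from the root (preorder => parents resolved first)
        self.depths = np.zeros(n)
        for i in range(n):
            if i != self.root:
                self.depths[i] = self.depths[self.parent[i]] + self.edge_length[i]
        self._mrca_depth: np.ndarray | None = None
        self._subtree_mask: np.ndarray | None = None

    # -- basic properties -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_indices]

    @property
    def internal_indices(self) -> np.ndarray:
        mask = np.ones(self.n_nodes, dtype=bool)
        mask[self.tip_indices] = False
        return np.flatnonzero(mask)

    @property
    def height(self) -> float:
        """Root-to-tip depth (maximum over tips), in Myr."""
        return float(self.depths[self.tip_indices].max())

    @property
    def node_times(self) -> np.ndarray:
        """Myr before present for every node (tips at ~0 when ultrametric)."""
        return self.height - self.depths

    def is_ultrametric(self, tol: float = ULTRAMETRIC_TOL) -> bool:
        d = self.depths[self.tip_indices]
        return float(d.max() - d.min()) <= tol * max(1.0, float(d.max()))

    # -- structure queries ------------------------------------------------

    def subtree_mask(self) -> np.ndarray:
        """Boolean matrix S with ``S[w, u]`` true iff u is in the clade of w."""
        if self._subtree_mask is None:
            n = self.n_nodes
            S = np.zeros((n, n), dtype=bool)
            for i in range(n - 1, -1, -1):  # postorder accumulate
                S[i, i] = True
                for c in self.children[i]:
                    S[i] |= S[c]
            self._subtree_mask = S
        return self._subtree_mask

    def mrca_depth_matrix(self) -> np.ndarray:
        """Depth of the MRCA for every node pair (shared path from the root)."""
        if self._mrca_depth is None:
            S = self.subtree_mask()
            n = self.n_nodes
            D = np.zeros((n, n))
            for w in np.argsort(self.depths, kind="stable"):  # shallow -> deep
                m = S[w]
                D[np.ix_(m, m)] = self.depths[w]
            self._mrca_depth = D
        return self._mrca_depth

    def mrca(self, nodes: Sequence[int]) -> int:
        """MRCA node index of a set of node indices."""
        S = self.subtree_mask()
        nodes = np.asarray(nodes, dtype=int)
        cover = np.flatnonzero(S[:, nodes].all(axis=1))
        return int(cover[np.argmax(self.depths[cover])])

    def path_to_root(self, node: int) -> list[int]:
        """Node indices from ``node`` up to and including the root."""
        path = [int(node)]
        while path[-1] != self.root:
            path.append(int(self.parent[path[-1]]))
        return path

    def path_to_ancestor(self, node: int, ancestor: int) -> list[int]:
        """Nodes from ``node`` up to and including ``ancestor``."""
        path = [int(node)]
        while path[-1] != ancestor:
            if path[-1] == self.root:
                raise ValueError(f"{ancestor} is not an ancestor of {node}")
            path.append(int(self.parent[path[-1]]))
        return path

    def clade_nodes(self, node: int) -> np.ndarray:
        return np.flatnonzero(self.subtree_mask()[node])

    def tip_index_of(self, label: str) -> int:
        try:
            return int(self.tip_indices[self.tip_labels.index(label)])
        except ValueError:
            raise KeyError(f"tip {label!r} not on tree") from None

    # -- covariances ------------------------------------------------------

    def vcv(self) -> np.ndarray:
        """Brownian-motion tip covariance: shared path length matrix (n_tips²)."""
        D = self.mrca_depth_matrix()
        return D[np.ix_(self.tip_indices, self.tip_indices)]

    # -- transforms -------------------------------------------------------

    def rescaled(self, depth: float) -> "Phylogeny":
        """Return a copy with branch lengths scaled so the height equals ``depth``."""
        f = depth / self.height
        return Phylogeny(self.parent, self.edge_length * f, self.labels)

    def pruned(self, keep_labels: Sequence[str]) -> "Phylogeny":
        """Subtree restricted to ``keep_labels`` tips.

        Internal nodes left with a single child are suppressed (their
        edges merge), and a dangling root stem is removed, so the
        result is a proper rooted tree on the kept tips.
        """
        keep = set(keep_labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise KeyError(f"tips not on tree: {sorted(missing)[:5]}")
        if len(keep) < 2:
            raise ValueError("need at least 2 tips to prune to")
        alive = np.zeros(self.n_nodes, dtype=bool)
        for i in self.tip_indices:
            if self.labels[i] in keep:
                alive[i] = True
        for i in range(self.n_nodes - 1, -1, -1):  # postorder: propagate up
            if any(alive[c] for c in self.children[i]):
                alive[i] = True

        def build(i: int) -> tuple:
            """Return (label, length, children) with unifurcations collapsed."""
            kids = [c for c in self.children[i] if alive[c]]
            length = self.edge_length[i]
            while len(kids) == 1 and self.children[i]:
                # suppress this unifurcation: descend, accumulating length
                j = kids[0]
                length += self.edge_length[j]
                i = j
                kids = [c for c in self.children[i] if alive[c]]
            return (self.labels[i], length, [build(c) for c in kids])

        # find the new root: walk down while the root has a single live child
        r = self.root
        live_kids = [c for c in self.children[r] if alive[c]]
        while len(live_kids) == 1:
            r = live_kids[0]
            live_kids = [c for c in self.children[r] if alive[c]]

        parent: list[int] = []
        lengths: list[float] = []
        labels: list[str | None] = []

        def emit(node: tuple, parent_idx: int) -> None:
            label, length, kids = node
            idx = len(parent)
            parent.append(parent_idx)
            lengths.append(length if parent_idx >= 0 else 0.0)
            labels.append(label)
            for k in kids:
                emit(k, idx)

        label_r, _, kids_r = build(r)
        emit((label_r, 0.0, kids_r), -1)
        return Phylogeny(parent, lengths, labels)

    # -- conversion -------------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent, lengths, labels = [], [], []
        for nd in nodes:
            parent.append(-1 if nd.parent_node is None else index[id(nd.parent_node)])
            if nd.parent_node is not None and nd.edge.length is None:
                raise ValueError("tree has edges with missing branch lengths")
            lengths.append(nd.edge.length or 0.0)
            if nd.taxon is not None:
                labels.append(nd.taxon.label.replace(" ", "_"))
            else:
                labels.append(nd.label)
        return cls(parent, lengths, labels)

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(tree)

    def to_newick(self, precision: int = 10) -> str:
        def render(i: int) -> str:
            if not self.children[i]:
                body = self.labels[i]
            else:
                body = "(" + ",".join(render(c) for c in self.children[i]) + ")"
                if self.labels[i]:
                    body += self.labels[i]
            if i == self.root:
                return body
            return f"{body}:{self.edge_length[i]:.{precision}g}"

        return render(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny(n_tips={self.n_tips}, height={self.height:.3g} Myr)"
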