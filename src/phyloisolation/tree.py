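"""Rooted phylogenies with branch lengths: the substrate of every isolation metric.

A :class:`PhyloTree` stores a rooted tree in flat arrays indexed in postorder
(children always precede their parent, the root is the last node).  This makes
the path accumulations used by the metrics simple linear sweeps.  Newick
parsing is delegated to :mod:`dendropy`; writing is done here so the output is
deterministic (children ordered by their smallest descendant tip label).

Branch lengths are arbitrary time units; the length is carried on the child
node of each edge and a root edge, if present in the input, is ignored.
"""

from __future__ import annotations

import warnings
from typing import Iterator, Sequence

import numpy as np

try:  # dendropy emits noisy deprecation chatter on some versions
    import dendropy
except ImportError as _exc:  # pragma: no cover
    raise ImportError("phyloisolation requires dendropy for newick I/O") from _exc

__all__ = [
    "PhyloTree",
    "NewickError",
    "parse_newick",
    "patristic_matrix",
    "is_ultrametric",
    "nested_clades",
]


class NewickError(ValueError):
    """Raised when a newick string cannot be turned into a valid PhyloTree."""


class PhyloTree:
    """Rooted phylogeny in postorder array form.

    Parameters
    ----------
    parent
        ``(n_nodes,)`` int array; ``parent[v]`` is the parent id of node ``v``
        and ``-1`` for the root.  Node ids must be a postorder: every child id
        is smaller than its parent id, and the root id is ``n_nodes - 1``.
    length
        ``(n_nodes,)`` float array of branch lengths on the edge *above* each
        node; the root entry is 0.
    labels
        Mapping from tip node id to its (unique) label.
    """

    __slots__ = (
        "parent",
        "length",
        "children",
        "_labels",
        "tip_ids",
        "tip_labels",
        "_tip_pos",
        "_ntips_below",
        "_depth",
        "_n_ancestors",
        "_patristic_cache",
    )

    def __init__(self, parent: np.ndarray, length: np.ndarray, labels: dict[int, str]):
        parent = np.asarray(parent, dtype=np.int64)
        length = np.asarray(length, dtype=float)
        m = parent.size
        if m == 0 or length.size != m:
            raise ValueError("parent and length arrays must be non-empty and equal-sized")
        if parent[m - 1] != -1 or (parent[: m - 1] <= np.arange(m - 1)).any():
            raise ValueError("node ids must form a postorder with the root last")
        if (length < 0).any():
            raise ValueError("negative branch lengths are not allowed")
        self.parent = parent
        self.length = length
        self.children: list[list[int]] = [[] for _ in range(m)]
        for v in range(m - 1):
            self.children[parent[v]].append(v)
        tip_ids = [v for v in range(m) if not self.children[v]]
        if len(tip_ids) != len(labels) or any(v not in labels for v in tip_ids):
            raise ValueError("labels must cover exactly the tip nodes")
        if len(set(labels.values())) != len(labels):
            raise ValueError("tip labels must be unique")
        self._labels = dict(labels)
        order = sorted(tip_ids, key=lambda v: labels[v])
        self.tip_ids = np.asarray(order, dtype=np.int64)
        self.tip_labels: tuple[str, ...] = tuple(labels[v] for v in order)
        self._tip_pos = {v: i for i, v in enumerate(order)}
        self._ntips_below: np.ndarray | None = None
        self._depth: np.ndarray | None = None
        self._n_ancestors: np.ndarray | None = None
        self._patristic_cache: np.ndarray | None = None

    # ------------------------------------------------------------------ basic
    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_tips(self) -> int:
        return self.tip_ids.size

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def label_of(self, node: int) -> str:
        return self._labels[node]

    def tip_id(self, label: str) -> int:
        for v, lab in self._labels.items():
            if lab == label:
                return v
        raise KeyError(f"unknown tip label {label!r}")

    @property
    def total_length(self) -> float:
        """Phylogenetic diversity of the whole tree (sum of all branch lengths)."""
        return float(self.length.sum())

    @property
    def ntips_below(self) -> np.ndarray:
        """Number of tips descending from (and including) each node."""
        if self._ntips_below is None:
            n = np.zeros(self.n_nodes, dtype=np.int64)
            for v in range(self.n_nodes):
                if not self.children[v]:
                    n[v] = 1
                else:
                    n[v] = sum(n[c] for c in self.children[v])
            self._ntips_below = n
        return self._ntips_below

    @property
    def depth(self) -> np.ndarray:
        """Branch-length distance from the root to each node."""
        if self._depth is None:
            d = np.zeros(self.n_nodes)
            for v in range(self.n_nodes - 2, -1, -1):
                d[v] = d[self.parent[v]] + self.length[v]
            self._depth = d
        return self._depth

    @property
    def n_ancestors(self) -> np.ndarray:
        """Number of interior nodes strictly above each node (root included)."""
        if self._n_ancestors is None:
            a = np.zeros(self.n_nodes, dtype=np.int64)
            for v in range(self.n_nodes - 2, -1, -1):
                a[v] = a[self.parent[v]] + 1
            self._n_ancestors = a
        return self._n_ancestors

    def ancestors(self, node: int) -> Iterator[int]:
        """Yield the ancestors of ``node`` from its parent up to the root."""
        v = self.parent[node]
        while v != -1:
            yield int(v)
            v = self.parent[v]

    def preorder(self) -> Iterator[int]:
        return iter(range(self.n_nodes - 1, -1, -1))

    def accumulate_down(self, per_node: np.ndarray) -> np.ndarray:
        """Root-to-node partial sums of a per-node quantity (root term included)."""
        acc = np.array(per_node, dtype=float)
        for v in range(self.n_nodes - 2, -1, -1):
            acc[v] += acc[self.parent[v]]
        return acc

    # ------------------------------------------------------------------- I/O
    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:
            raise NewickError(f"malformed newick: {exc}") from exc
        return cls.from_dendropy(dtree)

    @classmethod
    def from_dendropy(cls, dtree: "dendropy.Tree") -> "PhyloTree":
        nodes = list(dtree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        m = len(nodes)
        parent = np.full(m, -1, dtype=np.int64)
        length = np.zeros(m)
        labels: dict[int, str] = {}
        seen: set[str] = set()
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    who = nd.taxon.label if nd.taxon else "an internal node"
                    raise NewickError(f"missing branch length on the edge above {who}")
                length[i] = float(nd.edge.length)
            if nd.is_leaf():
                if nd.taxon is None or not nd.taxon.label:
                    raise NewickError("tip without a label")
                lab = nd.taxon.label
                if lab in seen:
                    raise NewickError(f"duplicate tip label {lab!r}")
                seen.add(lab)
                labels[i] = lab
        if len(labels) < 2:
            raise NewickError("a tree needs at least two tips")
        return cls(parent, length, labels)

    def to_newick(self) -> str:
        """Deterministic newick string: children sorted by smallest tip label."""
        min_label = [""] * self.n_nodes
        for v in range(self.n_nodes):
            if not self.children[v]:
                min_label[v] = self._labels[v]
            else:
                min_label[v] = min(min_label[c] for c in self.children[v])

        def fmt(v: int) -> str:
            if not self.children[v]:
                body = self._labels[v]
            else:
                kids = sorted(self.children[v], key=lambda c: min_label[c])
                body = "(" + ",".join(fmt(c) for c in kids) + ")"
            if v == self.root:
                return body
            # repr() emits the shortest string that round-trips the float
            return f"{body}:{float(self.length[v])!r}"

        return fmt(self.root) + ";"

    # -------------------------------------------------------------- distances
    def patristic(self) -> np.ndarray:
        """Tip-to-tip path-length matrix, rows/cols in ``tip_labels`` order."""
        if self._patristic_cache is None:
            n = self.n_tips
            depth = self.depth
            d = np.zeros((n, n))
            # tips under each node, as positions in tip order
            under: list[np.ndarray | None] = [None] * self.n_nodes
            for v in range(self.n_nodes):
                if not self.children[v]:
                    under[v] = np.array([self._tip_pos[v]], dtype=np.int64)
                else:
                    parts = [under[c] for c in self.children[v]]
                    for a in range(len(parts)):
                        for b in range(a + 1, len(parts)):
                            ia, ib = parts[a], parts[b]
                            block = (
                                depth[self.tip_ids[ia]][:, None]
                                + depth[self.tip_ids[ib]][None, :]
                                - 2.0 * depth[v]
                            )
                            d[np.ix_(ia, ib)] = block
                            d[np.ix_(ib, ia)] = block.T
                    under[v] = np.concatenate(parts)
            self._patristic_cache = d
        return self._patristic_cache

    # ------------------------------------------------------------- subtrees
    def extract_clade(self, node: int) -> "PhyloTree":
        """The complete subtree rooted at ``node`` as a new tree (root edge 0)."""
        if not self.children[node]:
            raise ValueError("cannot extract a clade rooted at a tip")
        order: list[int] = []
        stack: list[tuple[int, bool]] = [(node, False)]
        while stack:
            v, done = stack.pop()
            if done:
                order.append(v)
            else:
                stack.append((v, True))
                stack.extend((c, False) for c in self.children[v])
        remap = {old: new for new, old in enumerate(order)}
        m = len(order)
        parent = np.full(m, -1, dtype=np.int64)
        length = np.zeros(m)
        labels: dict[int, str] = {}
        for old in order:
            new = remap[old]
            if old != node:
                parent[new] = remap[self.parent[old]]
                length[new] = self.length[old]
            if not self.children[old]:
                labels[new] = self._labels[old]
        return PhyloTree(parent, length, labels)


# ---------------------------------------------------------------------- API


def parse_newick(text: str) -> PhyloTree:
    """Parse a newick string (branch lengths required, polytomies allowed)."""
    return PhyloTree.from_newick(text)


def patristic_matrix(tree: PhyloTree):
    """Patristic (path-length) distance matrix as a labelled DataFrame."""
    import pandas as pd

    d = tree.patristic()
    labels = list(tree.tip_labels)
    return pd.DataFrame(d, index=labels, columns=labels)


def is_ultrametric(tree: PhyloTree, tol: float = 1e-6) -> bool:
    """True when all root-to-tip depths agree within ``tol`` (relative to depth)."""
    depths = tree.depth[tree.tip_ids]
    dmax = depths.max()
    if dmax == 0:
        return True
    return bool((dmax - depths.min()) <= tol * dmax)


def warn_if_not_ultrametric(tree: PhyloTree, context: str = "metric computation") -> None:
    if not is_ultrametric(tree):
        warnings.warn(
            f"tree is not ultrametric; {context} proceeds but some scores "
            "(e.g. the Rao-entropy weights) are defined with ultrametric trees in mind",
            stacklevel=3,
        )


def nested_clades(tree: PhyloTree, target_tip: str) -> list[PhyloTree]:
    """Complete clades containing ``target_tip``, smallest to the full tree.

    One subtree per interior node on the tip's root path, i.e. the sequence of
    increasingly large complete clades a score could be computed on.
    """
    tip = tree.tip_id(target_tip)
    return [tree.extract_clade(anc) for anc in tree.ancestors(tip)]
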