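"""Phylogeny handling: validation, canonical indexing, and path design matrices.

A rooted, time-calibrated tree (branch lengths in Myr) is wrapped in a
:class:`TreeIndex`, which fixes a canonical preorder over nodes and branches
and exposes the root-to-node path-length matrices used by the ridge
regression. Every branch is identified by its child node; internal nodes are
labelled ``N<k>`` by preorder rank and tips keep their taxon labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["TreeIndex", "read_tree", "build_design_matrix"]


def read_tree(path_or_string: str, *, collapse_zero_branches: bool = False) -> dendropy.Tree:
    """Read a rooted Newick tree from a file path or a Newick string.

    Parameters
    ----------
    path_or_string
        Filesystem path to a Newick file, or a string starting with ``(``
        interpreted as Newick data directly.
    collapse_zero_branches
        If True, zero-length internal branches are collapsed into polytomies
        before indexing (zero-length branches otherwise make per-branch rates
        unidentifiable and are rejected by :class:`TreeIndex`).
    """
    s = str(path_or_string)
    if s.lstrip().startswith("("):
        tree = dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True)
    else:
        tree = dendropy.Tree.get(path=s, schema="newick", preserve_underscores=True)
    if collapse_zero_branches:
        tree.collapse_unweighted_edges()
    return tree


@dataclass
class TreeIndex:
    """Canonical arrays for one rooted phylogeny.

    Attributes
    ----------
    node_ids : list of str
        All node identifiers in preorder; the root is first.
    branch_ids : list of str
        Branch identifiers (= child node id), preorder, length ``n_branches``.
    branch_lengths : ndarray, shape (n_branches,)
        Strictly positive lengths in Myr.
    tip_labels : list of str
        Tip labels in preorder encounter order; rows of ``design_matrix``.
    design_matrix : ndarray, shape (n_tips, n_branches)
        Entry (i, b) is the length of branch b if it lies on the root-to-tip-i
        path, else 0. Row sums equal root-to-tip distances.
    node_paths : ndarray, shape (n_nodes, n_branches)
        Same construction for every node (the root row is all zero); used to
        accumulate ancestral states from per-branch rates.
    """

    tree: dendropy.Tree
    node_ids: list = field(init=False)
    branch_ids: list = field(init=False)
    branch_parent_ids: list = field(init=False)
    branch_lengths: np.ndarray = field(init=False)
    tip_labels: list = field(init=False)
    design_matrix: np.ndarray = field(init=False)
    node_paths: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        tree = self.tree
        root = tree.seed_node
        nodes = list(tree.preorder_node_iter())
        if nodes[0] is not root:  # pragma: no cover - dendropy guarantees this
            raise ValueError("preorder traversal must start at the root")

        node_ids, tip_labels = [], []
        internal_count = 0
        id_of = {}
        for nd in nodes:
            if nd.is_leaf():
                if nd.taxon is None or not nd.taxon.label:
                    raise ValueError("every tip must be labelled")
                nid = str(nd.taxon.label)
                tip_labels.append(nid)
            else:
                nid = f"N{internal_count}"
                internal_count += 1
            id_of[nd] = nid
            node_ids.append(nid)
        if len(set(tip_labels)) != len(tip_labels):
            raise ValueError("tip labels must be unique")
        if len(tip_labels) < 2:
            raise ValueError("tree must have at least 2 tips")

        branch_nodes = [nd for nd in nodes if nd is not root]
        lengths = np.array(
            [nd.edge.length if nd.edge.length is not None else np.nan for nd in branch_nodes],
            dtype=float,
        )
        if np.any(~np.isfinite(lengths)):
            raise ValueError("all branches must have finite lengths")
        if np.any(lengths <= 0):
            bad = [id_of[nd] for nd, ln in zip(branch_nodes, lengths) if ln <= 0]
            raise ValueError(
                f"zero/negative-length branches at {bad}; rates on them are "
                "unidentifiable (use read_tree(..., collapse_zero_branches=True))"
            )

        branch_index = {nd: i for i, nd in enumerate(branch_nodes)}
        n_nodes, n_branches = len(nodes), len(branch_nodes)
        paths = np.zeros((n_nodes, n_branches))
        node_row = {nd: i for i, nd in enumerate(nodes)}
        for nd in nodes:
            if nd is root:
                continue
            r = node_row[nd]
            paths[r] = paths[node_row[nd.parent_node]]
            paths[r, branch_index[nd]] = lengths[branch_index[nd]]

        tip_rows = [node_row[nd] for nd in nodes if nd.is_leaf()]
        self.node_ids = node_ids
        self.branch_ids = [id_of[nd] for nd in branch_nodes]
        self.branch_parent_ids = [id_of[nd.parent_node] for nd in branch_nodes]
        self.branch_lengths = lengths
        self.tip_labels = tip_labels
        self.node_paths = paths
        self.design_matrix = paths[tip_rows]
        self._tip_row_of = {lab: i for i, lab in enumerate(tip_labels)}
        self._node_row_of = {nid: i for i, nid in enumerate(node_ids)}
        self._branch_is_tip = np.array([nd.is_leaf() for nd in branch_nodes])

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_branches(self) -> int:
        return len(self.branch_ids)

    @property
    def branch_is_tip(self) -> np.ndarray:
        """Boolean mask over branches: True for terminal branches."""
        return self._branch_is_tip

    def node_row(self, node_id: str) -> int:
        return self._node_row_of[node_id]

    def tip_row(self, label: str) -> int:
        return self._tip_row_of[label]

    def align_traits(self, table) -> np.ndarray:
        """Reorder a (tips x k) trait table to this index's tip order.

        ``table`` may be a pandas DataFrame indexed by tip label, or an
        ndarray already in ``tip_labels`` order.
        """
        arr = np.asarray(table, dtype=float)
        if hasattr(table, "loc") and hasattr(table, "index"):
            missing = set(self.tip_labels) - set(map(str, table.index))
            if missing:
                raise ValueError(f"traits missing for tips: {sorted(missing)[:5]}...")
            arr = np.asarray(table.loc[self.tip_labels], dtype=float)
        if arr.shape[0] != self.n_tips:
            raise ValueError(
                f"trait table has {arr.shape[0]} rows but the tree has {self.n_tips} tips"
            )
        return arr

    def mrca_matrix(self) -> np.ndarray:
        """Tip x tip matrix of shared root-to-tip path length (MRCA depth).

        This is the Brownian-motion covariance structure of the tree (up to
        the rate constant sigma^2).
        """
        w = np.sqrt(self.design_matrix)
        return w @ w.T


def build_design_matrix(tree) -> np.ndarray:
    """Root-to-tip path matrix of a tree (tips x branches, entries = lengths).

    Convenience wrapper: accepts a dendropy Tree, a Newick string/path, or a
    TreeIndex, and returns the (tips x branches) design matrix in canonical
    preorder branch order.
    """
    index = as_tree_index(tree)
    return index.design_matrix.copy()


def as_tree_index(tree) -> TreeIndex:
    """Coerce a Tree / Newick string / path / TreeIndex into a TreeIndex."""
    if isinstance(tree, TreeIndex):
        return tree
    if isinstance(tree, dendropy.Tree):
        return TreeIndex(tree)
    return TreeIndex(read_tree(tree))
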