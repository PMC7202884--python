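"""Rooted phylogeny container with Newick I/O and branch-length queries.

The tree is stored as flat arrays (parent pointers, branch lengths,
post-order) so that downstream stages — phylogenetic diversity (PD),
shared-branch sums, site-by-node matrices — reduce to vectorized
operations over node indices.  Branch lengths are interpreted as
durations in millions of years; the branch subtending the root is
always treated as zero so PD sums are invariant to a root stalk.

Newick parsing and writing delegate to :mod:`dendropy`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "NewickError",
    "UnknownTipError",
    "read_newick",
    "write_newick",
    "pd_total",
    "branch_incidence",
    "normalize_label",
]


class NewickError(ValueError):
    """Malformed Newick input (bad parentheses, duplicate or missing labels,
    missing branch lengths)."""


class UnknownTipError(KeyError):
    """A requested tip label is not on the tree."""

    def __init__(self, missing: Sequence[str]):
        self.missing = list(missing)
        super().__init__(f"tip labels not on tree: {sorted(self.missing)}")


def normalize_label(label: str) -> str:
    """Canonical genus-name form: trimmed, spaces replaced by underscores."""
    return label.strip().replace(" ", "_")


@dataclass
class Phylogeny:
    """A rooted tree over genus tips.

    Attributes
    ----------
    parent : int array, shape (n_nodes,)
        Parent node index; -1 for the root.
    brlen : float array, shape (n_nodes,)
        Length of the branch subtending each node (Myr); 0.0 at the root.
    children : list of int lists
        Child node indices per node (empty for tips); polytomies allowed.
    tip_labels : str array, shape (n_nodes,)
        Genus name for tip nodes, "" for internal nodes.
    postorder : int array
        Node indices with every child preceding its parent.
    root : int
        Root node index.
    """

    parent: np.ndarray
    brlen: np.ndarray
    children: list
    tip_labels: np.ndarray
    postorder: np.ndarray
    root: int
    _tip_index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._tip_index:
            self._tip_index = {
                lab: i for i, lab in enumerate(self.tip_labels) if lab
            }

    # -- basic structure ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def tip_ids(self) -> np.ndarray:
        """Node indices of tips, in post-order."""
        return np.array([i for i in self.postorder if not self.children[i]])

    @property
    def internal_ids(self) -> np.ndarray:
        """Node indices of internal nodes, in post-order."""
        return np.array([i for i in self.postorder if self.children[i]])

    @property
    def n_tips(self) -> int:
        return len(self._tip_index)

    @property
    def labels(self) -> list:
        """Tip labels in post-order."""
        return [self.tip_labels[i] for i in self.tip_ids]

    @property
    def total_length(self) -> float:
        """Sum of all branch lengths (root branch excluded by convention)."""
        return float(self.brlen.sum())

    def tip_id(self, label: str) -> int:
        try:
            return self._tip_index[normalize_label(label)]
        except KeyError:
            raise UnknownTipError([label]) from None

    def has_tip(self, label: str) -> bool:
        return normalize_label(label) in self._tip_index

    # -- derived structure -------------------------------------------------
    def descendant_tips(self) -> list:
        """Per node, the set of descendant tip labels (tips descend themselves)."""
        out = [set() for _ in range(self.n_nodes)]
        for i in self.postorder:
            if not self.children[i]:
                out[i] = {self.tip_labels[i]}
            else:
                for c in self.children[i]:
                    out[i] |= out[c]
        return out

    def representative_tip_pair(self, node: int) -> tuple:
        """Two tip labels whose most recent common ancestor is ``node``.

        For a tip node, returns the tip label twice.
        """
        if not self.children[node]:
            lab = self.tip_labels[node]
            return (lab, lab)

        def first_tip(i: int) -> str:
            while self.children[i]:
                i = self.children[i][0]
            return self.tip_labels[i]

        return (first_tip(self.children[node][0]),
                first_tip(self.children[node][-1]))

    def prune_to(self, keep: Iterable[str]) -> "Phylogeny":
        """Subtree induced by the given tip labels (topology preserved,
        no branch suppression: internal nodes with one remaining child are
        kept so PD sums stay comparable to the full tree)."""
        keep_ids = resolve_tips(self, keep)
        mask = np.zeros(self.n_nodes, dtype=bool)
        for i in keep_ids:
            j = i
            while j != -1 and not mask[j]:
                mask[j] = True
                j = self.parent[j]
        old_to_new = -np.ones(self.n_nodes, dtype=int)
        kept = np.flatnonzero(mask)
        old_to_new[kept] = np.arange(len(kept))
        parent = np.array(
            [old_to_new[self.parent[i]] if self.parent[i] != -1 else -1
             for i in kept]
        )
        children = [[] for _ in kept]
        for new_i, p in enumerate(parent):
            if p != -1:
                children[p].append(new_i)
        post = np.array([old_to_new[i] for i in self.postorder if mask[i]])
        return Phylogeny(
            parent=parent,
            brlen=self.brlen[kept].copy(),
            children=children,
            tip_labels=self.tip_labels[kept].copy(),
            postorder=post,
            root=int(old_to_new[self.root]),
        )


def _from_dendropy(dtree: dendropy.Tree) -> Phylogeny:
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, -1, dtype=int)
    brlen = np.zeros(n, dtype=float)
    children: list = [[] for _ in range(n)]
    tip_labels = np.array([""] * n, dtype=object)
    seen: set = set()
    for i, nd in enumerate(nodes):
        if nd.parent_node is not None:
            p = index[id(nd.parent_node)]
            parent[i] = p
            children[p].append(i)
            if nd.edge.length is None:
                raise NewickError(
                    f"missing branch length on edge above node #{i}"
                )
            if nd.edge.length < 0:
                raise NewickError(f"negative branch length at node #{i}")
            brlen[i] = float(nd.edge.length)
        if nd.is_leaf():
            if nd.taxon is None or not str(nd.taxon.label).strip():
                raise NewickError(f"unlabeled tip at node #{i}")
            lab = normalize_label(str(nd.taxon.label))
            if lab in seen:
                raise NewickError(f"duplicate tip label {lab!r}")
            seen.add(lab)
            tip_labels[i] = lab
    postorder = np.array(
        [index[id(nd)] for nd in dtree.postorder_node_iter()]
    )
    return Phylogeny(
        parent=parent,
        brlen=brlen,
        children=children,
        tip_labels=tip_labels,
        postorder=postorder,
        root=0,
    )


def read_newick(source) -> Phylogeny:
    """Parse a single Newick tree from a path, string or text stream.

    Branch lengths are mandatory on every non-root edge; tip labels must
    be unique after whitespace/underscore normalization.  Polytomies are
    accepted as-is.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
        if "(" not in text:  # path, not newick literal
            with open(text) as fh:
                text = fh.read()
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"malformed Newick: {exc}") from exc
    return _from_dendropy(dtree)


def _to_dendropy(tree: Phylogeny) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace()
    dnodes = [dendropy.Node() for _ in range(tree.n_nodes)]
    for i in range(tree.n_nodes):
        if tree.parent[i] != -1:
            dnodes[i].edge.length = float(tree.brlen[i])
        if not tree.children[i]:
            dnodes[i].taxon = taxa.new_taxon(tree.tip_labels[i])
        for c in tree.children[i]:
            dnodes[i].add_child(dnodes[c])
    return dendropy.Tree(seed_node=dnodes[tree.root], taxon_namespace=taxa)


def write_newick(tree: Phylogeny, path=None) -> str:
    """Serialize to Newick with round-trip (shortest-repr) branch lengths."""
    s = _to_dendropy(tree).as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".17g",
        preserve_spaces=False,
        unquoted_underscores=True,
    ).strip()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s + "\n")
    return s


def resolve_tips(tree: Phylogeny, tips: Iterable[str]) -> np.ndarray:
    """Tip labels -> node indices; raises :class:`UnknownTipError` listing
    every missing name."""
    labels = [normalize_label(t) for t in tips]
    missing = [t for t in labels if t not in tree._tip_index]
    if missing:
        raise UnknownTipError(missing)
    return np.array([tree._tip_index[t] for t in labels], dtype=int)


def pd_total(tree: Phylogeny, tips: Iterable[str]) -> float:
    """Faith's phylogenetic diversity of a tip set, in Myr.

    Sum of branch lengths of the minimal subtree connecting the tips to
    the global root (root branch excluded).  Equals the total tree
    length when every branch has a descendant among ``tips``.
    """
    ids = resolve_tips(tree, tips)
    if len(ids) == 0:
        raise ValueError("tip set is empty")
    visited = np.zeros(tree.n_nodes, dtype=bool)
    total = 0.0
    for i in ids:
        j = i
        while j != -1 and not visited[j]:
            visited[j] = True
            total += tree.brlen[j]
            j = tree.parent[j]
    return float(total)


def branch_incidence(tree: Phylogeny, occupancy: np.ndarray,
                     genus_order: Sequence[str]) -> np.ndarray:
    """Branch x assemblage incidence from a site x genus occupancy matrix.

    Parameters
    ----------
    occupancy : bool/int array, shape (n_sites, n_genera)
    genus_order : tip labels matching occupancy columns (all must be on
        the tree).

    Returns
    -------
    bool array, shape (n_sites, n_nodes)
        Entry (i, b) is True iff at least one tip descending branch b
        occurs at site i.  Summing ``tree.brlen`` over a row's flagged
        branches yields that site's PD.
    """
    tip_ids = resolve_tips(tree, genus_order)
    occupancy = np.asarray(occupancy)
    inc = np.zeros((occupancy.shape[0], tree.n_nodes), dtype=bool)
    inc[:, tip_ids] = occupancy > 0
    for i in tree.postorder:
        for c in tree.children[i]:
            inc[:, i] |= inc[:, c]
    return inc
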