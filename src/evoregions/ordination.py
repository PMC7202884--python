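"""Evolutionary PCA: ordination of assemblages by lineage composition.

Each site is described not by its genera alone but by every branch of
the phylogeny it contains: the site x branch matrix has entry
``x_ib * l_b`` where ``x_ib`` indicates whether any tip descending
branch ``b`` occurs at site ``i`` and ``l_b`` is the branch length.
Rows are Hellinger-transformed (square root of the row-relative value),
which damps the dominance of long, widely shared deep branches and is a
standard pre-transformation for linear ordination of composition data.
A centered PCA (via SVD) of the transformed matrix yields site scores
and per-branch clade loadings.

On a star phylogeny with unit branch lengths every branch is one tip,
so the whole construction collapses to an ordinary centered PCA of the
Hellinger-transformed genus matrix — a useful analytic anchor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assemblages import AssemblageMatrix
from .tree import Phylogeny, branch_incidence

__all__ = ["EvoPcaResult", "site_by_branch_matrix", "evopca", "hellinger"]


@dataclass
class EvoPcaResult:
    site_scores: pd.DataFrame  # sites x axes
    clade_loadings: pd.DataFrame  # branches x axes, indexed by node id
    eigenvalues: np.ndarray
    var_explained: np.ndarray
    branch_nodes: list  # node ids in column order of the site x branch matrix
    mrca_pairs: list  # per branch, a defining tip pair for the subtended clade

    def top_clades(self, axis: int, n: int = 10) -> pd.DataFrame:
        """Branches with the largest |loading| on one axis (1-based)."""
        col = f"axis{axis}"
        order = self.clade_loadings[col].abs().sort_values(ascending=False)
        out = self.clade_loadings.loc[order.index[:n], [col]].copy()
        idx = {node: k for k, node in enumerate(self.branch_nodes)}
        out["mrca_tips"] = [
            "|".join(self.mrca_pairs[idx[node]]) for node in out.index
        ]
        return out


def site_by_branch_matrix(tree: Phylogeny, m: AssemblageMatrix):
    """Branch-length-weighted site x branch matrix.

    Returns (matrix, node ids in deterministic post-order).  The root
    branch (length 0) is excluded.
    """
    inc = branch_incidence(tree, m.occupancy, m.genus_ids)
    nodes = [int(i) for i in tree.postorder if i != tree.root]
    W = inc[:, nodes] * tree.brlen[nodes]
    return W, nodes


def hellinger(W: np.ndarray) -> np.ndarray:
    """Row-wise Hellinger transform: y_ib = sqrt(w_ib / sum_b w_ib).

    Every transformed row has unit sum of squares.
    """
    W = np.asarray(W, dtype=float)
    rowsum = W.sum(axis=1, keepdims=True)
    if (rowsum <= 0).any():
        bad = np.flatnonzero(rowsum[:, 0] <= 0)
        raise ValueError(f"all-zero rows at positions {bad.tolist()}")
    return np.sqrt(W / rowsum)


def evopca(tree: Phylogeny, m: AssemblageMatrix, n_axes: int = 5) -> EvoPcaResult:
    """Evolutionary PCA of an assemblage matrix on a phylogeny.

    Steps: site x branch weighting, row Hellinger transform, column
    centering, SVD.  Site scores are the left singular vectors scaled by
    the singular values; clade loadings are the right singular vectors.
    Axis signs are fixed so the largest-magnitude loading on each axis
    is positive.
    """
    if m.n_sites < 3:
        raise ValueError("evoPCA needs at least three sites")
    W, nodes = site_by_branch_matrix(tree, m)
    zero_rows = np.flatnonzero(W.sum(axis=1) <= 0)
    if len(zero_rows):
        raise ValueError(
            f"sites with no branch weight: {[m.site_ids[i] for i in zero_rows]}"
        )
    Y = hellinger(W)
    Yc = Y - Y.mean(axis=0)
    U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    n_axes = min(n_axes, len(s))
    U, s, Vt = U[:, :n_axes], s[:n_axes], Vt[:n_axes]
    # sign convention: largest |loading| positive per axis
    for k in range(n_axes):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    eig = s ** 2 / (m.n_sites - 1)
    total_var = float((Yc ** 2).sum()) / (m.n_sites - 1)
    axes = [f"axis{k + 1}" for k in range(n_axes)]
    scores = pd.DataFrame(U * s, index=m.site_ids, columns=axes)
    loadings = pd.DataFrame(Vt.T, index=pd.Index(nodes, name="node"),
                            columns=axes)
    return EvoPcaResult(
        site_scores=scores,
        clade_loadings=loadings,
        eigenvalues=eig,
        var_explained=eig / total_var,
        branch_nodes=nodes,
        mrca_pairs=[tree.representative_tip_pair(i) for i in nodes],
    )
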