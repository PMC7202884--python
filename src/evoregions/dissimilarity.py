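"""Pairwise phylogenetic dissimilarity between assemblages.

Both measures are defined on the sets of tree branches subtended by
each assemblage's genera (every branch with at least one descendant tip
present at the site counts, weighted by its length):

* PhyloSor complement (Sorensen-type, the primary measure)::

      d_ij = 1 - BL_ij / (0.5 * (BL_i + BL_j))

  where BL_ij is the summed length of branches shared by sites i and j,
  and BL_i, BL_j their total (rooted) PD.  d = 0 when the branch sets
  coincide, d = 1 when the two assemblages are reciprocally
  monophyletic and share no branches.

* UniFrac complement (Jaccard-type, secondary)::

      d_ij = 1 - BL_ij / (BL_i + BL_j - BL_ij)

Both are computed from a single post-order branch-incidence pass and a
site x site matrix product — never per-pair subtree extraction — so the
full matrix for thousands of sites stays cheap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .assemblages import AssemblageMatrix
from .tree import Phylogeny, branch_incidence

__all__ = ["DissimilarityMatrix", "phylosor_complement", "unifrac_complement"]


class DissimilarityMatrix:
    """Symmetric site x site dissimilarity in [0, 1] with zero diagonal."""

    def __init__(self, values: np.ndarray, site_ids):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if values.shape[0] != len(site_ids):
            raise ValueError("site_ids length mismatch")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if (values < -1e-12).any() or (values > 1 + 1e-12).any():
            raise ValueError("dissimilarities must lie in [0, 1]")
        values = np.clip((values + values.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(values, 0.0)
        self.values = values
        self.site_ids = list(site_ids)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_ids,
                            columns=self.site_ids)

    def to_csv(self, path):
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DissimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(), list(df.index))

    def loc(self, i, j) -> float:
        a = self.site_ids.index(i)
        b = self.site_ids.index(j)
        return float(self.values[a, b])

    def reorder(self, site_ids) -> "DissimilarityMatrix":
        idx = [self.site_ids.index(s) for s in site_ids]
        return DissimilarityMatrix(self.values[np.ix_(idx, idx)], site_ids)

    def __repr__(self):
        return f"DissimilarityMatrix({self.n_sites} sites)"


def _branch_sums(tree: Phylogeny, m: AssemblageMatrix):
    """Per-site PD vector and pairwise shared-branch-length matrix."""
    inc = branch_incidence(tree, m.occupancy, m.genus_ids)
    lengths = tree.brlen  # root entry is 0 -> root branch never counted
    pd_i = inc @ lengths
    if (pd_i <= 0).any():
        bad = [m.site_ids[k] for k in np.flatnonzero(pd_i <= 0)]
        raise ValueError(f"sites with zero PD (no tips on tree): {bad}")
    weighted = inc * lengths  # (S x B)
    shared = weighted @ inc.T  # BL_ij
    return pd_i, shared


def phylosor_complement(tree: Phylogeny, m: AssemblageMatrix) -> DissimilarityMatrix:
    """One-complement of the PhyloSor index for every site pair."""
    pd_i, shared = _branch_sums(tree, m)
    denom = 0.5 * (pd_i[:, None] + pd_i[None, :])
    d = 1.0 - shared / denom
    return DissimilarityMatrix(d, m.site_ids)


def unifrac_complement(tree: Phylogeny, m: AssemblageMatrix) -> DissimilarityMatrix:
    """One-complement of the (unweighted) UniFrac similarity for every
    site pair: unique branch length over union branch length."""
    pd_i, shared = _branch_sums(tree, m)
    union = pd_i[:, None] + pd_i[None, :] - shared
    d = 1.0 - shared / union
    return DissimilarityMatrix(d, m.site_ids)
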