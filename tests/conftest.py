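"""Shared fixtures and independent brute-force oracles.

The oracles recompute quantities by explicit enumeration (root-path
branch sets, double-loop silhouettes, per-combination site counting) so
the vectorized implementations are checked against logic that shares no
code with them.
"""

import numpy as np
import pandas as pd
import pytest

from evoregions import AssemblageMatrix, SimulationConfig, simulate_tree
from evoregions.tree import Phylogeny, read_newick


@pytest.fixture
def basic_tree() -> Phylogeny:
    """((A:1,B:1):1,C:2); — 3 tips, 5 nodes, total length 5."""
    return read_newick("((A:1,B:1):1,C:2);")


def make_random_tree(seed: int, n_tips: int = 20) -> Phylogeny:
    return simulate_tree(SimulationConfig(n_genera=n_tips, seed=seed))


def make_random_matrix(tree: Phylogeny, seed: int,
                       n_sites: int = 10) -> AssemblageMatrix:
    """Random presence/absence over the tree's tips, every row nonempty."""
    rng = np.random.default_rng(seed)
    labels = tree.labels
    occ = (rng.random((n_sites, len(labels))) < 0.4).astype(int)
    for i in range(n_sites):  # guarantee nonempty rows
        if occ[i].sum() == 0:
            occ[i, rng.integers(len(labels))] = 1
    return AssemblageMatrix(pd.DataFrame(
        occ, index=[f"s{i}" for i in range(n_sites)], columns=labels))


# -- oracles ---------------------------------------------------------------

def branch_set(tree: Phylogeny, tips) -> set:
    """Union of root-path branch ids for a tip set (root excluded)."""
    out = set()
    for t in tips:
        j = tree.tip_id(t)
        while tree.parent[j] != -1:
            out.add(j)
            j = tree.parent[j]
    return out


def branch_set_pd(tree: Phylogeny, tips) -> float:
    return sum(tree.brlen[b] for b in branch_set(tree, tips))


def naive_phylosor(tree: Phylogeny, tips_i, tips_j) -> float:
    bi, bj = branch_set(tree, tips_i), branch_set(tree, tips_j)
    shared = sum(tree.brlen[b] for b in bi & bj)
    pi = sum(tree.brlen[b] for b in bi)
    pj = sum(tree.brlen[b] for b in bj)
    return 1.0 - shared / (0.5 * (pi + pj))


def naive_unifrac(tree: Phylogeny, tips_i, tips_j) -> float:
    bi, bj = branch_set(tree, tips_i), branch_set(tree, tips_j)
    shared = sum(tree.brlen[b] for b in bi & bj)
    union = sum(tree.brlen[b] for b in bi | bj)
    return 1.0 - shared / union


def naive_silhouette(D: np.ndarray, labels: np.ndarray) -> np.ndarray:
    n = len(labels)
    s = np.zeros(n)
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            continue
        a = np.mean([D[i, j] for j in own])
        b = min(
            np.mean([D[i, j] for j in range(n) if labels[j] == g])
            for g in set(labels) if g != labels[i]
        )
        if max(a, b) > 0:
            s[i] = (b - a) / max(a, b)
    return s


def naive_indval(presence: pd.DataFrame, labels, combos):
    """(unit, combo) -> (A, B, stat) by explicit site counting."""
    labels = np.asarray(labels)
    out = {}
    for unit in presence.columns:
        col = presence[unit].to_numpy() > 0
        if col.sum() == 0:
            continue
        for combo in combos:
            in_c = np.isin(labels, list(combo))
            np_c = int((col & in_c).sum())
            A = np_c / col.sum()
            B = np_c / in_c.sum()
            out[(unit, tuple(sorted(combo)))] = (A, B, np.sqrt(A * B))
    return out
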