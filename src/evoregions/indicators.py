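"""Indicator analysis for genera and for phylogeny nodes.

For a unit (genus or internal node) and a candidate group combination c:

* specificity  A = P(site in c | unit present)
               = (occupied sites in c) / (occupied sites anywhere)
* fidelity     B = P(unit present | site in c)
               = (occupied sites in c) / (sites in c)
* stat = sqrt(A * B)

Candidate combinations are all nonempty proper subsets of the groups
(so the uninformative "everywhere" combination is never reported); per
unit the combination maximizing stat is selected, ties broken by
smallest combination then lexicographic order.  The group-size
corrected specificity (relative-frequency weighted, the "IndVal.g"
convention) is available behind a flag; the default follows the plain
probability definitions above.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .assemblages import AssemblageMatrix
from .tree import Phylogeny, branch_incidence

__all__ = [
    "IndicatorTable",
    "indval",
    "indval_genera",
    "site_by_node_matrix",
    "indicator_nodes",
]

MAX_GROUPS = 5  # keeps the subset lattice small (<= 30 combinations)


@dataclass
class IndicatorTable:
    """Best combination per unit plus the full per-combination table.

    ``best`` columns: unit, combo (sorted tuple of group ids), A, B, stat.
    ``per_combo`` holds every (unit, combo) pair.
    """

    best: pd.DataFrame
    per_combo: pd.DataFrame
    groups: list

    def for_combo(self, combo) -> pd.DataFrame:
        combo = tuple(sorted(combo))
        return self.best[self.best["combo"] == combo]

    def combos(self) -> list:
        return sorted(set(self.best["combo"]), key=lambda c: (len(c), c))

    def specificity(self, unit) -> float:
        row = self.best[self.best["unit"] == unit]
        if row.empty:
            raise KeyError(f"unit {unit!r} not in indicator table")
        return float(row["A"].iloc[0])


def _candidate_combos(groups, allow_combos: bool):
    groups = sorted(groups)
    if not allow_combos:
        return [(g,) for g in groups]
    out = []
    for r in range(1, len(groups)):  # proper subsets only
        out.extend(combinations(groups, r))
    return out


def indval(presence: pd.DataFrame, labels, allow_combos: bool = True,
           group_corrected: bool = False) -> IndicatorTable:
    """Indicator statistics for every column of a site x unit 0/1 table.

    ``labels`` assigns each site (row) to a group.  Units absent from
    every site are excluded.  Raises if fewer than two groups, more
    than :data:`MAX_GROUPS`, or any group has no sites.
    """
    labels = np.asarray(labels)
    if presence.shape[0] != len(labels):
        raise ValueError("labels length does not match matrix rows")
    groups = [g.item() if hasattr(g, "item") else g
              for g in np.unique(labels)]
    if len(groups) < 2:
        raise ValueError("indicator analysis needs at least two groups")
    if len(groups) > MAX_GROUPS:
        raise ValueError(f"more than {MAX_GROUPS} groups not supported")
    X = (presence.to_numpy() > 0)
    units = list(presence.columns)
    n_per_group = {g: int((labels == g).sum()) for g in groups}
    if any(v == 0 for v in n_per_group.values()):
        raise ValueError("every group must contain at least one site")
    # occupied-site counts per (group, unit)
    occ = {g: X[labels == g].sum(axis=0).astype(float) for g in groups}
    total_occ = X.sum(axis=0).astype(float)
    present = total_occ > 0
    rel = {g: occ[g] / n_per_group[g] for g in groups}
    rel_total = np.sum([rel[g] for g in groups], axis=0)

    rows = []
    for combo in _candidate_combos(groups, allow_combos):
        np_c = np.sum([occ[g] for g in combo], axis=0)
        n_c = sum(n_per_group[g] for g in combo)
        with np.errstate(invalid="ignore", divide="ignore"):
            if group_corrected:
                A = np.sum([rel[g] for g in combo], axis=0) / rel_total
            else:
                A = np_c / total_occ
        B = np_c / n_c
        stat = np.sqrt(A * B)
        for k in np.flatnonzero(present):
            rows.append((units[k], tuple(combo), float(A[k]), float(B[k]),
                         float(stat[k])))
    per_combo = pd.DataFrame(rows, columns=["unit", "combo", "A", "B", "stat"])

    # best combo per unit: max stat, ties -> smallest combo, lexicographic
    picks = []
    for _, df in per_combo.groupby("unit", sort=False):
        cand = df[df["stat"] >= df["stat"].max() - 1e-12]
        picks.append(min(cand.index,
                         key=lambda i: (len(cand.at[i, "combo"]),
                                        cand.at[i, "combo"])))
    best = (per_combo.loc[picks]
            .sort_values("stat", ascending=False, kind="stable")
            .reset_index(drop=True))
    return IndicatorTable(best=best, per_combo=per_combo, groups=groups)


def indval_genera(m: AssemblageMatrix, labels, allow_combos: bool = True,
                  group_corrected: bool = False) -> IndicatorTable:
    """Indicator genera for a clustering of the assemblages."""
    return indval(m.data, labels, allow_combos=allow_combos,
                  group_corrected=group_corrected)


def site_by_node_matrix(tree: Phylogeny, m: AssemblageMatrix) -> pd.DataFrame:
    """Site x internal-node presence/absence: a node is present at a site
    iff at least one of its descendant tips is."""
    inc = branch_incidence(tree, m.occupancy, m.genus_ids)
    nodes = [int(i) for i in tree.internal_ids]
    return pd.DataFrame(inc[:, nodes].astype(np.int8), index=m.site_ids,
                        columns=pd.Index(nodes, name="node"))


def indicator_nodes(tree: Phylogeny, m: AssemblageMatrix, labels,
                    allow_combos: bool = True,
                    group_corrected: bool = False):
    """Non-nested indicator clades per group combination.

    Runs the indicator analysis on the site x node matrix, then within
    each combination greedily keeps nodes by descending stat, skipping
    any node that is an ancestor or descendant of an already kept node.

    Returns (full node :class:`IndicatorTable`, selection DataFrame with
    columns node, mrca_tips, combo, A, B, stat, and a list of skipped
    (nested) node ids).
    """
    node_pa = site_by_node_matrix(tree, m)
    table = indval(node_pa, labels, allow_combos=allow_combos,
                   group_corrected=group_corrected)
    tipsets = tree.descendant_tips()

    def nested(a: int, b: int) -> bool:
        return tipsets[a] <= tipsets[b] or tipsets[b] <= tipsets[a]

    selected_rows = []
    skipped = []
    best = table.best.sort_values(["stat", "unit"],
                                  ascending=[False, True], kind="stable")
    for combo in sorted(set(best["combo"]), key=lambda c: (len(c), c)):
        kept: list = []
        for _, row in best[best["combo"] == combo].iterrows():
            node = int(row["unit"])
            if any(nested(node, k) for k in kept):
                skipped.append(node)
                continue
            kept.append(node)
            pair = tree.representative_tip_pair(node)
            selected_rows.append((node, "|".join(pair), combo,
                                  row["A"], row["B"], row["stat"]))
    selection = pd.DataFrame(
        selected_rows,
        columns=["node", "mrca_tips", "combo", "A", "B", "stat"],
    ).sort_values(["combo", "stat"], ascending=[True, False],
                  kind="stable").reset_index(drop=True)
    return table, selection, skipped
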