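"""Site x genus presence/absence matrices, site covariates, and site filters.

The assemblage matrix is the unit of analysis everywhere downstream: a
binary incidence of which genera occur at which sites.  Inputs may be
wide (sites x genera 0/1 with a site-id index) or long (site, genus
pairs); abundances are binarized at > 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tree import Phylogeny, normalize_label

__all__ = [
    "AssemblageMatrix",
    "SiteCovariates",
    "FilterReport",
    "filter_min_genera",
    "align_to_tree",
]

log = logging.getLogger(__name__)

CLIMATE_VARS = ["MAT", "MAP", "TS", "CWD"]
GEOGRAPHY_VARS = ["lat", "lon", "continent"]


@dataclass
class FilterReport:
    """Bookkeeping for a site/genus filtering step."""

    sites_in: int
    sites_out: int
    genera_in: int
    genera_out: int
    dropped_sites: list = field(default_factory=list)
    dropped_genera: list = field(default_factory=list)
    retained_fraction: dict = field(default_factory=dict)

    def __str__(self):
        return (f"sites {self.sites_in} -> {self.sites_out}, "
                f"genera {self.genera_in} -> {self.genera_out}")


class AssemblageMatrix:
    """Binary site x genus incidence with ordered identifiers.

    Wraps a pandas DataFrame (index = site ids, columns = genus names,
    values 0/1 int8).  Site and genus identifiers must be unique.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.duplicated().any():
            raise ValueError("duplicate site ids")
        if data.columns.duplicated().any():
            raise ValueError("duplicate genus ids")
        df = (data > 0).astype(np.int8)
        df.columns = [normalize_label(str(c)) for c in df.columns]
        if len(set(df.columns)) != len(df.columns):
            raise ValueError("duplicate genus ids after name normalization")
        self.data = df

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_wide_csv(cls, path, sep=",") -> "AssemblageMatrix":
        """Wide 0/1 matrix: first column site ids, header row genus names."""
        return cls(pd.read_csv(path, sep=sep, index_col=0))

    @classmethod
    def from_long(cls, records: pd.DataFrame,
                  site_col="site", genus_col="genus") -> "AssemblageMatrix":
        """Long-form (site, genus) occurrence records."""
        tab = pd.crosstab(records[site_col], records[genus_col])
        tab.index.name = None
        tab.columns.name = None
        return cls(tab)

    def to_csv(self, path):
        self.data.to_csv(path)

    # -- views -------------------------------------------------------------
    @property
    def site_ids(self) -> list:
        return list(self.data.index)

    @property
    def genus_ids(self) -> list:
        return list(self.data.columns)

    @property
    def n_sites(self) -> int:
        return self.data.shape[0]

    @property
    def n_genera(self) -> int:
        return self.data.shape[1]

    @property
    def occupancy(self) -> np.ndarray:
        return self.data.to_numpy()

    def richness(self) -> pd.Series:
        """Number of genera present per site."""
        return self.data.sum(axis=1)

    def tips_at(self, site) -> set:
        row = self.data.loc[site]
        return set(row.index[row > 0])

    def __repr__(self):
        return f"AssemblageMatrix({self.n_sites} sites x {self.n_genera} genera)"


class SiteCovariates:
    """Per-site climate, geography and binary delimitation flags.

    Expected columns: lat, lon (degrees), elevation (m), MAT (deg C),
    MAP (mm/yr), TS (SD x 100), CWD (mm/yr, <= 0), continent
    ({NorthCentral, South}), plus any number of 0/1 delimitation flags
    (e.g. ``freezing``).
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.duplicated().any():
            raise ValueError("duplicate site ids in covariates")
        self.data = data.copy()

    @classmethod
    def from_csv(cls, path) -> "SiteCovariates":
        return cls(pd.read_csv(path, index_col=0))

    def to_csv(self, path):
        self.data.to_csv(path)

    @property
    def site_ids(self) -> list:
        return list(self.data.index)

    def subset(self, site_ids) -> "SiteCovariates":
        return SiteCovariates(self.data.loc[list(site_ids)])

    def require(self, columns) -> None:
        missing = [c for c in columns if c not in self.data.columns]
        if missing:
            raise KeyError(f"missing covariate columns: {missing}")

    def __repr__(self):
        return (f"SiteCovariates({len(self.data)} sites, "
                f"columns={list(self.data.columns)})")


def filter_min_genera(m: AssemblageMatrix, min_genera: int = 5):
    """Drop sites with fewer than ``min_genera`` genera present.

    Genus columns left with zero occurrences are dropped too.  The
    default threshold of five reflects that sparser assemblages carry
    too little signal to be placed reliably in ordinations/clusterings.

    Returns (filtered matrix, :class:`FilterReport`).  Idempotent.
    """
    rich = m.richness()
    keep = rich[rich >= min_genera].index
    out = m.data.loc[keep]
    empty_genera = out.columns[out.sum(axis=0) == 0]
    out = out.drop(columns=empty_genera)
    report = FilterReport(
        sites_in=m.n_sites, sites_out=len(out),
        genera_in=m.n_genera, genera_out=out.shape[1],
        dropped_sites=[s for s in m.site_ids if s not in set(keep)],
        dropped_genera=list(empty_genera),
    )
    if len(out) == 0:
        log.warning("min-genera filter removed every site")
    log.info("min-genera filter (>=%d): %s", min_genera, report)
    return AssemblageMatrix(out), report


def align_to_tree(m: AssemblageMatrix, tree: Phylogeny):
    """Restrict the matrix to genera present on the tree.

    Genus names are reconciled by exact match after whitespace trimming
    and underscore/space normalization; unmatched genera are dropped and
    counted.  Sites losing every genus are dropped with a warning.

    Returns (aligned matrix, :class:`FilterReport`); the report carries
    the per-site retained fraction of genera.
    """
    on_tree = [g for g in m.genus_ids if tree.has_tip(g)]
    dropped = [g for g in m.genus_ids if not tree.has_tip(g)]
    out = m.data[on_tree]
    before = m.richness()
    after = out.sum(axis=1)
    retained = {
        s: (float(after[s]) / float(before[s])) if before[s] else 1.0
        for s in m.site_ids
    }
    empty_sites = after[after == 0].index
    if len(empty_sites):
        log.warning("%d sites lost all genera in tree alignment and were "
                    "dropped", len(empty_sites))
    out = out.drop(index=empty_sites)
    report = FilterReport(
        sites_in=m.n_sites, sites_out=len(out),
        genera_in=m.n_genera, genera_out=len(on_tree),
        dropped_sites=list(empty_sites),
        dropped_genera=dropped,
        retained_fraction=retained,
    )
    log.info("tree alignment: %s (%d genera not on tree)",
             report, len(dropped))
    return AssemblageMatrix(out), report
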