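"""K-means grouping of assemblages from a phylogenetic dissimilarity matrix.

Following common practice in regionalization studies, the rows of the
(symmetric) dissimilarity matrix are used directly as the feature
vectors handed to K-means — each site is represented by its profile of
dissimilarities to every site.  A classical PCoA embedding of the
matrix is available as an alternative representation.  Silhouette
widths are always computed on the original dissimilarities, the
quantity of scientific interest, not on the K-means feature space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .dissimilarity import DissimilarityMatrix

__all__ = [
    "ClusterSolution",
    "KSelectionReport",
    "kmeans_on_dissimilarity",
    "elbow_select",
    "silhouette_widths",
    "select_k",
    "pcoa_embedding",
]


@dataclass
class ClusterSolution:
    """Labels in 1..K for one K, with diagnostics."""

    K: int
    labels: np.ndarray  # site -> group id in 1..K
    tss: float  # total within-cluster sum of squares
    sil: np.ndarray  # per-site silhouette width on the dissimilarities
    seed: int
    n_init: int
    site_ids: list = field(default_factory=list)

    @property
    def mean_silhouette(self) -> float:
        return float(self.sil.mean())

    def group_sizes(self) -> dict:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


@dataclass
class KSelectionReport:
    k_range: list
    tss_curve: dict  # K -> tss
    avg_sil_curve: dict  # K -> mean silhouette
    elbow_k: int
    silhouette_k: int


def pcoa_embedding(d: DissimilarityMatrix, n_axes: int = 10) -> np.ndarray:
    """Classical (Torgerson) principal coordinates of the dissimilarities;
    negative eigenvalues are truncated."""
    D2 = d.values ** 2
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    pos = w > 1e-10
    coords = v[:, pos] * np.sqrt(w[pos])
    return coords[:, :n_axes]


def kmeans_on_dissimilarity(d: DissimilarityMatrix, K: int, seed: int,
                            n_init: int = 25,
                            representation: str = "rows") -> ClusterSolution:
    """Best-of-``n_init`` Lloyd's K-means on the chosen representation of
    the dissimilarity matrix.

    Parameters
    ----------
    representation : {"rows", "pcoa"}
        "rows" feeds the raw matrix rows as feature vectors; "pcoa"
        feeds a classical PCoA embedding.
    """
    n = d.n_sites
    if K < 2:
        raise ValueError("K must be at least 2")
    if K >= n:
        raise ValueError(f"K={K} must be smaller than the number of sites ({n})")
    if representation == "rows":
        X = d.values
    elif representation == "pcoa":
        X = pcoa_embedding(d)
    else:
        raise ValueError(f"unknown representation {representation!r}")
    km = KMeans(n_clusters=K, n_init=n_init, random_state=seed,
                algorithm="lloyd")
    raw = km.fit_predict(X)
    labels = raw + 1
    sil = silhouette_widths(d, labels)
    return ClusterSolution(K=K, labels=labels, tss=float(km.inertia_),
                           sil=sil, seed=seed, n_init=n_init,
                           site_ids=list(d.site_ids))


def silhouette_widths(d: DissimilarityMatrix, labels) -> np.ndarray:
    """Classical silhouette width per site, on the dissimilarities.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a(i) the mean
    dissimilarity to the own group (self excluded) and b(i) the minimum
    over other groups of the mean dissimilarity to that group.  Members
    of singleton groups get s(i) = 0 by convention.
    """
    labels = np.asarray(labels)
    if len(labels) != d.n_sites:
        raise ValueError("labels length does not match matrix")
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("silhouette needs at least two groups")
    D = d.values
    n = len(labels)
    # mean dissimilarity from every site to every group
    means = np.empty((n, len(groups)))
    sizes = np.empty(len(groups))
    for gi, g in enumerate(groups):
        mask = labels == g
        sizes[gi] = mask.sum()
        means[:, gi] = D[:, mask].sum(axis=1)
    own = np.searchsorted(groups, labels)
    s = np.zeros(n)
    for i in range(n):
        gi = own[i]
        if sizes[gi] == 1:
            continue  # singleton convention
        a = means[i, gi] / (sizes[gi] - 1)  # self term is 0 on the diagonal
        b = np.min([means[i, gj] / sizes[gj]
                    for gj in range(len(groups)) if gj != gi])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s


def elbow_select(tss_curve: dict) -> int:
    """Elbow of a TSS-vs-K curve, formalized as the interior K maximizing
    the discrete second difference tss(K-1) - 2 tss(K) + tss(K+1).

    A non-monotone curve or a curve with no clear curvature triggers a
    warning, not an error (the full curve should always be inspected).
    """
    ks = sorted(tss_curve)
    if len(ks) < 3:
        raise ValueError("elbow selection needs at least three K values")
    tss = np.array([tss_curve[k] for k in ks], dtype=float)
    if (np.diff(tss) > 0).any():
        warnings.warn("TSS curve is not monotonically decreasing",
                      stacklevel=2)
    second = tss[:-2] - 2 * tss[1:-1] + tss[2:]
    if np.allclose(second, 0.0, atol=1e-9 * max(1.0, abs(tss[0]))):
        warnings.warn("no clear elbow: TSS curve is essentially linear",
                      stacklevel=2)
        return ks[1]
    return ks[1 + int(np.argmax(second))]


def select_k(d: DissimilarityMatrix, seed: int, k_max: int = 10,
             n_init: int = 25, representation: str = "rows"):
    """Run K-means for K = 2..k_max and report Elbow and Silhouette
    choices of K.

    Returns (:class:`KSelectionReport`, dict K -> :class:`ClusterSolution`).
    The elbow is evaluated on the curve including the K = 1 baseline
    (total sum of squares), since the first drop carries the most
    curvature information.
    """
    if k_max < 4:
        raise ValueError("k_max must be at least 4")
    X = d.values if representation == "rows" else pcoa_embedding(d)
    baseline = float(((X - X.mean(axis=0)) ** 2).sum())  # K = 1 TSS
    solutions = {}
    tss_curve = {1: baseline}
    sil_curve = {}
    for k in range(2, k_max + 1):
        sol = kmeans_on_dissimilarity(d, k, seed=seed, n_init=n_init,
                                      representation=representation)
        solutions[k] = sol
        tss_curve[k] = sol.tss
        sil_curve[k] = sol.mean_silhouette
    elbow_k = elbow_select(tss_curve)
    silhouette_k = max(sil_curve, key=sil_curve.get)
    report = KSelectionReport(
        k_range=list(range(2, k_max + 1)),
        tss_curve=tss_curve,
        avg_sil_curve=sil_curve,
        elbow_k=elbow_k,
        silhouette_k=silhouette_k,
    )
    return report, solutions
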