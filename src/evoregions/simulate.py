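"""Synthetic phylogenies, assemblages and covariates with planted structure.

The generator emulates the data-generating assumptions behind
niche-conserved community assembly: a dated genus phylogeny (pure-birth),
two niche traits (cold tolerance, drought tolerance) evolving by
Brownian motion — so close relatives share tolerances — and sites along
a freezing/water-deficit landscape that filter genera by the match
between trait and local environment.  An alternative scenario plants
dispersal limitation instead: lineages inherit a continent along the
tree and occupancy follows landmass, not environment.  Climate and
geography covariates are generated before occupancy so they are
exogenous, and every stage is reproducible from a single seed.

The planted truths — site group labels and the fraction of phylogenetic
diversity restricted to the freezing-site pool — are returned alongside
the data so recovery by the analysis pipeline can be measured.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assemblages import AssemblageMatrix, SiteCovariates
from .tree import Phylogeny, pd_total, write_newick

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_tree",
    "simulate_niches",
    "assemble_sites",
    "simulate_dataset",
]

SCENARIOS = ("niche_conservatism", "dispersal_limitation", "mixed")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults give 150 genera x 400 sites with strong environmental
    filtering and 30% of sites experiencing freezing — large enough for
    stable clustering while keeping a full pipeline run fast.
    """

    n_genera: int = 150
    n_sites: int = 400
    birth_rate: float = 0.05  # splits per lineage per Myr
    sigma2: float = 1.0  # Brownian trait variance per Myr
    n_traits: int = 2  # cold tolerance, drought tolerance
    filter_width: float = 0.5  # niche breadth, in trait SD units
    scenario: str = "niche_conservatism"
    freezing_fraction: float = 0.3
    frost_tolerant_fraction: float = 0.2  # genera able to endure freezing
    continent_switch_rate: float = 0.01  # per Myr, dispersal scenario
    min_genera: int = 5  # sites below this are resampled
    seed: int = 0

    def __post_init__(self):
        if self.n_genera < 10:
            raise ValueError("n_genera must be at least 10")
        if not (0 < self.freezing_fraction < 1):
            raise ValueError("freezing_fraction must be in (0, 1)")
        if self.birth_rate <= 0 or self.filter_width <= 0:
            raise ValueError("rates and widths must be positive")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")

    def rng(self, stage: int) -> np.random.Generator:
        """Independent, reproducible stream per pipeline stage."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stage,))
        )


@dataclass
class SyntheticDataset:
    tree: Phylogeny
    matrix: AssemblageMatrix
    covariates: SiteCovariates
    true_labels: np.ndarray  # 1 = tropical/north pool, 2 = planted group
    true_restricted_fraction: float
    config: SimulationConfig
    niches: pd.DataFrame = field(default=None, repr=False)

    def write(self, outdir):
        """Write the standard pipeline inputs plus a truth JSON."""
        import os

        os.makedirs(outdir, exist_ok=True)
        write_newick(self.tree, os.path.join(outdir, "tree.nwk"))
        self.matrix.to_csv(os.path.join(outdir, "assemblages.csv"))
        self.covariates.to_csv(os.path.join(outdir, "covariates.csv"))
        truth = {
            "scenario": self.config.scenario,
            "seed": self.config.seed,
            "true_labels": {s: int(l) for s, l in
                            zip(self.matrix.site_ids, self.true_labels)},
            "true_restricted_fraction": self.true_restricted_fraction,
        }
        with open(os.path.join(outdir, "truth.json"), "w") as fh:
            json.dump(truth, fh, indent=2)


def simulate_tree(config: SimulationConfig) -> Phylogeny:
    """Pure-birth (Yule) tree with exactly ``n_genera`` tips.

    Waiting times between splits are exponential with rate
    ``birth_rate x (current lineage count)``; after the last split the
    tree is extended by one more such waiting time so terminal branches
    have positive length.  Expected root age grows ~ ln(n)/birth_rate.
    """
    rng = config.rng(0)
    n = config.n_genera
    lam = config.birth_rate

    parent = [-1]
    birth = [0.0]
    children: list = [[]]

    def add(p: int, t: float) -> int:
        idx = len(parent)
        parent.append(p)
        birth.append(t)
        children.append([])
        children[p].append(idx)
        return idx

    t = 0.0
    active = [add(0, 0.0), add(0, 0.0)]  # root splits at time 0
    while len(active) < n:
        t += rng.exponential(1.0 / (lam * len(active)))
        k = rng.integers(len(active))
        node = active.pop(k)
        active.extend([add(node, t), add(node, t)])
    t_end = t + rng.exponential(1.0 / (lam * n))

    n_nodes = len(parent)
    brlen = np.zeros(n_nodes)
    for i in range(1, n_nodes):
        end = birth[children[i][0]] if children[i] else t_end
        brlen[i] = end - birth[i]
    tip_labels = np.array([""] * n_nodes, dtype=object)
    width = max(4, len(str(n)))
    counter = 0
    for i in range(n_nodes):
        if not children[i]:
            counter += 1
            tip_labels[i] = f"G{counter:0{width}d}"
    # post-order via iterative DFS
    post = []
    stack = [(0, False)]
    while stack:
        node, done = stack.pop()
        if done:
            post.append(node)
        else:
            stack.append((node, True))
            for c in reversed(children[node]):
                stack.append((c, False))
    return Phylogeny(parent=np.array(parent), brlen=brlen,
                     children=children, tip_labels=tip_labels,
                     postorder=np.array(post), root=0)


def simulate_niches(tree: Phylogeny, config: SimulationConfig) -> pd.DataFrame:
    """Brownian-motion niche traits along the tree.

    Each trait starts at 0 at the root and accumulates independent
    Gaussian increments with variance ``sigma2 x branch length``, so the
    covariance between two tips equals sigma2 times their shared path
    length from the root — sister genera get similar tolerances
    (phylogenetic niche conservatism).

    Returns a DataFrame indexed by tip label with columns
    ``cold_tol`` and ``drought_tol`` (first two traits).
    """
    rng = config.rng(1)
    vals = np.zeros((tree.n_nodes, config.n_traits))
    for i in tree.postorder[::-1]:  # pre-order: parents before children
        p = tree.parent[i]
        if p == -1:
            continue
        sd = np.sqrt(config.sigma2 * tree.brlen[i])
        vals[i] = vals[p] + rng.normal(0.0, sd, size=config.n_traits)
    tips = tree.tip_ids
    names = ["cold_tol", "drought_tol"][:config.n_traits] + [
        f"trait{k}" for k in range(2, config.n_traits)
    ]
    return pd.DataFrame(vals[tips], columns=names[:config.n_traits],
                        index=[tree.tip_labels[i] for i in tips])


def _tip_continents(tree: Phylogeny, config: SimulationConfig,
                    rng: np.random.Generator) -> dict:
    """Continent inherited along the tree with rare switching: clades are
    strongly continent-faithful (the dispersal-limitation planting)."""
    state = np.zeros(tree.n_nodes, dtype=int)
    state[tree.root] = rng.integers(2)
    for i in tree.postorder[::-1]:
        p = tree.parent[i]
        if p == -1:
            continue
        switch = 1.0 - np.exp(-config.continent_switch_rate * tree.brlen[i])
        state[i] = 1 - state[p] if rng.random() < switch else state[p]
    names = np.array(["NorthCentral", "South"])
    return {tree.tip_labels[i]: names[state[i]] for i in tree.tip_ids}


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _tau_hi(cold_tol: np.ndarray, config: SimulationConfig) -> float:
    """Warm-exclusion threshold: genera above it are frost specialists,
    unable to persist where it never freezes.  Sits a fifth of the way
    into the frost-tolerant tail, leaving a thin band of genera that
    occur on both sides of the freeze line."""
    q_tau = 1.0 - config.frost_tolerant_fraction
    return float(np.quantile(cold_tol,
                             q_tau + 0.2 * config.frost_tolerant_fraction))


def assemble_sites(tree: Phylogeny, niches: pd.DataFrame,
                   config: SimulationConfig):
    """Generate covariates and a presence/absence matrix for one scenario.

    Environment first: each site draws a latitude, longitude and
    elevation; a cold score (latitude + elevation + noise) whose top
    ``freezing_fraction`` quantile defines the freezing flag; and a dry
    score defining the water-deficit gradient.  MAT, MAP, TS and CWD
    are generated consistently with those scores.  Site environmental
    optima are quantile-mapped into the realized trait distributions so
    the landscape spans the niches actually present.

    Occupancy then follows the scenario: under niche conservatism the
    probability of genus g at site s is logistic in the squared
    trait-environment mismatch scaled by ``filter_width`` (per trait),
    independent of continent; under dispersal limitation it depends only
    on whether the genus's inherited continent matches the site's;
    ``mixed`` multiplies the two.  Sites ending up with fewer than
    ``min_genera`` genera are resampled (at most 100 draws each).

    Returns (AssemblageMatrix, SiteCovariates, true_labels array).
    """
    rng = config.rng(2)
    n = config.n_sites
    if (config.scenario != "dispersal_limitation"
            and config.n_genera * config.frost_tolerant_fraction
            < 2 * config.min_genera):
        raise ValueError(
            "frost-tolerant pool too small to assemble freezing sites: "
            f"need n_genera * frost_tolerant_fraction >= "
            f"{2 * config.min_genera}"
        )

    lat = rng.uniform(-55.0, 55.0, n)
    lon = rng.uniform(-120.0, -35.0, n)
    elevation = np.clip(rng.exponential(600.0, n), 0.0, 4500.0)

    cold_score = (np.abs(lat) / 55.0 + 0.8 * elevation / 4500.0
                  + rng.normal(0.0, 0.05, n))
    freezing = cold_score >= np.quantile(cold_score,
                                         1.0 - config.freezing_fraction)
    dry_score = np.clip(rng.beta(2.0, 2.0, n)
                        + rng.normal(0.0, 0.05, n), 0.0, 1.0)

    cold_rank = pd.Series(cold_score).rank(method="average").to_numpy() / (n + 1)
    dry_q = np.clip(dry_score, 0.005, 0.995)  # water-deficit quantile

    mat = 28.0 - 24.0 * cold_rank - 2.0 * freezing + rng.normal(0, 1.0, n)
    ts = (80.0 + 1100.0 * np.abs(lat) / 55.0 + 250.0 * freezing
          + rng.normal(0, 60.0, n))
    continent = np.where(lon > -77.5, "South", "NorthCentral")

    # Site optima in trait space.  Freezing imposes a hard physiological
    # threshold: only genera whose cold tolerance exceeds tau (the upper
    # frost_tolerant_fraction of the realized distribution) can persist
    # where temperatures drop below freezing.  Freezing sites draw their
    # cold optimum from the frost-tolerant trait range, non-freezing
    # sites from the rest, so the landscape spans the niches present.
    cold_tol = niches["cold_tol"].to_numpy()
    dr_tol = niches["drought_tol"].to_numpy()
    q_tau = 1.0 - config.frost_tolerant_fraction
    tau = np.quantile(cold_tol, q_tau)

    def _within_rank(mask):
        r = pd.Series(cold_rank[mask]).rank(method="average").to_numpy()
        return r / (mask.sum() + 1)

    env_cold = np.empty(n)
    env_cold[freezing] = np.quantile(
        cold_tol, q_tau + config.frost_tolerant_fraction
        * _within_rank(freezing))
    env_cold[~freezing] = np.quantile(cold_tol,
                                      q_tau * _within_rank(~freezing))
    # drought optima of freezing sites stay within the drought range
    # realized by the frost-tolerant pool (the extratropics span less of
    # the water-deficit gradient than the tropics)
    tolerant = cold_tol >= tau

    def _env_dry_at(q, freeze):
        pool = dr_tol[tolerant] if freeze else dr_tol
        return np.quantile(pool, q)

    env_dry = np.array([_env_dry_at(dry_q[s], freezing[s])
                        for s in range(n)])

    # per-genus niche breadth varies lognormally around filter_width, so
    # the pool holds a few widespread generalists alongside specialists
    breadth = np.exp(rng.normal(0.0, 0.4, config.n_genera))
    fw_c = config.filter_width * cold_tol.std() * breadth
    fw_d = config.filter_width * dr_tol.std() * breadth
    # frost-intolerant genera are excluded from freezing sites by a
    # steep tolerance cutoff at tau; conversely the most frost-adapted
    # specialists (above tau_hi) cannot persist where it never freezes —
    # the cold-adaptation trade-off that leaves unique extratropical
    # lineages
    # cutoff steepness shares the niche-breadth scale: wide filters also
    # soften the physiological thresholds (no structure remains in the
    # filter_width -> infinity limit)
    scale = 0.1 * config.filter_width * cold_tol.std()
    tau_hi = _tau_hi(cold_tol, config)
    frost_filter = _sigmoid((cold_tol - tau) / scale)
    warm_filter = _sigmoid((tau_hi - cold_tol) / scale)

    def _p_niche_row(s):
        d2 = (((cold_tol - env_cold[s]) / fw_c) ** 2
              + ((dr_tol - env_dry[s]) / fw_d) ** 2)
        p = _sigmoid(4.0 - d2)
        return p * (frost_filter if freezing[s] else warm_filter)

    p_niche = np.vstack([_p_niche_row(s) for s in range(n)])

    tip_cont = _tip_continents(tree, config, rng)
    genus_cont = np.array([tip_cont[g] for g in niches.index])
    match = genus_cont[None, :] == continent[:, None]
    p_disp = np.where(match, 0.35, 0.01)

    def _compose(p_niche_row, s):
        if config.scenario == "niche_conservatism":
            return p_niche_row
        if config.scenario == "dispersal_limitation":
            return p_disp[s]
        return p_niche_row * np.where(match[s], 0.9, 0.1)

    prob = np.vstack([_compose(p_niche[s], s) for s in range(n)])

    # Habitability: a site whose environment supports too few genera in
    # expectation redraws its drought quantile (trees assemble where
    # trees can live); the cold/freezing structure is never altered.
    if config.scenario != "dispersal_limitation":
        floor = config.min_genera + 2.0
        for s in np.flatnonzero(prob.sum(axis=1) < floor):
            best = (prob[s].sum(), dry_q[s], env_dry[s], env_cold[s],
                    prob[s].copy())
            for attempt in range(200):
                dry_q[s] = rng.uniform(0.05, 0.95)
                env_dry[s] = _env_dry_at(dry_q[s], freezing[s])
                if attempt >= 50:
                    # stubborn joint gap: also re-place the cold optimum
                    # within the site's own (frost-defined) pool
                    u = rng.uniform(0.05, 0.95)
                    env_cold[s] = np.quantile(
                        cold_tol,
                        q_tau + config.frost_tolerant_fraction * u
                        if freezing[s] else q_tau * u)
                prob[s] = _compose(_p_niche_row(s), s)
                if prob[s].sum() > best[0]:
                    best = (prob[s].sum(), dry_q[s], env_dry[s],
                            env_cold[s], prob[s].copy())
                if prob[s].sum() >= floor:
                    break
            else:
                # keep the most habitable environment found; small genus
                # pools may not reach the comfortable floor
                _, dry_q[s], env_dry[s], env_cold[s], prob[s] = best
                if best[0] < config.min_genera:
                    raise RuntimeError(
                        f"site {s} cannot support {config.min_genera} "
                        "genera under any sampled environment; widen "
                        "filter_width"
                    )

    map_ = np.clip(3200.0 * (1.0 - dry_q) + rng.normal(0, 150.0, n),
                   100.0, None)
    cwd = -np.clip(1600.0 * dry_q + rng.normal(0, 50.0, n), 0.0, None)

    occ = np.zeros((n, config.n_genera), dtype=np.int8)
    for s in range(n):
        for attempt in range(100):
            draw = rng.random(config.n_genera) < prob[s]
            if draw.sum() >= config.min_genera:
                occ[s] = draw
                break
        else:
            raise RuntimeError(
                f"site {s} stayed below {config.min_genera} genera after "
                "100 resamples; widen filter_width or raise baseline "
                "occupancy"
            )

    site_ids = [f"S{k + 1:04d}" for k in range(n)]
    matrix = AssemblageMatrix(
        pd.DataFrame(occ, index=site_ids, columns=list(niches.index))
    )
    cov = SiteCovariates(pd.DataFrame({
        "lat": lat, "lon": lon, "elevation": elevation,
        "MAT": mat, "MAP": map_, "TS": ts, "CWD": cwd,
        "continent": continent,
        "freezing": freezing.astype(int),
    }, index=site_ids))

    if config.scenario == "dispersal_limitation":
        true_labels = np.where(continent == "South", 2, 1)
    else:
        true_labels = np.where(freezing, 2, 1)
    return matrix, cov, true_labels


def _restricted_fraction(tree: Phylogeny, matrix: AssemblageMatrix,
                         niches: pd.DataFrame,
                         config: SimulationConfig) -> float:
    """Planted fraction of PD restricted to the cold pool: the branch
    length lost from the phylogeny of all present genera when the
    frost-specialist genera (cold tolerance above the warm-exclusion
    threshold, hence confined to freezing sites by construction) are
    removed."""
    present = [g for g in matrix.genus_ids
               if matrix.data[g].sum() > 0]
    tau_hi = _tau_hi(niches["cold_tol"].to_numpy(), config)
    specialists = set(niches.index[niches["cold_tol"] > tau_hi])
    remaining = [g for g in present if g not in specialists]
    total = pd_total(tree, present)
    if len(remaining) == len(present):
        return 0.0
    return float((total - pd_total(tree, remaining)) / total)


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run all three stages and package the dataset with its truths."""
    tree = simulate_tree(config)
    niches = simulate_niches(tree, config)
    matrix, cov, labels = assemble_sites(tree, niches, config)
    frac = _restricted_fraction(tree, matrix, niches, config)
    return SyntheticDataset(tree=tree, matrix=matrix, covariates=cov,
                            true_labels=labels,
                            true_restricted_fraction=frac,
                            config=config, niches=niches)
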