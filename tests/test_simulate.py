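"""Synthetic-data generator: tree, traits, assemblages, planted truths."""

import numpy as np
import pytest

from evoregions import (
    SimulationConfig,
    assemble_sites,
    kmeans_on_dissimilarity,
    phylosor_complement,
    simulate_dataset,
    simulate_niches,
    simulate_tree,
    write_newick,
)


class TestSimulateTree:
    def test_binary_tree_node_count(self):
        tree = simulate_tree(SimulationConfig(n_genera=10, seed=0))
        assert tree.n_tips == 10
        assert tree.n_nodes == 19  # n tips + n-1 internal nodes

    def test_same_seed_same_newick(self):
        cfg = SimulationConfig(n_genera=25, seed=3)
        assert write_newick(simulate_tree(cfg)) \
            == write_newick(simulate_tree(cfg))

    def test_branch_lengths_positive(self):
        tree = simulate_tree(SimulationConfig(n_genera=40, seed=1))
        assert (tree.brlen[np.arange(tree.n_nodes) != tree.root] > 0).all()

    def test_root_age_grows_logarithmically(self):
        """Yule expectation: depth ~ ln(n)/lambda, so quadrupling n adds
        roughly ln(4)/lambda to the mean root age."""
        def mean_depth(n, reps=40):
            out = []
            for s in range(reps):
                t = simulate_tree(SimulationConfig(
                    n_genera=n, birth_rate=0.1, seed=s))
                tips = t.tip_ids
                depth = [sum(t.brlen[list(_path(t, i))]) for i in tips[:1]]
                out.append(depth[0])
            return np.mean(out)

        def _path(tree, i):
            while tree.parent[i] != -1:
                yield i
                i = tree.parent[i]

        d20, d80 = mean_depth(20), mean_depth(80)
        assert d80 > d20
        assert d80 - d20 == pytest.approx(np.log(4) / 0.1, rel=0.5)

    def test_too_few_genera_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genera=5, seed=0)


class TestSimulateNiches:
    def test_zero_variance_gives_constant_traits(self):
        cfg = SimulationConfig(n_genera=15, sigma2=0.0, seed=2)
        tree = simulate_tree(cfg)
        niches = simulate_niches(tree, cfg)
        assert (niches.to_numpy() == 0).all()

    def test_brownian_covariance_matches_shared_path(self):
        """Across replicate trait histories on one fixed tree, the
        covariance of two tips equals sigma2 x their shared root path."""
        base = SimulationConfig(n_genera=12, sigma2=2.0, seed=5)
        tree = simulate_tree(base)
        a, b = tree.labels[0], tree.labels[1]
        ia, ib = tree.tip_id(a), tree.tip_id(b)
        # shared path length = depth of the MRCA
        anc_a = set()
        j = ia
        while j != -1:
            anc_a.add(j)
            j = tree.parent[j]
        j = ib
        while j not in anc_a:
            j = tree.parent[j]
        mrca = j
        shared = 0.0
        while tree.parent[mrca] != -1:
            shared += tree.brlen[mrca]
            mrca = tree.parent[mrca]
        draws = []
        for s in range(500):
            cfg = SimulationConfig(n_genera=12, sigma2=2.0, seed=s)
            niches = simulate_niches(tree, cfg)
            draws.append((niches.loc[a, "cold_tol"],
                          niches.loc[b, "cold_tol"]))
        draws = np.array(draws)
        emp = np.cov(draws.T)[0, 1]
        assert emp == pytest.approx(2.0 * shared, rel=0.25, abs=0.5)

    def test_phylogenetic_signal_in_traits(self):
        """Sister tips are more similar than random tip pairs."""
        cfg = SimulationConfig(n_genera=60, seed=8)
        tree = simulate_tree(cfg)
        niches = simulate_niches(tree, cfg)
        sisters = []
        for i in tree.internal_ids:
            kids = [c for c in tree.children[i] if not tree.children[c]]
            if len(kids) == 2:
                sisters.append((tree.tip_labels[kids[0]],
                                tree.tip_labels[kids[1]]))
        sis_d = np.mean([
            abs(niches.loc[a, "cold_tol"] - niches.loc[b, "cold_tol"])
            for a, b in sisters])
        rng = np.random.default_rng(0)
        labels = list(niches.index)
        rand_d = np.mean([
            abs(niches.loc[a, "cold_tol"] - niches.loc[b, "cold_tol"])
            for a, b in zip(rng.choice(labels, 200),
                            rng.choice(labels, 200))])
        assert sis_d < rand_d


class TestAssembleSites:
    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(n_genera=60, n_sites=60, seed=4)
        tree = simulate_tree(cfg)
        niches = simulate_niches(tree, cfg)
        m1, c1, l1 = assemble_sites(tree, niches, cfg)
        m2, c2, l2 = assemble_sites(tree, niches, cfg)
        assert (m1.occupancy == m2.occupancy).all()
        assert c1.data.equals(c2.data)
        assert (l1 == l2).all()

    def test_covariate_dependency_structure(self):
        ds = simulate_dataset(SimulationConfig(n_genera=60, n_sites=150,
                                               seed=6))
        cov = ds.covariates.data
        assert (cov["CWD"] <= 0).all()
        freeze = cov["freezing"].astype(bool)
        assert freeze.mean() == pytest.approx(0.3, abs=0.02)
        # freezing sites are colder on average
        assert cov.loc[freeze, "MAT"].mean() \
            < cov.loc[~freeze, "MAT"].mean() - 5
        assert set(cov["continent"]) <= {"South", "NorthCentral"}

    def test_every_site_meets_minimum_richness(self):
        ds = simulate_dataset(SimulationConfig(n_genera=60, n_sites=100,
                                               seed=7))
        assert int(ds.matrix.richness().min()) >= 5

    def test_wide_filter_yields_weak_structure(self):
        """filter_width -> large removes environmental filtering, so a
        K = 2 clustering finds no crisp groups (low mean silhouette)."""
        ds = simulate_dataset(SimulationConfig(
            n_genera=80, n_sites=120, filter_width=50.0, seed=9))
        d = phylosor_complement(ds.tree, ds.matrix)
        sol = kmeans_on_dissimilarity(d, 2, seed=9, n_init=10)
        assert sol.mean_silhouette < 0.15

    def test_dispersal_scenario_labels_follow_continent(self):
        ds = simulate_dataset(SimulationConfig(
            n_genera=60, n_sites=100, scenario="dispersal_limitation",
            seed=10))
        cont = ds.covariates.data["continent"].to_numpy()
        assert ((ds.true_labels == 2) == (cont == "South")).all()

    def test_truth_fraction_positive_under_niche_scenario(self):
        ds = simulate_dataset(SimulationConfig(n_genera=80, n_sites=120,
                                               seed=11))
        assert 0.0 < ds.true_restricted_fraction < 0.5


class TestDatasetRoundTrip:
    def test_written_files_reload_consistently(self, tmp_path):
        from evoregions import AssemblageMatrix, SiteCovariates, read_newick

        ds = simulate_dataset(SimulationConfig(n_genera=60, n_sites=40,
                                               seed=12))
        ds.write(tmp_path)
        tree = read_newick(tmp_path / "tree.nwk")
        m = AssemblageMatrix.from_wide_csv(tmp_path / "assemblages.csv")
        cov = SiteCovariates.from_csv(tmp_path / "covariates.csv")
        assert sorted(tree.labels) == sorted(ds.tree.labels)
        assert (m.occupancy == ds.matrix.occupancy).all()
        assert cov.site_ids == ds.covariates.site_ids
        import json
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert truth["scenario"] == "niche_conservatism"
        assert truth["true_restricted_fraction"] == pytest.approx(
            ds.true_restricted_fraction)
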