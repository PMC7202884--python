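# Methods

## Scope and data model

The package analyses three inputs: a rooted, temporally calibrated
genus-level phylogeny (Newick; branch lengths in millions of years;
polytomies allowed), a binary site × genus assemblage matrix, and a
per-site covariate table (latitude, longitude, elevation, MAT, MAP,
temperature seasonality TS, maximum climatological water deficit CWD ≤ 0,
a continent factor, and binary delimitation flags such as `freezing`).
Genus names are reconciled by exact match after whitespace trimming and
underscore/space normalization; genera absent from the tree are dropped
with a logged count, and sites left with fewer than five genera are
excluded (the default threshold reflects that sparser assemblages
cannot be placed reliably in ordinations or clusterings). The five-genus
filter is applied *after* tree alignment, so "genera" always means
genera that carry branch length.

All phylogenetic diversity (PD) sums are rooted: the PD of a tip set is
the summed length of the branches connecting those tips to the global
root, with the root's own (stem) branch always treated as zero. This
makes PD invariant to a root stalk and gives the boundary behaviour the
dissimilarity measures rely on. The alternative convention (unrooted at
the tip set's MRCA) is not offered; sensitivity to this choice can be
probed by re-rooting the input tree.

## Dissimilarity

Both measures are functions of per-site branch sets, where a branch
belongs to a site if at least one tip descending it occurs there.
PhyloSor complement: 1 − shared/(mean of the two PD values)
(Sørensen-type). UniFrac complement: 1 − shared/union (Jaccard-type).
Sørensen ≥ Jaccard similarity always, a property the tests assert.
Implementation: one post-order pass builds a sites × branches boolean
incidence matrix; per-site PD is a matrix–vector product and all
pairwise shared sums are one matrix product, so the full matrix for
thousands of sites takes seconds and never materializes per-pair
subtrees.

## Clustering and selection of K

K-means (Lloyd's algorithm, best of `n_init = 25` restarts, seeded)
runs on the rows of the symmetric dissimilarity matrix — each site is
represented by its profile of dissimilarities to every site, which is
what applying a standard K-means routine directly to a dissimilarity
matrix does. A classical PCoA embedding (negative eigenvalues
truncated) is available via `representation="pcoa"` as the
statistically cleaner alternative; conclusions on the synthetic data do
not differ. Empty clusters cannot occur (the underlying scikit-learn
implementation relocates them), and results are bit-reproducible given
the seed.

The Elbow criterion is formalized as the interior K maximizing the
discrete second difference of the TSS curve (including the K = 1
baseline, which carries most of the curvature information); an
essentially linear curve triggers a warning rather than a confident
answer. The Silhouette criterion maximizes the mean silhouette width,
computed on the *original dissimilarities* (not the K-means feature
space): a(i) is the mean within-group dissimilarity excluding self,
b(i) the smallest other-group mean, s(i) = (b − a)/max(a, b), with
s = 0 for singleton groups by convention.

## Evolutionary PCA

The site × branch matrix has entry x·l (presence indicator of any
descendant tip, times branch length). Rows are Hellinger-transformed —
y = √(w / Σw), giving every row unit sum of squares — which damps the
dominance of long, universally shared deep branches; the transformed
matrix is column-centered and decomposed by SVD. Site scores are U·s,
clade loadings are V, variance explained is σ²ₖ/Σσ². Axis signs are
fixed by making the largest-magnitude loading on each axis positive.
Among the several conceivable branch weightings, the
presence/absence × branch-length variant is used because it has an
exact analytic anchor: on a star tree with unit branch lengths it
coincides, eigenvalue for eigenvalue, with an ordinary centered PCA of
the Hellinger-transformed genus matrix, and the test suite asserts that
limit at 1e-8. Five axes are returned by default.

## Indicator analysis

For a unit (genus or internal node) and a group combination c:
A = occupied sites within c / occupied sites anywhere (specificity),
B = occupied sites within c / sites in c (fidelity), stat = √(A·B).
Candidates are all nonempty *proper* subsets of the groups (capped at
five groups, ≤ 30 combinations), so a ubiquitous taxon can never be
"indicative of everything"; ties are broken toward the smallest, then
lexicographically first combination, for determinism. The group-size
corrected specificity (relative-frequency weighted) is available behind
`group_corrected=True`; the default follows the plain conditional-
probability definitions. No permutation p-values are computed — the
pipeline ranks indicators by stat.

Indicator clades run the same statistic on the site × node matrix
(node present where any descendant tip is) and then keep, per
combination, a greedy antichain: nodes in descending stat order,
skipping any node nested (ancestor or descendant, by tip-set inclusion)
within an already kept node.

## PD partitioning

For each combination c appearing in the genus indicator table, the
pruning set is the genera whose *best* combination is c and whose
specificity exceeds the threshold (default 0.6). Restricted PD for c is
the branch length lost when that set is pruned from the phylogeny of
all genera present anywhere in the data (absent genera never inflate
totals); shared PD is the remainder. Because each genus belongs to at
most one pruning set, the lost branch sets are disjoint, every
component is non-negative, and Σ restricted + shared = total holds
exactly — the tests assert the identity to 1e-9 and the monotone
decrease of every component as the threshold rises.

## Climate versus geography

Random forests (500 trees, seeded, out-of-bag scoring) classify sites
into their evolutionary groups from two feature sets: climatic
(MAT, MAP, TS, CWD; raw scales — trees are scale-invariant) and
geographic (a South-America indicator, latitude, longitude). Sites
lacking a continent assignment or any covariate are excluded from both
models so accuracies are comparable. Importances are mean decrease in
Gini impurity, normalized to sum to one within a model. Out-of-bag
accuracy stands in for "proportion classified correctly on average";
repeated-split estimates behave equivalently on the synthetic data.

Single-variable ranking within a two-group split uses a binomial
regression of the label on the z-scored variable with a varying
intercept per 1° × 1° grid cell (floor(lat), floor(lon)), absorbing
spatial autocorrelation. The random intercept is integrated out by
25-node Gauss–Hermite quadrature (cells are independent, so the
marginal likelihood factorizes) and the three-parameter model
(intercept, slope, random-intercept SD) is maximized by Nelder–Mead
started from the plain-GLM fit; since the GLM is nested at σ = 0 the
fit never falls below it. AIC = −2ℓ + 6. If every grid cell holds a
single site the variance is unidentifiable and the plain GLM is used,
with a logged notice. AIC is invariant to affine rescaling of the
candidate variable (asserted in tests).

Delimitation correspondence compares K = 2 labels with binary
tropics delimitations: the latitude band (|lat| ≤ 23.4°) is computed
internally; other delimitations (e.g. the freezing line) are consumed
as user-supplied 0/1 flags, since they require climatologies the
synthetic generator does not model. The match fraction maximizes over
the two label-to-class mappings and is therefore ≥ 0.5 by construction.

## Synthetic data generator

The generator emulates niche-conserved assembly across a
freezing/water-deficit landscape.

*Phylogeny* — pure-birth (Yule) with `birth_rate = 0.05`/Myr and
exactly `n_genera = 150` tips (defaults); expected root age grows as
ln n / λ (≈ 100 Myr), a reasonable magnitude for an angiosperm genus
tree. Birth–death extinction dynamics are deliberately omitted; they
are not needed for structure-recovery testing.

*Niches* — two traits, cold tolerance and drought tolerance, evolve by
Brownian motion (`sigma2 = 1` per Myr) from the root, so tip covariance
equals σ² × shared path length and close relatives share tolerances.

*Landscape* — 400 sites draw latitude, longitude and elevation; a cold
score (latitude + elevation + noise) defines the freezing flag at its
upper `freezing_fraction = 0.3` quantile, and a dry score defines the
water-deficit gradient. MAT, TS (cold side) and MAP, CWD (dry side) are
generated consistently with those scores, and the continent follows a
longitude split — covariates are created *before* occupancy, so they
are exogenous, matching the causal direction the analysis assumes.

*Occupancy, niche-conservatism scenario* — the freeze line acts as a
hard physiological threshold: only the upper
`frost_tolerant_fraction = 0.2` of the cold-tolerance distribution can
occur at freezing sites, and the most frost-adapted specialists (the
upper fifth of that tolerant tail) cannot persist where it never
freezes — the cold-adaptation trade-off that leaves unique
extratropical lineages. Within the admissible pool, occupancy is
logistic in the squared trait–environment mismatch with niche breadth
`filter_width = 0.5` trait SD (per-genus lognormal spread, SD 0.4, so a
few widespread generalists exist). Site optima are quantile-mapped into
the realized trait distributions, and a site whose drawn environment
cannot support the five-genus minimum in expectation redraws its
drought (and, if still stuck, cold) optimum within its own pool —
assemblages exist where trees can live. The cutoff steepness scales
with `filter_width`, so in the wide-filter limit all structure
dissolves (asserted: mean K = 2 silhouette < 0.15).

*Dispersal-limitation scenario* — tips inherit a continent along the
tree with a rare switch rate (0.01/Myr), and occupancy follows
continent match (0.35 vs 0.01) independent of environment. The `mixed`
scenario multiplies the two.

*Planted truths* — the site labels (freezing flag, or continent under
dispersal limitation) and the planted restricted-PD fraction: the share
of PD over present genera lost when the frost-specialist genera are
removed. Under defaults this share is ≈ 0.10–0.18 across seeds.

What the generator does **not** emulate: real spatial autocorrelation
beyond the grid-cell level, sampling error and detection failure,
abundance structure, migration history, diversification–niche feedbacks,
or realistic climatology for delimitations other than latitude and
freezing. Passing tests therefore demonstrate that the pipeline
recovers planted structure of the hypothesized kind at realistic sizes —
not that real data are free of confounding.

## Validation summary (what the test suite computes)

Boundary identities of the dissimilarities (exactly 0 and 1);
equivalence with brute-force branch-set, double-loop silhouette and
contingency-count oracles (≤ 1e-10 / 1e-12); the star-tree evoPCA
limit (1e-8); the exact PD-partition identity and its threshold
monotonicity; and, across seeds 1–10 at the default study conditions:
mean agreement of the K = 2 clustering with the planted freezing
delimitation ≥ 0.95 (measured ≈ 0.99), climate out-predicting geography
under niche conservatism and the reverse under dispersal limitation in
≥ 9/10 seeds (measured 10/10 each), recovery of the planted
restricted-PD share within 5 percentage points on average (measured
≈ 1), and MAP ranked first by AIC when labels are generated from MAP
alone in ≥ 9/10 seeds (measured 10/10).

## Numerical and engineering notes

Problem sizes were chosen so the full default pipeline runs in a few
seconds and the complete test suite in under a minute on one CPU.
Dissimilarity matrices are symmetrized and clipped to [0, 1] with a
1e-12 tolerance before validation; silhouette and indicator
computations are O(n²) and O(units × combinations) respectively. The
pipeline runner hashes stage inputs (SHA-256) and skips stages whose
inputs and recorded outputs are unchanged; a cached file that no longer
matches its checksum raises rather than being silently reused or
recomputed. Every stochastic component takes an explicit seed; there is
no hidden global RNG state.
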