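# Methods

This note documents the models and procedures implemented in `multitraj`,
the defaults and why they were chosen, and what the synthetic experiments
do and do not demonstrate.

## Multiplex modularity and the Louvain optimizer

The quality function is the **sum of per-layer Newman–Girvan modularities
under one shared partition**, with the resolution γ multiplying the null
term identically in every layer:

Q(c; γ) = Σₛ (1/2mₛ) Σᵢⱼ [A⁽ˢ⁾ᵢⱼ − γ k⁽ˢ⁾ᵢ k⁽ˢ⁾ⱼ / 2mₛ] δ(cᵢ, cⱼ).

Layers are summed, not averaged (a 1/L factor would rescale Q without
moving its optima). Nodes absent from a layer have degree 0 there and
contribute nothing to that layer's terms. A layer with zero edges makes
1/(2mₛ) undefined and is rejected. Edges may carry weights, but the default
pipeline treats layers as unweighted (`weighted=False`), since binary
evidence layers (interacts / shares a pathway / shares a drug) are the
typical input; weighted modularity is available behind the flag.

The optimizer is classical Louvain adapted to the shared partition: local
moves evaluate the summed gain over all layers; each pass visits nodes in a
seeded random order; a node moves to the neighbouring community with
maximal gain, accepting only improvements > 1e-12, with ties resolved to
the smallest community id; the aggregation phase contracts all layers with
the same super-nodes. Q after every pass is recorded and is non-decreasing
by construction. The returned quality is re-evaluated on the original
network with the direct formula, so the optimizer cannot silently disagree
with the definition. On graphs small enough to enumerate (Bell(6) = 203,
Bell(8) = 4140 partitions), `exhaustive_max_modularity` provides an exact
oracle; the test suite verifies the optimizer attains it.

**Resolution grid.** The package default is γ = 1…50 in integer steps — a
modest discrete grid suited to large (10⁴-node) networks. The grid must be
chosen relative to network size: for the 300-gene synthetic scenario the
whole structure dissolves into singletons beyond γ ≈ 15, so the scenario
uses γ = 1…12, which spans the coarse module scale (γ ≈ 1), the submodule
scale (γ ≈ 2–8) and the fragmentation onset (γ ≈ 9–12). Per-γ runs use
derived seeds (seed + grid index) and communities are renumbered canonically
by first-node appearance.

## Trajectories and their distances

A gene's trajectory is its community label sequence along the grid. The
Hamming trajectory distance dH counts grid positions at which two genes are
in *different* communities — a co-membership comparison, invariant to any
per-column relabelling, and an integer on the same scale as θ (a normalized
variant, dH/T, sits behind a flag). dH is a pseudometric; the suite
property-tests symmetry, identity and the triangle inequality.

Dynamic communities are identified by **exact member-set equality** across
grid positions. Each maximal run of consecutive presence is an interval:
k intervals mean k births and k − 1 resurgences; deaths are k − 1 when the
community is still present at the last grid point, k otherwise. Whether to
additionally count a terminal death is convention; the default does not
(`terminal_death=False`), so deaths − resurgences ∈ {0, 1} exactly, with 1
iff the community is absent at the end.

The gene dendrogram uses average linkage (UPGMA) by default — the linkage
used for trajectory landscapes is a presentation choice, and UPGMA is the
least committal; Ward is reserved for patient clustering where the
silhouette/PAM machinery expects variance-like behaviour. Trees serialize
to newick via scikit-bio.

## Minimal-gene-set selection, clustering, scoring

For one patient, grouping is computed **among that patient's altered genes
only**: at θ = 0 the groups are exact trajectory-equivalence classes
(identical label rows); at θ > 0 they are complete-linkage clusters of the
patient-restricted dH matrix cut at height θ, so every within-group pair
satisfies dH ≤ θ. The minimal set keeps groups of size s with
smin ≤ s ≤ λ. smin defaults to 2: a selected gene must co-travel with at
least one other gene; singletons carry no association evidence
(configurable). Grouping does not involve λ, hence selections are nested in
λ — a property the tests assert.

Patient similarity is the Jaccard index of the minimal sets (J = 1 when
both are empty, 0 when exactly one is); clustering is Ward on 1 − J using
the squared-distance Lance–Williams update (the convention usually called
Ward.D2, appropriate for non-Euclidean dissimilarities). The number of
clusters is chosen by running a deterministic PAM (BUILD + steepest-descent
SWAP, ties to smaller indices) for k = 2…kmax on the same distance matrix
and maximizing the average silhouette width (ties to the smallest k); the
final labels cut the Ward tree at that k (`pam_direct` returns the PAM
labels instead). Patients are sorted internally, so results do not depend
on input order.

Scoring maps each cluster to its majority reference label (ties to the
lexicographically smallest label; several clusters may map to one label,
which is how a mixed cluster can absorb borderline patients). Two
accuracies are reported: micro (percent of patients whose mapped label
matches their reference) and macro (mean per-reference-class recall) —
published accuracy figures for this kind of pipeline are not always integer
ratios of the cohort size, so both conventions are exposed rather than
certifying either. MCC is the multiclass (Gorodkin) coefficient of the
mapped confusion table, defined as 0 when its denominator vanishes.

Optimization scans the (θ, λ) grid (defaults θ ∈ {0,…,3}, λ ∈ {2,…,10},
kmax = 8) and picks the maximum accuracy, with ties resolved by maximum
MCC, then minimum average selected genes per patient, then minimum λ, then
minimum θ. Held-out patients are selected at the optimal (θ, λ) and
assigned the cluster of the highest-J trained patient; an empty held-out
selection is an explicit *unclassifiable* outcome, never a silent
assignment.

## Robustness procedures

**Shuffling** permutes the pooled (patient, gene) incidence and repairs
within-patient duplicates by random pairwise swaps that never create new
duplicates, preserving both marginals exactly — each patient's gene count
and the pooled gene multiset (equivalent in distribution to checkerboard
swaps). Each replicate re-runs selection, clustering and scoring at fixed
(θ, λ): the published form of this analysis holds the optimized parameters
fixed, so that is the default; re-optimizing per replicate is possible by
calling `optimize_parameters` on the shuffled cohort. The study-scale
default is 10,000 replicates; tests and the acceptance script use 50 with
fixed seeds, which already separates planted cohorts from their nulls by
> 50 accuracy points.

**Iterative exclusion** re-optimizes after removing each patient's selected
genes from its altered set, stopping when selection dries up, any patient
empties, accuracy reaches 0, or an iteration cap is hit. Removed sets are
disjoint across iterations per patient by construction.

## Cluster significance

The feature object for both procedures is the binary patients ×
union-of-selected-genes incidence matrix at the optimal (θ, λ): the
clustering consumes selected gene sets, so resampling must act on genes.

**Multiscale bootstrap (AU).** For each scale r ∈ {0.5, …, 1.4} (step 0.1),
round(r·p) gene columns are drawn with replacement; the weighted Jaccard
distance (column-multiplicity form, identical to duplicating columns)
and Ward tree are recomputed, and BP(r) is the fraction of replicates
containing each original clade. AU follows the signed-distance model:
Φ⁻¹(1 − BP(r)) is regressed on (v√r + c/√r) by weighted least squares with
the standard binomial weights, and AU = 1 − Φ(v − c), clamped to [0, 1].
Clades recovered always (or never) at every scale are clamped to AU 1
(or 0); with fewer than two informative scales the majority BP decides the
clamp. Default 1000 replicates per scale; tests use 100.

**Monte Carlo p values.** This construction is the package's own design —
it exposes the empirical-p / Gaussian-approximate-p interface of Monte
Carlo cluster-significance procedures whose exact statistic is not
standardized — and two of its choices are deliberate corrections found
necessary for calibration:

* The patient distance matrix is embedded once (classical Torgerson
  embedding), truncated to its d = min(rank, max(2, n//4)) leading axes,
  and each axis whitened to unit variance. Truncation well below n is
  essential — whitening a full-rank embedding maps any point set onto a
  regular simplex. Whitening makes the statistic pivotal, so nulls can be
  drawn from a standard Gaussian instead of a covariance estimated from n
  points, whose eigenvalue overdispersion otherwise biases null splits
  strong.
* Each internal node (≥ 3 members) is scored by the separation index
  (between-children / total dispersion of its member rows); the null pools
  the same index from the clades of Ward trees built on M complete
  standard-Gaussian datasets, **matched by clade size** (the size window
  widens symmetrically until ≥ 19 null values are pooled). Size-matching
  corrects the selection effect — Ward clades are conditioned to be
  compact, so unconditioned same-size Gaussian samples are a biased null.

The empirical p is the add-one rank (1 + #{null ≥ observed}) / (pool + 1),
never 0; the Gaussian approximate p is the upper tail of a normal fitted to
the pooled nulls. On single-Gaussian data the empirical p is approximately
uniform over nodes × repeats (KS-tested in the suite); on planted two-block
data the root reaches the minimal attainable p and block clades reach
AU ≥ 0.95.

## Link enrichment (NEAT)

For gene sets A (a patient's minimal set) and B (an entity's genes) in a
layer with m edges and summed degrees dA, dB, the observed cross-link count
n_AB (each edge once) is tested against
X ~ Hypergeometric(2m, dB, dA), mean μ_AB = dA·dB/2m, one-sided upper tail
(overrepresentation only). Overlapping sets are handled as B \ A with a
warning (strict mode raises). p values are BH-adjusted per patient per
layer across entities (α = 0.05 default). An entity is a cluster's
*consensus* hit when adjusted p ≤ α in every patient of the cluster and
*unique* when consensus nowhere else. The hypergeometric null approximates
a degree-preserving configuration model; under explicit degree-preserving
rewiring the empirical false-positive rate at α = 0.05 stays ≤ 0.08
(checked in the suite). Whether B is a gene set or a single gene's
neighbourhood is up to the entity map — a singleton entry expresses the
latter.

## Synthetic data: what it emulates, what it does not

`simulate_multiplex` plants two nested scales: modules split into
submodules, per-layer independent edges at p_fine (within submodule),
p_coarse (within module) and p_background, with per-layer submodule dropout
(p_fine → p_coarse) creating layer heterogeneity. `simulate_cohort` gives
each subgroup disjoint signature submodules; a patient carries its
signature genes (kept with probability 1 − dropout) plus uniform background
genes.

The reference scenario is 300 genes, 4 modules × 3 submodules, 3 layers,
p_fine = 0.9, p_coarse = 0.05, p_background = 0.005, 10% submodule dropout;
4 subgroups × 8 patients, 2 signature submodules each, 10% signature
dropout, 40 background genes per patient; sweep grid γ = 1…12. The edge
probabilities mirror the classical 2-block planted-partition regime
(0.9 within / 0.05 between); two signature submodules per subgroup use 8 of
the 12 submodules, leaving free submodules to supply structured background.
At these sizes the suite and the acceptance script complete in well under a
minute each; the shuffle null uses 50 replicates, significance uses 60–99
null datasets and 100 bootstrap replicates per scale.

What passing these experiments shows: the full pipeline — detection,
trajectories, selection, clustering, optimization, held-out assignment —
recovers planted structure exactly and its null procedures are calibrated.
What it does not show: behaviour under real biological degree
distributions, correlated layers, identifier noise, or cohort batch
effects; the generator makes no attempt to emulate those. Gene identifiers
are opaque strings throughout — no Entrez/symbol mapping is performed — and
building real evidence layers from source databases is outside the
package's scope: it consumes pre-built edge lists.

## Numerical and degenerate-input conventions

* Louvain move threshold 1e-12; move ties → smallest community id;
  silhouette ties → smallest k; PAM ties → smallest index; majority-label
  ties → lexicographically smallest label.
* J(∅, ∅) = 1, J(∅, S) = 0; an all-empty selection across the cohort is an
  error ("no signal at these parameters"), and an all-empty shuffle
  replicate scores 0 and is flagged.
* Empirical p values are add-one and can never be 0; AU is clamped to
  [0, 1]; MCC with a degenerate denominator is 0.
* γ = 0 is allowed (null term vanishes; a connected network merges into one
  community) — useful for testing, not for analysis.
* All stochastic entry points take explicit integer seeds; sweep, shuffle
  and bootstrap replicates use derived seeds (base + index), so any prefix
  of a run is reproducible.
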