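# Methods

## Model

`clonetree` treats an N×M binary marker matrix — rows are observed
sequences (bisulfite reads summarized as methylation patterns, or
single-cell SNV genotypes), columns are marker sites — as a draw from an
infinite mixture whose components ("clones") occupy the nodes of a
rooted tree. Unlike classical phylogenetics, observed data may sit at
inner nodes as well as leaves: a clone can be an ancestor of another
clone.

### Tree prior

Clone proportions follow a tree-structured stick-breaking process
TSSB(λ, α₀, γ). Each node ε (a tuple of child indices; the root is the
empty tuple) draws a depth stick ν_ε ~ Beta(1, α₀λ^{−|ε|}) deciding how
much of the mass arriving at the node stays there, and each child draws
a breadth stick ψ ~ Beta(1, γ) splitting the rest among siblings:

    φ_{εi} = ψ_{εi} ∏_{j<i} (1 − ψ_{εj}),
    π_ε    = ν_ε φ_ε ∏_{ε′ ancestor} φ_{ε′}(1 − ν_{ε′}),   π_root = ν_root.

We fix λ = 2, α₀ = 0.3, γ = 0.1 (no hyperparameter resampling). λ is
the depth *decay* rate: the stick parameter shrinks geometrically with
depth, so deep sticks concentrate near 1, descents terminate almost
surely, and trees stay shallow (a few levels), which is the regime
clone trees live in. The opposite reading — a stick parameter that
*grows* with depth — makes the process improper (a positive fraction of
mass never stops descending) and, empirically, collapses the posterior
into a single maximally deep chain of clones, so it is rejected on
both theoretical and observed grounds. λ is exposed as a configuration
knob; a `max_depth` truncation (default 15, ν ≡ 1 at the cap) bounds
the work per descent and keeps the improper regime usable for
experimentation.

### Observation model and transition kernel

Each clone carries a real vector θ_ε of length M; the probability of
observing a 1 at site i is σ(θ_{i,ε}) (logistic σ, clamped at 1e−15 for
stable logarithms). Sites are independent; missing entries (encoded NA,
assumed missing completely at random, as for allele dropout) simply
drop out of the likelihood.

Parent-to-child evolution of θ is a per-site two-component Laplace
mixture with modes ±μ and scale Λ. The mixture weight of the +μ
component is an entry of the two-state CTMC transition matrix
P(t) = exp(At): sites whose parent parameter is at or above the calling
threshold η use P(m→m), the rest P(u→m). The branch length t_ε of each
non-root clone scales the chain. η = 1 by default (a conservative call:
σ(1) ≈ 0.73). The root prior is Laplace(−μ, Λ) at every site, favoring
a fully unmethylated/unmutated root.

Two rate matrices are supported. For methylation, A is the reversible
two-state generator with equilibrium (β_u, β_m) scaled so the mean
event rate is one (2β_uβ_mρ = 1). For SNVs, the rate out of the mutated
state is zero (irreversible evolution; β_m(1−β_m)ρ = 1), so
P(m→u) = 0 exactly for every t — transition matrices are computed in
closed form rather than by numerical exponentiation so this structural
zero is exact. β_m is estimated up front as the mean of the observed
entries (the frequency-weighted average methylated/mutated fraction);
μ and Λ are inferred.

## Inference

A Gibbs/Metropolis sweep comprises:

1. **Assignments** — two complementary kernels. First, per-observation
   slice sampling over the stick-breaking layout of the unit interval:
   the descent instantiates sticks and nodes lazily (new nodes draw θ
   from the parent transition kernel and t from its prior), and the
   interval-shrinkage step uses the pre-order of clone labels, which
   coincides with the interval order of the layout. Second, a
   vectorized restricted Gibbs refinement: one fresh child per node is
   instantiated from the prior (lazy instantiation made eager), and all
   N assignments are redrawn at once from their exact conditional
   Discrete(π_ε p(x_n|θ_ε)) restricted to the instantiated nodes.
   Assignments are conditionally independent given sticks and θ, so the
   joint redraw is a single categorical sample per observation; the
   restriction satisfies detailed balance, and the slice pass supplies
   ergodicity over the un-instantiated remainder. The refinement is the
   sampler's main clone-birth mechanism — it proposes a birth at every
   extension point for every observation with its exact conditional
   probability, where the slice pass alone probes a heavy node's child
   region with probability proportional to its tiny leftover stick
   mass. Each pass ends with culling of empty leaf-side nodes; culling
   keeps the ψ sticks of removed middle children in place, so surviving
   siblings keep their weights and stick identities stay stable.
2. **Clone parameters** — per-site Gaussian random-walk Metropolis
   (step 0.5, no adaptation) against the local likelihood, the incoming
   transition density, and the outgoing transition terms of the
   children. Sites factorize, so all M sites are proposed and
   accepted/rejected independently in one vectorized step.
3. **Branch lengths** — random-walk Metropolis on log t under an
   Exponential(mean 1) prior. The prior matches the CTMC time scaling
   (one expected event per unit time) and is configurable.
4. **Sticks** — Gibbs draws of ν and ψ from their Beta full
   conditionals given subtree counts.
5. **Kernel hyperparameters** — Metropolis updates of μ (Gamma(4, 1)
   hyperprior, mode 3) and Λ (Gamma(2, 0.5) hyperprior, mean 1,
   log-scale walk). The originals are not published; these are
   explicit, documented substitutes chosen to respect the kernel's
   design intent: the two Laplace modes at ±μ must stay separated
   (μ = 0 erases the signal) and the within-mode spread must stay below
   the mode separation (Λ ≫ 1 lets the modes overlap, and the
   transition kernel then stops discriminating present from absent
   markers — a degeneracy we observed before adopting these priors).
6. **Swap-clone moves** — the parameters, assigned observations and ν
   masses of two uniformly chosen nodes are exchanged; the move is
   accepted by a Metropolis ratio on the joint density, after which the
   sticks are re-drawn from their conditionals. States whose root holds
   no observations are invalid: if a swap empties the root, the root is
   forcibly exchanged with a randomly chosen occupied node. (Whether
   the original's follow-up root swaps were themselves
   Metropolis-accepted is not documented; the forced exchange bounds
   the repair loop.)
7. **Prune-and-regraft moves** — a non-root subtree is detached (its
   stick position stays behind as an unoccupied ghost, so sibling
   weights are untouched) and proposed as a fresh child of another
   node, with a Metropolis accept on the joint density and a Hastings
   correction for the target counts; the new breadth stick is drawn
   from its prior, which cancels in the ratio. This relocates whole
   clades in one step — something neither the assignment kernels nor
   the swap move can do — and is the main repair mechanism for wrong
   attachments. Like the swap move, it relies on the subsequent stick
   Gibbs step for the stick bookkeeping, so the pair (move + stick
   resampling) is the unit that preserves the target.

The default schedule discards 30,000 sweeps as burn-in, keeps 50,000
and thins by 5, retaining 10,000 samples. Each retained sample stores
the assignment vector, a tree snapshot (labels, π, θ, t), the
complete-data log-likelihood, and the big-node count (nodes with
π > 0.01).

**Complete-data log-likelihood.** Assignment indicators are integrated
out against the instantiated weights: Σ_n log Σ_ε π_ε p(x_n|θ_ε), plus
the transition terms of the occupied part of the tree and the root
prior. Parameters of empty leaf-side nodes marginalize out (their
kernel integrates to one), so instantiating one does not move the
value.

**Summaries.** The posterior similarity matrix holds pairwise
co-clustering frequencies across the trace. The summary partition
maximizes the posterior expected adjusted Rand index (PEAR,
Fritsch–Ickstadt form) over average-linkage cuts of 1 − PSM at 1..20
clusters (ties prefer fewer clusters; exact maximization over all
partitions is infeasible). The reported MAP tree is selected by
grouping samples by big-node count, taking the most frequent group
(ties toward fewer big nodes — parsimony), and within it the sample
with the highest complete-data log-likelihood.

### Sampler settings and initialization

The per-sweep structure is fixed in the order above. Per sweep, the
defaults run one slice pass, one restricted-Gibbs refinement pass,
three θ Metropolis iterations, five swap-move attempts and five
regraft attempts (all configurable counts). At reduced schedules (a
few thousand sweeps) a minimal one-scan sweep leaves clone births as
the mixing bottleneck and chains visibly under-split; the refinement
pass and the extra move attempts attack exactly that bottleneck while
leaving the invariant distribution unchanged.

Chains start over-split by default: observations are grouped by their
observed marker pattern (up to 30 groups; rarer patterns fold into the
nearest frequent pattern by Hamming distance on observed sites), the
group with the fewest present markers seeds the root, and the rest
attach as a star under it with θ initialized at ±μ per site. Merging
redundant clones is the easy direction for the sampler — plain Gibbs
reassignment does it — whereas splitting a heavy clone requires rare
birth events, so short chains mix far better from an over-split state.
Initialization has no effect on the invariant distribution; an
all-at-root start remains available (`init="root"`).

## Synthetic benchmark

`simulate.make_fixture` builds five canonical ground-truth trees over
8 sites: monoclonal (healthy root 0.2, tumor clone 0.8), polyclonal-low
(6 clones in 3 layers, dominant mid-layer clone), polyclonal-medium
(the low tree scaled by 0.87 plus a fourth layer of five clones at
frequencies 0.03, 0.03, 0.03, 0.02, 0.02), polyclonal-high (18 clones;
seven additions at ≈0.02, all renormalized), and mutator (a star of
twelve equal leaves under a 0.04 root). Genotypes evolve along edges by
fixed per-edge site flips; every child differs from its parent in at
least one site, and several fourth-layer clones differ from their much
larger parent at exactly one site. Observations are drawn i.i.d. from
the clone frequencies and corrupted by independent per-site flip noise
(rates 0, 0.01, 0.02, 0.05 in the benchmark).

The exact published topologies are figure-only; the fixtures encode all
stated clone counts, frequencies and layer structures, and deliberately
retain the hard regime of near-identical, highly asymmetric clones.
That regime is why noise-free polyclonal clustering plateaus just below
perfect accuracy: merging a ten-observation clone into its parent costs
little likelihood, and short chains rarely resolve every such split.
What the synthetic benchmark does *not* emulate: within-clone
heterogeneity, site-dependent error rates, linkage between sites, and
the read-sampling process of real bisulfite or single-cell data — so
passing these tests demonstrates correct inference under the model's
own assumptions, not robustness to model misspecification.

## Baselines and metrics

The baseline pipelines compute Jaccard distances between rows, cluster
by complete-linkage hierarchical clustering or k-medoids (PAM-style,
greedy build plus Voronoi refinement, implemented in-package), select
the cluster number in 2..20 by mean silhouette, estimate per-cluster
"methyltypes" (thresholded means for hierarchical — strictly > 0.5 maps
to 1 — or medoids), and build a minimum spanning tree of Hamming
distances between methyltypes (stable Kruskal, lexicographic tie
breaks), rooted at the pattern with fewest 1s (ties: lexicographically
smallest).

Clusterings are scored by the v-measure. Trees are compared by the
consensus node-based shortest path distance: over the marker patterns
present in the ground truth and in *every* compared tree, the
lower-triangular hop-distance matrices are compared by the sum of
absolute differences. "Markers" are read as node-level patterns (clone
genotypes/methyltypes) — the only entities present in all trees — and
paths are counted in hops on the undirected tree; a pattern occurring
at several nodes is represented by its heaviest node. Branch-length
weighting is available behind a flag of the hop-matrix helper but is
not the default.

Tree summaries follow the case-study statistics: maximum depth and
clone counts over non-empty clones, big clones (π > 0.01, strict), total
branch length, per-level mass distribution (posterior means across the
trace when summarizing a chain), and symmetrized Kullback–Leibler
divergence between level-mass distributions (smoothing 1e−10).

## Problem sizes and numerical choices

The test suite and the acceptance script run the benchmark at reduced
sizes chosen to keep a laptop-scale run comfortable: n = 200–500
observations (instead of 2,000) and chains of 2,000 burn-in plus 3,000
kept sweeps thinned by 5 (instead of 30,000 + 50,000). Noise-ordering
checks are asserted by majority over three seeds because single short
chains are stochastic.

Numerical details: σ clamped at 1e−15; stick-depletion tolerance 1e−10
(far below the 1% big-clone threshold); new branch lengths floored at
1e−6; slice intervals abandoned below width 1e−12 (the current
assignment is kept); Laplace Λ is a scale (density (2Λ)^{-1}
exp(−|x−loc|/Λ)).

## Known limitations

* Binary alphabets only; no copy-number or homozygous states.
* Sites are modeled as independent; real CpG neighborhoods and linked
  SNVs violate this.
* Setting the depth decay below 1 makes the stick process improper and
  forces deep degenerate chains; it is supported only behind the
  `max_depth` truncation.
* Short chains under-split near-identical clones; the v-measure
  plateau on noise-free polyclonal data is a mixing property, and its
  exact level varies by a few points across seeds.
* MPEAR searches only hierarchical cuts of the PSM, not all partitions.
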