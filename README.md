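# clonetree

Bayesian nonparametric reconstruction of intra-tumor clone trees from
binary marker matrices.

## The problem

A tumor is a mixture of subclones related by descent. Binary marker
profiles — CpG methylation patterns from bisulfite reads, or
single-cell SNV genotypes — sample that mixture, but each observed
sequence is noisy and the number of clones is unknown. The intra-tumor
phylogeny problem asks for both at once: *which* clones are present
(clustering), and *how* they are related (tree building). Crucially,
ancestral clones are often still alive, so clones must be allowed at
inner nodes of the tree, not just at its leaves — which rules out
classical phylogenetic methods that place all observations at leaves.

`clonetree` solves both subproblems in one model: observed sequences
`x_n ∈ {0,1}^M` are assigned to the nodes of an infinite tree whose
node proportions `π_ε` follow a tree-structured stick-breaking process,

    ν_ε ~ Beta(1, α₀ λ^{−|ε|}),   ψ_ε ~ Beta(1, γ),
    π_ε = ν_ε φ_ε ∏_{ε′ ancestor} φ_{ε′} (1 − ν_{ε′}),

each clone emits markers through a sigmoid-Bernoulli likelihood with
parameters `θ_ε ∈ R^M`, and parent→child parameter evolution is a
Laplace mixture steered by a two-state continuous-time Markov chain
`P(t) = exp(At)` along branch lengths `t_ε` (irreversible for SNVs:
`P(m→u) = 0`). Inference is by MCMC (slice-sampled assignments with
lazy node creation, Metropolis parameter updates, Gibbs stick updates,
and swap-clone moves); the trace is summarized by an MPEAR consensus
partition and an empirical MAP tree. The package also ships the
simulation benchmark (five canonical ground-truth trees), two
distance-based baseline pipelines (hierarchical / k-medoids clustering
with silhouette model selection plus Hamming minimum spanning trees),
and the evaluation metrics (v-measure, consensus node-based shortest
path distance, tree summary statistics).

See `docs/methods.md` for the full model, sampler, and design choices.

## Worked example

Simulate 500 noise-free observations from the 11-clone
polyclonal-medium benchmark tree, run a reduced-schedule chain, and
score the result:

```sh
clonetree simulate --tree polyclonal-medium --n 500 --error 0 \
    --seed 1 --out demo/sim
clonetree run --input demo/sim_matrix.csv --burnin 2000 \
    --samples 3000 --thin 5 --seed 1 --out demo/run
clonetree baseline --input demo/sim_matrix.csv --method hclust \
    --out demo/bl
clonetree evaluate --true demo/sim_fixture.json \
    --true-labels demo/sim_labels.csv --pred demo/run \
    --baseline demo/bl --out demo/metrics.csv
```

Output printed by the commands:

```
wrote demo/sim_matrix.csv (500 x 8, error=0.0)
read 500 x 8 matrix (0 missing entries)
MPEAR clusters: 8; MAP tree: 9 clones, 9 big, max depth 2
hierarchical: k=11, silhouette=1.000
wrote demo/metrics.csv
```

and `demo/metrics.csv` contains (one row per method):

```
method,consensus_sp_distance,max_depth,n_clones,n_big_clones,total_branch_length,v_measure
clonetree,38.0,2.0,9.0,9.0,7.427996912563179,0.9569338729452546
hierarchical,0.0,,,,,1.0
```

Reading the numbers: on noise-free data the baseline is perfect (every
clone has a distinct genotype, so silhouette selection finds k = 11
exactly and its spanning tree matches the truth), while the mixture
model merges two or three of the near-identical low-frequency clones
into their parents and lands at v ≈ 0.96 — the characteristic
sub-perfect plateau of this benchmark. The model's value shows under
noise, where the baselines degrade sharply: at a 5% per-site flip rate
the MAP tree's consensus shortest-path distance to the truth drops to
0–4 versus 6–21 for the hierarchical baseline's spanning tree, and the
MPEAR partition scores well above hierarchical clustering (around 0.6
versus 0.55; the k-medoids baseline stays competitive at this reduced
sample size). `tests/test_acceptance.py` runs these comparisons.

The same pipeline runs on real matrices: a delimited 0/1/NA file with
one row per sequence or cell (`--model snv` for single-cell genotype
matrices with missing entries).

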