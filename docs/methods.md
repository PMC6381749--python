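# Methods

## Overview

`hetrank` predicts lncRNA–disease associations by network propagation. The
pipeline has four stages:

1. **Evidence similarity networks.** Three lncRNA networks — co-expression
   (positive, significant Pearson correlation between expression profiles),
   and two Gaussian interaction-profile (GIP) kernels over lncRNA–miRNA and
   lncRNA–protein interactions — and three disease networks — Wang semantic
   similarity on a disease-ontology DAG, and GIP kernels over disease–miRNA
   and disease–gene associations.
2. **Topological similarity.** Each network is row-normalised into a
   transition matrix `W(i,j) = B(i,j)/Σ_j B(i,j)` and diffused by random walk
   with restart, `S ← (1−α) S W + α S₀` with `S₀ = I`, iterated until the
   entrywise L1 change falls below ε. Row *i* of the stationary `S` is node
   *i*'s diffusion state. Pairwise positive pointwise mutual information,
   `MI(i,j) = max(0, log₂ (S(i,j)·ΣΣS / (Σ_i S(i,j) · Σ_j S(i,j))))`, is
   symmetrised by averaging `MI(i,j)` and `MI(j,i)`, and the three matrices
   per node kind are averaged entrywise into the fused topological
   similarity (`X′ = (X¹+X²+X³)/3`). A raw-averaging variant skips
   diffusion+PPMI and averages the similarity matrices directly; it exists
   for ablation comparison.
3. **Heterogeneous network.** The fused lncRNA and disease matrices become
   the diagonal blocks of `A = [[A_L, A_LD], [A_DL, A_D]]`, with `A_LD` the
   binary known-association matrix. The transition matrix gives each
   associated node `γ` of its outgoing mass to its bipartite edges and
   `1−γ` to its own layer; unassociated nodes walk purely within their
   layer.
4. **Ranking.** For a query disease, the restart vector is
   `p₀ = [η·u₀ ; (1−η)·v₀]` with `u₀` uniform over the disease's known
   lncRNA partners and `v₀` a unit mass on the disease; the walk
   `p ← (1−β) p M + β p₀` is iterated to its fixed point and the non-seed
   lncRNAs are ranked by their stationary probability, ties broken by node
   index.

## Parameters

| name | meaning | default | notes |
|---|---|---|---|
| α | restart probability of the per-network diffusion | 0.9 | sweepable 0.1–0.9 |
| β | restart probability of the heterogeneous walk | 0.6 | sweepable |
| γ | jump probability between layers | 0.9 | sweepable |
| η | lncRNA-layer weight in the restart vector | 0.2 | sweepable |
| ε | L1 convergence tolerance of both walks | 1e−10 | |
| p_threshold | Pearson significance gate (two-sided, unadjusted) | 0.01 | |
| w_is_a | Wang is_a contribution factor | 0.8 | |

All restart-style parameters live in `(0,1]`; the evaluation module
provides a grid sweep (`parameter_sweep`) that caches the topology stage
per α, since β, γ and η do not touch it.

## Conventions and edge-case policy

- **GIP kernel.** `KD(i,j) = exp(−κ‖IP(i)−IP(j)‖²)` with bandwidth
  `κ = 1/((1/N)Σ‖IP(i)‖²)` over all N nodes on the chosen side. The
  squared Euclidean norm is used in the exponent, the standard form of
  this kernel. An all-empty interaction side is an error (κ undefined).
- **Pearson network.** Only positive correlations passing the significance
  gate are kept, at their raw value `r`; row normalisation of a random walk
  needs nonnegative weights and the graded value preserves "similarity
  weighted network" semantics. Zero-variance rows contribute zero
  similarity with a warning.
- **Diagonals.** Every evidence similarity network has a zeroed diagonal
  (self-transitions would dilute the restart). The PPMI matrices keep their
  diagonal, as the formula produces it.
- **Isolated nodes.** An all-zero row in row normalisation becomes an
  identity self-loop so the chain stays stochastic. In the heterogeneous
  transition matrix, an associated node whose intra-layer row is all zero
  sends its full unit mass across the bipartite edges (renormalised); a
  node with no weight in any block gets an identity self-loop with a
  warning. After these repairs every row of `M` sums to 1 ± 1e−9.
- **New-disease mode.** A query with no seed lncRNAs puts the whole unit
  mass on the disease entry. The fixed point scales linearly with `‖p₀‖₁`,
  so this changes no ranking relative to leaving mass `1−η`; it only keeps
  `p₀` a probability vector.
- **Convergence.** Both walks use the entrywise L1 residual uniformly and
  error out (rather than returning silently) when the iteration cap is hit.
  The diffusion stage switches to CSR matvecs above 2000 nodes; results are
  identical to the dense path.

## Evaluation protocols

- **LOOCV.** One fold per known association: the bipartite edge is removed
  (similarity layers are association-independent and stay fixed), the
  transition matrix rebuilt, the walk re-run seeded with the disease's
  remaining partners, and the held-out lncRNA's rank recorded. Scores are
  pooled across folds into single ROC and precision–recall curves
  (trapezoidal AUC; step-interpolated AUPR). Negatives are candidates not
  associated with the disease anywhere in the full table, so held-out
  positives of other folds never enter as negatives.
- **Recall@k** is the fraction of folds whose held-out lncRNA ranks within
  the cutoff (10/20/50/100 by default).
- **New-disease evaluation** removes *all* of a disease's associations,
  seeds only the disease, and scores every removed partner as a positive.
- **Permutation null.** `null_calibration` repeats LOOCV on
  degree-preserving rewirings of the association table (repeated
  double-edge swaps; per-node degrees conserved exactly) and pools folds
  across several independent rewirings, which estimates the null AUC with
  much less variance than a single rewiring.

The null AUC of this protocol sits *slightly below* 0.5 by construction,
for two reasons we verified with control experiments. First, during its
fold the held-out positive carries one fewer association than
equal-nominal-degree negatives, and stationary scores increase with
bipartite degree (under the default γ = 0.9 most walker mass routes through
association edges). Second, pooling scores across query diseases mixes
fold-specific score scales, which costs another point or two of AUC even
for randomly placed pseudo-positives. On the default synthetic data the
pooled null converges to ≈ 0.44–0.50 depending on the generated dataset,
while the planted-signal AUC is ≈ 0.92; the gap, not the absolute null
value, is the meaningful recovery check.

## Synthetic data

The generator plants the exact assumption the method exploits: lncRNAs and
diseases fall into k matched clusters; within a matched cluster lncRNAs
share an expression program (cluster-mean profile plus independent Gaussian
noise) and interaction partners (each bipartite layer is Bernoulli(p_in)
inside matched clusters, Bernoulli(p_out) outside); same-cluster diseases
share deep ontology ancestors (per-cluster subtrees under one root); and
the planted associations live only inside matched clusters. Defaults:
k = 4 clusters over 80 lncRNAs × 60 diseases, p_in = 0.3, p_out = 0.02,
53 expression samples (matching the tissue-panel width of typical
expression atlases), noise scale 0.5, 130 associations per cluster (520
total — enough folds for stable pooled curves while staying inside the
20 × 15 within-cluster pair budget), 60 miRNAs, 60 proteins, 80 genes, and
an ontology of depth 3 with 2 leaf branches per cluster. Everything is
reproducible from one seed.

What the generator does **not** emulate: realistic expression count
distributions, tissue specificity, heavy-tailed interaction degree
distributions, or the size of curated databases. Passing recovery tests on
this data shows the pipeline's machinery is sound and that planted
cluster signal is recoverable; it says nothing about performance on real
curated snapshots.

## A desk-scale caveat: PPMI sparsity at high α

PPMI keeps an off-diagonal entry only when the diffusion mass `S(i,j)`
exceeds its independence expectation, roughly `col_j / n`. With the default
α = 0.9 the diffusion state retains ≈ 0.9 of its mass on the diagonal, so a
neighbour survives only if it concentrates a large share (≳ 1/(0.09·n)) of
its row's remaining mass. On networks with thousands of nodes that bar is
tiny and the stage is informative. On the 60–80-node synthetic default,
where each node spreads its similarity evenly over ~15–20 cluster
neighbours, *no* off-diagonal entry clears the bar and the fused
topological matrices reduce to their diagonals; ranking signal then flows
through the bipartite block alone (which still recovers the planted
associations), and new-disease queries — whose only outgoing path would be
intra-layer similarity — receive constant zero candidate scores. Lowering
α (≤ 0.5) makes the stage non-degenerate at desk scale; the parameter
sweep covers this. We deliberately keep the formulas and the published
defaults untouched rather than special-casing small networks.

## Known limitations

- Identifiers are opaque strings; no namespace mapping or database
  download is performed.
- Two node kinds only; miRNA/protein/gene layers enter through similarity
  kernels, not as walkable layers.
- The fusion weights the three evidence sources equally; learned fusion is
  out of scope.
- Missing expression values are rejected at load rather than imputed.
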