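# hetrank

Prediction of lncRNA–disease associations by multi-network integration and
random walk with restart on a heterogeneous network.

Long non-coding RNAs (lncRNAs) are implicated in many diseases, but
experimentally confirming individual lncRNA–disease links is slow, so
computational prioritisation of candidate lncRNAs for a disease of interest
is a standard step in study design. `hetrank` is for computational
biologists who have (a) lncRNA evidence — expression profiles, lncRNA–miRNA
and lncRNA–protein interactions — (b) disease evidence — an ontology DAG,
disease–miRNA and disease–gene associations — and (c) a table of known
lncRNA–disease associations, and who want a ranked list of novel candidate
lncRNAs per disease together with a cross-validated estimate of how well
that ranking recovers held-out knowledge.

## Method

Three lncRNA similarity networks (Pearson co-expression with a p < 0.01
gate; Gaussian interaction-profile kernels `KD(i,j) = exp(−κ‖IP(i)−IP(j)‖²)`
over the miRNA and protein interaction layers) and three disease networks
(Wang semantic similarity on the ontology; GIP kernels over the miRNA and
gene layers) are each converted to a topological similarity matrix: random
walk with restart

    S ← (1−α)·S·W + α·S₀,   W(i,j) = B(i,j)/Σ_j B(i,j),   S₀ = I

gives every node a diffusion state (its row of the stationary S), and
positive pointwise mutual information

    MI(i,j) = max(0, log₂ [ S(i,j)·ΣΣS / (Σ_i S(i,j) · Σ_j S(i,j)) ])

scores each pair, symmetrised as (MI(i,j)+MI(j,i))/2. The three matrices
per node kind are averaged into fused matrices X′_L and X′_D, which become
the diagonal blocks of the heterogeneous adjacency

    A = [[A_L, A_LD], [A_DL, A_D]]

with A_LD the binary known-association matrix. The block transition matrix
M sends fraction γ of an associated node's mass across the bipartite edges
and 1−γ within its layer. For a query disease, a second restart walk

    p ← (1−β)·p·M + β·p₀,   p₀ = [η·u₀ ; (1−η)·v₀]

(u₀ uniform over the disease's known lncRNA partners, v₀ unit mass on the
disease) is iterated to its fixed point p*, and candidate lncRNAs are
ranked by their entries of p*. Defaults: α = 0.9, β = 0.6, γ = 0.9,
η = 0.2, convergence at L1 change < 1e−10. See `docs/methods.md` for
conventions, edge-case policy and evaluation protocols.

Evaluation is leave-one-out cross-validation over known associations with
pooled ROC/PR curves, recall@k, a degree-preserving permutation null, a
new-disease protocol (all of a disease's associations removed), and a
raw-averaging ablation that skips the diffusion+PPMI step.

## Worked example

All inputs are plain TSV/OBO files; a self-contained synthetic dataset with
planted cluster structure stands in for the curated databases:

```sh
hetrank simulate --seed 11 --out data
hetrank run --config run.yaml --out out
```

where `run.yaml` lists the input paths (all other parameters default):

```yaml
expression: data/expression.tsv
lnc_mirna: data/lnc_mirna.tsv
lnc_protein: data/lnc_protein.tsv
dis_mirna: data/dis_mirna.tsv
dis_gene: data/dis_gene.tsv
ontology: data/ontology.obo
associations: data/associations.tsv
```

which prints the run summary

```json
{
  "n_lncRNA": 80,
  "n_disease": 60,
  "n_associations": 520,
  "n_predictions": 900
}
```

(80 lncRNAs and 60 diseases entered the network; 520 known associations
were planted; 15 top-ranked novel candidates were written for each of the
60 diseases). `out/predictions.tsv` begins

```
disease  rank  lncRNA   score
DIS0000  1     LNC0004  0.003609400286276933
DIS0000  2     LNC0010  0.003378466574383396
DIS0000  3     LNC0011  0.003089293189132074
```

— for disease `DIS0000`, `LNC0004` is the strongest novel candidate and the
score is its stationary visiting probability. Cross-validating the same
configuration:

```sh
hetrank evaluate --config run.yaml --mode loocv --out eval.json
# loocv: AUC=0.9208 AUPR=0.0795 over 520 folds -> eval.json
```

Each of the 520 known associations was held out and re-ranked in turn; an
AUC of 0.92 means a held-out true partner outranks a random non-partner 92%
of the time, against a chance level of 0.5 (the AUPR chance level here is
the positive rate, ≈ 0.014). The other modes are `newdisease`, `sweep`
(nine-point parameter grids) and `ablation`; `hetrank simulate`, `validate`,
`similarity`, `topo`, `fuse`, `heteronet` and `predict` expose the
individual stages.

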