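"""Evidence-level similarity networks.

Three builders produce the weighted networks that feed the topology stage:

* :func:`pearson_similarity_network` — co-expression (positive, significant
  Pearson r between expression profiles);
* :func:`gip_kernel_matrix` — Gaussian interaction-profile kernel over the
  binary incidence vectors of a bipartite interaction layer;
* :func:`ontology_similarity_matrix` — Wang's DAG-based semantic similarity
  between ontology terms.

All three return a symmetric, nonnegative, finite matrix with a zeroed
diagonal carried with its node index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_io import BipartiteInteractions, DataError, ExpressionMatrix, NodeIndex, OntologyDAG, logger

SOURCE_TAGS = ("expression_pearson", "gip_kernel", "ontology_wang")


@dataclass
class SimilarityNetwork:
    node_index: NodeIndex
    weights: np.ndarray
    source_tag: str

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        n = len(self.node_index)
        if w.shape != (n, n):
            raise DataError(f"similarity matrix shape {w.shape} does not match index of size {n}")
        if not np.all(np.isfinite(w)):
            raise DataError("similarity matrix contains non-finite values")
        if np.any(w < 0):
            raise DataError("similarity matrix contains negative weights")
        if not np.allclose(w, w.T, atol=1e-12):
            raise DataError("similarity matrix is not symmetric")
        self.weights = w


def pearson_similarity_network(
    expr: ExpressionMatrix, p_threshold: float = 0.01
) -> SimilarityNetwork:
    """Co-expression network: w[i,j] = r(i,j) when r > 0 and two-sided p < threshold.

    Negative and non-significant correlations are zeroed (downstream random
    walks need nonnegative weights), as is the diagonal.  Zero-variance rows
    get all-zero similarities with a warning.  Requires >= 3 samples so the
    t-test of zero correlation has at least one degree of freedom.
    """
    n_samples = len(expr.samples)
    if n_samples < 3:
        raise DataError(f"Pearson network needs >=3 samples, got {n_samples}")
    values = expr.values
    sd = values.std(axis=1)
    flat = sd == 0
    if flat.any():
        logger.warning("%d zero-variance expression rows; their similarities are 0", int(flat.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(values)
    r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 0.0)
    r = np.clip(r, -1.0, 1.0)
    # two-sided p-value of the t transform t = r*sqrt(df/(1-r^2)), df = n-2
    df = n_samples - 2
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r * r, 0.0))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    w = np.where((r > 0) & (p < p_threshold), r, 0.0)
    w[flat, :] = 0.0
    w[:, flat] = 0.0
    np.fill_diagonal(w, 0.0)
    return SimilarityNetwork(expr.node_index, (w + w.T) / 2.0, "expression_pearson")


def gip_kernel_matrix(
    interactions: BipartiteInteractions, side: str = "left"
) -> SimilarityNetwork:
    """Gaussian interaction-profile kernel similarity for one side of a bipartite layer.

    KD(i,j) = exp(-kappa * ||IP(i) - IP(j)||^2) with the bandwidth
    kappa = 1 / ((1/N) * sum_i ||IP(i)||^2) taken over all N nodes on the
    chosen side.  IP(i) is node i's binary incidence vector over the other
    side.  The diagonal (KD(i,i) = 1) is zeroed in the returned network.
    """
    if side not in ("left", "right"):
        raise DataError(f"side must be 'left' or 'right', got {side!r}")
    inc = interactions.incidence()
    index = interactions.left_index
    if side == "right":
        inc = inc.T
        index = interactions.right_index
    norms_sq = (inc * inc).sum(axis=1)
    mean_norm = norms_sq.mean() if len(norms_sq) else 0.0
    if mean_norm == 0:
        raise DataError("all interaction profiles are empty; GIP bandwidth undefined")
    kappa = 1.0 / mean_norm
    # ||a-b||^2 = ||a||^2 + ||b||^2 - 2 a.b  (profiles are binary so exact)
    sq_dist = norms_sq[:, None] + norms_sq[None, :] - 2.0 * inc @ inc.T
    sq_dist = np.maximum(sq_dist, 0.0)
    kd = np.exp(-kappa * sq_dist)
    kd = (kd + kd.T) / 2.0
    np.fill_diagonal(kd, 0.0)
    return SimilarityNetwork(index, kd, "gip_kernel")


def _wang_svalues(dag: OntologyDAG, term: str, w_is_a: float) -> dict[str, float]:
    """Wang S-values of ``term``'s ancestor closure.

    S_A(A) = 1; for an ancestor t, S_A(t) = max over children t' of t inside
    DAG_A of w_is_a * S_A(t').  Computed by relaxation over the (small)
    ancestor closure; is_a edges run child -> parent.
    """
    closure = dag.ancestors_and_self(term)
    s = {t: 0.0 for t in closure}
    s[term] = 1.0
    # children of t within the closure: nodes whose parent list contains t
    children: dict[str, list[str]] = {t: [] for t in closure}
    for t in closure:
        for p in dag.parents(t):
            if p in closure:
                children[p].append(t)
    # process terms in decreasing distance from the ancestors (topological
    # order child-before-parent); iterate until stable, DAG so it terminates
    order = sorted(closure, key=lambda t: len(dag.ancestors_and_self(t)), reverse=True)
    for t in order:
        if t == term:
            continue
        if children[t]:
            s[t] = w_is_a * max(s[c] for c in children[t])
    return s


def ontology_similarity_matrix(
    dag: OntologyDAG, terms: NodeIndex, w_is_a: float = 0.8
) -> SimilarityNetwork:
    """Wang semantic similarity between ontology terms.

    sim(A,B) = sum over shared closure terms t of (S_A(t) + S_B(t)),
    divided by (SV(A) + SV(B)) where SV is the total S-value of a term's
    closure.  Symmetric, in [0,1]; the diagonal is zeroed in the returned
    network.
    """
    svals = {t: _wang_svalues(dag, t, w_is_a) for t in terms.ids}
    sv = {t: sum(svals[t].values()) for t in terms.ids}
    n = len(terms)
    sim = np.zeros((n, n))
    for i, a in enumerate(terms.ids):
        for j in range(i + 1, n):
            b = terms.ids[j]
            shared = svals[a].keys() & svals[b].keys()
            if shared:
                num = sum(svals[a][t] + svals[b][t] for t in shared)
                sim[i, j] = sim[j, i] = num / (sv[a] + sv[b])
    return SimilarityNetwork(terms, sim, "ontology_wang")
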