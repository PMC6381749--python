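"""Planted-cluster synthetic datasets covering every input class.

The generator instantiates the assumption the predictor exploits: lncRNAs
and diseases fall into matched latent clusters; within a matched cluster,
lncRNAs share expression programs and interaction partners, diseases share
ontology ancestors and molecular associations, and the planted
lncRNA-disease associations live only inside matched clusters — they are
the recoverable signal.  Every output is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import (
    AssociationTable,
    BipartiteInteractions,
    DataError,
    ExpressionMatrix,
    NodeIndex,
    OntologyDAG,
    logger,
)


@dataclass
class PlantedConfig:
    """Shape and strength of the planted structure.

    Defaults give four matched clusters of 20 lncRNAs x 15 diseases with
    clearly detectable but noisy block structure in every evidence layer.
    """

    n_lnc: int = 80
    n_dis: int = 60
    n_mirna: int = 60
    n_protein: int = 60
    n_gene: int = 80
    k: int = 4
    p_in: float = 0.3
    p_out: float = 0.02
    n_samples: int = 53
    expr_noise: float = 0.5
    assoc_per_cluster: int = 130
    dag_depth: int = 3
    dag_branching: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.p_in > self.p_out:
            raise DataError("p_in must exceed p_out")
        for name in ("n_lnc", "n_dis", "n_mirna", "n_protein", "n_gene", "k", "n_samples"):
            if getattr(self, name) < 1:
                raise DataError(f"{name} must be >= 1")


@dataclass
class PlantedDataset:
    expression: ExpressionMatrix
    lnc_mirna: BipartiteInteractions
    lnc_protein: BipartiteInteractions
    dis_mirna: BipartiteInteractions
    dis_gene: BipartiteInteractions
    ontology: OntologyDAG
    associations: AssociationTable
    lnc_clusters: dict[str, int]
    dis_clusters: dict[str, int]


def _cluster_of(n: int, k: int) -> np.ndarray:
    """Contiguous-block cluster labels for n items over k clusters."""
    return np.concatenate([np.full(len(b), c) for c, b in enumerate(np.array_split(np.arange(n), k))])


def _bipartite_layer(
    rng: np.random.Generator,
    left_ids: list[str],
    right_ids: list[str],
    left_cl: np.ndarray,
    right_cl: np.ndarray,
    p_in: float,
    p_out: float,
    left_kind: str,
    right_kind: str,
) -> BipartiteInteractions:
    prob = np.where(left_cl[:, None] == right_cl[None, :], p_in, p_out)
    adj = rng.random(prob.shape) < prob
    edges = frozenset(
        (left_ids[i], right_ids[j]) for i, j in zip(*np.nonzero(adj))
    )
    return BipartiteInteractions(
        NodeIndex.from_ids(left_ids, left_kind), NodeIndex.from_ids(right_ids, right_kind), edges
    )


def _ontology(dis_ids: list[str], dis_cl: np.ndarray, k: int, depth: int, branching: int) -> OntologyDAG:
    """Balanced per-cluster subtrees under one root; same-cluster diseases share
    ancestors at every depth, cross-cluster diseases share only the root."""
    root = "TERM:root"
    terms = [root]
    edges: set[tuple[str, str]] = set()
    attach_points: dict[int, list[str]] = {}
    for c in range(k):
        parent = root
        chain = []
        for level in range(depth):
            t = f"TERM:c{c}_l{level}"
            terms.append(t)
            edges.add((t, parent))
            parent = t
            chain.append(t)
        leaves_parents = []
        for b in range(branching):
            t = f"TERM:c{c}_b{b}"
            terms.append(t)
            edges.add((t, parent))
            leaves_parents.append(t)
        attach_points[c] = leaves_parents
    for i, d in enumerate(dis_ids):
        c = int(dis_cl[i])
        terms.append(d)
        edges.add((d, attach_points[c][i % len(attach_points[c])]))
    return OntologyDAG(NodeIndex.from_ids(terms, "disease"), frozenset(edges))


def generate_planted_dataset(cfg: PlantedConfig) -> PlantedDataset:
    """Generate all input classes with matched planted clusters.

    Expression rows are a per-cluster mean profile plus independent Gaussian
    noise; each bipartite layer is Bernoulli(p_in) inside matched clusters
    and Bernoulli(p_out) outside; associations are sampled uniformly without
    replacement inside matched clusters only.
    """
    rng = np.random.default_rng(cfg.seed)
    lnc_ids = [f"LNC{i:04d}" for i in range(cfg.n_lnc)]
    dis_ids = [f"DIS{i:04d}" for i in range(cfg.n_dis)]
    mirna_ids = [f"MIR{i:04d}" for i in range(cfg.n_mirna)]
    prot_ids = [f"PRO{i:04d}" for i in range(cfg.n_protein)]
    gene_ids = [f"GEN{i:04d}" for i in range(cfg.n_gene)]

    lnc_cl = _cluster_of(cfg.n_lnc, cfg.k)
    dis_cl = _cluster_of(cfg.n_dis, cfg.k)
    mir_cl = _cluster_of(cfg.n_mirna, cfg.k)
    pro_cl = _cluster_of(cfg.n_protein, cfg.k)
    gen_cl = _cluster_of(cfg.n_gene, cfg.k)

    cluster_means = rng.standard_normal((cfg.k, cfg.n_samples))
    expr = cluster_means[lnc_cl] + cfg.expr_noise * rng.standard_normal((cfg.n_lnc, cfg.n_samples))
    expression = ExpressionMatrix(
        NodeIndex.from_ids(lnc_ids, "lncRNA"),
        tuple(f"sample{s:02d}" for s in range(cfg.n_samples)),
        expr,
    )

    lnc_mirna = _bipartite_layer(rng, lnc_ids, mirna_ids, lnc_cl, mir_cl, cfg.p_in, cfg.p_out, "lncRNA", "miRNA")
    lnc_protein = _bipartite_layer(rng, lnc_ids, prot_ids, lnc_cl, pro_cl, cfg.p_in, cfg.p_out, "lncRNA", "protein")
    dis_mirna = _bipartite_layer(rng, dis_ids, mirna_ids, dis_cl, mir_cl, cfg.p_in, cfg.p_out, "disease", "miRNA")
    dis_gene = _bipartite_layer(rng, dis_ids, gene_ids, dis_cl, gen_cl, cfg.p_in, cfg.p_out, "disease", "gene")

    ontology = _ontology(dis_ids, dis_cl, cfg.k, cfg.dag_depth, cfg.dag_branching)

    pairs: set[tuple[str, str]] = set()
    for c in range(cfg.k):
        lncs = [lnc_ids[i] for i in np.nonzero(lnc_cl == c)[0]]
        diss = [dis_ids[i] for i in np.nonzero(dis_cl == c)[0]]
        n_possible = len(lncs) * len(diss)
        if cfg.assoc_per_cluster > n_possible:
            raise DataError(
                f"assoc_per_cluster={cfg.assoc_per_cluster} exceeds the {n_possible} "
                f"within-cluster pairs of cluster {c}"
            )
        chosen = rng.choice(n_possible, size=cfg.assoc_per_cluster, replace=False)
        for idx in chosen:
            pairs.add((lncs[idx // len(diss)], diss[idx % len(diss)]))
    associations = AssociationTable(
        NodeIndex.from_ids(lnc_ids, "lncRNA"), NodeIndex.from_ids(dis_ids, "disease"), frozenset(pairs)
    )

    return PlantedDataset(
        expression,
        lnc_mirna,
        lnc_protein,
        dis_mirna,
        dis_gene,
        ontology,
        associations,
        {l: int(c) for l, c in zip(lnc_ids, lnc_cl)},
        {d: int(c) for d, c in zip(dis_ids, dis_cl)},
    )


def write_dataset(ds: PlantedDataset, outdir) -> dict[str, str]:
    """Write every piece of a planted dataset in the formats the readers consume.

    Returns a mapping of input name to file path, directly usable as the
    path block of a run configuration.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    p = outdir / "expression.tsv"
    with p.open("w") as fh:
        fh.write("\t".join(["id", *ds.expression.samples]) + "\n")
        for i, lnc in enumerate(ds.expression.node_index.ids):
            fh.write("\t".join([lnc, *(repr(float(v)) for v in ds.expression.values[i])]) + "\n")
    paths["expression"] = str(p)

    for name, layer in (
        ("lnc_mirna", ds.lnc_mirna),
        ("lnc_protein", ds.lnc_protein),
        ("dis_mirna", ds.dis_mirna),
        ("dis_gene", ds.dis_gene),
    ):
        p = outdir / f"{name}.tsv"
        with p.open("w") as fh:
            for l, r in sorted(layer.edges):
                fh.write(f"{l}\t{r}\n")
        paths[name] = str(p)

    p = outdir / "ontology.obo"
    parents: dict[str, list[str]] = {}
    for c, par in ds.ontology.is_a_edges:
        parents.setdefault(c, []).append(par)
    with p.open("w") as fh:
        fh.write("format-version: 1.2\n")
        for t in ds.ontology.terms.ids:
            fh.write(f"\n[Term]\nid: {t}\nname: {t}\n")
            for par in sorted(parents.get(t, [])):
                fh.write(f"is_a: {par}\n")
    paths["ontology"] = str(p)

    p = outdir / "associations.tsv"
    with p.open("w") as fh:
        for l, d in sorted(ds.associations.pairs):
            fh.write(f"{l}\t{d}\n")
    paths["associations"] = str(p)
    return paths


def shuffle_null(assoc: AssociationTable, seed: int, n_sweeps: int = 10) -> AssociationTable:
    """Degree-preserving rewiring of the association bipartite graph.

    Repeated double-edge swaps: two edges (l1,d1), (l2,d2) become (l1,d2),
    (l2,d1) when the replacements do not already exist.  Per-node degrees
    and the pair count are conserved exactly.  If no swap ever succeeds the
    input is returned unchanged with a warning.
    """
    if not assoc.pairs:
        raise DataError("cannot shuffle an empty association table")
    rng = np.random.default_rng(seed)
    edges = sorted(assoc.pairs)
    present = set(edges)
    n_attempts = n_sweeps * len(edges)
    swapped = 0
    for _ in range(n_attempts):
        i, j = rng.integers(0, len(edges), size=2)
        (l1, d1), (l2, d2) = edges[i], edges[j]
        if l1 == l2 or d1 == d2:
            continue
        if (l1, d2) in present or (l2, d1) in present:
            continue
        present.discard((l1, d1))
        present.discard((l2, d2))
        present.add((l1, d2))
        present.add((l2, d1))
        edges[i], edges[j] = (l1, d2), (l2, d1)
        swapped += 1
    if swapped == 0:
        logger.warning("association graph too constrained to swap; returning input unchanged")
        return assoc
    return AssociationTable(assoc.lncRNA_index, assoc.disease_index, frozenset(present))
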