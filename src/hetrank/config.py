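"""Run configuration, provenance stamping and the end-to-end pipeline.

A run is described by one YAML-serialisable :class:`RunConfig`.  Stage
outputs are content-addressed: each stage's hash covers exactly the inputs
and parameters that can change its output, so changing only the restart
probability of the ranking walk invalidates the prediction stage but not
the similarity or topology stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .data_io import (
    AssociationTable,
    DataError,
    NodeIndex,
    logger,
    read_associations,
    read_edge_list,
    read_expression,
    read_obo,
    write_matrix,
)
from .heteronet import assemble_adjacency, build_transition_matrix, hnet_s_filter
from .predict import predict_for_disease
from .similarity import gip_kernel_matrix, ontology_similarity_matrix, pearson_similarity_network
from .topology import RwrConfig, topo_fuse


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    # input paths (all TSV except the OBO ontology)
    expression: str = ""
    lnc_mirna: str = ""
    lnc_protein: str = ""
    dis_mirna: str = ""
    dis_gene: str = ""
    ontology: str = ""
    associations: str = ""
    # model parameters
    alpha: float = 0.9  # restart probability of the per-network diffusion
    beta: float = 0.6  # restart probability of the heterogeneous walk
    gamma: float = 0.9  # jump probability between layers
    eta: float = 0.2  # lncRNA-layer weight in the restart vector
    epsilon: float = 1e-10  # L1 convergence tolerance, both walks
    max_iter: int = 1000
    p_threshold: float = 0.01  # Pearson significance gate
    w_is_a: float = 0.8  # Wang is_a contribution factor
    # mode flags
    hnet_s_filter: bool = False  # keep only nodes with >=1 association
    fusion_mode: str = "ppmi"  # "ppmi" or "raw" (ablation)
    top_k: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "eta"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise DataError(f"{name} must be in (0, 1], got {v}")
        if self.fusion_mode not in ("ppmi", "raw"):
            raise DataError(f"fusion_mode must be 'ppmi' or 'raw', got {self.fusion_mode!r}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    # --- content addressing -------------------------------------------------

    def _digest(self, fields: list[str], with_inputs: bool = True) -> str:
        payload: dict = {f: getattr(self, f) for f in fields}
        if with_inputs:
            for f in ("expression", "lnc_mirna", "lnc_protein", "dis_mirna", "dis_gene",
                      "ontology", "associations"):
                p = Path(getattr(self, f)) if getattr(self, f) else None
                payload[f"file:{f}"] = (
                    hashlib.sha256(p.read_bytes()).hexdigest() if p and p.exists() else None
                )
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]

    def stage_hashes(self) -> dict[str, str]:
        """Per-stage content hashes; later stages include earlier stages' knobs."""
        sim = ["p_threshold", "w_is_a"]
        topo = sim + ["alpha", "epsilon", "max_iter", "fusion_mode"]
        hetero = topo + ["gamma", "hnet_s_filter"]
        pred = hetero + ["beta", "eta", "top_k"]
        return {
            "similarity": self._digest(sim),
            "topology": self._digest(topo),
            "heteronet": self._digest(hetero),
            "predict": self._digest(pred),
        }


def load_inputs(cfg: RunConfig) -> dict:
    """Parse every configured input file into its in-memory type."""
    return {
        "expression": read_expression(cfg.expression),
        "lnc_mirna": read_edge_list(cfg.lnc_mirna, "lncRNA", "miRNA"),
        "lnc_protein": read_edge_list(cfg.lnc_protein, "lncRNA", "protein"),
        "dis_mirna": read_edge_list(cfg.dis_mirna, "disease", "miRNA"),
        "dis_gene": read_edge_list(cfg.dis_gene, "disease", "gene"),
        "ontology": read_obo(cfg.ontology),
        "associations": read_associations(cfg.associations),
    }


def ontology_leaf_terms(dag) -> NodeIndex:
    """Terms with no children: the concrete diseases of a scaffolded hierarchy."""
    with_children = {p for _, p in dag.is_a_edges}
    leaves = [t for t in dag.terms.ids if t not in with_children]
    return NodeIndex.from_ids(leaves, "disease")


def build_similarity_networks(cfg: RunConfig, inputs: dict) -> tuple[list, list]:
    """The three lncRNA and three disease evidence networks."""
    lnc_nets = [
        pearson_similarity_network(inputs["expression"], p_threshold=cfg.p_threshold),
        gip_kernel_matrix(inputs["lnc_mirna"], side="left"),
        gip_kernel_matrix(inputs["lnc_protein"], side="left"),
    ]
    dis_nets = [
        ontology_similarity_matrix(inputs["ontology"], ontology_leaf_terms(inputs["ontology"]),
                                   w_is_a=cfg.w_is_a),
        gip_kernel_matrix(inputs["dis_mirna"], side="left"),
        gip_kernel_matrix(inputs["dis_gene"], side="left"),
    ]
    return lnc_nets, dis_nets


def union_universe(indexes: list[NodeIndex], kind: str) -> NodeIndex:
    """Union of node ids across sources, in order of first appearance."""
    seen: set[str] = set()
    ids: list[str] = []
    for idx in indexes:
        for i in idx.ids:
            if i not in seen:
                seen.add(i)
                ids.append(i)
    return NodeIndex.from_ids(ids, kind)


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Execute the four stages in order and write all artifacts.

    Stages already on disk with a matching content hash are reused, so a
    rerun with the same inputs and config is idempotent and a change to one
    knob recomputes only the stages downstream of it.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hashes = cfg.stage_hashes()
    stamp_path = outdir / "stage_hashes.json"
    old = json.loads(stamp_path.read_text()) if stamp_path.exists() else {}

    inputs = load_inputs(cfg)
    lnc_nets, dis_nets = build_similarity_networks(cfg, inputs)
    lnc_universe = union_universe([n.node_index for n in lnc_nets], "lncRNA")
    dis_universe = union_universe([n.node_index for n in dis_nets], "disease")

    ts_l_path, ts_d_path = outdir / "lnc_ts.tsv", outdir / "dis_ts.tsv"
    from .data_io import read_matrix
    from .topology import TopoSimilarity

    if old.get("topology") == hashes["topology"] and ts_l_path.exists() and ts_d_path.exists():
        logger.info("topology stage unchanged (%s); reusing fused matrices", hashes["topology"])
        Xl, ril, _ = read_matrix(ts_l_path)
        Xd, rid_, _ = read_matrix(ts_d_path)
        lncTS, disTS = TopoSimilarity(ril, Xl), TopoSimilarity(rid_, Xd)
    else:
        rcfg = RwrConfig(alpha=cfg.alpha, epsilon=cfg.epsilon, max_iter=cfg.max_iter)
        lncTS = topo_fuse(lnc_nets, lnc_universe, mode=cfg.fusion_mode, config=rcfg)
        disTS = topo_fuse(dis_nets, dis_universe, mode=cfg.fusion_mode, config=rcfg)
        write_matrix(ts_l_path, lncTS.X, lncTS.node_index)
        write_matrix(ts_d_path, disTS.X, disTS.node_index)

    assoc = read_associations(cfg.associations, lncTS.node_index, disTS.node_index)
    if cfg.hnet_s_filter:
        lncTS, disTS, assoc = hnet_s_filter(lncTS, disTS, assoc)
    h = assemble_adjacency(lncTS, disTS, assoc)
    build_transition_matrix(h, gamma=cfg.gamma)
    write_matrix(outdir / "a_ld.tsv", h.A_LD, h.lnc_index, h.dis_index)

    pred_rows = []
    for d in sorted({d for _, d in assoc.pairs}):
        pred = predict_for_disease(
            h, d, assoc.partners_of_disease(d), eta=cfg.eta, beta=cfg.beta,
            epsilon=cfg.epsilon, max_iter=cfg.max_iter,
        )
        for rank, (l, score) in enumerate(pred.top(cfg.top_k), start=1):
            pred_rows.append((d, rank, l, score))
    with (outdir / "predictions.tsv").open("w") as fh:
        fh.write("disease\trank\tlncRNA\tscore\n")
        for d, rank, l, score in pred_rows:
            fh.write(f"{d}\t{rank}\t{l}\t{float(score)!r}\n")

    report = {
        "hetrank_version": __version__,
        "numpy_version": np.__version__,
        "config": asdict(cfg),
        "stage_hashes": hashes,
        "n_lncRNA": len(h.lnc_index),
        "n_disease": len(h.dis_index),
        "n_associations": int(h.A_LD.sum()),
        "n_predictions": len(pred_rows),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    stamp_path.write_text(json.dumps(hashes, indent=2, sort_keys=True) + "\n")
    return report
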