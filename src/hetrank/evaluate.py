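"""Leave-one-out cross-validation, ranking metrics and parameter sweeps.

LOOCV holds out each known lncRNA-disease association in turn: the bipartite
edge is removed (similarity layers are association-independent and stay
fixed), the transition matrix is rebuilt, the walk is re-run seeded with the
disease's remaining partners, and the held-out lncRNA's rank among
candidates is recorded.  Scores are pooled across folds into single ROC and
precision-recall curves; per-fold negatives are candidates not associated
with the disease anywhere in the full dataset, so positives of other folds
never pollute the labels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .data_io import AssociationTable, DataError, NodeIndex
from .heteronet import HeteroNetwork, assemble_adjacency, build_transition_matrix
from .predict import predict_for_disease
from .similarity import SimilarityNetwork
from .topology import RwrConfig, TopoSimilarity, topo_fuse


@dataclass
class FoldRecord:
    disease: str
    held_out: str
    rank: int
    n_candidates: int


@dataclass
class EvalReport:
    folds: list[FoldRecord]
    scores: np.ndarray  # pooled candidate scores across folds
    labels: np.ndarray  # 1 = held-out association, 0 = non-association
    config: dict = field(default_factory=dict)

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(f.disease, f.held_out, f.rank, f.n_candidates) for f in self.folds],
            columns=["disease", "held_out_lncRNA", "rank", "n_candidates"],
        )


def pooled_auc(report: EvalReport) -> float:
    """Trapezoidal area under the pooled ROC curve."""
    if len(np.unique(report.labels)) < 2:
        raise DataError("AUC undefined: pooled labels are all identical")
    return float(roc_auc_score(report.labels, report.scores))


def pooled_aupr(report: EvalReport) -> float:
    """Step-interpolated area under the pooled precision-recall curve."""
    if len(np.unique(report.labels)) < 2:
        raise DataError("AUPR undefined: pooled labels are all identical")
    return float(average_precision_score(report.labels, report.scores))


def recall_at(report: EvalReport, cutoffs: tuple[int, ...] = (10, 20, 50, 100)) -> dict[int, float]:
    """Fraction of folds whose held-out lncRNA ranks within each cutoff."""
    ranks = np.array([f.rank for f in report.folds])
    return {k: float((ranks <= k).mean()) for k in sorted(cutoffs)}


def _run_fold(
    h: HeteroNetwork,
    disease: str,
    seeds: set[str],
    positives: set[str],
    gamma: float,
    eta: float,
    beta: float,
    epsilon: float,
    max_iter: int,
) -> tuple[list[FoldRecord], np.ndarray, np.ndarray]:
    build_transition_matrix(h, gamma=gamma)
    pred = predict_for_disease(h, disease, seeds, eta=eta, beta=beta, epsilon=epsilon, max_iter=max_iter)
    scores = np.array([pred.scores[l] for l in pred.ranking])
    labels = np.array([1.0 if l in positives else 0.0 for l in pred.ranking])
    records = [FoldRecord(disease, l, pred.rank_of(l), len(pred.ranking)) for l in sorted(positives)]
    return records, scores, labels


def loocv(
    lncTS: TopoSimilarity,
    disTS: TopoSimilarity,
    assoc: AssociationTable,
    gamma: float = 0.9,
    eta: float = 0.2,
    beta: float = 0.6,
    epsilon: float = 1e-10,
    max_iter: int = 1000,
) -> EvalReport:
    """One fold per known association; the bipartite edge is removed and restored.

    A disease whose only association is held out runs in new-disease mode
    (empty seed set, all restart mass on the disease).
    """
    if not assoc.pairs:
        raise DataError("LOOCV needs at least one association")
    h = assemble_adjacency(lncTS, disTS, assoc)
    A_LD_before = h.A_LD.copy()
    folds: list[FoldRecord] = []
    scores_parts: list[np.ndarray] = []
    labels_parts: list[np.ndarray] = []
    for l, d in sorted(assoc.pairs):
        li = h.lnc_index.position(l)
        di = h.dis_index.position(d)
        h.A_LD[li, di] = 0.0
        seeds = assoc.partners_of_disease(d) - {l}
        records, s, y = _run_fold(h, d, seeds, {l}, gamma, eta, beta, epsilon, max_iter)
        folds.extend(records)
        scores_parts.append(s)
        labels_parts.append(y)
        h.A_LD[li, di] = 1.0
    assert np.array_equal(h.A_LD, A_LD_before), "A_LD not restored after LOOCV"
    return EvalReport(
        folds,
        np.concatenate(scores_parts),
        np.concatenate(labels_parts),
        config={"gamma": gamma, "eta": eta, "beta": beta, "epsilon": epsilon, "protocol": "loocv"},
    )


def null_calibration(
    lncTS: TopoSimilarity,
    disTS: TopoSimilarity,
    assoc: AssociationTable,
    seed: int,
    n_replicates: int = 5,
    **loocv_params,
) -> EvalReport:
    """Permutation-null LOOCV: pool folds over several degree-preserving rewirings.

    A single rewiring gives a noisy estimate of the null AUC; pooling
    independent replicates estimates the same quantity with less variance.
    Note the null sits slightly below 0.5 by construction: the held-out
    positive has one fewer association than equal-degree negatives during
    its fold, and scores increase with bipartite degree.
    """
    from .synthetic import shuffle_null

    parts = []
    for r in range(n_replicates):
        null = shuffle_null(assoc, seed=seed + r)
        parts.append(loocv(lncTS, disTS, null, **loocv_params))
    return EvalReport(
        [f for p in parts for f in p.folds],
        np.concatenate([p.scores for p in parts]),
        np.concatenate([p.labels for p in parts]),
        config={"protocol": "null_calibration", "n_replicates": n_replicates, "seed": seed},
    )


def new_disease_eval(
    lncTS: TopoSimilarity,
    disTS: TopoSimilarity,
    assoc: AssociationTable,
    gamma: float = 0.9,
    eta: float = 0.2,
    beta: float = 0.6,
    epsilon: float = 1e-10,
    max_iter: int = 1000,
) -> EvalReport:
    """Per disease: remove ALL its associations, seed only the disease itself.

    Every removed lncRNA is a labelled positive of that query; every lncRNA
    is a candidate (there are no seeds to exclude).
    """
    diseases = sorted({d for _, d in assoc.pairs})
    if not diseases:
        raise DataError("new-disease evaluation needs at least one association")
    h = assemble_adjacency(lncTS, disTS, assoc)
    A_LD_before = h.A_LD.copy()
    folds: list[FoldRecord] = []
    scores_parts: list[np.ndarray] = []
    labels_parts: list[np.ndarray] = []
    for d in diseases:
        di = h.dis_index.position(d)
        saved = h.A_LD[:, di].copy()
        h.A_LD[:, di] = 0.0
        positives = assoc.partners_of_disease(d)
        records, s, y = _run_fold(h, d, set(), positives, gamma, eta, beta, epsilon, max_iter)
        folds.extend(records)
        scores_parts.append(s)
        labels_parts.append(y)
        h.A_LD[:, di] = saved
    assert np.array_equal(h.A_LD, A_LD_before), "A_LD not restored after new-disease eval"
    return EvalReport(
        folds,
        np.concatenate(scores_parts),
        np.concatenate(labels_parts),
        config={"gamma": gamma, "eta": eta, "beta": beta, "epsilon": epsilon, "protocol": "new_disease"},
    )


def parameter_sweep(
    lnc_nets: list[SimilarityNetwork],
    dis_nets: list[SimilarityNetwork],
    assoc: AssociationTable,
    lnc_universe: NodeIndex,
    dis_universe: NodeIndex,
    grid: dict[str, list[float]],
    fusion_mode: str = "ppmi",
    epsilon: float = 1e-10,
    max_iter: int = 1000,
) -> pd.DataFrame:
    """LOOCV AUC/AUPR over the Cartesian product of a parameter grid.

    ``grid`` maps any of {"alpha", "beta", "gamma", "eta"} to value lists;
    omitted parameters stay at their defaults (0.9, 0.6, 0.9, 0.2).  The
    topology stage is cached per alpha since beta/gamma/eta do not touch it.
    """
    defaults = {"alpha": 0.9, "beta": 0.6, "gamma": 0.9, "eta": 0.2}
    unknown = set(grid) - set(defaults)
    if unknown:
        raise DataError(f"unknown sweep parameters: {sorted(unknown)}")
    axes = {p: list(grid.get(p, [defaults[p]])) for p in defaults}
    ts_cache: dict[float, tuple[TopoSimilarity, TopoSimilarity]] = {}
    rows = []
    for alpha, beta, gamma, eta in itertools.product(
        axes["alpha"], axes["beta"], axes["gamma"], axes["eta"]
    ):
        if alpha not in ts_cache:
            cfg = RwrConfig(alpha=alpha, epsilon=epsilon, max_iter=max_iter)
            ts_cache[alpha] = (
                topo_fuse(lnc_nets, lnc_universe, mode=fusion_mode, config=cfg),
                topo_fuse(dis_nets, dis_universe, mode=fusion_mode, config=cfg),
            )
        lncTS, disTS = ts_cache[alpha]
        report = loocv(lncTS, disTS, assoc, gamma=gamma, eta=eta, beta=beta,
                       epsilon=epsilon, max_iter=max_iter)
        rows.append({
            "alpha": alpha, "beta": beta, "gamma": gamma, "eta": eta,
            "auc": pooled_auc(report), "aupr": pooled_aupr(report),
        })
    return pd.DataFrame(rows)
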