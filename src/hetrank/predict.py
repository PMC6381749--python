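"""RWRH propagation from a per-disease seed and candidate ranking.

The restart vector places weight eta on the lncRNA layer (uniform over the
query disease's known lncRNA partners) and 1-eta on the disease layer (unit
mass on the query disease).  A disease with no seed lncRNAs runs in
new-disease mode: the whole unit mass goes to the disease entry, which
rescales scores uniformly and changes no ranking but keeps p0 a probability
vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import DataError
from .heteronet import HeteroNetwork


@dataclass
class SeedConfig:
    query_disease: str
    seed_lncRNAs: frozenset[str] = frozenset()
    eta: float = 0.2
    beta: float = 0.6

    def __post_init__(self) -> None:
        if not 0 < self.eta < 1:
            raise DataError(f"eta must be in (0, 1), got {self.eta}")
        if not 0 < self.beta <= 1:
            raise DataError(f"beta must be in (0, 1], got {self.beta}")


@dataclass
class RankedPrediction:
    query_disease: str
    scores: dict[str, float]  # candidate lncRNA -> stationary probability
    ranking: list[str]  # candidates, best first; ties broken by index order
    seeds: frozenset[str]

    def rank_of(self, lnc_id: str) -> int:
        """1-based rank of a candidate lncRNA."""
        return self.ranking.index(lnc_id) + 1

    def top(self, k: int) -> list[tuple[str, float]]:
        return [(l, self.scores[l]) for l in self.ranking[:k]]


def build_initial_vector(seeds: SeedConfig, h: HeteroNetwork) -> np.ndarray:
    """p0 = [eta * u0 ; (1-eta) * v0], summing to 1 in every mode."""
    h.dis_index.position(seeds.query_disease)  # raises on unknown disease
    n_l, n_d = h.n_lnc, h.n_dis
    u0 = np.zeros(n_l)
    seed_pos = [h.lnc_index.position(l) for l in seeds.seed_lncRNAs]
    if seed_pos:
        u0[seed_pos] = 1.0 / len(seed_pos)
    v0 = np.zeros(n_d)
    v0[h.dis_index.position(seeds.query_disease)] = 1.0
    if seed_pos:
        p0 = np.concatenate([seeds.eta * u0, (1.0 - seeds.eta) * v0])
    else:
        # new-disease mode: all mass on the query disease
        p0 = np.concatenate([u0, v0])
    return p0


def rwrh_propagate(
    p0: np.ndarray,
    M: np.ndarray,
    beta: float = 0.6,
    epsilon: float = 1e-10,
    max_iter: int = 1000,
) -> np.ndarray:
    """Iterate p <- (1-beta) p M + beta p0 until the L1 change < epsilon."""
    p0 = np.asarray(p0, dtype=float)
    if not np.isclose(p0.sum(), 1.0, atol=1e-9):
        raise DataError(f"p0 must sum to 1, got {p0.sum()}")
    if beta == 1.0:
        return p0.copy()
    p = p0.copy()
    trace: list[float] = []
    for _ in range(max_iter):
        p_next = (1.0 - beta) * (p @ M) + beta * p0
        residual = np.abs(p_next - p).sum()
        p = p_next
        if residual < epsilon:
            return p
        trace.append(residual)
    raise DataError(f"RWRH did not converge in {max_iter} iterations; last residuals {trace[-3:]}")


def rank_candidates(p_star: np.ndarray, seeds: SeedConfig, h: HeteroNetwork) -> RankedPrediction:
    """Rank non-seed lncRNAs by their stationary probability, descending.

    Ties are broken by node-index order, making the ranking deterministic.
    """
    lnc_scores = p_star[: h.n_lnc]
    candidates = [(i, l) for i, l in enumerate(h.lnc_index.ids) if l not in seeds.seed_lncRNAs]
    # stable sort on index order then score keeps index-order tie-breaking
    ordered = sorted(candidates, key=lambda t: (-lnc_scores[t[0]], t[0]))
    ranking = [l for _, l in ordered]
    scores = {l: float(lnc_scores[i]) for i, l in candidates}
    return RankedPrediction(seeds.query_disease, scores, ranking, frozenset(seeds.seed_lncRNAs))


def predict_for_disease(
    h: HeteroNetwork,
    disease_id: str,
    seed_lncRNAs: frozenset[str] | set[str],
    eta: float = 0.2,
    beta: float = 0.6,
    epsilon: float = 1e-10,
    max_iter: int = 1000,
) -> RankedPrediction:
    """Seed, propagate and rank in one call; transition blocks must be built."""
    seeds = SeedConfig(disease_id, frozenset(seed_lncRNAs), eta=eta, beta=beta)
    p0 = build_initial_vector(seeds, h)
    p_star = rwrh_propagate(p0, h.full_M(), beta=beta, epsilon=epsilon, max_iter=max_iter)
    return rank_candidates(p_star, seeds, h)
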