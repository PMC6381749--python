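"""Topological similarity: RWR diffusion states, PPMI, and fusion.

Each similarity network is converted to a row-stochastic transition matrix,
diffused with random walk with restart (restart probability ``alpha``) to
obtain every node's diffusion state, scored pairwise with positive pointwise
mutual information, symmetrised, and finally averaged across evidence
sources on a shared node universe.  The raw-averaging variant
(:func:`fuse_raw_average`) bypasses diffusion+PPMI and averages the raw
similarity matrices instead; it exists for ablation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .data_io import DataError, NodeIndex
from .similarity import SimilarityNetwork


@dataclass
class RwrConfig:
    """Random-walk-with-restart settings.

    alpha: restart probability in (0, 1]; the walker teleports back to its
    start node with probability alpha at each step.
    epsilon: L1 convergence tolerance on the whole state matrix.
    max_iter: iteration cap; exceeding it is an error, not a silent return.
    """

    alpha: float = 0.9
    epsilon: float = 1e-10
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise DataError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.epsilon <= 0:
            raise DataError("epsilon must be > 0")


@dataclass
class DiffusionState:
    node_index: NodeIndex
    S: np.ndarray  # row-stochastic: row i is node i's stationary visiting distribution
    alpha: float
    n_iter: int = 0

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        if not np.allclose(S.sum(axis=1), 1.0, atol=1e-9):
            raise DataError("diffusion state rows must sum to 1")
        self.S = S


@dataclass
class TopoSimilarity:
    node_index: NodeIndex
    X: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        n = len(self.node_index)
        if X.shape != (n, n):
            raise DataError(f"topological similarity shape {X.shape} vs index size {n}")
        if not np.all(np.isfinite(X)) or np.any(X < 0):
            raise DataError("topological similarity must be finite and nonnegative")
        if not np.allclose(X, X.T, atol=1e-12):
            raise DataError("topological similarity must be symmetric")
        self.X = X


def row_normalize(net: SimilarityNetwork | np.ndarray) -> np.ndarray:
    """W(i,j) = B(i,j) / sum_j B(i,j); all-zero rows become identity self-loops."""
    B = np.asarray(net.weights if isinstance(net, SimilarityNetwork) else net, dtype=float)
    if np.any(B < 0):
        raise DataError("row_normalize requires nonnegative weights")
    sums = B.sum(axis=1)
    W = np.zeros_like(B)
    nz = sums > 0
    W[nz] = B[nz] / sums[nz, None]
    for i in np.nonzero(~nz)[0]:
        W[i, i] = 1.0
    return W


def rwr_diffusion(
    W: np.ndarray, config: RwrConfig | None = None, node_index: NodeIndex | None = None
) -> DiffusionState:
    """Iterate S <- (1-alpha) S W + alpha S0 from S0 = I until the L1 change < epsilon.

    The stationary S is the matrix of diffusion states; row i is the
    visiting distribution of a walker restarting at node i.
    """
    cfg = config or RwrConfig()
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if W.shape != (n, n):
        raise DataError("transition matrix must be square")
    if not np.allclose(W.sum(axis=1), 1.0, atol=1e-8):
        raise DataError("transition matrix rows must sum to 1")
    S0 = np.eye(n)
    S = S0.copy()
    one_minus = 1.0 - cfg.alpha
    # above ~2k nodes the transition matrix is typically sparse enough that
    # CSR matvecs win; results are identical to the dense path
    W_op = W if n <= 2000 else sparse.csr_array(W)
    for it in range(1, cfg.max_iter + 1):
        S_next = one_minus * (S @ W_op) + cfg.alpha * S0
        residual = np.abs(S_next - S).sum()
        S = S_next
        if residual < cfg.epsilon:
            idx = node_index or NodeIndex.from_ids((f"n{i}" for i in range(n)), "lncRNA")
            return DiffusionState(idx, S, cfg.alpha, n_iter=it)
    raise DataError(f"RWR did not converge in {cfg.max_iter} iterations (last L1 residual {residual:.3e})")


def ppmi_matrix(S: np.ndarray) -> np.ndarray:
    """Positive pointwise mutual information of a nonnegative state matrix.

    MI(i,j) = max(0, log2( S(i,j) * total / (rowsum_i * colsum_j) )).
    Cells with S(i,j) = 0 map to 0 via the clamp; an all-zero column makes
    its MI column 0 (warning) rather than dividing by zero.
    """
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise DataError("PPMI requires nonnegative input")
    total = S.sum()
    if total == 0:
        raise DataError("PPMI input is all zero")
    row = S.sum(axis=1)
    col = S.sum(axis=0)
    if np.any(col == 0):
        from .data_io import logger

        logger.warning("%d all-zero columns in PPMI input; their MI set to 0", int((col == 0).sum()))
    denom = row[:, None] * col[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = S * total / denom
        mi = np.log2(ratio)
    mi = np.where((S > 0) & (denom > 0), mi, -np.inf)
    return np.maximum(mi, 0.0)


def symmetrize(MI: np.ndarray, node_index: NodeIndex | None = None) -> np.ndarray | TopoSimilarity:
    """X(i,j) = (MI(i,j) + MI(j,i)) / 2; wrapped as TopoSimilarity when an index is given."""
    MI = np.asarray(MI, dtype=float)
    if MI.ndim != 2 or MI.shape[0] != MI.shape[1]:
        raise DataError("symmetrize requires a square matrix")
    X = (MI + MI.T) / 2.0
    if node_index is not None:
        return TopoSimilarity(node_index, X)
    return X


def topo_similarity(net: SimilarityNetwork, config: RwrConfig | None = None) -> TopoSimilarity:
    """One evidence source end to end: row-normalise, diffuse, PPMI, symmetrise."""
    W = row_normalize(net)
    state = rwr_diffusion(W, config, node_index=net.node_index)
    return symmetrize(ppmi_matrix(state.S), node_index=net.node_index)


def _expand(X: np.ndarray, index: NodeIndex, universe: NodeIndex) -> np.ndarray:
    pos = np.array([universe.position(i) for i in index.ids])
    out = np.zeros((len(universe), len(universe)))
    out[np.ix_(pos, pos)] = X
    return out


def fuse_average(parts: list[TopoSimilarity], universe: NodeIndex) -> TopoSimilarity:
    """Entrywise average of topological similarity matrices on a shared universe.

    Each part is zero-filled onto the universe first; the denominator is the
    number of parts supplied, so a pair covered by only one source is
    diluted accordingly.
    """
    if not parts:
        raise DataError("fuse_average needs at least one part")
    acc = np.zeros((len(universe), len(universe)))
    for part in parts:
        acc += _expand(part.X, part.node_index, universe)
    return TopoSimilarity(universe, acc / len(parts))


def topo_fuse(
    nets: list[SimilarityNetwork],
    universe: NodeIndex,
    mode: str = "ppmi",
    config: RwrConfig | None = None,
) -> TopoSimilarity:
    """Fuse one node kind's evidence networks into its final similarity matrix.

    mode "ppmi" runs each network through diffusion + PPMI before averaging;
    mode "raw" averages the raw similarity matrices (the ablation path) and
    wraps the result so downstream assembly is unchanged.
    """
    if mode == "ppmi":
        return fuse_average([topo_similarity(net, config) for net in nets], universe)
    if mode == "raw":
        fused = fuse_raw_average(nets, universe)
        return TopoSimilarity(universe, fused.weights)
    raise DataError(f"unknown fusion mode {mode!r}; expected 'ppmi' or 'raw'")


def fuse_raw_average(nets: list[SimilarityNetwork], universe: NodeIndex) -> SimilarityNetwork:
    """Raw-similarity counterpart of :func:`fuse_average` (ablation path)."""
    if not nets:
        raise DataError("fuse_raw_average needs at least one network")
    acc = np.zeros((len(universe), len(universe)))
    for net in nets:
        acc += _expand(net.weights, net.node_index, universe)
    return SimilarityNetwork(universe, acc / len(nets), nets[0].source_tag)
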