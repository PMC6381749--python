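"""Heterogeneous lncRNA-disease network assembly and its block transition matrix.

The adjacency is the 2x2 block matrix

    A = [[A_L,  A_LD],
         [A_DL, A_D ]]

with A_L / A_D the fused topological similarity networks, A_LD the binary
known-association matrix and A_DL its transpose.  The transition matrix M
splits each node's outgoing mass between its own layer and the bipartite
edges: a node with at least one association sends gamma of its mass across
and 1-gamma within; a node with none walks purely within its layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import AssociationTable, DataError, NodeIndex, logger
from .topology import TopoSimilarity


@dataclass
class HeteroNetwork:
    lnc_index: NodeIndex
    dis_index: NodeIndex
    A_L: np.ndarray
    A_D: np.ndarray
    A_LD: np.ndarray  # binary, lncRNA x disease
    gamma: float | None = None
    M_L: np.ndarray | None = None
    M_D: np.ndarray | None = None
    M_LD: np.ndarray | None = None
    M_DL: np.ndarray | None = None

    @property
    def A_DL(self) -> np.ndarray:
        return self.A_LD.T

    @property
    def n_lnc(self) -> int:
        return len(self.lnc_index)

    @property
    def n_dis(self) -> int:
        return len(self.dis_index)

    def full_M(self) -> np.ndarray:
        """Concatenated (n_lnc + n_dis) square transition matrix."""
        if self.M_L is None:
            raise DataError("transition blocks not built; call build_transition_matrix")
        return np.block([[self.M_L, self.M_LD], [self.M_DL, self.M_D]])


def assemble_adjacency(
    lncTS: TopoSimilarity, disTS: TopoSimilarity, assoc: AssociationTable
) -> HeteroNetwork:
    """Fill the A blocks; association pairs outside the indexes are dropped and logged."""
    n_l, n_d = len(lncTS.node_index), len(disTS.node_index)
    A_LD = np.zeros((n_l, n_d))
    dropped = 0
    for l, d in assoc.pairs:
        if l in lncTS.node_index and d in disTS.node_index:
            A_LD[lncTS.node_index.position(l), disTS.node_index.position(d)] = 1.0
        else:
            dropped += 1
    if dropped:
        logger.info("dropped %d associations naming nodes outside the similarity universes", dropped)
    if not A_LD.any():
        logger.warning("empty association matrix: heterogeneous network has no bipartite edges")
    return HeteroNetwork(lncTS.node_index, disTS.node_index, lncTS.X.copy(), disTS.X.copy(), A_LD)


def _layer_blocks(
    A_intra: np.ndarray, A_cross: np.ndarray, gamma: float
) -> tuple[np.ndarray, np.ndarray]:
    """Transition rows for one layer.

    Per node: no cross edges -> intra row normalised to 1, cross row 0;
    cross edges and intra weight -> (1-gamma) intra + gamma cross, each
    renormalised; cross edges but an all-zero intra row -> all mass on the
    cross row (stochasticity repair); no weight anywhere -> identity
    self-loop with a warning.
    """
    M_intra = np.zeros_like(A_intra)
    M_cross = np.zeros_like(A_cross)
    intra_sum = A_intra.sum(axis=1)
    cross_sum = A_cross.sum(axis=1)
    has_intra = intra_sum > 0
    has_cross = cross_sum > 0

    intra_only = has_intra & ~has_cross
    M_intra[intra_only] = A_intra[intra_only] / intra_sum[intra_only, None]
    both = has_intra & has_cross
    M_intra[both] = (1.0 - gamma) * A_intra[both] / intra_sum[both, None]
    M_cross[both] = gamma * A_cross[both] / cross_sum[both, None]
    # stochasticity repair: associated node isolated in its own layer walks
    # across with full unit mass
    cross_only = ~has_intra & has_cross
    M_cross[cross_only] = A_cross[cross_only] / cross_sum[cross_only, None]

    isolated = np.nonzero(~has_intra & ~has_cross)[0]
    M_intra[isolated, isolated] = 1.0
    if isolated.size:
        logger.warning("%d nodes with zero weight in every block got identity self-loops", isolated.size)
    return M_intra, M_cross


def build_transition_matrix(h: HeteroNetwork, gamma: float = 0.9) -> HeteroNetwork:
    """Fill the M blocks; every non-isolated row of the full M sums to 1."""
    if not 0 < gamma < 1:
        raise DataError(f"gamma must be in (0, 1), got {gamma}")
    h.M_L, h.M_LD = _layer_blocks(h.A_L, h.A_LD, gamma)
    h.M_D, h.M_DL = _layer_blocks(h.A_D, h.A_DL, gamma)
    h.gamma = gamma
    return h


def hnet_s_filter(
    lncTS: TopoSimilarity, disTS: TopoSimilarity, assoc: AssociationTable
) -> tuple[TopoSimilarity, TopoSimilarity, AssociationTable]:
    """Restrict both universes to nodes with >=1 known association (small-scale network).

    The full-universe alternative keeps every node observed in any source;
    this filter reproduces the association-restricted construction for
    comparison harnesses.
    """
    lnc_keep = sorted({l for l, _ in assoc.pairs}, key=lncTS.node_index.position)
    dis_keep = sorted({d for _, d in assoc.pairs}, key=disTS.node_index.position)
    if not lnc_keep or not dis_keep:
        raise DataError("association table has no usable pairs to filter on")
    li = NodeIndex.from_ids(lnc_keep, lncTS.node_index.kind)
    di = NodeIndex.from_ids(dis_keep, disTS.node_index.kind)
    lp = np.array([lncTS.node_index.position(i) for i in lnc_keep])
    dp = np.array([disTS.node_index.position(i) for i in dis_keep])
    sub_l = TopoSimilarity(li, lncTS.X[np.ix_(lp, lp)])
    sub_d = TopoSimilarity(di, disTS.X[np.ix_(dp, dp)])
    sub_assoc = AssociationTable(li, di, assoc.pairs)
    return sub_l, sub_d, sub_assoc
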