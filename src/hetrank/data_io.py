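"""Readers, writers and the node-index contract.

Every matrix in the pipeline is carried together with a :class:`NodeIndex`
per axis; matrix position i always refers to ``index.ids[i]``.  Binary
operations on mismatched indexes raise — nothing is silently reindexed.

Identifiers are opaque strings: no mapping between ID namespaces is
attempted, inputs are expected to be pre-harmonised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import obonet

logger = logging.getLogger("hetrank")

NODE_KINDS = ("lncRNA", "disease", "miRNA", "protein", "gene")

#: Dense TSV serialisation is used up to this many nodes per axis; above it
#: matrices are written in coordinate (row_id, col_id, value) form.
DENSE_LIMIT = 5000


class DataError(ValueError):
    """Malformed input file or violated index contract."""


@dataclass(frozen=True)
class NodeIndex:
    """Ordered, unique node identifiers of one kind.

    The position of an id in ``ids`` is the row/column of that node in any
    matrix carrying this index.
    """

    ids: tuple[str, ...]
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in NODE_KINDS:
            raise DataError(f"unknown node kind {self.kind!r}; expected one of {NODE_KINDS}")
        if len(set(self.ids)) != len(self.ids):
            raise DataError(f"duplicate ids in {self.kind} index")
        object.__setattr__(self, "_pos", {n: i for i, n in enumerate(self.ids)})

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._pos

    def position(self, node_id: str) -> int:
        try:
            return self._pos[node_id]
        except KeyError:
            raise DataError(f"{self.kind} id {node_id!r} not in index") from None

    @classmethod
    def from_ids(cls, ids: Iterable[str], kind: str) -> "NodeIndex":
        return cls(tuple(ids), kind)


def check_same_index(a: NodeIndex, b: NodeIndex, what: str = "operation") -> None:
    """Guard for binary operations: indexes must be identical, not just equal sets."""
    if a.ids != b.ids or a.kind != b.kind:
        raise DataError(f"{what}: node indexes differ ({a.kind}[{len(a)}] vs {b.kind}[{len(b)}])")


@dataclass
class ExpressionMatrix:
    node_index: NodeIndex
    samples: tuple[str, ...]
    values: np.ndarray  # (nodes, samples), float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.node_index), len(self.samples)):
            raise DataError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.node_index)} nodes x {len(self.samples)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataError("expression matrix contains non-finite values")


@dataclass
class BipartiteInteractions:
    """Edge set between two node kinds; profiles are binary incidence vectors."""

    left_index: NodeIndex
    right_index: NodeIndex
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for l, r in self.edges:
            if l not in self.left_index:
                raise DataError(f"edge endpoint {l!r} missing from left index")
            if r not in self.right_index:
                raise DataError(f"edge endpoint {r!r} missing from right index")

    def incidence(self) -> np.ndarray:
        """Binary matrix (left x right); row i is IP(left i)."""
        m = np.zeros((len(self.left_index), len(self.right_index)))
        for l, r in self.edges:
            m[self.left_index.position(l), self.right_index.position(r)] = 1.0
        return m


@dataclass
class OntologyDAG:
    """is_a hierarchy of disease terms; child -> parent edges, acyclic."""

    terms: NodeIndex
    is_a_edges: frozenset[tuple[str, str]]  # (child, parent)

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms.ids)
        for c, p in self.is_a_edges:
            if c not in self.terms or p not in self.terms:
                raise DataError(f"is_a edge ({c!r}, {p!r}) references unknown term")
            g.add_edge(c, p)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise DataError(f"ontology contains a cycle: {cycle}")
        self._graph = g

    def parents(self, term: str) -> list[str]:
        if term not in self.terms:
            raise DataError(f"term {term!r} not in ontology")
        return sorted(self._graph.successors(term))

    def ancestors_and_self(self, term: str) -> set[str]:
        if term not in self.terms:
            raise DataError(f"term {term!r} not in ontology")
        return nx.descendants(self._graph, term) | {term}


@dataclass
class AssociationTable:
    lncRNA_index: NodeIndex
    disease_index: NodeIndex
    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for l, d in self.pairs:
            if l not in self.lncRNA_index or d not in self.disease_index:
                raise DataError(f"association ({l!r}, {d!r}) references unknown id")

    def matrix(self) -> np.ndarray:
        """Binary lncRNA x disease adjacency A_LD."""
        m = np.zeros((len(self.lncRNA_index), len(self.disease_index)))
        for l, d in self.pairs:
            m[self.lncRNA_index.position(l), self.disease_index.position(d)] = 1.0
        return m

    def partners_of_disease(self, disease_id: str) -> set[str]:
        self.disease_index.position(disease_id)
        return {l for l, d in self.pairs if d == disease_id}

    def degree_lncRNA(self, lnc_id: str) -> int:
        return sum(1 for l, _ in self.pairs if l == lnc_id)

    def degree_disease(self, dis_id: str) -> int:
        return sum(1 for _, d in self.pairs if d == dis_id)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a nodes x samples TSV (header = sample labels, col 0 = node ids).

    Duplicate node ids keep the first occurrence (logged); any non-numeric
    cell (including NA) is a parse error naming the offending row and column.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise DataError(f"{path}: empty expression file")
    header = lines[0].rstrip("\n").split("\t")
    samples = tuple(header[1:])
    if not samples:
        raise DataError(f"{path}: header has no sample columns")
    ids: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(samples) + 1:
            raise DataError(f"{path}:{lineno}: expected {len(samples) + 1} fields, got {len(fields)}")
        node_id = fields[0]
        if node_id in seen:
            logger.warning("%s:%d: duplicate node id %r, first occurrence kept", path, lineno, node_id)
            continue
        values = []
        for col, cell in enumerate(fields[1:]):
            try:
                values.append(float(cell))
            except ValueError:
                raise DataError(
                    f"{path}:{lineno}: non-numeric value {cell!r} in column {samples[col]!r}"
                ) from None
        seen.add(node_id)
        ids.append(node_id)
        rows.append(values)
    if not ids:
        raise DataError(f"{path}: no data rows")
    return ExpressionMatrix(NodeIndex.from_ids(ids, "lncRNA"), samples, np.array(rows))


def read_edge_list(
    path: str | Path,
    left_kind: str,
    right_kind: str,
    *,
    detect_header: bool = True,
) -> BipartiteInteractions:
    """Read a 2-column TSV of (left_id, right_id) pairs.

    Indexes are induced from observed ids in order of first appearance and
    duplicate edges collapse to one.  A first line whose ids never recur is
    treated as a header when ``detect_header`` is set.
    """
    path = Path(path)
    raw: list[tuple[str, str]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise DataError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
        raw.append((fields[0], fields[1]))
    if detect_header and len(raw) > 1:
        first, rest = raw[0], raw[1:]
        rest_ids = {x for e in rest for x in e}
        if first[0] not in rest_ids and first[1] not in rest_ids:
            raw = rest
    left_ids: list[str] = []
    right_ids: list[str] = []
    seen_l: set[str] = set()
    seen_r: set[str] = set()
    edges: set[tuple[str, str]] = set()
    for l, r in raw:
        if l not in seen_l:
            seen_l.add(l)
            left_ids.append(l)
        if r not in seen_r:
            seen_r.add(r)
            right_ids.append(r)
        edges.add((l, r))
    return BipartiteInteractions(
        NodeIndex.from_ids(left_ids, left_kind),
        NodeIndex.from_ids(right_ids, right_kind),
        frozenset(edges),
    )


def read_obo(path: str | Path) -> OntologyDAG:
    """Parse an OBO ontology into an is_a DAG.

    Only [Term] stanzas are consumed; obsolete terms are dropped, and is_a
    edges into dropped or unknown terms are ignored.  Cycles are rejected.
    """
    graph = obonet.read_obo(Path(path))
    # obonet returns child -> parent edges keyed by relation; keep is_a only,
    # restricted to non-obsolete terms (obonet already drops obsolete ones).
    terms = sorted(graph.nodes)
    edges = {
        (c, p)
        for c, p, rel in graph.edges(keys=True)
        if rel == "is_a" and c in graph.nodes and p in graph.nodes
    }
    return OntologyDAG(NodeIndex.from_ids(terms, "disease"), frozenset(edges))


def read_associations(
    path: str | Path,
    lncRNA_index: NodeIndex | None = None,
    disease_index: NodeIndex | None = None,
) -> AssociationTable:
    """Read (lncRNA_id, disease_id) pairs; duplicates stored once.

    When indexes are supplied, rows naming unknown ids are dropped and the
    drop count logged; otherwise indexes are induced from the file.
    """
    path = Path(path)
    pairs: set[tuple[str, str]] = set()
    lnc_ids: list[str] = []
    dis_ids: list[str] = []
    seen_l: set[str] = set()
    seen_d: set[str] = set()
    dropped = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise DataError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
        l, d = fields
        if lncRNA_index is not None and l not in lncRNA_index:
            dropped += 1
            continue
        if disease_index is not None and d not in disease_index:
            dropped += 1
            continue
        if l not in seen_l:
            seen_l.add(l)
            lnc_ids.append(l)
        if d not in seen_d:
            seen_d.add(d)
            dis_ids.append(d)
        pairs.add((l, d))
    if dropped:
        logger.info("%s: dropped %d association rows with ids outside the supplied indexes", path, dropped)
    li = lncRNA_index if lncRNA_index is not None else NodeIndex.from_ids(lnc_ids, "lncRNA")
    di = disease_index if disease_index is not None else NodeIndex.from_ids(dis_ids, "disease")
    return AssociationTable(li, di, frozenset(pairs))


# ---------------------------------------------------------------------------
# matrix round-trip
# ---------------------------------------------------------------------------

def write_matrix(
    path: str | Path,
    matrix: np.ndarray,
    row_index: NodeIndex,
    col_index: NodeIndex | None = None,
) -> None:
    """Serialise a pipeline matrix with its node indexes.

    Dense TSV (ids as header/first column) up to :data:`DENSE_LIMIT` nodes
    per axis, coordinate-format sparse TSV above; values are written with
    ``repr`` round-trip precision either way.
    """
    path = Path(path)
    matrix = np.asarray(matrix, dtype=float)
    ci = col_index if col_index is not None else row_index
    if matrix.shape != (len(row_index), len(ci)):
        raise DataError(f"matrix shape {matrix.shape} does not match indexes ({len(row_index)}, {len(ci)})")
    with path.open("w") as fh:
        if max(matrix.shape, default=0) <= DENSE_LIMIT:
            fh.write(f"# hetrank dense matrix rows={row_index.kind} cols={ci.kind}\n")
            fh.write("\t".join(["id", *ci.ids]) + "\n")
            for i, rid in enumerate(row_index.ids):
                fh.write("\t".join([rid, *(repr(float(v)) for v in matrix[i])]) + "\n")
        else:
            fh.write(f"# hetrank sparse matrix rows={row_index.kind} cols={ci.kind}\n")
            fh.write("##rows\t" + "\t".join(row_index.ids) + "\n")
            fh.write("##cols\t" + "\t".join(ci.ids) + "\n")
            for i, j in zip(*np.nonzero(matrix)):
                fh.write(f"{row_index.ids[i]}\t{ci.ids[j]}\t{float(matrix[i, j])!r}\n")


def read_matrix(path: str | Path) -> tuple[np.ndarray, NodeIndex, NodeIndex]:
    """Inverse of :func:`write_matrix`; reproduces values and index order exactly."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("# hetrank"):
        raise DataError(f"{path}: not a hetrank matrix file")
    header = dict(tok.split("=") for tok in lines[0].split() if "=" in tok)
    row_kind, col_kind = header["rows"], header["cols"]
    if "dense" in lines[0]:
        col_ids = tuple(lines[1].split("\t")[1:])
        row_ids: list[str] = []
        rows: list[list[float]] = []
        for line in lines[2:]:
            fields = line.split("\t")
            row_ids.append(fields[0])
            rows.append([float(v) for v in fields[1:]])
        ri = NodeIndex.from_ids(row_ids, row_kind)
        ci = NodeIndex.from_ids(col_ids, col_kind)
        m = np.array(rows) if rows else np.zeros((0, len(ci)))
        if m.shape != (len(ri), len(ci)):
            raise DataError(f"{path}: shape/index mismatch")
        return m, ri, ci
    ri = NodeIndex.from_ids(lines[1].split("\t")[1:], row_kind)
    ci = NodeIndex.from_ids(lines[2].split("\t")[1:], col_kind)
    m = np.zeros((len(ri), len(ci)))
    for line in lines[3:]:
        r, c, v = line.split("\t")
        m[ri.position(r), ci.position(c)] = float(v)
    return m, ri, ci
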