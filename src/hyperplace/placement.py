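"""From learned embeddings to placements and tree-update distance matrices.

A trained model turns query sequences into a query x backbone distance
table (:class:`QueryDistanceTable`), de-normalised back to tree-distance
units.  Three consumers are provided:

* :func:`place_query` — a deliberately simple distance-based placement:
  for each candidate backbone edge it solves a two-parameter weighted
  least-squares problem (pendant length and attachment offset along the
  edge) against the distances to the nearest reference leaves, and keeps
  the edge with the smallest residual.  Production placement with external
  tools (APPLES-2) remains available through the PHYLIP matrix export.
* :func:`build_update_matrix` — the hybrid matrix for tree updating: tree
  distances between backbone pairs, embedding distances for every pair
  involving a query; FastME or similar consumes it to produce a fully
  resolved tree containing the queries.
* :func:`merge_gene_matrices` — entrywise median across per-gene matrices
  (the multi-gene route; the lower median is taken for even counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .alignio import Alignment
from .encoder import EmbeddingModel, encoder_forward
from .geometry import pairwise_unit_distances
from .trees import TreeDistances, edge_ids, leaf_distance_matrix, leaf_labels

__all__ = [
    "QueryDistanceTable",
    "UpdateMatrix",
    "PlacementResult",
    "query_distances",
    "nearest_references",
    "place_query",
    "place_all",
    "build_update_matrix",
    "merge_gene_matrices",
    "write_phylip_matrix",
    "read_phylip_matrix",
    "write_placements_tsv",
]


@dataclass
class QueryDistanceTable:
    """Query x backbone distances in tree-distance units (all finite)."""

    query_ids: list[str]
    backbone_ids: list[str]
    values: np.ndarray
    query_query: np.ndarray | None = None
    _qindex: dict[str, int] = field(init=False, repr=False)
    _bindex: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.query_ids), len(self.backbone_ids)):
            raise ValueError("table shape does not match id lists")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("distances must be finite and nonnegative")
        self._qindex = {q: i for i, q in enumerate(self.query_ids)}
        self._bindex = {b: i for i, b in enumerate(self.backbone_ids)}

    def row(self, q: str) -> np.ndarray:
        return self.values[self._qindex[q]]


@dataclass
class UpdateMatrix:
    """Full symmetric matrix over backbone + query labels.

    The backbone block equals the backbone tree distances exactly; every
    pair involving a query carries the embedding distance.
    """

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("matrix must be symmetric")


@dataclass(frozen=True)
class PlacementResult:
    """Outcome of placing one query on a backbone edge."""

    query_id: str
    edge_id: int
    pendant_length: float
    distal_offset: float
    residual: float
    degenerate: bool = False


def query_distances(
    model: EmbeddingModel, backbone_aln: Alignment, query_aln: Alignment
) -> QueryDistanceTable:
    """Embedding distances between queries and backbone, de-normalised.

    Entry (q, b) = normalization_factor * s * d_unit(phi(q), phi(b)).
    Backbone and query sequences are embedded jointly so query-query
    distances come from the same model; they are stored on the table.
    """
    for aln in (backbone_aln, query_aln):
        if aln.length != model.spec.input_length:
            raise ValueError(
                f"alignment length {aln.length} != model input length "
                f"{model.spec.input_length}"
            )
    mode = model.geometry.mode
    factor = model.normalization_factor * model.geometry.scale
    Vb = encoder_forward(model, backbone_aln.one_hot())
    Vq = encoder_forward(model, query_aln.one_hot())
    V = np.vstack([Vq, Vb])
    D = pairwise_unit_distances(V, mode) * factor
    nq = len(query_aln)
    return QueryDistanceTable(
        query_ids=list(query_aln.ids),
        backbone_ids=list(backbone_aln.ids),
        values=D[:nq, nq:],
        query_query=D[:nq, :nq],
    )


def nearest_references(table: QueryDistanceTable, q: str, b: int) -> list[str]:
    """The b backbone ids nearest to query ``q`` (distance, then id, order)."""
    if b < 1:
        raise ValueError("b must be >= 1")
    row = table.row(q)
    order = sorted(range(len(row)), key=lambda i: (row[i], table.backbone_ids[i]))
    return [table.backbone_ids[i] for i in order[:b]]


# ---------------------------------------------------------------------------
# simplified least-squares placement


def _split_distances(tree: dendropy.Tree) -> tuple[dict, dict, list]:
    """Per-edge bookkeeping for attachment least squares.

    For edge e (child node c) and each leaf l: the path from a point at
    offset x above c reaches l either through c (distance d(c, l) + x) or
    through the parent (distance d(parent, l) + len - x).
    """
    labels = leaf_labels(tree)
    lab_index = {l: i for i, l in enumerate(labels)}
    # distances from every node to every leaf, by sweeping leaf matrix
    node_leaf: dict[int, np.ndarray] = {}
    D = leaf_distance_matrix(tree)
    n = len(labels)
    # accumulate: distance from node to each leaf via simple recursion
    below: dict[int, set[str]] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            below[id(nd)] = {nd.taxon.label}
        else:
            below[id(nd)] = set().union(*(below[id(c)] for c in nd.child_nodes()))
    # distance from node v to leaf l: pick any leaf a below v:
    # d(v,l) = d(a,l) - d(a,v) for l not below v; for l below v use recursion.
    # Simpler: compute directly by post+pre order dynamic programming.
    down: dict[int, np.ndarray] = {}
    for nd in tree.postorder_node_iter():
        arr = np.full(n, np.inf)
        if nd.is_leaf():
            arr[lab_index[nd.taxon.label]] = 0.0
        else:
            for c in nd.child_nodes():
                w = c.edge.length or 0.0
                arr = np.minimum(arr, down[id(c)] + w)
        down[id(nd)] = arr
    full: dict[int, np.ndarray] = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            full[id(nd)] = down[id(nd)].copy()
        else:
            w = nd.edge.length or 0.0
            up = full[id(nd.parent_node)] + w
            full[id(nd)] = np.minimum(down[id(nd)], up)
    return full, below, labels


def place_query(
    backbone: dendropy.Tree,
    table: QueryDistanceTable,
    q: str,
    b: int = 5,
    weighting: str = "inverse_sq",
) -> PlacementResult:
    """Least-squares placement of one query on the backbone.

    Candidate edges are those on paths among the ``b`` nearest reference
    leaves plus every edge incident to those paths; if no candidate fits
    the distances (relative residual above tolerance) the search falls
    back to all edges.  On each candidate edge the pendant length and the
    attachment offset are fit by weighted least squares against the model
    distances to the ``b`` references (weights 1/d^2 by default, matching
    the relative-error objective of training; ``weighting="none"``
    disables them), with both parameters clamped to their feasible range.
    """
    if set(table.backbone_ids) != set(leaf_labels(backbone)):
        raise ValueError("table backbone ids do not match backbone leaves")
    refs = nearest_references(table, q, b)
    row = table.row(q)
    bindex = table._bindex
    if row[bindex[refs[0]]] == 0.0:
        # query coincides with a backbone leaf: terminal edge, zero pendant
        catalog = edge_ids(backbone)
        for eid, nd in catalog.items():
            if nd.is_leaf() and nd.taxon.label == refs[0]:
                return PlacementResult(q, eid, 0.0, 0.0, 0.0, degenerate=False)

    node_leaf, below, labels = _split_distances(backbone)
    lab_index = {l: i for i, l in enumerate(labels)}
    catalog = edge_ids(backbone)

    d_model = np.array([row[bindex[r]] for r in refs])
    if weighting == "inverse_sq":
        w = 1.0 / np.maximum(d_model, 1e-12) ** 2
    elif weighting == "none":
        w = np.ones_like(d_model)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    # candidate edges: union of paths between reference leaves + incident edges
    ref_set = set(refs)
    on_path: set[int] = set()
    for eid, nd in catalog.items():
        bl = below[id(nd)]
        inside = len(ref_set & bl)
        if 0 < inside < len(ref_set):
            on_path.add(eid)
        # terminal edges of the references themselves
        if nd.is_leaf() and nd.taxon.label in ref_set:
            on_path.add(eid)
    path_nodes: set[int] = set()
    for eid in on_path:
        nd = catalog[eid]
        path_nodes.add(id(nd))
        if nd.parent_node is not None:
            path_nodes.add(id(nd.parent_node))
    candidates = set(on_path)
    for eid, nd in catalog.items():
        if id(nd) in path_nodes or (nd.parent_node is not None and id(nd.parent_node) in path_nodes):
            candidates.add(eid)

    def make_fitter(ref_labels: list[str]):
        dm = np.array([row[bindex[r]] for r in ref_labels])
        if weighting == "inverse_sq":
            ww = 1.0 / np.maximum(dm, 1e-12) ** 2
        else:
            ww = np.ones_like(dm)
        ref_rows = np.array([lab_index[r] for r in ref_labels])
        ref_set_local = set(ref_labels)

        def fit_edge(eid: int) -> tuple[float, float, float]:
            nd = catalog[eid]
            elen = nd.edge.length or 0.0
            d_child = node_leaf[id(nd)][ref_rows]
            d_parent = node_leaf[id(nd.parent_node)][ref_rows]
            through_child = np.array([r in below[id(nd)] for r in ref_labels])
            # distance from a point at offset x above the child to reference
            # i: d_child_i + x through the child side, d_parent_i + (elen - x)
            # through the parent side; model: d_i ~ pendant + base_i + sign_i*x
            base = np.where(through_child, d_child, d_parent + elen)
            sign = np.where(through_child, 1.0, -1.0)
            y = dm - base
            sw = ww.sum()
            swx = (ww * sign).sum()
            swy = (ww * y).sum()
            swxy = (ww * sign * y).sum()
            det = sw * sw - swx**2  # sign^2 == 1
            if abs(det) < 1e-12 * sw * sw:
                p_hat, x_hat = max(swy / sw, 0.0), 0.0
            else:
                p_hat = (swy * sw - swx * swxy) / det
                x_hat = (sw * swxy - swx * swy) / det
            x_hat = float(np.clip(x_hat, 0.0, elen))
            p_hat = (ww * (y - sign * x_hat)).sum() / sw
            p_hat = max(float(p_hat), 0.0)
            resid = float((ww * (p_hat + sign * x_hat - y) ** 2).sum())
            return p_hat, x_hat, resid

        scale = float((ww * dm**2).sum())
        return fit_edge, scale

    fit_b, scale_b = make_fitter(refs)
    tol = 1e-10 * max(scale_b, 1.0)

    def scores(edge_set, fitter) -> list[tuple[float, int, float, float]]:
        out = []
        for eid in sorted(edge_set):
            p_hat, x_hat, resid = fitter(eid)
            out.append((resid, eid, p_hat, x_hat))
        return out

    results = scores(candidates, fit_b)
    best = min(results)
    if best[0] > tol and len(candidates) < len(catalog):
        # the restricted candidate set does not fit well; search all edges
        results = scores(set(catalog), fit_b)
        best = min(results)
    tied = [r for r in results if r[0] <= best[0] + tol]
    if len(tied) > 1 and len(table.backbone_ids) > len(refs):
        # ambiguous fit (the b references all sit on one side of the
        # attachment, so several edges fit equally well); re-score every
        # edge against the full reference set, which always spans both
        # sides of the true attachment edge
        fit_all, _ = make_fitter(sorted(table.backbone_ids))
        tied = scores(set(catalog), fit_all)
    resid, eid, p_hat, x_hat = min(tied)

    degenerate = bool(np.allclose(d_model, d_model[0])) and len(refs) > 1
    return PlacementResult(q, eid, p_hat, x_hat, resid, degenerate=degenerate)


def place_all(
    backbone: dendropy.Tree, table: QueryDistanceTable, b: int = 5, **kw
) -> list[PlacementResult]:
    return [place_query(backbone, table, q, b=b, **kw) for q in table.query_ids]


# ---------------------------------------------------------------------------
# update matrices


def build_update_matrix(
    backbone: dendropy.Tree,
    tables: QueryDistanceTable | list[QueryDistanceTable],
    query_query_distances: np.ndarray | None = None,
) -> UpdateMatrix:
    """Hybrid matrix: exact tree distances between backbone pairs,
    embedding distances for every pair involving a query.

    With several tables (one per gene) each is turned into an update
    matrix and the entrywise median is taken via
    :func:`merge_gene_matrices`.
    """
    if isinstance(tables, list):
        if len(tables) == 0:
            raise ValueError("need at least one table")
        mats = [build_update_matrix(backbone, t) for t in tables]
        return merge_gene_matrices(mats)
    table = tables
    D = leaf_distance_matrix(backbone)
    blabels = D.labels
    qlabels = list(table.query_ids)
    qq = query_query_distances if query_query_distances is not None else table.query_query
    if qq is None:
        raise ValueError("query-query distances required (embed queries jointly)")
    qq = np.asarray(qq, dtype=float)
    nb, nq = len(blabels), len(qlabels)
    M = np.zeros((nb + nq, nb + nq))
    M[:nb, :nb] = D.matrix
    qb = np.stack([table.row(q) for q in qlabels])  # query x table-backbone order
    col = [table._bindex[b] for b in blabels]
    M[nb:, :nb] = qb[:, col]
    M[:nb, nb:] = M[nb:, :nb].T
    M[nb:, nb:] = (qq + qq.T) / 2.0
    np.fill_diagonal(M, 0.0)
    return UpdateMatrix(labels=blabels + qlabels, matrix=M)


def merge_gene_matrices(tables: list):
    """Entrywise median across genes (lower median for even counts)."""
    if len(tables) == 0:
        raise ValueError("need at least one input")
    first = tables[0]
    if isinstance(first, UpdateMatrix):
        labels = first.labels
        stacks = []
        for t in tables:
            if t.labels != labels:
                if set(t.labels) != set(labels):
                    raise ValueError("update matrices have differing label sets")
                idx = [t.labels.index(l) for l in labels]
                stacks.append(t.matrix[np.ix_(idx, idx)])
            else:
                stacks.append(t.matrix)
        return UpdateMatrix(labels=list(labels), matrix=_lower_median(np.stack(stacks)))
    # QueryDistanceTable inputs
    q_ids, b_ids = first.query_ids, first.backbone_ids
    stacks = []
    qq_stacks = []
    for t in tables:
        if set(t.query_ids) != set(q_ids) or set(t.backbone_ids) != set(b_ids):
            raise ValueError("tables have differing label sets")
        qi = [t._qindex[q] for q in q_ids]
        bi = [t._bindex[b] for b in b_ids]
        stacks.append(t.values[np.ix_(qi, bi)])
        if t.query_query is not None:
            qq_stacks.append(t.query_query[np.ix_(qi, qi)])
    qq = _lower_median(np.stack(qq_stacks)) if len(qq_stacks) == len(tables) else None
    return QueryDistanceTable(
        query_ids=list(q_ids),
        backbone_ids=list(b_ids),
        values=_lower_median(np.stack(stacks)),
        query_query=qq,
    )


def _lower_median(stack: np.ndarray) -> np.ndarray:
    """Lower median along axis 0 (deterministic for even counts)."""
    srt = np.sort(stack, axis=0)
    return srt[(stack.shape[0] - 1) // 2]


# ---------------------------------------------------------------------------
# PHYLIP square matrix I/O (FastME / APPLES input) and placement TSV


def write_phylip_matrix(m: UpdateMatrix | TreeDistances, path: str | Path) -> None:
    """Full square PHYLIP distance matrix, 10 significant digits."""
    labels = m.labels
    matrix = m.matrix
    for l in labels:
        if any(ch.isspace() for ch in l):
            raise ValueError(f"label contains whitespace: {l!r}")
    with open(path, "w") as fh:
        fh.write(f"{len(labels)}\n")
        for l, rowv in zip(labels, matrix):
            fh.write(l + "\t" + " ".join(f"{x:.10g}" for x in rowv) + "\n")


def read_phylip_matrix(path: str | Path) -> UpdateMatrix:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError("first line must contain the taxon count")
    rows = lines[1:]
    if len(rows) != n:
        raise ValueError(f"header says {n} taxa but found {len(rows)} rows")
    labels, values = [], []
    for ln in rows:
        parts = ln.split()
        if len(parts) != n + 1:
            raise ValueError(f"row has {len(parts) - 1} values, expected {n}")
        labels.append(parts[0])
        values.append([float(x) for x in parts[1:]])
    return UpdateMatrix(labels=labels, matrix=np.array(values))


def write_placements_tsv(results: list[PlacementResult], path: str | Path) -> None:
    """jplace-lite TSV: query, edge id, pendant, offset, residual, flag."""
    with open(path, "w") as fh:
        fh.write("query\tedge_id\tpendant_length\tdistal_offset\tresidual\tdegenerate\n")
        for r in results:
            fh.write(
                f"{r.query_id}\t{r.edge_id}\t{r.pendant_length:.10g}\t"
                f"{r.distal_offset:.10g}\t{r.residual:.10g}\t{int(r.degenerate)}\n"
            )
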