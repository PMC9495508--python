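"""Metric-tree handling: newick I/O, path distances, splits and comparisons.

Trees are :class:`dendropy.Tree` objects throughout; this module adds the
operations the embedding workflow needs on top of them:

* leaf-to-leaf path-length distance matrices (:class:`TreeDistances`);
* Robinson-Foulds and Monte-Carlo / exhaustive quartet distances;
* query selection (random fraction or whole clades) with pruning that
  preserves residual path lengths;
* a canonical edge catalogue and topological placement-error counting.

Edges are identified by the child node of the edge in a canonical
post-order traversal; for cross-tree comparison an edge is the bipartition
of the leaf set it induces, canonicalised as the side not containing the
lexicographically smallest leaf label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path

import dendropy
import numpy as np

__all__ = [
    "TreeDistances",
    "parse_newick",
    "write_newick",
    "read_newick",
    "leaf_labels",
    "leaf_distance_matrix",
    "rf_distance",
    "rf_count",
    "sampled_quartet_distance",
    "random_query_split",
    "clade_query_split",
    "prune_leaves",
    "graft_leaf",
    "edge_ids",
    "edge_bipartition",
    "placement_edge_error",
]


@dataclass
class TreeDistances:
    """Labelled symmetric leaf-distance matrix with zero diagonal.

    ``normalization_factor`` records the pre-normalisation maximum when the
    matrix has been rescaled to max 1 (see training); 1.0 otherwise.
    """

    labels: list[str]
    matrix: np.ndarray
    normalization_factor: float = 1.0
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError(f"matrix shape {self.matrix.shape} does not match {n} labels")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.matrix < 0):
            raise ValueError("distances must be nonnegative")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def value(self, a: str, b: str) -> float:
        return float(self.matrix[self._index[a], self._index[b]])

    def submatrix(self, labels: list[str]) -> "TreeDistances":
        idx = [self._index[l] for l in labels]
        return TreeDistances(
            list(labels), self.matrix[np.ix_(idx, idx)], self.normalization_factor
        )


# ---------------------------------------------------------------------------
# newick I/O


def _own_copy(tree: dendropy.Tree) -> dendropy.Tree:
    """Deep copy with its own taxon namespace (safe to mutate)."""
    out = tree.clone(depth=1)
    out.migrate_taxon_namespace(dendropy.TaxonNamespace())
    return out


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a newick string; missing branch lengths become 0 with a warning."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except dendropy.utility.error.DataParseError as exc:
        if "duplicate" in str(exc).lower():
            raise ValueError(f"duplicate leaf labels: {exc}") from exc
        raise
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate leaf labels: {dup}")
    missing = False
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            edge.length = None
            continue
        if edge.length is None:
            edge.length = 0.0
            missing = True
        elif edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")
    if missing:
        warnings.warn("newick had edges without branch lengths; set to 0", stacklevel=2)
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialise with branch lengths at full double precision."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".17g",
    ).strip() + "\n"


def read_newick(path: str | Path) -> dendropy.Tree:
    return parse_newick(Path(path).read_text())


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return sorted(lf.taxon.label for lf in tree.leaf_node_iter())


# ---------------------------------------------------------------------------
# distance matrix


def leaf_distance_matrix(tree: dendropy.Tree) -> TreeDistances:
    """Path-length distances between all leaf pairs, labels sorted.

    Single post-order sweep: each node carries distances from the leaves of
    its subtree to its root; sibling lists are combined pairwise.
    """
    labels = leaf_labels(tree)
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    D = np.zeros((n, n))
    # node -> (leaf indices in subtree, distances from those leaves to node)
    carry: dict[int, tuple[list[int], list[float]]] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            carry[id(nd)] = ([index[nd.taxon.label]], [0.0])
            continue
        child_data = []
        for ch in nd.child_nodes():
            idxs, dists = carry.pop(id(ch))
            w = ch.edge.length or 0.0
            child_data.append((idxs, [d + w for d in dists]))
        for (ia, da), (ib, db) in combinations(child_data, 2):
            for i, di in zip(ia, da):
                for j, dj in zip(ib, db):
                    D[i, j] = D[j, i] = di + dj
        merged_i = [i for idxs, _ in child_data for i in idxs]
        merged_d = [d for _, dists in child_data for d in dists]
        carry[id(nd)] = (merged_i, merged_d)
    return TreeDistances(labels, D)


# ---------------------------------------------------------------------------
# bipartitions, RF distance


def _leafsets(tree: dendropy.Tree) -> dict[int, frozenset[str]]:
    """Map node id -> frozenset of leaf labels below it (post-order)."""
    out: dict[int, frozenset[str]] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            out[id(nd)] = frozenset([nd.taxon.label])
        else:
            s: frozenset[str] = frozenset()
            for ch in nd.child_nodes():
                s = s | out[id(ch)]
            out[id(nd)] = s
    return out


def _canonical_split(side: frozenset[str], all_leaves: frozenset[str], anchor: str) -> frozenset[str]:
    return all_leaves - side if anchor in side else side


def _nontrivial_splits(tree: dendropy.Tree) -> set[frozenset[str]]:
    leafsets = _leafsets(tree)
    all_leaves = leafsets[id(tree.seed_node)]
    anchor = min(all_leaves)
    n = len(all_leaves)
    splits: set[frozenset[str]] = set()
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node or nd.is_leaf():
            continue
        side = leafsets[id(nd)]
        if 2 <= len(side) <= n - 2:
            splits.add(_canonical_split(side, all_leaves, anchor))
    return splits


def rf_count(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Raw Robinson-Foulds symmetric-difference count of non-trivial splits."""
    if set(leaf_labels(t1)) != set(leaf_labels(t2)):
        raise ValueError("trees must share a leaf label set")
    return len(_nontrivial_splits(t1) ^ _nontrivial_splits(t2))


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree, denominator: str = "binary") -> float:
    """Normalised RF distance in [0, 1].

    ``denominator="binary"`` divides by 2(n-3), the maximum for binary
    trees; ``denominator="observed"`` divides by the total number of
    non-trivial splits present in the two trees (useful when either tree
    has polytomies).
    """
    raw = rf_count(t1, t2)
    n = len(leaf_labels(t1))
    if denominator == "binary":
        denom = 2 * (n - 3)
    elif denominator == "observed":
        denom = len(_nontrivial_splits(t1)) + len(_nontrivial_splits(t2))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        return 0.0
    return raw / denom


# ---------------------------------------------------------------------------
# quartet distance (Monte-Carlo, with exhaustive mode for small trees)


def _topological_distances(tree: dendropy.Tree, labels: list[str]) -> np.ndarray:
    """Unrooted edge-count distances between leaves (root bifurcation merged)."""
    t = tree.clone(depth=1)
    for e in t.preorder_edge_iter():
        e.length = 1.0
    root_children = t.seed_node.child_nodes()
    if len(root_children) == 2:
        # a degree-2 root splits one unrooted edge in two; cancel the extra count
        root_children[0].edge.length = 0.0
    D = leaf_distance_matrix(t)
    return D.submatrix(labels).matrix


def _quartet_codes(D: np.ndarray, quartets: np.ndarray) -> np.ndarray:
    """Pairing code per quartet row [a,b,c,d]: 0=ab|cd, 1=ac|bd, 2=ad|bc."""
    a, b, c, d = quartets.T
    s0 = D[a, b] + D[c, d]
    s1 = D[a, c] + D[b, d]
    s2 = D[a, d] + D[b, c]
    sums = np.stack([s0, s1, s2])
    return np.argmin(sums, axis=0)


def sampled_quartet_distance(
    t1: dendropy.Tree,
    t2: dendropy.Tree,
    n_samples: int = 100_000,
    seed: int = 0,
    exhaustive: bool | None = None,
) -> float:
    """Fraction of 4-leaf subsets whose induced unrooted topologies differ.

    Monte-Carlo estimate over ``n_samples`` quartets drawn with replacement;
    exhaustive enumeration over all C(n,4) quartets when ``exhaustive`` is
    true (the default for trees with at most 15 leaves).  Deterministic
    given ``seed``.
    """
    labels = leaf_labels(t1)
    if set(labels) != set(leaf_labels(t2)):
        raise ValueError("trees must share a leaf label set")
    n = len(labels)
    if n < 4:
        raise ValueError("need at least 4 shared leaves")
    if exhaustive is None:
        exhaustive = n <= 15
    D1 = _topological_distances(t1, labels)
    D2 = _topological_distances(t2, labels)
    if exhaustive:
        quartets = np.array(list(combinations(range(n), 4)))
    else:
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        rng = np.random.default_rng(seed)
        # vectorised sampling without replacement: 4 smallest random keys per row
        keys = rng.random((n_samples, n))
        quartets = np.argpartition(keys, 4, axis=1)[:, :4]
    return float(np.mean(_quartet_codes(D1, quartets) != _quartet_codes(D2, quartets)))


# ---------------------------------------------------------------------------
# pruning, grafting and query selection


def prune_leaves(tree: dendropy.Tree, labels: list[str]) -> dendropy.Tree:
    """Copy of ``tree`` with ``labels`` removed.

    Degree-2 nodes left by the removal are suppressed with their incident
    branch lengths summed, so path lengths between surviving leaves are
    unchanged.
    """
    out = _own_copy(tree)
    present = {t.label for t in out.taxon_namespace}
    missing = set(labels) - present
    if missing:
        raise KeyError(f"labels not in tree: {sorted(missing)}")
    keep = [t for t in out.taxon_namespace if t.label not in set(labels)]
    out.retain_taxa(keep)
    out.purge_taxon_namespace()
    return out


def graft_leaf(
    tree: dendropy.Tree,
    edge_id: int,
    label: str,
    pendant_length: float,
    distal_offset: float,
) -> dendropy.Tree:
    """Attach a new leaf onto edge ``edge_id``.

    The edge is split ``distal_offset`` above its child node; the new leaf
    hangs from the split point with ``pendant_length``.
    """
    out = _own_copy(tree)
    child = edge_ids(out)[edge_id]
    elen = child.edge.length or 0.0
    if not 0.0 <= distal_offset <= elen + 1e-12:
        raise ValueError(f"offset {distal_offset} outside edge of length {elen}")
    parent = child.parent_node
    split = dendropy.Node()
    parent.remove_child(child)
    parent.add_child(split)
    split.edge.length = elen - distal_offset
    split.add_child(child)
    child.edge.length = distal_offset
    taxon = dendropy.Taxon(label=label)
    out.taxon_namespace.add_taxon(taxon)
    leaf = dendropy.Node(taxon=taxon)
    split.add_child(leaf)
    leaf.edge.length = pendant_length
    return out


def random_query_split(
    tree: dendropy.Tree, fraction: float, seed: int = 0
) -> tuple[dendropy.Tree, list[str]]:
    """Hold out a uniform random fraction of leaves as queries.

    The query count is round-half-up of ``fraction * n``.  Returns the
    pruned backbone and the sorted query labels.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    labels = leaf_labels(tree)
    n = len(labels)
    n_query = int(np.floor(fraction * n + 0.5))
    if n - n_query < 4:
        raise ValueError(f"backbone would have {n - n_query} < 4 leaves")
    rng = np.random.default_rng(seed)
    queries = sorted(rng.choice(labels, size=n_query, replace=False).tolist())
    return prune_leaves(tree, queries), queries


def clade_query_split(
    tree: dendropy.Tree,
    n_clades: int,
    min_size: int = 5,
    max_size: int = 10,
    seed: int = 0,
) -> tuple[dendropy.Tree, list[str]]:
    """Hold out whole clades (monophyletic groups) as queries.

    Chooses ``n_clades`` pairwise-disjoint clades whose leaf counts lie in
    ``[min_size, max_size]`` by greedy sequential sampling among eligible
    candidates.  All their leaves become queries.
    """
    leafsets = _leafsets(tree)
    all_leaves = leafsets[id(tree.seed_node)]
    candidates = sorted(
        (
            tuple(sorted(leafsets[id(nd)]))
            for nd in tree.preorder_internal_node_iter()
            if nd is not tree.seed_node and min_size <= len(leafsets[id(nd)]) <= max_size
        ),
    )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(candidates))
    chosen: list[tuple[str, ...]] = []
    used: set[str] = set()
    for k in order:
        cl = candidates[k]
        if used.isdisjoint(cl):
            chosen.append(cl)
            used.update(cl)
            if len(chosen) == n_clades:
                break
    if len(chosen) < n_clades:
        raise ValueError(
            f"only {len(chosen)} disjoint clades of size [{min_size}, {max_size}] "
            f"available, {n_clades} requested"
        )
    if len(all_leaves) - len(used) < 4:
        raise ValueError("backbone would have fewer than 4 leaves")
    queries = sorted(used)
    return prune_leaves(tree, queries), queries


# ---------------------------------------------------------------------------
# edge catalogue and placement error


def edge_ids(tree: dendropy.Tree) -> dict[int, dendropy.Node]:
    """Canonical edge catalogue: id -> child node, in post-order."""
    return {
        i: nd
        for i, nd in enumerate(
            nd for nd in tree.postorder_node_iter() if nd.parent_node is not None
        )
    }


def edge_bipartition(tree: dendropy.Tree, edge_id: int) -> frozenset[str]:
    """Canonical leaf-set bipartition induced by removing edge ``edge_id``."""
    catalog = edge_ids(tree)
    leafsets = _leafsets(tree)
    all_leaves = leafsets[id(tree.seed_node)]
    anchor = min(all_leaves)
    return _canonical_split(leafsets[id(catalog[edge_id])], all_leaves, anchor)


def _unrooted_edge_graph(
    tree: dendropy.Tree,
) -> tuple[dict[frozenset[str], set[int]], dict[int, set[frozenset[str]]]]:
    """Unrooted edges keyed by canonical bipartition, with node incidences.

    A degree-2 root merges its two incident edges into one unrooted edge.
    Returns (edge -> endpoint node ids, node id -> incident edges).
    """
    leafsets = _leafsets(tree)
    all_leaves = leafsets[id(tree.seed_node)]
    anchor = min(all_leaves)
    root = tree.seed_node
    root_merged = len(root.child_nodes()) == 2
    edge_nodes: dict[frozenset[str], set[int]] = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        key = _canonical_split(leafsets[id(nd)], all_leaves, anchor)
        ends = edge_nodes.setdefault(key, set())
        ends.add(id(nd))
        if not (root_merged and nd.parent_node is root):
            ends.add(id(nd.parent_node))
    node_edges: dict[int, set[frozenset[str]]] = {}
    for key, ends in edge_nodes.items():
        for e in ends:
            node_edges.setdefault(e, set()).add(key)
    return edge_nodes, node_edges


def _edge_graph_distance(
    tree: dendropy.Tree, sources: set[frozenset[str]], target: frozenset[str]
) -> int:
    """BFS edge-count between unrooted edges (adjacent edges are 1 apart)."""
    edge_nodes, node_edges = _unrooted_edge_graph(tree)
    for key in sources | {target}:
        if key not in edge_nodes:
            raise KeyError(f"bipartition not present in tree: {sorted(key)}")
    if target in sources:
        return 0
    frontier = set(sources)
    seen = set(sources)
    dist = 0
    while frontier:
        dist += 1
        nxt: set[frozenset[str]] = set()
        for key in frontier:
            for nid in edge_nodes[key]:
                nxt |= node_edges[nid]
        nxt -= seen
        if target in nxt:
            return dist
        seen |= nxt
        frontier = nxt
    raise RuntimeError("edge graph is disconnected (corrupt tree)")


def true_attachment_bipartitions(
    true_tree: dendropy.Tree, backbone: dendropy.Tree, query: str
) -> set[frozenset[str]]:
    """Backbone edges onto which ``query`` truly attaches.

    Restrict the true tree to the backbone leaves plus the query, remove
    the query's pendant edge, and identify the backbone edge(s) that its
    attachment point lands on.  Normally a single edge; when the query is
    attached at what becomes a node of the unrooted backbone (a degree-2
    root situation), every incident edge is returned.
    """
    backbone_leaves = set(leaf_labels(backbone))
    wanted = backbone_leaves | {query}
    restricted = prune_leaves(true_tree, [l for l in leaf_labels(true_tree) if l not in wanted])
    leafsets = _leafsets(restricted)
    anchor = min(backbone_leaves)
    qleaf = next(
        lf for lf in restricted.leaf_node_iter() if lf.taxon.label == query
    )
    parent = qleaf.parent_node
    neighbors = [ch for ch in parent.child_nodes() if ch is not qleaf]
    out: set[frozenset[str]] = set()
    for nb in neighbors:
        side = leafsets[id(nb)] - {query}
        if 1 <= len(side) <= len(backbone_leaves) - 1:
            out.add(_canonical_split(side, frozenset(backbone_leaves), anchor))
    if parent.parent_node is not None:
        side = (frozenset(backbone_leaves) | {query}) - leafsets[id(parent)]
        if 1 <= len(side) <= len(backbone_leaves) - 1:
            out.add(_canonical_split(side, frozenset(backbone_leaves), anchor))
    if not out and len(neighbors) == 1:
        # query hangs off a degree-2 root: its attachment point lies on the
        # unrooted edge (or at the node) formed by the sibling's children
        for ch in neighbors[0].child_nodes():
            side = leafsets[id(ch)] - {query}
            if 1 <= len(side) <= len(backbone_leaves) - 1:
                out.add(_canonical_split(side, frozenset(backbone_leaves), anchor))
    if not out:
        raise RuntimeError(f"could not locate attachment of {query!r}")
    return out


def placement_edge_error(
    true_tree: dendropy.Tree,
    backbone: dendropy.Tree,
    query: str,
    placed_edge: int,
) -> int:
    """Topological edge count between the placed and the true attachment edge.

    0 means the query was placed on exactly the edge it attaches to in the
    true tree; adjacent edges score 1; and so on along the backbone.
    """
    truth = true_attachment_bipartitions(true_tree, backbone, query)
    placed = edge_bipartition(backbone, placed_edge)
    return _edge_graph_distance(backbone, truth, placed)
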