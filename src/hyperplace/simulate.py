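"""Synthetic benchmarks: random trees, discordant gene trees, JC alignments.

The generator emulates the structure of the data the embedding workflow is
meant for: a species tree acts as the backbone (the source of the target
distances), sequences evolve on a *gene* tree that disagrees with the
species tree, and a held-out fraction of taxa serves as queries.  Gene-tree
discordance is produced by random nearest-neighbour interchanges (NNI), a
controllable structural stand-in for incomplete lineage sorting; sequences
evolve under the Jukes-Cantor model with no indels, so alignments are
gap-free and branch lengths are in expected substitutions per site.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import dendropy
import numpy as np

from .alignio import Alignment, write_fasta
from .trees import parse_newick, random_query_split, write_newick

__all__ = [
    "SimulationConfig",
    "random_binary_tree",
    "balanced_tree",
    "caterpillar_tree",
    "perturb_gene_tree",
    "simulate_jc_alignment",
    "make_benchmark",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic benchmark.

    ``branch_length_mean`` is the mean of the exponential law for branch
    lengths in substitutions per site; 0.1 gives pairwise distances mostly
    in the 0.1-1.5 range where JC sequences of a few hundred sites remain
    informative.  ``nni_moves`` controls gene-tree discordance (0 means
    the gene tree equals the species tree).
    """

    n_leaves: int = 16
    tree_shape: str = "birth_death"
    branch_length_mean: float = 0.1
    seq_length: int = 500
    nni_moves: int = 0
    query_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 4:
            raise ValueError("n_leaves must be >= 4")
        if self.tree_shape not in ("birth_death", "balanced", "caterpillar"):
            raise ValueError(f"unknown tree_shape {self.tree_shape!r}")
        if self.branch_length_mean <= 0:
            raise ValueError("branch_length_mean must be positive")
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")
        if self.nni_moves < 0:
            raise ValueError("nni_moves must be >= 0")


def _tree_from_newick(newick: str) -> dendropy.Tree:
    return parse_newick(newick)


def random_binary_tree(cfg: SimulationConfig) -> dendropy.Tree:
    """Random rooted binary tree with i.i.d. exponential branch lengths.

    The topology comes from uniform coalescent-style joining: lineages are
    merged two at a time, each pair chosen uniformly.  Leaf labels are
    t1..tn; deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_leaves
    nodes = [f"t{i + 1}" for i in range(n)]
    subtrees = list(nodes)
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        a = subtrees.pop(j)
        b = subtrees.pop(i)
        subtrees.append(f"({a}:0,{b}:0)")
    skeleton = _tree_from_newick(subtrees[0] + ";")
    for edge in skeleton.preorder_edge_iter():
        if edge.head_node is not skeleton.seed_node:
            edge.length = float(rng.exponential(cfg.branch_length_mean))
    return skeleton


def balanced_tree(depth: int, edge_length: float = 1.0) -> dendropy.Tree:
    """Perfectly height-balanced binary tree: 2**depth leaves, uniform edges.

    Every leaf sits at distance ``depth * edge_length`` from the root; the
    closest leaf pairs are ``2 * edge_length`` apart.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")

    counter = iter(range(1, 2**depth + 1))

    def build(d: int) -> str:
        if d == 0:
            return f"t{next(counter)}:{edge_length}"
        return f"({build(d - 1)},{build(d - 1)}):{edge_length}"

    inner = f"({build(depth - 1)},{build(depth - 1)});"
    tree = _tree_from_newick(inner)
    for ch in tree.seed_node.child_nodes():
        ch.edge.length = edge_length
    return tree


def caterpillar_tree(n_leaves: int, edge_length: float = 1.0) -> dendropy.Tree:
    """Fully unbalanced (ladder) tree with uniform edge lengths."""
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    s = f"t1:{edge_length}"
    for i in range(2, n_leaves + 1):
        s = f"({s},t{i}:{edge_length}):{edge_length}"
    # outermost grouping closes the root
    return _tree_from_newick(s.rsplit(":", 1)[0] + ";")


def perturb_gene_tree(
    species_tree: dendropy.Tree, nni_moves: int, seed: int = 0
) -> dendropy.Tree:
    """Apply random NNI moves to internal edges (topology discordance).

    Each move picks an internal edge uniformly and swaps one subtree from
    each side; 0 moves returns an identical topology.  Branch lengths move
    with their subtrees.  Deterministic given ``seed``.
    """
    if nni_moves < 0:
        raise ValueError("nni_moves must be >= 0")
    tree = species_tree.clone(depth=1)
    rng = np.random.default_rng(seed)
    root = tree.seed_node
    for _ in range(nni_moves):
        # candidate internal (unrooted) edges: both endpoints internal.  At a
        # degree-2 root the two root edges are one unrooted edge between the
        # root's children, so the exchange partner is a child of the sibling.
        candidates = []
        for nd in tree.preorder_internal_node_iter():
            if nd.parent_node is None or len(nd.child_nodes()) != 2:
                continue
            parent = nd.parent_node
            sib = next(c for c in parent.child_nodes() if c is not nd)
            if parent is root and len(root.child_nodes()) == 2:
                if sib.is_leaf():
                    continue  # unrooted edge (nd, sib) is terminal
                candidates.append((nd, sib, True))
            else:
                candidates.append((nd, sib, False))
        if not candidates:
            break
        nd, sib, across_root = candidates[rng.integers(len(candidates))]
        child = nd.child_nodes()[rng.integers(2)]
        if across_root:
            other = sib.child_nodes()[rng.integers(len(sib.child_nodes()))]
            sib.remove_child(other)
            nd.remove_child(child)
            sib.add_child(child)
            nd.add_child(other)
        else:
            parent = nd.parent_node
            parent.remove_child(sib)
            nd.remove_child(child)
            parent.add_child(child)
            nd.add_child(sib)
    return tree


def _jc_evolve(parent_seq: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """One branch of Jukes-Cantor evolution on an integer-coded sequence.

    Per site the state is retained with probability 1/4 + 3/4 exp(-4t/3),
    otherwise replaced by one of the other three bases uniformly.
    """
    p_change = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
    out = parent_seq.copy()
    hit = rng.random(parent_seq.size) < p_change
    n_hit = int(hit.sum())
    if n_hit:
        # uniform over the three other bases
        shift = rng.integers(1, 4, size=n_hit)
        out[hit] = (out[hit] + shift) % 4
    return out


def simulate_jc_alignment(tree: dendropy.Tree, L: int, seed: int = 0) -> Alignment:
    """Gap-free alignment evolved on ``tree`` under the Jukes-Cantor model.

    The root sequence is uniform over {A, C, G, T}; branch lengths are in
    expected substitutions per site.  Deterministic given ``seed``.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = np.random.default_rng(seed)
    seqs: dict[int, np.ndarray] = {}
    ids: list[str] = []
    rows: list[str] = []
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            seqs[id(nd)] = rng.integers(0, 4, size=L)
        else:
            t = nd.edge.length or 0.0
            seqs[id(nd)] = _jc_evolve(seqs[id(nd.parent_node)], t, rng)
        if nd.is_leaf():
            ids.append(nd.taxon.label)
            rows.append("".join(_BASES[seqs[id(nd)]]))
        # free parent memory once all children are generated
    order = np.argsort(ids)
    return Alignment([ids[i] for i in order], [rows[i] for i in order])


def make_benchmark(cfg: SimulationConfig, out_dir: str | Path | None = None) -> dict:
    """Full benchmark bundle: species tree, gene tree, alignment, query split.

    The species tree is the backbone (source of target distances); the
    alignment evolves on the gene tree, which differs from the species
    tree by ``cfg.nni_moves`` NNI moves.  A ``query_fraction`` random split
    holds out queries.  When ``out_dir`` is given, files are written:
    species.nwk, gene.nwk, alignment.fasta, queries.txt, backbone.nwk and
    a manifest.json recording the configuration.
    """
    if cfg.tree_shape == "birth_death":
        species = random_binary_tree(cfg)
    elif cfg.tree_shape == "balanced":
        depth = int(np.round(np.log2(cfg.n_leaves)))
        if 2**depth != cfg.n_leaves:
            raise ValueError("balanced shape needs a power-of-two n_leaves")
        species = balanced_tree(depth)
    else:
        species = caterpillar_tree(cfg.n_leaves)
    gene = perturb_gene_tree(species, cfg.nni_moves, seed=cfg.seed + 1)
    aln = simulate_jc_alignment(gene, cfg.seq_length, seed=cfg.seed + 2)
    backbone, queries = random_query_split(species, cfg.query_fraction, seed=cfg.seed + 3)
    bundle = {
        "config": cfg,
        "species_tree": species,
        "gene_tree": gene,
        "alignment": aln,
        "backbone_tree": backbone,
        "query_ids": queries,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "species.nwk").write_text(write_newick(species))
        (out / "gene.nwk").write_text(write_newick(gene))
        (out / "backbone.nwk").write_text(write_newick(backbone))
        write_fasta(aln, out / "alignment.fasta")
        (out / "queries.txt").write_text("".join(q + "\n" for q in queries))
        (out / "manifest.json").write_text(json.dumps(asdict(cfg), indent=2) + "\n")
    return bundle
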