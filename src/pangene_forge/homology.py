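"""Orthology and paralogy prediction.

Two complementary routes, mirroring common practice in comparative genomics
pipelines:

* **Reciprocal best hits (RBH)** between genome pairs: two sequences that are
  each other's best similarity hit are reported as a putative ortholog pair.
* **Rooted gene trees**: gene trees (built externally, e.g. with FastTree, or
  by the bundled neighbor-joining fallback) are rooted on the edge minimizing
  the number of duplication events under the *species-overlap* rule — a node
  is a duplication iff at least two of its child subtrees share a species —
  and leaf pairs are then classified as orthologs (cross-species, speciation
  at the LCA) or in-paralogs (same species, single-species LCA subtree).

The species-overlap labeling is this package's documented replacement for
reconciliation-based scoring tools; outputs record
``source=tree, method=species_overlap``.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from Bio import Phylo
from Bio.Phylo.TreeConstruction import DistanceMatrix as _BioDM
from Bio.Phylo.TreeConstruction import DistanceTreeConstructor

from .distances import DistanceMatrix
from .io_formats import Hit

__all__ = [
    "Event",
    "Relation",
    "TreeNode",
    "HomologyPair",
    "rbh",
    "parse_newick",
    "label_events",
    "root_tree",
    "extract_homologs",
    "prune_tree",
    "neighbor_joining",
]


class Event(str, Enum):
    SPECIATION = "speciation"
    DUPLICATION = "duplication"


class Relation(str, Enum):
    ORTHOLOG = "ortholog"
    IN_PARALOG = "in_paralog"
    RBH = "rbh"


@dataclass
class TreeNode:
    """A rooted gene-tree node; leaves carry an id and a species code."""

    name: str | None = None
    species: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    event: Event | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [lf for c in self.children for lf in c.leaves()]

    def species_set(self) -> set[str]:
        return {lf.species for lf in self.leaves() if lf.species}

    def to_newick(self) -> str:
        def fmt(n: TreeNode) -> str:
            if n.is_leaf:
                return n.name or ""
            return "(" + ",".join(fmt(c) for c in n.children) + ")"

        return fmt(self) + ";"


@dataclass(frozen=True)
class HomologyPair:
    """An unordered predicted homology relation between two identifiers."""

    id_a: str
    id_b: str
    relation: Relation
    source: str  # "tree" or "rbh"

    def __post_init__(self) -> None:
        if self.id_a == self.id_b:
            raise ValueError("self-pair")
        if self.id_a > self.id_b:
            a, b = self.id_b, self.id_a
            object.__setattr__(self, "id_a", a)
            object.__setattr__(self, "id_b", b)


# ---------------------------------------------------------------------------
# Reciprocal best hits


def _best_hits(hits: Iterable[Hit]) -> dict[str, str]:
    """Best subject per query: max bitscore, then min e-value, then smallest
    subject id."""
    best: dict[str, tuple[float, float, str]] = {}
    for h in hits:
        key = (-h.bitscore, h.evalue, h.subject_id)
        if h.query_id not in best or key < best[h.query_id]:
            best[h.query_id] = key
    return {q: k[2] for q, k in best.items()}


def rbh(hits_ab: Iterable[Hit], hits_ba: Iterable[Hit]) -> set[HomologyPair]:
    """Reciprocal best hits between two genomes' directed hit tables."""
    best_ab = _best_hits(hits_ab)
    best_ba = _best_hits(hits_ba)
    pairs: set[HomologyPair] = set()
    for a, b in best_ab.items():
        if best_ba.get(b) == a:
            pairs.add(HomologyPair(a, b, Relation.RBH, source="rbh"))
    return pairs


# ---------------------------------------------------------------------------
# Gene trees


def parse_newick(text: str, species_of: Mapping[str, str] | None = None) -> TreeNode:
    """Parse a Newick string (branch lengths and support values tolerated and
    ignored) into a TreeNode; leaf species come from ``species_of``."""
    tree = Phylo.read(io.StringIO(text), "newick")

    def convert(clade) -> TreeNode:
        if not clade.clades:
            name = clade.name or ""
            sp = species_of.get(name) if species_of else None
            if species_of is not None and sp is None:
                raise KeyError(f"leaf {name!r} has no species mapping")
            return TreeNode(name=name, species=sp)
        return TreeNode(children=[convert(c) for c in clade.clades])

    return convert(tree.root)


def label_events(root: TreeNode) -> TreeNode:
    """Label internal nodes speciation/duplication by the species-overlap
    rule: duplication iff the species sets of at least two child subtrees
    intersect (generalized over all child pairs for multifurcations)."""

    def visit(node: TreeNode) -> set[str]:
        if node.is_leaf:
            node.event = None
            return {node.species} if node.species else set()
        child_sets = [visit(c) for c in node.children]
        dup = any(
            a & b for a, b in itertools.combinations(child_sets, 2)
        )
        node.event = Event.DUPLICATION if dup else Event.SPECIATION
        return set().union(*child_sets)

    visit(root)
    return root


def count_duplications(root: TreeNode) -> int:
    label_events(root)
    return sum(
        1
        for n in _iter_nodes(root)
        if n.event == Event.DUPLICATION
    )


def _iter_nodes(root: TreeNode):
    stack = [root]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


def _copy(node: TreeNode) -> TreeNode:
    return TreeNode(
        name=node.name,
        species=node.species,
        children=[_copy(c) for c in node.children],
    )


def _to_adjacency(root: TreeNode):
    """Undirected adjacency of the tree's topology, suppressing a degree-2
    root so the edge set is that of the unrooted tree.  Returns (payload per
    vertex, adjacency dict, deterministic edge list)."""
    payload: dict[int, TreeNode] = {}
    adj: dict[int, list[int]] = {}
    counter = itertools.count()

    def add(node: TreeNode) -> int:
        vid = next(counter)
        payload[vid] = node
        adj[vid] = []
        for c in node.children:
            cid = add(c)
            adj[vid].append(cid)
            adj[cid].append(vid)
        return vid

    root_id = add(root)
    if len(adj[root_id]) == 2:
        a, b = adj[root_id]
        adj[a] = [x if x != root_id else b for x in adj[a]]
        adj[b] = [x if x != root_id else a for x in adj[b]]
        del adj[root_id], payload[root_id]
    edges = []
    seen = set()
    for u in sorted(adj):
        for v in adj[u]:
            if (min(u, v), max(u, v)) not in seen:
                seen.add((min(u, v), max(u, v)))
                edges.append((u, v))
    return payload, adj, edges


def _orient(vid: int, parent: int | None, payload, adj) -> TreeNode:
    node = payload[vid]
    kids = [w for w in adj[vid] if w != parent]
    if not kids:
        return TreeNode(name=node.name, species=node.species)
    return TreeNode(
        name=node.name if node.is_leaf else None,
        species=node.species if node.is_leaf else None,
        children=[_orient(w, vid, payload, adj) for w in kids],
    )


def root_tree(tree: TreeNode) -> TreeNode:
    """Root an (effectively unrooted) gene tree on the edge that minimizes
    the duplication count under species-overlap labeling.

    Ties go to the edge splitting the leaves most evenly, then to the
    smallest edge index in a deterministic traversal.  The input's own root
    orientation is ignored; a degree-2 root is suppressed first.
    """
    payload, adj, edges = _to_adjacency(tree)
    if len(payload) == 1:
        only = next(iter(payload.values()))
        return label_events(_copy(only))
    best: tuple[int, int, int] | None = None
    best_tree: TreeNode | None = None
    for eidx, (u, v) in enumerate(edges):
        rooted = TreeNode(
            children=[_orient(u, v, payload, adj), _orient(v, u, payload, adj)]
        )
        ndup = count_duplications(rooted)
        left = len(rooted.children[0].leaves())
        right = len(rooted.children[1].leaves())
        key = (ndup, abs(left - right), eidx)
        if best is None or key < best:
            best, best_tree = key, rooted
    assert best_tree is not None
    return label_events(best_tree)


def extract_homologs(root: TreeNode, source: str = "tree") -> set[HomologyPair]:
    """Classify all leaf pairs of a labeled rooted tree.

    A pair whose LCA is a speciation node and whose species differ is an
    ortholog.  A same-species pair whose LCA subtree contains only that
    species is an in-paralog.  Everything else goes unreported.
    """
    if root.event is None and not root.is_leaf:
        label_events(root)
    pairs: set[HomologyPair] = set()

    def visit(node: TreeNode) -> list[TreeNode]:
        if node.is_leaf:
            return [node]
        child_leaves = [visit(c) for c in node.children]
        all_leaves = [lf for cl in child_leaves for lf in cl]
        single_species = len({lf.species for lf in all_leaves}) == 1
        for ca, cb in itertools.combinations(child_leaves, 2):
            for la in ca:
                for lb in cb:
                    if la.species != lb.species:
                        if node.event == Event.SPECIATION:
                            pairs.add(
                                HomologyPair(la.name, lb.name, Relation.ORTHOLOG, source)
                            )
                    elif single_species:
                        pairs.add(
                            HomologyPair(la.name, lb.name, Relation.IN_PARALOG, source)
                        )
        return all_leaves

    visit(root)
    return pairs


def prune_tree(root: TreeNode, keep_species: set[str]) -> TreeNode:
    """Restrict the tree to leaves of the given species, collapsing unary
    nodes and recomputing event labels."""

    def prune(node: TreeNode) -> TreeNode | None:
        if node.is_leaf:
            return (
                TreeNode(name=node.name, species=node.species)
                if node.species in keep_species
                else None
            )
        kids = [k for k in (prune(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        return TreeNode(children=kids)

    pruned = prune(root)
    if pruned is None:
        raise ValueError("pruning removed every leaf")
    return label_events(pruned)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Toy neighbor-joining fallback over a package distance matrix, for
    self-contained runs; external tree builders are the production path."""
    n = len(dm.ids)
    if n < 2:
        raise ValueError("neighbor joining needs >= 2 taxa")
    if n == 2:
        return TreeNode(
            children=[TreeNode(name=dm.ids[0]), TreeNode(name=dm.ids[1])]
        )
    lower = [[float(dm.d[i, j]) for j in range(i + 1)] for i in range(n)]
    bio_dm = _BioDM(names=list(dm.ids), matrix=lower)
    tree = DistanceTreeConstructor().nj(bio_dm)

    def convert(clade) -> TreeNode:
        if not clade.clades:
            return TreeNode(name=clade.name)
        return TreeNode(children=[convert(c) for c in clade.clades])

    return convert(tree.root)
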