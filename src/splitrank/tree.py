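"""Trees, splits, and the combinatorial statistics attached to them.

A phylogenetic tree on a taxon set ``X`` displays one split (bipartition
``A|B`` of ``X``) per edge.  Everything downstream of this module -- the
flattening and subflattening constructions and their rank-based split
scores -- is indexed by splits, so this module fixes the conventions once:

* taxa are plain strings, globally ordered lexicographically (an explicit
  order may be supplied where it matters);
* a :class:`Split` is canonicalised so that the side containing the
  globally smallest taxon is stored first;
* trees are unrooted, held as undirected ``networkx`` graphs whose
  degree-1 nodes are the taxon labels and whose internal nodes are
  integers.  Edges carry a ``length`` (expected substitutions per site)
  and optionally an explicit ``matrix`` (a row-stochastic Markov matrix).

Besides Newick I/O and split enumeration, the module provides the two
"how false is this split" statistics used to analyse split-score
behaviour: the split parsimony score (minimum number of state changes on
the tree for the two-state character induced by the split) and the
shared-edges count (edges common to the two minimal subtrees spanning the
two sides; zero exactly for displayed splits), plus the orbits of the
tree's automorphism group acting on splits.
"""

from __future__ import annotations

import io
import itertools
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import dendropy
import networkx as nx
import numpy as np

__all__ = [
    "Split",
    "PhyloTree",
    "parse_newick",
    "write_newick",
    "enumerate_splits",
    "splits_of_size",
    "displayed_splits",
    "is_compatible",
    "parsimony_score",
    "shared_edges",
    "automorphisms",
    "split_orbits",
    "random_binary_tree",
]


class Split:
    """A bipartition ``A|B`` of a taxon set.

    The side containing the globally smallest taxon (lexicographic) is
    stored as :attr:`side_a`.  Splits compare equal iff they induce the
    same bipartition, and sort by ``(size, sorted(side_a), sorted(side_b))``
    which gives the deterministic "by size then lexicographic" order used
    for enumeration and tie-breaking.
    """

    __slots__ = ("_a", "_b")

    def __init__(self, side_a: Iterable[str], side_b: Iterable[str]):
        a, b = frozenset(side_a), frozenset(side_b)
        if not a or not b:
            raise ValueError("both sides of a split must be non-empty")
        if a & b:
            raise ValueError(f"split sides overlap: {sorted(a & b)}")
        if min(a | b) in b:
            a, b = b, a
        self._a = a
        self._b = b

    @classmethod
    def from_string(cls, text: str, taxa: Sequence[str]) -> "Split":
        """Parse ``"014|235"`` (or one-sided shorthand ``"014"``).

        Single-character taxon labels are read character by character;
        otherwise sides must be comma-separated.  With the one-sided form
        the other side is the complement within *taxa*.
        """
        taxa_set = frozenset(taxa)
        single = all(len(t) == 1 for t in taxa_set)

        def read_side(part: str) -> frozenset:
            labels = list(part) if (single and "," not in part) else [
                p.strip() for p in part.split(",") if p.strip()
            ]
            unknown = set(labels) - taxa_set
            if unknown:
                raise ValueError(f"unknown taxa in split text: {sorted(unknown)}")
            return frozenset(labels)

        if "|" in text:
            left, right = text.split("|", 1)
            a, b = read_side(left), read_side(right)
            if a | b != taxa_set:
                raise ValueError("split sides do not cover the taxon set")
            return cls(a, b)
        a = read_side(text)
        return cls(a, taxa_set - a)

    @property
    def side_a(self) -> frozenset:
        return self._a

    @property
    def side_b(self) -> frozenset:
        return self._b

    @property
    def taxa(self) -> tuple:
        return tuple(sorted(self._a | self._b))

    @property
    def size(self) -> int:
        """Size of the smaller side; a measure of the split's balance."""
        return min(len(self._a), len(self._b))

    @property
    def is_trivial(self) -> bool:
        return self.size == 1

    def sides(self) -> tuple[tuple, tuple]:
        return tuple(sorted(self._a)), tuple(sorted(self._b))

    def apply_permutation(self, perm: Mapping[str, str]) -> "Split":
        return Split({perm[x] for x in self._a}, {perm[x] for x in self._b})

    def sort_key(self):
        return (self.size, tuple(sorted(self._a)), tuple(sorted(self._b)))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Split)
            and self._a == other._a
            and self._b == other._b
        )

    def __hash__(self) -> int:
        return hash((self._a, self._b))

    def __lt__(self, other: "Split") -> bool:
        return self.sort_key() < other.sort_key()

    def __str__(self) -> str:
        a, b = self.sides()
        join = "" if all(len(t) == 1 for t in a + b) else ","
        return f"{join.join(a)}|{join.join(b)}"

    def __repr__(self) -> str:
        return f"Split({str(self)!r})"


class PhyloTree:
    """Unrooted leaf-labelled tree with branch lengths and edge matrices.

    Parameters
    ----------
    graph:
        Undirected tree whose degree-1 nodes are taxon labels (strings)
        and whose internal nodes are integers.  Edge attribute ``length``
        (default 0.0) is the branch length in expected substitutions per
        site; optional attribute ``matrix`` pins an explicit row-stochastic
        transition matrix to the edge.
    k:
        State-space size (4 for DNA, 2 for the binary examples).
    root_distribution:
        Length-``k`` probability vector for the state at an (arbitrary)
        root; defaults to uniform.
    """

    def __init__(self, graph: nx.Graph, k: int = 4, root_distribution=None):
        if not nx.is_tree(graph):
            raise ValueError("graph must be a tree")
        leaves = [n for n in graph.nodes if graph.degree(n) <= 1]
        if graph.number_of_nodes() == 2:
            leaves = list(graph.nodes)
        if not all(isinstance(n, str) for n in leaves):
            raise ValueError("leaf nodes must be string taxon labels")
        if len(set(leaves)) != len(leaves):
            raise ValueError("duplicate leaf labels")
        for u, v, d in graph.edges(data=True):
            length = d.setdefault("length", 0.0)
            if length < 0:
                raise ValueError(f"negative branch length on edge ({u}, {v})")
        if root_distribution is None:
            root_distribution = np.full(k, 1.0 / k)
        pi = np.asarray(root_distribution, dtype=float)
        if pi.shape != (k,) or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("root distribution must be a length-k probability vector")
        self.graph = graph
        self.k = int(k)
        self.root_distribution = pi
        self._taxa = tuple(sorted(leaves))

    @property
    def taxa(self) -> tuple:
        return self._taxa

    @property
    def n_taxa(self) -> int:
        return len(self._taxa)

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.graph.copy(), self.k, self.root_distribution.copy())

    def is_leaf(self, node) -> bool:
        return node in set(self._taxa)

    def internal_nodes(self) -> list:
        leaf_set = set(self._taxa)
        return [n for n in self.graph.nodes if n not in leaf_set]

    def set_all_lengths(self, length: float) -> "PhyloTree":
        for _, _, d in self.graph.edges(data=True):
            d["length"] = float(length)
            d.pop("matrix", None)
        return self

    def set_lengths(self, lengths: Callable[[], float]) -> "PhyloTree":
        """Assign each edge a length drawn from the callable *lengths*."""
        for _, _, d in self.graph.edges(data=True):
            d["length"] = float(lengths())
            d.pop("matrix", None)
        return self

    def edge_matrix(self, u, v) -> np.ndarray:
        """Transition matrix for edge (u, v); Jukes-Cantor from the length
        when no explicit matrix was assigned."""
        from .models import jc_matrix  # local import avoids a cycle

        d = self.graph.edges[u, v]
        if d.get("matrix") is not None:
            m = np.asarray(d["matrix"], dtype=float)
            if m.shape != (self.k, self.k):
                raise ValueError(f"edge ({u}, {v}) matrix has wrong shape {m.shape}")
            return m
        return jc_matrix(d.get("length", 0.0), self.k)

    def leaf_side(self, u, v) -> frozenset:
        """Taxa on the *u* side of edge (u, v)."""
        g = self.graph.copy()
        g.remove_edge(u, v)
        comp = nx.node_connected_component(g, u)
        return frozenset(x for x in comp if x in set(self._taxa))

    def split_of_edge(self, u, v) -> Split:
        side = self.leaf_side(u, v)
        return Split(side, frozenset(self._taxa) - side)

    def displayed_splits(self) -> set:
        """One split per edge; trivial splits included."""
        return {self.split_of_edge(u, v) for u, v in self.graph.edges}

    def newick(self) -> str:
        return write_newick(self)

    def __repr__(self) -> str:
        return f"PhyloTree(taxa={self._taxa}, k={self.k})"


# ---------------------------------------------------------------------------
# Newick I/O (parsing delegated to dendropy; unrooted convention)


def parse_newick(text: str, k: int = 4, root_distribution=None) -> PhyloTree:
    """Parse a Newick string into an unrooted :class:`PhyloTree`.

    Branch lengths default to 0.  A degree-2 root (rooted input) is
    suppressed by fusing its two incident edges, so rooted and unrooted
    writings of the same tree parse identically.  Quoted labels are not
    part of the supported dialect.
    """
    if "'" in text or '"' in text:
        raise ValueError("quoted Newick labels are not supported")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"malformed Newick string: {exc}") from exc

    g = nx.Graph()
    counter = itertools.count()
    node_id: dict = {}

    def ident(node):
        if node not in node_id:
            if node.is_leaf():
                if node.taxon is None or not node.taxon.label:
                    raise ValueError("leaf without a label in Newick string")
                node_id[node] = str(node.taxon.label)
            else:
                node_id[node] = next(counter)
        return node_id[node]

    labels = [str(lf.taxon.label) for lf in dtree.leaf_node_iter() if lf.taxon]
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate leaf labels: {dupes}")

    for node in dtree.preorder_node_iter():
        u = ident(node)
        for child in node.child_nodes():
            v = ident(child)
            length = child.edge.length if child.edge.length is not None else 0.0
            g.add_edge(u, v, length=float(length))
    if g.number_of_nodes() == 0:
        raise ValueError("empty Newick string")

    # suppress a degree-2 root left over from a rooted writing
    root = ident(dtree.seed_node)
    if g.degree(root) == 2 and not isinstance(root, str):
        (a, da), (b, db) = [(n, g.edges[root, n]["length"]) for n in g.neighbors(root)]
        g.remove_node(root)
        g.add_edge(a, b, length=da + db)

    return PhyloTree(g, k=k, root_distribution=root_distribution)


def write_newick(tree: PhyloTree) -> str:
    """Write an unrooted tree rooted at an arbitrary internal node."""
    g = tree.graph
    internals = tree.internal_nodes()
    root = internals[0] if internals else tree.taxa[0]

    def fmt(node, parent) -> str:
        children = [n for n in g.neighbors(node) if n != parent]
        if not children:
            return str(node)
        inner = ",".join(
            f"{fmt(c, node)}:{g.edges[node, c]['length']:g}" for c in children
        )
        return f"({inner})"

    return fmt(root, None) + ";"


# ---------------------------------------------------------------------------
# Split enumeration and tests


def enumerate_splits(taxa: Sequence[str]) -> list:
    """All ``2^(t-1) - 1`` splits of *taxa*, sorted by size then
    lexicographically."""
    taxa = tuple(sorted(set(taxa)))
    t = len(taxa)
    if t < 2:
        raise ValueError("need at least 2 taxa to form a split")
    first, rest = taxa[0], taxa[1:]
    out = []
    for r in range(len(rest)):
        for combo in itertools.combinations(rest, r):
            side_a = frozenset((first,) + combo)
            out.append(Split(side_a, frozenset(taxa) - side_a))
    out.sort()
    return out


def splits_of_size(taxa: Sequence[str], m: int) -> Iterator[Split]:
    """All splits of *taxa* whose smaller side has exactly *m* taxa.

    There are ``C(t, m)`` of them (halved when ``2m = t`` since ``A|B``
    equals ``B|A``)."""
    taxa = tuple(sorted(set(taxa)))
    t = len(taxa)
    if not 1 <= m <= t // 2:
        raise ValueError(f"split size must be in [1, {t // 2}]")
    full = frozenset(taxa)
    for combo in itertools.combinations(taxa, m):
        if 2 * m == t and taxa[0] not in combo:
            continue  # avoid double counting A|B and B|A
        yield Split(frozenset(combo), full - frozenset(combo))


def displayed_splits(tree: PhyloTree) -> set:
    return tree.displayed_splits()


def is_compatible(s1: Split, s2: Split) -> bool:
    """True iff some tree displays both splits: at least one of the four
    pairwise side intersections is empty."""
    if frozenset(s1.taxa) != frozenset(s2.taxa):
        raise ValueError("splits are on different taxon sets")
    a1, b1, a2, b2 = s1.side_a, s1.side_b, s2.side_a, s2.side_b
    return not (a1 & a2) or not (a1 & b2) or not (b1 & a2) or not (b1 & b2)


# ---------------------------------------------------------------------------
# Split statistics on a tree


def _check_split_on_tree(tree: PhyloTree, split: Split) -> None:
    if frozenset(split.taxa) != frozenset(tree.taxa):
        raise ValueError("split is not over the tree's taxa")


def parsimony_score(tree: PhyloTree, split: Split) -> int:
    """Minimum number of state changes on the tree for the binary character
    assigning one state to ``A`` and another to ``B``.

    Unit-cost Sankoff dynamic programme over an arbitrary rooting; exact
    for any node degrees (so star trees are fine), and independent of the
    root placement.  Equals 1 exactly when the split is displayed.
    """
    _check_split_on_tree(tree, split)
    g = tree.graph
    internals = tree.internal_nodes()
    root = internals[0] if internals else tree.taxa[0]
    INF = float("inf")
    leaf_state = {x: 0 for x in split.side_a}
    leaf_state.update({x: 1 for x in split.side_b})

    cost: dict = {}
    parent = {c: p for p, c in nx.bfs_edges(g, root)}
    for node in nx.dfs_postorder_nodes(g, root):
        if node != root and g.degree(node) == 1:
            s = leaf_state[node]
            cost[node] = np.array([0.0, INF]) if s == 0 else np.array([INF, 0.0])
            continue
        c = np.zeros(2)
        for child in g.neighbors(node):
            if parent.get(child) != node:
                continue
            cc = cost[child]
            c += np.minimum(cc, cc.min() + 1.0)
        if node in leaf_state:  # root of a two-taxon tree is itself a leaf
            c[1 - leaf_state[node]] = INF
        cost[node] = c
    return int(cost[root].min())


def _spanning_edges(tree: PhyloTree, side: frozenset) -> set:
    """Edges of the minimal subtree connecting the taxa in *side*."""
    edges = set()
    for u, v in tree.graph.edges:
        part = tree.leaf_side(u, v)
        if (side & part) and (side - part):
            edges.add(frozenset((u, v)))
    return edges


def shared_edges(tree: PhyloTree, split: Split) -> int:
    """Number of edges common to the minimal subtrees spanning the two
    sides of the split; 0 iff the split is displayed."""
    _check_split_on_tree(tree, split)
    return len(_spanning_edges(tree, split.side_a) & _spanning_edges(tree, split.side_b))


# ---------------------------------------------------------------------------
# Automorphisms and orbits


def automorphisms(tree: PhyloTree) -> list:
    """All leaf permutations induced by automorphisms of the tree shape.

    Branch lengths are ignored: orbits are a property of the unweighted
    topology.  Automorphisms are enumerated as self-isomorphisms of the
    underlying graph; on a tree each one restricts to a unique leaf
    permutation, returned as a dict ``{label: label}``.
    """
    g = tree.graph
    leaf_set = set(tree.taxa)
    matcher = nx.algorithms.isomorphism.GraphMatcher(g, g)
    perms = []
    seen = set()
    for mapping in matcher.isomorphisms_iter():
        perm = {x: mapping[x] for x in leaf_set}
        key = tuple(sorted(perm.items()))
        if key not in seen:
            seen.add(key)
            perms.append(perm)
    return perms


def split_orbits(tree: PhyloTree) -> list:
    """Partition of all splits of the tree's taxa into orbits of the
    automorphism-group action.  Orbits are sorted lists of splits, ordered
    by their smallest member."""
    splits = enumerate_splits(tree.taxa)
    perms = automorphisms(tree)
    remaining = set(splits)
    orbits = []
    for s in splits:
        if s not in remaining:
            continue
        orbit = {s.apply_permutation(p) for p in perms}
        remaining -= orbit
        orbits.append(sorted(orbit))
    orbits.sort(key=lambda orb: orb[0].sort_key())
    return orbits


# ---------------------------------------------------------------------------
# Random trees (uniform sequential leaf addition)


def random_binary_tree(
    taxa: Sequence[str],
    rng: np.random.Generator,
    branch_lengths: Callable[[], float] | float = 0.1,
    k: int = 4,
) -> PhyloTree:
    """Random unrooted binary tree built by attaching leaves to uniformly
    chosen edges.  *branch_lengths* is a constant or a zero-argument
    callable sampled per edge."""
    taxa = tuple(sorted(set(taxa)))
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa for a binary tree")
    g = nx.Graph()
    centre = 0
    counter = itertools.count(1)
    for x in taxa[:3]:
        g.add_edge(centre, x)
    for x in taxa[3:]:
        u, v = list(g.edges)[rng.integers(g.number_of_edges())]
        w = next(counter)
        g.remove_edge(u, v)
        g.add_edge(u, w)
        g.add_edge(w, v)
        g.add_edge(w, x)
    draw = branch_lengths if callable(branch_lengths) else (lambda: branch_lengths)
    for _, _, d in g.edges(data=True):
        d["length"] = float(draw())
    return PhyloTree(g, k=k)
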