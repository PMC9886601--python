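"""Markov substitution models, exact site-pattern distributions, and
sequence simulation.

Site patterns are length-``t`` tuples of integer states (``0..k-1``; for
DNA the state order is A, C, G, T), held sparsely as dictionaries keyed
by pattern.  :func:`site_pattern_distribution` computes the exact joint
distribution of leaf states on a tree by a post-order conditional-
likelihood recursion; :func:`simulate_pattern_counts` draws a multinomial
sample from such a distribution, and :func:`simulate_alignment_counts`
simulates site-by-site down the tree for taxon counts too large for the
exact distribution to be materialised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

STATE_ORDERS = {4: "ACGT", 2: "01"}

__all__ = [
    "PatternCounts",
    "PatternDistribution",
    "jc_matrix",
    "validate_markov",
    "site_pattern_distribution",
    "simulate_pattern_counts",
    "simulate_alignment_counts",
    "counts_from_alignment",
]


def jc_matrix(branch_length: float, k: int = 4) -> np.ndarray:
    """Jukes-Cantor transition matrix for a branch of the given length.

    The length is the expected number of substitutions per site under the
    unit-rate normalisation, so the off-diagonal entries are
    ``(1/k) (1 - exp(-k d / (k-1)))``.
    """
    if branch_length < 0:
        raise ValueError("branch length must be non-negative")
    if k < 2:
        raise ValueError("state space must have at least 2 states")
    off = (1.0 - np.exp(-k * branch_length / (k - 1))) / k
    m = np.full((k, k), off)
    np.fill_diagonal(m, 1.0 - (k - 1) * off)
    return m


def validate_markov(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("Markov matrix must be square")
    if np.any(m < -1e-12) or np.any(m > 1 + 1e-12):
        raise ValueError("Markov matrix entries must lie in [0, 1]")
    if np.max(np.abs(m.sum(axis=1) - 1.0)) > 1e-12:
        raise ValueError("Markov matrix rows must sum to 1")
    return m


def _pattern_string(pattern: tuple, k: int) -> str:
    alphabet = STATE_ORDERS.get(k)
    if alphabet:
        return "".join(alphabet[s] for s in pattern)
    return ",".join(str(s) for s in pattern)


def _pattern_from_string(text: str, k: int) -> tuple:
    alphabet = STATE_ORDERS.get(k)
    if alphabet and "," not in text:
        return tuple(alphabet.index(c) for c in text)
    return tuple(int(p) for p in text.split(","))


class _PatternData:
    """Shared behaviour of sparse pattern-indexed tables."""

    data: dict
    taxon_order: tuple
    k: int

    @property
    def t(self) -> int:
        return len(self.taxon_order)

    @property
    def total(self) -> float:
        return sum(self.data.values())

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Distinct patterns as an ``(n, t)`` int array plus their weights."""
        if not self.data:
            return np.empty((0, self.t), dtype=np.int64), np.empty(0)
        pats = np.array(list(self.data.keys()), dtype=np.int64)
        w = np.array(list(self.data.values()), dtype=float)
        return pats, w

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["pattern", "count"])
            for pat in sorted(self.data):
                writer.writerow([_pattern_string(pat, self.k), self.data[pat]])

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class PatternCounts(_PatternData):
    """Observed site-pattern counts from an alignment of length ``L``."""

    data: dict
    taxon_order: tuple
    k: int = 4
    dropped_columns: int = 0

    def __post_init__(self):
        self.taxon_order = tuple(self.taxon_order)
        if any(c < 0 for c in self.data.values()):
            raise ValueError("pattern counts must be non-negative")
        for pat in self.data:
            if len(pat) != self.t or not all(0 <= s < self.k for s in pat):
                raise ValueError(f"bad pattern {pat} for t={self.t}, k={self.k}")

    @property
    def L(self) -> int:
        return int(round(self.total))

    def normalise(self) -> "PatternDistribution":
        L = self.total
        if L <= 0:
            raise ValueError("cannot normalise empty counts")
        return PatternDistribution(
            {p: c / L for p, c in self.data.items()}, self.taxon_order, self.k
        )

    @classmethod
    def from_csv(cls, path, taxon_order, k: int = 4) -> "PatternCounts":
        import csv

        data = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                data[_pattern_from_string(row["pattern"], k)] = float(row["count"])
        return cls(data, tuple(taxon_order), k)


@dataclass
class PatternDistribution(_PatternData):
    """Exact (or empirical) site-pattern probability distribution."""

    data: dict
    taxon_order: tuple
    k: int = 4

    def __post_init__(self):
        self.taxon_order = tuple(self.taxon_order)
        if any(p < -1e-12 for p in self.data.values()):
            raise ValueError("probabilities must be non-negative")
        if abs(self.total - 1.0) > 1e-10:
            raise ValueError(f"probabilities sum to {self.total:.12f}, not 1")


# ---------------------------------------------------------------------------
# Exact distributions on trees

_MAX_DENSE_PATTERNS = 4**10


def site_pattern_distribution(tree) -> PatternDistribution:
    """Exact joint distribution of leaf states under the tree's model.

    Each edge contributes its assigned Markov matrix (or Jukes-Cantor
    from its length); the root state follows ``tree.root_distribution``.
    Computed by the standard conditional-likelihood recursion; on quartet
    trees this agrees with the Kronecker-product formulation of applying
    pendant-edge matrices to the leaves.  Only nonzero patterns are stored,
    so trees with zero-length pendant edges stay sparse.
    """
    import networkx as nx

    k, g = tree.k, tree.graph
    t = tree.n_taxa
    if k**t > _MAX_DENSE_PATTERNS:
        raise ValueError(
            f"k^t = {k**t} patterns is too large for an exact distribution; "
            "simulate with simulate_alignment_counts instead"
        )
    internals = tree.internal_nodes()
    root = internals[0] if internals else tree.taxa[0]
    leaf_set = set(tree.taxa)

    def combine_children(node, parent):
        """Array (k, k^m): P(leaf patterns below | state at node)."""
        arr = np.ones((k, 1))
        leaves: list = []
        for child in g.neighbors(node):
            if child == parent:
                continue
            sub_leaves, b = below(child, node)
            leaves.extend(sub_leaves)
            arr = (arr[:, :, None] * b[:, None, :]).reshape(k, -1)
        return leaves, arr

    def below(node, parent):
        m = tree.edge_matrix(parent, node)
        if node in leaf_set and g.degree(node) == 1:
            return [node], m
        leaves, arr = combine_children(node, parent)
        return leaves, m @ arr

    if root in leaf_set:  # two-taxon tree rooted at a leaf
        leaves, arr = combine_children(root, None)
        leaves = [root] + leaves
        probs = (tree.root_distribution[:, None] * arr).reshape(-1)
    else:
        leaves, arr = combine_children(root, None)
        probs = tree.root_distribution @ arr

    # reorder pattern axes from traversal order to sorted taxon order
    perm = [leaves.index(x) for x in tree.taxa]
    tensor = probs.reshape((k,) * t).transpose(perm)
    flat = tensor.reshape(-1)
    nz = np.nonzero(flat)[0]
    data = {}
    for idx in nz:
        pat = tuple((idx // k ** (t - 1 - j)) % k for j in range(t))
        data[pat] = float(flat[idx])
    return PatternDistribution(data, tree.taxa, k)


# ---------------------------------------------------------------------------
# Simulation


def simulate_pattern_counts(
    dist: PatternDistribution, L: int, seed
) -> PatternCounts:
    """One multinomial draw of ``L`` sites from the distribution.

    *seed* may be an integer, a seed sequence, or a ``numpy`` Generator.
    """
    if L <= 0:
        raise ValueError("sequence length must be positive")
    rng = np.random.default_rng(seed)
    pats, w = dist.as_arrays()
    draws = rng.multinomial(L, w / w.sum())
    data = {
        tuple(pats[i]): int(c) for i, c in enumerate(draws) if c > 0
    }
    return PatternCounts(data, dist.taxon_order, dist.k)


def simulate_alignment_counts(tree, L: int, seed) -> PatternCounts:
    """Simulate an ``L``-site alignment down the tree and count patterns.

    Draws the root state per site from the root distribution and
    propagates along each edge with its transition matrix; equivalent in
    distribution to a multinomial draw from the exact site-pattern
    distribution, but usable for taxon counts where the ``k^t`` exact
    table cannot be built.
    """
    import networkx as nx

    if L <= 0:
        raise ValueError("sequence length must be positive")
    rng = np.random.default_rng(seed)
    k, g = tree.k, tree.graph
    internals = tree.internal_nodes()
    root = internals[0] if internals else tree.taxa[0]
    states = {root: rng.choice(k, size=L, p=tree.root_distribution)}
    for parent, child in nx.bfs_edges(g, root):
        cum = np.cumsum(tree.edge_matrix(parent, child), axis=1)
        u = rng.random(L)
        states[child] = (u[:, None] >= cum[states[parent]]).sum(axis=1)
    cols = np.stack([states[x] for x in tree.taxa], axis=1)
    pats, counts = np.unique(cols, axis=0, return_counts=True)
    data = {tuple(p): int(c) for p, c in zip(pats, counts)}
    return PatternCounts(data, tree.taxa, k)


# ---------------------------------------------------------------------------
# Alignments


def counts_from_alignment(path, k: int = 4, taxon_order=None) -> PatternCounts:
    """Site-pattern counts from a FASTA alignment.

    Sequences must be equal length over A, C, G, T plus gap/ambiguity
    symbols; any column containing a non-ACGT symbol is dropped and the
    number of dropped columns is logged (and recorded on the result).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences found in {path}")
    names = [r.id for r in records]
    if len(set(names)) != len(names):
        raise ValueError("duplicate sequence identifiers in alignment")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    if taxon_order is None:
        taxon_order = tuple(sorted(names))
    else:
        taxon_order = tuple(taxon_order)
        if set(taxon_order) != set(names):
            raise ValueError("taxon_order does not match alignment identifiers")
    seqs = {r.id: str(r.seq).upper() for r in records}
    alphabet = STATE_ORDERS[k]
    lookup = np.full(256, -1, dtype=np.int64)
    for i, c in enumerate(alphabet):
        lookup[ord(c)] = i
    mat = np.stack(
        [lookup[np.frombuffer(seqs[x].encode(), dtype=np.uint8)] for x in taxon_order]
    )
    good = np.all(mat >= 0, axis=0)
    dropped = int((~good).sum())
    if dropped:
        logger.info("dropped %d columns containing non-ACGT symbols", dropped)
    cols = mat[:, good].T
    if cols.shape[0] == 0:
        raise ValueError("no usable columns in alignment")
    pats, counts = np.unique(cols, axis=0, return_counts=True)
    data = {tuple(p): int(c) for p, c in zip(pats, counts)}
    return PatternCounts(data, taxon_order, k, dropped_columns=dropped)
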