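"""Subflattening matrices: the dense, low-dimensional alternative to
flattenings.

Conjugating every axis of the site-pattern tensor by a Hadamard-type
matrix ``H`` (first row all ones, every other row summing to zero) turns
each row-stochastic Markov matrix ``M`` into ``H M H^{-1}`` of the form
``[[1, v], [0, z]]``.  All substitution information then lives in the
rows/columns of the transformed flattening whose index tuples have at
most one non-trivial (nonzero) transformed coordinate, so that submatrix
-- the subflattening -- of shape ``(|A|(k-1)+1) x (|B|(k-1)+1)`` can
replace the ``k^|A| x k^|B|`` flattening.  It has generic rank ``k`` for
displayed splits and ``(k-1) p + 1`` otherwise (``p`` the split parsimony
score).

Row/column layout: index 0 is the all-trivial component (entry ``(0, 0)``
is the total weight); row ``r = (k-1) a + j`` (``j`` in ``1..k-1``)
applies row ``j`` of ``H`` to the ``a``-th taxon of side ``A`` in global
order and the trivial all-ones row of ``H`` to every other taxon, and
likewise for columns.

Each subflattening entry is a sum over observed patterns of at most two
non-trivial ``H`` coefficients, so construction is
``O(distinct patterns x output size)`` and never touches the ``k^t``
tensor.  The per-state coefficient columns of ``H`` are memoised in a
process-wide cache keyed by ``(H, state)`` and reused across splits and
datasets.  :func:`subflattening_oracle` builds the full transformed
flattening and extracts the submatrix directly; it exists to cross-check
the fast path on small inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce

import numpy as np

from .flattening import flattening
from .tree import Split

__all__ = [
    "transform_matrix",
    "validate_transform",
    "transformed_distribution",
    "Subflattening",
    "subflattening",
    "subflattening_oracle",
]

_H2 = np.array([[1.0, 1.0], [1.0, -1.0]])


def transform_matrix(k: int) -> np.ndarray:
    """The similarity transform used to build subflattenings.

    For ``k = 2`` this is the Hadamard matrix ``[[1, 1], [1, -1]]``; for
    powers of two, its Kronecker powers (so ``k = 4`` uses the two-fold
    Kronecker square).  For other ``k`` a non-orthogonal matrix with the
    required structure (first row ones, remaining rows ``e_0 - e_i``) is
    returned.  Any invertible matrix whose first row is all ones and whose
    other rows sum to zero works.
    """
    if k < 2:
        raise ValueError("state space must have at least 2 states")
    if k & (k - 1) == 0:  # power of two
        h = _H2
        while h.shape[0] < k:
            h = np.kron(h, _H2)
        return h
    h = np.zeros((k, k))
    h[0] = 1.0
    for i in range(1, k):
        h[i, 0] = 1.0
        h[i, i] = -1.0
    return h


def validate_transform(H: np.ndarray) -> np.ndarray:
    H = np.asarray(H, dtype=float)
    k = H.shape[0]
    if H.shape != (k, k):
        raise ValueError("transform must be square")
    if np.max(np.abs(H[0] - 1.0)) > 1e-12:
        raise ValueError("first row of the transform must be all ones")
    if k > 1 and np.max(np.abs(H[1:].sum(axis=1))) > 1e-12:
        raise ValueError("rows 1..k-1 of the transform must sum to zero")
    if abs(np.linalg.det(H)) < 1e-12:
        raise ValueError("transform must be invertible")
    return H


def transformed_distribution(dist, H: np.ndarray | None = None) -> np.ndarray:
    """Dense ``t``-fold tensor action of ``H`` on a pattern distribution.

    Returns the transformed tensor with shape ``(k,) * t`` (axes in the
    distribution's taxon order).  Invertible: applying the same routine
    with ``H^{-1}`` recovers the original tensor.
    """
    k, t = dist.k, dist.t
    H = transform_matrix(k) if H is None else validate_transform(H)
    if k**t > 4**10:
        raise ValueError("distribution too large for a dense transform")
    tensor = np.zeros((k,) * t)
    for pat, w in dist.data.items():
        tensor[pat] += w
    for axis in range(t):
        tensor = np.moveaxis(np.tensordot(H, tensor, axes=([1], [axis])), 0, axis)
    return tensor


@dataclass
class Subflattening:
    """Dense subflattening for one split; see module docstring for the
    row/column layout."""

    split: Split
    matrix: np.ndarray
    row_taxa: tuple
    col_taxa: tuple
    k: int

    @property
    def shape(self) -> tuple:
        return self.matrix.shape

    def to_csv(self, path) -> None:
        np.savetxt(path, self.matrix, delimiter=",")


# process-wide memoisation of H coefficient columns, keyed by (k, H bytes,
# state); reused across splits and datasets
_COEFF_CACHE: dict = {}


def _h_column(H: np.ndarray, state: int, memoize: bool) -> np.ndarray:
    if not memoize:
        return H[:, state]
    key = (H.shape[0], H.tobytes(), state)
    col = _COEFF_CACHE.get(key)
    if col is None:
        col = H[:, state].copy()
        col.flags.writeable = False
        _COEFF_CACHE[key] = col
    return col


def _side_matrix(H, patterns, positions, memoize) -> np.ndarray:
    """Rows of coefficients for one side: shape (1 + m(k-1), n_patterns).

    Row 0 is all ones (the trivial component); the block for the ``a``-th
    taxon holds ``H[1:, state]`` looked up per pattern.
    """
    k = H.shape[0]
    n = patterns.shape[0]
    cols = np.stack([_h_column(H, s, memoize) for s in range(k)], axis=1)
    out = np.empty((1 + len(positions) * (k - 1), n))
    out[0] = 1.0
    for a, p in enumerate(positions):
        out[1 + a * (k - 1) : 1 + (a + 1) * (k - 1)] = cols[1:, patterns[:, p]]
    return out


def subflattening(
    data, split: Split, H: np.ndarray | None = None, memoize: bool = True
) -> Subflattening:
    """Build the subflattening of a pattern table for a split.

    Works directly from the sparse pattern table: entry ``(r, c)`` is the
    weighted sum over patterns of the ``H`` coefficient for the row index
    times the one for the column index (all other taxa contribute the
    trivial all-ones row).  ``memoize=False`` bypasses the coefficient
    cache; the result is identical.
    """
    k = data.k
    H = transform_matrix(k) if H is None else validate_transform(H)
    if frozenset(split.taxa) != frozenset(data.taxon_order):
        raise ValueError("split is not over the data's taxa")
    pos = {x: i for i, x in enumerate(data.taxon_order)}
    rows = tuple(sorted(split.side_a))
    cols = tuple(sorted(split.side_b))
    pats, w = data.as_arrays()
    ma = _side_matrix(H, pats, [pos[x] for x in rows], memoize)
    mb = _side_matrix(H, pats, [pos[x] for x in cols], memoize)
    mat = (ma * w) @ mb.T
    return Subflattening(split, mat, rows, cols, k)


def subflattening_oracle(
    data, split: Split, H: np.ndarray | None = None
) -> Subflattening:
    """Reference construction via the full transformed flattening.

    Builds ``(H (x) ... (x) H) Flat_{A|B} (H (x) ... (x) H)^T`` densely
    and extracts the rows/columns whose base-k index tuples have at most
    one nonzero coordinate, in the same order as the fast path.  Intended
    for testing on small taxon counts only.
    """
    k = data.k
    H = transform_matrix(k) if H is None else validate_transform(H)
    if k**data.t > 4**8:
        raise ValueError("oracle construction is restricted to small inputs")
    flat = flattening(data, split)
    ha = reduce(np.kron, [H] * len(flat.row_taxa))
    hb = reduce(np.kron, [H] * len(flat.col_taxa))
    full = ha @ flat.dense() @ hb.T

    def selection(m: int) -> list:
        idx = [0]
        for a in range(m):
            for j in range(1, k):
                idx.append(j * k ** (m - 1 - a))
        return idx

    sel_r = selection(len(flat.row_taxa))
    sel_c = selection(len(flat.col_taxa))
    return Subflattening(
        split, full[np.ix_(sel_r, sel_c)], flat.row_taxa, flat.col_taxa, k
    )
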