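"""Flattening matrices and their rank machinery.

For a split ``A|B`` of ``t`` taxa and state space of size ``k``, the
flattening of a site-pattern table is the ``k^|A| x k^|B|`` matrix whose
``(I, J)`` entry is the weight (count or probability) of the full pattern
obtained by interleaving the sub-pattern ``I`` on ``A`` with ``J`` on
``B``.  Row and column indices use base-``k`` positional encoding with
the taxa of each side in global (sorted) order, first taxon most
significant.  For a split displayed by the generating tree the flattening
has generic rank ``k``; for a non-displayed split the generic rank is
``k^p`` where ``p`` is the split's parsimony score on the tree.

Flattenings are stored sparsely (one nonzero per distinct observed
pattern), which is what makes them usable beyond a handful of taxa: the
dense entry count is ``4^t`` while the number of nonzeros is at most the
number of distinct site patterns, itself at most the sequence length.
:func:`expected_nonzeros` quantifies this in the worst (uniform) case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import reduce

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg

from .tree import Split

__all__ = [
    "Flattening",
    "flattening",
    "apply_pendant_action",
    "singular_values",
    "numerical_rank",
    "expected_nonzeros",
    "break_even_length",
]

_MAX_DENSE_ENTRIES = 4**12  # largest entry count we will densify


@dataclass
class Flattening:
    """Sparse flattening matrix for one split.

    ``row_taxa``/``col_taxa`` record the axis conventions: the row index
    encodes the sub-pattern on ``row_taxa`` (global order, first taxon
    most significant, base-k), and likewise for columns.
    """

    split: Split
    matrix: sp.spmatrix
    row_taxa: tuple
    col_taxa: tuple
    k: int

    @property
    def shape(self) -> tuple:
        return self.matrix.shape

    def dense(self) -> np.ndarray:
        if self.shape[0] * self.shape[1] > _MAX_DENSE_ENTRIES:
            raise ValueError(f"refusing to densify a {self.shape} flattening")
        return self.matrix.toarray()

    def transpose(self) -> "Flattening":
        mat = self.matrix.T
        if max(mat.shape) <= 4**8:
            mat = mat.tocsr()
        return Flattening(self.split, mat, self.col_taxa, self.row_taxa, self.k)

    def to_coordinate_text(self, path) -> None:
        """MatrixMarket-style coordinate export for debugging."""
        coo = self.matrix.tocoo()
        with open(path, "w") as fh:
            fh.write("%%MatrixMarket matrix coordinate real general\n")
            fh.write(f"{self.shape[0]} {self.shape[1]} {coo.nnz}\n")
            for i, j, v in zip(coo.row, coo.col, coo.data):
                fh.write(f"{i + 1} {j + 1} {v:.17g}\n")


def _side_positions(data, split: Split) -> tuple:
    order = data.taxon_order
    if frozenset(split.taxa) != frozenset(order):
        raise ValueError("split is not over the data's taxa")
    pos = {x: i for i, x in enumerate(order)}
    rows = tuple(sorted(split.side_a))
    cols = tuple(sorted(split.side_b))
    return rows, cols, [pos[x] for x in rows], [pos[x] for x in cols]


def _encode(patterns: np.ndarray, positions, k: int) -> np.ndarray:
    """Base-k index of the sub-pattern at the given taxon positions."""
    idx = np.zeros(patterns.shape[0], dtype=np.int64)
    for p in positions:
        idx = idx * k + patterns[:, p]
    return idx


def flattening(data, split: Split) -> Flattening:
    """Build the sparse flattening of a pattern table for a split.

    Stored in CSR form at ordinary sizes; kept in coordinate form when a
    side dimension is so large that even a CSR row-pointer array would
    not fit (row/column index arrays scale only with the nonzero count).
    """
    k = data.k
    rows, cols, rpos, cpos = _side_positions(data, split)
    pats, w = data.as_arrays()
    i = _encode(pats, rpos, k)
    j = _encode(pats, cpos, k)
    shape = (k ** len(rows), k ** len(cols))
    mat = sp.coo_matrix((w, (i, j)), shape=shape)
    if max(shape) <= 4**8:
        mat = mat.tocsr()
    return Flattening(split, mat, rows, cols, k)


def apply_pendant_action(
    flat: Flattening, left_matrices, right_matrices
) -> Flattening:
    """Transform a flattening by pendant-edge Markov matrices.

    Growing a pendant edge with row-stochastic matrix ``M`` (entry
    ``M[parent, child]``, the package-wide convention) below each leaf
    sends ``F`` to ``(kron of left)^T F (kron of right)``; with the
    transposed (distribution-acting) convention this is the familiar
    ``(kron of left) F (kron of right)^T`` transformation rule.  The
    result equals the flattening of the grown tree's distribution, and
    the rank is unchanged whenever all matrices are invertible.
    """
    k = flat.k
    if len(left_matrices) != len(flat.row_taxa) or len(right_matrices) != len(
        flat.col_taxa
    ):
        raise ValueError("need one matrix per taxon on each side")
    for m in list(left_matrices) + list(right_matrices):
        if np.asarray(m).shape != (k, k):
            raise ValueError("pendant matrices must be k x k")
    if flat.shape[0] * flat.shape[1] > _MAX_DENSE_ENTRIES:
        raise ValueError("pendant action is only supported at dense-safe sizes")
    left = reduce(np.kron, [np.asarray(m, dtype=float) for m in left_matrices])
    right = reduce(np.kron, [np.asarray(m, dtype=float) for m in right_matrices])
    out = left.T @ flat.dense() @ right
    return Flattening(
        flat.split, sp.csr_matrix(out), flat.row_taxa, flat.col_taxa, k
    )


# ---------------------------------------------------------------------------
# Singular values and rank


def _compact(matrix: sp.spmatrix) -> np.ndarray:
    """Dense submatrix on the nonzero rows and columns.

    Deleting all-zero rows and columns leaves the nonzero singular values
    unchanged, so the (typically tiny) compact block is all that is needed
    for scores and ranks even when the nominal shape is astronomically
    large.  Works entirely from the coordinate representation so that no
    allocation ever scales with the nominal shape.
    """
    coo = matrix.tocoo()
    rows, rinv = np.unique(coo.row, return_inverse=True)
    cols, cinv = np.unique(coo.col, return_inverse=True)
    out = np.zeros((len(rows), len(cols)))
    np.add.at(out, (rinv, cinv), coo.data)
    return out


def singular_values(matrix, top: int | None = None) -> np.ndarray:
    """Singular values in descending order (the ``top`` largest if asked).

    Sparse inputs are compacted to their nonzero rows/columns first; a
    truncated iterative SVD is used only when the compact block is itself
    large.
    """
    if sp.issparse(matrix):
        if matrix.nnz == 0:
            return np.zeros(0)
        dense = _compact(matrix)
    else:
        dense = np.asarray(matrix, dtype=float)
        if not np.all(np.isfinite(dense)):
            raise ValueError("matrix has non-finite entries")
        if dense.size == 0 or not dense.any():
            return np.zeros(0)
    if top is not None and top < min(dense.shape) - 1 and min(dense.shape) > 1000:
        sv = scipy.sparse.linalg.svds(
            sp.csr_matrix(dense), k=top, return_singular_vectors=False
        )
        return np.sort(sv)[::-1]
    sv = scipy.linalg.svd(dense, compute_uv=False)
    return sv if top is None else sv[:top]


def numerical_rank(matrix, tolerance: float = 1e-8) -> int:
    """Number of singular values above ``tolerance`` times the largest."""
    if isinstance(matrix, Flattening):
        matrix = matrix.matrix
    sv = singular_values(matrix)
    if sv.size == 0 or sv[0] == 0:
        return 0
    return int(np.sum(sv > tolerance * sv[0]))


# ---------------------------------------------------------------------------
# Sparsity arithmetic (worst case: uniform site-pattern distribution)


def expected_nonzeros(t: int, L: int) -> tuple[float, float]:
    """Worst-case expected nonzero entries for DNA (k=4).

    Returns ``(flattening, subflattening)`` where the flattening value is
    ``4^t (1 - (1 - 4^-t)^L)`` (occupied cells after ``L`` uniform site
    draws) and the subflattening value is its full entry count
    ``(3t + 1)^2`` -- subflattenings are never sparse.
    """
    if t < 2:
        raise ValueError("need at least 2 taxa")
    if L < 1:
        raise ValueError("sequence length must be at least 1")
    flat = 4.0**t * (1.0 - (1.0 - 4.0**-t) ** L)
    sub = float((3 * t + 1) ** 2)
    return flat, sub


def break_even_length(t: int) -> int:
    """Smallest sequence length (rounded up to the nearest ten) at which
    the worst-case flattening is expected to hold at least as many
    nonzeros as the subflattening has entries."""
    target = (3 * t + 1) ** 2
    if target >= 4**t:
        raise ValueError("subflattening is never larger at this taxon count")
    # 4^t (1 - (1 - 4^-t)^L) >= target  <=>  L >= log(1 - target/4^t) / log(1 - 4^-t)
    exact = math.log(1.0 - target / 4.0**t) / math.log(1.0 - 4.0**-t)
    L = int(math.ceil(exact))
    while expected_nonzeros(t, L)[0] < target:  # guard against rounding
        L += 1
    return int(math.ceil(L / 10.0) * 10)
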