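"""Exact linear algebra over the rationals for small integer matrices.

The combinatorial statements about multiplicity vectors (which vectors
lie on a hyperplane, whether n random integer vectors are dependent) are
exact, so they are checked with exact arithmetic rather than floating
point.  Everything here uses fraction-free Gaussian elimination: rows are
combined as ``pivot * row_i - coef * row_pivot``, which keeps all entries
integral, so with Python integers there is no precision loss ever, and
with small inputs no overflow either.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Sequence

import numpy as np

__all__ = ["integer_rank", "row_echelon_int", "points_in_span", "in_span"]


def row_echelon_int(matrix: Sequence[Sequence[int]]) -> list[list[int]]:
    """Integer row-echelon form (Bareiss fraction-free); the nonzero rows.

    Uses the one-step Bareiss update ``(piv*a - c*b) // prev_piv`` whose
    division is exact (entries stay determinantal minors of the input),
    so intermediate integers grow polynomially rather than exponentially.
    The row space is preserved, so rank and span-membership tests against
    the result are exact.
    """
    rows = [[int(x) for x in row] for row in matrix]
    if not rows:
        return []
    n_cols = len(rows[0])
    echelon: list[list[int]] = []
    col = 0
    prev_piv = 1
    while rows and col < n_cols:
        pivot_row = next((r for r in rows if r[col] != 0), None)
        if pivot_row is None:
            col += 1
            continue
        rows.remove(pivot_row)
        piv = pivot_row[col]
        new_rows = []
        for r in rows:
            c = r[col]
            r = [(piv * a - c * b) // prev_piv for a, b in zip(r, pivot_row)]
            if any(r):
                new_rows.append(r)
        rows = new_rows
        prev_piv = piv
        echelon.append(pivot_row)
        col += 1
    return echelon


def integer_rank(matrix: Sequence[Sequence[int]]) -> int:
    """Exact rank of an integer matrix over the rationals."""
    return len(row_echelon_int(matrix))


def in_span(vector: Sequence[int], basis: Sequence[Sequence[int]]) -> bool:
    """Whether an integer vector lies in the rational span of the basis rows."""
    return bool(points_in_span(np.asarray([vector]), basis)[0])


def points_in_span(points: np.ndarray, basis: Sequence[Sequence[int]]) -> np.ndarray:
    """Vectorized exact span-membership test for many integer points.

    Reduces all points simultaneously against the integer echelon form of
    the basis; a point is in the span iff its reduction is the zero
    vector.  Entries grow by a pivot factor per elimination step; the
    computation falls back from int64 to unbounded Python integers if
    they threaten to overflow.
    """
    echelon = row_echelon_int(basis)
    pts = np.asarray(points, dtype=np.int64).copy()
    if pts.ndim != 2:
        raise ValueError("points must be a 2-D array")
    for row in echelon:
        col = next(i for i, x in enumerate(row) if x != 0)
        piv = row[col]
        rarr = np.asarray(row, dtype=pts.dtype if pts.dtype != object else object)
        # overflow guard: |new| <= |piv|*|pts| + |coef|*|row|
        if pts.dtype == np.int64:
            bound = abs(piv) * np.abs(pts).max(initial=0) + np.abs(pts[:, col]).max(
                initial=0
            ) * max(abs(x) for x in row)
            if bound > 2**62:
                pts = pts.astype(object)
                rarr = np.asarray(row, dtype=object)
        pts = pts * piv - np.outer(pts[:, col], rarr)
    return ~np.any(pts != 0, axis=1)


def fraction_rref(matrix: Sequence[Sequence[int]]) -> list[list[Fraction]]:
    """Reduced row-echelon form over Fractions (kept for cross-checking)."""
    rows = [[Fraction(x) for x in row] for row in matrix]
    out: list[list[Fraction]] = []
    col, n_cols = 0, (len(rows[0]) if rows else 0)
    while rows and col < n_cols:
        pivot_row = next((r for r in rows if r[col] != 0), None)
        if pivot_row is None:
            col += 1
            continue
        rows.remove(pivot_row)
        pivot_row = [x / pivot_row[col] for x in pivot_row]
        rows = [
            [a - r[col] * b for a, b in zip(r, pivot_row)] for r in rows
        ]
        rows = [r for r in rows if any(r)]
        out.append(pivot_row)
        col += 1
    return out
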