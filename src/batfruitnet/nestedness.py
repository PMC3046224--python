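"""Nestedness of a binary bipartite matrix: the NODF metric on [0, 1].

NODF evaluates every unordered pair of rows and every unordered pair of
columns.  A pair contributes 0 when the two lines have equal marginal
totals (no "decreasing fill"); otherwise it contributes the paired
overlap: the fraction of the sparser line's presences that also occur in
the denser line.  The network value is the plain mean over all
``A(A-1)/2 + P(P-1)/2`` pair contributions.  Because only marginal totals
and shared presences enter, the value is invariant to row/column order,
which is equivalent to the usual formulation on a matrix sorted by
marginal totals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateMatrixError, NotComputableError
from .netio import InteractionMatrix, validate_matrix


@dataclass(frozen=True)
class NestednessResult:
    """NODF decomposition: overall value plus row-pair and column-pair parts."""

    nodf: float
    nodf_rows: float
    nodf_cols: float
    n_row_pairs: int
    n_col_pairs: int


def _check_binary_nondegenerate(m: InteractionMatrix) -> np.ndarray:
    if not m.is_binary:
        raise NotComputableError(
            "NODF is defined on presence/absence data; call binarize() on weighted matrices"
        )
    if m.n_animals < 2 or m.n_plants < 2:
        raise DegenerateMatrixError(f"matrix {m.shape} too small for NODF (need >= 2 x 2)")
    b = m.presence()
    if np.any(b.sum(axis=1) == 0) or np.any(b.sum(axis=0) == 0):
        raise DegenerateMatrixError("matrix has empty rows or columns; validate_matrix first")
    return b


def _pair_contributions(b: np.ndarray) -> tuple[float, int]:
    """Sum of pairwise nestedness contributions along axis 0, plus pair count."""
    n = b.shape[0]
    marg = b.sum(axis=1)
    overlap = b @ b.T  # shared presences for every line pair
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if marg[i] == marg[j]:
                continue
            total += overlap[i, j] / min(marg[i], marg[j])
    return total, n * (n - 1) // 2


def nodf(m: InteractionMatrix) -> NestednessResult:
    """Normalized NODF of a binary matrix, with row/column decomposition."""
    b = _check_binary_nondegenerate(m)
    row_sum, n_row_pairs = _pair_contributions(b)
    col_sum, n_col_pairs = _pair_contributions(b.T)
    n_pairs = n_row_pairs + n_col_pairs
    return NestednessResult(
        nodf=(row_sum + col_sum) / n_pairs,
        nodf_rows=row_sum / n_row_pairs if n_row_pairs else 0.0,
        nodf_cols=col_sum / n_col_pairs if n_col_pairs else 0.0,
        n_row_pairs=n_row_pairs,
        n_col_pairs=n_col_pairs,
    )


def nodf_delta(m: InteractionMatrix, species_id: str) -> float:
    """Proportional change in NODF after removing one species.

    Returns ``(NODF_reduced - NODF_original) / NODF_original`` where the
    reduced matrix has the species' row or column deleted and any lines
    left empty by the removal dropped (mirroring secondary-loss
    bookkeeping).  Negative values mean the removal decreased nestedness.

    Raises
    ------
    DegenerateMatrixError
        If the reduced matrix has fewer than two animals or two plants.
    """
    original = nodf(m).nodf
    reduced = m.drop_species(species_id)
    reduced, _ = validate_matrix(reduced, drop_empty=True)
    observed = nodf(reduced).nodf
    if original == 0:
        raise NotComputableError("original NODF is 0; proportional change undefined")
    return (observed - original) / original
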