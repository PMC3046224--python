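"""Network-level complementary specialization: the H2' index.

H2 is the Shannon entropy (nats) of the interaction-frequency
distribution ``p_ij = w_ij / sum(w)``.  Given the matrix marginals, H2
is bounded: the maximum is reached by the marginal-product (maximally
mixed) table and the minimum by concentrating mass on as few cells as
the marginals allow.  H2' rescales the observed entropy between those
extremes,

    H2' = (H2_max - H2) / (H2_max - H2_min),

so 0 means all species share partners in proportion to availability
(full redundancy) and 1 means each species keeps its own partners (full
complementarity).  The index needs interaction frequencies; binary-only
matrices are rejected as not computable.

The maximum uses the continuous marginal-product table rather than an
integer-rounding heuristic; the discrepancy is O(1/total) and vanishes
for the sample sizes of fecal-sample matrices.  The minimum uses greedy
concentration: repeatedly put ``min(remaining row, remaining column)``
mass into the cell of the currently largest row x largest column, ties
broken by larger row total, then larger column total, then index order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateMatrixError, NotComputableError
from .netio import InteractionMatrix

_CLAMP_TOL = 1e-9


@dataclass(frozen=True)
class SpecializationResult:
    h2: float
    h2_min: float
    h2_max: float
    h2_prime: float


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def h2_entropy(m: InteractionMatrix) -> float:
    """Shannon entropy (nats) of the cell-proportion distribution."""
    total = m.total
    if total <= 0:
        raise NotComputableError("all-zero matrix has no interaction distribution")
    return _entropy(m.weights.ravel() / total)


def h2_bounds(row_totals: np.ndarray, col_totals: np.ndarray) -> tuple[float, float]:
    """Entropy extrema achievable by tables with the given marginals.

    Returns ``(h2_min, h2_max)`` in nats.
    """
    r = np.asarray(row_totals, dtype=float)
    c = np.asarray(col_totals, dtype=float)
    total_r, total_c = r.sum(), c.sum()
    if total_r <= 0:
        raise NotComputableError("marginals sum to zero")
    if abs(total_r - total_c) > 1e-6 * max(total_r, total_c):
        raise ValueError(f"row and column marginals disagree: {total_r} vs {total_c}")
    total = total_r

    # maximum: independence table p_ij = (r_i/total)(c_j/total)
    p_max = np.outer(r / total, c / total)
    h_max = _entropy(p_max.ravel())

    # minimum: greedy concentration
    rem_r = list(r)
    rem_c = list(c)
    masses: list[float] = []
    while rem_r and rem_c:
        # argmax with ties broken by index order (lists keep insertion order)
        i = max(range(len(rem_r)), key=lambda k: (rem_r[k], -k))
        j = max(range(len(rem_c)), key=lambda k: (rem_c[k], -k))
        mass = min(rem_r[i], rem_c[j])
        if mass > 0:
            masses.append(mass)
        rem_r[i] -= mass
        rem_c[j] -= mass
        if rem_r[i] <= 0:
            rem_r.pop(i)
        if rem_c[j] <= 0:
            rem_c.pop(j)
    h_min = _entropy(np.array(masses) / total)
    return h_min, h_max


def h2_prime(m: InteractionMatrix) -> SpecializationResult:
    """Complementary specialization H2' of a weighted interaction matrix."""
    if m.n_animals < 2 or m.n_plants < 2:
        raise DegenerateMatrixError(f"matrix {m.shape} too small for H2' (need >= 2 x 2)")
    if m.is_binary:
        raise NotComputableError(
            "H2' needs interaction frequencies; not computable for binary-only data"
        )
    h2 = h2_entropy(m)
    h2_min, h2_max = h2_bounds(m.weights.sum(axis=1), m.weights.sum(axis=0))
    denom = h2_max - h2_min
    if denom <= 0:
        raise NotComputableError("degenerate marginals: entropy extrema coincide")
    value = (h2_max - h2) / denom
    if value < -_CLAMP_TOL or value > 1 + _CLAMP_TOL:
        raise NotComputableError(
            f"H2' = {value} falls outside [0, 1] beyond numerical tolerance; "
            "entropy bounds inconsistent with observed table"
        )
    return SpecializationResult(
        h2=h2, h2_min=h2_min, h2_max=h2_max, h2_prime=float(np.clip(value, 0.0, 1.0))
    )
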