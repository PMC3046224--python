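"""Null matrices and Monte Carlo significance tests.

Two null models are provided:

* ``ce`` — a binary, degree-proportional model: cell (i, j) is filled
  independently with probability ``(d_i/P + d_j/A)/2``, the average of
  the row fill and the column fill of the observed presence pattern.
  Draws with an empty row or column are rejected and the whole matrix is
  resampled (repairing would bias the cell probabilities).
* ``patefield`` — weighted contingency tables drawn uniformly over the
  assignments of the ``sum(w)`` interaction events, conditional on both
  marginal vectors, which are conserved exactly.

``mc_test`` wraps either model around any of the package's network
statistics and reports a one-sided p-value: the proportion of null
matrices whose statistic is equal to or higher than the observed one.
When no null reaches the observed value the p-value is reported as the
bound ``1/N`` with ``p_is_bound`` set (printed as ``P < 1/N``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

from .errors import BatFruitNetError, NotComputableError
from .netio import InteractionMatrix

DEFAULT_N_NULL = {"nodf": 1000, "h2_prime": 10000, "modularity": 100}


@dataclass(frozen=True)
class MCResult:
    observed: float
    null_values: tuple[float, ...]
    n_null: int
    p_value: float
    p_is_bound: bool

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_values))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_values, ddof=1)) if self.n_null > 1 else 0.0

    def format_p(self) -> str:
        return f"P < {self.p_value:g}" if self.p_is_bound else f"P = {self.p_value:g}"


def sample_ce(
    m: InteractionMatrix,
    rng: np.random.Generator | int,
    max_attempts: int = 1000,
    require_connected: bool = True,
) -> InteractionMatrix:
    """One binary null matrix under the degree-proportional (Ce) model.

    With ``require_connected`` (the default) whole matrices are resampled
    until no row or column is empty; note this conditioning shifts the
    realized cell frequencies slightly above the nominal probabilities.
    Set it to False to get the raw independent-Bernoulli draw.
    """
    if not m.is_binary:
        raise NotComputableError("the Ce null model operates on presence/absence data")
    rng = np.random.default_rng(rng)
    a, p = m.shape
    prob = (m.row_degrees()[:, None] / p + m.col_degrees()[None, :] / a) / 2.0
    for attempt in range(max_attempts):
        draw = (rng.random((a, p)) < prob).astype(float)
        if not require_connected or (draw.sum(axis=1).all() and draw.sum(axis=0).all()):
            return InteractionMatrix(m.animal_ids, m.plant_ids, draw)
    raise BatFruitNetError(
        f"Ce sampling produced an empty row/column in all {max_attempts} attempts; "
        "the matrix is too sparse for this null model"
    )


def ce_cell_probabilities(m: InteractionMatrix) -> np.ndarray:
    """The fill probability matrix used by :func:`sample_ce`."""
    a, p = m.shape
    return (m.row_degrees()[:, None] / p + m.col_degrees()[None, :] / a) / 2.0


def sample_patefield(
    row_totals: np.ndarray,
    col_totals: np.ndarray,
    rng: np.random.Generator | int,
    animal_ids: tuple[str, ...] | None = None,
    plant_ids: tuple[str, ...] | None = None,
) -> InteractionMatrix:
    """One weighted null table with both marginal vectors conserved exactly."""
    r = np.asarray(np.round(row_totals), dtype=int)
    c = np.asarray(np.round(col_totals), dtype=int)
    if r.sum() != c.sum():
        raise ValueError(f"marginal sums disagree: {r.sum()} vs {c.sum()}")
    if r.sum() <= 0:
        raise ValueError("marginals must have a positive grand total")
    rng = np.random.default_rng(rng)
    table = stats.random_table(r, c).rvs(method="patefield", random_state=rng)
    if animal_ids is None:
        animal_ids = tuple(f"A{i + 1}" for i in range(len(r)))
    if plant_ids is None:
        plant_ids = tuple(f"P{j + 1}" for j in range(len(c)))
    return InteractionMatrix(animal_ids, plant_ids, np.asarray(table, dtype=float))


def sample_patefield_batch(
    row_totals: np.ndarray,
    col_totals: np.ndarray,
    n: int,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """``n`` Patefield tables at once, shape (n, A, P); marginals exact."""
    r = np.asarray(np.round(row_totals), dtype=int)
    c = np.asarray(np.round(col_totals), dtype=int)
    if r.sum() != c.sum():
        raise ValueError(f"marginal sums disagree: {r.sum()} vs {c.sum()}")
    rng = np.random.default_rng(rng)
    return np.asarray(
        stats.random_table(r, c).rvs(n, method="patefield", random_state=rng)
    ).reshape(n, len(r), len(c))


def _null_matrix(
    m: InteractionMatrix, model: str, rng: np.random.Generator
) -> InteractionMatrix:
    if model == "ce":
        return sample_ce(m, rng)
    if model == "patefield":
        return sample_patefield(
            m.weights.sum(axis=1), m.weights.sum(axis=0), rng, m.animal_ids, m.plant_ids
        )
    raise ValueError(f"unknown null model '{model}' (expected 'ce' or 'patefield')")


def _resolve_statistic(name: str, statistic_kwargs: dict | None) -> Callable[[InteractionMatrix, np.random.Generator], float]:
    kwargs = dict(statistic_kwargs or {})
    if name == "nodf":
        from .nestedness import nodf
        from .netio import binarize

        return lambda mat, rng: nodf(binarize(mat)).nodf
    if name == "h2_prime":
        from .specialization import h2_prime

        return lambda mat, rng: h2_prime(mat).h2_prime
    if name == "modularity":
        from .modularity_guilds import anneal_modularity

        return lambda mat, rng: anneal_modularity(
            mat, rng_seed=rng, **kwargs
        ).m_value
    raise ValueError(f"unknown statistic '{name}' (expected nodf, h2_prime or modularity)")


def mc_test(
    m: InteractionMatrix,
    statistic: str | Callable[[InteractionMatrix, np.random.Generator], float],
    model: str,
    n: int | None = None,
    rng_seed: int | np.random.SeedSequence = 0,
    statistic_kwargs: dict | None = None,
) -> MCResult:
    """Monte Carlo significance of a network statistic against a null model.

    Nulls equal to the observed value count toward the numerator ("equal
    or higher").  A master seed spawns one substream per replicate, so
    the null ensemble is identical whether replicates are evaluated
    serially or in parallel.
    """
    if isinstance(statistic, str):
        if statistic == "h2_prime" and model == "ce":
            raise NotComputableError(
                "H2' needs interaction frequencies; the binary Ce model cannot supply them "
                "(use the Patefield model)"
            )
        if n is None:
            n = DEFAULT_N_NULL[statistic]
        stat_fn = _resolve_statistic(statistic, statistic_kwargs)
    else:
        stat_fn = statistic
        if n is None:
            raise ValueError("n must be given for a callable statistic")
    if n < 1:
        raise ValueError("n must be >= 1")

    seq = (
        rng_seed
        if isinstance(rng_seed, np.random.SeedSequence)
        else np.random.SeedSequence(rng_seed)
    )
    obs_stream, null_root = seq.spawn(2)
    observed = stat_fn(m, np.random.default_rng(obs_stream))

    null_values = []
    for child in null_root.spawn(n):
        rng = np.random.default_rng(child)
        null_m = _null_matrix(m, model, rng)
        null_values.append(stat_fn(null_m, rng))

    n_ge = int(sum(v >= observed for v in null_values))
    if n_ge == 0:
        return MCResult(observed, tuple(null_values), n, 1.0 / n, True)
    return MCResult(observed, tuple(null_values), n, n_ge / n, False)
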