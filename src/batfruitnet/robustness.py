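"""Robustness to species loss: cumulative removal curves and jackknife.

Cumulative removals: species on one side are removed one by one in a
uniformly random order; after each removal, species on the opposite side
whose partners are all gone count as secondary losses.  The curve of the
surviving opposite-side fraction against the removed fraction starts at
(0, 1) and ends at (1, 0); the area below it (trapezoid rule) is the
robustness ``R``: 1 means the system keeps almost everything until the
end, 0 means it collapses after the first removals.

Jackknife: each species is removed alone and the proportional change in
nestedness ``NODF_r = (NODF_reduced - NODF_original)/NODF_original`` and
the fraction of opposite-side species immediately orphaned (``SL_r``)
are recorded.  Removals model exclusion from the seed-dispersal service,
not literal extinction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import BatFruitNetError, DegenerateMatrixError, NotComputableError
from .nestedness import nodf_delta
from .netio import InteractionMatrix, SpeciesMeta
from .roles import SpeciesRole


@dataclass(frozen=True)
class RobustnessResult:
    side_removed: str
    n_replicates: int
    curve_x: np.ndarray
    curve_y_mean: np.ndarray
    curve_y_sd: np.ndarray
    r_values: np.ndarray
    r_mean: float
    r_sd: float


@dataclass(frozen=True)
class RemovalImpact:
    species_id: str
    side: str
    nodf_r: float | None  # None when removal degenerates the matrix
    sl_r: float


def _side_arrays(m: InteractionMatrix, side: str) -> np.ndarray:
    """Presence pattern with the removal side along axis 0."""
    b = m.presence()
    if side == "animal":
        return b
    if side == "plant":
        return b.T
    raise ValueError("side must be 'animal' or 'plant'")


def extinction_replicate(
    m: InteractionMatrix,
    side: str,
    rng: np.random.Generator | int,
    order: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One removal sequence: (removed fractions, surviving fractions, area).

    ``order`` overrides the uniformly random removal order (for targeted
    removal experiments); it must be a permutation of the removal side.
    """
    rng = np.random.default_rng(rng)
    b = _side_arrays(m, side)
    n_removed_side, n_opposite = b.shape
    if order is None:
        order = rng.permutation(n_removed_side)
    else:
        order = np.asarray(order)
        if sorted(order.tolist()) != list(range(n_removed_side)):
            raise ValueError("order must be a permutation of the removal-side indices")
    partners_left = b.sum(axis=0).astype(int)  # per opposite-side species
    alive = partners_left > 0
    y = [alive.sum() / n_opposite]
    for idx in order:
        partners_left -= b[idx]
        alive = partners_left > 0
        y.append(alive.sum() / n_opposite)
    x = np.arange(n_removed_side + 1) / n_removed_side
    y = np.array(y)
    area = float(np.trapezoid(y, x))
    return x, y, area


def robustness(
    m: InteractionMatrix,
    side: str,
    n_replicates: int = 100,
    rng_seed: int | np.random.SeedSequence = 0,
) -> RobustnessResult:
    """Aggregate extinction curves over replicate random removal orders."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    seq = (
        rng_seed
        if isinstance(rng_seed, np.random.SeedSequence)
        else np.random.SeedSequence(rng_seed)
    )
    curves = []
    areas = []
    x = None
    for child in seq.spawn(n_replicates):
        x, y, r = extinction_replicate(m, side, np.random.default_rng(child))
        curves.append(y)
        areas.append(r)
    curves = np.array(curves)
    areas = np.array(areas)
    return RobustnessResult(
        side_removed=side,
        n_replicates=n_replicates,
        curve_x=x,
        curve_y_mean=curves.mean(axis=0),
        curve_y_sd=curves.std(axis=0, ddof=1) if n_replicates > 1 else np.zeros_like(x),
        r_values=areas,
        r_mean=float(areas.mean()),
        r_sd=float(areas.std(ddof=1)) if n_replicates > 1 else 0.0,
    )


def jackknife_removals(m: InteractionMatrix) -> list[RemovalImpact]:
    """Single-species removal impacts for every species on both sides."""
    b = m.presence()
    impacts: list[RemovalImpact] = []
    for s in m.species_ids():
        side = m.side_of(s)
        if side == "animal":
            i = m.animal_ids.index(s)
            orphaned = int(((b[:, :].sum(axis=0) - b[i, :]) == 0)[b[i, :] > 0].sum())
            n_opposite = m.n_plants
        else:
            j = m.plant_ids.index(s)
            orphaned = int(((b.sum(axis=1) - b[:, j]) == 0)[b[:, j] > 0].sum())
            n_opposite = m.n_animals
        sl_r = orphaned / n_opposite
        try:
            nr: float | None = nodf_delta(m, s)
        except (DegenerateMatrixError, NotComputableError):
            nr = None
        impacts.append(RemovalImpact(species_id=s, side=side, nodf_r=nr, sl_r=sl_r))
    return impacts


@dataclass(frozen=True)
class ImpactCorrelation:
    side: str
    n: int
    spearman_r: float
    p_value: float


@dataclass(frozen=True)
class ImpactByFrugivory:
    n: int
    df: int
    statistic: float
    p_value: float
    group_medians: dict[str, float]


def correlate_impact(
    impacts: list[RemovalImpact],
    roles: list[SpeciesRole],
    meta: dict[str, SpeciesMeta] | None = None,
) -> tuple[dict[str, ImpactCorrelation], ImpactByFrugivory | None]:
    """Spearman correlation of k_r vs NODF_r per side, and (when metadata
    is given) a Kruskal-Wallis test of NODF_r across frugivory levels."""
    kr = {r.species_id: r.k_r for r in roles}
    by_side: dict[str, tuple[list[float], list[float]]] = {"animal": ([], []), "plant": ([], [])}
    for imp in impacts:
        if imp.nodf_r is None or imp.species_id not in kr:
            continue
        xs, ys = by_side[imp.side]
        xs.append(kr[imp.species_id])
        ys.append(imp.nodf_r)
    correlations: dict[str, ImpactCorrelation] = {}
    for side, (xs, ys) in by_side.items():
        if len(xs) < 3:
            continue
        if len(set(xs)) == 1 or len(set(ys)) == 1:
            raise BatFruitNetError(
                f"{side}: impact or degree constant across species; Spearman undefined"
            )
        r, p = stats.spearmanr(xs, ys)
        correlations[side] = ImpactCorrelation(side=side, n=len(xs), spearman_r=float(r), p_value=float(p))

    kw: ImpactByFrugivory | None = None
    if meta is not None:
        groups: dict[str, list[float]] = {}
        for imp in impacts:
            if imp.side != "animal" or imp.nodf_r is None:
                continue
            rec = meta.get(imp.species_id)
            if rec is None:
                continue
            groups.setdefault(rec.frugivory_level, []).append(imp.nodf_r)
        groups = {k: v for k, v in groups.items() if len(v) >= 2}
        if len(groups) >= 2:
            flat = [x for v in groups.values() for x in v]
            if len(set(flat)) > 1:
                stat, p = stats.kruskal(*groups.values())
                kw = ImpactByFrugivory(
                    n=len(flat),
                    df=len(groups) - 1,
                    statistic=float(stat),
                    p_value=float(p),
                    group_medians={k: float(np.median(v)) for k, v in groups.items()},
                )
    return correlations, kw
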