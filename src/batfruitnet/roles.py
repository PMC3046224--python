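"""Species functional roles: normalized degree, betweenness, hubs/connectors.

Normalized degree ``k_r`` is a species' partner count divided by the
number of possible partners on the other side (plants available to a bat,
bats available to a plant).  Betweenness centrality ``bc`` is the
proportion of shortest paths between all species pairs (either side) that
pass through the focal species, normalized by ``(n-1)(n-2)/2``; pairs in
different components simply contribute no paths.  Species in the top tail
of ``k_r`` within their network are flagged as hubs, species in the top
tail of ``bc`` as connectors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
from scipy import stats

from .errors import DegenerateMatrixError
from .netio import InteractionMatrix, SpeciesMeta


@dataclass(frozen=True)
class SpeciesRole:
    species_id: str
    side: str
    k_r: float
    bc: float
    is_hub: bool = False
    is_connector: bool = False


@dataclass(frozen=True)
class GroupComparison:
    grouping: str
    test: str
    statistic: float
    df: float
    n: int
    p_value: float
    group_means: dict[str, float]


def _check(m: InteractionMatrix) -> None:
    if m.n_animals < 2 or m.n_plants < 2:
        raise DegenerateMatrixError(f"matrix {m.shape} too small for role metrics")


def normalized_degree(m: InteractionMatrix) -> dict[str, float]:
    """k_r per species: degree over the count of possible partners."""
    _check(m)
    b = m.presence()
    out: dict[str, float] = {}
    for i, a in enumerate(m.animal_ids):
        out[a] = b[i].sum() / m.n_plants
    for j, p in enumerate(m.plant_ids):
        out[p] = b[:, j].sum() / m.n_animals
    return out


def to_graph(m: InteractionMatrix) -> nx.Graph:
    """Undirected unipartite embedding of the bipartite presence pattern."""
    g = nx.Graph()
    g.add_nodes_from(m.animal_ids, side="animal")
    g.add_nodes_from(m.plant_ids, side="plant")
    b = m.presence()
    for i, a in enumerate(m.animal_ids):
        for j, p in enumerate(m.plant_ids):
            if b[i, j]:
                g.add_edge(a, p)
    return g


def betweenness(m: InteractionMatrix) -> dict[str, float]:
    """Normalized shortest-path betweenness on the unipartite embedding."""
    _check(m)
    g = to_graph(m)
    return {k: float(v) for k, v in nx.betweenness_centrality(g, normalized=True).items()}


def species_roles(m: InteractionMatrix) -> list[SpeciesRole]:
    kr = normalized_degree(m)
    bc = betweenness(m)
    return [
        SpeciesRole(species_id=s, side=m.side_of(s), k_r=kr[s], bc=bc[s])
        for s in m.species_ids()
    ]


def classify_roles(
    roles: list[SpeciesRole],
    hub_quantile: float = 0.9,
    connector_quantile: float = 0.9,
) -> list[SpeciesRole]:
    """Flag hubs (top k_r quantile) and connectors (top bc quantile).

    Thresholding is ``>=`` the within-network quantile, so ties at the
    threshold are all flagged.
    """
    kr_thr = float(np.quantile([r.k_r for r in roles], hub_quantile))
    bc_thr = float(np.quantile([r.bc for r in roles], connector_quantile))
    return [
        replace(r, is_hub=r.k_r >= kr_thr, is_connector=r.bc >= bc_thr) for r in roles
    ]


def compare_roles_by_group(
    roles: list[SpeciesRole],
    meta: dict[str, SpeciesMeta],
    grouping: str,
    metric: str = "bc",
) -> GroupComparison:
    """Compare a role metric between sides (t test) or across frugivory
    levels of the animals (Kruskal-Wallis)."""
    if metric not in ("k_r", "bc"):
        raise ValueError("metric must be 'k_r' or 'bc'")
    values: dict[str, list[float]] = {}
    for r in roles:
        if grouping == "side":
            key = r.side
        elif grouping == "frugivory_level":
            if r.side != "animal":
                continue
            key = meta[r.species_id].frugivory_level
        else:
            raise ValueError("grouping must be 'side' or 'frugivory_level'")
        values.setdefault(key, []).append(getattr(r, metric))
    groups = {k: v for k, v in values.items() if len(v) >= 2}
    if len(groups) < 2:
        raise ValueError(f"need >= 2 groups with >= 2 members each, got {list(values)}")
    samples = list(groups.values())
    n = sum(len(v) for v in samples)
    flat = [x for v in samples for x in v]
    if len(set(flat)) == 1:
        # identical values in every group: no difference by construction
        test = "t" if grouping == "side" else "kruskal"
        dof = float(n - 2) if grouping == "side" else float(len(groups) - 1)
        return GroupComparison(
            grouping=grouping, test=test, statistic=0.0, df=dof, n=n, p_value=1.0,
            group_means={k: float(np.mean(v)) for k, v in groups.items()},
        )
    if grouping == "side":
        res = stats.ttest_ind(samples[0], samples[1], equal_var=True)
        return GroupComparison(
            grouping=grouping,
            test="t",
            statistic=float(res.statistic),
            df=float(n - 2),
            n=n,
            p_value=float(res.pvalue),
            group_means={k: float(np.mean(v)) for k, v in groups.items()},
        )
    stat, p = stats.kruskal(*samples)
    return GroupComparison(
        grouping=grouping,
        test="kruskal",
        statistic=float(stat),
        df=float(len(groups) - 1),
        n=n,
        p_value=float(p),
        group_means={k: float(np.mean(v)) for k, v in groups.items()},
    )
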