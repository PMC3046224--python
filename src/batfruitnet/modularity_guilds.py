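"""Modular structure by simulated annealing, and genus-module guild tests.

The bipartite network is embedded as an undirected unipartite graph (no
within-side edges exist, so the embedding adds nothing) and Newman-Girvan
modularity is used:

    M = sum_s [ l_s / L - (d_s / 2L)^2 ]

with ``L`` the edge count, ``l_s`` the edges inside module ``s`` and
``d_s`` the summed degree of module ``s``.  A single connected module has
M = 0; ``k`` equal disconnected blocks have M = 1 - 1/k.

``anneal_modularity`` maximizes M with Metropolis simulated annealing:
per temperature, ``S^2`` single-node moves plus ``S`` collective moves
(module merges and random-bisection splits, the split followed by a local
node-move pass at the current temperature), with geometric cooling.  The
best partition seen is polished by greedy node moves before it is
returned, and the best of several restarts wins.  Weighted matrices are
binarized on entry: modularity here is about who interacts with whom,
not how often.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sstats

from .errors import DegenerateMatrixError
from .netio import InteractionMatrix, SpeciesMeta


@dataclass(frozen=True)
class Partition:
    """Module assignment over both sides, with its modularity value."""

    assignment: dict[str, int]
    m_value: float
    n_modules: int

    def modules(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for sp, mod in self.assignment.items():
            out.setdefault(mod, []).append(sp)
        return out


@dataclass(frozen=True)
class GuildTestResult:
    genus: str
    n_follow: int
    n_not: int
    proportion: float
    g_statistic: float
    p_value: float


# --- graph embedding -------------------------------------------------------


def _build_graph(m: InteractionMatrix) -> tuple[list[str], list[list[int]], np.ndarray, int]:
    """Unipartite embedding: node ids, adjacency lists, degrees, edge count."""
    nodes = list(m.species_ids())
    a = m.n_animals
    adj: list[list[int]] = [[] for _ in nodes]
    b = m.presence()
    for i in range(m.n_animals):
        for j in range(m.n_plants):
            if b[i, j]:
                adj[i].append(a + j)
                adj[a + j].append(i)
    deg = np.array([len(nb) for nb in adj])
    return nodes, adj, deg, int(b.sum())


def modularity_of_partition(m: InteractionMatrix, assignment: dict[str, int]) -> float:
    """Newman-Girvan modularity of a given module assignment."""
    nodes, adj, deg, L = _build_graph(m)
    missing = [s for s in nodes if s not in assignment]
    if missing:
        raise KeyError(f"species missing from assignment: {', '.join(missing[:5])}")
    if L == 0:
        raise DegenerateMatrixError("matrix has no interactions")
    labels = [assignment[s] for s in nodes]
    mods = set(labels)
    q = 0.0
    for s in mods:
        idx = [i for i, lab in enumerate(labels) if lab == s]
        in_s = set(idx)
        l_s = sum(1 for i in idx for j in adj[i] if j in in_s) // 2
        d_s = int(deg[list(idx)].sum())
        q += l_s / L - (d_s / (2 * L)) ** 2
    return q


# --- simulated annealing ---------------------------------------------------


class _AnnealState:
    """Mutable partition state with integer bookkeeping (no float drift)."""

    def __init__(self, adj: list[list[int]], deg: np.ndarray, L: int):
        n = len(adj)
        self.adj = adj
        self.deg = deg
        self.L = L
        self.labels = list(range(n))
        self.members: list[set[int]] = [{i} for i in range(n)]
        self.d_mod = [int(d) for d in deg]
        self.l_mod = [0] * n
        self.free: list[int] = []

    def quality(self) -> float:
        L = self.L
        q = 0.0
        for s, mem in enumerate(self.members):
            if mem:
                q += self.l_mod[s] / L - (self.d_mod[s] / (2 * L)) ** 2
        return q

    def links_to(self, v: int, mod: int) -> int:
        labels = self.labels
        return sum(1 for u in self.adj[v] if labels[u] == mod)

    def delta_move(self, v: int, b: int) -> tuple[float, int, int]:
        a = self.labels[v]
        l_va = self.links_to(v, a)
        l_vb = self.links_to(v, b)
        dv = int(self.deg[v])
        L = self.L
        dq = (l_vb - l_va) / L - dv * (self.d_mod[b] - self.d_mod[a] + dv) / (2 * L * L)
        return dq, l_va, l_vb

    def apply_move(self, v: int, b: int, l_va: int, l_vb: int) -> None:
        a = self.labels[v]
        dv = int(self.deg[v])
        self.labels[v] = b
        self.members[a].discard(v)
        self.members[b].add(v)
        self.d_mod[a] -= dv
        self.d_mod[b] += dv
        self.l_mod[a] -= l_va
        self.l_mod[b] += l_vb
        if not self.members[a]:
            self.free.append(a)

    def new_module(self) -> int:
        while self.free:
            s = self.free.pop()
            if not self.members[s]:
                return s
        raise RuntimeError("no free module slot")  # cannot happen: n slots, <= n modules

    def nonempty(self) -> list[int]:
        return [s for s, mem in enumerate(self.members) if mem]

    def internal_links(self, group: set[int]) -> int:
        return sum(1 for v in group for u in self.adj[v] if u in group) // 2


def _metropolis(dq: float, t: float, rng: np.random.Generator) -> bool:
    return dq >= 0 or rng.random() < math.exp(dq / t)


def _try_node_move(state: _AnnealState, t: float, rng: np.random.Generator) -> bool:
    n = len(state.labels)
    v = int(rng.integers(n))
    a = state.labels[v]
    # target: module of a random other node, or a fresh singleton module
    if rng.random() < 0.1 and len(state.members[a]) > 1 and state.free:
        b = state.new_module()
        chose_new = True
    else:
        b = state.labels[int(rng.integers(n))]
        chose_new = False
    if b == a:
        if chose_new:
            state.free.append(b)
        return False
    dq, l_va, l_vb = state.delta_move(v, b)
    if _metropolis(dq, t, rng):
        state.apply_move(v, b, l_va, l_vb)
        return True
    if chose_new:
        state.free.append(b)
    return False


def _try_merge(state: _AnnealState, t: float, rng: np.random.Generator) -> bool:
    mods = state.nonempty()
    if len(mods) < 2:
        return False
    a, b = rng.choice(len(mods), size=2, replace=False)
    a, b = mods[a], mods[b]
    if len(state.members[a]) > len(state.members[b]):
        a, b = b, a  # a is the smaller: relabel fewer nodes
    labels = state.labels
    l_ab = sum(1 for v in state.members[a] for u in state.adj[v] if labels[u] == b)
    L = state.L
    dq = l_ab / L - state.d_mod[a] * state.d_mod[b] / (2 * L * L)
    if not _metropolis(dq, t, rng):
        return False
    for v in list(state.members[a]):
        labels[v] = b
        state.members[b].add(v)
    state.members[a].clear()
    state.l_mod[b] += state.l_mod[a] + l_ab
    state.d_mod[b] += state.d_mod[a]
    state.l_mod[a] = 0
    state.d_mod[a] = 0
    state.free.append(a)
    return True


def _try_split(state: _AnnealState, t: float, rng: np.random.Generator) -> bool:
    mods = [s for s in state.nonempty() if len(state.members[s]) >= 2]
    if not mods or not state.free:
        return False
    a = mods[int(rng.integers(len(mods)))]
    group = sorted(state.members[a])
    mask = rng.random(len(group)) < 0.5
    if mask.all() or not mask.any():
        return False
    snapshot_l_a, snapshot_d_a = state.l_mod[a], state.d_mod[a]
    before = snapshot_l_a / state.L - (snapshot_d_a / (2 * state.L)) ** 2
    c = state.new_module()
    # bisect
    for v, to_c in zip(group, mask):
        if to_c:
            state.labels[v] = c
            state.members[a].discard(v)
            state.members[c].add(v)
            state.d_mod[a] -= int(state.deg[v])
            state.d_mod[c] += int(state.deg[v])
    state.l_mod[a] = state.internal_links(state.members[a])
    state.l_mod[c] = state.internal_links(state.members[c])
    # local refinement between the two halves at the current temperature
    order = list(group)
    rng.shuffle(order)
    for v in order:
        cur = state.labels[v]
        tgt = c if cur == a else a
        if len(state.members[cur]) <= 1:
            continue
        dq, l_v_cur, l_v_tgt = state.delta_move(v, tgt)
        if _metropolis(dq, t, rng):
            state.apply_move(v, tgt, l_v_cur, l_v_tgt)
    after = (
        state.l_mod[a] / state.L
        - (state.d_mod[a] / (2 * state.L)) ** 2
        + state.l_mod[c] / state.L
        - (state.d_mod[c] / (2 * state.L)) ** 2
    )
    if _metropolis(after - before, t, rng):
        return True
    # roll back
    for v in group:
        if state.labels[v] != a:
            state.labels[v] = a
            state.members[c].discard(v)
            state.members[a].add(v)
    state.l_mod[a], state.d_mod[a] = snapshot_l_a, snapshot_d_a
    state.l_mod[c], state.d_mod[c] = 0, 0
    state.free.append(c)
    return False


def _greedy_polish(state: _AnnealState, rng: np.random.Generator, max_sweeps: int = 50) -> None:
    """Hill-climb node moves until no single move improves modularity."""
    n = len(state.labels)
    for _ in range(max_sweeps):
        improved = False
        order = rng.permutation(n)
        for v in order:
            a = state.labels[v]
            candidates = {state.labels[u] for u in state.adj[v]}
            candidates.discard(a)
            best_dq, best = 1e-12, None
            for b in candidates:
                dq, l_va, l_vb = state.delta_move(v, b)
                if dq > best_dq:
                    best_dq, best = dq, (b, l_va, l_vb)
            if best is not None:
                state.apply_move(v, best[0], best[1], best[2])
                improved = True
        if not improved:
            break


def _anneal_once(
    adj: list[list[int]],
    deg: np.ndarray,
    L: int,
    rng: np.random.Generator,
    t0: float,
    cooling: float,
    t_min: float,
    stagnation: int,
    proposal_factor: float,
) -> tuple[list[int], float]:
    n = len(adj)
    state = _AnnealState(adj, deg, L)
    n_node = max(1, int(round(proposal_factor * n * n)))
    n_coll = max(1, int(round(proposal_factor * n)))
    best_q = state.quality()
    best_labels = list(state.labels)
    t = t0
    stagnant = 0
    while t > t_min and stagnant < stagnation:
        for _ in range(n_node):
            _try_node_move(state, t, rng)
        for _ in range(n_coll):
            if rng.random() < 0.5:
                _try_merge(state, t, rng)
            else:
                _try_split(state, t, rng)
        q = state.quality()
        if q > best_q + 1e-10:
            best_q = q
            best_labels = list(state.labels)
            stagnant = 0
        else:
            stagnant += 1
        t *= cooling
    # polish the best state found
    polish = _AnnealState(adj, deg, L)
    _restore(polish, best_labels)
    _greedy_polish(polish, rng)
    return list(polish.labels), polish.quality()


def _restore(state: _AnnealState, labels: list[int]) -> None:
    n = len(labels)
    state.labels = list(labels)
    state.members = [set() for _ in range(n)]
    state.d_mod = [0] * n
    state.l_mod = [0] * n
    for v, lab in enumerate(labels):
        state.members[lab].add(v)
        state.d_mod[lab] += int(state.deg[v])
    for s, mem in enumerate(state.members):
        state.l_mod[s] = state.internal_links(mem) if mem else 0
    state.free = [s for s in range(n) if not state.members[s]]


def anneal_modularity(
    m: InteractionMatrix,
    rng_seed: int | np.random.Generator | np.random.SeedSequence = 0,
    restarts: int = 5,
    t0: float = 0.05,
    cooling: float = 0.95,
    t_min: float = 1e-5,
    stagnation: int = 50,
    proposal_factor: float = 1.0,
) -> Partition:
    """Best modularity partition over several annealing restarts.

    Deterministic given the seed.  ``proposal_factor`` scales the number
    of proposals per temperature (1.0 = ``S^2`` node moves and ``S``
    collective moves, ``S`` = node count).  The default initial
    temperature sits near the scale of single-move modularity deltas
    (~1/L for these network sizes); starting far above it wastes the
    schedule on an unselective random walk and lets the stagnation stop
    fire before any real annealing has happened.
    """
    if not 0 < cooling < 1:
        raise ValueError("cooling factor must be in (0, 1)")
    if t0 <= 0 or t_min <= 0:
        raise ValueError("temperatures must be positive")
    nodes, adj, deg, L = _build_graph(m)
    if len(nodes) < 3:
        raise DegenerateMatrixError("need at least 3 species for modularity search")
    if L == 0:
        raise DegenerateMatrixError("matrix has no interactions")
    if isinstance(rng_seed, np.random.Generator):
        rng = rng_seed
        streams = [rng for _ in range(restarts)]
    else:
        seq = (
            rng_seed
            if isinstance(rng_seed, np.random.SeedSequence)
            else np.random.SeedSequence(rng_seed)
        )
        streams = [np.random.default_rng(s) for s in seq.spawn(restarts)]
    best_labels, best_q = None, -np.inf
    for stream in streams:
        labels, q = _anneal_once(adj, deg, L, stream, t0, cooling, t_min, stagnation, proposal_factor)
        if q > best_q:
            best_q, best_labels = q, labels
    # canonical module ids: 0..k-1 in order of first appearance
    remap: dict[int, int] = {}
    assignment = {}
    for node, lab in zip(nodes, best_labels):
        if lab not in remap:
            remap[lab] = len(remap)
        assignment[node] = remap[lab]
    return Partition(assignment=assignment, m_value=float(best_q), n_modules=len(remap))


# --- guild tests -----------------------------------------------------------

DEFAULT_PAIRING = {"Artibeus": "Ficus", "Carollia": "Piper", "Sturnira": "Solanum"}


@dataclass
class PairingCounts:
    n_follow: int = 0
    n_not: int = 0
    split_events: list[str] = field(default_factory=list)

    @property
    def proportion(self) -> float:
        tot = self.n_follow + self.n_not
        return self.n_follow / tot if tot else float("nan")


def count_preferred_pairings(
    partitions: list[Partition],
    metas: list[dict[str, SpeciesMeta]],
    pairing: dict[str, str] | None = None,
) -> dict[str, PairingCounts]:
    """Count, across networks, how often each bat genus shares its module
    with at least one plant of its predicted preferred genus.

    If the bats of a genus are split across modules within one network
    (possible on synthetic data), the module holding the majority of them
    is used and the event is logged in ``split_events``.
    """
    if pairing is None:
        pairing = dict(DEFAULT_PAIRING)
    counts = {g: PairingCounts() for g in pairing}
    for k, (part, meta) in enumerate(zip(partitions, metas)):
        module_plant_genera: dict[int, set[str]] = {}
        for sp, mod in part.assignment.items():
            rec = meta.get(sp)
            if rec is not None and rec.side == "plant":
                module_plant_genera.setdefault(mod, set()).add(rec.genus)
        for genus, plant_genus in pairing.items():
            bat_modules: dict[int, int] = {}
            for sp, mod in part.assignment.items():
                rec = meta.get(sp)
                if rec is not None and rec.side == "animal" and rec.genus == genus:
                    bat_modules[mod] = bat_modules.get(mod, 0) + 1
            if not bat_modules:
                continue
            if len(bat_modules) > 1:
                counts[genus].split_events.append(
                    f"network {k}: {genus} split across modules {sorted(bat_modules)}"
                )
            majority = max(bat_modules, key=lambda s: (bat_modules[s], -s))
            if plant_genus in module_plant_genera.get(majority, set()):
                counts[genus].n_follow += 1
            else:
                counts[genus].n_not += 1
    return counts


def g_test_yates(n_follow: int, n_not: int, genus: str = "") -> GuildTestResult:
    """Goodness-of-fit G test against equal proportions, Yates-corrected.

    Each observed count is moved 0.5 toward the expected value (without
    crossing it) before evaluating ``G = 2 * sum O' ln(O'/E)``; the
    p-value comes from chi-square with 1 degree of freedom.
    """
    total = n_follow + n_not
    if total < 1:
        raise ValueError("need at least one counted module")
    expected = total / 2.0
    g = 0.0
    for obs in (n_follow, n_not):
        if obs > expected:
            adj = max(obs - 0.5, expected)
        elif obs < expected:
            adj = min(obs + 0.5, expected)
        else:
            adj = float(obs)
        if adj > 0:
            g += adj * math.log(adj / expected)
    g = max(2.0 * g, 0.0)
    p = float(_sstats.chi2.sf(g, df=1))
    return GuildTestResult(
        genus=genus,
        n_follow=n_follow,
        n_not=n_not,
        proportion=n_follow / total,
        g_statistic=g,
        p_value=p,
    )
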