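"""Independent brute-force oracles used to check the package's metrics.

These deliberately re-derive each quantity along a different path than
the implementation (sorting + positional definition for NODF, explicit
geodesic enumeration for betweenness, exhaustive contingency-table
enumeration for the entropy bounds and the Patefield distribution).
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def nodf_sorted_oracle(b: np.ndarray) -> float:
    """NODF via the positional definition on a matrix sorted by marginals.

    Sort rows and columns by decreasing marginal totals; a pair (upper,
    lower) contributes overlap/size(lower) only when the upper line has a
    strictly larger marginal total; mean over all pairs, in [0, 1].
    """
    b = np.asarray(b, dtype=int)
    rows = b[np.argsort(-b.sum(axis=1), kind="stable")]
    cols = rows[:, np.argsort(-rows.sum(axis=0), kind="stable")]

    def axis_sum(mat: np.ndarray) -> tuple[float, int]:
        n = mat.shape[0]
        marg = mat.sum(axis=1)
        total, pairs = 0.0, 0
        for up in range(n):
            for lo in range(up + 1, n):
                pairs += 1
                if marg[up] > marg[lo]:
                    shared = int(np.sum(mat[up] & mat[lo]))
                    total += shared / marg[lo]
        return total, pairs

    r_sum, r_pairs = axis_sum(cols)
    c_sum, c_pairs = axis_sum(cols.T)
    return (r_sum + c_sum) / (r_pairs + c_pairs)


def enumerate_binary_matrices(n_rows: int, n_cols: int):
    """All 0/1 matrices of the given shape with no empty row or column."""
    for bits in itertools.product((0, 1), repeat=n_rows * n_cols):
        b = np.array(bits, dtype=int).reshape(n_rows, n_cols)
        if b.sum(axis=1).all() and b.sum(axis=0).all():
            yield b


def betweenness_enumeration_oracle(adj: dict[str, set[str]]) -> dict[str, float]:
    """Betweenness by exhaustive enumeration of all simple shortest paths."""
    nodes = sorted(adj)
    n = len(nodes)

    def all_shortest_paths(src: str, dst: str) -> list[list[str]]:
        # BFS layering, then enumerate paths through the layers
        from collections import deque

        dist = {src: 0}
        queue = deque([src])
        while queue:
            v = queue.popleft()
            for u in adj[v]:
                if u not in dist:
                    dist[u] = dist[v] + 1
                    queue.append(u)
        if dst not in dist:
            return []
        paths: list[list[str]] = []

        def extend(path: list[str]) -> None:
            v = path[-1]
            if v == dst:
                paths.append(list(path))
                return
            for u in adj[v]:
                if dist.get(u) == dist[v] + 1 and dist.get(u, n + 1) <= dist[dst]:
                    path.append(u)
                    extend(path)
                    path.pop()

        extend([src])
        return paths

    score = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            paths = all_shortest_paths(s, t)
            if not paths:
                continue
            for path in paths:
                for interior in path[1:-1]:
                    score[interior] += 1.0 / len(paths)
    norm = (n - 1) * (n - 2) / 2
    return {v: score[v] / norm for v in nodes}


def enumerate_contingency_tables(row_totals, col_totals):
    """All non-negative integer tables with the given marginals."""
    rows = list(row_totals)
    cols = list(col_totals)

    def fill(row_idx: int, remaining_cols: list[int], acc: list[list[int]]):
        if row_idx == len(rows):
            if all(c == 0 for c in remaining_cols):
                yield [list(r) for r in acc]
            return
        target = rows[row_idx]

        def cells(j: int, left: int, row: list[int]):
            if j == len(cols) - 1:
                if left <= remaining_cols[j]:
                    yield row + [left]
                return
            for v in range(min(left, remaining_cols[j]) + 1):
                yield from cells(j + 1, left - v, row + [v])

        for row in cells(0, target, []):
            new_cols = [c - v for c, v in zip(remaining_cols, row)]
            yield from fill(row_idx + 1, new_cols, acc + [row])

    yield from fill(0, cols, [])


def table_entropy(table) -> float:
    flat = [v for row in table for v in row if v > 0]
    total = sum(flat)
    return -sum((v / total) * math.log(v / total) for v in flat)


def patefield_table_probability(table, row_totals, col_totals) -> float:
    """Multiple-hypergeometric probability of a table given its marginals."""
    n = sum(row_totals)
    log_p = (
        sum(math.lgamma(r + 1) for r in row_totals)
        + sum(math.lgamma(c + 1) for c in col_totals)
        - math.lgamma(n + 1)
        - sum(math.lgamma(v + 1) for row in table for v in row)
    )
    return math.exp(log_p)
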